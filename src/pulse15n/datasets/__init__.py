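"""Bundled reference tables.

Two small CSVs carry the published group means of a decadal heathland
¹⁵N pulse-labelling experiment (seven plots, paired labelled/reference
subplots, nine annual sampling occasions):

* ``published_delta_means.csv`` — mean ± SE of δ¹⁵N (‰) per compartment and
  year, separately for labelled and reference subplots;
* ``published_recovery_means.csv`` — mean ± SE of ¹⁵N enrichment (‰) and of
  tracer recovery (% of dose) per compartment and year.

These are group-level summaries (n = 7 plots), not raw field data; the
loaders return them as tidy DataFrames.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_published_deltas",
    "load_published_recovery",
    "published_means_as_measurements",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_published_deltas() -> pd.DataFrame:
    """Published δ¹⁵N group means (‰) per year × compartment × subplot role."""
    return _read("published_delta_means.csv")


def load_published_recovery() -> pd.DataFrame:
    """Published enrichment (‰) and recovery (% of dose) group means."""
    return _read("published_recovery_means.csv")


def published_means_as_measurements() -> pd.DataFrame:
    """Recast the δ group means as a one-"plot" measurement table.

    Useful for pushing the published means through the paired-subplot
    pipeline: with a single pseudo-plot holding the group means, the
    ``mean_of_deltas`` aggregation reproduces enrichment-of-means exactly.
    """
    deltas = load_published_deltas()
    rows = []
    for r in deltas.itertuples():
        for role, val in (("reference", r.delta_ref_mean), ("labelled", r.delta_lab_mean)):
            rows.append(
                {
                    "plot": "group_mean",
                    "role": role,
                    "year": int(r.year),
                    "compartment": r.compartment,
                    "delta15n_permil": float(val),
                    "n_content_fraction": float("nan"),
                }
            )
    return pd.DataFrame(rows)
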