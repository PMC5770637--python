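"""Per-plot paired enrichment and tracer-recovery tables.

The experimental unit is a plot holding a labelled and an unlabelled
(reference) subplot.  Every computation here is paired within plot, year and
compartment: enrichment compares the two δ values directly, recovery converts
them to atom fractions and applies the tracer mass balance against the
compartment's N pool, and the paired Student's t-test asks whether labelling
shifted δ at all.

Measurement tables are long-format pandas DataFrames with columns
``plot, role, year, compartment, delta15n_permil, n_content_fraction``
(role ∈ {labelled, reference}); results are returned as tidy frames with one
row per compartment × year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import isotopes
from .pools import NON_ANNUAL_COMPARTMENTS, TracerApplication

__all__ = [
    "MEASUREMENT_COLUMNS",
    "PairingError",
    "pair_measurements",
    "compute_enrichment_table",
    "compute_recovery_table",
    "annual_totals",
    "paired_delta_tests",
]

MEASUREMENT_COLUMNS = (
    "plot",
    "role",
    "year",
    "compartment",
    "delta15n_permil",
    "n_content_fraction",
)


class PairingError(ValueError):
    """A labelled record has no reference partner and fallback is disabled."""


def _check_measurements(data: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in data.columns and c != "n_content_fraction"]
    if missing:
        raise ValueError(f"measurement table lacks columns {missing}")
    bad_roles = set(data["role"].unique()) - {"labelled", "reference"}
    if bad_roles:
        raise ValueError(f"unknown subplot roles {sorted(bad_roles)}")
    dupes = data.duplicated(subset=["plot", "role", "year", "compartment"])
    if dupes.any():
        cells = data.loc[dupes, ["plot", "role", "year", "compartment"]]
        raise ValueError(f"duplicate measurement cells:\n{cells}")
    return data


def pair_measurements(data: pd.DataFrame, fallback: bool = True) -> pd.DataFrame:
    """Match labelled records with their same-plot reference partner.

    Returns one row per (plot, year, compartment) with ``delta_lab`` and
    ``delta_ref``.  A labelled record without a same-plot partner takes the
    compartment × year mean of reference δ when ``fallback`` is enabled,
    otherwise a :class:`PairingError` names the offending cells.
    """
    _check_measurements(data)
    lab = data[data["role"] == "labelled"]
    ref = data[data["role"] == "reference"]
    merged = lab.merge(
        ref[["plot", "year", "compartment", "delta15n_permil"]],
        on=["plot", "year", "compartment"],
        how="left",
        suffixes=("", "_ref"),
    ).rename(columns={"delta15n_permil": "delta_lab", "delta15n_permil_ref": "delta_ref"})

    unmatched = merged["delta_ref"].isna()
    if unmatched.any():
        if not fallback:
            cells = merged.loc[unmatched, ["plot", "year", "compartment"]].to_dict("records")
            raise PairingError(f"labelled records without a reference partner: {cells}")
        ref_means = ref.groupby(["year", "compartment"])["delta15n_permil"].mean()
        keys = list(zip(merged.loc[unmatched, "year"], merged.loc[unmatched, "compartment"]))
        fills = []
        for key in keys:
            if key not in ref_means.index:
                raise PairingError(f"no reference measurements at all for cell {key}")
            fills.append(ref_means[key])
        merged.loc[unmatched, "delta_ref"] = fills
    cols = ["plot", "year", "compartment", "delta_lab", "delta_ref"]
    if "n_content_fraction" in merged.columns:
        cols.append("n_content_fraction")
    return merged[cols]


def _mean_se(values: np.ndarray) -> tuple[float, float, int]:
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    n = len(values)
    if n == 0:
        return np.nan, np.nan, 0
    mean = float(np.mean(values))
    se = float(np.std(values, ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
    return mean, se, n


def compute_enrichment_table(
    data: pd.DataFrame,
    mode: str = "per_plot_mean",
    fallback: bool = True,
) -> pd.DataFrame:
    """¹⁵N enrichment (‰) per compartment × year, mean ± SE over plots.

    mode="per_plot_mean" computes the enrichment within each plot pair and
    averages over plots (SE = SD/√n); mode="mean_of_deltas" averages the
    labelled and reference δ values first and applies the enrichment formula
    to the two group means (then the SE column reflects the spread of
    per-plot enrichments around that value and n is the pair count).
    """
    if mode not in ("per_plot_mean", "mean_of_deltas"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    paired = pair_measurements(data, fallback=fallback)
    rows = []
    for (year, comp), grp in paired.groupby(["year", "compartment"], sort=True):
        per_plot = isotopes.enrichment(grp["delta_lab"].to_numpy(), grp["delta_ref"].to_numpy())
        mean, se, n = _mean_se(per_plot)
        if mode == "mean_of_deltas":
            mean = isotopes.enrichment(
                float(np.mean(grp["delta_lab"])), float(np.mean(grp["delta_ref"]))
            )
        rows.append(
            {
                "compartment": comp,
                "year": year,
                "n_plots": n,
                "enrichment_mean": mean,
                "enrichment_se": se,
            }
        )
    return pd.DataFrame(rows).sort_values(["year", "compartment"]).reset_index(drop=True)


def compute_recovery_table(
    data: pd.DataFrame,
    pools: pd.DataFrame,
    tracer: TracerApplication,
    mode: str = "per_plot_mean",
    fallback: bool = True,
    r_standard: float = isotopes.R_STANDARD_AIR,
) -> pd.DataFrame:
    """Full recovery table: enrichment plus tracer mass and % of dose.

    For every plot pair the labelled and reference δ values are converted to
    atom-% ¹⁵N, pushed through the tracer mass balance against the
    compartment × year N pool, and expressed as percent of the applied excess
    ¹⁵N; plot values are then averaged (mean ± SE).
    """
    paired = pair_measurements(data, fallback=fallback)
    pool_map = {
        (str(r.compartment), int(r.year)): float(r.m_pool_gN_m2) for r in pools.itertuples()
    }
    missing = sorted(
        {(c, int(y)) for c, y in zip(paired["compartment"], paired["year"])} - set(pool_map)
    )
    if missing:
        raise ValueError(f"no pool mass for measured cells: {missing}")

    applied = tracer.applied_excess_g_m2
    enr_table = compute_enrichment_table(data, mode=mode, fallback=fallback)

    rows = []
    for (year, comp), grp in paired.groupby(["year", "compartment"], sort=True):
        ap_lab = isotopes.delta_to_atom_percent(grp["delta_lab"].to_numpy(), r_standard)
        ap_ref = isotopes.delta_to_atom_percent(grp["delta_ref"].to_numpy(), r_standard)
        m_pool = pool_map[(comp, int(year))]
        below_floor = ap_lab < ap_ref
        if below_floor.any():
            warnings.warn(
                f"{int(below_floor.sum())} labelled sample(s) below the reference "
                f"atom fraction in {comp} {year}; raw (negative) recovery reported",
                stacklevel=2,
            )
        rec = isotopes.recovery_mass(m_pool, ap_lab, ap_ref, tracer.label_atom_percent)
        pct = isotopes.relative_recovery(rec, applied)
        rec_mean, _, _ = _mean_se(rec)
        pct_mean, pct_se, n = _mean_se(pct)
        rows.append(
            {
                "compartment": comp,
                "year": year,
                "n_plots": n,
                "recovery_gN_m2": rec_mean,
                "recovery_pct_mean": pct_mean,
                "recovery_pct_se": pct_se,
            }
        )
    rec_table = pd.DataFrame(rows)
    out = enr_table.merge(rec_table, on=["compartment", "year", "n_plots"], how="outer")
    return out.sort_values(["year", "compartment"]).reset_index(drop=True)


def annual_totals(
    table: pd.DataFrame,
    include_non_annual: bool = False,
    value_column: str = "recovery_pct_mean",
) -> pd.Series:
    """Sum of compartment recovery means per year (% of tracer applied).

    Compartments sampled only in some years simply drop out of the sum for
    the years they are absent; with ``include_non_annual`` the occasionally
    sampled woody-biomass and root compartments are included where present,
    otherwise they are excluded everywhere.
    """
    if table.empty:
        warnings.warn("empty recovery table; annual totals are empty", stacklevel=2)
        return pd.Series(dtype=float, name="total_recovery_pct")
    tab = table
    if not include_non_annual:
        tab = tab[~tab["compartment"].isin(NON_ANNUAL_COMPARTMENTS)]
    totals = tab.groupby("year")[value_column].sum(min_count=1)
    totals.name = "total_recovery_pct"
    return totals


def paired_delta_tests(
    data: pd.DataFrame, alpha: float = 0.05, fallback: bool = False
) -> pd.DataFrame:
    """Two-sided paired Student's t-tests of labelled vs reference δ¹⁵N.

    One test per compartment × year over plot pairs.  Cells with fewer than
    two complete pairs, or with zero variance of the differences, are flagged
    ``evaluable = False`` with NaN statistics rather than raising.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    paired = pair_measurements(data, fallback=fallback)
    rows = []
    for (year, comp), grp in paired.groupby(["year", "compartment"], sort=True):
        diffs = grp["delta_lab"].to_numpy() - grp["delta_ref"].to_numpy()
        diffs = diffs[~np.isnan(diffs)]
        n = len(diffs)
        if n < 2 or np.allclose(np.std(diffs, ddof=0), 0.0):
            t_stat, p_val, evaluable = np.nan, np.nan, False
        else:
            t_stat, p_val = stats.ttest_rel(
                grp["delta_lab"].to_numpy(), grp["delta_ref"].to_numpy(), nan_policy="omit"
            )
            evaluable = True
        rows.append(
            {
                "compartment": comp,
                "year": year,
                "n_pairs": n,
                "t_statistic": t_stat,
                "p_value": p_val,
                "significant": bool(evaluable and p_val < alpha),
                "evaluable": evaluable,
            }
        )
    return pd.DataFrame(rows).sort_values(["year", "compartment"]).reset_index(drop=True)
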