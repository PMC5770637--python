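"""Synthetic tracer-fate and enrichment data with known ground truth.

Two generators live here.

``simulate_tracer_fate`` pushes a single ¹⁵N pulse through a compartment
chain (moss carpet -> organic and mineral soil horizons -> drainage, with a
vascular-plant uptake/litter loop and an unattributed gaseous-loss pathway)
in annual discrete time.  A configurable share of the pulse is intercepted
by the moss at application, the rest is split over the other compartments;
each following year every compartment exports fixed first-order fractions of
its current tracer stock along the topology.  Per-plot lognormal jitter on
the transfer rates creates realistic between-plot variation, and Gaussian
noise on the δ scale emulates IRMS measurement error.  Mass is conserved
exactly at every step, and the paired-subplot measurement generator inverts
the tracer mass balance, so the full pipeline (simulate -> measure ->
recover) returns the truth exactly when noise is switched off.

``simulate_enrichment_glmm`` draws enrichment data from the gamma log-link
mixed model itself (normal plot intercepts, AR-1 Gaussian-copula dependence
within each plot x compartment series, gamma marginals), for parameter
recovery and model-selection studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from . import isotopes
from .pools import COMPARTMENTS, TracerApplication
from ._gamma_glmm import sd_resid_to_shape

__all__ = [
    "SimulationConfig",
    "SimulationOutput",
    "simulate_tracer_fate",
    "tracer_to_measurements",
    "simulate_enrichment_glmm",
    "trend_design",
]

#: Internal nodes of the simulator in addition to the measured compartments.
SINK_NODES = ("loss", "leachate")


def _default_natural_delta() -> dict[str, float]:
    # Natural-abundance baselines: depleted in plant/moss material, increasing
    # with soil depth (published reference-subplot means are of this order).
    return {
        "current_year_shoots": -6.3,
        "shoots_1_2yr": -7.3,
        "calluna_old": -7.2,
        "calluna_roots": -5.4,
        "litter_current": -6.8,
        "moss": -6.2,
        "O_horizon": -4.3,
        "A_horizon": 4.5,
        "B_horizon": 7.0,
    }


def _default_pool_masses() -> dict[str, float]:
    # Plausible standing N pools (g N m-2) for a dwarf-shrub heath on podzol;
    # synthetic values, not taken from any published pool table.
    return {
        "current_year_shoots": 1.2,
        "shoots_1_2yr": 1.6,
        "calluna_old": 5.0,
        "calluna_roots": 6.0,
        "litter_current": 1.6,
        "moss": 8.6,
        "O_horizon": 70.0,
        "A_horizon": 170.0,
        "B_horizon": 160.0,
    }


def _default_n_content() -> dict[str, float]:
    return {
        "current_year_shoots": 0.012,
        "shoots_1_2yr": 0.010,
        "calluna_old": 0.006,
        "calluna_roots": 0.008,
        "litter_current": 0.009,
        "moss": 0.010,
        "O_horizon": 0.012,
        "A_horizon": 0.002,
        "B_horizon": 0.001,
    }


def _default_transfer_rates() -> dict[tuple[str, str], float]:
    # Annual first-order export fractions.  Moss loses about a third of its
    # stock per year, split roughly half to the O-horizon and half to the
    # unattributed (gaseous) loss; a slow O -> A -> B -> leachate chain and a
    # small plant uptake/litter loop complete the topology.
    return {
        ("moss", "O_horizon"): 0.155,
        ("moss", "loss"): 0.165,
        ("O_horizon", "A_horizon"): 0.025,
        ("O_horizon", "current_year_shoots"): 0.010,
        ("O_horizon", "calluna_roots"): 0.005,
        ("A_horizon", "B_horizon"): 0.020,
        ("B_horizon", "leachate"): 0.002,
        ("current_year_shoots", "shoots_1_2yr"): 0.50,
        ("current_year_shoots", "litter_current"): 0.20,
        ("shoots_1_2yr", "calluna_old"): 0.30,
        ("shoots_1_2yr", "litter_current"): 0.20,
        ("calluna_old", "litter_current"): 0.05,
        ("calluna_roots", "O_horizon"): 0.10,
        ("litter_current", "O_horizon"): 0.70,
    }


def _default_initial_split() -> dict[str, float]:
    # Fate of the non-retained share of the pulse at application: throughfall
    # into the soil profile, interception by shoots and litter, and a first
    # volatilisation loss.  Fractions of the whole dose; together with the
    # moss retention they sum to 1.
    return {
        "O_horizon": 0.180,
        "A_horizon": 0.050,
        "current_year_shoots": 0.017,
        "shoots_1_2yr": 0.009,
        "litter_current": 0.006,
        "B_horizon": 0.004,
        "loss": 0.074,
    }


@dataclass
class SimulationConfig:
    """Full description of one synthetic pulse-labelling experiment."""

    n_plots: int = 7
    years: tuple[int, ...] = tuple(range(2007, 2016))
    moss_retention: float = 0.66
    initial_split: dict[str, float] = field(default_factory=_default_initial_split)
    transfer_rates: dict[tuple[str, str], float] = field(default_factory=_default_transfer_rates)
    natural_delta: dict[str, float] = field(default_factory=_default_natural_delta)
    pool_masses: dict[str, float] = field(default_factory=_default_pool_masses)
    n_content: dict[str, float] = field(default_factory=_default_n_content)
    tracer: TracerApplication = field(default_factory=TracerApplication)
    rate_jitter_sd: float = 0.25     # lognormal SD of per-plot rate multipliers
    delta_noise_sd: float = 1.0      # Gaussian IRMS noise on the δ scale (‰)
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_plots < 1:
            raise ValueError("need at least one plot")
        if not 0.0 <= self.moss_retention <= 1.0:
            raise ValueError("moss_retention must lie in [0, 1]")
        split_total = sum(self.initial_split.values())
        if self.moss_retention + split_total > 1.0 + 1e-9:
            raise ValueError(
                f"initial split ({split_total:.3f}) plus moss retention "
                f"({self.moss_retention:.3f}) exceeds the dose"
            )
        outgoing: dict[str, float] = {}
        for (src, dst), rate in self.transfer_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"transfer rate {src}->{dst} outside [0, 1]: {rate}")
            outgoing[src] = outgoing.get(src, 0.0) + rate
        bad = {k: v for k, v in outgoing.items() if v > 1.0 + 1e-9}
        if bad:
            raise ValueError(f"outgoing rate fractions exceed 1 for nodes: {bad}")
        if self.delta_noise_sd < 0 or self.rate_jitter_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        return self


@dataclass
class SimulationOutput:
    """Ground truth plus the synthetic measurement tables derived from it."""

    config: SimulationConfig
    applied_g15n_m2: float
    truth: pd.DataFrame         # plot, year, compartment (incl sinks), tracer_g15N_m2
    true_flows: pd.DataFrame    # plot, year_from, year_to, from, to, flow_g15N_m2
    pools: pd.DataFrame         # compartment, year, m_pool_gN_m2
    measurements: pd.DataFrame  # long-format paired-subplot measurement table


def simulate_tracer_fate(config: SimulationConfig | None = None, seed: int | None = None) -> SimulationOutput:
    """Run the annual discrete-time tracer-fate simulation.

    Deterministic for a fixed config and seed; per plot and year the tracer
    stocks over all nodes (compartments plus loss and leachate sinks) sum to
    the applied dose exactly.
    """
    config = (config or SimulationConfig()).validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    applied = config.tracer.applied_excess_g_m2
    nodes = [c for c in COMPARTMENTS if c != "leachate"] + list(SINK_NODES)

    truth_rows, flow_rows = [], []
    for plot in range(1, config.n_plots + 1):
        # plot-specific rates: lognormal jitter, rescaled if a node would
        # export more than its stock
        rates: dict[tuple[str, str], float] = {}
        for edge, rate in config.transfer_rates.items():
            jitter = rng.lognormal(0.0, config.rate_jitter_sd) if config.rate_jitter_sd else 1.0
            rates[edge] = rate * jitter
        outgoing: dict[str, float] = {}
        for (src, _), r in rates.items():
            outgoing[src] = outgoing.get(src, 0.0) + r
        for src, total in outgoing.items():
            if total > 1.0:
                for edge in list(rates):
                    if edge[0] == src:
                        rates[edge] /= total

        state = {n: 0.0 for n in nodes}
        state["moss"] = config.moss_retention * applied
        for comp, frac in config.initial_split.items():
            state[comp] += frac * applied
        state["loss"] += (1.0 - config.moss_retention - sum(config.initial_split.values())) * applied

        years = list(config.years)
        for yi, year in enumerate(years):
            for comp in nodes:
                truth_rows.append(
                    {"plot": plot, "year": year, "compartment": comp,
                     "tracer_g15N_m2": state[comp]}
                )
            if yi == len(years) - 1:
                break
            exports: dict[tuple[str, str], float] = {
                edge: state[edge[0]] * r for edge, r in rates.items()
            }
            for (src, dst), amount in exports.items():
                state[src] -= amount
                state[dst] += amount
                flow_rows.append(
                    {"plot": plot, "year_from": year, "year_to": years[yi + 1],
                     "from": src, "to": dst, "flow_g15N_m2": amount}
                )

    truth = pd.DataFrame(truth_rows)
    flows = pd.DataFrame(flow_rows)
    pools = pd.DataFrame(
        [
            {"compartment": comp, "year": year, "m_pool_gN_m2": m}
            for comp, m in config.pool_masses.items()
            for year in config.years
        ]
    )
    measurements = tracer_to_measurements(truth, pools, config, rng=rng)
    return SimulationOutput(
        config=config,
        applied_g15n_m2=applied,
        truth=truth,
        true_flows=flows,
        pools=pools,
        measurements=measurements,
    )


def tracer_to_measurements(
    truth: pd.DataFrame,
    pools: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """Invert the tracer mass balance into paired-subplot δ¹⁵N measurements.

    The labelled subplot's atom fraction is the compartment's natural
    abundance plus ``tracer_mass / m_pool × (at%_tracer − at%_ref)``; both
    subplots then receive Gaussian noise on the δ scale.  With zero noise the
    recovery pipeline returns the simulated tracer masses exactly.
    """
    rng = rng or np.random.default_rng(config.seed)
    sd = config.delta_noise_sd if noise_sd is None else noise_sd
    pool_map = {
        (str(r.compartment), int(r.year)): float(r.m_pool_gN_m2) for r in pools.itertuples()
    }
    ap_tracer = config.tracer.label_atom_percent

    rows = []
    for r in truth.itertuples():
        comp = str(r.compartment)
        if comp in SINK_NODES:
            continue
        key = (comp, int(r.year))
        if key not in pool_map:
            continue
        m_pool = pool_map[key]
        if m_pool <= 0:
            raise ValueError(f"non-positive pool mass for {key}")
        if r.tracer_g15N_m2 > m_pool:
            raise ValueError(
                f"tracer mass {r.tracer_g15N_m2:.3g} exceeds the N pool {m_pool:.3g} "
                f"in {comp} {r.year} (non-physical)"
            )
        d_nat = config.natural_delta[comp]
        ap_ref = isotopes.delta_to_atom_percent(d_nat)
        ap_lab = ap_ref + r.tracer_g15N_m2 / m_pool * (ap_tracer - ap_ref)
        if ap_lab >= 100.0:
            raise ValueError(f"atom fraction beyond 100% in {comp} {r.year}")
        d_lab = isotopes.atom_percent_to_delta(ap_lab)
        noise_lab = rng.normal(0.0, sd) if sd else 0.0
        noise_ref = rng.normal(0.0, sd) if sd else 0.0
        n_cont = config.n_content.get(comp, np.nan)
        rows.append(
            {"plot": r.plot, "role": "labelled", "year": r.year, "compartment": comp,
             "delta15n_permil": d_lab + noise_lab, "n_content_fraction": n_cont}
        )
        rows.append(
            {"plot": r.plot, "role": "reference", "year": r.year, "compartment": comp,
             "delta15n_permil": d_nat + noise_ref, "n_content_fraction": n_cont}
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# enrichment-model simulation


def trend_design(
    n_plots: int = 7,
    times=tuple(range(9)),
    compartments=("above_ground_biomass", "moss", "O_horizon", "A_horizon", "B_horizon"),
) -> pd.DataFrame:
    """The balanced plot × time × compartment grid of the field design."""
    rows = [
        {"plot": p, "time": float(t), "compartment": c}
        for p in range(1, n_plots + 1)
        for c in compartments
        for t in times
    ]
    return pd.DataFrame(rows)


def simulate_enrichment_glmm(
    design: pd.DataFrame,
    intercept: float,
    contrasts: dict[str, float] | None = None,
    smooth=None,
    sd_plot: float = 0.0,
    sd_resid: float = 0.0,
    rho: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw enrichment data from the gamma log-link mixed model.

    ``smooth`` may be None (flat time effect), a callable f(t), or a mapping
    compartment -> callable for compartment-specific trends.  The linear
    predictor is intercept + contrast + f(t) + b_plot; responses are gamma
    with that conditional mean and shape matching ``sd_resid`` on the link
    scale, with AR-1 Gaussian-copula dependence (parameter ``rho``) along
    each plot × compartment time series.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("|rho| must be below 1")
    if sd_plot < 0 or sd_resid < 0:
        raise ValueError("variance components must be non-negative")
    rng = rng or np.random.default_rng(seed)
    contrasts = contrasts or {}

    df = design.copy().reset_index(drop=True)
    eta = np.full(len(df), float(intercept))
    eta += df["compartment"].map(lambda c: contrasts.get(c, 0.0)).to_numpy(dtype=float)
    if smooth is not None:
        if callable(smooth):
            eta += np.asarray([smooth(t) for t in df["time"]], dtype=float)
        else:
            eta += np.asarray(
                [smooth[c](t) if c in smooth else 0.0
                 for c, t in zip(df["compartment"], df["time"])],
                dtype=float,
            )

    plots = df["plot"].unique()
    b = dict(zip(plots, rng.normal(0.0, sd_plot, size=len(plots)) if sd_plot else np.zeros(len(plots))))
    eta += df["plot"].map(b).to_numpy(dtype=float)
    mu = np.exp(eta)

    if sd_resid == 0.0:
        df["enrichment"] = mu
        return df

    shape = sd_resid_to_shape(sd_resid)
    y = np.empty(len(df))
    for (_, _), idx in df.groupby(["plot", "compartment"], sort=False).groups.items():
        idx = df.loc[idx].sort_values("time").index.to_numpy()
        m = len(idx)
        z = np.empty(m)
        z[0] = rng.normal()
        for t in range(1, m):
            z[t] = rho * z[t - 1] + np.sqrt(1.0 - rho**2) * rng.normal()
        u = np.clip(special.ndtr(z), 1e-12, 1.0 - 1e-12)
        y[idx] = stats.gamma.ppf(u, a=shape, scale=mu[idx] / shape)
    df["enrichment"] = y
    return df
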