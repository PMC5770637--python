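"""Exact isotope arithmetic for ¹⁵N/¹⁴N tracer work.

All measurements enter the pipeline on the δ scale (per-mil deviation of the
¹⁵N/¹⁴N ratio from atmospheric N₂).  Tracer recovery, however, is a statement
about atom fractions, so this module provides the conversions between the
three equivalent representations

    δ¹⁵N [‰]   <->   R = ¹⁵N/¹⁴N   <->   atom-% ¹⁵N = 100·R/(1+R)

together with the two quantities the tracer mass balance is built from:

* ``enrichment`` — per-mil excess of a labelled sample over its unlabelled
  reference, ``1000·(δ_s − δ_r)/(δ_r + 1000)``;
* ``recovery_mass`` — mass of tracer in a pool,
  ``m_pool·(at%_pool − at%_ref)/(at%_tracer − at%_ref)``.

Every function accepts scalars or numpy arrays and carries full floating
precision; rounding happens only in report writers.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "R_STANDARD_AIR",
    "delta_to_ratio",
    "ratio_to_delta",
    "ratio_to_atom_percent",
    "atom_percent_to_ratio",
    "delta_to_atom_percent",
    "atom_percent_to_delta",
    "enrichment",
    "recovery_mass",
    "relative_recovery",
]

#: Conventional ¹⁵N/¹⁴N ratio of atmospheric N₂ (the δ-scale standard).
R_STANDARD_AIR = 0.0036765


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def delta_to_ratio(delta, r_standard: float = R_STANDARD_AIR):
    """Convert δ¹⁵N (‰ vs air N₂) to the isotope ratio ¹⁵N/¹⁴N.

    Parameters
    ----------
    delta : float or array-like
        δ¹⁵N in per mil.  Must exceed −1000 ‰ (the zero-¹⁵N limit).
    r_standard : float
        ¹⁵N/¹⁴N ratio of the standard, default air N₂.
    """
    if r_standard <= 0:
        raise ValueError(f"r_standard must be positive, got {r_standard}")
    d = _as_array(delta)
    if np.any(d <= -1000.0):
        raise ValueError("delta values must exceed -1000 permil (ratio must stay positive)")
    out = r_standard * (d / 1000.0 + 1.0)
    return out if out.ndim else float(out)


def ratio_to_delta(ratio, r_standard: float = R_STANDARD_AIR):
    """Inverse of :func:`delta_to_ratio`."""
    if r_standard <= 0:
        raise ValueError(f"r_standard must be positive, got {r_standard}")
    r = _as_array(ratio)
    if np.any(r <= 0):
        raise ValueError("isotope ratio must be strictly positive")
    out = (r / r_standard - 1.0) * 1000.0
    return out if out.ndim else float(out)


def ratio_to_atom_percent(ratio):
    """Convert an isotope ratio R = ¹⁵N/¹⁴N to atom-% ¹⁵N = 100·R/(1+R)."""
    r = _as_array(ratio)
    if np.any(r <= 0):
        raise ValueError("isotope ratio must be strictly positive")
    out = 100.0 * r / (1.0 + r)
    return out if out.ndim else float(out)


def atom_percent_to_ratio(atom_percent):
    """Inverse of :func:`ratio_to_atom_percent`; input in (0, 100)."""
    a = _as_array(atom_percent)
    if np.any((a <= 0) | (a >= 100)):
        raise ValueError("atom percent must lie strictly between 0 and 100")
    f = a / 100.0
    out = f / (1.0 - f)
    return out if out.ndim else float(out)


def delta_to_atom_percent(delta, r_standard: float = R_STANDARD_AIR):
    """δ¹⁵N (‰) to atom-% ¹⁵N in one step."""
    return ratio_to_atom_percent(delta_to_ratio(delta, r_standard))


def atom_percent_to_delta(atom_percent, r_standard: float = R_STANDARD_AIR):
    """atom-% ¹⁵N to δ¹⁵N (‰) in one step."""
    return ratio_to_delta(atom_percent_to_ratio(atom_percent), r_standard)


def enrichment(delta_sample, delta_ref):
    """Per-mil ¹⁵N enrichment of a labelled sample over its reference.

    ``1000 · (δ_sample − δ_ref) / (δ_ref + 1000)`` — zero iff the two δ values
    coincide, with the sign of ``δ_sample − δ_ref``.  Independent of the
    standard ratio (it cancels).
    """
    ds = _as_array(delta_sample)
    dr = _as_array(delta_ref)
    if np.any(dr <= -1000.0):
        raise ValueError("reference delta must exceed -1000 permil")
    out = 1000.0 * (ds - dr) / (dr + 1000.0)
    return out if out.ndim else float(out)


def recovery_mass(m_pool, ap_pool, ap_ref, ap_tracer):
    """Tracer mass recovered in a pool, in applied-tracer-N equivalents.

    ``m_pool · (at%_pool − at%_ref) / (at%_tracer − at%_ref)`` with
    ``m_pool`` the pool's N mass in g N m⁻².  Linear in ``m_pool``, zero when
    the pool sits at the reference abundance.
    """
    m = _as_array(m_pool)
    ap = _as_array(ap_pool)
    ar = _as_array(ap_ref)
    at = _as_array(ap_tracer)
    if np.any(m < 0):
        raise ValueError("pool N mass must be non-negative")
    if np.any(at <= ar):
        raise ValueError("tracer atom percent must exceed the reference atom percent")
    out = m * (ap - ar) / (at - ar)
    return out if out.ndim else float(out)


def relative_recovery(recovered, applied):
    """Recovered tracer as percent of the amount applied (additive over pools)."""
    rec = _as_array(recovered)
    app = _as_array(applied)
    if np.any(app <= 0):
        raise ValueError("applied tracer mass must be positive")
    out = 100.0 * rec / app
    return out if out.ndim else float(out)
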