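"""Activity unit conversion and pairwise activity differences.

Input tables report activity as ``modl_ga``, the log10 of AC50 in micromolar.
All downstream thresholding happens on the pAC50 scale (-log10 molar), where a
2 log-unit difference equals a 100-fold potency change:

    AC50(M) = 10**modl_ga * 1e-6
    pAC50   = -log10(AC50(M)) = 6 - modl_ga
"""

from __future__ import annotations

import math


def modl_ga_to_pac50(modl_ga: float) -> float:
    """Convert log10(AC50 in uM) to pAC50 = 6 - modl_ga."""
    if not math.isfinite(modl_ga):
        raise ValueError(f"modl_ga must be finite, got {modl_ga!r}")
    return 6.0 - modl_ga


def pac50_to_modl_ga(pac50: float) -> float:
    """Inverse of :func:`modl_ga_to_pac50` (the map is an involution)."""
    if not math.isfinite(pac50):
        raise ValueError(f"pac50 must be finite, got {pac50!r}")
    return 6.0 - pac50


def ac50_molar(modl_ga: float) -> float:
    """AC50 in molar units: 10^modl_ga x 10^-6."""
    if not math.isfinite(modl_ga):
        raise ValueError(f"modl_ga must be finite, got {modl_ga!r}")
    return 10.0 ** modl_ga * 1e-6


def activity_difference(pac50_i: float, pac50_j: float) -> float:
    """Absolute pAC50 difference |pAC50_i - pAC50_j| (symmetric, >= 0)."""
    if not (math.isfinite(pac50_i) and math.isfinite(pac50_j)):
        raise ValueError(f"pAC50 values must be finite, got {pac50_i!r}, {pac50_j!r}")
    return abs(pac50_i - pac50_j)
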