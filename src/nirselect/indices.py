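"""Arithmetic of the lipid-oxidation indices.

PV (peroxide value, meq O2/kg) tracks primary oxidation; AnV (p-anisidine
value) tracks secondary aldehydes; TOTOX = 2*PV + AnV combines them. K232
and K270 are specific UV extinction coefficients (Beer-Lambert,
K = A / (c*l)) for conjugated dienes/trienes, and dK measures the deviation
of K270 from the straight line through its neighboring extinctions,
flagging advanced degradation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .spectra import MARKER_NAMES

__all__ = ["totox", "specific_extinction", "delta_k", "marker_correlations"]


def totox(pv, anv):
    """Total oxidation index: ``2*pv + anv`` (elementwise on arrays)."""
    pv = np.asarray(pv, dtype=float)
    anv = np.asarray(anv, dtype=float)
    if np.any(pv < 0) or np.any(anv < 0):
        raise ValueError("pv and anv must be non-negative")
    out = 2.0 * pv + anv
    return float(out) if out.ndim == 0 else out


def specific_extinction(absorbance, concentration_g_per_100ml, path_cm):
    """Specific extinction ``K = A / (c*l)`` (Beer-Lambert)."""
    A = np.asarray(absorbance, dtype=float)
    c = float(concentration_g_per_100ml)
    l = float(path_cm)
    if c <= 0 or l <= 0:
        raise ValueError("concentration and path length must be positive")
    if np.any(A < 0):
        raise ValueError("absorbance must be non-negative")
    out = A / (c * l)
    return float(out) if out.ndim == 0 else out


def delta_k(k266, k270, k274):
    """dK = K270 minus the linear baseline through K266 and K274.

    Zero for any collinear triple; invariant under adding a straight line in
    wavelength to the three extinctions.
    """
    k266 = np.asarray(k266, dtype=float)
    k270 = np.asarray(k270, dtype=float)
    k274 = np.asarray(k274, dtype=float)
    if not (np.all(np.isfinite(k266)) and np.all(np.isfinite(k270))
            and np.all(np.isfinite(k274))):
        raise ValueError("extinction inputs must be finite")
    out = k270 - (k266 + k274) / 2.0
    return float(out) if out.ndim == 0 else out


def marker_correlations(markers: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix over the seven oxidation markers.

    Requires at least 3 samples. Entries involving a constant marker are
    returned as NaN (flagged) rather than raising.
    """
    cols = [c for c in MARKER_NAMES if c in markers.columns]
    missing = set(MARKER_NAMES) - set(cols)
    if missing:
        raise ValueError(f"marker table is missing column(s): {sorted(missing)}")
    sub = markers[list(MARKER_NAMES)].astype(float)
    if len(sub) < 3:
        raise ValueError("need at least 3 samples for marker correlations")
    if sub.isna().any().any():
        raise ValueError("marker table contains missing values")
    corr = sub.corr(method="pearson")  # constant columns -> NaN row/col
    np.fill_diagonal(corr.values, 1.0)
    return corr
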