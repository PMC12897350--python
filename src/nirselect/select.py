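"""SELECT: stepwise decorrelation variable selection.

At each step the channel whose (partial) Pearson correlation with the
current response residual is largest in magnitude is selected; the remaining
channels and the response are then orthogonalized (Gram-Schmidt deflation)
against the selected channel, so later steps see only information not
already carried by earlier picks. Redundant, collinear channels therefore
drop out of contention after their first representative is chosen, which is
the property that makes the selected subset compact and interpretable on
heavily overlapping NIR bands.

The recorded ``weight`` of a step is the absolute partial correlation at the
moment of selection; it lies in [0, 1] and need not decrease monotonically
(a channel can become highly informative only after earlier channels have
been projected out).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import WavelengthGrid, STUDY_GRID

__all__ = ["SelectionStep", "SelectionTrace", "run_select"]

# Deflated columns whose remaining variance falls below this fraction of
# their original variance are treated as exhausted (pure redundancy).
_EXHAUSTED_REL_VAR = 1e-12


@dataclass(frozen=True)
class SelectionStep:
    order: int            # 1-based step number
    predictor_index: int  # 1-based channel index
    wavelength_nm: float
    weight: float         # |partial correlation| at selection, in [0, 1]


@dataclass
class SelectionTrace:
    """Ordered record of SELECT steps."""

    steps: list

    def __post_init__(self) -> None:
        idx = [s.predictor_index for s in self.steps]
        if len(set(idx)) != len(idx):
            raise ValueError("predictor indices in a trace must be unique")
        for s in self.steps:
            if not (0.0 <= s.weight <= 1.0 + 1e-12):
                raise ValueError(f"step {s.order}: weight {s.weight} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.steps)

    def __iter__(self):
        return iter(self.steps)

    @property
    def indices(self) -> list[int]:
        """Selected 1-based channel indices in selection order."""
        return [s.predictor_index for s in self.steps]

    @property
    def wavelengths(self) -> list[float]:
        return [s.wavelength_nm for s in self.steps]

    @property
    def weights(self) -> list[float]:
        return [s.weight for s in self.steps]

    def head(self, k: int) -> "SelectionTrace":
        """The first ``k`` steps as a new trace."""
        return SelectionTrace(self.steps[:k])


def _safe_corr(X: np.ndarray, y: np.ndarray, active: np.ndarray) -> np.ndarray:
    """Pearson correlation of each active column of centered X with centered y.

    Columns flagged inactive, or with negligible remaining variance, get 0.
    """
    r = np.zeros(X.shape[1])
    ynorm = np.linalg.norm(y)
    if ynorm <= 0:
        return r
    norms = np.linalg.norm(X, axis=0)
    ok = active & (norms > 0)
    r[ok] = (X[:, ok].T @ y) / (norms[ok] * ynorm)
    return r


def run_select(
    Xs: np.ndarray,
    y: np.ndarray,
    *,
    k_max: int = 30,
    r_min: float = 0.05,
    tol_var: float = 1e-6,
    grid: WavelengthGrid = STUDY_GRID,
    excluded: np.ndarray | None = None,
) -> SelectionTrace:
    """Run SELECT on an autoscaled predictor matrix.

    Parameters
    ----------
    Xs : (n, p) array
        Autoscaled predictor matrix (each column mean 0; scale is irrelevant
        to the selection order, which depends only on correlations).
    y : (n,) array
        Response; centered internally.
    k_max : int
        Maximum number of steps (default 30, bracketing the 16-30 wavelength
        models typical of NIR oxidation calibrations).
    r_min : float
        Stop when the best remaining |partial correlation| falls below this.
    tol_var : float
        Stop when the deflated response variance falls below
        ``tol_var * var(y)``.
    grid : WavelengthGrid
        Maps column positions to reported 1-based indices and wavelengths.
    excluded : boolean mask, optional
        Channels to skip (e.g. flagged zero-variance channels).

    Returns
    -------
    SelectionTrace
    """
    X = np.array(Xs, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError(f"y has length {y.size}, X has {n} rows")
    if n <= 2:
        raise ValueError("SELECT needs more than 2 rows")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in predictors or response")
    if p != grid.n_channels:
        raise ValueError(
            f"X has {p} columns but the grid defines {grid.n_channels} channels"
        )

    active = np.ones(p, dtype=bool)
    if excluded is not None:
        active &= ~np.asarray(excluded, dtype=bool)
    if not active.any():
        raise ValueError("all channels are excluded")

    # working (deflated) copies; columns centered by autoscaling, y centered here
    X = X - X.mean(axis=0)
    yt = y - y.mean()
    var_y0 = float(yt @ yt)
    col_var0 = np.einsum("ij,ij->j", X, X)
    active &= col_var0 > 0

    steps: list[SelectionStep] = []
    for t in range(1, k_max + 1):
        if var_y0 > 0 and float(yt @ yt) < tol_var * var_y0:
            break
        # retire columns whose remaining variance is pure numerical residue
        col_var = np.einsum("ij,ij->j", X, X)
        live = active & (col_var > _EXHAUSTED_REL_VAR * col_var0)
        if not live.any():
            break
        r = _safe_corr(X, yt, live)
        best = float(np.max(np.abs(r)))
        if best < r_min:
            break
        k_star = int(np.argmax(np.abs(r)))  # argmax takes the smallest index on ties
        steps.append(
            SelectionStep(
                order=t,
                predictor_index=k_star + 1,
                wavelength_nm=grid.index_to_wavelength(k_star + 1),
                weight=min(abs(float(r[k_star])), 1.0),
            )
        )
        active[k_star] = False
        u = X[:, k_star].copy()
        uu = float(u @ u)
        if uu <= 0:
            break
        proj = (X.T @ u) / uu
        X -= np.outer(u, proj)
        yt = yt - (float(yt @ u) / uu) * u
        X[:, k_star] = 0.0
    if not steps:
        raise ValueError(
            "SELECT selected no channels (best |r| below r_min or response constant)"
        )
    return SelectionTrace(steps)
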