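"""Column autoscaling with stored parameters.

Autoscaling (mean-centering each channel and dividing by its standard
deviation, denominator n-1) is fitted on a training matrix and stored so a
calibrated model can be applied to new raw spectra. Channels whose standard
deviation falls below a relative floor are flagged rather than rejected;
downstream variable selection skips flagged channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScalingParams", "fit_autoscale", "apply_autoscale", "invert_autoscale"]

#: Relative floor below which a channel counts as zero-variance.
SD_FLOOR_REL = 1e-12


@dataclass
class ScalingParams:
    """Per-channel autoscaling parameters (sample mean and SD, ddof=1)."""

    means: np.ndarray
    sds: np.ndarray
    n_fit: int
    flagged: np.ndarray = field(default=None)  # boolean mask of near-constant channels

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.means.shape != self.sds.shape or self.means.ndim != 1:
            raise ValueError("means and sds must be 1-D and equally long")
        if self.flagged is None:
            self.flagged = np.zeros(self.means.shape, dtype=bool)
        self.flagged = np.asarray(self.flagged, dtype=bool)

    @property
    def n_channels(self) -> int:
        return self.means.size

    def to_dict(self) -> dict:
        return {
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "n_fit": int(self.n_fit),
            "flagged": np.flatnonzero(self.flagged).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingParams":
        means = np.asarray(d["means"], dtype=float)
        flagged = np.zeros(means.size, dtype=bool)
        flagged[np.asarray(d.get("flagged", []), dtype=int)] = True
        return cls(means, np.asarray(d["sds"], dtype=float), int(d["n_fit"]), flagged)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "ScalingParams":
        return cls.from_dict(json.loads(s))


def fit_autoscale(X: np.ndarray) -> ScalingParams:
    """Fit autoscaling parameters on the rows of ``X`` (requires >= 2 rows).

    Near-constant columns (SD below ``1e-12 * (|mean| + 1)``) are flagged and
    given a unit SD so scaling them is a no-op beyond centering.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("autoscaling needs a 2-D matrix with at least 2 rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    flagged = sds < SD_FLOOR_REL * (np.abs(means) + 1.0)
    sds = np.where(flagged, 1.0, sds)
    return ScalingParams(means=means, sds=sds, n_fit=X.shape[0], flagged=flagged)


def apply_autoscale(X: np.ndarray, params: ScalingParams) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != params.n_channels:
        raise ValueError(
            f"matrix has {X.shape[-1]} columns, scaling expects {params.n_channels}"
        )
    return (X - params.means) / params.sds


def invert_autoscale(Xs: np.ndarray, params: ScalingParams) -> np.ndarray:
    Xs = np.asarray(Xs, dtype=float)
    if Xs.shape[-1] != params.n_channels:
        raise ValueError(
            f"matrix has {Xs.shape[-1]} columns, scaling expects {params.n_channels}"
        )
    return Xs * params.sds + params.means
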