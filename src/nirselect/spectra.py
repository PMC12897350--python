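"""Spectral and marker data containers and their delimited-text formats.

The instrument convention used throughout the package is a fixed wavelength
grid from 1100 to 2498 nm in 2 nm steps (700 channels), with predictor
indices reported 1-based so that channel ``i`` sits at ``1100 + 2*(i-1)`` nm.
Spectra are exchanged as wide CSV (one row per recorded spectrum, columns
named by wavelength in nm); markers and sample metadata are plain long CSVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "STUDY_GRID",
    "SpectraSet",
    "SampleMeta",
    "MARKER_NAMES",
    "read_spectra",
    "write_spectra",
    "read_markers",
    "write_markers",
    "read_metadata",
    "write_metadata",
    "average_replicates",
]

#: Canonical order of the seven oxidation markers handled by the pipeline.
MARKER_NAMES = ("acidity", "k232", "k270", "delta_k", "pv", "anv", "totox")

#: Sentinel replicate label used after replicate averaging.
MEAN_REPLICATE_ID = "mean"


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid of an NIR acquisition.

    Parameters
    ----------
    start_nm : float
        First channel wavelength in nm.
    step_nm : float
        Channel spacing in nm; must be positive.
    n_channels : int
        Number of channels.
    """

    start_nm: float = 1100.0
    step_nm: float = 2.0
    n_channels: int = 700

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError(f"step_nm must be positive, got {self.step_nm}")
        if self.n_channels < 1:
            raise ValueError(f"n_channels must be >= 1, got {self.n_channels}")

    @property
    def end_nm(self) -> float:
        return self.start_nm + self.step_nm * (self.n_channels - 1)

    @property
    def wavelengths(self) -> np.ndarray:
        """All channel wavelengths in ascending order (nm)."""
        return self.start_nm + self.step_nm * np.arange(self.n_channels)

    def index_to_wavelength(self, index):
        """Map 1-based predictor index(es) to wavelength(s) in nm."""
        idx = np.asarray(index)
        if np.any((idx < 1) | (idx > self.n_channels)):
            raise ValueError(
                f"predictor index out of range 1..{self.n_channels}: {index}"
            )
        nm = self.start_nm + self.step_nm * (idx - 1)
        return float(nm) if np.isscalar(index) else nm

    def wavelength_to_index(self, nm):
        """Map on-grid wavelength(s) in nm to 1-based predictor index(es)."""
        wl = np.asarray(nm, dtype=float)
        pos = (wl - self.start_nm) / self.step_nm
        idx = np.rint(pos).astype(int) + 1
        off = np.abs(pos - np.rint(pos)) > 1e-9
        bad = off | (idx < 1) | (idx > self.n_channels)
        if np.any(bad):
            raise ValueError(
                f"wavelength {nm} nm is not on the grid "
                f"{self.start_nm}..{self.end_nm} nm step {self.step_nm}"
            )
        return int(idx) if np.isscalar(nm) else idx

    def to_dict(self) -> dict:
        return {
            "start_nm": self.start_nm,
            "step_nm": self.step_nm,
            "n_channels": self.n_channels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WavelengthGrid":
        return cls(d["start_nm"], d["step_nm"], int(d["n_channels"]))


#: The acquisition grid of the deep-frying study: 1100-2498 nm, 2 nm, 700 channels.
STUDY_GRID = WavelengthGrid(1100.0, 2.0, 700)


def index_wavelength(value, grid: WavelengthGrid = STUDY_GRID, *, to: str = "auto"):
    """Convert between 1-based predictor index and wavelength on ``grid``.

    ``to='nm'`` treats ``value`` as an index, ``to='index'`` as a wavelength;
    the default ``'auto'`` infers the direction (indices lie in
    ``1..n_channels``, wavelengths at or beyond ``start_nm``).
    """
    if to == "nm":
        return grid.index_to_wavelength(value)
    if to == "index":
        return grid.wavelength_to_index(value)
    if to == "auto":
        if np.all(np.asarray(value) >= grid.start_nm):
            return grid.wavelength_to_index(value)
        return grid.index_to_wavelength(value)
    raise ValueError(f"'to' must be 'nm', 'index' or 'auto', got {to!r}")


@dataclass
class SpectraSet:
    """A set of absorbance spectra on a common wavelength grid.

    ``absorbance`` has one row per recorded spectrum; ``sample_ids`` and
    ``replicate_ids`` label the rows, and each (sample, replicate) pair must
    be unique.
    """

    grid: WavelengthGrid
    absorbance: np.ndarray
    sample_ids: list = field(default_factory=list)
    replicate_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        n, p = self.absorbance.shape
        if p != self.grid.n_channels:
            raise ValueError(
                f"absorbance has {p} columns but the grid has "
                f"{self.grid.n_channels} channels"
            )
        if len(self.sample_ids) != n or len(self.replicate_ids) != n:
            raise ValueError("sample_ids/replicate_ids length must match row count")
        if not np.all(np.isfinite(self.absorbance)):
            bad = np.argwhere(~np.isfinite(self.absorbance))[0]
            raise ValueError(
                f"non-finite absorbance at row {bad[0]}, channel {bad[1]}"
            )
        pairs = list(zip(self.sample_ids, map(str, self.replicate_ids)))
        if len(set(pairs)) != n:
            raise ValueError("(sample_id, replicate_id) pairs must be unique")

    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{int(w)}" for w in self.grid.wavelengths]
        df = pd.DataFrame(self.absorbance, columns=cols)
        df.insert(0, "replicate_id", list(self.replicate_ids))
        df.insert(0, "sample_id", list(self.sample_ids))
        return df


def write_spectra(spectra: SpectraSet, path) -> None:
    """Write a :class:`SpectraSet` as wide CSV (columns = wavelengths in nm)."""
    spectra.to_frame().to_csv(path, index=False)


def read_spectra(path, grid: WavelengthGrid = STUDY_GRID) -> SpectraSet:
    """Read a wide spectra CSV and validate it against ``grid``.

    The header must name channels by wavelength in ascending order and match
    the grid exactly; the first two columns are ``sample_id`` and
    ``replicate_id``.
    """
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["sample_id", "replicate_id"]:
        raise ValueError(
            f"{path}: first two columns must be sample_id, replicate_id, "
            f"got {list(df.columns[:2])}"
        )
    try:
        header_nm = np.array([float(c) for c in df.columns[2:]])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric channel column name: {exc}") from exc
    expected = grid.wavelengths
    if header_nm.size != expected.size or not np.allclose(header_nm, expected):
        raise ValueError(
            f"{path}: channel columns do not match the grid "
            f"({header_nm.size} channels vs expected {expected.size}, "
            f"{grid.start_nm}..{grid.end_nm} nm step {grid.step_nm})"
        )
    values = df.iloc[:, 2:].apply(pd.to_numeric, errors="coerce")
    mat = values.to_numpy(dtype=float)
    if np.isnan(mat).any():
        r, c = np.argwhere(np.isnan(mat))[0]
        raise ValueError(
            f"{path}: missing/non-numeric absorbance at row {r}, "
            f"column {df.columns[2 + c]}"
        )
    return SpectraSet(
        grid=grid,
        absorbance=mat,
        sample_ids=df["sample_id"].astype(str).tolist(),
        replicate_ids=df["replicate_id"].astype(str).tolist(),
    )


def average_replicates(spectra: SpectraSet) -> SpectraSet:
    """Average replicate spectra of each sample (unweighted arithmetic mean).

    Returns one row per ``sample_id`` in first-appearance order, with the
    replicate label set to ``'mean'``.
    """
    order: list = []
    seen = {}
    for sid in spectra.sample_ids:
        if sid not in seen:
            seen[sid] = len(order)
            order.append(sid)
    sums = np.zeros((len(order), spectra.grid.n_channels))
    counts = np.zeros(len(order))
    for row, sid in enumerate(spectra.sample_ids):
        i = seen[sid]
        sums[i] += spectra.absorbance[row]
        counts[i] += 1
    return SpectraSet(
        grid=spectra.grid,
        absorbance=sums / counts[:, None],
        sample_ids=order,
        replicate_ids=[MEAN_REPLICATE_ID] * len(order),
    )


@dataclass(frozen=True)
class SampleMeta:
    """Treatment metadata of one oil sample.

    ``treatment`` follows the deep-frying study's coding: controls C1/C2/S
    (olive) or C (sunflower) carry no temperature or duration; frying
    experiments E1-E4 are unsupplemented and E5-E8 polyphenol-supplemented,
    on the {170, 210} degC x {3, 6} h grid.
    """

    sample_id: str
    category: str
    treatment: str
    temperature_C: float | None = None
    duration_h: float | None = None
    supplemented: bool = False

    def __post_init__(self) -> None:
        if self.treatment in ("E1", "E2", "E3", "E4") and self.supplemented:
            raise ValueError(f"{self.sample_id}: E1-E4 must be unsupplemented")
        if self.treatment in ("E5", "E6", "E7", "E8") and not self.supplemented:
            raise ValueError(f"{self.sample_id}: E5-E8 must be supplemented")
        if self.is_control and (
            self.temperature_C is not None or self.duration_h is not None
        ):
            raise ValueError(
                f"{self.sample_id}: control {self.treatment} must not carry "
                "temperature/duration"
            )

    @property
    def is_control(self) -> bool:
        return self.treatment in ("C", "C1", "C2", "S")


def write_metadata(meta: Sequence[SampleMeta], path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "category": m.category,
            "treatment": m.treatment,
            "temperature_C": m.temperature_C,
            "duration_h": m.duration_h,
            "supplemented": m.supplemented,
        }
        for m in meta
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_metadata(path) -> list[SampleMeta]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        out.append(
            SampleMeta(
                sample_id=str(r["sample_id"]),
                category=str(r["category"]),
                treatment=str(r["treatment"]),
                temperature_C=None if pd.isna(r["temperature_C"]) else float(r["temperature_C"]),
                duration_h=None if pd.isna(r["duration_h"]) else float(r["duration_h"]),
                supplemented=bool(r["supplemented"]),
            )
        )
    return out


def validate_markers(df: pd.DataFrame, *, check_totox: bool = True) -> pd.DataFrame:
    """Validate a marker table (one row per sample, seven marker columns).

    All markers must be non-negative except ``delta_k``; where both ``pv``
    and ``anv`` are present, ``totox`` must equal ``2*pv + anv``.
    """
    missing = [c for c in ("sample_id", *MARKER_NAMES) if c not in df.columns]
    if missing:
        raise ValueError(f"marker table is missing column(s): {missing}")
    for col in MARKER_NAMES:
        if col == "delta_k":
            continue
        vals = df[col].to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValueError(f"marker {col!r} contains negative values")
    if check_totox:
        expect = 2.0 * df["pv"].to_numpy(float) + df["anv"].to_numpy(float)
        if not np.allclose(df["totox"].to_numpy(float), expect, rtol=1e-9, atol=1e-9):
            raise ValueError("totox column does not equal 2*pv + anv")
    return df


def write_markers(df: pd.DataFrame, path) -> None:
    validate_markers(df).to_csv(path, index=False)


def read_markers(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["sample_id"] = df["sample_id"].astype(str)
    return validate_markers(df)
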