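"""Synthetic deep-frying study generator.

Emulates the statistical structure of a frying-oxidation experiment on
edible oils: 12 olive-oil categories each observed under 11 treatments
(controls C1/C2/S plus frying experiments E1-E8 on a {170, 210} degC x
{3, 6} h grid, E5-E8 polyphenol-supplemented) and 2 sunflower categories
under 5 treatments (control C plus E1-E4), i.e. 142 samples; each sample's
NIR spectrum is recorded in triplicate (426 spectra).

Markers follow ``m = base(category) * g(T, t) * s * exp(eps)`` with a
monotone power-law growth ``g = 1 + stability * a_m * ((T-160)/50)^qT *
(t/6)^qt``, a supplementation attenuation ``s`` in (0, 1] for E5-E8, and
lognormal measurement noise; TOTOX is always computed exactly as
``2*PV + AnV``, never sampled. Spectra are a smooth positive category
baseline plus marker-linked Gaussian absorption bands (signed slopes encode
the observed directions: absorbance falls at 1792 nm with rising acidity
and at 1392 nm with rising K232, rises at 2114 nm with K270 and near
1970/2254-2404 nm with the secondary-oxidation indices) plus white
replicate noise.

All randomness derives from one root seed through named streams
(``markers``, ``baseline``, ``replicates``), so each stage is independently
reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .spectra import (
    MARKER_NAMES,
    STUDY_GRID,
    SampleMeta,
    SpectraSet,
    WavelengthGrid,
)

__all__ = [
    "OilCategory",
    "StudyDesign",
    "BandSpec",
    "SimConfig",
    "default_design",
    "default_band_table",
    "simulate_markers",
    "simulate_spectra",
    "generate_study",
    "StudyData",
]

_OLIVE_TREATMENTS = ("C1", "C2", "S", "E1", "E2", "E3", "E4", "E5", "E6", "E7", "E8")
_SUNFLOWER_TREATMENTS = ("C", "E1", "E2", "E3", "E4")

#: frying grid: treatment -> (temperature degC, duration h, supplemented)
_EXPERIMENTS = {
    "E1": (170.0, 3.0, False),
    "E2": (170.0, 6.0, False),
    "E3": (210.0, 3.0, False),
    "E4": (210.0, 6.0, False),
    "E5": (170.0, 3.0, True),
    "E6": (170.0, 6.0, True),
    "E7": (210.0, 3.0, True),
    "E8": (210.0, 6.0, True),
}


@dataclass(frozen=True)
class OilCategory:
    code: str
    oil_class: str   # "olive" | "sunflower"
    stability: float  # relative oxidative susceptibility (1 = typical olive)


@dataclass
class StudyDesign:
    categories: list

    def samples(self) -> list[SampleMeta]:
        out = []
        for cat in self.categories:
            treatments = (_OLIVE_TREATMENTS if cat.oil_class == "olive"
                          else _SUNFLOWER_TREATMENTS)
            for tr in treatments:
                if tr in _EXPERIMENTS:
                    T, t, sup = _EXPERIMENTS[tr]
                    out.append(SampleMeta(f"{cat.code}_{tr}", cat.code, tr,
                                          temperature_C=T, duration_h=t,
                                          supplemented=sup))
                else:
                    sup = tr == "S"
                    out.append(SampleMeta(f"{cat.code}_{tr}", cat.code, tr,
                                          supplemented=sup))
        return out

    @property
    def n_samples(self) -> int:
        return len(self.samples())

    def category(self, code: str) -> OilCategory:
        for c in self.categories:
            if c.code == code:
                return c
        raise KeyError(code)


def default_design() -> StudyDesign:
    """The 14-category, 142-sample deep-frying design.

    Stability scalars encode the observed ordering: high-oleic sunflower
    (SOHO) and cultivars like Empeltre/Arbosana resist oxidation best,
    regular sunflower (SO) and Hojiblanca degrade fastest.
    """
    olive = [
        ("PC", 1.00), ("CC", 0.95), ("EP", 0.75), ("AQ", 0.90),
        ("HB", 1.25), ("MZ", 0.95), ("RY", 1.00), ("OJ", 1.10),
        ("KN", 0.90), ("AS", 0.80), ("O1", 1.15), ("O04", 1.05),
    ]
    cats = [OilCategory(c, "olive", s) for c, s in olive]
    cats += [OilCategory("SO", "sunflower", 1.35),
             OilCategory("SOHO", "sunflower", 0.30)]
    return StudyDesign(cats)


@dataclass(frozen=True)
class BandSpec:
    """A marker-linked Gaussian absorption band."""

    center_nm: float
    width_nm: float     # Gaussian sd
    marker: str
    slope: float        # absorbance per marker unit (signed)


def default_band_table() -> list[BandSpec]:
    """Default forward-model bands, one principal band per marker.

    Signs follow the observed directions; the 12 nm widths span several
    2 nm channels so neighboring channels are realistically collinear.
    """
    return [
        BandSpec(1792.0, 12.0, "acidity", -0.030),
        BandSpec(1392.0, 12.0, "k232", -0.009),
        BandSpec(2114.0, 12.0, "k270", +0.020),
        BandSpec(2118.0, 12.0, "delta_k", +0.100),
        BandSpec(1376.0, 12.0, "pv", -0.0015),
        BandSpec(1970.0, 12.0, "anv", +0.0008),
        BandSpec(2362.0, 12.0, "anv", +0.0003),
        BandSpec(2254.0, 12.0, "totox", +0.00025),
        BandSpec(2404.0, 12.0, "totox", +0.00012),
    ]


#: control-level marker ranges (lo, hi) by oil class
_DEFAULT_BASE = {
    "olive": {
        "acidity": (0.08, 0.30), "k232": (1.30, 1.70), "k270": (0.13, 0.20),
        "delta_k": (0.015, 0.030), "pv": (7.0, 10.0), "anv": (2.0, 4.0),
    },
    "sunflower": {
        "acidity": (0.05, 0.15), "k232": (1.70, 2.10), "k270": (0.22, 0.32),
        "delta_k": (0.020, 0.040), "pv": (5.0, 7.0), "anv": (3.0, 5.0),
    },
}

#: growth amplitude a_m: relative marker increase at 210 degC / 6 h for
#: a stability-1 category
_DEFAULT_AMPLITUDE = {
    "acidity": 1.8, "k232": 0.75, "k270": 5.0,
    "delta_k": 7.0, "pv": 1.3, "anv": 10.0,
}

#: smooth NIR baseline anchors (nm, absorbance); pins ~0.40 @1392 nm and
#: ~1.08 @2114 nm
_DEFAULT_ANCHORS = (
    (1100.0, 0.45), (1250.0, 0.42), (1392.0, 0.40), (1600.0, 0.50),
    (1750.0, 0.62), (1900.0, 0.80), (2114.0, 1.08), (2300.0, 1.14),
    (2498.0, 1.22),
)


@dataclass
class SimConfig:
    """Configuration of the synthetic study."""

    seed: int = 0
    marker_base: dict = field(default_factory=lambda: {
        cls: dict(v) for cls, v in _DEFAULT_BASE.items()})
    amplitude: dict = field(default_factory=lambda: dict(_DEFAULT_AMPLITUDE))
    temp_exponent: float = 1.0
    time_exponent: float = 1.0
    suppl_factor: float = 0.6
    marker_noise_sd: float = 0.08
    band_table: list = field(default_factory=default_band_table)
    baseline_anchors: tuple = _DEFAULT_ANCHORS
    baseline_jitter_sd: float = 0.004   # per-category baseline offset SD
    replicate_noise_sd: float = 0.015   # absorbance, per channel
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.suppl_factor <= 1.0):
            raise ValueError("suppl_factor must lie in (0, 1]")
        if self.marker_noise_sd < 0 or self.replicate_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for b in self.band_table:
            STUDY_GRID.wavelength_to_index(b.center_nm)  # must be on-grid

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band_table"] = [asdict(b) for b in self.band_table]
        d["baseline_anchors"] = [list(a) for a in self.baseline_anchors]
        return d


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named substream of the root seed (stable across runs/platforms)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


def growth_factor(meta: SampleMeta, stability: float, cfg: SimConfig,
                  marker: str) -> float:
    """Multiplicative marker growth ``g(T, t)`` (1 for controls)."""
    if meta.is_control:
        return 1.0
    tf = (meta.temperature_C - 160.0) / 50.0
    df = meta.duration_h / 6.0
    a = cfg.amplitude[marker]
    return 1.0 + stability * a * tf ** cfg.temp_exponent * df ** cfg.time_exponent


def simulate_markers(design: StudyDesign, cfg: SimConfig):
    """Draw the per-sample marker table and its generative truth record.

    Each category draws one control-level base per marker from the class
    range; treatments scale it by ``g(T, t)``, supplementation (E5-E8) by
    ``suppl_factor``, and lognormal noise is applied. TOTOX is computed
    exactly from the realized PV and AnV.
    """
    rng = _stream(cfg.seed, "markers")
    base_markers = [m for m in MARKER_NAMES if m != "totox"]
    bases = {}
    for cat in design.categories:
        ranges = cfg.marker_base[cat.oil_class]
        # stable oils start cleaner: mild coupling of control level to stability
        lvl = 0.7 + 0.3 * cat.stability
        bases[cat.code] = {
            m: rng.uniform(*ranges[m]) * lvl for m in base_markers
        }
    rows = []
    for meta in design.samples():
        cat = design.category(meta.category)
        s = cfg.suppl_factor if meta.treatment in ("E5", "E6", "E7", "E8") else 1.0
        row = {"sample_id": meta.sample_id}
        for m in base_markers:
            g = growth_factor(meta, cat.stability, cfg, m)
            eps = rng.normal(0.0, cfg.marker_noise_sd) if cfg.marker_noise_sd else 0.0
            row[m] = bases[cat.code][m] * g * s * np.exp(eps)
        row["totox"] = 2.0 * row["pv"] + row["anv"]
        rows.append(row)
    markers = pd.DataFrame(rows, columns=["sample_id", *MARKER_NAMES])
    truth = {
        "seed": int(cfg.seed),
        "bases": bases,
        "bands": [asdict(b) for b in cfg.band_table],
        "strongest_band": strongest_bands(markers, cfg.band_table),
    }
    return markers, truth


def strongest_bands(markers: pd.DataFrame, band_table) -> dict:
    """Per marker, the generating band with the largest absorbance swing.

    The swing of a band is ``|slope| * sd(linked marker)`` across samples.
    TOTOX is a composite of PV and AnV, so its candidate bands include
    theirs.
    """
    swings = {}
    for b in band_table:
        sd = float(markers[b.marker].std(ddof=1))
        swings.setdefault(b.marker, []).append((abs(b.slope) * sd, b.center_nm))
    out = {}
    for m in MARKER_NAMES:
        cands = list(swings.get(m, []))
        if m == "totox":
            cands += swings.get("pv", []) + swings.get("anv", [])
        if cands:
            out[m] = max(cands)[1]
    return out


def _baseline_curve(grid: WavelengthGrid, anchors) -> np.ndarray:
    pts = np.asarray(anchors, dtype=float)
    interp = PchipInterpolator(pts[:, 0], pts[:, 1])
    return interp(grid.wavelengths)


def simulate_spectra(markers: pd.DataFrame, design: StudyDesign,
                     cfg: SimConfig, grid: WavelengthGrid = STUDY_GRID) -> SpectraSet:
    """Forward-model NIR spectra for a marker table.

    ``A(lambda) = baseline_category + sum_bands slope * (marker - median) *
    Gaussian(lambda; center, width) + replicate noise``.
    """
    base = _baseline_curve(grid, cfg.baseline_anchors)
    wl = grid.wavelengths
    rng_base = _stream(cfg.seed, "baseline")
    rng_rep = _stream(cfg.seed, "replicates")
    # per-category smooth perturbation: offset + gentle tilt
    cat_curves = {}
    for cat in design.categories:
        off = rng_base.normal(0.0, cfg.baseline_jitter_sd)
        tilt = rng_base.normal(0.0, cfg.baseline_jitter_sd)
        cat_curves[cat.code] = base + off + tilt * (wl - wl.mean()) / (wl[-1] - wl[0])
    medians = {m: float(markers[m].median()) for m in MARKER_NAMES}
    shapes = [
        (b, np.exp(-((wl - b.center_nm) ** 2) / (2.0 * b.width_nm ** 2)))
        for b in cfg.band_table
    ]
    by_id = markers.set_index("sample_id")
    rows, sids, rids = [], [], []
    for meta in design.samples():
        rec = by_id.loc[meta.sample_id]
        clean = cat_curves[meta.category].copy()
        for b, shape in shapes:
            clean = clean + b.slope * (float(rec[b.marker]) - medians[b.marker]) * shape
        for rep in range(1, cfg.n_replicates + 1):
            noise = (rng_rep.normal(0.0, cfg.replicate_noise_sd, size=wl.size)
                     if cfg.replicate_noise_sd else 0.0)
            rows.append(clean + noise)
            sids.append(meta.sample_id)
            rids.append(str(rep))
    return SpectraSet(grid=grid, absorbance=np.asarray(rows),
                      sample_ids=sids, replicate_ids=rids)


@dataclass
class StudyData:
    """One realized synthetic study."""

    spectra: SpectraSet
    markers: pd.DataFrame
    meta: list
    truth: dict

    def write(self, outdir) -> None:
        from pathlib import Path
        from .spectra import write_markers, write_metadata, write_spectra

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_spectra(self.spectra, outdir / "spectra.csv")
        write_markers(self.markers, outdir / "markers.csv")
        write_metadata(self.meta, outdir / "metadata.csv")
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=1))


def generate_study(cfg: SimConfig, design: StudyDesign | None = None) -> StudyData:
    """Generate a complete study: markers, triplicate spectra, metadata, truth."""
    if design is None:
        design = default_design()
    markers, truth = simulate_markers(design, cfg)
    spectra = simulate_spectra(markers, design, cfg)
    truth["config"] = cfg.to_dict()
    return StudyData(spectra=spectra, markers=markers,
                     meta=design.samples(), truth=truth)
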