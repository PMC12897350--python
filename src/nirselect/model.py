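"""SELECT-OLS calibration models.

Two surfaces are provided. The functional layer (:func:`fit_ols`,
:func:`predict`, :func:`coefficients_raw`, :func:`model_report`) operates on
explicit matrices and mirrors the building blocks of the pipeline. The
object layer (:class:`SelectOLS` / :class:`SelectOLSResults`) wraps them in
the conventional model/results idiom: build a model from a response and a
spectra matrix, call :meth:`SelectOLS.fit`, and read estimates, diagnostics
and a two-panel summary off the results object.

The final regression is always refit on the ORIGINAL autoscaled selected
channels, not on the orthogonalized working copies used during selection;
with collinear neighboring wavelengths this produces the large opposing
coefficient pairs characteristic of correlated-predictor OLS, while the
predictions remain stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .preprocess import ScalingParams, fit_autoscale, apply_autoscale
from .select import SelectionStep, SelectionTrace, run_select
from .spectra import WavelengthGrid, STUDY_GRID, SpectraSet, average_replicates
from .validation import ModelStats, choose_model_size, loo_stats

__all__ = [
    "OlsModel",
    "fit_ols",
    "predict",
    "coefficients_raw",
    "model_report",
    "parse_report",
    "SelectOLS",
    "SelectOLSResults",
]


@dataclass
class OlsModel:
    """An OLS calibration on SELECT-chosen channels, with its preprocessing."""

    trace: SelectionTrace
    coefficients: np.ndarray   # response units per autoscaled absorbance unit
    intercept: float           # response units
    scaling: ScalingParams
    response_name: str = "response"
    grid: WavelengthGrid = field(default_factory=lambda: STUDY_GRID)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.size != len(self.trace):
            raise ValueError("coefficient count must equal trace length")

    @property
    def indices(self) -> list[int]:
        return self.trace.indices

    def to_dict(self) -> dict:
        b_raw, a_raw = coefficients_raw(self)
        return {
            "response_name": self.response_name,
            "grid": self.grid.to_dict(),
            "indices": self.trace.indices,
            "wavelengths_nm": self.trace.wavelengths,
            "weights": self.trace.weights,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "coefficients_raw": b_raw.tolist(),
            "intercept_raw": a_raw,
            "scaling": self.scaling.to_dict(),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "OlsModel":
        grid = WavelengthGrid.from_dict(d["grid"])
        steps = [
            SelectionStep(order=t + 1, predictor_index=int(i),
                          wavelength_nm=float(w), weight=float(wt))
            for t, (i, w, wt) in enumerate(
                zip(d["indices"], d["wavelengths_nm"], d["weights"]))
        ]
        return cls(
            trace=SelectionTrace(steps),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            scaling=ScalingParams.from_dict(d["scaling"]),
            response_name=d.get("response_name", "response"),
            grid=grid,
        )

    @classmethod
    def from_json(cls, s: str) -> "OlsModel":
        return cls.from_dict(json.loads(s))


def _design(Xs_sel: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(Xs_sel.shape[0]), Xs_sel])


def fit_ols(
    Xs: np.ndarray,
    y: np.ndarray,
    indices,
    *,
    scaling: ScalingParams | None = None,
    trace: SelectionTrace | None = None,
    response_name: str = "response",
    grid: WavelengthGrid = STUDY_GRID,
) -> OlsModel:
    """Least-squares fit (with intercept) on the selected autoscaled channels.

    ``indices`` are 1-based channel indices. The solve uses an orthogonal
    (QR/SVD) factorization; rank deficiency among the selected channels is an
    error that names the offending wavelengths.
    """
    Xs = np.asarray(Xs, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    indices = [int(i) for i in indices]
    n = y.size
    p = len(indices)
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 rows (n={n}, p={p})")
    cols = [i - 1 for i in indices]
    A = _design(Xs[:, cols])
    # pivoted QR names dependent columns before the actual solve
    _, R, piv = scipy.linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < A.shape[1]:
        dead = [piv[j] for j in range(rank, A.shape[1]) if piv[j] > 0]
        bad = [f"{grid.index_to_wavelength(indices[j - 1]):.0f} nm" for j in dead]
        raise ValueError(
            "rank-deficient design: linearly dependent channel(s) "
            + ", ".join(bad)
        )
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    if trace is None:
        steps = [
            SelectionStep(order=t + 1, predictor_index=i,
                          wavelength_nm=grid.index_to_wavelength(i), weight=0.0)
            for t, i in enumerate(indices)
        ]
        trace = SelectionTrace(steps)
    elif trace.indices != indices:
        raise ValueError("trace indices do not match the fitted indices")
    if scaling is None:
        scaling = ScalingParams(
            means=np.zeros(Xs.shape[1]), sds=np.ones(Xs.shape[1]), n_fit=n
        )
    return OlsModel(
        trace=trace,
        coefficients=beta[1:],
        intercept=float(beta[0]),
        scaling=scaling,
        response_name=response_name,
        grid=grid,
    )


def predict(model: OlsModel, X_raw: np.ndarray) -> np.ndarray:
    """Apply a calibration to raw spectra on the model's grid."""
    X_raw = np.atleast_2d(np.asarray(X_raw, dtype=float))
    if X_raw.shape[1] != model.grid.n_channels:
        raise ValueError(
            f"spectra have {X_raw.shape[1]} channels, model grid has "
            f"{model.grid.n_channels}"
        )
    Xs = apply_autoscale(X_raw, model.scaling)
    cols = [i - 1 for i in model.indices]
    return Xs[:, cols] @ model.coefficients + model.intercept


def coefficients_raw(model: OlsModel) -> tuple[np.ndarray, float]:
    """The model in raw-absorbance space: ``y = b_raw . x[sel] + a_raw``."""
    cols = np.array([i - 1 for i in model.indices], dtype=int)
    sd = model.scaling.sds[cols]
    mu = model.scaling.means[cols]
    b_raw = model.coefficients / sd
    a_raw = model.intercept - float(np.sum(model.coefficients * mu / sd))
    return b_raw, a_raw


# ---------------------------------------------------------------------------
# two-panel report


def _fmt(x: float, decimals: int | None) -> str:
    if decimals is None:
        return repr(float(x))
    return f"{x:.{decimals}f}"


def model_report(model: OlsModel, stats: ModelStats, *, decimals: int | None = None) -> str:
    """Render the two-panel TSV report of a calibration.

    Panel A lists the selection order, 1-based predictor index, wavelength,
    selection weight and OLS coefficient per channel, followed by the
    intercept; panel B lists the seven performance statistics. With
    ``decimals=None`` (default) numbers are written at full precision, so
    ``parse_report`` round-trips the report byte-identically.
    """
    lines = ["(A) SELECT-OLS Chemometric Modeling",
             "Order of Selection\tPredictor Index\tWavelength (nm)\tWeight\tCoefficient"]
    for step, coef in zip(model.trace, model.coefficients):
        lines.append(
            "\t".join([
                str(step.order),
                str(step.predictor_index),
                f"{step.wavelength_nm:.0f}",
                _fmt(step.weight, decimals),
                _fmt(coef, decimals),
            ])
        )
    lines.append(f"Intercept\t{_fmt(model.intercept, decimals)}")
    lines.append("(B) Statistical Characteristics")
    for attr, label in ModelStats.LABELS:
        lines.append(f"{label}\t{_fmt(getattr(stats, attr), decimals)}")
    return "\n".join(lines) + "\n"


def parse_report(text: str) -> dict:
    """Parse a :func:`model_report` back into its numeric content."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("(A)"):
        raise ValueError("not a SELECT-OLS report (missing panel A header)")
    rows = []
    intercept = None
    stats: dict[str, float] = {}
    label_map = {label: attr for attr, label in ModelStats.LABELS}
    panel = "A"
    for ln in lines[2:]:
        if ln.startswith("(B)"):
            panel = "B"
            continue
        parts = ln.split("\t")
        if panel == "A":
            if parts[0] == "Intercept":
                intercept = float(parts[1])
            else:
                rows.append({
                    "order": int(parts[0]),
                    "predictor_index": int(parts[1]),
                    "wavelength_nm": float(parts[2]),
                    "weight": float(parts[3]),
                    "coefficient": float(parts[4]),
                })
        else:
            stats[label_map[parts[0]]] = float(parts[1])
    if intercept is None:
        raise ValueError("report has no Intercept row")
    return {"rows": rows, "intercept": intercept, "stats": stats}


# ---------------------------------------------------------------------------
# model/results objects


class SelectOLS:
    """SELECT-OLS calibration model for one oxidation marker.

    Parameters
    ----------
    endog : (n,) array
        Response values (one per spectrum row), e.g. peroxide values.
    exog : (n, 700) array or SpectraSet
        Raw absorbance spectra on ``grid``.
    response_name : str
        Marker label used in reports and artifacts.
    grid : WavelengthGrid
        Channel grid (defaults to the 1100-2498 nm / 2 nm study grid).

    Examples
    --------
    >>> model = SelectOLS(markers["pv"], spectra_matrix, response_name="pv")
    >>> res = model.fit(k_max=30)
    >>> res.stats.loo_explained_variance_pct  # doctest: +SKIP
    """

    def __init__(self, endog, exog, *, response_name: str = "response",
                 grid: WavelengthGrid | None = None):
        if isinstance(exog, SpectraSet):
            grid = exog.grid
            exog = exog.absorbance
        self.grid = grid if grid is not None else STUDY_GRID
        self.exog = np.asarray(exog, dtype=float)
        self.endog = np.asarray(endog, dtype=float).ravel()
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.size:
            raise ValueError("endog length must equal the spectra row count")
        if self.exog.shape[1] != self.grid.n_channels:
            raise ValueError(
                f"spectra have {self.exog.shape[1]} channels, grid defines "
                f"{self.grid.n_channels}"
            )
        self.response_name = response_name

    @classmethod
    def from_study(cls, markers, spectra: SpectraSet, marker: str,
                   *, replicates: str = "average") -> "SelectOLS":
        """Build a model from a marker table and a SpectraSet.

        ``replicates='average'`` (default) averages replicate spectra per
        sample before aligning with the per-sample marker values;
        ``'individual'`` keeps every replicate row, repeating the sample's
        marker value.
        """
        if marker not in markers.columns:
            raise KeyError(f"marker table has no column {marker!r}")
        if replicates == "average":
            spectra = average_replicates(spectra)
        elif replicates != "individual":
            raise ValueError("replicates must be 'average' or 'individual'")
        by_id = dict(zip(markers["sample_id"].astype(str), markers[marker]))
        missing = [s for s in spectra.sample_ids if s not in by_id]
        if missing:
            raise ValueError(f"markers missing for sample(s): {missing[:5]}")
        y = np.array([by_id[s] for s in spectra.sample_ids], dtype=float)
        return cls(y, spectra.absorbance, response_name=marker, grid=spectra.grid)

    def fit(self, *, k_max: int = 30, r_min: float = 0.05, tol_var: float = 1e-6,
            size="loo", loo_scaling: str = "refit") -> "SelectOLSResults":
        """Run selection, choose the model size, and fit the final OLS.

        ``size='loo'`` (default) picks the trace prefix minimizing the LOO
        mean prediction error; an integer forces that prefix length.
        """
        scaling = fit_autoscale(self.exog)
        Xs = apply_autoscale(self.exog, scaling)
        trace = run_select(Xs, self.endog, k_max=k_max, r_min=r_min,
                           tol_var=tol_var, grid=self.grid,
                           excluded=scaling.flagged)
        if size == "loo":
            k_star, curve = choose_model_size(Xs, self.endog, trace,
                                              scaling=loo_scaling)
        else:
            k_star = int(size)
            if not 1 <= k_star <= len(trace):
                raise ValueError(f"size {k_star} outside 1..{len(trace)}")
            curve = None
        final_trace = trace.head(k_star)
        cols = [i - 1 for i in final_trace.indices]
        model = fit_ols(Xs, self.endog, final_trace.indices, scaling=scaling,
                        trace=final_trace, response_name=self.response_name,
                        grid=self.grid)
        stats = loo_stats(Xs[:, cols], self.endog, scaling=loo_scaling)
        return SelectOLSResults(self, model, stats, full_trace=trace,
                                loo_curve=curve)


class SelectOLSResults:
    """Fitted SELECT-OLS calibration: estimates, diagnostics, reports."""

    def __init__(self, model_spec: SelectOLS, model: OlsModel, stats: ModelStats,
                 *, full_trace: SelectionTrace, loo_curve=None):
        self.model_spec = model_spec
        self.model = model
        self.stats = stats
        self.full_trace = full_trace
        self.loo_curve = loo_curve

    # -- estimates ---------------------------------------------------------
    @property
    def params(self) -> np.ndarray:
        """Coefficients in autoscaled-predictor space, selection order."""
        return self.model.coefficients

    @property
    def intercept(self) -> float:
        return self.model.intercept

    @property
    def trace(self) -> SelectionTrace:
        return self.model.trace

    @property
    def k(self) -> int:
        """Number of selected wavelengths in the final model."""
        return len(self.model.trace)

    @property
    def wavelengths(self) -> list[float]:
        return self.model.trace.wavelengths

    # -- predictions -------------------------------------------------------
    def predict(self, X_raw=None) -> np.ndarray:
        """Predict the marker from raw spectra (training spectra by default)."""
        if X_raw is None:
            X_raw = self.model_spec.exog
        if isinstance(X_raw, SpectraSet):
            X_raw = X_raw.absorbance
        return predict(self.model, X_raw)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict()

    @property
    def resid(self) -> np.ndarray:
        return self.model_spec.endog - self.fittedvalues

    # -- reporting ---------------------------------------------------------
    def summary(self, *, decimals: int | None = 2) -> str:
        """Two-panel report; ``decimals=None`` gives full precision."""
        return model_report(self.model, self.stats, decimals=decimals)

    def to_json(self, **kw) -> str:
        d = self.model.to_dict()
        d["stats"] = self.stats.to_dict()
        if self.loo_curve is not None:
            d["loo_curve"] = np.asarray(self.loo_curve).tolist()
        return json.dumps(d, **kw)

    # -- plotting ----------------------------------------------------------
    def plot_loo_curve(self, ax=None):
        """LOO mean prediction error vs. number of selected wavelengths."""
        if self.loo_curve is None:
            raise ValueError("no LOO curve: model was fitted with a fixed size")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = np.asarray(self.loo_curve)
        ax.plot(curve[:, 0], curve[:, 1], marker="o")
        ax.axvline(self.k, ls="--", color="grey")
        ax.set_xlabel("number of selected wavelengths")
        ax.set_ylabel("LOO mean prediction error")
        ax.set_title(self.model.response_name)
        return ax

    def plot_fit(self, ax=None):
        """Observed vs. predicted marker values on the calibration set."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = self.model_spec.endog
        ax.scatter(y, self.fittedvalues, s=12)
        lims = [min(y.min(), self.fittedvalues.min()),
                max(y.max(), self.fittedvalues.max())]
        ax.plot(lims, lims, color="grey", lw=1)
        ax.set_xlabel(f"observed {self.model.response_name}")
        ax.set_ylabel(f"predicted {self.model.response_name}")
        return ax
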