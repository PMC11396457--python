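"""Spectral preprocessing operators and their composition into pipelines.

Each operator acts row-wise on a :class:`~saffronir.spectra.SpectraSet`.
Stateless operators (SNV, detrend, Savitzky-Golay, first difference) are
plain functions; operators with train-fitted state (MSC reference spectrum,
mean-centering column means) are :class:`PreprocessStep` subclasses with
``fit``/``apply`` semantics so that statistics estimated on the calibration
set are reused unchanged on prediction spectra.

The three canonical pipelines mirror the preprocessing combinations used to
build the saffron calibration models:

* ``method1`` — SNV, detrend, SG smoothing, SG first derivative, mean centering
* ``method2`` — MSC, SG smoothing, SG first derivative, mean centering
* ``method3`` — SG smoothing, SG first derivative, mean centering
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.signal import savgol_filter

from .spectra import SpectraSet, WavelengthGrid

__all__ = [
    "snv",
    "detrend",
    "savgol",
    "first_difference",
    "PreprocessStep",
    "MSCStep",
    "MeanCenterStep",
    "SNVStep",
    "DetrendStep",
    "SavgolStep",
    "PreprocessPipeline",
    "build_method_pipeline",
    "pipeline_fit_apply",
    "METHOD_STEPS",
]

DEFAULT_SG_WINDOW = 11
DEFAULT_SG_POLYORDER = 2
DEFAULT_DETREND_ORDER = 2


def snv(s: SpectraSet) -> SpectraSet:
    """Standard normal variate: centre and scale each spectrum to unit SD.

    Uses the sample (n-1) standard deviation. Constant rows are rejected
    because they cannot be scaled.
    """
    X = s.absorbance
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = np.where(sd[:, 0] == 0)[0]
    if flat.size:
        bad = [s.sample_ids[i] for i in flat]
        raise ValueError(f"SNV undefined for constant spectra: {bad}")
    return s.with_absorbance((X - mean) / sd)


def detrend(s: SpectraSet, order: int = DEFAULT_DETREND_ORDER) -> SpectraSet:
    """Subtract a least-squares polynomial in wavelength from each spectrum."""
    if order < 0:
        raise ValueError("polynomial order must be >= 0")
    if order >= s.n_wavelengths:
        raise ValueError(
            f"order {order} >= number of wavelengths {s.n_wavelengths}"
        )
    # centre/scale the wavelength axis for conditioning; the fitted subspace
    # is identical to the raw-lambda Vandermonde one
    lam = s.grid.values
    x = (lam - lam.mean()) / (np.ptp(lam) / 2)
    V = npoly.polyvander(x, order)
    coef, *_ = np.linalg.lstsq(V, s.absorbance.T, rcond=None)
    return s.with_absorbance(s.absorbance - (V @ coef).T)


def savgol(
    s: SpectraSet,
    window: int = DEFAULT_SG_WINDOW,
    polyorder: int = DEFAULT_SG_POLYORDER,
    deriv: int = 0,
) -> SpectraSet:
    """Savitzky-Golay filtering (smoothing or derivative) along wavelength.

    ``deriv=1`` output is scaled by the grid step, i.e. absorbance per nm.
    Edges are handled by evaluating the polynomial fitted to the first/last
    full window, so output length equals input length. Requires a uniform
    grid.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if polyorder >= window:
        raise ValueError(f"polyorder {polyorder} must be < window {window}")
    if deriv > polyorder:
        raise ValueError(f"deriv {deriv} must be <= polyorder {polyorder}")
    if window > s.n_wavelengths:
        raise ValueError("window longer than the spectrum")
    out = savgol_filter(
        s.absorbance,
        window_length=window,
        polyorder=polyorder,
        deriv=deriv,
        delta=s.grid.step,
        axis=1,
        mode="interp",
    )
    return s.with_absorbance(out)


def first_difference(s: SpectraSet) -> SpectraSet:
    """Forward first difference divided by the grid step (midpoint grid)."""
    if s.n_wavelengths < 3:
        raise ValueError(
            "first difference needs at least 3 wavelengths "
            "(the midpoint grid must keep >= 2 points)"
        )
    lam = s.grid.values
    dlam = np.diff(lam)
    out = np.diff(s.absorbance, axis=1) / dlam
    mid = WavelengthGrid((lam[:-1] + lam[1:]) / 2)
    return s.with_absorbance(out, grid=mid)


# ---------------------------------------------------------------------------
# steps


class PreprocessStep:
    """One pipeline stage: ``kind``, parameters, and optional fitted state."""

    kind: str = ""
    requires_fit = False

    def __init__(self, **params: Any) -> None:
        self.params = params
        self.fitted_state: dict[str, Any] | None = None

    @property
    def is_fitted(self) -> bool:
        return not self.requires_fit or self.fitted_state is not None

    def fit(self, calibration: SpectraSet) -> "PreprocessStep":
        return self

    def apply(self, s: SpectraSet) -> SpectraSet:
        raise NotImplementedError

    # serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        state = None
        if self.fitted_state is not None:
            state = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.fitted_state.items()
            }
        return {"kind": self.kind, "params": self.params, "fitted_state": state}

    @staticmethod
    def from_dict(d: dict[str, Any]) -> "PreprocessStep":
        cls = _STEP_KINDS[d["kind"]]
        step = cls(**d.get("params", {}))
        state = d.get("fitted_state")
        if state is not None:
            step.fitted_state = {
                k: (np.asarray(v, dtype=float) if isinstance(v, list) else v)
                for k, v in state.items()
            }
        return step


class SNVStep(PreprocessStep):
    kind = "SNV"

    def apply(self, s: SpectraSet) -> SpectraSet:
        return snv(s)


class DetrendStep(PreprocessStep):
    kind = "DT"

    def __init__(self, order: int = DEFAULT_DETREND_ORDER) -> None:
        super().__init__(order=order)

    def apply(self, s: SpectraSet) -> SpectraSet:
        return detrend(s, order=self.params["order"])


class MSCStep(PreprocessStep):
    """Multiplicative scatter correction against the mean calibration spectrum.

    Each spectrum x is regressed on (1, reference) by ordinary least squares,
    x ~= a + b*ref, and corrected to (x - a)/b — inverting the additive/
    multiplicative scatter model.
    """

    kind = "MSC"
    requires_fit = True
    _MIN_SLOPE = 1e-12

    def fit(self, calibration: SpectraSet) -> "MSCStep":
        if calibration.n_samples < 2:
            raise ValueError("MSC reference needs >= 2 calibration spectra")
        self.fitted_state = {
            "reference": calibration.absorbance.mean(axis=0),
            "grid": calibration.grid.values.copy(),
        }
        return self

    def apply(self, s: SpectraSet) -> SpectraSet:
        if self.fitted_state is None:
            raise RuntimeError("MSC step applied before fitting")
        ref = self.fitted_state["reference"]
        if not np.array_equal(self.fitted_state["grid"], s.grid.values):
            raise ValueError("wavelength grid differs from the MSC fit grid")
        rc = ref - ref.mean()
        denom = rc @ rc
        if denom < self._MIN_SLOPE:
            raise ValueError("MSC reference spectrum is constant")
        X = s.absorbance
        b = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
        small = np.where(np.abs(b) < self._MIN_SLOPE)[0]
        if small.size:
            bad = [s.sample_ids[i] for i in small]
            raise ValueError(f"spectra uncorrelated with MSC reference: {bad}")
        a = X.mean(axis=1) - b * ref.mean()
        return s.with_absorbance((X - a[:, None]) / b[:, None])


class SavgolStep(PreprocessStep):
    kind = "SG"

    def __init__(
        self,
        window: int = DEFAULT_SG_WINDOW,
        polyorder: int = DEFAULT_SG_POLYORDER,
        deriv: int = 0,
    ) -> None:
        super().__init__(window=window, polyorder=polyorder, deriv=deriv)

    def apply(self, s: SpectraSet) -> SpectraSet:
        return savgol(s, **self.params)


class FirstDifferenceStep(PreprocessStep):
    kind = "FIRST_DIFF"

    def apply(self, s: SpectraSet) -> SpectraSet:
        return first_difference(s)


class MeanCenterStep(PreprocessStep):
    kind = "MEAN_CENTER"
    requires_fit = True

    def fit(self, calibration: SpectraSet) -> "MeanCenterStep":
        if calibration.n_samples < 2:
            raise ValueError("mean centering needs >= 2 calibration spectra")
        self.fitted_state = {
            "column_means": calibration.absorbance.mean(axis=0),
            "grid": calibration.grid.values.copy(),
        }
        return self

    def apply(self, s: SpectraSet) -> SpectraSet:
        if self.fitted_state is None:
            raise RuntimeError("mean-center step applied before fitting")
        if not np.array_equal(self.fitted_state["grid"], s.grid.values):
            raise ValueError("wavelength grid differs from the centering fit grid")
        return s.with_absorbance(s.absorbance - self.fitted_state["column_means"])


_STEP_KINDS: dict[str, type[PreprocessStep]] = {
    c.kind: c
    for c in (
        SNVStep,
        DetrendStep,
        MSCStep,
        SavgolStep,
        FirstDifferenceStep,
        MeanCenterStep,
    )
}


# ---------------------------------------------------------------------------
# pipelines


class PreprocessPipeline:
    """Ordered list of steps applied left to right."""

    def __init__(self, steps: Sequence[PreprocessStep], name: str = "") -> None:
        self.steps = list(steps)
        self.name = name

    @property
    def is_fitted(self) -> bool:
        return all(step.is_fitted for step in self.steps)

    def fit_apply(
        self, calibration: SpectraSet, others: Sequence[SpectraSet] = ()
    ) -> tuple[SpectraSet, list[SpectraSet]]:
        """Fit stateful steps on the calibration set and transform all sets.

        Each step is fitted on the calibration data as transformed by the
        preceding steps, then applied with that fitted state to every set.
        No statistic ever derives from the ``others`` (prediction) sets.
        """
        for o in others:
            if o.grid != calibration.grid:
                raise ValueError("all sets must share the calibration grid")
        cal = calibration
        rest = list(others)
        for step in self.steps:
            step.fit(cal)
            cal = step.apply(cal)
            rest = [step.apply(o) for o in rest]
        return cal, rest

    def apply(self, s: SpectraSet) -> SpectraSet:
        if not self.is_fitted:
            unfitted = [st.kind for st in self.steps if not st.is_fitted]
            raise RuntimeError(f"pipeline has unfitted steps: {unfitted}")
        for step in self.steps:
            s = step.apply(s)
        return s

    # serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return {"name": self.name, "steps": [s.to_dict() for s in self.steps]}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PreprocessPipeline":
        return cls([PreprocessStep.from_dict(s) for s in d["steps"]], d.get("name", ""))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict()))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PreprocessPipeline":
        return cls.from_dict(json.loads(Path(path).read_text()))


METHOD_STEPS: dict[str, tuple[str, ...]] = {
    "method1": ("SNV", "DT", "SG_SMOOTH", "SG_FIRST_DERIV", "MEAN_CENTER"),
    "method2": ("MSC", "SG_SMOOTH", "SG_FIRST_DERIV", "MEAN_CENTER"),
    "method3": ("SG_SMOOTH", "SG_FIRST_DERIV", "MEAN_CENTER"),
}


def build_method_pipeline(
    name: str,
    sg_window: int = DEFAULT_SG_WINDOW,
    sg_polyorder: int = DEFAULT_SG_POLYORDER,
    detrend_order: int = DEFAULT_DETREND_ORDER,
) -> PreprocessPipeline:
    """Construct one of the three canonical preprocessing pipelines."""
    if name not in METHOD_STEPS:
        raise ValueError(f"unknown method {name!r}; choose from {sorted(METHOD_STEPS)}")
    builders = {
        "SNV": lambda: SNVStep(),
        "DT": lambda: DetrendStep(order=detrend_order),
        "MSC": lambda: MSCStep(),
        "SG_SMOOTH": lambda: SavgolStep(sg_window, sg_polyorder, deriv=0),
        "SG_FIRST_DERIV": lambda: SavgolStep(sg_window, sg_polyorder, deriv=1),
        "MEAN_CENTER": lambda: MeanCenterStep(),
    }
    return PreprocessPipeline([builders[k]() for k in METHOD_STEPS[name]], name=name)


def pipeline_fit_apply(
    p: PreprocessPipeline, calibration: SpectraSet, others: Sequence[SpectraSet] = ()
) -> tuple[PreprocessPipeline, SpectraSet, list[SpectraSet]]:
    """Functional wrapper around :meth:`PreprocessPipeline.fit_apply`."""
    cal, rest = p.fit_apply(calibration, others)
    return p, cal, rest
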