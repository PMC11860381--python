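"""Spectral pre-treatment operators and composable chains.

Six operators, each targeting one class of artefact in diffuse-reflectance
NIR spectra of bulked seeds:

* ``detrend``    — removes a tilted polynomial baseline per scan,
* ``snv``        — standard normal variate: per-scan centre and unit-variance
                   scaling, correcting multiplicative scatter without a
                   reference spectrum,
* ``msc``        — multiplicative scatter correction: regresses each scan on a
                   reference spectrum (the calibration mean, "MSC-mean") and
                   inverts the fitted slope/offset,
* ``emsc``       — extended MSC: adds polynomial wavelength terms to the MSC
                   regression so smooth baselines are removed jointly,
* ``savgol``     — Savitzky-Golay derivative (window 15, polynomial order 2;
                   first or second derivative in the two standard chains),
* ``mean_center``— subtracts calibration column means.

State-bearing steps (the MSC/EMSC reference, the mean-centring means) are
fitted on calibration scans only and applied unchanged to validation or
prediction scans; fitting and applying are separate calls so that no
validation information leaks into the model.

Two named chains are provided, the optimised pre-treatments for the two
classification tasks:

* :func:`cultivar_chain`  — Detrend -> MSC(mean) -> SavGol(15, 2, d2) -> mean centre
* :func:`endophyte_chain` — Detrend -> SNV -> SavGol(15, 2, d1) -> mean centre
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "detrend",
    "snv",
    "msc",
    "emsc",
    "savgol",
    "mean_center_fit",
    "mean_center_apply",
    "PreprocessStep",
    "PreprocessPipeline",
    "cultivar_chain",
    "endophyte_chain",
    "fit_apply_pipeline",
]


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[np.newaxis, :]
    if X.ndim != 2:
        raise ValueError("expected a 2-D (n_scans x n_points) matrix")
    return X


def _poly_basis(n_points: int, order: int) -> np.ndarray:
    """Column basis of polynomials in the point index, degrees 0..order.

    Uses Legendre polynomials on [-1, 1] for conditioning; spans the same
    space as raw monomials.
    """
    t = np.linspace(-1.0, 1.0, n_points)
    return np.polynomial.legendre.legvander(t, order)


def detrend(X, order: int = 1) -> np.ndarray:
    """Replace each scan by its residual from a polynomial baseline fit.

    The baseline is a least-squares polynomial of degree ``order`` in the
    point index (default linear).  Residuals are orthogonal to the
    polynomial basis, so detrending is idempotent at a fixed order.
    """
    X = _as_matrix(X)
    n_points = X.shape[1]
    if order < 0:
        raise ValueError(f"detrend order must be >= 0, got {order}")
    if order >= n_points:
        raise ValueError(
            f"detrend order {order} must be < number of points {n_points}"
        )
    basis = _poly_basis(n_points, order)
    coef, *_ = np.linalg.lstsq(basis, X.T, rcond=None)
    return X - (basis @ coef).T


def snv(X) -> np.ndarray:
    """Standard normal variate: each scan to mean 0, sample sd 1 (ddof=1)."""
    X = _as_matrix(X)
    if X.shape[1] < 2:
        raise ValueError("SNV needs at least 2 points per scan")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() < 1e-15)
    if bad.size:
        raise ValueError(
            f"SNV undefined for constant scan(s) at row(s) {bad.tolist()}"
        )
    return (X - mu) / sd


def _msc_coefficients(X: np.ndarray, reference: np.ndarray):
    """Per-row least-squares fit row ~ b + a*reference (2x2 normal equations)."""
    ref = np.asarray(reference, dtype=float).ravel()
    n = ref.size
    ref_mean = ref.mean()
    ref_c = ref - ref_mean
    denom = float(ref_c @ ref_c)
    if denom < 1e-15:
        raise ValueError("MSC reference spectrum has zero variance")
    row_means = X.mean(axis=1)
    a = (X - row_means[:, None]) @ ref_c / denom
    b = row_means - a * ref_mean
    return a, b


def msc(X, reference) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each scan is regressed on the reference (offset ``b``, slope ``a``) and
    corrected to ``(scan - b) / a``.  A scan equal to ``a*reference + b`` is
    mapped back to the reference exactly.
    """
    X = _as_matrix(X)
    ref = np.asarray(reference, dtype=float).ravel()
    if ref.size != X.shape[1]:
        raise ValueError("reference length does not match number of points")
    a, b = _msc_coefficients(X, ref)
    bad = np.flatnonzero(np.abs(a) < 1e-12)
    if bad.size:
        raise ValueError(
            f"MSC slope vanishes for scan(s) at row(s) {bad.tolist()}"
        )
    return (X - b[:, None]) / a[:, None]


def emsc(X, reference, order: int = 2) -> np.ndarray:
    """Extended MSC: joint fit of reference plus polynomial baseline terms.

    Each scan is modelled as ``a*reference + sum_k c_k p_k`` with ``p_k`` a
    polynomial basis (degree 0..order) in the point index; the corrected scan
    is ``(scan - sum_k c_k p_k) / a``.  With ``order=0`` and a mean-centred
    reference this reduces algebraically to plain MSC.
    """
    X = _as_matrix(X)
    ref = np.asarray(reference, dtype=float).ravel()
    n_points = X.shape[1]
    if ref.size != n_points:
        raise ValueError("reference length does not match number of points")
    if order < 0:
        raise ValueError(f"EMSC polynomial order must be >= 0, got {order}")
    basis = _poly_basis(n_points, order)
    design = np.column_stack([ref, basis])
    # Reject a reference lying in the polynomial span (collinear design).
    proj, *_ = np.linalg.lstsq(basis, ref, rcond=None)
    resid = ref - basis @ proj
    if float(resid @ resid) < 1e-12 * max(1.0, float(ref @ ref)):
        raise ValueError(
            "EMSC design is collinear: the reference spectrum lies in the "
            "polynomial baseline span"
        )
    coef, *_ = np.linalg.lstsq(design, X.T, rcond=None)
    a = coef[0]
    baseline = (basis @ coef[1:]).T
    bad = np.flatnonzero(np.abs(a) < 1e-12)
    if bad.size:
        raise ValueError(
            f"EMSC reference coefficient vanishes for scan(s) {bad.tolist()}"
        )
    return (X - baseline) / a[:, None]


def savgol(X, window: int = 15, polyorder: int = 2, deriv: int = 1) -> np.ndarray:
    """Savitzky-Golay smoothing/derivative with respect to the point index.

    Interior points use the centred window; near the edges the window is
    truncated to the available points and a fresh local polynomial fit is
    made, so no data are fabricated beyond the spectrum and output length
    equals input length.  The derivative is taken per point index (uniform
    grid); rescaling by the grid spacing is left to the caller since the
    downstream classifiers are scale-invariant after mean-centring.
    """
    X = _as_matrix(X)
    n_points = X.shape[1]
    if window % 2 == 0:
        raise ValueError(f"Savitzky-Golay window must be odd, got {window}")
    if window <= polyorder:
        raise ValueError(
            f"window ({window}) must exceed polynomial order ({polyorder})"
        )
    if window > n_points:
        raise ValueError(
            f"window ({window}) exceeds number of points ({n_points})"
        )
    if deriv not in (0, 1, 2):
        raise ValueError(f"derivative order must be 0, 1 or 2, got {deriv}")
    out = savgol_filter(X, window, polyorder, deriv=deriv, delta=1.0, axis=1,
                        mode="interp")
    # Shrink-window refit at the edges (scipy's interp mode instead evaluates
    # the outermost full-window polynomial there).
    half = window // 2
    for i in range(half):
        for pos in (i, n_points - 1 - i):
            lo = max(0, pos - half)
            hi = min(n_points, pos + half + 1)
            t = np.arange(lo, hi) - pos
            V = np.vander(t, polyorder + 1, increasing=True)
            coef, *_ = np.linalg.lstsq(V, X[:, lo:hi].T, rcond=None)
            # d-th derivative at t=0 is d! * coef[d]
            out[:, pos] = coef[deriv] * math.factorial(deriv)
    return out


def mean_center_fit(X_cal) -> np.ndarray:
    """Column means of the calibration matrix."""
    return _as_matrix(X_cal).mean(axis=0)


def mean_center_apply(X, means) -> np.ndarray:
    """Subtract calibration column means (never the data's own means)."""
    X = _as_matrix(X)
    means = np.asarray(means, dtype=float).ravel()
    if means.size != X.shape[1]:
        raise ValueError(
            f"means length {means.size} does not match {X.shape[1]} points"
        )
    return X - means


# ---------------------------------------------------------------------------
# Pipelines
# ---------------------------------------------------------------------------

@dataclass
class PreprocessStep:
    """One operator in a chain, with its parameters and fitted state."""

    kind: str
    params: dict[str, Any] = field(default_factory=dict)
    fitted_state: dict[str, Any] | None = None

    _KINDS = ("detrend", "snv", "msc", "emsc", "savgol", "mean_center")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown preprocessing step kind {self.kind!r}")
        if self.kind == "savgol":
            w = self.params.get("window", 15)
            p = self.params.get("polyorder", 2)
            d = self.params.get("deriv", 1)
            if w % 2 == 0 or w <= p or d not in (0, 1, 2):
                raise ValueError(
                    f"invalid Savitzky-Golay parameters window={w}, "
                    f"polyorder={p}, deriv={d}"
                )

    @property
    def stateful(self) -> bool:
        return self.kind in ("msc", "emsc", "mean_center")

    def fit(self, X_cal: np.ndarray) -> None:
        if self.kind in ("msc", "emsc"):
            self.fitted_state = {"reference": _as_matrix(X_cal).mean(axis=0)}
        elif self.kind == "mean_center":
            self.fitted_state = {"means": mean_center_fit(X_cal)}
        else:
            self.fitted_state = {}

    def apply(self, X: np.ndarray) -> np.ndarray:
        if self.stateful and not self.fitted_state:
            raise RuntimeError(
                f"step {self.kind!r} must be fitted on calibration data "
                "before applying to new data"
            )
        if self.kind == "detrend":
            return detrend(X, order=self.params.get("order", 1))
        if self.kind == "snv":
            return snv(X)
        if self.kind == "msc":
            return msc(X, self.fitted_state["reference"])
        if self.kind == "emsc":
            return emsc(X, self.fitted_state["reference"],
                        order=self.params.get("order", 2))
        if self.kind == "savgol":
            return savgol(X, window=self.params.get("window", 15),
                          polyorder=self.params.get("polyorder", 2),
                          deriv=self.params.get("deriv", 1))
        return mean_center_apply(X, self.fitted_state["means"])

    def to_dict(self) -> dict[str, Any]:
        state = None
        if self.fitted_state is not None:
            state = {k: np.asarray(v).tolist()
                     for k, v in self.fitted_state.items()}
        return {"kind": self.kind, "params": dict(self.params), "fitted_state": state}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PreprocessStep":
        step = cls(kind=d["kind"], params=dict(d.get("params", {})))
        state = d.get("fitted_state")
        if state is not None:
            step.fitted_state = {k: np.asarray(v, dtype=float)
                                 for k, v in state.items()}
        return step


@dataclass
class PreprocessPipeline:
    """Ordered chain of steps with calibration-fitted state.

    ``fit_transform`` fits each state-bearing step on the (progressively
    transformed) calibration matrix; ``transform`` then applies the frozen
    chain to any matrix.  An empty chain is the identity.
    """

    steps: list[PreprocessStep] = field(default_factory=list)
    fitted: bool = False

    def clone_unfitted(self) -> "PreprocessPipeline":
        return PreprocessPipeline(
            steps=[PreprocessStep(kind=s.kind, params=dict(s.params))
                   for s in self.steps]
        )

    def fit_transform(self, X_cal) -> np.ndarray:
        X = _as_matrix(X_cal).copy()
        for step in self.steps:
            step.fit(X)
            X = step.apply(X)
        self.fitted = True
        return X

    def transform(self, X) -> np.ndarray:
        if not self.fitted and any(s.stateful for s in self.steps):
            raise RuntimeError(
                "pipeline must be fitted on calibration data before use"
            )
        X = _as_matrix(X).copy()
        for step in self.steps:
            X = step.apply(X)
        return X

    def to_dict(self) -> dict[str, Any]:
        return {"fitted": self.fitted,
                "steps": [s.to_dict() for s in self.steps]}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PreprocessPipeline":
        return cls(steps=[PreprocessStep.from_dict(s) for s in d["steps"]],
                   fitted=bool(d.get("fitted", False)))


def cultivar_chain(detrend_order: int = 1) -> PreprocessPipeline:
    """Detrend -> MSC(mean) -> SavGol(15, 2, 2nd derivative) -> mean centre."""
    return PreprocessPipeline(steps=[
        PreprocessStep("detrend", {"order": detrend_order}),
        PreprocessStep("msc"),
        PreprocessStep("savgol", {"window": 15, "polyorder": 2, "deriv": 2}),
        PreprocessStep("mean_center"),
    ])


def endophyte_chain(detrend_order: int = 1) -> PreprocessPipeline:
    """Detrend -> SNV -> SavGol(15, 2, 1st derivative) -> mean centre."""
    return PreprocessPipeline(steps=[
        PreprocessStep("detrend", {"order": detrend_order}),
        PreprocessStep("snv"),
        PreprocessStep("savgol", {"window": 15, "polyorder": 2, "deriv": 1}),
        PreprocessStep("mean_center"),
    ])


def fit_apply_pipeline(pipeline: PreprocessPipeline, X_cal, X_val=None):
    """Fit a chain on calibration data and apply it to validation data.

    Returns ``(X_cal_transformed, X_val_transformed)``; ``X_val`` may be
    ``None``, in which case the second element is ``None``.
    """
    Xc = pipeline.fit_transform(X_cal)
    Xv = pipeline.transform(X_val) if X_val is not None else None
    return Xc, Xv
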