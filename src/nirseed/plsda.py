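"""Binary PLS-DA, the error metrics, CV-based model selection and nesting.

Partial least squares discriminant analysis couples the spectral matrix
(X-block) to class membership codes (Y-block, here a single +/-1 column)
through a small number of latent variables.  The decomposition is NIPALS
for a univariate response: each latent variable's weight vector is the
covariance direction between the deflated X and the response, the score is
the projection onto it, and X alone is deflated — deterministic, and at
full rank exactly equivalent to ordinary least squares.

Class assignment thresholds the predicted response.  The default threshold
is the crossing point of two normal densities fitted to the calibration
predictions of the two classes (falling back to the midpoint of the class
means when no crossing lies between them); a fixed threshold of 0, the
midpoint of the +/-1 codes, is selectable.

Model quality is summarised by the per-class classification error

    class_error = 1 - (sensitivity + specificity) / 2,

the average of the false-positive and false-negative rates, and the overall
accuracy is reported as ``1 - class_error`` of the stated context
(calibration, cross-validation or prediction) — the convention under which
the headline accuracies of the reference workflow are exact complements of
the printed CV errors.

Multi-class problems are handled by *nested* class elimination: the easiest
class is modelled against the pool of all others, removed, and the process
repeats until a plain two-class model remains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocess import PreprocessPipeline
from .selection import CVFolds, venetian_blinds

__all__ = [
    "PLSFit",
    "BinaryPLSDAModel",
    "ClassificationReport",
    "NestedStep",
    "NestedSequence",
    "fit_pls",
    "decision_threshold",
    "classify",
    "evaluate",
    "evaluate_counts",
    "cross_validate",
    "select_lv",
    "fit_nested",
    "model_to_json",
    "model_from_json",
]

_RANK_TOL = 1e-12


@dataclass
class PLSFit:
    """NIPALS decomposition state for a univariate response."""

    x_weights: np.ndarray      # (p, k)
    x_loadings: np.ndarray     # (p, k)
    y_loadings: np.ndarray     # (k,)
    x_mean: np.ndarray         # (p,)
    y_mean: float
    n_lv: int

    def coefficients(self, n_lv: int | None = None) -> np.ndarray:
        """Regression coefficients using the first ``n_lv`` latent variables."""
        k = self.n_lv if n_lv is None else n_lv
        if not 1 <= k <= self.n_lv:
            raise ValueError(f"n_lv must be in [1, {self.n_lv}], got {k}")
        W = self.x_weights[:, :k]
        P = self.x_loadings[:, :k]
        q = self.y_loadings[:k]
        return W @ np.linalg.solve(P.T @ W, q)

    def predict(self, X, n_lv: int | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        b = self.coefficients(n_lv)
        return (X - self.x_mean) @ b + self.y_mean


def _nipals(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSFit:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("y length does not match number of rows of X")
    if n_lv < 1:
        raise ValueError(f"n_lv must be >= 1, got {n_lv}")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yc = y - y_mean
    scale = float(np.abs(Xd).max()) or 1.0

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros(n_lv)
    for k in range(n_lv):
        w = Xd.T @ yc
        nw = float(np.linalg.norm(w))
        if nw <= _RANK_TOL * scale * max(1.0, float(np.abs(yc).max() or 1.0)):
            raise ValueError(
                f"requested {n_lv} latent variables but the decomposition "
                f"is exhausted after {k} (X rank or Y variance attained)"
            )
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= (_RANK_TOL * scale) ** 2:
            raise ValueError(
                f"requested {n_lv} latent variables but the decomposition "
                f"is exhausted after {k} (degenerate score)"
            )
        pk = Xd.T @ t / tt
        qk = float(yc @ t) / tt
        Xd = Xd - np.outer(t, pk)
        W[:, k], P[:, k], Q[k] = w, pk, qk
    return PLSFit(x_weights=W, x_loadings=P, y_loadings=Q,
                  x_mean=x_mean, y_mean=y_mean, n_lv=n_lv)


@dataclass
class BinaryPLSDAModel:
    """A fitted binary PLS-DA classifier.

    ``class_map`` assigns original labels to the two sides: ``class1``
    labels are coded +1 in the response, ``class2`` labels -1.  Predicted
    responses at or above ``threshold`` are assigned to class1 (ties go to
    class1 by convention).  ``pipeline`` is the fitted pre-processing chain
    applied upstream of the coefficients; it may be ``None`` when the model
    operates on already-processed matrices.
    """

    fit: PLSFit
    class_map: dict[str, tuple[str, ...]]
    threshold: float
    class1_name: str
    class2_name: str
    pipeline: PreprocessPipeline | None = None

    @property
    def n_lv(self) -> int:
        return self.fit.n_lv

    @property
    def regression_coefficients(self) -> np.ndarray:
        return self.fit.coefficients()

    def predict_response(self, X, *, preprocessed: bool = True) -> np.ndarray:
        """Predicted response for rows of ``X`` (raw if a pipeline is set)."""
        X = np.asarray(X, dtype=float)
        if not preprocessed:
            if self.pipeline is None:
                raise RuntimeError("model has no pre-processing pipeline")
            X = self.pipeline.transform(X)
        return self.fit.predict(X)


def fit_pls(X_cal, y_cal, n_lv: int,
            class_map: dict[str, tuple[str, ...]] | None = None,
            class1_name: str = "class1", class2_name: str = "class2",
            pipeline: PreprocessPipeline | None = None,
            threshold_method: str = "gaussian") -> BinaryPLSDAModel:
    """Fit a binary PLS-DA model on pre-processed calibration data.

    ``y_cal`` holds +/-1 class codes (+1 = class1).  The decision threshold
    is derived from the calibration predictions (see
    :func:`decision_threshold`).
    """
    y = np.asarray(y_cal, dtype=float).ravel()
    uniq = np.unique(y)
    if uniq.size < 2:
        raise ValueError("both classes must be present in the calibration set")
    if not np.all(np.isin(uniq, (-1.0, 1.0))):
        raise ValueError("y must contain +/-1 class codes")
    fit = _nipals(X_cal, y, n_lv)
    preds = fit.predict(X_cal)
    threshold = decision_threshold(preds, y > 0, method=threshold_method)
    if class_map is None:
        class_map = {"class1": (class1_name,), "class2": (class2_name,)}
    return BinaryPLSDAModel(fit=fit, class_map=class_map, threshold=threshold,
                            class1_name=class1_name, class2_name=class2_name,
                            pipeline=pipeline)


def decision_threshold(cal_predictions, cal_is_class1,
                       method: str = "gaussian") -> float:
    """Decision value separating the two classes on the response scale.

    ``"gaussian"`` fits one normal per class to the calibration predictions
    and returns the density-crossing point between the class means; if no
    crossing lies between the means (or a class has fewer than 2 values or
    zero spread) it falls back to the midpoint of the class means.
    ``"zero"`` returns the fixed midpoint of the +/-1 codes.
    """
    if method == "zero":
        return 0.0
    if method != "gaussian":
        raise ValueError(f"unknown threshold method {method!r}")
    preds = np.asarray(cal_predictions, dtype=float).ravel()
    mask = np.asarray(cal_is_class1, dtype=bool).ravel()
    p1, p2 = preds[mask], preds[~mask]
    if p1.size == 0 or p2.size == 0:
        raise ValueError("both classes are needed to derive a threshold")
    m1, m2 = float(p1.mean()), float(p2.mean())
    midpoint = 0.5 * (m1 + m2)
    if p1.size < 2 or p2.size < 2:
        return midpoint
    s1, s2 = float(p1.std(ddof=1)), float(p2.std(ddof=1))
    if s1 < 1e-12 or s2 < 1e-12:
        return midpoint
    lo, hi = (m1, m2) if m1 <= m2 else (m2, m1)
    if abs(s1 - s2) < 1e-12 * max(s1, s2):
        return midpoint
    # Crossing of two normal densities: quadratic in x.
    a = 0.5 / s2**2 - 0.5 / s1**2
    b = m1 / s1**2 - m2 / s2**2
    c = m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2) + np.log(s2 / s1)
    roots = np.roots([a, b, c])
    real = roots[np.abs(roots.imag) < 1e-9].real
    inside = real[(real >= lo) & (real <= hi)]
    if inside.size == 0:
        return midpoint
    # Pick the crossing nearest the midpoint when both roots fall inside.
    return float(inside[np.argmin(np.abs(inside - midpoint))])


def classify(model: BinaryPLSDAModel, X_new, *,
             preprocessed: bool = True) -> np.ndarray:
    """Assign class1/class2 names; responses >= threshold go to class1."""
    resp = model.predict_response(X_new, preprocessed=preprocessed)
    return np.where(resp >= model.threshold, model.class1_name,
                    model.class2_name)


@dataclass
class ClassificationReport:
    """2x2 confusion summary with the class-error metric.

    ``confusion`` is ``[[TP, FN], [FP, TN]]`` with class1 as positive.
    ``class_error = 1 - (sensitivity + specificity)/2`` and
    ``overall_accuracy = 1 - class_error`` in the stated context.
    """

    confusion: np.ndarray
    sensitivity: float
    specificity: float
    class_error: float
    overall_accuracy: float
    context: str

    def as_dict(self) -> dict:
        return {
            "tp": int(self.confusion[0, 0]), "fn": int(self.confusion[0, 1]),
            "fp": int(self.confusion[1, 0]), "tn": int(self.confusion[1, 1]),
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "class_error": self.class_error,
            "overall_accuracy": self.overall_accuracy,
            "context": self.context,
        }


_CONTEXTS = ("calibration", "cross-validation", "prediction")


def evaluate_counts(tp: int, fn: int, fp: int, tn: int,
                    context: str = "prediction") -> ClassificationReport:
    """Build a report directly from confusion-matrix counts."""
    if context not in _CONTEXTS:
        raise ValueError(f"context must be one of {_CONTEXTS}, got {context!r}")
    if min(tp, fn, fp, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fn == 0 or fp + tn == 0:
        raise ValueError("both classes must be present in the truth labels")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    err = 1.0 - (sens + spec) / 2.0
    return ClassificationReport(
        confusion=np.array([[tp, fn], [fp, tn]], dtype=int),
        sensitivity=sens, specificity=spec, class_error=err,
        overall_accuracy=1.0 - err, context=context,
    )


def evaluate(y_true, y_pred, context: str = "prediction",
             positive=None) -> ClassificationReport:
    """Score predictions against truth for a binary problem.

    ``y_true``/``y_pred`` are either boolean arrays (True = class1) or label
    arrays, in which case ``positive`` names the class1 label (or a set of
    labels pooled as class1).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    if y_true.dtype == bool and y_pred.dtype == bool:
        t, p = y_true, y_pred
    else:
        if positive is None:
            raise ValueError("positive label(s) required for non-boolean input")
        pos = (positive,) if isinstance(positive, str) else tuple(positive)
        t = np.isin(y_true, pos)
        p = np.isin(y_pred, pos)
    tp = int(np.sum(t & p))
    fn = int(np.sum(t & ~p))
    fp = int(np.sum(~t & p))
    tn = int(np.sum(~t & ~p))
    return evaluate_counts(tp, fn, fp, tn, context=context)


# ---------------------------------------------------------------------------
# Cross-validation and latent-variable selection
# ---------------------------------------------------------------------------

def _cv_prediction_curve(X, y, folds: CVFolds,
                         pipeline: PreprocessPipeline | None,
                         max_lv: int) -> np.ndarray:
    """Held-out class1 predictions for every LV count 1..max_lv.

    Returns a boolean matrix (max_lv, n): entry [k-1, i] is the CV-predicted
    class1 membership of scan i using k latent variables.  Pre-processing
    state is refitted inside every fold on the retained scans only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    out = np.zeros((max_lv, n), dtype=bool)
    for fold in range(folds.n_splits):
        test = folds.fold_indices(fold)
        train = np.setdiff1d(np.arange(n), test)
        Xtr, Xte = X[train], X[test]
        if pipeline is not None:
            pipe = pipeline.clone_unfitted()
            Xtr = pipe.fit_transform(Xtr)
            Xte = pipe.transform(Xte)
        fit = _nipals(Xtr, y[train], max_lv)
        for k in range(1, max_lv + 1):
            cal_pred = fit.predict(Xtr, n_lv=k)
            thr = decision_threshold(cal_pred, y[train] > 0)
            out[k - 1, test] = fit.predict(Xte, n_lv=k) >= thr
    return out


def _max_usable_lv(X, y, folds: CVFolds,
                   pipeline: PreprocessPipeline | None, max_lv: int) -> int:
    """Largest LV count attainable in every CV fold (and in the full fit)."""
    n, p = np.asarray(X).shape
    smallest_train = min(
        int(np.sum(folds.assignment != f)) for f in range(folds.n_splits)
    )
    return max(1, min(max_lv, smallest_train - 1, p))


def cross_validate(X, y, folds: CVFolds,
                   pipeline: PreprocessPipeline | None,
                   n_lv: int) -> ClassificationReport:
    """Venetian-blinds CV: pool every fold's held-out predictions.

    Each fold refits the pre-processing state and the PLS decomposition on
    the retained scans only, then predicts the held-out blind; every scan is
    predicted exactly once and the pooled predictions are scored in the
    cross-validation context.
    """
    y = np.asarray(y, dtype=float).ravel()
    preds = _cv_prediction_curve(X, y, folds, pipeline, n_lv)[n_lv - 1]
    return evaluate(y > 0, preds, context="cross-validation")


def select_lv(X, y, folds: CVFolds,
              pipeline: PreprocessPipeline | None,
              max_lv: int = 10) -> tuple[int, np.ndarray]:
    """Choose the LV count minimising the CV class error (ties -> fewer LVs).

    Returns ``(n_lv, errors)`` where ``errors[k-1]`` is the CV class error
    with ``k`` latent variables.
    """
    y = np.asarray(y, dtype=float).ravel()
    max_lv = _max_usable_lv(X, y, folds, pipeline, max_lv)
    curve = _cv_prediction_curve(X, y, folds, pipeline, max_lv)
    truth = y > 0
    errors = np.array([
        evaluate(truth, curve[k], context="cross-validation").class_error
        for k in range(max_lv)
    ])
    best = int(np.argmin(errors)) + 1  # argmin takes the first (fewest LVs)
    return best, errors


# ---------------------------------------------------------------------------
# Nested class elimination
# ---------------------------------------------------------------------------

@dataclass
class NestedStep:
    """One elimination step: ``target`` vs the pooled remaining classes."""

    target: str
    pool: tuple[str, ...]
    model: BinaryPLSDAModel
    cv_report: ClassificationReport
    cal_report: ClassificationReport


@dataclass
class NestedSequence:
    """Ordered binary models implementing a multi-class elimination scheme."""

    steps: list[NestedStep]
    elimination_order: tuple[str, ...]

    def __post_init__(self) -> None:
        for i, step in enumerate(self.steps):
            for later in self.steps[i + 1:]:
                if step.target in later.pool or step.target == later.target:
                    raise ValueError(
                        f"class {step.target!r} reappears after its "
                        "elimination step"
                    )


def fit_nested(X, labels, order: Sequence[str] | None,
               folds_template: CVFolds,
               pipeline: PreprocessPipeline,
               max_lv: int = 10,
               threshold_method: str = "gaussian") -> NestedSequence:
    """Fit a nested sequence of binary PLS-DA models on raw spectra.

    Step ``k`` models ``order[k]`` (class1, coded +1) against the pooled
    remaining classes, then drops the target's scans from the working set;
    the final step is the plain two-class model between the last two
    classes.  The LV count of every step is chosen by venetian-blinds CV
    (fold geometry taken from ``folds_template``, re-laid on each working
    subset in recorded order), and each step's model is refitted on the
    whole working set at the chosen count with its own fitted copy of the
    pre-processing chain.

    ``order=None`` chooses the elimination order greedily: at each level the
    candidate class whose model against the pooled rest attains the lowest
    CV class error is eliminated first.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    observed = sorted(set(labels.tolist()))
    if len(observed) < 2:
        raise ValueError("need at least two classes")

    auto = order is None
    if not auto:
        order = list(order)
        if sorted(order) != observed:
            raise ValueError(
                f"order {order!r} is not a permutation of the observed "
                f"classes {observed!r}"
            )

    work = np.arange(X.shape[0])
    remaining = list(observed) if auto else list(order)
    steps: list[NestedStep] = []
    chosen_order: list[str] = []

    def _fit_step(target: str, pool: list[str], idx: np.ndarray):
        Xw = X[idx]
        yw = np.where(labels[idx] == target, 1.0, -1.0)
        folds = venetian_blinds(len(idx), folds_template.n_splits,
                                folds_template.blind_width)
        pipe = pipeline.clone_unfitted()
        n_lv, errors = select_lv(Xw, yw, folds, pipe, max_lv=max_lv)
        cv_preds = _cv_prediction_curve(Xw, yw, folds, pipe, n_lv)[n_lv - 1]
        cv_report = evaluate(yw > 0, cv_preds, context="cross-validation")
        pipe = pipeline.clone_unfitted()
        Xp = pipe.fit_transform(Xw)
        model = fit_pls(Xp, yw, n_lv, class1_name=target,
                        class2_name="+".join(pool),
                        class_map={"class1": (target,), "class2": tuple(pool)},
                        pipeline=pipe, threshold_method=threshold_method)
        cal_pred = classify(model, Xp)
        cal_report = evaluate(yw > 0, cal_pred == target, context="calibration")
        return model, cv_report, cal_report

    while len(remaining) > 2:
        if auto:
            scored = []
            for cand in remaining:
                pool = [c for c in remaining if c != cand]
                _, errors = select_lv(
                    X[work], np.where(labels[work] == cand, 1.0, -1.0),
                    venetian_blinds(len(work), folds_template.n_splits,
                                    folds_template.blind_width),
                    pipeline.clone_unfitted(), max_lv=max_lv)
                scored.append((float(errors.min()), cand))
            target = min(scored)[1]
        else:
            target = remaining[0]
        pool = [c for c in remaining if c != target]
        model, cv_report, cal_report = _fit_step(target, pool, work)
        steps.append(NestedStep(target=target, pool=tuple(pool), model=model,
                                cv_report=cv_report, cal_report=cal_report))
        chosen_order.append(target)
        remaining = pool
        work = work[labels[work] != target]

    # Final plain two-class model.
    first, second = remaining
    model, cv_report, cal_report = _fit_step(first, [second], work)
    steps.append(NestedStep(target=first, pool=(second,), model=model,
                            cv_report=cv_report, cal_report=cal_report))
    chosen_order.extend([first, second])
    return NestedSequence(steps=steps, elimination_order=tuple(chosen_order))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def model_to_json(model: BinaryPLSDAModel) -> str:
    """Serialise a fitted model (with its pipeline state) to JSON."""
    doc = {
        "format_version": _FORMAT_VERSION,
        "n_lv": model.n_lv,
        "x_weights": model.fit.x_weights.tolist(),
        "x_loadings": model.fit.x_loadings.tolist(),
        "y_loadings": model.fit.y_loadings.tolist(),
        "x_mean": model.fit.x_mean.tolist(),
        "y_mean": model.fit.y_mean,
        "threshold": model.threshold,
        "class_map": {k: list(v) for k, v in model.class_map.items()},
        "class1_name": model.class1_name,
        "class2_name": model.class2_name,
        "pipeline": model.pipeline.to_dict() if model.pipeline else None,
    }
    return json.dumps(doc)


def model_from_json(text: str) -> BinaryPLSDAModel:
    doc = json.loads(text)
    if doc.get("format_version") != _FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {doc.get('format_version')!r}"
        )
    fit = PLSFit(
        x_weights=np.asarray(doc["x_weights"], dtype=float),
        x_loadings=np.asarray(doc["x_loadings"], dtype=float),
        y_loadings=np.asarray(doc["y_loadings"], dtype=float),
        x_mean=np.asarray(doc["x_mean"], dtype=float),
        y_mean=float(doc["y_mean"]),
        n_lv=int(doc["n_lv"]),
    )
    pipeline = None
    if doc.get("pipeline") is not None:
        pipeline = PreprocessPipeline.from_dict(doc["pipeline"])
    return BinaryPLSDAModel(
        fit=fit,
        class_map={k: tuple(v) for k, v in doc["class_map"].items()},
        threshold=float(doc["threshold"]),
        class1_name=doc["class1_name"],
        class2_name=doc["class2_name"],
        pipeline=pipeline,
    )
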