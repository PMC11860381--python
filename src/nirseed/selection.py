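"""Sample selection, cross-validation folds and outlier screening.

Three pieces of infrastructure around the classifiers:

* :func:`kennard_stone` — deterministic max-min Euclidean-distance selection
  of a representative calibration subset (75% by default), the remainder
  becoming the validation set.
* :func:`venetian_blinds` — interleaved cross-validation folds ("10 data
  slits, one sample per blind"): scan at position ``i`` of the dataset's
  recorded random ordering goes to fold ``(i // blind_width) % n_splits``.
* :func:`q_residual_outliers` — PCA reconstruction-error (Q residual)
  screening of anomalous scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SplitResult",
    "CVFolds",
    "OutlierReport",
    "kennard_stone",
    "venetian_blinds",
    "q_residual_outliers",
]


@dataclass(frozen=True)
class SplitResult:
    """Disjoint calibration/validation index sets covering all scans."""

    calibration_indices: np.ndarray
    validation_indices: np.ndarray
    fraction: float

    def __post_init__(self) -> None:
        cal = set(self.calibration_indices.tolist())
        val = set(self.validation_indices.tolist())
        if cal & val:
            raise ValueError("calibration and validation sets overlap")


def kennard_stone(X, fraction: float = 0.75,
                  groups=None) -> SplitResult:
    """Kennard-Stone max-min selection of a calibration subset.

    The first two selections are the pair of points at maximum Euclidean
    distance; each subsequent selection maximises its minimum distance to
    the already-selected set.  Fully deterministic; distance ties are broken
    by the lowest index.  ``round(fraction * n)`` points go to calibration.

    ``groups`` (optional, e.g. bag ids) switches to group-aware selection:
    whole groups are selected on their mean spectra, so scans from one bag
    never straddle the split.  Off by default — the standard workflow splits
    scan-wise, which places sub-samples of one bag on both sides (a known
    leakage caveat of the design).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n = X.shape[0]
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")

    if groups is not None:
        groups = np.asarray(groups)
        uniq, inverse = np.unique(groups, return_inverse=True)
        means = np.vstack([X[inverse == g].mean(axis=0)
                           for g in range(uniq.size)])
        inner = kennard_stone(means, fraction=fraction)
        cal_groups = set(inner.calibration_indices.tolist())
        cal_mask = np.isin(inverse, list(cal_groups))
        return SplitResult(
            calibration_indices=np.flatnonzero(cal_mask),
            validation_indices=np.flatnonzero(~cal_mask),
            fraction=fraction,
        )

    if n < 2:
        raise ValueError("Kennard-Stone needs at least 2 samples")
    n_cal = int(round(fraction * n))
    n_cal = max(1, min(n_cal, n - 1))

    # Pairwise squared distances via the Gram matrix; n is at most ~1e3 here.
    sq = np.einsum("ij,ij->i", X, X)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, -np.inf)
    # Farthest pair, ties broken by the lexicographically smallest (i, j).
    flat = np.argmax(d2)  # argmax returns the first (lowest) flat index on ties
    i, j = divmod(int(flat), n)
    first, second = min(i, j), max(i, j)

    selected = [first]
    np.fill_diagonal(d2, np.inf)
    min_d2 = d2[first].copy()
    if n_cal >= 2:
        selected.append(second)
        min_d2 = np.minimum(min_d2, d2[second])
    while len(selected) < n_cal:
        min_d2[selected] = -np.inf
        nxt = int(np.argmax(min_d2))  # first index on ties
        selected.append(nxt)
        min_d2 = np.minimum(min_d2, d2[nxt])

    cal = np.array(sorted(selected), dtype=int)
    val = np.setdiff1d(np.arange(n), cal)
    return SplitResult(calibration_indices=cal, validation_indices=val,
                       fraction=fraction)


@dataclass(frozen=True)
class CVFolds:
    """Venetian-blinds fold assignment: one fold label per scan."""

    n_splits: int
    blind_width: int
    assignment: np.ndarray

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)


def venetian_blinds(n: int, n_splits: int = 10,
                    blind_width: int = 1) -> CVFolds:
    """Interleaved CV folds over ``n`` scans in their recorded order.

    Scan ``i`` is assigned fold ``(i // blind_width) % n_splits``; with the
    default one sample per blind this is simply ``i mod n_splits``, giving
    fold sizes that differ by at most one.
    """
    if n_splits < 2:
        raise ValueError(f"need at least 2 splits, got {n_splits}")
    if blind_width < 1:
        raise ValueError(f"blind width must be >= 1, got {blind_width}")
    if n < n_splits:
        raise ValueError(
            f"cannot form {n_splits} venetian-blind folds from {n} scans"
        )
    assignment = (np.arange(n) // blind_width) % n_splits
    return CVFolds(n_splits=n_splits, blind_width=blind_width,
                   assignment=assignment)


@dataclass
class OutlierReport:
    """Q residuals, decision threshold and the flagged scan indices."""

    q_residuals: np.ndarray
    threshold: float
    flagged: np.ndarray
    n_components: int
    threshold_method: str = "chi2-moment"
    warnings: list[str] = field(default_factory=list)


def _robust_noise_sd(X: np.ndarray) -> np.ndarray:
    """Per-scan noise sd from the median absolute successive difference.

    For smooth spectra plus white noise, successive differences are
    dominated by the noise (sd ``sqrt(2)*sigma``); the median makes the
    estimate immune to narrow artefacts such as spikes.
    """
    diffs = np.abs(np.diff(X, axis=1))
    mad = np.median(diffs, axis=1)
    return 1.4826 * mad / np.sqrt(2.0)


def q_residual_outliers(X, n_components: int = 5,
                        confidence: float = 0.99,
                        threshold_method: str = "chi2-moment",
                        scale: str = "noise") -> OutlierReport:
    """Flag scans whose PCA reconstruction error (Q residual) is unusual.

    A principal-component model of rank ``n_components`` is fitted to the
    column-centred matrix; each scan's Q residual is its squared
    reconstruction error.  With the default ``scale="noise"`` the statistic
    is studentized: each Q is divided by a robust per-scan noise variance
    (median absolute successive difference), so scans whose noise floor
    differs — e.g. after scatter normalisation rescales each spectrum — are
    screened on a common footing; ``scale="none"`` keeps raw Q.

    The decision threshold at ``confidence`` is, by default, the upper
    quantile of a moment-matched ``g * chi2_h`` approximation to the
    statistic's distribution (mean/variance matching), the standard
    residual-statistic approximation in chemometrics; it degrades
    gracefully when gross outliers inflate the variance, flagging only the
    genuinely extreme scans.  ``threshold_method="percentile"`` uses the
    empirical quantile instead (which by construction flags about
    ``1 - confidence`` of the scans even when none are anomalous).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= n_components < min(n, p):
        raise ValueError(
            f"n_components must be in [1, {min(n, p) - 1}], got {n_components}"
        )
    warnings: list[str] = []
    Xc = X - X.mean(axis=0)
    # Economy SVD; scores/loadings beyond the data rank carry ~zero energy.
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_components >= rank:
        warnings.append(
            f"PCA rank is {rank} <= n_components={n_components}; "
            "all Q residuals are ~0"
        )
    V = Vt[:n_components].T
    resid = Xc - (Xc @ V) @ V.T
    q = np.einsum("ij,ij->i", resid, resid)
    if scale == "noise":
        noise_var = _robust_noise_sd(X) ** 2
        floor = max(float(noise_var.max()) * 1e-9, 1e-300)
        q = q / np.maximum(noise_var, floor)
    elif scale != "none":
        raise ValueError(f"unknown scale {scale!r}")

    if threshold_method == "percentile":
        threshold = float(np.quantile(q, confidence))
    elif threshold_method == "chi2-moment":
        # ``confidence`` is family-wise: the probability, under the fitted
        # moment model, that NO nominal scan is flagged.  A per-scan
        # quantile would by design flag ~(1-confidence) of clean scans
        # (~8 of 810 at 0.99), which is not how gross-outlier screening is
        # used; the Sidak-adjusted quantile flags only scans incompatible
        # with the whole batch.
        m = float(q.mean())
        v = float(q.var(ddof=1)) if n > 1 else 0.0
        if m <= 0 or v <= 0:
            threshold = 0.0
        else:
            g = v / (2.0 * m)
            h = 2.0 * m * m / v
            per_scan = confidence ** (1.0 / n)
            threshold = float(g * stats.chi2.ppf(per_scan, h))
    else:
        raise ValueError(f"unknown threshold method {threshold_method!r}")

    flagged = np.flatnonzero(q > threshold)
    return OutlierReport(q_residuals=q, threshold=threshold, flagged=flagged,
                         n_components=n_components,
                         threshold_method=threshold_method, warnings=warnings)
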