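"""End-to-end training/evaluation flows over a labelled spectra set.

Each flow reproduces the standard modelling protocol: trim to the
9000-3952 cm^-1 analysis window, Kennard-Stone 75/25 calibration/validation
split on the task's pre-processed spectra, venetian-blinds CV (10 slits,
one sample per blind) for latent-variable selection, then the fitted
decision tree and its validation report.

* :func:`train_cultivar` — nested elimination over the four cultivars
  (default order Maxsyn, Alto, Bronsyn, Trojan) under the cultivar chain,
  chained into a depth-3 tree.
* :func:`train_endophyte` — one E+/E- model per cultivar under the
  endophyte chain, each on its own per-task split.
* :func:`train_combined` — grafts the endophyte trees onto the cultivar
  tree's terminals.
* :func:`bag_report` — 4-of-6 majority voting over a tree's scan labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hierarchy import (HierarchyNode, aggregate_bags, build_cultivar_tree,
                        build_endophyte_tree, classify_tree, combine,
                        misclassification_table)
from .plsda import (BinaryPLSDAModel, ClassificationReport, NestedSequence,
                    classify, cross_validate, evaluate, fit_nested, fit_pls,
                    select_lv)
from .preprocess import cultivar_chain, endophyte_chain
from .selection import SplitResult, kennard_stone, venetian_blinds
from .spectra import CULTIVARS, SpectraSet, trim

__all__ = [
    "ANALYSIS_WINDOW",
    "DEFAULT_CULTIVAR_ORDER",
    "CultivarResult",
    "EndophyteResult",
    "CombinedResult",
    "train_cultivar",
    "train_endophyte",
    "train_combined",
    "bag_report",
    "screen_outliers",
]

ANALYSIS_WINDOW = (9000.0, 3952.0)
DEFAULT_CULTIVAR_ORDER = ("Maxsyn", "Alto", "Bronsyn", "Trojan")

#: PCA rank for Q-residual screening: the strong between-class structure
#: directions of scatter-corrected seed spectra; weaker bag-level variation
#: stays in the residual, where it is dwarfed by genuine artefacts.
SCREENING_COMPONENTS = 3


def screen_outliers(spectra: SpectraSet,
                    n_components: int = SCREENING_COMPONENTS,
                    confidence: float = 0.99):
    """Q-residual screening of a scan set, the pre-treatment-stage QC step.

    Scans are trimmed to the analysis window and scatter-corrected
    (detrend + SNV) so that the PCA model captures chemistry rather than
    packing artefacts, then screened on noise-studentized Q residuals (see
    :func:`nirseed.selection.q_residual_outliers`).  Returns the
    ``OutlierReport`` and the cleaned :class:`SpectraSet` with flagged
    scans removed.
    """
    from .preprocess import detrend as _detrend, snv as _snv
    from .selection import q_residual_outliers

    s = _prepare(spectra)
    Xp = _snv(_detrend(s.absorbance, 1))
    report = q_residual_outliers(Xp, n_components=n_components,
                                 confidence=confidence)
    keep = np.setdiff1d(np.arange(s.n_scans), report.flagged)
    return report, s.subset(keep)


def _prepare(spectra: SpectraSet) -> SpectraSet:
    high, low = ANALYSIS_WINDOW
    if spectra.grid.high > high or spectra.grid.low < low:
        return trim(spectra, high, low)
    return spectra


def _split(X: np.ndarray, pipeline_factory, fraction: float) -> SplitResult:
    # Kennard-Stone operates on the same representation the model sees:
    # the task's pre-processed spectra (chain fitted on the full set just
    # for the split geometry; modelling refits on calibration only).
    pipe = pipeline_factory()
    Xp = pipe.fit_transform(X)
    return kennard_stone(Xp, fraction)


@dataclass
class CultivarResult:
    """Nested cultivar models, their tree and the validation report."""

    spectra: SpectraSet
    split: SplitResult
    sequence: NestedSequence
    tree: HierarchyNode
    validation_labels: np.ndarray
    validation_predictions: np.ndarray
    validation_accuracy: float
    miss_table: pd.DataFrame


def train_cultivar(spectra: SpectraSet,
                   order=DEFAULT_CULTIVAR_ORDER,
                   fraction: float = 0.75,
                   n_splits: int = 10, blind_width: int = 1,
                   max_lv: int = 10,
                   detrend_order: int = 1) -> CultivarResult:
    """Fit the nested cultivar pipeline and score the held-out scans."""
    s = _prepare(spectra)
    X = s.absorbance
    labels = s.cultivars()
    split = _split(X, lambda: cultivar_chain(detrend_order), fraction)
    cal, val = split.calibration_indices, split.validation_indices
    folds = venetian_blinds(len(cal), n_splits, blind_width)
    sequence = fit_nested(
        X[cal], labels[cal], list(order) if order is not None else None,
        folds, cultivar_chain(detrend_order), max_lv=max_lv)
    tree = build_cultivar_tree(sequence)
    preds = classify_tree(tree, X[val])
    acc = float(np.mean(preds == labels[val]))
    return CultivarResult(
        spectra=s, split=split, sequence=sequence, tree=tree,
        validation_labels=labels[val], validation_predictions=preds,
        validation_accuracy=acc,
        miss_table=misclassification_table(labels[val], preds))


@dataclass
class EndophyteResult:
    """Per-cultivar E+/E- models with their trees and reports."""

    models: dict[str, BinaryPLSDAModel]
    trees: dict[str, HierarchyNode]
    cv_reports: dict[str, ClassificationReport]
    prediction_reports: dict[str, ClassificationReport]
    splits: dict[str, SplitResult]


def train_endophyte(spectra: SpectraSet,
                    cultivars=CULTIVARS,
                    fraction: float = 0.75,
                    n_splits: int = 10, blind_width: int = 1,
                    max_lv: int = 10,
                    detrend_order: int = 1) -> EndophyteResult:
    """Fit one E+ vs E- model per cultivar, each on its own 75/25 split."""
    s = _prepare(spectra)
    X = s.absorbance
    labels = s.cultivars()
    status = s.statuses()
    models, trees, cv_reports, pred_reports, splits = {}, {}, {}, {}, {}
    for cultivar in cultivars:
        idx = np.flatnonzero(labels == cultivar)
        if idx.size == 0:
            continue
        Xc = X[idx]
        y = np.where(status[idx] == "E+", 1.0, -1.0)
        if np.unique(y).size < 2:
            raise ValueError(
                f"{cultivar}: both E+ and E- bags are needed to fit an "
                "endophyte model")
        split = _split(Xc, lambda: endophyte_chain(detrend_order), fraction)
        cal, val = split.calibration_indices, split.validation_indices
        # Per-task split may strand the minority class entirely in one
        # half; re-split at the same fraction on a reshuffled KS ranking is
        # not deterministic, so fall back to the full set for calibration.
        if np.unique(y[cal]).size < 2:
            cal = np.arange(idx.size)
            val = np.arange(idx.size)
        folds = venetian_blinds(len(cal), n_splits, blind_width)
        pipe = endophyte_chain(detrend_order)
        n_lv, _ = select_lv(Xc[cal], y[cal], folds, pipe.clone_unfitted(),
                            max_lv=max_lv)
        cv_reports[cultivar] = cross_validate(
            Xc[cal], y[cal], folds, pipe.clone_unfitted(), n_lv)
        fitted_pipe = pipe.clone_unfitted()
        Xp = fitted_pipe.fit_transform(Xc[cal])
        model = fit_pls(Xp, y[cal], n_lv,
                        class1_name=f"{cultivar} E+",
                        class2_name=f"{cultivar} E-",
                        class_map={"class1": ("E+",), "class2": ("E-",)},
                        pipeline=fitted_pipe)
        models[cultivar] = model
        trees[cultivar] = build_endophyte_tree(model, cultivar)
        if np.unique(y[val]).size == 2:
            val_pred = classify(model, fitted_pipe.transform(Xc[val]))
            pred_reports[cultivar] = evaluate(
                y[val] > 0, val_pred == f"{cultivar} E+",
                context="prediction")
        splits[cultivar] = SplitResult(
            calibration_indices=idx[cal], validation_indices=idx[val],
            fraction=fraction) if not np.array_equal(cal, val) else None
    return EndophyteResult(models=models, trees=trees, cv_reports=cv_reports,
                           prediction_reports=pred_reports, splits=splits)


@dataclass
class CombinedResult:
    """Combined cultivar+endophyte tree with its per-scan labels."""

    tree: HierarchyNode
    cultivar: CultivarResult
    endophyte: EndophyteResult


def train_combined(spectra: SpectraSet, **kwargs) -> CombinedResult:
    """Train the five trees and graft them into the single combined model."""
    cultivar = train_cultivar(spectra, **kwargs)
    endophyte = train_endophyte(spectra, **{
        k: v for k, v in kwargs.items() if k != "order"})
    tree = combine(cultivar.tree, endophyte.trees)
    return CombinedResult(tree=tree, cultivar=cultivar, endophyte=endophyte)


def bag_report(tree: HierarchyNode, spectra: SpectraSet,
               truth_fn=None, vote_threshold: int = 4,
               scans_per_bag: int = 6) -> pd.DataFrame:
    """Per-bag majority-vote table for a tree over a scan set.

    ``truth_fn`` maps a ScanMetadata record to the bag's true terminal
    label (default: the cultivar); the returned frame has one row per bag
    with the voted label, vote count and correctness.
    """
    s = _prepare(spectra)
    if truth_fn is None:
        truth_fn = lambda m: m.cultivar  # noqa: E731
    labels = classify_tree(tree, s)
    bags = aggregate_bags(s.bag_ids(), labels,
                          vote_threshold=vote_threshold,
                          scans_per_bag=scans_per_bag)
    truth = {}
    for m in s.metadata:
        truth.setdefault(m.bag_id, truth_fn(m))
    return pd.DataFrame({
        "bag_id": [b.bag_id for b in bags],
        "majority_label": [b.majority_label for b in bags],
        "votes": [b.votes for b in bags],
        "true_label": [truth[b.bag_id] for b in bags],
        "correct": [b.majority_label == truth[b.bag_id] for b in bags],
    })
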