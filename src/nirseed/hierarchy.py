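"""Hierarchical classification trees and bag-level majority voting.

A hierarchy node holds one fitted binary PLS-DA model (with its own
pre-processing chain) and two branches: hitting class1 routes a scan to
that branch, class2 to the other; a branch is either a terminal label or a
child node.  A scan that cannot be processed at a node (for instance a
degenerate spectrum rejected by a pre-processing step, or a non-finite
prediction) takes the "otherwise" exit and is labelled ``Unclassified``
instead of raising.

The cultivar tree chains the nested elimination steps: rule 1 is the
first-step model (easiest cultivar vs the pooled rest), its class2 branch
leads to rule 2, and so on until the final two-class rule — depth 3 for the
four-cultivar problem.  Each cultivar then gets a one-rule endophyte tree
(E+ vs E-), and the combined tree replaces every cultivar terminal with
that cultivar's endophyte tree, yielding the eight (cultivar, status)
terminals in a single model.

Because every bag of seeds is scanned six times, scan-level labels are
aggregated per bag by majority vote: the modal label is accepted only if it
reaches the vote threshold (default 4 of 6), otherwise the bag is reported
``Inconclusive`` rather than force-assigned.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from math import ceil
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .plsda import BinaryPLSDAModel, NestedSequence
from .spectra import SpectraSet

__all__ = [
    "UNCLASSIFIED",
    "INCONCLUSIVE",
    "HierarchyNode",
    "BagPrediction",
    "build_cultivar_tree",
    "build_endophyte_tree",
    "combine",
    "classify_tree",
    "aggregate_bag",
    "aggregate_bags",
    "misclassification_table",
]

UNCLASSIFIED = "Unclassified"
INCONCLUSIVE = "Inconclusive"

Branch = Union[str, "HierarchyNode"]


@dataclass
class HierarchyNode:
    """One rule of the decision tree: a binary model plus two branches."""

    model: BinaryPLSDAModel
    branch_class1: Branch
    branch_class2: Branch
    name: str = ""
    otherwise_label: str = UNCLASSIFIED

    def terminals(self) -> list[str]:
        """All terminal labels reachable from this node (no duplicates)."""
        out: list[str] = []
        for branch in (self.branch_class1, self.branch_class2):
            if isinstance(branch, HierarchyNode):
                out.extend(branch.terminals())
            else:
                out.append(branch)
        seen: set[str] = set()
        return [x for x in out if not (x in seen or seen.add(x))]

    def depth(self) -> int:
        child_depths = [
            b.depth() for b in (self.branch_class1, self.branch_class2)
            if isinstance(b, HierarchyNode)
        ]
        return 1 + max(child_depths, default=0)


def build_cultivar_tree(sequence: NestedSequence) -> HierarchyNode:
    """Chain nested elimination steps into a decision tree.

    Step k's model becomes rule k; its class1 branch is the step's target
    cultivar and its class2 branch descends to rule k+1.  The final rule's
    class2 branch is the last remaining cultivar.
    """
    if not sequence.steps:
        raise ValueError("nested sequence has no steps")
    node: Branch = sequence.steps[-1].pool[0]  # last remaining class
    for k in reversed(range(len(sequence.steps))):
        step = sequence.steps[k]
        node = HierarchyNode(
            model=step.model,
            branch_class1=step.target,
            branch_class2=node,
            name=f"rule {k + 1}: {step.target} vs "
                 f"{'+'.join(step.pool)}",
        )
    return node


def build_endophyte_tree(model: BinaryPLSDAModel,
                         cultivar: str) -> HierarchyNode:
    """Single-rule tree deciding E+/E- within one cultivar.

    Terminal labels carry the cultivar prefix ("<cultivar> E+"/"... E-") so
    combined-tree terminals are unambiguous.  The model's class1 side must
    be the E+ labels.
    """
    return HierarchyNode(
        model=model,
        branch_class1=f"{cultivar} E+",
        branch_class2=f"{cultivar} E-",
        name=f"{cultivar}: E+ vs E-",
    )


def combine(cultivar_tree: HierarchyNode,
            endophyte_trees: dict[str, HierarchyNode]) -> HierarchyNode:
    """Replace each cultivar terminal with that cultivar's endophyte tree."""

    def _graft(branch: Branch) -> Branch:
        if isinstance(branch, HierarchyNode):
            return HierarchyNode(
                model=branch.model,
                branch_class1=_graft(branch.branch_class1),
                branch_class2=_graft(branch.branch_class2),
                name=branch.name,
                otherwise_label=branch.otherwise_label,
            )
        if branch in endophyte_trees:
            return endophyte_trees[branch]
        return branch

    grafted = _graft(cultivar_tree)
    assert isinstance(grafted, HierarchyNode)
    return grafted


def _route_one(node: HierarchyNode, x: np.ndarray) -> str:
    try:
        resp = node.model.predict_response(x[np.newaxis, :],
                                           preprocessed=False)
        if not np.isfinite(resp[0]):
            return node.otherwise_label
        branch = (node.branch_class1 if resp[0] >= node.model.threshold
                  else node.branch_class2)
    except (ValueError, RuntimeError, np.linalg.LinAlgError):
        return node.otherwise_label
    if isinstance(branch, HierarchyNode):
        return _route_one(branch, x)
    return branch


def classify_tree(tree: HierarchyNode, scans: SpectraSet | np.ndarray,
                  ) -> np.ndarray:
    """Route each scan through the tree; failures become ``Unclassified``.

    Each node applies its own fitted pre-processing chain to the raw scan
    before thresholding its model's predicted response.  Routing partitions
    the scans: every scan receives exactly one terminal label.
    """
    X = scans.absorbance if isinstance(scans, SpectraSet) else np.asarray(
        scans, dtype=float)
    return np.array([_route_one(tree, X[i]) for i in range(X.shape[0])])


@dataclass
class BagPrediction:
    """Majority-vote outcome over one bag's sub-sample scans."""

    bag_id: str
    scan_labels: list[str]
    majority_label: str
    votes: int

    @property
    def conclusive(self) -> bool:
        return self.majority_label != INCONCLUSIVE


def aggregate_bag(scan_labels: Sequence[str], bag_id: str = "",
                  vote_threshold: int = 4,
                  scans_per_bag: int = 6) -> BagPrediction:
    """Majority vote over a bag's scan labels.

    The most frequent label is accepted iff its count reaches the vote
    threshold (default 4 of 6); below that the bag is ``Inconclusive``.
    If the number of scans differs from the nominal ``scans_per_bag`` the
    threshold is rescaled proportionally to ``ceil(2/3 * n)``.
    Ties on the modal count are broken by label order (alphabetical), which
    can only matter below the threshold.
    """
    labels = list(scan_labels)
    if not labels:
        raise ValueError("a bag needs at least one scan label")
    threshold = vote_threshold
    if len(labels) != scans_per_bag:
        threshold = ceil(2 * len(labels) / 3)
    counts = Counter(labels)
    top = max(counts.items(), key=lambda kv: (kv[1], [-ord(c) for c in kv[0]]))
    label, votes = top
    if votes < threshold:
        return BagPrediction(bag_id=bag_id, scan_labels=labels,
                             majority_label=INCONCLUSIVE, votes=votes)
    return BagPrediction(bag_id=bag_id, scan_labels=labels,
                         majority_label=label, votes=votes)


def aggregate_bags(bag_ids: Sequence[str], scan_labels: Sequence[str],
                   vote_threshold: int = 4,
                   scans_per_bag: int = 6) -> list[BagPrediction]:
    """Group scan labels by bag (input order preserved) and vote each bag."""
    bag_ids = list(bag_ids)
    scan_labels = list(scan_labels)
    if len(bag_ids) != len(scan_labels):
        raise ValueError("bag_ids and scan_labels must have the same length")
    order: dict[str, list[str]] = {}
    for b, lab in zip(bag_ids, scan_labels):
        order.setdefault(b, []).append(lab)
    return [
        aggregate_bag(labels, bag_id=b, vote_threshold=vote_threshold,
                      scans_per_bag=scans_per_bag)
        for b, labels in order.items()
    ]


def misclassification_table(true_labels: Sequence[str],
                            predicted_labels: Sequence[str]) -> pd.DataFrame:
    """Tally hits and misses per (predicted, actual) label pair.

    One row per misclassification pattern plus the per-pattern share of the
    actual class, mirroring the per-rule miss tables of the hierarchical
    workflow; correct predictions are summarised in the attributes
    ``df.attrs['n_total']`` and ``df.attrs['n_correct']``.
    """
    true_arr = np.asarray(true_labels)
    pred_arr = np.asarray(predicted_labels)
    if true_arr.shape != pred_arr.shape:
        raise ValueError("label arrays must have the same length")
    rows = []
    for actual in sorted(set(true_arr.tolist())):
        mask = true_arr == actual
        n_actual = int(mask.sum())
        for predicted in sorted(set(pred_arr[mask].tolist())):
            if predicted == actual:
                continue
            n = int(np.sum(pred_arr[mask] == predicted))
            rows.append({
                "classified_as": predicted,
                "actual": actual,
                "times_misclassified": n,
                "of_actual": n_actual,
                "percent_misclassified": 100.0 * n / n_actual,
            })
    df = pd.DataFrame(
        rows, columns=["classified_as", "actual", "times_misclassified",
                       "of_actual", "percent_misclassified"])
    df.attrs["n_total"] = int(true_arr.size)
    df.attrs["n_correct"] = int(np.sum(true_arr == pred_arr))
    return df
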