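"""ROC-based accuracy scoring of pairwise-effect predictions.

A trait is predicted positive at a P-value cutoff when its predicted locus
pair equals the planted causal pair (identity match, order-free) and its
pair P-value — the max of the primary and secondary P — passes the cutoff.
Sweeping the cutoff over the achieved pair P-values traces an ROC curve;
the accuracy score is the trapezoidal area under the achieved points,
anchored at (0,0) and carried flat at the final sensitivity out to
FPR = 1 (never extrapolated up to (1,1)).  A mapper that never names the
causal pair scores 0; one that names it for every dual trait, and nothing
else, scores 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .baselines import PairPrediction
from .matrices import GenotypeMatrix, TraitMatrix
from .simulate import TruthTable

__all__ = [
    "RocCurve",
    "classify_predictions",
    "roc_accuracy",
    "compare_methods",
    "pool_collections",
    "mean_collection_accuracy",
    "pairs_match",
]

Mapper = Callable[[TraitMatrix, GenotypeMatrix], Sequence[PairPrediction]]


@dataclass
class RocCurve:
    """Achieved (FPR, TPR) sweep points and the resulting accuracy score."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    accuracy_score: float

    def specificity_at(self, tpr_grid: np.ndarray) -> np.ndarray:
        """Specificity (1 - FPR) at given sensitivity levels, step-interpolated.

        For each requested sensitivity the smallest achieved FPR reaching at
        least that TPR is used; sensitivities above the achieved maximum get
        the final point's specificity.
        """
        fpr = np.concatenate([[0.0], self.fpr])
        tpr = np.concatenate([[0.0], self.tpr])
        out = np.empty_like(np.asarray(tpr_grid, dtype=float))
        for i, level in enumerate(np.atleast_1d(tpr_grid)):
            reached = np.flatnonzero(tpr >= level)
            out[i] = 1.0 - (fpr[reached[0]] if reached.size else fpr[-1])
        return out


def pairs_match(
    pred_pair: frozenset[str],
    truth_pair: frozenset[str],
    G: GenotypeMatrix | None = None,
    match_window_bp: int | None = None,
) -> bool:
    """Order-free pair comparison: exact identity, or window-based.

    With a genotype panel carrying coordinates and a ``match_window_bp``,
    each truth locus must be matched by a distinct predicted locus on the
    same chromosome within the window — appropriate for linked real-data
    panels where the mapped variant may be a close proxy of the causal one.
    """
    if match_window_bp is None or G is None:
        return pred_pair == truth_pair
    if not G.has_coordinates:
        raise ValueError("window-based matching requires variant coordinates")

    def near(a: str, b: str) -> bool:
        ia, ib = G.variant_index(a), G.variant_index(b)
        return (
            G.variant_chrom[ia] == G.variant_chrom[ib]
            and abs(int(G.variant_pos_bp[ia]) - int(G.variant_pos_bp[ib])) <= match_window_bp
        )

    pred = sorted(pred_pair)
    t1, t2 = sorted(truth_pair)
    if len(pred) != 2:
        return False
    return (near(pred[0], t1) and near(pred[1], t2)) or (
        near(pred[0], t2) and near(pred[1], t1)
    )


def _pair_table(
    preds: Iterable[PairPrediction],
    truth: TruthTable,
    G: GenotypeMatrix | None = None,
    match_window_bp: int | None = None,
) -> tuple[pd.DataFrame, int, int]:
    """Per-trait correctness/pair_P table plus positive and negative totals."""
    dual = truth.dual_traits
    target = truth.variant_pair
    rows = []
    for p in preds:
        if p.variant_pair is None or p.pair_P is None:
            continue
        rows.append(
            {
                "trait_id": p.trait_id,
                "correct": pairs_match(p.variant_pair, target, G, match_window_bp),
                "pair_P": p.pair_P,
                "is_dual": p.trait_id in dual,
            }
        )
    table = pd.DataFrame(rows, columns=["trait_id", "correct", "pair_P", "is_dual"])
    n_pos = len(dual)
    n_neg = len(truth.table) - n_pos
    return table, n_pos, n_neg


def classify_predictions(
    preds: Iterable[PairPrediction],
    truth: TruthTable,
    cutoff: float,
    G: GenotypeMatrix | None = None,
    match_window_bp: int | None = None,
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) counts at one pair-P cutoff.

    Positive prediction = correct pair (exact identity, or window match
    when configured) and pair_P <= cutoff; the truth-positive class is the
    dual-effect traits.  The four counts partition all traits in the truth
    table.
    """
    table, n_pos, n_neg = _pair_table(preds, truth, G, match_window_bp)
    positive = table[table["correct"] & (table["pair_P"] <= cutoff)]
    tp = int(positive["is_dual"].sum())
    fp = len(positive) - tp
    return tp, fp, n_neg - fp, n_pos - tp


def roc_accuracy(
    preds: Iterable[PairPrediction],
    truth: TruthTable,
    G: GenotypeMatrix | None = None,
    match_window_bp: int | None = None,
) -> RocCurve:
    """Sweep the achieved pair P-values and integrate the ROC curve.

    Only predictions naming the causal pair can ever be positive, so the
    sweep runs over their distinct pair P-values.
    """
    table, n_pos, n_neg = _pair_table(preds, truth, G, match_window_bp)
    if n_pos == 0:
        raise ValueError("truth table contains no dual-effect traits; ROC undefined")
    correct = table[table["correct"]]
    thresholds = np.unique(correct["pair_P"].to_numpy())
    fpr_pts = []
    tpr_pts = []
    p_sorted = np.sort(correct.loc[correct["is_dual"], "pair_P"].to_numpy())
    f_sorted = np.sort(correct.loc[~correct["is_dual"], "pair_P"].to_numpy())
    for t in thresholds:
        tp = int(np.searchsorted(p_sorted, t, side="right"))
        fp = int(np.searchsorted(f_sorted, t, side="right"))
        tpr_pts.append(tp / n_pos)
        fpr_pts.append(fp / n_neg if n_neg else 0.0)
    fpr = np.asarray(fpr_pts)
    tpr = np.asarray(tpr_pts)
    if fpr.size:
        area = float(np.trapezoid(np.concatenate([[0.0], tpr]), np.concatenate([[0.0], fpr])))
        area += float(tpr[-1] * (1.0 - fpr[-1]))  # carry the final sensitivity flat
    else:
        area = 0.0
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, accuracy_score=area)


def pool_collections(
    collections: Sequence[tuple[TraitMatrix, GenotypeMatrix, TruthTable]],
    mapper: Mapper,
) -> tuple[list[PairPrediction], TruthTable]:
    """Run a mapper per collection and pool predictions and truth for one ROC.

    Trait identifiers are collection-qualified at generation time, so the
    pooled truth table is a plain concatenation; the causal pair occupies
    the same variant identities in every collection.
    """
    all_preds: list[PairPrediction] = []
    tables = []
    v1 = v2 = None
    for Y, G, truth in collections:
        all_preds.extend(mapper(Y, G))
        tables.append(truth.table)
        if v1 is None:
            v1, v2 = truth.v1, truth.v2
        elif (truth.v1, truth.v2) != (v1, v2):
            raise ValueError("pooled collections must plant the same variant identities")
    pooled = TruthTable(table=pd.concat(tables, ignore_index=True), v1=v1, v2=v2)
    return all_preds, pooled


def mean_collection_accuracy(
    collections: Sequence[tuple[TraitMatrix, GenotypeMatrix, TruthTable]],
    mapper: Mapper,
) -> float:
    """Mean of per-collection accuracy scores (sensitivity analysis for the
    pooled sweep; rankings agree with pooling on large datasets)."""
    scores = [
        roc_accuracy(mapper(Y, G), truth).accuracy_score for Y, G, truth in collections
    ]
    return float(np.mean(scores))


def compare_methods(
    collections: Sequence[tuple[TraitMatrix, GenotypeMatrix, TruthTable]],
    methods: dict[str, Mapper],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Accuracy scores per method plus paired t-tests between ROC curves.

    The paired test compares specificity at matched sensitivity levels (the
    union of the two curves' achieved TPR values).  Curves with a single
    achieved point are excluded from pairing; identical curves yield the
    degenerate P = 1.
    """
    if len(methods) < 2:
        raise ValueError("at least two methods are required for a comparison")
    curves: dict[str, RocCurve] = {}
    for name, mapper in methods.items():
        preds, truth = pool_collections(collections, mapper)
        curves[name] = roc_accuracy(preds, truth)
    accuracy = pd.DataFrame(
        {
            "method": list(curves),
            "accuracy": [curves[m].accuracy_score for m in curves],
            "n_collections": len(collections),
        }
    )
    rows = []
    names = list(curves)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            ca, cb = curves[a], curves[b]
            if ca.tpr.size < 2 or cb.tpr.size < 2:
                rows.append({"method_a": a, "method_b": b, "t": np.nan, "P": np.nan,
                             "note": "degenerate curve excluded"})
                continue
            grid = np.union1d(ca.tpr, cb.tpr)
            diff = ca.specificity_at(grid) - cb.specificity_at(grid)
            if np.allclose(diff, 0.0):
                rows.append({"method_a": a, "method_b": b, "t": 0.0, "P": 1.0, "note": "identical"})
                continue
            t_stat, p = stats.ttest_rel(ca.specificity_at(grid), cb.specificity_at(grid))
            rows.append({"method_a": a, "method_b": b, "t": float(t_stat), "P": float(p), "note": ""})
    tests = pd.DataFrame(rows, columns=["method_a", "method_b", "t", "P", "note"])
    return accuracy, tests
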