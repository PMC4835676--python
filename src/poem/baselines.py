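"""Single-trait stepwise pairwise-eQTL mappers: RBSR and PBSR.

RBSR (residual-based stepwise regression) finds each trait's best locus,
regresses it out, and scans the residuals for a second locus — the natural
strategy when the two loci act additively.

PBSR (partition-based stepwise regression) splits the individuals by the
primary locus genotype and scans each half separately, which targets
allele-specific (epistatic) secondaries at the price of halved sample size.

Neither mapper applies a significance cutoff; thresholds are swept at
evaluation time when building ROC curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .association import _scan_scores, one_locus_scan
from .matrices import GenotypeMatrix, TraitMatrix, check_aligned

__all__ = ["PairPrediction", "rbsr", "pbsr"]

#: Minimum individuals per allele partition for a within-partition scan.
MIN_PARTITION = 4


@dataclass(frozen=True)
class PairPrediction:
    """A trait's predicted (primary, secondary) locus pair with P-values.

    ``pair_P`` is the maximum of the two member P-values: the pair is only
    as significant as its weaker locus.  ``secondary_variant`` may be None
    when no admissible secondary scan existed (e.g. both allele partitions
    of PBSR were too small).
    """

    trait_id: str
    primary_variant: str
    secondary_variant: str | None
    primary_P: float
    secondary_P: float | None

    def __post_init__(self) -> None:
        if self.secondary_variant is not None and self.secondary_variant == self.primary_variant:
            raise ValueError("primary and secondary variants must differ")

    @property
    def pair_P(self) -> float | None:
        if self.secondary_P is None:
            return None
        return max(self.primary_P, self.secondary_P)

    @property
    def variant_pair(self) -> frozenset[str] | None:
        if self.secondary_variant is None:
            return None
        return frozenset((self.primary_variant, self.secondary_variant))


def _residual_matrix(Y: TraitMatrix, G: GenotypeMatrix, primary_idx: np.ndarray) -> np.ndarray:
    """Residuals of each trait on its own primary variant (vectorised OLS)."""
    Gv = G.values
    resid = np.empty_like(Y.values)
    for j in range(Y.n_traits):
        g = Gv[:, primary_idx[j]]
        gc = g - g.mean()
        y = Y.values[:, j]
        yc = y - y.mean()
        beta = float(gc @ yc) / float(gc @ gc)
        resid[:, j] = yc - gc * beta
    return resid


def rbsr(Y: TraitMatrix, G: GenotypeMatrix) -> list[PairPrediction]:
    """Residual-based stepwise regression, applied to each trait independently.

    Step 1: plain one-locus scan; the primary is the best-scoring variant.
    Step 2: one-locus scan on the residuals of the primary; the secondary is
    the best-scoring variant excluding the primary itself.
    """
    check_aligned(Y, G)
    A1 = one_locus_scan(Y, G)
    primary_idx = np.argmax(A1.scores, axis=1)
    resid = _residual_matrix(Y, G, primary_idx)
    s2 = _scan_scores(resid, G.values)
    s2[np.arange(Y.n_traits), primary_idx] = -1.0  # never re-select the primary
    secondary_idx = np.argmax(s2, axis=1)
    preds = []
    for j, trait_id in enumerate(Y.trait_ids):
        pj, sj = int(primary_idx[j]), int(secondary_idx[j])
        preds.append(
            PairPrediction(
                trait_id=trait_id,
                primary_variant=G.variant_ids[pj],
                secondary_variant=G.variant_ids[sj],
                primary_P=float(10.0 ** -A1.scores[j, pj]),
                secondary_P=float(10.0 ** -s2[j, sj]),
            )
        )
    return preds


def pbsr(Y: TraitMatrix, G: GenotypeMatrix) -> list[PairPrediction]:
    """Partition-based stepwise regression, applied to each trait independently.

    The primary is found as in RBSR step 1.  Individuals are then split by
    the primary genotype and a separate one-locus scan runs in each allele
    partition; the reported secondary is the more significant of the two
    allele-specific candidates.  A partition smaller than ``MIN_PARTITION``
    (or a variant monomorphic within a partition) contributes no candidate.
    """
    check_aligned(Y, G)
    A1 = one_locus_scan(Y, G)
    primary_idx = np.argmax(A1.scores, axis=1)
    preds = []
    for j, trait_id in enumerate(Y.trait_ids):
        pj = int(primary_idx[j])
        g_primary = G.values[:, pj]
        best_score = -1.0
        best_var: int | None = None
        for allele in (-1.0, 1.0):
            keep = g_primary == allele
            if int(keep.sum()) < MIN_PARTITION:
                continue
            scores = _scan_scores(Y.values[keep][:, [j]], G.values[keep])[0]
            scores[pj] = -1.0
            k = int(np.argmax(scores))
            if scores[k] > best_score:
                best_score = float(scores[k])
                best_var = k
        if best_var is None:
            preds.append(
                PairPrediction(
                    trait_id=trait_id,
                    primary_variant=G.variant_ids[pj],
                    secondary_variant=None,
                    primary_P=float(10.0 ** -A1.scores[j, pj]),
                    secondary_P=None,
                )
            )
        else:
            preds.append(
                PairPrediction(
                    trait_id=trait_id,
                    primary_variant=G.variant_ids[pj],
                    secondary_variant=G.variant_ids[best_var],
                    primary_P=float(10.0 ** -A1.scores[j, pj]),
                    secondary_P=float(10.0 ** -best_score),
                )
            )
    return preds
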