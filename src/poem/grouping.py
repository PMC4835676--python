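"""Agglomerative construction of co-association groups.

A co-association group is a set of traits governed by one representative
variant.  Grouping starts from singletons (each trait with its best-scoring
variant), then greedily merges pairs of groups whose representatives are
"nearby" — on the same chromosome within a window when coordinates exist,
or the identical variant when they do not (independent synthetic panels).
Group coherence is the median of the member traits' association scores to
the representative; a merge is accepted only while the best achievable
merged coherence stays above the significance cutoff.

This is a from-scratch reimplementation of the agglomerative strategy; no
attempt is made to be bit-compatible with any external tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .association import fit_single_locus
from .matrices import (
    AssociationMatrix,
    EQTLEntry,
    EQTLMap,
    GenotypeMatrix,
    TraitMatrix,
)

__all__ = [
    "CoAssociationGroup",
    "GroupingSolution",
    "initialize_groups",
    "update_representative",
    "agglomerate",
    "build_groups",
    "group_eqtl_map",
]


@dataclass(frozen=True)
class CoAssociationGroup:
    """A nonempty trait set with one representative variant.

    ``score`` is the median of the member traits' association scores
    (-log10 P) to the representative; it is recomputed whenever membership
    or the representative changes.
    """

    trait_ids: tuple[str, ...]
    representative: str
    score: float

    def __post_init__(self) -> None:
        if not self.trait_ids:
            raise ValueError("a co-association group cannot be empty")

    @property
    def size(self) -> int:
        return len(self.trait_ids)


@dataclass
class GroupingSolution:
    """A disjoint family of co-association groups from one association matrix."""

    groups: list[CoAssociationGroup] = field(default_factory=list)
    source: str = "plain"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            overlap = seen.intersection(g.trait_ids)
            if overlap:
                raise ValueError(f"groups are not disjoint: {sorted(overlap)}")
            seen.update(g.trait_ids)

    def __len__(self) -> int:
        return len(self.groups)

    @property
    def grouped_traits(self) -> set[str]:
        return {t for g in self.groups for t in g.trait_ids}

    @property
    def n_traits(self) -> int:
        return sum(g.size for g in self.groups)

    def by_representative(self) -> dict[str, list[CoAssociationGroup]]:
        out: dict[str, list[CoAssociationGroup]] = {}
        for g in self.groups:
            out.setdefault(g.representative, []).append(g)
        return out


def initialize_groups(A: AssociationMatrix, score_cutoff: float = 2.0) -> GroupingSolution:
    """One singleton group per trait whose best score passes the cutoff."""
    if score_cutoff < 0:
        raise ValueError("score_cutoff must be non-negative")
    groups = []
    for i, trait_id in enumerate(A.trait_ids):
        row = A.scores[i]
        j = int(np.argmax(row))
        if row[j] > score_cutoff:
            groups.append(CoAssociationGroup((trait_id,), A.variant_ids[j], float(row[j])))
    return GroupingSolution(groups, source=A.kind)


def update_representative(
    trait_ids: Sequence[str],
    A: AssociationMatrix,
    candidate_variants: Sequence[str],
) -> tuple[str, float]:
    """Candidate maximising the median member score; ties -> lowest column index."""
    if len(candidate_variants) == 0:
        raise ValueError("candidate variant set must be nonempty")
    rows = [A.trait_ids.index(t) for t in trait_ids]
    cols = sorted(A.variant_ids.index(v) for v in set(candidate_variants))
    medians = np.median(A.scores[np.ix_(rows, cols)], axis=0)
    k = int(np.argmax(medians))  # argmax returns the first (lowest-index) max
    return A.variant_ids[cols[k]], float(medians[k])


def _nearby_mask(G: GenotypeMatrix, window_bp: int | None) -> np.ndarray | None:
    """m x m boolean matrix of variant proximity, or None for identity-only."""
    if not G.has_coordinates or window_bp is None:
        return None
    chrom = np.asarray(G.variant_chrom)
    pos = np.asarray(G.variant_pos_bp)
    same_chrom = chrom[:, None] == chrom[None, :]
    close = np.abs(pos[:, None] - pos[None, :]) <= window_bp
    return same_chrom & close


def agglomerate(
    solution: GroupingSolution,
    A: AssociationMatrix,
    G: GenotypeMatrix,
    window_bp: int | None = None,
    score_cutoff: float = 2.0,
) -> GroupingSolution:
    """Greedy best-first merging of groups with nearby representatives.

    Repeatedly evaluates every admissible pair of groups (representatives
    nearby per ``window_bp``; identical variant when coordinates are
    absent), scores the best achievable merged group via
    :func:`update_representative` over the union of the two
    representatives' windows, and performs the highest-scoring merge while
    it exceeds ``score_cutoff``.  Groups failing the cutoff at the end are
    dropped.  Deterministic: ties resolve by merged score, then by group
    order.
    """
    near = _nearby_mask(G, window_bp)
    vidx = {v: i for i, v in enumerate(G.variant_ids)}
    groups = list(solution.groups)

    def candidates(rep_a: str, rep_b: str) -> list[str]:
        if near is None:
            return [rep_a]  # admissible only when rep_a == rep_b
        mask = near[vidx[rep_a]] | near[vidx[rep_b]]
        return [G.variant_ids[i] for i in np.flatnonzero(mask)]

    def admissible(rep_a: str, rep_b: str) -> bool:
        if near is None:
            return rep_a == rep_b
        return bool(near[vidx[rep_a], vidx[rep_b]])

    while len(groups) > 1:
        best: tuple[float, int, int, CoAssociationGroup] | None = None
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                ga, gb = groups[a], groups[b]
                if not admissible(ga.representative, gb.representative):
                    continue
                union = tuple(sorted(set(ga.trait_ids) | set(gb.trait_ids)))
                rep, score = update_representative(
                    union, A, candidates(ga.representative, gb.representative)
                )
                if score <= score_cutoff:
                    continue
                merged = CoAssociationGroup(union, rep, score)
                if best is None or score > best[0]:
                    best = (score, a, b, merged)
        if best is None:
            break
        _, a, b, merged = best
        groups = [g for i, g in enumerate(groups) if i not in (a, b)]
        groups.append(merged)

    groups = [g for g in groups if g.score > score_cutoff]
    return GroupingSolution(groups, source=solution.source)


def group_eqtl_map(
    solution: GroupingSolution, Y: TraitMatrix, G: GenotypeMatrix
) -> EQTLMap:
    """Every trait of every group mapped to the group's representative variant."""
    entries = {}
    for grp in solution.groups:
        g = G.column(grp.representative)
        for trait_id in grp.trait_ids:
            mu, beta, _, _ = fit_single_locus(Y.column(trait_id), g)
            entries[trait_id] = EQTLEntry(grp.representative, mu, beta)
    return EQTLMap(entries)


def build_groups(
    A: AssociationMatrix,
    G: GenotypeMatrix,
    window_bp: int | None = None,
    score_cutoff: float = 2.0,
) -> GroupingSolution:
    """Initialise singletons and agglomerate in one call."""
    return agglomerate(
        initialize_groups(A, score_cutoff), A, G, window_bp=window_bp, score_cutoff=score_cutoff
    )
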