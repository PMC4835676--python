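"""The iterative primary/secondary refinement at the heart of the method.

The run starts from a plain one-locus scan whose grouping yields the
initial primary groups and primary eQTL map.  Each iteration then learns
secondary eQTLs from a scan conditioned on the current primary map, and —
from the second iteration on — relearns primary eQTLs from a scan
conditioned on the current secondary map (Gauss–Seidel style: always the
most recent map).  With ``k = 1`` the run is exactly two sequential scans,
which for singleton groups reduces to RBSR at the trait level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

from .association import conditioned_scan, one_locus_scan
from .baselines import PairPrediction
from .grouping import GroupingSolution, build_groups, group_eqtl_map
from .matrices import AssociationMatrix, EQTLMap, GenotypeMatrix, TraitMatrix

if TYPE_CHECKING:  # pragma: no cover
    from .modules import PoeModule

__all__ = ["PoemParams", "PoemModel", "poem_run", "pair_predictions"]


@dataclass(frozen=True)
class PoemParams:
    """Tunable parameters of a full run.

    ``group_score_cutoff`` is on the -log10(P) scale (2.0 means P=0.01).
    ``window_bp=None`` restricts merging to identical representative
    variants, the right choice for panels of unlinked variants.
    """

    k: int = 6
    group_score_cutoff: float = 2.0
    window_bp: int | None = None
    overlap_cutoff_pairs: float = 1e-6
    overlap_cutoff_larger: float = 1e-3
    min_overlap: int = 2
    epistasis_fdr: float = 0.01

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be at least 1")
        if self.group_score_cutoff < 0:
            raise ValueError("group_score_cutoff must be non-negative")


@dataclass
class PoemModel:
    """Final groups, maps and association matrices of a run."""

    primary_groups: GroupingSolution
    secondary_groups: GroupingSolution
    primary_map: EQTLMap
    secondary_map: EQTLMap
    primary_scores: AssociationMatrix
    secondary_scores: AssociationMatrix
    iteration_trace: list[dict] = field(default_factory=list)
    modules: list["PoeModule"] = field(default_factory=list)


def poem_run(
    Y: TraitMatrix,
    G: GenotypeMatrix,
    k: int = 6,
    group_score_cutoff: float = 2.0,
    window_bp: int | None = None,
) -> PoemModel:
    """Initialisation plus ``k`` iterations of alternating conditioned scans.

    Iteration 1 uses the initialisation (plain scan) as its primary stage;
    iterations 2..k recondition the primary scan on the latest secondary
    map.  Every stage re-groups the traits and rebuilds the stage's eQTL
    map from the group representatives.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    trace: list[dict] = []

    A_P = one_locus_scan(Y, G)
    c_P = build_groups(A_P, G, window_bp=window_bp, score_cutoff=group_score_cutoff)
    V_P = group_eqtl_map(c_P, Y, G)
    trace.append({"iteration": 0, "stage": "init", "groups": len(c_P), "traits": c_P.n_traits})

    c_S: GroupingSolution | None = None
    A_S: AssociationMatrix | None = None
    V_S: EQTLMap | None = None
    for it in range(1, k + 1):
        if it > 1:
            A_P = conditioned_scan(Y, G, V_S)
            c_P = build_groups(A_P, G, window_bp=window_bp, score_cutoff=group_score_cutoff)
            V_P = group_eqtl_map(c_P, Y, G)
            trace.append(
                {"iteration": it, "stage": "primary", "groups": len(c_P), "traits": c_P.n_traits}
            )
        A_S = conditioned_scan(Y, G, V_P)
        c_S = build_groups(A_S, G, window_bp=window_bp, score_cutoff=group_score_cutoff)
        V_S = group_eqtl_map(c_S, Y, G)
        trace.append(
            {"iteration": it, "stage": "secondary", "groups": len(c_S), "traits": c_S.n_traits}
        )

    return PoemModel(
        primary_groups=c_P,
        secondary_groups=c_S,
        primary_map=V_P,
        secondary_map=V_S,
        primary_scores=A_P,
        secondary_scores=A_S,
        iteration_trace=trace,
    )


def pair_predictions(model: PoemModel) -> list[PairPrediction]:
    """Per-trait pair predictions from the final primary/secondary maps.

    A trait present in both maps is predicted to be governed by the two
    group representatives; the per-locus P-values come from the final
    association matrices, so thresholds can be swept at evaluation time.
    Traits whose two representatives coincide carry no valid pair and are
    omitted.
    """
    preds = []
    A_P, A_S = model.primary_scores, model.secondary_scores
    ti_P = {t: i for i, t in enumerate(A_P.trait_ids)}
    vi_P = {v: i for i, v in enumerate(A_P.variant_ids)}
    ti_S = {t: i for i, t in enumerate(A_S.trait_ids)}
    vi_S = {v: i for i, v in enumerate(A_S.variant_ids)}
    for trait_id, entry_p in model.primary_map.entries.items():
        if trait_id not in model.secondary_map:
            continue
        entry_s = model.secondary_map[trait_id]
        if entry_p.variant_id == entry_s.variant_id:
            continue
        p_primary = 10.0 ** -float(A_P.scores[ti_P[trait_id], vi_P[entry_p.variant_id]])
        p_secondary = 10.0 ** -float(A_S.scores[ti_S[trait_id], vi_S[entry_s.variant_id]])
        preds.append(
            PairPrediction(
                trait_id=trait_id,
                primary_variant=entry_p.variant_id,
                secondary_variant=entry_s.variant_id,
                primary_P=p_primary,
                secondary_P=p_secondary,
            )
        )
    return preds
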