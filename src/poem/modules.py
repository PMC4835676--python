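"""Construction and annotation of pairwise-effect modules.

A module is the significant intersection of one primary co-association
group and one secondary group: a set of traits jointly governed by a
specific (primary, secondary) eQTL pair.  Overlap significance is the
one-sided hypergeometric (Fisher exact) upper tail; stringent dual cutoffs
(1e-6 for two-trait overlaps, 1e-3 for larger ones) keep the final output
conservative even though the intermediate groups use a permissive cutoff.

Annotation covers the interaction test (epistatic vs additive modules),
permutation-based false-discovery estimates, cis/trans labels from genomic
distance, and a bipartite module/eQTL graph summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy import stats

from .matrices import P_FLOOR, GenotypeMatrix, TraitMatrix, check_aligned
from .pipeline import PoemModel, PoemParams, poem_run

__all__ = [
    "PoeModule",
    "overlap_pvalue",
    "build_poemodules",
    "remove_nested",
    "epistasis_score",
    "classify_epistatic",
    "PermutationFDR",
    "permutation_fdr",
    "classify_cis_trans",
    "module_graph",
    "run_poem_pipeline",
]


@dataclass(frozen=True)
class PoeModule:
    """Trait set governed by one (primary, secondary) eQTL pair."""

    trait_ids: frozenset[str]
    primary_variant: str
    secondary_variant: str
    overlap_P: float
    primary_group_size: int
    secondary_group_size: int
    epistasis_P: dict[str, float] = field(default_factory=dict)
    epistasis_q: dict[str, float] = field(default_factory=dict)
    is_epistatic: bool | None = None
    cis_trans_label: str | None = None  # trans-acting | cis-acting | unannotated
    trait_pair_class: dict[str, str] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.trait_ids)

    @property
    def variant_pair(self) -> frozenset[str]:
        return frozenset((self.primary_variant, self.secondary_variant))


def overlap_pvalue(n1: int, n2: int, overlap: int, l: int) -> float:
    """Hypergeometric upper-tail probability of an overlap at least this large.

    Drawing ``n2`` traits from ``l`` with ``n1`` marked, the probability of
    seeing ``overlap`` or more marked draws.
    """
    if not (0 <= overlap <= min(n1, n2) <= max(n1, n2) <= l):
        raise ValueError(f"inconsistent counts: n1={n1}, n2={n2}, overlap={overlap}, l={l}")
    if overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, l, n1, n2))


def build_poemodules(
    c_P,
    c_S,
    l: int,
    cutoff_pairs: float = 1e-6,
    cutoff_larger: float = 1e-3,
    min_overlap: int = 2,
    merge_mirrored: bool = True,
) -> list["PoeModule"]:
    """Significant primary x secondary group overlaps.

    Group pairs whose representatives are the identical variant are not
    tested (a pairwise effect needs two distinct loci).  Overlaps of
    exactly two traits must pass ``cutoff_pairs``; overlaps of three or
    more must pass ``cutoff_larger``.

    When the two loci of a pairwise program have comparable effects, the
    stepwise search assigns the primary/secondary roles per trait
    essentially at random, so one program can surface as two role-mirrored
    overlaps, (a, b) and (b, a).  Because a module is defined by its
    unordered locus pair, ``merge_mirrored`` (default) unites the two
    orientations before the significance filter: the module's traits are
    (cP_a ∩ cS_b) ∪ (cP_b ∩ cS_a), tested once against the union group
    sizes.  When the opposite orientation's groups are absent this reduces
    exactly to the plain ordered construction.
    """
    if merge_mirrored:
        return _build_unordered(c_P, c_S, l, cutoff_pairs, cutoff_larger, min_overlap)
    modules = []
    for gp in c_P.groups:
        traits_p = set(gp.trait_ids)
        for gs in c_S.groups:
            if gp.representative == gs.representative:
                continue
            shared = traits_p.intersection(gs.trait_ids)
            if len(shared) < min_overlap:
                continue
            p = overlap_pvalue(gp.size, gs.size, len(shared), l)
            cutoff = cutoff_pairs if len(shared) == 2 else cutoff_larger
            if p < cutoff:
                modules.append(
                    PoeModule(
                        trait_ids=frozenset(shared),
                        primary_variant=gp.representative,
                        secondary_variant=gs.representative,
                        overlap_P=p,
                        primary_group_size=gp.size,
                        secondary_group_size=gs.size,
                    )
                )
    return modules


def _build_unordered(
    c_P, c_S, l: int, cutoff_pairs: float, cutoff_larger: float, min_overlap: int
) -> list["PoeModule"]:
    """One module per unordered locus pair, uniting both role orientations."""

    def traits_by_rep(solution) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for g in solution.groups:
            out.setdefault(g.representative, set()).update(g.trait_ids)
        return out

    p_side = traits_by_rep(c_P)
    s_side = traits_by_rep(c_S)
    pairs = {
        frozenset((a, b))
        for a in p_side
        for b in s_side
        if a != b
    }
    modules = []
    for pair in sorted(pairs, key=sorted):
        a, b = sorted(pair)
        fwd = p_side.get(a, set()) & s_side.get(b, set())
        rev = p_side.get(b, set()) & s_side.get(a, set())
        shared = fwd | rev
        if len(shared) < min_overlap:
            continue
        n1 = len(p_side.get(a, set())) + len(p_side.get(b, set()))
        n2 = len(s_side.get(a, set())) + len(s_side.get(b, set()))
        p = overlap_pvalue(n1, n2, len(shared), l)
        cutoff = cutoff_pairs if len(shared) == 2 else cutoff_larger
        if p >= cutoff:
            continue
        # The dominant orientation donates the primary/secondary labels.
        primary, secondary = (a, b) if len(fwd) >= len(rev) else (b, a)
        modules.append(
            PoeModule(
                trait_ids=frozenset(shared),
                primary_variant=primary,
                secondary_variant=secondary,
                overlap_P=p,
                primary_group_size=n1,
                secondary_group_size=n2,
            )
        )
    return modules


def remove_nested(modules: list[PoeModule]) -> list[PoeModule]:
    """Drop modules whose trait set is strictly contained in another's.

    Among modules with identical trait sets only the most significant
    (smallest overlap P) survives; remaining ties resolve by variant-pair
    order so the result is deterministic.
    """
    ordered = sorted(
        modules,
        key=lambda m: (-m.size, m.overlap_P, m.primary_variant, m.secondary_variant),
    )
    kept: list[PoeModule] = []
    seen_sets: list[frozenset[str]] = []
    for mod in ordered:
        if any(mod.trait_ids < s or mod.trait_ids == s for s in seen_sets):
            continue
        kept.append(mod)
        seen_sets.append(mod.trait_ids)
    return kept


def epistasis_score(y: np.ndarray, g1: np.ndarray, g2: np.ndarray) -> float:
    """P-value of the interaction term in the two-locus model.

    Fits ``y = mu + g1*b1 + g2*b2 + (g1*g2)*b12 + e`` by OLS and F-tests
    ``b12`` against the additive submodel with df (1, n-4).  A design whose
    interaction column is collinear with (1, g1, g2) has no testable
    interaction and reports P = 1.
    """
    y = np.asarray(y, dtype=float)
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    n = y.shape[0]
    if np.array_equal(g1, g2):
        raise ValueError("the two loci must differ")
    X_full = np.column_stack([np.ones(n), g1, g2, g1 * g2])
    if np.linalg.matrix_rank(X_full) < 4:
        return 1.0  # collinear interaction column: untestable
    X_red = X_full[:, :3]
    sse_full = _ols_sse(X_full, y)
    sse_red = _ols_sse(X_red, y)
    ss_int = max(sse_red - sse_full, 0.0)
    sst = float(((y - y.mean()) ** 2).sum())
    if ss_int <= 1e-12 * max(sst, 1.0):
        return 1.0
    if sse_full <= 1e-12 * max(sst, 1.0):
        return P_FLOOR
    f_stat = ss_int / (sse_full / (n - 4))
    return max(float(stats.f.sf(f_stat, 1, n - 4)), P_FLOOR)


def _ols_sse(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def classify_epistatic(
    modules: list[PoeModule],
    Y: TraitMatrix,
    G: GenotypeMatrix,
    fdr_level: float = 0.01,
) -> list[PoeModule]:
    """Interaction-test every module trait; BH-correct across all tests pooled.

    A module is epistatic iff at least one member trait's interaction
    passes the FDR level; all other modules are additive.
    """
    check_aligned(Y, G)
    tests: list[tuple[int, str, float]] = []
    for mi, mod in enumerate(modules):
        g1 = G.column(mod.primary_variant)
        g2 = G.column(mod.secondary_variant)
        for trait_id in sorted(mod.trait_ids):
            p = epistasis_score(Y.column(trait_id), g1, g2)
            tests.append((mi, trait_id, p))
    if not tests:
        return []
    qvals = stats.false_discovery_control([t[2] for t in tests], method="bh")
    annotated = []
    for mi, mod in enumerate(modules):
        p_map = {t: p for m, t, p in tests if m == mi}
        q_map = {t: float(q) for (m, t, _), q in zip(tests, qvals) if m == mi}
        annotated.append(
            replace(
                mod,
                epistasis_P=p_map,
                epistasis_q=q_map,
                is_epistatic=any(q < fdr_level for q in q_map.values()),
            )
        )
    return annotated


def run_poem_pipeline(
    Y: TraitMatrix, G: GenotypeMatrix, params: PoemParams = PoemParams()
) -> PoemModel:
    """Full run: iterations, module construction, nested removal, epistasis."""
    model = poem_run(
        Y,
        G,
        k=params.k,
        group_score_cutoff=params.group_score_cutoff,
        window_bp=params.window_bp,
    )
    modules = build_poemodules(
        model.primary_groups,
        model.secondary_groups,
        l=Y.n_traits,
        cutoff_pairs=params.overlap_cutoff_pairs,
        cutoff_larger=params.overlap_cutoff_larger,
        min_overlap=params.min_overlap,
    )
    modules = remove_nested(modules)
    model.modules = classify_epistatic(modules, Y, G, fdr_level=params.epistasis_fdr)
    return model


@dataclass
class PermutationFDR:
    """Permutation-null false-discovery estimates for modules and trait counts."""

    fdr_modules: float
    fdr_traits: float
    real_modules: int
    real_traits: int
    permuted_modules: list[int]
    permuted_traits: list[int]


def permutation_fdr(
    Y: TraitMatrix,
    G: GenotypeMatrix,
    params: PoemParams = PoemParams(),
    n_perm: int = 100,
    seed: int = 0,
) -> PermutationFDR:
    """Reshuffle individual labels of the expression data and rerun the pipeline.

    The FDR estimate is the mean permuted module count (or traits-in-module
    count) divided by the real count; with a real count of zero the ratio
    is undefined and reported as NaN.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    real = run_poem_pipeline(Y, G, params)
    real_modules = len(real.modules)
    real_traits = sum(m.size for m in real.modules)
    perm_modules: list[int] = []
    perm_traits: list[int] = []
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_perm):
        rng = np.random.default_rng(child)
        order = rng.permutation(Y.n_individuals)
        Y_perm = Y.with_values(Y.values[order])
        model = run_poem_pipeline(Y_perm, G, params)
        perm_modules.append(len(model.modules))
        perm_traits.append(sum(m.size for m in model.modules))
    fdr_m = float(np.mean(perm_modules)) / real_modules if real_modules else math.nan
    fdr_t = float(np.mean(perm_traits)) / real_traits if real_traits else math.nan
    return PermutationFDR(
        fdr_modules=fdr_m,
        fdr_traits=fdr_t,
        real_modules=real_modules,
        real_traits=real_traits,
        permuted_modules=perm_modules,
        permuted_traits=perm_traits,
    )


def classify_cis_trans(
    module: PoeModule,
    G: GenotypeMatrix,
    Y: TraitMatrix,
    cis_window_bp: int = 10_000_000,
    trans_fraction: float = 0.66,
) -> PoeModule:
    """Label each trait cis-cis / cis-trans / trans-trans and the module overall.

    A locus is cis for a trait when it lies on the trait's gene chromosome
    within ``cis_window_bp`` of the gene position.  The module is
    trans-acting when the trans-trans fraction (over locatable traits)
    strictly exceeds ``trans_fraction``, cis-acting when strictly below,
    and unannotated otherwise (including the exact boundary and modules
    with no locatable traits).
    """
    if not G.has_coordinates:
        raise ValueError("cis/trans annotation requires variant coordinates")
    if Y.gene_chrom is None or Y.gene_pos_bp is None:
        raise ValueError("cis/trans annotation requires per-trait gene locations")
    v1 = G.variant_index(module.primary_variant)
    v2 = G.variant_index(module.secondary_variant)
    classes: dict[str, str] = {}
    n_trans_trans = 0
    n_located = 0
    for trait_id in sorted(module.trait_ids):
        ti = Y.trait_index(trait_id)
        chrom, pos = Y.gene_chrom[ti], Y.gene_pos_bp[ti]
        if chrom is None or pos is None:
            continue
        n_located += 1
        n_cis = sum(
            1
            for vi in (v1, v2)
            if G.variant_chrom[vi] == chrom and abs(int(G.variant_pos_bp[vi]) - int(pos)) < cis_window_bp
        )
        classes[trait_id] = ("trans-trans", "cis-trans", "cis-cis")[n_cis]
        if n_cis == 0:
            n_trans_trans += 1
    if n_located == 0:
        label = "unannotated"
    else:
        frac = n_trans_trans / n_located
        if frac > trans_fraction:
            label = "trans-acting"
        elif frac < trans_fraction:
            label = "cis-acting"
        else:
            label = "unannotated"
    return replace(module, cis_trans_label=label, trait_pair_class=classes)


def module_graph(modules: list[PoeModule]) -> tuple[nx.Graph, list[dict]]:
    """Bipartite module/eQTL graph and its connected-component architectures.

    eQTL nodes are (side, variant) pairs so a variant acting as a primary in
    one module and a secondary in another is two distinct anchors, matching
    the two-sided layout of the module map.  Components are labelled:

    - ``singleton``: one module, both its eQTLs private;
    - ``multifurcating``: several modules sharing exactly one eQTL, every
      other eQTL private;
    - ``composite``: any richer sharing pattern.
    """
    graph = nx.Graph()
    for i, mod in enumerate(modules):
        mnode = ("module", i)
        graph.add_node(mnode, bipartite="module", obj=mod)
        for side, variant in (("P", mod.primary_variant), ("S", mod.secondary_variant)):
            enode = ("eqtl", side, variant)
            graph.add_node(enode, bipartite="eqtl")
            graph.add_edge(mnode, enode)
    summaries = []
    for comp in nx.connected_components(graph):
        mod_nodes = [v for v in comp if v[0] == "module"]
        eqtl_nodes = [v for v in comp if v[0] == "eqtl"]
        shared = [e for e in eqtl_nodes if graph.degree(e) >= 2]
        if len(mod_nodes) == 1:
            label = "singleton"
        elif len(shared) == 1:
            label = "multifurcating"
        else:
            label = "composite"
        summaries.append(
            {
                "architecture": label,
                "n_modules": len(mod_nodes),
                "module_indices": sorted(v[1] for v in mod_nodes),
                "shared_eqtls": sorted((e[1], e[2]) for e in shared),
            }
        )
    summaries.sort(key=lambda s: s["module_indices"])
    return graph, summaries
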