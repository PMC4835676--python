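"""Single-locus association scans, plain and residual-conditioned.

The workhorse model is the one-locus fixed-effect regression
``y = mu + g*beta + e`` with ``g`` coded -1/+1.  Its F-test is identical to
the two-group one-way ANOVA on the allele split, and the F statistic equals
the square of the pooled-variance two-sample t statistic.  Scans are
vectorised over the full trait x variant grid via the closed-form OLS
sufficient statistics, which keeps a full scan at a few matrix products.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .matrices import (
    P_FLOOR,
    SCORE_CAP,
    AssociationMatrix,
    EQTLEntry,
    EQTLMap,
    GenotypeMatrix,
    MonomorphicVariantError,
    TraitMatrix,
    check_aligned,
)

__all__ = [
    "fit_single_locus",
    "one_locus_scan",
    "compute_residuals",
    "conditioned_scan",
    "best_eqtl_map",
]

# Relative tolerance deciding when a residual sum of squares is "exactly" zero.
_REL_EPS = 1e-12


def fit_single_locus(y: np.ndarray, g: np.ndarray) -> tuple[float, float, float, float]:
    """OLS fit of ``y = mu + g*beta + e`` and the F-test of ``beta``.

    Parameters
    ----------
    y : (n,) trait values.
    g : (n,) genotypes coded -1/+1; both alleles must be present.

    Returns
    -------
    (mu_hat, beta_hat, F, P) where P is the upper tail of F(1, n-2).

    Raises
    ------
    MonomorphicVariantError
        If ``g`` carries a single allele (the slope is unidentifiable).
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    n = y.shape[0]
    if n < 4:
        raise ValueError("at least 4 individuals are required")
    if g.shape != y.shape:
        raise ValueError("y and g must have the same length")
    gc = g - g.mean()
    sgg = float(gc @ gc)
    if sgg == 0.0:
        raise MonomorphicVariantError("variant is monomorphic in this panel")
    yc = y - y.mean()
    beta = float(gc @ yc) / sgg
    mu = float(y.mean() - beta * g.mean())
    sst = float(yc @ yc)
    ssr = beta * beta * sgg
    sse = max(sst - ssr, 0.0)
    if sst == 0.0:
        # Constant trait: nothing to explain.
        return mu, beta, 0.0, 1.0
    if sse <= _REL_EPS * sst:
        # Perfect fit: zero residual variance with nonzero SSR; P is floored.
        return mu, beta, float("inf"), P_FLOOR
    f_stat = ssr / (sse / (n - 2))
    p = max(float(stats.f.sf(f_stat, 1, n - 2)), P_FLOOR)
    return mu, beta, f_stat, p


def _scan_scores(Yv: np.ndarray, Gv: np.ndarray) -> np.ndarray:
    """-log10(P) for every (trait, variant) pair; monomorphic variants score 0."""
    n = Gv.shape[0]
    Gc = Gv - Gv.mean(axis=0)
    Yc = Yv - Yv.mean(axis=0)
    sgg = np.einsum("ij,ij->j", Gc, Gc)  # (m,)
    poly = sgg > 0
    sgg_safe = np.where(poly, sgg, 1.0)
    sgy = Yc.T @ Gc  # (l, m)
    ssr = sgy**2 / sgg_safe
    sst = np.einsum("ij,ij->j", Yc, Yc)[:, None]  # (l, 1)
    sse = np.maximum(sst - ssr, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = ssr / (sse / (n - 2))
    scale = np.maximum(sst, 1.0)
    null = (sst == 0.0) | (ssr <= _REL_EPS * sst)
    perfect = (sse <= _REL_EPS * scale) & ~null
    f_stat = np.where(null, 0.0, f_stat)
    with np.errstate(over="ignore"):
        logp = stats.f.logsf(np.where(perfect, 0.0, f_stat), 1, n - 2) / np.log(10.0)
    scores = np.clip(-logp, 0.0, SCORE_CAP)
    scores[perfect] = SCORE_CAP
    scores[null] = 0.0
    scores[:, ~poly] = 0.0
    return scores


def one_locus_scan(Y: TraitMatrix, G: GenotypeMatrix) -> AssociationMatrix:
    """Association scores of every trait against every variant.

    Scores are ``-log10(P)`` of the single-locus F-test; monomorphic
    variants receive score 0 for all traits so the matrix keeps its shape.
    """
    check_aligned(Y, G)
    if Y.n_individuals < 4:
        raise ValueError("at least 4 individuals are required for a scan")
    scores = _scan_scores(Y.values, G.values)
    return AssociationMatrix(scores, list(Y.trait_ids), list(G.variant_ids), kind="plain")


def compute_residuals(Y: TraitMatrix, G: GenotypeMatrix, V0: EQTLMap) -> TraitMatrix:
    """Residual traits after regressing out each trait's mapped eQTL.

    For traits present in ``V0`` the residual is ``y - mu_hat - g*beta_hat``
    with the coefficients re-estimated by OLS on the full data (stateless:
    iterations never accumulate stale fits).  Traits absent from the map
    pass through unchanged.
    """
    check_aligned(Y, G)
    V0.validate_against(G)
    resid = Y.values.copy()
    for trait_id, entry in V0.entries.items():
        j = Y.trait_index(trait_id)
        g = G.column(entry.variant_id)
        mu, beta, _, _ = fit_single_locus(Y.values[:, j], g)
        resid[:, j] = Y.values[:, j] - mu - g * beta
    return Y.with_values(resid)


def conditioned_scan(Y: TraitMatrix, G: GenotypeMatrix, V0: EQTLMap) -> AssociationMatrix:
    """One-locus scan on the residuals of a previous eQTL map."""
    R = compute_residuals(Y, G, V0)
    A = one_locus_scan(R, G)
    A.kind = "conditioned"
    return A


def best_eqtl_map(
    A: AssociationMatrix,
    G: GenotypeMatrix,
    Y: TraitMatrix,
    score_cutoff: float = 2.0,
) -> EQTLMap:
    """Significant best-eQTL map: each trait's argmax variant, if it passes.

    ``score_cutoff`` is on the -log10(P) scale (default 2.0, i.e. P=0.01).
    Ties in the argmax resolve to the lowest variant index.  The intercept
    and slope are refitted per selected pair for later residual scans.
    """
    if score_cutoff < 0:
        raise ValueError("score_cutoff must be non-negative")
    entries = {}
    for i, trait_id in enumerate(A.trait_ids):
        row = A.scores[i]
        j = int(np.argmax(row))
        if row[j] > score_cutoff:
            g = G.column(A.variant_ids[j])
            mu, beta, _, _ = fit_single_locus(Y.column(trait_id), g)
            entries[trait_id] = EQTLEntry(A.variant_ids[j], mu, beta)
    return EQTLMap(entries)
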