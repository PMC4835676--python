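"""In-memory containers for genotype, trait and association data.

The containers are thin, validated wrappers around numpy arrays plus
identifier lists.  Genotypes are restricted to homozygous/haploid panels
(recombinant inbred strains), so every call is coded -1 or +1.
Association scores are stored as -log10(P) of the per-(trait, variant)
F-test so that "more significant" is always a maximisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "TraitMatrix",
    "AssociationMatrix",
    "EQTLEntry",
    "EQTLMap",
    "MonomorphicVariantError",
    "P_FLOOR",
    "SCORE_CAP",
]

#: P-values that underflow to 0 are floored here so scores stay finite.
P_FLOOR = 1e-300
#: -log10(P_FLOOR): the maximal association score.
SCORE_CAP = 300.0


class MonomorphicVariantError(ValueError):
    """Raised when a single-locus model is requested for a variant with one allele."""


def _as_id_list(ids: Iterable, what: str) -> list[str]:
    out = [str(i) for i in ids]
    if len(set(out)) != len(out):
        raise ValueError(f"duplicate {what} identifiers")
    return out


@dataclass
class GenotypeMatrix:
    """n individuals x m variants, entries in {-1, +1}.

    Genomic coordinates (``variant_chrom``, ``variant_pos_bp``) are optional;
    synthetic panels with independent variants carry none, in which case
    position-based operations (merge windows, cis/trans calls) treat every
    pair of distinct variants as unlinked.
    """

    values: np.ndarray
    variant_ids: Sequence[str]
    individual_ids: Sequence[str]
    variant_chrom: Sequence[str] | None = None
    variant_pos_bp: Sequence[int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D (individuals x variants)")
        self.variant_ids = _as_id_list(self.variant_ids, "variant")
        self.individual_ids = _as_id_list(self.individual_ids, "individual")
        n, m = self.values.shape
        if len(self.individual_ids) != n or len(self.variant_ids) != m:
            raise ValueError("genotype shape does not match identifier counts")
        if not np.isin(self.values, (-1.0, 1.0)).all():
            bad = np.argwhere(~np.isin(self.values, (-1.0, 1.0)))[0]
            raise ValueError(
                f"genotype entries must be -1 or +1; offending cell "
                f"(individual {self.individual_ids[bad[0]]}, variant {self.variant_ids[bad[1]]})"
            )
        if (self.variant_chrom is None) != (self.variant_pos_bp is None):
            raise ValueError("variant_chrom and variant_pos_bp must be given together")
        if self.variant_chrom is not None:
            self.variant_chrom = [str(c) for c in self.variant_chrom]
            self.variant_pos_bp = np.asarray(self.variant_pos_bp, dtype=np.int64)
            if len(self.variant_chrom) != m or self.variant_pos_bp.shape != (m,):
                raise ValueError("variant coordinate lengths do not match variant count")
            if (self.variant_pos_bp < 0).any():
                raise ValueError("variant positions must be non-negative")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    @property
    def has_coordinates(self) -> bool:
        return self.variant_chrom is not None

    def variant_index(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"unknown variant {variant_id!r}") from None

    def column(self, variant_id: str) -> np.ndarray:
        return self.values[:, self.variant_index(variant_id)]


@dataclass
class TraitMatrix:
    """n individuals x l expression traits.

    A trait is one gene's response under one stimulus.  Optional per-trait
    gene locations support cis/trans annotation of the mapped loci.
    """

    values: np.ndarray
    trait_ids: Sequence[str]
    individual_ids: Sequence[str]
    gene_name: Sequence[str] | None = None
    stimulus: Sequence[str] | None = None
    gene_chrom: Sequence[str] | None = None
    gene_pos_bp: Sequence[int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("trait values must be 2-D (individuals x traits)")
        self.trait_ids = _as_id_list(self.trait_ids, "trait")
        self.individual_ids = _as_id_list(self.individual_ids, "individual")
        n, l = self.values.shape
        if len(self.individual_ids) != n or len(self.trait_ids) != l:
            raise ValueError("trait shape does not match identifier counts")
        if np.isnan(self.values).any():
            raise ValueError("trait matrix contains missing values after ingestion")
        for name in ("gene_name", "stimulus", "gene_chrom"):
            val = getattr(self, name)
            if val is not None:
                val = [None if v is None else str(v) for v in val]
                if len(val) != l:
                    raise ValueError(f"{name} length does not match trait count")
                setattr(self, name, val)
        if self.gene_pos_bp is not None:
            self.gene_pos_bp = list(self.gene_pos_bp)
            if len(self.gene_pos_bp) != l:
                raise ValueError("gene_pos_bp length does not match trait count")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def trait_index(self, trait_id: str) -> int:
        try:
            return self.trait_ids.index(trait_id)
        except ValueError:
            raise KeyError(f"unknown trait {trait_id!r}") from None

    def column(self, trait_id: str) -> np.ndarray:
        return self.values[:, self.trait_index(trait_id)]

    def with_values(self, values: np.ndarray) -> "TraitMatrix":
        """Copy of this matrix with new measurements and identical metadata."""
        return TraitMatrix(
            values=values,
            trait_ids=list(self.trait_ids),
            individual_ids=list(self.individual_ids),
            gene_name=None if self.gene_name is None else list(self.gene_name),
            stimulus=None if self.stimulus is None else list(self.stimulus),
            gene_chrom=None if self.gene_chrom is None else list(self.gene_chrom),
            gene_pos_bp=None if self.gene_pos_bp is None else list(self.gene_pos_bp),
        )


def check_aligned(Y: TraitMatrix, G: GenotypeMatrix) -> None:
    """Traits and genotypes must cover the same individuals in the same order."""
    if list(Y.individual_ids) != list(G.individual_ids):
        raise ValueError("trait and genotype matrices are not aligned on individuals")


@dataclass
class AssociationMatrix:
    """l traits x m variants of association scores, -log10(P) of the F-test."""

    scores: np.ndarray
    trait_ids: Sequence[str]
    variant_ids: Sequence[str]
    kind: str = "plain"  # "plain" | "conditioned"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.trait_ids = list(self.trait_ids)
        self.variant_ids = list(self.variant_ids)
        if self.scores.shape != (len(self.trait_ids), len(self.variant_ids)):
            raise ValueError("score shape does not match identifier counts")
        if not np.isfinite(self.scores).all() or (self.scores < 0).any():
            raise ValueError("association scores must be finite and non-negative")
        if self.kind not in ("plain", "conditioned"):
            raise ValueError("kind must be 'plain' or 'conditioned'")

    @property
    def pvalues(self) -> np.ndarray:
        return 10.0 ** (-self.scores)

    def score(self, trait_id: str, variant_id: str) -> float:
        return float(
            self.scores[self.trait_ids.index(trait_id), self.variant_ids.index(variant_id)]
        )

    def best_variant(self, trait_id: str) -> tuple[str, float]:
        """Best-scoring variant for a trait; ties broken by lowest column index."""
        row = self.scores[self.trait_ids.index(trait_id)]
        j = int(np.argmax(row))
        return self.variant_ids[j], float(row[j])


@dataclass(frozen=True)
class EQTLEntry:
    variant_id: str
    mu_hat: float
    beta_hat: float


@dataclass
class EQTLMap:
    """At most one (trait -> variant) assignment, with the fitted intercept/slope.

    The per-pair OLS coefficients are stored because residual-conditioned
    scans subtract exactly ``mu_hat + g * beta_hat`` from the trait.
    """

    entries: Mapping[str, EQTLEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = dict(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, trait_id: str) -> bool:
        return trait_id in self.entries

    def __getitem__(self, trait_id: str) -> EQTLEntry:
        return self.entries[trait_id]

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return {(t, e.variant_id) for t, e in self.entries.items()}

    def validate_against(self, G: GenotypeMatrix) -> None:
        known = set(G.variant_ids)
        for t, e in self.entries.items():
            if e.variant_id not in known:
                raise ValueError(f"eQTL map references unknown variant {e.variant_id!r}")
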