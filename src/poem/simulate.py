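"""Synthetic two-locus trait collections with known ground truth.

A collection plants two causal variants, v1 and v2, in a panel of
independent +/-1 variants and draws four trait classes around them:

- ``dual``  traits from the two-locus model: additive (b1 = b2 = gamma,
  b12 = 0) or epistatic / co-adaptive (b1 = b2 = 0, b12 = gamma);
- ``only-v1`` / ``only-v2`` single-effect traits (slope gamma at one locus);
- ``null`` traits of pure Gaussian noise.

Defaults mirror the benchmark conditions: 100 variants, trait counts
(10, 10, 10, 50), error variance 0.5, equal allele probabilities.  In the
epistatic model each planted locus has zero marginal effect; only the
product g1*g2 carries signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrices import GenotypeMatrix, TraitMatrix

__all__ = ["SimulationSpec", "TruthTable", "simulate_collection", "simulate_dataset"]


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic collection."""

    model: str = "additive"  # "additive" | "epistatic"
    gamma: float = 0.6
    n_individuals: int = 100
    m_variants: int = 100
    l_dual: int = 10
    l_only1: int = 10
    l_only2: int = 10
    l_null: int = 50
    sigma2: float = 0.5
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in ("additive", "epistatic"):
            raise ValueError("model must be 'additive' or 'epistatic'")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if min(self.l_dual, self.l_only1, self.l_only2, self.l_null) < 0:
            raise ValueError("trait counts must be non-negative")
        if self.m_variants < 2:
            raise ValueError("at least two variants are required")

    @property
    def n_traits(self) -> int:
        return self.l_dual + self.l_only1 + self.l_only2 + self.l_null


@dataclass(frozen=True)
class TruthTable:
    """Planted per-trait classes and the identities of the causal pair."""

    table: pd.DataFrame  # columns: trait_id, trait_class
    v1: str
    v2: str

    @property
    def classes(self) -> pd.Series:
        return self.table.set_index("trait_id")["trait_class"]

    @property
    def dual_traits(self) -> set[str]:
        t = self.table
        return set(t.loc[t["trait_class"] == "dual", "trait_id"])

    @property
    def variant_pair(self) -> frozenset[str]:
        return frozenset((self.v1, self.v2))


def _draw_genotypes(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    """i.i.d. +/-1 alleles at probability 1/2; monomorphic columns resampled."""
    G = rng.choice((-1.0, 1.0), size=(n, m))
    for _ in range(100):
        mono = np.flatnonzero(np.abs(G.sum(axis=0)) == n)
        if mono.size == 0:
            break
        G[:, mono] = rng.choice((-1.0, 1.0), size=(n, mono.size))
    return G


def simulate_collection(
    spec: SimulationSpec, seed: int | np.random.SeedSequence = 0, collection_id: str = "c0"
) -> tuple[TraitMatrix, GenotypeMatrix, TruthTable]:
    """One collection: genotypes, traits and the planted truth.

    The causal pair occupies the first two variant columns; evaluation
    matches predictions by variant identity, never by position.
    """
    rng = np.random.default_rng(seed)
    n, m = spec.n_individuals, spec.m_variants
    G = _draw_genotypes(rng, n, m)
    g1, g2 = G[:, 0], G[:, 1]
    sigma = float(np.sqrt(spec.sigma2))

    blocks: list[np.ndarray] = []
    classes: list[str] = []
    if spec.l_dual:
        e = rng.normal(0.0, sigma, size=(n, spec.l_dual))
        if spec.model == "additive":
            signal = spec.gamma * g1 + spec.gamma * g2
        else:
            signal = spec.gamma * g1 * g2
        blocks.append(spec.mu + signal[:, None] + e)
        classes += ["dual"] * spec.l_dual
    for count, g, label in (
        (spec.l_only1, g1, "only-v1"),
        (spec.l_only2, g2, "only-v2"),
    ):
        if count:
            e = rng.normal(0.0, sigma, size=(n, count))
            blocks.append(spec.mu + spec.gamma * g[:, None] + e)
            classes += [label] * count
    if spec.l_null:
        blocks.append(rng.normal(0.0, sigma, size=(n, spec.l_null)))
        classes += ["null"] * spec.l_null

    values = np.hstack(blocks) if blocks else np.empty((n, 0))
    trait_ids = [f"{collection_id}:t{j}" for j in range(len(classes))]
    individual_ids = [f"{collection_id}:i{i}" for i in range(n)]
    variant_ids = [f"v{x}" for x in range(m)]

    Y = TraitMatrix(values, trait_ids, individual_ids)
    Gm = GenotypeMatrix(G, variant_ids, individual_ids)
    truth = TruthTable(
        table=pd.DataFrame({"trait_id": trait_ids, "trait_class": classes}),
        v1=variant_ids[0],
        v2=variant_ids[1],
    )
    return Y, Gm, truth


def simulate_dataset(
    spec: SimulationSpec, n_collections: int, seed: int = 0
) -> list[tuple[TraitMatrix, GenotypeMatrix, TruthTable]]:
    """Independent collections from per-collection substreams of one seed."""
    if n_collections < 1:
        raise ValueError("n_collections must be at least 1")
    root = np.random.SeedSequence(seed)
    return [
        simulate_collection(spec, seed=child, collection_id=f"c{i}")
        for i, child in enumerate(root.spawn(n_collections))
    ]
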