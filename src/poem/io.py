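"""Readers and writers for the tabular formats, plus run configuration.

Conventions
-----------
- Genotype TSV: one row per variant with columns ``variant_id``, ``chrom``,
  ``pos_bp`` (both optional as a pair), then one column per individual.
  Calls are either numeric (-1/+1) or biallelic letters mapped through an
  explicit allele map (e.g. ``{"B": -1, "D": +1}``).  Coordinates are
  1-based inclusive.
- Expression TSV: one row per trait with ``trait_id`` and optional
  ``gene``, ``stimulus``, ``gene_chrom``, ``gene_pos_bp`` columns, then one
  column per individual.
- Gene locations: BED (0-based, half-open); converted to 1-based point
  positions (interval start) on read.
- Trait identifiers for stimulus-response data are ``gene@stimulus``
  composites, so one gene yields one trait per stimulus.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .baselines import PairPrediction
from .grouping import GroupingSolution
from .matrices import GenotypeMatrix, TraitMatrix
from .modules import PoeModule
from .pipeline import PoemModel, PoemParams

__all__ = [
    "RunConfig",
    "read_genotypes",
    "write_genotypes",
    "read_expression",
    "write_expression",
    "read_gene_locations",
    "compute_response",
    "write_grouping",
    "write_predictions",
    "write_modules",
    "model_to_json",
]

_GENO_META = ("variant_id", "chrom", "pos_bp")
_EXPR_META = ("trait_id", "gene", "stimulus", "gene_chrom", "gene_pos_bp")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Full-run configuration: algorithm parameters plus annotation settings."""

    params: PoemParams = PoemParams()
    cis_window_bp: int = 10_000_000
    trans_fraction: float = 0.66
    n_permutations: int = 100
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        params = PoemParams(**raw.pop("params", {}))
        return cls(params=params, **raw)

    def to_json(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(data, indent=2) + "\n")


def read_genotypes(
    path: str | Path,
    dialect: str = "numeric",
    allele_map: Mapping[str, int] | None = None,
) -> GenotypeMatrix:
    """Read a genotype TSV in the numeric or biallelic-letter dialect.

    Unknown symbols (including heterozygous calls such as ``H``) are
    rejected with the offending variant and individual named.
    """
    if dialect not in ("numeric", "letter"):
        raise ValueError("dialect must be 'numeric' or 'letter'")
    if dialect == "letter" and not allele_map:
        raise ValueError("the letter dialect requires an allele_map")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "variant_id" not in df.columns:
        raise ValueError("genotype table lacks a variant_id column")
    has_coords = "chrom" in df.columns and "pos_bp" in df.columns
    individual_ids = [c for c in df.columns if c not in _GENO_META]
    if not individual_ids:
        raise ValueError("genotype table has no individual columns")
    calls = df[individual_ids]
    if dialect == "letter":
        mapped = calls.apply(lambda col: col.map({str(k): v for k, v in allele_map.items()}))
        if mapped.isna().any().any():
            r, c = np.argwhere(mapped.isna().to_numpy())[0]
            raise ValueError(
                f"unmapped genotype symbol {calls.iat[r, c]!r} at variant "
                f"{df['variant_id'].iat[r]!r}, individual {individual_ids[c]!r}"
            )
        values = mapped.to_numpy(dtype=float)
    else:
        try:
            values = calls.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"non-numeric genotype call: {exc}") from None
    bad = ~np.isin(values, (-1.0, 1.0))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"genotype call {calls.iat[r, c]!r} at variant {df['variant_id'].iat[r]!r}, "
            f"individual {individual_ids[c]!r} is not a valid homozygous -1/+1 call"
        )
    return GenotypeMatrix(
        values=values.T,
        variant_ids=df["variant_id"].tolist(),
        individual_ids=individual_ids,
        variant_chrom=df["chrom"].tolist() if has_coords else None,
        variant_pos_bp=df["pos_bp"].astype(int).tolist() if has_coords else None,
    )


def write_genotypes(G: GenotypeMatrix, path: str | Path) -> None:
    data = {"variant_id": list(G.variant_ids)}
    if G.has_coordinates:
        data["chrom"] = list(G.variant_chrom)
        data["pos_bp"] = [int(p) for p in G.variant_pos_bp]
    df = pd.DataFrame(data)
    calls = pd.DataFrame(
        G.values.T.astype(int), columns=list(G.individual_ids), index=df.index
    )
    pd.concat([df, calls], axis=1).to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> TraitMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"trait_id": str})
    if "trait_id" not in df.columns:
        raise ValueError("expression table lacks a trait_id column")
    individual_ids = [c for c in df.columns if c not in _EXPR_META]
    values = df[individual_ids].to_numpy(dtype=float)
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"non-numeric or missing expression value at trait "
            f"{df['trait_id'].iat[r]!r}, individual {individual_ids[c]!r}"
        )

    def col(name):
        return df[name].tolist() if name in df.columns else None

    pos = None
    if "gene_pos_bp" in df.columns:
        pos = [None if pd.isna(p) else int(p) for p in df["gene_pos_bp"]]
    return TraitMatrix(
        values=values.T,
        trait_ids=df["trait_id"].tolist(),
        individual_ids=individual_ids,
        gene_name=col("gene"),
        stimulus=col("stimulus"),
        gene_chrom=col("gene_chrom"),
        gene_pos_bp=pos,
    )


def write_expression(Y: TraitMatrix, path: str | Path) -> None:
    data = {"trait_id": list(Y.trait_ids)}
    if Y.gene_name is not None:
        data["gene"] = list(Y.gene_name)
    if Y.stimulus is not None:
        data["stimulus"] = list(Y.stimulus)
    if Y.gene_chrom is not None:
        data["gene_chrom"] = list(Y.gene_chrom)
    if Y.gene_pos_bp is not None:
        data["gene_pos_bp"] = list(Y.gene_pos_bp)
    df = pd.DataFrame(data)
    vals = pd.DataFrame(Y.values.T, columns=list(Y.individual_ids), index=df.index)
    pd.concat([df, vals], axis=1).to_csv(path, sep="\t", index=False)


def read_gene_locations(path: str | Path) -> pd.DataFrame:
    """BED-like gene locations -> DataFrame(gene, chrom, pos_bp), 1-based."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene"], usecols=range(4), dtype={"chrom": str},
    )
    # BED is 0-based half-open; the gene's point position is its start, 1-based.
    df["pos_bp"] = df["start"].astype(int) + 1
    return df[["gene", "chrom", "pos_bp"]]


def compute_response(
    stimulated: TraitMatrix, steady: TraitMatrix, log_base: float | None = 2.0
) -> TraitMatrix:
    """Per-gene stimulation response: difference of log expression levels.

    With ``log_base=None`` the inputs are taken as already log-transformed
    and subtracted directly.
    """
    if list(stimulated.trait_ids) != list(steady.trait_ids):
        raise ValueError("stimulated and steady-state tables must list the same traits")
    if list(stimulated.individual_ids) != list(steady.individual_ids):
        raise ValueError("stimulated and steady-state tables must share individuals")
    if log_base is None:
        diff = stimulated.values - steady.values
    else:
        scale = np.log(log_base)
        diff = (np.log(stimulated.values) - np.log(steady.values)) / scale
    return stimulated.with_values(diff)


def write_grouping(solution: GroupingSolution, path: str | Path) -> None:
    rows = []
    for gid, grp in enumerate(solution.groups):
        for trait_id in grp.trait_ids:
            rows.append(
                {
                    "trait_id": trait_id,
                    "group_id": gid,
                    "representative_variant": grp.representative,
                    "group_score": grp.score,
                }
            )
    pd.DataFrame(
        rows, columns=["trait_id", "group_id", "representative_variant", "group_score"]
    ).to_csv(path, sep="\t", index=False)


def write_predictions(preds: list[PairPrediction], path: str | Path) -> None:
    rows = [
        {
            "trait_id": p.trait_id,
            "primary_variant": p.primary_variant,
            "secondary_variant": p.secondary_variant,
            "primary_P": p.primary_P,
            "secondary_P": p.secondary_P,
            "pair_P": p.pair_P,
        }
        for p in preds
    ]
    pd.DataFrame(
        rows,
        columns=["trait_id", "primary_variant", "secondary_variant",
                 "primary_P", "secondary_P", "pair_P"],
    ).to_csv(path, sep="\t", index=False)


def _variant_label(G: GenotypeMatrix, variant_id: str) -> str:
    if G.has_coordinates:
        i = G.variant_index(variant_id)
        return f"{G.variant_chrom[i]}:{int(G.variant_pos_bp[i])}"
    return variant_id


def write_modules(modules: list[PoeModule], G: GenotypeMatrix, path: str | Path) -> None:
    rows = [
        {
            "module_id": f"M{i + 1}",
            "primary_variant": _variant_label(G, m.primary_variant),
            "secondary_variant": _variant_label(G, m.secondary_variant),
            "n_traits": m.size,
            "overlap_P": m.overlap_P,
            "is_epistatic": m.is_epistatic,
            "cis_trans_label": m.cis_trans_label,
            "trait_ids": ",".join(sorted(m.trait_ids)),
        }
        for i, m in enumerate(modules)
    ]
    pd.DataFrame(
        rows,
        columns=["module_id", "primary_variant", "secondary_variant", "n_traits",
                 "overlap_P", "is_epistatic", "cis_trans_label", "trait_ids"],
    ).to_csv(path, sep="\t", index=False)


def model_to_json(model: PoemModel, path: str | Path) -> None:
    """Serialize a full model (groups, maps, trace, modules) as JSON."""

    def groups(sol: GroupingSolution):
        return [
            {
                "trait_ids": sorted(g.trait_ids),
                "representative": g.representative,
                "score": g.score,
            }
            for g in sol.groups
        ]

    def eqtl_map(vmap):
        return {
            t: {"variant": e.variant_id, "mu_hat": e.mu_hat, "beta_hat": e.beta_hat}
            for t, e in sorted(vmap.entries.items())
        }

    payload = {
        "primary_groups": groups(model.primary_groups),
        "secondary_groups": groups(model.secondary_groups),
        "primary_map": eqtl_map(model.primary_map),
        "secondary_map": eqtl_map(model.secondary_map),
        "iteration_trace": model.iteration_trace,
        "modules": [
            {
                "trait_ids": sorted(m.trait_ids),
                "primary_variant": m.primary_variant,
                "secondary_variant": m.secondary_variant,
                "overlap_P": m.overlap_P,
                "is_epistatic": m.is_epistatic,
                "cis_trans_label": m.cis_trans_label,
            }
            for m in model.modules
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
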