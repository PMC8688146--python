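"""Translatome (TRAP) differential-expression overlap filter.

Operates on generic DE result tables — one row per gene with biotype, mean
expression (TPM), log2 fold change and BH-adjusted p-value — and applies the
filter chain used to compare a cell-type translatome across two conditions:

1. ``prefilter``: keep protein-coding genes with mean TPM ≥ 1.
2. ``tanycyte_enriched``: genes upregulated in the ribosomal pulldown (IP)
   versus input (adjusted p ≤ 0.05 and log2FC > 0) define the cell-type
   (tanycyte) related set.
3. ``common_degs``: genes significant (adjusted p < 0.05) in *both*
   condition comparisons with the *same* fold-change sign, partitioned into
   concordant-up and concordant-down sets.
4. ``restrict_to``: intersect those sets with the cell-type set and report
   counts.

Boundary conventions are deliberately asymmetric (≤ 0.05 for the enrichment
gate, < 0.05 for the common-DEG gate), matching the printed thresholds of
the filter chain this reproduces.  DE statistics themselves are *not*
computed here: any table honouring the schema works.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "GeneSet",
    "PlantSpec",
    "prefilter",
    "tanycyte_enriched",
    "common_degs",
    "restrict_to",
    "simulate_de_tables",
    "overlap_report",
]

REQUIRED_COLUMNS = ("gene_id", "biotype", "mean_tpm", "log2fc", "padj")


class SchemaError(ValueError):
    """A DE table is missing required columns or has duplicate gene ids."""


def _check_schema(table: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(f"DE table is missing columns: {sorted(missing)}")
    if table["gene_id"].duplicated().any():
        raise SchemaError("gene_id values must be unique")


@dataclass(frozen=True)
class GeneSet:
    """A set of gene ids with a provenance label."""

    genes: frozenset[str]
    label: str

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, g: str) -> bool:
        return g in self.genes


def prefilter(table: pd.DataFrame) -> pd.DataFrame:
    """Keep protein-coding genes with mean TPM ≥ 1 (boundary inclusive)."""
    _check_schema(table)
    keep = (table["biotype"] == "protein_coding") & (table["mean_tpm"] >= 1.0)
    return table.loc[keep].reset_index(drop=True)


def tanycyte_enriched(ip_vs_input: pd.DataFrame) -> GeneSet:
    """IP-vs-input enrichment gate: adjusted p ≤ 0.05 and log2FC > 0."""
    _check_schema(ip_vs_input)
    sel = (ip_vs_input["padj"] <= 0.05) & (ip_vs_input["log2fc"] > 0)
    return GeneSet(frozenset(ip_vs_input.loc[sel, "gene_id"]), label="tanycyte_enriched")


def common_degs(table_a: pd.DataFrame, table_b: pd.DataFrame) -> tuple[GeneSet, GeneSet]:
    """Genes significant (adjusted p < 0.05) in both tables with concordant
    log2FC sign, partitioned into (up, down)."""
    _check_schema(table_a)
    _check_schema(table_b)
    a = table_a.set_index("gene_id")
    b = table_b.set_index("gene_id")
    shared = a.index.intersection(b.index)
    a, b = a.loc[shared], b.loc[shared]
    sig = (a["padj"] < 0.05) & (b["padj"] < 0.05)
    up = sig & (a["log2fc"] > 0) & (b["log2fc"] > 0)
    down = sig & (a["log2fc"] < 0) & (b["log2fc"] < 0)
    return (
        GeneSet(frozenset(shared[up]), label="common_up"),
        GeneSet(frozenset(shared[down]), label="common_down"),
    )


def restrict_to(
    sets: tuple[GeneSet, GeneSet], tanycyte: GeneSet
) -> tuple[GeneSet, GeneSet, dict[str, int]]:
    """Intersect (up, down) with the cell-type set; returns sets plus counts."""
    up, down = sets
    up_t = GeneSet(up.genes & tanycyte.genes, label=f"{up.label}&{tanycyte.label}")
    down_t = GeneSet(down.genes & tanycyte.genes, label=f"{down.label}&{tanycyte.label}")
    counts = {
        "n_common_up": len(up),
        "n_common_down": len(down),
        "n_common": len(up) + len(down),
        "n_common_up_tanycyte": len(up_t),
        "n_common_down_tanycyte": len(down_t),
    }
    return up_t, down_t, counts


@dataclass(frozen=True)
class PlantSpec:
    """Planted structure for the synthetic DE-table generator.

    Defaults mirror the published overlap structure: 74 concordant-up and 50
    concordant-down genes, of which 60 and 28 respectively lie inside the
    cell-type-enriched set.  ``n_null`` background genes are non-significant
    everywhere; ``n_discordant`` are significant in both comparisons with
    opposite signs; ``n_single`` are significant in only one comparison;
    ``n_noncoding`` and ``n_low_tpm`` exercise the pre-filter.
    """

    n_up: int = 74
    n_down: int = 50
    n_up_tanycyte: int = 60
    n_down_tanycyte: int = 28
    n_null: int = 1500
    n_discordant: int = 20
    n_single: int = 40
    n_noncoding: int = 60
    n_low_tpm: int = 40

    def __post_init__(self) -> None:
        if self.n_up_tanycyte > self.n_up or self.n_down_tanycyte > self.n_down:
            raise ValueError("tanycyte-overlap counts cannot exceed the common-DEG counts")
        if min(self.n_up, self.n_down, self.n_up_tanycyte, self.n_down_tanycyte) < 0:
            raise ValueError("planted counts must be nonnegative")


def simulate_de_tables(
    spec: PlantSpec = PlantSpec(), seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (ip_vs_input, comparison_a, comparison_b) tables whose filter
    outcomes equal the planted truth exactly.  Deterministic given ``seed``."""
    rng = np.random.default_rng([seed, 47])

    roles: list[tuple[str, str, bool]] = []  # (role, biotype, tanycyte-member)
    for i in range(spec.n_up):
        roles.append(("up", "protein_coding", i < spec.n_up_tanycyte))
    for i in range(spec.n_down):
        roles.append(("down", "protein_coding", i < spec.n_down_tanycyte))
    for i in range(spec.n_discordant):
        roles.append(("discordant", "protein_coding", i % 2 == 0))
    for i in range(spec.n_single):
        roles.append(("single", "protein_coding", i % 3 == 0))
    for i in range(spec.n_null):
        roles.append(("null", "protein_coding", i % 4 == 0))
    for _ in range(spec.n_noncoding):
        roles.append(("null", "lncRNA", False))
    for _ in range(spec.n_low_tpm):
        roles.append(("low_tpm", "protein_coding", False))

    n = len(roles)
    gene_ids = [f"gene{i:05d}" for i in range(n)]
    order = rng.permutation(n)

    def sig_p() -> float:
        return float(rng.uniform(1e-8, 0.04))

    def null_p() -> float:
        return float(rng.uniform(0.1, 1.0))

    rows_ip, rows_a, rows_b = [], [], []
    for gid, (role, biotype, tany) in zip(gene_ids, roles):
        tpm = float(rng.uniform(0.01, 0.9)) if role == "low_tpm" else float(rng.lognormal(3.0, 1.0) + 1.0)
        ip_lfc = float(rng.uniform(0.5, 4.0)) if tany else float(rng.uniform(-3.0, 0.0))
        ip_p = sig_p() if tany else null_p()
        rows_ip.append((gid, biotype, tpm, ip_lfc, ip_p))

        if role == "up":
            la, pa = rng.uniform(0.3, 3.0), sig_p()
            lb, pb = rng.uniform(0.3, 3.0), sig_p()
        elif role == "down":
            la, pa = rng.uniform(-3.0, -0.3), sig_p()
            lb, pb = rng.uniform(-3.0, -0.3), sig_p()
        elif role == "discordant":
            la, pa = rng.uniform(0.3, 3.0), sig_p()
            lb, pb = rng.uniform(-3.0, -0.3), sig_p()
        elif role == "single":
            la, pa = rng.uniform(0.3, 3.0), sig_p()
            lb, pb = rng.uniform(-1.0, 1.0), null_p()
        else:
            la, pa = rng.uniform(-1.0, 1.0), null_p()
            lb, pb = rng.uniform(-1.0, 1.0), null_p()
        rows_a.append((gid, biotype, tpm, float(la), float(pa)))
        rows_b.append((gid, biotype, tpm, float(lb), float(pb)))

    cols = list(REQUIRED_COLUMNS)
    make = lambda rows: pd.DataFrame(rows, columns=cols).iloc[order].reset_index(drop=True)
    return make(rows_ip), make(rows_a), make(rows_b)


def overlap_report(
    ip_vs_input: pd.DataFrame, table_a: pd.DataFrame, table_b: pd.DataFrame
) -> dict:
    """Full filter chain; returns the counts report plus the gene sets."""
    ip = prefilter(ip_vs_input)
    a = prefilter(table_a)
    b = prefilter(table_b)
    tany = tanycyte_enriched(ip)
    up, down = common_degs(a, b)
    up_t, down_t, counts = restrict_to((up, down), tany)
    counts["n_tanycyte_enriched"] = len(tany)
    return {
        "counts": counts,
        "up": sorted(up.genes),
        "down": sorted(down.genes),
        "up_tanycyte": sorted(up_t.genes),
        "down_tanycyte": sorted(down_t.genes),
        "tanycyte_enriched": sorted(tany.genes),
    }
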