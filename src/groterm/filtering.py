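"""Gene inclusion filters for the termination analysis.

Three criteria restrict the analyzed set to genes whose terminator
region is interpretable: (1) the 3' end must be at least 500 nt from the
next gene on the same strand, so readthrough signal is not confounded by
a neighbor's transcription; (2) the gene must be at least 500 nt long,
so the upstream reference window sits in the gene body; (3) the gene
must be transcriptionally active — at least 1 read per nucleotide within
the CDS in a minimum number of replicates (default 3, pooled across
genotypes). All thresholds are inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotation import GeneModel, NeighborDistance
from .coverage import CoverageTrack, cds_reads


class FilterError(ValueError):
    pass


@dataclass(frozen=True)
class FilterConfig:
    min_neighbor_distance_nt: int = 500
    min_length_nt: int = 500
    min_expression_reads_per_nt: float = 1.0
    min_replicates_passing: int = 3

    def __post_init__(self) -> None:
        if (
            self.min_neighbor_distance_nt < 0
            or self.min_length_nt < 0
            or self.min_expression_reads_per_nt < 0
            or self.min_replicates_passing < 0
        ):
            raise FilterError("filter thresholds must be >= 0")


@dataclass
class FilterReport:
    per_gene: pd.DataFrame  # gene_id, distance_ok, length_ok, expression_ok, passed
    funnel: dict[str, int]  # successive surviving counts in filter order
    passed_genes: list[str]

    def to_tsv(self, per_gene_path: str | Path, funnel_path: str | Path) -> None:
        self.per_gene.to_csv(per_gene_path, sep="\t", index=False)
        pd.DataFrame(
            {"filter": list(self.funnel), "surviving": list(self.funnel.values())}
        ).to_csv(funnel_path, sep="\t", index=False)


def expression_level(track: CoverageTrack, gene: GeneModel) -> float:
    """Reads per nucleotide within the CDS (strand-matched)."""
    if gene.cds_length_nt <= 0:
        raise FilterError(f"{gene.gene_id}: zero-length CDS")
    return cds_reads(track, gene) / gene.cds_length_nt


def apply_filters(
    genes: Sequence[GeneModel],
    distances: Sequence[NeighborDistance] | Mapping[str, float],
    tracks: Sequence[CoverageTrack],
    config: FilterConfig = FilterConfig(),
) -> FilterReport:
    """Apply the three inclusion filters; thresholds are inclusive.

    The expression criterion pools replicates across genotypes and asks
    for at least ``min_replicates_passing`` of them at or above the
    reads/nt threshold. The funnel counts survivors after each filter
    applied in order distance -> length -> expression; the final set is
    order-independent (pure intersection).
    """
    if not genes:
        raise FilterError("empty gene set")
    if not tracks:
        raise FilterError("empty track set")
    if not isinstance(distances, Mapping):
        distances = {d.gene_id: d.distance_nt for d in distances}

    rows = []
    for g in genes:
        dist = distances.get(g.gene_id, math.inf)
        distance_ok = dist >= config.min_neighbor_distance_nt
        length_ok = g.length_nt >= config.min_length_nt
        n_pass = sum(
            expression_level(t, g) >= config.min_expression_reads_per_nt
            for t in tracks
        )
        expression_ok = n_pass >= config.min_replicates_passing
        rows.append(
            {
                "gene_id": g.gene_id,
                "neighbor_distance": dist,
                "length_nt": g.length_nt,
                "replicates_expressed": n_pass,
                "distance_ok": distance_ok,
                "length_ok": length_ok,
                "expression_ok": expression_ok,
                "passed": distance_ok and length_ok and expression_ok,
            }
        )
    per_gene = pd.DataFrame(rows)
    funnel = {
        "input": len(per_gene),
        "distance": int(per_gene["distance_ok"].sum()),
        "length": int((per_gene["distance_ok"] & per_gene["length_ok"]).sum()),
        "expression": int(per_gene["passed"].sum()),
    }
    return FilterReport(
        per_gene=per_gene,
        funnel=funnel,
        passed_genes=per_gene.loc[per_gene["passed"], "gene_id"].tolist(),
    )
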