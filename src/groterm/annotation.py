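"""Gene annotation I/O and neighbor-distance computation.

All coordinates are held in a single internal convention: 0-based,
half-open ``[start, end)``. GFF3 input (1-based, inclusive) is converted
on read; BED input is taken as-is. Each gene carries one poly(A) site —
the strand-aware last transcribed nucleotide — which anchors every
readthrough window downstream in the pipeline. An optional sidecar TSV
can override the poly(A) site per gene, because curated 3'-end (cleavage
site) annotations generally differ from CDS/transcript ends.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


class AnnotationError(ValueError):
    """Raised for malformed annotation records."""


@dataclass(frozen=True)
class GeneModel:
    """One protein-coding gene in internal 0-based half-open coordinates.

    ``polyA_site`` is the 0-based coordinate of the last transcribed
    nucleotide (``end - 1`` on the + strand, ``start`` on the - strand,
    unless overridden).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    polyA_site: int
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise AnnotationError(f"{self.gene_id}: strand must be one of {STRANDS}")
        if not self.start < self.end:
            raise AnnotationError(f"{self.gene_id}: start must be < end")
        if not (self.start <= self.cds_start < self.cds_end <= self.end):
            raise AnnotationError(f"{self.gene_id}: CDS bounds not nested in gene")
        if self.polyA_site < 0:
            raise AnnotationError(f"{self.gene_id}: negative polyA_site")

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def cds_length_nt(self) -> int:
        return self.cds_end - self.cds_start


@dataclass(frozen=True)
class NeighborDistance:
    """Distance (nt) from a gene's 3' end to the nearest same-strand
    downstream gene edge; ``math.inf`` when no such neighbor exists."""

    gene_id: str
    distance_nt: float

    def __post_init__(self) -> None:
        if self.distance_nt < 0:
            raise AnnotationError(f"{self.gene_id}: negative neighbor distance")


def default_polya_site(strand: str, start: int, end: int) -> int:
    """Strand-aware transcript 3' end: last transcribed base."""
    return end - 1 if strand == "+" else start


def load_polya_override(path: str | Path) -> dict[str, int]:
    """Read a sidecar TSV (gene_id, chrom, coord, strand) of poly(A) sites."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["gene_id", "chrom", "coord", "strand"],
        comment="#",
    )
    return dict(zip(df["gene_id"], df["coord"].astype(int)))


def _genes_from_gff3(path: str | Path) -> list[GeneModel]:
    import gffutils

    with open(path) as fh:
        has_features = any(
            line.strip() and not line.startswith("#") for line in fh
        )
    if not has_features:
        return []  # valid header-only file: no genes
    try:
        db = gffutils.create_db(
            str(path), ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises heterogeneous errors
        raise AnnotationError(f"failed to parse GFF3 {path}: {exc}") from exc

    genes: list[GeneModel] = []
    skipped_no_cds = 0
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        start = feat.start - 1  # GFF3 is 1-based inclusive
        end = feat.end
        cds = [c for c in db.children(feat, featuretype="CDS")]
        if cds:
            cds_start = min(c.start for c in cds) - 1
            cds_end = max(c.end for c in cds)
        else:
            skipped_no_cds += 1
            cds_start, cds_end = start, end
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=feat.seqid,
                strand=feat.strand,
                start=start,
                end=end,
                polyA_site=default_polya_site(feat.strand, start, end),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    if skipped_no_cds:
        logger.info(
            "%d genes had no CDS feature; gene bounds used as CDS", skipped_no_cds
        )
    return genes


def _genes_from_bed(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AnnotationError(
                    f"{path}:{lineno}: BED6 requires 6 columns, got {len(fields)}"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinate") from exc
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    start=start_i,
                    end=end_i,
                    polyA_site=default_polya_site(strand, start_i, end_i),
                    cds_start=start_i,
                    cds_end=end_i,
                )
            )
    return genes


def load_annotation(
    path: str | Path,
    fmt: str | None = None,
    polya_override: Mapping[str, int] | str | Path | None = None,
) -> list[GeneModel]:
    """Load gene models from GFF3 or BED6 into internal coordinates.

    Parameters
    ----------
    path:
        Annotation file. Format inferred from the extension unless ``fmt``
        is given ("gff3" or "bed").
    polya_override:
        Mapping (or sidecar TSV path) of gene_id -> poly(A) coordinate,
        replacing the default transcript-end poly(A) site.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower().lstrip(".")
        fmt = {"gff": "gff3", "gff3": "gff3", "bed": "bed"}.get(suffix)
        if fmt is None:
            raise AnnotationError(f"cannot infer format from {path.name}")
    if fmt == "gff3":
        genes = _genes_from_gff3(path)
    elif fmt == "bed":
        genes = _genes_from_bed(path)
    else:
        raise AnnotationError(f"unsupported annotation format: {fmt}")

    if polya_override is not None:
        if not isinstance(polya_override, Mapping):
            polya_override = load_polya_override(polya_override)
        genes = [
            replace(g, polyA_site=polya_override.get(g.gene_id, g.polyA_site))
            for g in genes
        ]
    return genes


def neighbor_distances(genes: Sequence[GeneModel]) -> list[NeighborDistance]:
    """Distance from each gene's 3' end to the nearest same-strand gene
    lying downstream of its poly(A) site (readthrough direction).

    Downstream means increasing coordinates on the + strand, decreasing
    on the - strand. The distance counts intervening nucleotides between
    the poly(A) site and the neighbor's nearest edge; overlapping genes
    give 0, and a gene with no downstream same-strand neighbor gets
    ``math.inf``, which passes any threshold.
    """
    out: list[NeighborDistance] = []
    by_group: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_group.setdefault((g.chrom, g.strand), []).append(g)

    for (_, strand), group in by_group.items():
        for g in group:
            best = math.inf
            for h in group:
                if h.gene_id == g.gene_id:
                    continue
                if strand == "+":
                    if h.end > g.polyA_site:  # some part lies 3' of the poly(A)
                        best = min(best, max(0, h.start - g.polyA_site - 1))
                else:
                    if h.start < g.polyA_site:
                        best = min(best, max(0, g.polyA_site - h.end))
            out.append(NeighborDistance(gene_id=g.gene_id, distance_nt=best))
    return out


def write_bed6(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def write_gene_table(
    genes: Sequence[GeneModel],
    distances: Sequence[NeighborDistance],
    path: str | Path,
) -> pd.DataFrame:
    """Write the canonical gene table TSV and return it as a DataFrame."""
    dist = {d.gene_id: d.distance_nt for d in distances}
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "polyA_site": [g.polyA_site for g in genes],
            "cds_start": [g.cds_start for g in genes],
            "cds_end": [g.cds_end for g in genes],
            "neighbor_distance": [dist.get(g.gene_id, math.inf) for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return df
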