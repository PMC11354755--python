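"""Strand-specific per-nucleotide coverage tracks and gene signal extraction.

A :class:`CoverageTrack` holds one replicate's dense per-chromosome,
per-strand arrays of 3'-end read counts per nucleotide. The primary
ingestion format is a bedGraph pair (plus/minus strand); BAM input is a
convenience that counts the 3'-terminal aligned base of each read on the
read's strand. No between-library normalization happens at load time —
every downstream statistic is a ratio or CDS-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .annotation import GeneModel

STRANDS = ("+", "-")


class CoverageError(ValueError):
    pass


@dataclass
class CoverageTrack:
    """Dense strand-specific 3'-end read coverage for one replicate."""

    sample_id: str
    genotype: str
    replicate: int
    chrom_sizes: dict[str, int]
    data: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def array(self, chrom: str, strand: str) -> np.ndarray:
        key = (chrom, strand)
        if key not in self.data:
            if chrom not in self.chrom_sizes:
                raise CoverageError(f"unknown chromosome {chrom!r}")
            self.data[key] = np.zeros(self.chrom_sizes[chrom], dtype=np.float64)
        return self.data[key]

    def total_reads(self) -> float:
        return float(sum(a.sum() for a in self.data.values()))

    def scaled(self, k: float) -> "CoverageTrack":
        """Return a copy with every count multiplied by ``k``."""
        return CoverageTrack(
            sample_id=self.sample_id,
            genotype=self.genotype,
            replicate=self.replicate,
            chrom_sizes=dict(self.chrom_sizes),
            data={key: arr * k for key, arr in self.data.items()},
        )


@dataclass(frozen=True)
class GeneSignal:
    """Signal vector oriented 5'->3' along the gene's strand.

    ``truncated`` marks windows that ran off a chromosome end; such genes
    are excluded wherever full windows are required (padding with zeros
    would bias readthrough ratios).
    """

    gene_id: str
    sample_id: str
    values: np.ndarray
    truncated: bool = False


def load_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def _read_bedgraph(path: str | Path, chrom_sizes: Mapping[str, int]) -> dict[str, np.ndarray]:
    arrays = {c: np.zeros(n, dtype=np.float64) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise CoverageError(f"{path}:{lineno}: bedGraph needs 4 columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in chrom_sizes:
                raise CoverageError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if start < 0 or end > chrom_sizes[chrom]:
                raise CoverageError(
                    f"{path}:{lineno}: interval [{start},{end}) outside {chrom!r} "
                    f"(length {chrom_sizes[chrom]})"
                )
            arrays[chrom][start:end] += value
    return arrays


def load_coverage(
    plus_path: str | Path,
    minus_path: str | Path,
    chrom_sizes: Mapping[str, int],
    sample_id: str = "sample",
    genotype: str = "WT",
    replicate: int = 1,
) -> CoverageTrack:
    """Load a strand-specific bedGraph pair into a dense track."""
    for p in (plus_path, minus_path):
        if not Path(p).exists():
            raise CoverageError(f"strand coverage file missing: {p}")
    plus = _read_bedgraph(plus_path, chrom_sizes)
    minus = _read_bedgraph(minus_path, chrom_sizes)
    data: dict[tuple[str, str], np.ndarray] = {}
    for chrom in chrom_sizes:
        data[(chrom, "+")] = plus[chrom]
        data[(chrom, "-")] = minus[chrom]
    return CoverageTrack(
        sample_id=sample_id,
        genotype=genotype,
        replicate=replicate,
        chrom_sizes=dict(chrom_sizes),
        data=data,
    )


def load_coverage_bam(
    path: str | Path,
    chrom_sizes: Mapping[str, int],
    sample_id: str = "sample",
    genotype: str = "WT",
    replicate: int = 1,
) -> CoverageTrack:
    """Count each aligned read once, at its 3'-most aligned position on
    its strand (reference end - 1 for forward reads, reference start for
    reverse reads)."""
    import pysam

    track = CoverageTrack(
        sample_id=sample_id,
        genotype=genotype,
        replicate=replicate,
        chrom_sizes=dict(chrom_sizes),
    )
    with pysam.AlignmentFile(str(path)) as bam:  # autodetects SAM/BAM
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            chrom = read.reference_name
            if chrom not in chrom_sizes:
                raise CoverageError(f"BAM read on unknown chromosome {chrom!r}")
            if read.is_reverse:
                track.array(chrom, "-")[read.reference_start] += 1
            else:
                track.array(chrom, "+")[read.reference_end - 1] += 1
    return track


def extract_signal(
    track: CoverageTrack,
    gene: GeneModel,
    window: tuple[int, int],
    anchor: str = "polya",
) -> GeneSignal:
    """Extract a strand-oriented signal vector around an anchor.

    ``window`` is half-open ``[lo, hi)`` in transcription-sense offsets:
    negative = upstream of the anchor, index 0 of the returned array is
    the most 5' requested offset. On the - strand positions run in
    decreasing genomic coordinates. Positions off the chromosome are
    dropped and the signal flagged ``truncated``.
    """
    lo, hi = window
    if hi <= lo:
        raise CoverageError(f"empty window {window}")
    if anchor == "polya":
        anchor_pos = gene.polyA_site
    elif anchor == "cds":
        anchor_pos = gene.cds_start if gene.strand == "+" else gene.cds_end - 1
    else:
        raise CoverageError(f"unknown anchor {anchor!r}")

    arr = track.array(gene.chrom, gene.strand)
    offsets = np.arange(lo, hi)
    pos = anchor_pos + offsets if gene.strand == "+" else anchor_pos - offsets
    mask = (pos >= 0) & (pos < arr.shape[0])
    values = arr[pos[mask]]
    return GeneSignal(
        gene_id=gene.gene_id,
        sample_id=track.sample_id,
        values=values,
        truncated=not bool(mask.all()),
    )


def cds_reads(track: CoverageTrack, gene: GeneModel) -> float:
    """Total strand-matched reads within the gene's CDS."""
    arr = track.array(gene.chrom, gene.strand)
    return float(arr[gene.cds_start : gene.cds_end].sum())


def write_bedgraph_pair(
    track: CoverageTrack, plus_path: str | Path, minus_path: str | Path
) -> None:
    """Run-length encode each strand's dense array back to bedGraph."""
    for strand, path in (("+", plus_path), ("-", minus_path)):
        with open(path, "w") as fh:
            for chrom in sorted(track.chrom_sizes):
                arr = track.data.get((chrom, strand))
                if arr is None:
                    continue
                for start, end, value in _runs(arr):
                    fh.write(f"{chrom}\t{start}\t{end}\t{_fmt(value)}\n")


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def _runs(arr: np.ndarray) -> Iterator[tuple[int, int, float]]:
    """Yield (start, end, value) runs of nonzero values."""
    if arr.size == 0:
        return
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [arr.size]))
    for s, e in zip(starts, ends):
        v = float(arr[s])
        if v != 0.0:
            yield int(s), int(e), v


def load_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet TSV: sample_id, genotype, replicate, plus_path, minus_path."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "genotype", "replicate", "plus_path", "minus_path"}
    missing = required - set(df.columns)
    if missing:
        raise CoverageError(f"sample sheet missing columns: {sorted(missing)}")
    return df


def load_tracks_from_sheet(
    sheet: pd.DataFrame, chrom_sizes: Mapping[str, int], base_dir: str | Path = "."
) -> list[CoverageTrack]:
    base = Path(base_dir)
    tracks = []
    for row in sheet.itertuples():
        tracks.append(
            load_coverage(
                base / row.plus_path,
                base / row.minus_path,
                chrom_sizes,
                sample_id=str(row.sample_id),
                genotype=str(row.genotype),
                replicate=int(row.replicate),
            )
        )
    return tracks
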