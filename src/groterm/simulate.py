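"""Synthetic data with known ground truth for the whole pipeline.

The coverage simulator emulates strand-specific nascent-RNA 3'-end
coverage: polymerase density is flat across the gene body (Poisson with
mean ``body_rate`` reads/nt), drops at the poly(A) site, and a fraction
``r`` of polymerases read through, giving downstream density
``body_rate * r`` — constant over ``readthrough_extent_nt`` and zero
beyond (or decaying with a half-life when requested). Because the
readthrough index only sees densities, a plateau/decay model suffices;
no per-polymerase trajectories or sequencing reads are simulated.

Default parameters mirror the study conditions the pipeline is meant to
analyze: 200 genes, body rate 10 reads/nt, readthrough fraction 0.05 in
wild type vs 0.15 in the mutant, three biological replicates per
genotype. Gene lengths (1000-2000 nt) and same-strand spacings
(600-1200 nt) are drawn so the standard inclusion filters (>=500 nt
length, >=500 nt neighbor distance, >=1 read/nt) pass by construction
and the RTI windows sit inside the gene body.

Everything is deterministic given the seed; per-replicate streams use
independent child seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, default_polya_site
from .coverage import CoverageTrack, write_bedgraph_pair


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 200
    chrom: str = "chrS"
    chrom_length_nt: int | None = None  # None: sized to fit the placements
    gene_length_range: tuple[int, int] = (1000, 2000)
    spacing_range: tuple[int, int] = (600, 1200)
    plus_strand_prob: float = 0.5
    body_rate: float = 10.0  # Poisson mean, reads per nucleotide in the body
    readthrough_wt: float = 0.05
    readthrough_mut: float = 0.15
    readthrough_extent_nt: int = 500
    decay_halflife_nt: float | None = None  # None = constant plateau then zero
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.body_rate < 0:
            raise SimulationError("body_rate must be >= 0")
        for r in (self.readthrough_wt, self.readthrough_mut):
            if not 0.0 <= r <= 1.0:
                raise SimulationError("readthrough fraction must be in [0, 1]")
        if self.gene_length_range[0] > self.gene_length_range[1]:
            raise SimulationError("invalid gene_length_range")
        if self.spacing_range[0] > self.spacing_range[1]:
            raise SimulationError("invalid spacing_range")

    def readthrough(self, genotype: str) -> float:
        return self.readthrough_wt if genotype == "WT" else self.readthrough_mut


@dataclass
class GroundTruth:
    """Noise-free per-gene truth recorded at generation time."""

    readthrough: dict[str, dict[str, float]]  # genotype -> gene_id -> r
    expression: dict[str, float]  # gene_id -> body rate (reads/nt)
    placement: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


# gene placement pads chromosome ends so +/-500 nt windows never truncate
_EDGE_PAD = 1200


def simulate_genome(
    config: SimulationConfig,
) -> tuple[list[GeneModel], dict[str, int], GroundTruth]:
    """Place non-overlapping genes along one chromosome.

    Genes are laid down left to right with a random strand each and a
    random inter-gene spacing, so same-strand neighbor distances are at
    least the requested minimum spacing. Deterministic given the seed.
    """
    rng = np.random.default_rng([config.seed, 101])
    genes: list[GeneModel] = []
    placement = []
    pos = _EDGE_PAD
    for i in range(config.n_genes):
        length = int(rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1))
        strand = "+" if rng.random() < config.plus_strand_prob else "-"
        start, end = pos, pos + length
        gid = f"g{i + 1:04d}"
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=config.chrom,
                strand=strand,
                start=start,
                end=end,
                polyA_site=default_polya_site(strand, start, end),
                cds_start=start,
                cds_end=end,
            )
        )
        placement.append(dict(gene_id=gid, start=start, end=end, strand=strand))
        pos = end + int(rng.integers(config.spacing_range[0], config.spacing_range[1] + 1))

    needed = (genes[-1].end if genes else _EDGE_PAD) + _EDGE_PAD
    if config.chrom_length_nt is None:
        chrom_length = needed
    else:
        chrom_length = config.chrom_length_nt
        if chrom_length < needed:
            raise SimulationError(
                f"placements need {needed} nt but chrom_length_nt={chrom_length}; "
                "increase the chromosome length"
            )
    chrom_sizes = {config.chrom: chrom_length}
    truth = GroundTruth(
        readthrough={
            "WT": {g.gene_id: config.readthrough_wt for g in genes},
            "mut": {g.gene_id: config.readthrough_mut for g in genes},
        },
        expression={g.gene_id: config.body_rate for g in genes},
        placement=placement,
    )
    return genes, chrom_sizes, truth


def simulate_coverage(
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    config: SimulationConfig,
    chrom_sizes: dict[str, int],
    genotype: str,
    replicate: int,
) -> CoverageTrack:
    """One replicate's strand-specific Poisson coverage.

    Per nucleotide of the gene body the count is Poisson(body_rate); for
    strandward offsets 1..readthrough_extent past the poly(A) site it is
    Poisson(body_rate * r * g(d)) with g(d) = 1 in constant mode or
    2^(-d/halflife); zero elsewhere. Overlapping gene windows on one
    strand sum their signals.
    """
    geno_idx = 0 if genotype == "WT" else 1
    rng = np.random.default_rng([config.seed, 211, geno_idx, replicate])
    track = CoverageTrack(
        sample_id=f"{genotype}_rep{replicate}",
        genotype=genotype,
        replicate=replicate,
        chrom_sizes=dict(chrom_sizes),
    )
    ext = config.readthrough_extent_nt
    offsets = np.arange(1, ext + 1, dtype=float)
    if config.decay_halflife_nt is None:
        shape = np.ones_like(offsets)
    else:
        shape = np.power(2.0, -offsets / config.decay_halflife_nt)

    for g in genes:
        arr = track.array(g.chrom, g.strand)
        rate = truth.expression.get(g.gene_id, config.body_rate)
        r = truth.readthrough.get(genotype, {}).get(g.gene_id, config.readthrough(genotype))
        arr[g.start : g.end] += rng.poisson(rate, g.length_nt)
        lam = rate * r * shape
        if lam.max() > 0:
            counts = rng.poisson(lam)
            if g.strand == "+":
                lo = g.polyA_site + 1
                hi = min(lo + ext, arr.shape[0])
                arr[lo:hi] += counts[: hi - lo]
            else:
                hi = g.polyA_site  # exclusive
                lo = max(hi - ext, 0)
                # offset d maps to position polyA - d
                arr[lo:hi] += counts[: hi - lo][::-1]
    return track


def simulate_tracks(
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    config: SimulationConfig,
    chrom_sizes: dict[str, int],
) -> list[CoverageTrack]:
    """All replicates of both genotypes."""
    return [
        simulate_coverage(genes, truth, config, chrom_sizes, genotype, rep)
        for genotype in ("WT", "mut")
        for rep in range(1, config.n_replicates + 1)
    ]


# --- proteomics fixtures -------------------------------------------------

# Synthetic affinity-purification panel: the bait (TFIIB/Sua7) plus
# termination-complex subunits and general transcription factors, with
# realistic yeast protein lengths (aa).
DEFAULT_PROTEIN_PANEL: dict[str, dict] = {
    "SUA7":  dict(length_aa=345, abundance=1.00, mut_multiplier=1.0),   # bait
    "RNA14": dict(length_aa=677, abundance=0.30, mut_multiplier=0.2),
    "RNA15": dict(length_aa=296, abundance=0.35, mut_multiplier=0.2),
    "PCF11": dict(length_aa=626, abundance=0.25, mut_multiplier=0.2),
    "CLP1":  dict(length_aa=445, abundance=0.20, mut_multiplier=0.2),
    "HRP1":  dict(length_aa=534, abundance=0.20, mut_multiplier=0.2),
    "RAT1":  dict(length_aa=1006, abundance=0.25, mut_multiplier=0.2),
    "RAI1":  dict(length_aa=387, abundance=0.18, mut_multiplier=0.2),
    "PTA1":  dict(length_aa=785, abundance=0.15, mut_multiplier=0.5),
    "YSH1":  dict(length_aa=779, abundance=0.15, mut_multiplier=0.5),
    "CFT1":  dict(length_aa=1357, abundance=0.12, mut_multiplier=0.5),
    "SSU72": dict(length_aa=206, abundance=0.18, mut_multiplier=0.5),
    "TOA1":  dict(length_aa=286, abundance=0.20, mut_multiplier=1.2),
    "TOA2":  dict(length_aa=122, abundance=0.20, mut_multiplier=1.2),
    "TFG1":  dict(length_aa=735, abundance=0.22, mut_multiplier=1.2),
    "TFG2":  dict(length_aa=400, abundance=0.22, mut_multiplier=1.2),
}


def simulate_spectral_counts(
    panel: dict[str, dict] | None = None,
    n_pairs: int = 4,
    fraction: str = "chromatin",
    count_scale: float = 0.5,
    replicate_cv: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired-replicate spectral-count table with a planted genotype effect.

    Counts are Poisson(abundance * length * scale * replicate_factor);
    the per-replicate lognormal factor is shared between genotypes so the
    design is genuinely paired. The bait abundance is constant across
    genotypes (``mut_multiplier`` 1.0).
    """
    panel = DEFAULT_PROTEIN_PANEL if panel is None else panel
    rng = np.random.default_rng([seed, 307])
    sigma = np.sqrt(np.log(1.0 + replicate_cv**2))
    rows = []
    for rep in range(1, n_pairs + 1):
        rep_factor = float(rng.lognormal(mean=-sigma**2 / 2, sigma=sigma))
        for genotype in ("WT", "mut"):
            for pid, spec in panel.items():
                mult = 1.0 if genotype == "WT" else spec["mut_multiplier"]
                lam = spec["abundance"] * mult * spec["length_aa"] * count_scale * rep_factor
                rows.append(
                    dict(
                        protein_id=pid,
                        length_aa=spec["length_aa"],
                        count=int(rng.poisson(lam)),
                        sample_id=f"{genotype}_{fraction}_rep{rep}",
                        genotype=genotype,
                        fraction=fraction,
                        replicate=rep,
                    )
                )
    return pd.DataFrame(rows)


# --- targeted-assay fixtures ---------------------------------------------

CHIP_FACTORS = ("Pta1", "Rna15", "Rat1")
CHIP_GENES = ("BLM10", "HEM3", "KAP123", "SUR1")


def simulate_chip_table(
    decline: float = 0.9,
    n_replicates: int = 3,
    noise_cv: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """ChIP-qPCR fixture: termination-factor occupancy at terminator
    amplicons with a planted fractional decline in the mutant."""
    rng = np.random.default_rng([seed, 401])
    sigma = np.sqrt(np.log(1.0 + noise_cv**2))
    rows = []
    for factor in CHIP_FACTORS:
        for gene in CHIP_GENES:
            base_occ = rng.uniform(1.5, 4.0)
            for genotype in ("WT", "mut"):
                occ = base_occ * (1.0 - decline if genotype == "mut" else 1.0)
                for rep in range(1, n_replicates + 1):
                    noise = rng.lognormal(-sigma**2 / 2, sigma)
                    input_signal = rng.uniform(0.8, 1.2)
                    polII_input = rng.uniform(0.8, 1.2)
                    polII_ratio = rng.uniform(1.5, 2.5)
                    rows.append(
                        dict(
                            factor=factor,
                            gene_id=gene,
                            amplicon="terminator",
                            genotype=genotype,
                            replicate=rep,
                            chip_signal=occ * noise * polII_ratio * input_signal,
                            input_signal=input_signal,
                            polII_chip_signal=polII_ratio * polII_input,
                            polII_input_signal=polII_input,
                        )
                    )
    return pd.DataFrame(rows)


TRO_BODY_PRIMERS = ("5F_3R",)
TRO_DOWNSTREAM_PRIMERS = ("RT1", "RT2", "RT3", "RT4", "RT5")


def simulate_tro_table(
    genes: Sequence[str] = ("BLM10", "HEM3", "KAP123", "SUR1"),
    downstream_fold_increase: float = 3.0,
    n_replicates: int = 3,
    noise_cv: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """TRO fixture: gene-body nascent signal similar between genotypes,
    downstream (post-terminator) signal elevated in the mutant."""
    rng = np.random.default_rng([seed, 503])
    sigma = np.sqrt(np.log(1.0 + noise_cv**2))
    rows = []
    for gene in genes:
        body = rng.uniform(0.5, 1.5)
        down_wt = body * rng.uniform(0.05, 0.15)
        for primer in TRO_BODY_PRIMERS + TRO_DOWNSTREAM_PRIMERS:
            for genotype in ("WT", "mut"):
                if primer in TRO_BODY_PRIMERS:
                    level = body
                else:
                    level = down_wt * (downstream_fold_increase if genotype == "mut" else 1.0)
                for rep in range(1, n_replicates + 1):
                    control = rng.uniform(0.9, 1.1)
                    rows.append(
                        dict(
                            gene_id=gene,
                            primer_id=primer,
                            genotype=genotype,
                            replicate=rep,
                            signal=level * rng.lognormal(-sigma**2 / 2, sigma) * control,
                            control_18S=control,
                        )
                    )
    return pd.DataFrame(rows)


# --- on-disk fixture emission ---------------------------------------------

def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Emit gene + CDS features (1-based inclusive on write)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};biotype=protein_coding"
            fh.write(
                f"{g.chrom}\tgroterm_sim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\tgroterm_sim\tCDS\t{g.cds_start + 1}\t{g.cds_end}\t.\t{g.strand}\t0\t"
                f"ID=cds-{g.gene_id};Parent={g.gene_id}\n"
            )


def write_chrom_sizes(chrom_sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def simulate_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, str]:
    """Write a complete synthetic dataset in the formats the pipeline
    reads, returning a manifest of relative paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, chrom_sizes, truth = simulate_genome(config)
    manifest: dict[str, str] = {}

    write_gff3(genes, outdir / "annotation.gff3")
    manifest["annotation"] = "annotation.gff3"
    write_chrom_sizes(chrom_sizes, outdir / "chrom.sizes")
    manifest["chrom_sizes"] = "chrom.sizes"
    truth.to_json(outdir / "ground_truth.json")
    manifest["ground_truth"] = "ground_truth.json"

    sheet_rows = []
    for track in simulate_tracks(genes, truth, config, chrom_sizes):
        plus = f"{track.sample_id}.plus.bedgraph"
        minus = f"{track.sample_id}.minus.bedgraph"
        write_bedgraph_pair(track, outdir / plus, outdir / minus)
        sheet_rows.append(
            dict(
                sample_id=track.sample_id,
                genotype=track.genotype,
                replicate=track.replicate,
                plus_path=plus,
                minus_path=minus,
            )
        )
    pd.DataFrame(sheet_rows).to_csv(outdir / "samples.tsv", sep="\t", index=False)
    manifest["sample_sheet"] = "samples.tsv"

    simulate_spectral_counts(seed=config.seed).to_csv(
        outdir / "spectral_counts.tsv", sep="\t", index=False
    )
    manifest["spectral_counts"] = "spectral_counts.tsv"
    simulate_chip_table(seed=config.seed).to_csv(
        outdir / "chip.tsv", sep="\t", index=False
    )
    manifest["chip"] = "chip.tsv"
    simulate_tro_table(seed=config.seed).to_csv(
        outdir / "tro.tsv", sep="\t", index=False
    )
    manifest["tro"] = "tro.tsv"
    return manifest
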