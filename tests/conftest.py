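import numpy as np
import pytest

from groterm.annotation import GeneModel, default_polya_site
from groterm.coverage import CoverageTrack
from groterm.simulate import SimulationConfig, simulate_genome, simulate_tracks


def make_gene(
    gene_id="gene1",
    chrom="chrI",
    strand="+",
    start=1000,
    end=2500,
    cds=None,
    polya=None,
) -> GeneModel:
    cds_start, cds_end = cds if cds else (start, end)
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        start=start,
        end=end,
        polyA_site=polya if polya is not None else default_polya_site(strand, start, end),
        cds_start=cds_start,
        cds_end=cds_end,
    )


def make_track(
    arrays: dict[tuple[str, str], np.ndarray],
    chrom_sizes: dict[str, int] | None = None,
    sample_id="s1",
    genotype="WT",
    replicate=1,
) -> CoverageTrack:
    if chrom_sizes is None:
        chrom_sizes = {}
        for (chrom, _), arr in arrays.items():
            chrom_sizes[chrom] = max(chrom_sizes.get(chrom, 0), arr.shape[0])
    return CoverageTrack(
        sample_id=sample_id,
        genotype=genotype,
        replicate=replicate,
        chrom_sizes=chrom_sizes,
        data={k: np.asarray(v, dtype=float) for k, v in arrays.items()},
    )


def uniform_track(genes, density, chrom_sizes, downstream=None, extent=500, **kw):
    """Deterministic coverage: constant `density` over each gene body and
    optionally constant `downstream` density over `extent` nt past the
    poly(A) site (transcription sense)."""
    track = CoverageTrack(
        sample_id=kw.pop("sample_id", "u1"),
        genotype=kw.pop("genotype", "WT"),
        replicate=kw.pop("replicate", 1),
        chrom_sizes=dict(chrom_sizes),
    )
    for g in genes:
        arr = track.array(g.chrom, g.strand)
        arr[g.start : g.end] += density
        if downstream:
            if g.strand == "+":
                arr[g.polyA_site + 1 : g.polyA_site + 1 + extent] += downstream
            else:
                arr[max(g.polyA_site - extent, 0) : g.polyA_site] += downstream
    return track


@pytest.fixture(scope="session")
def recovery_sim():
    """The standard study conditions: 200 genes, body rate 10 reads/nt,
    readthrough 0.05 (WT) vs 0.15 (mutant), 3 replicates per genotype."""
    cfg = SimulationConfig(n_genes=200, seed=11)
    genes, chrom_sizes, truth = simulate_genome(cfg)
    tracks = simulate_tracks(genes, truth, cfg, chrom_sizes)
    return cfg, genes, chrom_sizes, truth, tracks


@pytest.fixture(scope="session")
def null_sim():
    """Null conditions: identical readthrough in both genotypes."""
    cfg = SimulationConfig(n_genes=200, readthrough_mut=0.05, seed=13)
    genes, chrom_sizes, truth = simulate_genome(cfg)
    tracks = simulate_tracks(genes, truth, cfg, chrom_sizes)
    return cfg, genes, chrom_sizes, truth, tracks


@pytest.fixture(scope="session")
def small_sim():
    cfg = SimulationConfig(n_genes=30, seed=7)
    genes, chrom_sizes, truth = simulate_genome(cfg)
    tracks = simulate_tracks(genes, truth, cfg, chrom_sizes)
    return cfg, genes, chrom_sizes, truth, tracks
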