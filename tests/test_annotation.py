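import math

import numpy as np
import pytest

from groterm.annotation import (
    AnnotationError,
    GeneModel,
    default_polya_site,
    load_annotation,
    neighbor_distances,
    write_bed6,
)
from conftest import make_gene

GFF3_TOY = """##gff-version 3
chrI\ttoy\tgene\t101\t200\t.\t+\t.\tID=geneA
chrI\ttoy\tCDS\t111\t190\t.\t+\t0\tID=cds-geneA;Parent=geneA
chrI\ttoy\tgene\t401\t900\t.\t-\t.\tID=geneB
chrI\ttoy\tCDS\t401\t900\t.\t-\t0\tID=cds-geneB;Parent=geneB
chrII\ttoy\tgene\t51\t1050\t.\t+\t.\tID=geneC
chrII\ttoy\tCDS\t51\t1050\t.\t+\t0\tID=cds-geneC;Parent=geneC
"""


@pytest.fixture()
def toy_gff3(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(GFF3_TOY)
    return path


def test_gff3_converts_to_zero_based_half_open(toy_gff3):
    genes = load_annotation(toy_gff3)
    assert [g.gene_id for g in genes] == ["geneA", "geneB", "geneC"]
    a = genes[0]
    assert (a.start, a.end) == (100, 200)
    assert (a.cds_start, a.cds_end) == (110, 190)
    assert a.polyA_site == 199  # + strand: last transcribed base
    b = genes[1]
    assert b.polyA_site == 400  # - strand: 3' end at the low coordinate


def test_bed6_is_taken_as_is(tmp_path):
    bed = tmp_path / "g.bed"
    bed.write_text("chrI\t100\t200\tgeneA\t0\t+\nchrI\t400\t900\tgeneB\t0\t-\n")
    genes = load_annotation(bed)
    assert (genes[0].start, genes[0].end) == (100, 200)
    assert genes[1].strand == "-"


def test_bed6_round_trip_preserves_coordinates(tmp_path):
    rng = np.random.default_rng(5)
    genes = []
    pos = 0
    for i in range(12):
        pos += int(rng.integers(10, 400))
        length = int(rng.integers(50, 900))
        genes.append(
            make_gene(f"g{i}", start=pos, end=pos + length,
                      strand="+" if rng.random() < 0.5 else "-")
        )
        pos += length
    path = tmp_path / "rt.bed"
    write_bed6(genes, path)
    back = load_annotation(path)
    assert [(g.gene_id, g.start, g.end, g.strand) for g in back] == [
        (g.gene_id, g.start, g.end, g.strand) for g in genes
    ]


def test_malformed_bed_names_line(tmp_path):
    bed = tmp_path / "bad.bed"
    bed.write_text("chrI\t100\t200\tgeneA\t0\t+\nchrI\tnope\t300\tg\t0\t+\n")
    with pytest.raises(AnnotationError, match="bad.bed:2"):
        load_annotation(bed)


def test_polya_override_replaces_default(toy_gff3, tmp_path):
    sidecar = tmp_path / "polya.tsv"
    sidecar.write_text("geneA\tchrI\t185\t+\n")
    genes = load_annotation(toy_gff3, polya_override=sidecar)
    by_id = {g.gene_id: g for g in genes}
    assert by_id["geneA"].polyA_site == 185
    assert by_id["geneB"].polyA_site == 400  # untouched


def test_gene_model_invariants_enforced():
    with pytest.raises(AnnotationError):
        make_gene(start=200, end=100)
    with pytest.raises(AnnotationError):
        make_gene(strand="*")
    with pytest.raises(AnnotationError):
        make_gene(start=100, end=200, cds=(50, 150))


def test_neighbor_distance_plus_strand_direct():
    g1 = make_gene("a", start=500, end=1000, strand="+")
    g2 = make_gene("b", start=1600, end=2400, strand="+")
    dist = {d.gene_id: d.distance_nt for d in neighbor_distances([g1, g2])}
    assert dist["a"] == 600
    assert dist["b"] == math.inf  # no downstream neighbor passes any threshold


def test_neighbor_distance_minus_strand_symmetry():
    g1 = make_gene("a", start=5000, end=6000, strand="-")  # 3' end at 5000
    g2 = make_gene("b", start=4000, end=4500, strand="-")
    dist = {d.gene_id: d.distance_nt for d in neighbor_distances([g1, g2])}
    assert dist["a"] == 500


def test_overlapping_same_strand_genes_give_zero():
    g1 = make_gene("a", start=100, end=1000, strand="+")
    g2 = make_gene("b", start=900, end=1800, strand="+")
    dist = {d.gene_id: d.distance_nt for d in neighbor_distances([g1, g2])}
    assert dist["a"] == 0


def _brute_force_distance(g, genes):
    best = math.inf
    for h in genes:
        if h.gene_id == g.gene_id or h.strand != g.strand or h.chrom != g.chrom:
            continue
        if g.strand == "+":
            # any base of h strictly 3' of the poly(A)?
            positions = [p for p in (h.start, h.end - 1) if p > g.polyA_site]
            if h.start <= g.polyA_site < h.end:
                positions.append(g.polyA_site + 1)
            if positions:
                best = min(best, max(0, min(positions) - g.polyA_site - 1))
        else:
            positions = [p for p in (h.start, h.end - 1) if p < g.polyA_site]
            if h.start <= g.polyA_site < h.end:
                positions.append(g.polyA_site - 1)
            if positions:
                best = min(best, max(0, g.polyA_site - max(positions) - 1))
    return best


def test_neighbor_distances_match_brute_force_scan():
    rng = np.random.default_rng(17)
    genes = []
    for i in range(24):
        start = int(rng.integers(0, 20000))
        length = int(rng.integers(50, 1500))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(make_gene(f"g{i:02d}", start=start, end=start + length, strand=strand))
    result = {d.gene_id: d.distance_nt for d in neighbor_distances(genes)}
    for g in genes:
        assert result[g.gene_id] == _brute_force_distance(g, genes), g.gene_id


def test_neighbor_distances_invariant_under_reflection():
    """Reflecting all coordinates and flipping all strands must preserve
    every distance (strand symmetry of the readthrough direction)."""
    rng = np.random.default_rng(23)
    genes = []
    for i in range(16):
        start = int(rng.integers(0, 9000))
        length = int(rng.integers(60, 800))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(make_gene(f"g{i:02d}", start=start, end=start + length, strand=strand))
    L = 20000
    reflected = [
        GeneModel(
            gene_id=g.gene_id,
            chrom=g.chrom,
            strand="-" if g.strand == "+" else "+",
            start=L - g.end,
            end=L - g.start,
            polyA_site=L - 1 - g.polyA_site,
            cds_start=L - g.cds_end,
            cds_end=L - g.cds_start,
        )
        for g in genes
    ]
    d1 = {d.gene_id: d.distance_nt for d in neighbor_distances(genes)}
    d2 = {d.gene_id: d.distance_nt for d in neighbor_distances(reflected)}
    assert d1 == d2


def test_default_polya_site_is_strand_aware():
    assert default_polya_site("+", 100, 200) == 199
    assert default_polya_site("-", 100, 200) == 100
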