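import math

import numpy as np
import pytest
from scipy import stats

from groterm.readthrough import (
    RTIConfigError,
    RTIRecord,
    compute_rti,
    compute_rti_table,
    differential_readthrough,
    summarize_rti,
)
from conftest import make_gene, make_track, uniform_track


def _rec(gene_id, sample_id, genotype, rti):
    return RTIRecord(
        gene_id=gene_id, sample_id=sample_id, genotype=genotype,
        upstream_reads=100.0, downstream_reads=100.0 * rti, rti=rti,
    )


def _gene_and_track(up_density, down_density, strand="+"):
    n = 5000
    arr = np.zeros(n)
    if strand == "+":
        gene = make_gene(strand="+", start=1000, end=3000)  # polyA at 2999
        arr[1000:3000] = up_density
        arr[3000:3500] = down_density
    else:
        gene = make_gene(strand="-", start=2000, end=4000)  # polyA at 2000
        arr[2000:4000] = up_density
        arr[1500:2000] = down_density
    track = make_track({("chrI", strand): arr})
    return gene, track


def test_zero_downstream_gives_zero_rti():
    gene, track = _gene_and_track(2.0, 0.0)
    rec = compute_rti(track, gene)
    assert rec.rti == 0.0
    assert rec.upstream_reads == 900.0  # 2.0 x 450-nt window


def test_uniform_coverage_gives_rti_one():
    gene, track = _gene_and_track(3.0, 3.0)
    assert compute_rti(track, gene).rti == 1.0


@pytest.mark.parametrize("strand", ["+", "-"])
def test_piecewise_constant_coverage_gives_exact_ratio(strand):
    """Body density 10/nt and downstream density 2/nt give exactly
    (2x450)/(10x450) = 0.2 on either strand."""
    gene, track = _gene_and_track(10.0, 2.0, strand=strand)
    rec = compute_rti(track, gene)
    assert rec.rti == pytest.approx(0.2)
    assert rec.downstream_reads == 900.0
    assert rec.upstream_reads == 4500.0


def test_undefined_rti_when_upstream_is_zero():
    gene, track = _gene_and_track(0.0, 2.0)
    rec = compute_rti(track, gene)
    assert rec.rti is None


def test_truncated_window_is_flagged_and_excluded():
    arr = np.ones(1200)
    track = make_track({("chrI", "+"): arr})
    gene = make_gene(strand="+", start=100, end=1000)  # downstream window off end
    rec = compute_rti(track, gene)
    assert rec.flagged and rec.rti is None


def test_nonpositive_window_parameters_rejected():
    gene, track = _gene_and_track(1.0, 1.0)
    with pytest.raises(RTIConfigError):
        compute_rti(track, gene, exclusion_nt=0)
    with pytest.raises(RTIConfigError):
        compute_rti(track, gene, window_nt=-10)


def test_window_sums_match_brute_force_loop():
    rng = np.random.default_rng(57)
    for trial in range(20):
        n = 4000
        arr = rng.integers(0, 7, n).astype(float)
        strand = "+" if trial % 2 == 0 else "-"
        gene = make_gene(strand=strand, start=1200, end=2800)
        track = make_track({("chrI", strand): arr})
        rec = compute_rti(track, gene)
        pa = gene.polyA_site
        sgn = 1 if strand == "+" else -1
        up = sum(arr[pa + sgn * o] for o in range(-500, -50))
        down = sum(arr[pa + sgn * o] for o in range(50, 500))
        assert rec.upstream_reads == up
        assert rec.downstream_reads == down


def test_rti_is_scale_invariant():
    rng = np.random.default_rng(61)
    arr = rng.poisson(4, 4000).astype(float)
    gene = make_gene(strand="+", start=1200, end=2800)
    track = make_track({("chrI", "+"): arr})
    base = compute_rti(track, gene).rti
    for k in (0.5, 3.0, 1000.0):
        assert compute_rti(track.scaled(k), gene).rti == pytest.approx(base)


def test_window_accounting_conserves_span_reads():
    """Upstream + downstream + both excluded zones + the poly(A) position
    account for every read in the +/-500 nt span."""
    rng = np.random.default_rng(67)
    arr = rng.integers(0, 5, 4000).astype(float)
    gene = make_gene(strand="+", start=1200, end=2800)
    track = make_track({("chrI", "+"): arr})
    rec = compute_rti(track, gene)
    pa = gene.polyA_site
    span = arr[pa - 500 : pa + 500].sum()    # offsets -500..+499
    # up window covers offsets -500..-51, down covers +50..+499; the
    # excluded zone -50..+49 makes up the rest of the span
    up = arr[pa - 500 : pa - 50].sum()
    down = arr[pa + 50 : pa + 500].sum()
    excluded = arr[pa - 50 : pa + 50].sum()
    assert up + down + excluded == span
    assert rec.upstream_reads == up and rec.downstream_reads == down


def _welch_one_sided(mut, wt):
    """Independent closed-form Welch statistic (mutant > WT)."""
    m, w = np.asarray(mut, float), np.asarray(wt, float)
    vm, vw = m.var(ddof=1) / m.size, w.var(ddof=1) / w.size
    t = (m.mean() - w.mean()) / math.sqrt(vm + vw)
    df = (vm + vw) ** 2 / (vm**2 / (m.size - 1) + vw**2 / (w.size - 1))
    return float(stats.t.sf(t, df))


def test_identical_groups_give_half_p_and_no_call():
    wt = [_rec("g", f"w{i}", "WT", v) for i, v in enumerate((0.05, 0.06, 0.04))]
    mut = [_rec("g", f"m{i}", "mut", v) for i, v in enumerate((0.05, 0.06, 0.04))]
    (rec,) = differential_readthrough(wt, mut)
    assert rec.p_value == pytest.approx(0.5)
    assert not rec.significant


def test_zero_variance_exact_fold_change():
    wt = [_rec("g", f"w{i}", "WT", 0.05) for i in range(3)]
    mut = [_rec("g", f"m{i}", "mut", 0.20) for i in range(3)]
    (rec,) = differential_readthrough(wt, mut)
    assert rec.log2_ratio == pytest.approx(2.0)  # log2(0.20/0.05)
    assert rec.degenerate and rec.p_value == 0.0 and rec.significant


def test_welch_p_matches_closed_form():
    rng = np.random.default_rng(71)
    wt_vals = rng.normal(0.05, 0.01, 3)
    mut_vals = rng.normal(0.15, 0.02, 3)
    wt = [_rec("g", f"w{i}", "WT", v) for i, v in enumerate(wt_vals)]
    mut = [_rec("g", f"m{i}", "mut", v) for i, v in enumerate(mut_vals)]
    (rec,) = differential_readthrough(wt, mut)
    assert rec.p_value == pytest.approx(_welch_one_sided(mut_vals, wt_vals))


def test_simulated_gene_with_tripled_readthrough_is_called(small_sim):
    """Planted r=0.05 vs 0.15 should be recovered as significant with a
    log2 ratio near log2(3) ~ 1.585."""
    cfg, genes, chrom_sizes, truth, tracks = small_sim
    recs = compute_rti_table(tracks, genes)
    wt = [r for r in recs if r.genotype == "WT"]
    mut = [r for r in recs if r.genotype == "mut"]
    diff = differential_readthrough(wt, mut)
    ratios = np.array([d.log2_ratio for d in diff])
    assert abs(ratios.mean() - math.log2(3)) < 0.25
    assert np.mean([d.significant for d in diff]) > 0.5


def test_replicate_minimums_give_reason_not_call():
    wt = [_rec("g", "w0", "WT", 0.05)]
    mut = [_rec("g", f"m{i}", "mut", v) for i, v in enumerate((0.2, 0.25, 0.22))]
    (rec,) = differential_readthrough(wt, mut)
    assert rec.reason == "insufficient_replicates"
    assert not rec.significant


def test_undefined_replicates_are_dropped_not_imputed():
    wt = [_rec("g", f"w{i}", "WT", v) for i, v in enumerate((0.05, 0.06))]
    wt.append(
        RTIRecord(gene_id="g", sample_id="w2", genotype="WT",
                  upstream_reads=0.0, downstream_reads=3.0, rti=None)
    )
    mut = [_rec("g", f"m{i}", "mut", v) for i, v in enumerate((0.2, 0.25, 0.22))]
    (rec,) = differential_readthrough(wt, mut)
    assert rec.n_wt == 2 and rec.n_mut == 3


def test_summary_single_gene_median_equals_mean():
    wt = [_rec("g", f"w{i}", "WT", v) for i, v in enumerate((0.04, 0.05, 0.06))]
    mut = [_rec("g", f"m{i}", "mut", v) for i, v in enumerate((0.1, 0.2, 0.15))]
    diff = differential_readthrough(wt, mut)
    s = summarize_rti(diff)
    assert s.median_rti_wt == s.mean_rti_wt
    assert s.median_rti_mut == s.mean_rti_mut
    assert s.n_genes == 1


def test_summary_constant_fields():
    wt, mut = [], []
    for g in range(5):
        wt += [_rec(f"g{g}", f"w{i}", "WT", 0.0) for i in range(3)]
        mut += [_rec(f"g{g}", f"m{i}", "mut", 0.2) for i in range(3)]
    diff = differential_readthrough(wt, mut)
    s = summarize_rti(diff)
    assert s.mean_rti_wt == 0.0 and s.mean_rti_mut == pytest.approx(0.2)
    assert 0.0 <= s.fraction_significant <= 1.0


def test_type_one_error_controlled_under_null():
    """With identical generative parameters in both genotypes, the
    fraction of genes called significant stays below ~8% (loose bound for
    a small-n one-sided Welch test plus the fold-change gate)."""
    from groterm.simulate import SimulationConfig, simulate_genome, simulate_tracks

    cfg = SimulationConfig(n_genes=500, readthrough_wt=0.05, readthrough_mut=0.05,
                           gene_length_range=(1000, 1200), seed=97)
    genes, chrom_sizes, truth = simulate_genome(cfg)
    tracks = simulate_tracks(genes, truth, cfg, chrom_sizes)
    recs = compute_rti_table(tracks, genes)
    diff = differential_readthrough(
        [r for r in recs if r.genotype == "WT"],
        [r for r in recs if r.genotype == "mut"],
    )
    assert len(diff) >= 490
    assert np.mean([d.significant for d in diff]) <= 0.08
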