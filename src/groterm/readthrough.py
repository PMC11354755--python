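"""Readthrough index (RTI) and per-gene differential readthrough testing.

The RTI quantifies failure to terminate at the poly(A) signal: reads in
a downstream window (+50..+500 nt past the poly(A) site, transcription
sense) divided by reads in an upstream window (-500..-50 nt), i.e. two
450-nt windows separated by a 50-nt exclusion zone on either side of the
cleavage site. Efficient termination gives RTI near 0; readthrough
elevates it.

Differential readthrough between genotypes is called per gene with a
one-sided Welch (unequal-variance) t-test, alternative mutant > WT, on
the per-replicate RTI values, requiring at least 5 replicates in total
and at least 2 per genotype. A gene is significant when p < alpha and
the log2 mutant/WT ratio of mean RTIs exceeds the fold-change threshold
(default log2 ratio > 1, i.e. a 2-fold increase). No multiple-testing
correction gates the default call; a Benjamini-Hochberg q-value column
is emitted alongside for the user.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel
from .coverage import CoverageTrack, extract_signal


class RTIConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RTIRecord:
    gene_id: str
    sample_id: str
    genotype: str
    upstream_reads: float
    downstream_reads: float
    rti: float | None  # None when upstream sum is 0 (undefined)
    flagged: bool = False  # window truncated at a chromosome end


@dataclass(frozen=True)
class DifferentialRecord:
    gene_id: str
    mean_rti_wt: float
    mean_rti_mut: float
    log2_ratio: float
    p_value: float
    q_value: float
    n_wt: int
    n_mut: int
    significant: bool
    reason: str = ""  # non-empty when replicate minimums failed etc.
    degenerate: bool = False  # zero-variance t-test limit was taken


@dataclass
class RTISummary:
    mean_rti_wt: float
    mean_rti_mut: float
    median_rti_wt: float
    median_rti_mut: float
    fraction_significant: float
    n_genes: int
    paired_p: float  # two-sided paired t-test across genes (mean comparison)
    unpaired_p: float  # two-sided Welch t-test across genes


def compute_rti(
    track: CoverageTrack,
    gene: GeneModel,
    exclusion_nt: int = 50,
    window_nt: int = 450,
) -> RTIRecord:
    """Readthrough index for one gene in one replicate.

    Downstream window covers strandward offsets
    ``[+exclusion, +exclusion+window)`` from the poly(A) site, upstream
    covers ``[-exclusion-window, -exclusion)``. Windows that run off the
    chromosome flag the record (excluded from downstream testing).
    """
    if exclusion_nt <= 0 or window_nt <= 0:
        raise RTIConfigError("exclusion_nt and window_nt must be positive")
    up = extract_signal(
        track, gene, window=(-exclusion_nt - window_nt, -exclusion_nt), anchor="polya"
    )
    down = extract_signal(
        track, gene, window=(exclusion_nt, exclusion_nt + window_nt), anchor="polya"
    )
    up_sum = float(up.values.sum())
    down_sum = float(down.values.sum())
    flagged = up.truncated or down.truncated
    rti = down_sum / up_sum if up_sum > 0 and not flagged else None
    return RTIRecord(
        gene_id=gene.gene_id,
        sample_id=track.sample_id,
        genotype=track.genotype,
        upstream_reads=up_sum,
        downstream_reads=down_sum,
        rti=rti,
        flagged=flagged,
    )


def compute_rti_table(
    tracks: Sequence[CoverageTrack],
    genes: Sequence[GeneModel],
    exclusion_nt: int = 50,
    window_nt: int = 450,
) -> list[RTIRecord]:
    return [
        compute_rti(t, g, exclusion_nt=exclusion_nt, window_nt=window_nt)
        for t in tracks
        for g in genes
    ]


def _one_sided_welch(mut: np.ndarray, wt: np.ndarray) -> tuple[float, bool]:
    """One-sided Welch p-value for mutant > WT, with degenerate
    zero-variance inputs resolved by their limit."""
    if np.ptp(mut) == 0.0 and np.ptp(wt) == 0.0:  # all values identical per group
        diff = float(np.mean(mut) - np.mean(wt))
        if diff == 0.0:
            return 0.5, True  # t = 0 limit
        return (0.0 if diff > 0 else 1.0), True
    res = stats.ttest_ind(mut, wt, equal_var=False, alternative="greater")
    return float(res.pvalue), False


def differential_readthrough(
    rti_wt: Sequence[RTIRecord],
    rti_mut: Sequence[RTIRecord],
    alpha: float = 0.05,
    log2_fc_threshold: float = 1.0,
    min_total: int = 5,
    min_per_group: int = 2,
) -> list[DifferentialRecord]:
    """Per-gene one-sided Welch t-test of mutant vs WT replicate RTIs.

    Replicates with undefined RTI (zero upstream reads or truncated
    windows) are dropped rather than imputed; genes then failing the
    replicate minimums are reported with ``significant=False`` and a
    reason code. Genes with zero defined replicates in a genotype are
    skipped entirely.
    """

    def by_gene(records: Sequence[RTIRecord]) -> dict[str, list[float]]:
        out: dict[str, list[float]] = {}
        for r in records:
            if r.rti is not None:
                out.setdefault(r.gene_id, []).append(r.rti)
        return out

    wt, mut = by_gene(rti_wt), by_gene(rti_mut)
    gene_ids = sorted(set(wt) | set(mut))

    rows: list[dict] = []
    for gid in gene_ids:
        w = np.asarray(wt.get(gid, ()), dtype=float)
        m = np.asarray(mut.get(gid, ()), dtype=float)
        if w.size == 0 or m.size == 0:
            continue  # untestable: a genotype has no defined replicate
        mean_wt, mean_mut = float(w.mean()), float(m.mean())
        if mean_wt > 0:
            log2_ratio = math.log2(mean_mut / mean_wt) if mean_mut > 0 else -math.inf
        else:
            log2_ratio = math.inf if mean_mut > 0 else 0.0
        reason = ""
        degenerate = False
        if w.size < min_per_group or m.size < min_per_group or w.size + m.size < min_total:
            p = math.nan
            reason = "insufficient_replicates"
        else:
            p, degenerate = _one_sided_welch(m, w)
        rows.append(
            dict(
                gene_id=gid,
                mean_rti_wt=mean_wt,
                mean_rti_mut=mean_mut,
                log2_ratio=log2_ratio,
                p_value=p,
                n_wt=int(w.size),
                n_mut=int(m.size),
                reason=reason,
                degenerate=degenerate,
            )
        )

    # BH correction over the genes actually tested (informational column)
    tested = [r for r in rows if not math.isnan(r["p_value"])]
    if tested:
        from statsmodels.stats.multitest import multipletests

        qvals = multipletests([r["p_value"] for r in tested], method="fdr_bh")[1]
        for r, q in zip(tested, qvals):
            r["q_value"] = float(q)
    for r in rows:
        r.setdefault("q_value", math.nan)

    records = []
    for r in rows:
        significant = (
            not r["reason"]
            and r["p_value"] < alpha
            and r["log2_ratio"] > log2_fc_threshold
        )
        records.append(
            DifferentialRecord(
                gene_id=r["gene_id"],
                mean_rti_wt=r["mean_rti_wt"],
                mean_rti_mut=r["mean_rti_mut"],
                log2_ratio=r["log2_ratio"],
                p_value=r["p_value"],
                q_value=r["q_value"],
                n_wt=r["n_wt"],
                n_mut=r["n_mut"],
                significant=bool(significant),
                reason=r["reason"],
                degenerate=r["degenerate"],
            )
        )
    return records


def summarize_rti(
    differential: Sequence[DifferentialRecord],
    rti_wt: Sequence[RTIRecord] | None = None,
    rti_mut: Sequence[RTIRecord] | None = None,
) -> RTISummary:
    """Genome-wide readthrough summary over the analyzed genes.

    The per-genotype mean is the unweighted mean over genes of each
    gene's replicate-mean RTI; the median is over the same per-gene
    values. The mean comparison is tested with a two-sided paired t-test
    across genes, the overall shift also with a two-sided Welch t-test.
    """
    if not differential:
        raise ValueError("no differential records to summarize")
    wt_means = np.array([d.mean_rti_wt for d in differential])
    mut_means = np.array([d.mean_rti_mut for d in differential])
    n = len(differential)
    if n > 1 and (np.std(wt_means) > 0 or np.std(mut_means) > 0):
        paired_p = float(stats.ttest_rel(mut_means, wt_means).pvalue)
        unpaired_p = float(stats.ttest_ind(mut_means, wt_means, equal_var=False).pvalue)
    else:
        paired_p = unpaired_p = math.nan
    frac = float(np.mean([d.significant for d in differential]))
    return RTISummary(
        mean_rti_wt=float(wt_means.mean()),
        mean_rti_mut=float(mut_means.mean()),
        median_rti_wt=float(np.median(wt_means)),
        median_rti_mut=float(np.median(mut_means)),
        fraction_significant=frac,
        n_genes=n,
        paired_p=paired_p,
        unpaired_p=unpaired_p,
    )


def rti_records_to_frame(records: Sequence[RTIRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "sample_id": [r.sample_id for r in records],
            "genotype": [r.genotype for r in records],
            "upstream_reads": [r.upstream_reads for r in records],
            "downstream_reads": [r.downstream_reads for r in records],
            "rti": [math.nan if r.rti is None else r.rti for r in records],
            "flagged": [r.flagged for r in records],
        }
    )


def differential_to_frame(records: Sequence[DifferentialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "mean_rti_wt": [r.mean_rti_wt for r in records],
            "mean_rti_mut": [r.mean_rti_mut for r in records],
            "log2_ratio": [r.log2_ratio for r in records],
            "p_value": [r.p_value for r in records],
            "q_value": [r.q_value for r in records],
            "n_wt": [r.n_wt for r in records],
            "n_mut": [r.n_mut for r in records],
            "significant": [r.significant for r in records],
            "reason": [r.reason for r in records],
            "degenerate": [r.degenerate for r in records],
        }
    )


def volcano_frame(records: Sequence[DifferentialRecord]) -> pd.DataFrame:
    """Scatter data: log2 mutant/WT RTI ratio vs -log10 p."""
    df = differential_to_frame(records)
    df = df[~df["p_value"].isna()].copy()
    df["neg_log10_p"] = -np.log10(df["p_value"].clip(lower=1e-300))
    return df[["gene_id", "log2_ratio", "neg_log10_p", "significant"]]


def write_summary_json(summary: RTISummary, path: str | Path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(
            {
                "mean_rti_wt": summary.mean_rti_wt,
                "mean_rti_mut": summary.mean_rti_mut,
                "median_rti_wt": summary.median_rti_wt,
                "median_rti_mut": summary.median_rti_mut,
                "fraction_significant": summary.fraction_significant,
                "n_genes": summary.n_genes,
                "paired_p": summary.paired_p,
                "unpaired_p": summary.unpaired_p,
            },
            fh,
            indent=2,
        )
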