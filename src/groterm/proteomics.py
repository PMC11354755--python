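"""Bait-normalized spectral abundance factors (BNSAF) for affinity-
purification mass spectrometry.

The spectral abundance factor (SAF) of a protein is its spectral count
divided by its length in amino acids, correcting for the fact that long
proteins yield more peptides. In a bait (TFIIB) affinity purification,
dividing each protein's SAF by the bait's SAF in the same sample gives
the bait-normalized SAF (BNSAF): a self-normalized relative abundance
that is invariant to per-sample scaling, with the bait itself pinned at
exactly 1. Genotypes are compared per protein with a two-sided paired
t-test across replicate purifications; chromatin and soluble fractions
are analyzed separately and never merged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class ProteomicsError(ValueError):
    pass


# Complex membership used for Fig-style grouping of termination machinery
# (CF1 and Rat1 complexes, CPF, and general transcription factors).
COMPLEXES: dict[str, frozenset[str]] = {
    "CF1": frozenset({"RNA14", "RNA15", "PCF11", "CLP1", "HRP1"}),
    "Rat1": frozenset({"RAT1", "RAI1"}),
    "CPF": frozenset(
        {"PTA1", "YSH1", "CFT1", "CFT2", "PFS2", "FIP1", "PAP1",
         "SSU72", "GLC7", "MPE1", "PTI1", "REF2", "SWD2", "SYC1", "YTH1"}
    ),
    "GTF": frozenset(
        {"TOA1", "TOA2", "TFG1", "TFG2", "TAF1", "TAF2", "TAF3", "TAF4",
         "TAF5", "TAF6", "TAF7", "TAF8", "TAF9", "TAF10", "TAF11",
         "TAF12", "TAF13", "TAF14", "SPT15"}
    ),
}

REQUIRED_COLUMNS = {
    "protein_id", "length_aa", "count", "sample_id", "genotype", "fraction", "replicate",
}


def complex_label(protein_id: str) -> str:
    pid = protein_id.upper()
    for name, members in COMPLEXES.items():
        if pid in members:
            return name
    return "other"


def compute_saf(spectral_counts: float, protein_length_aa: float) -> float:
    """Spectral abundance factor: counts per amino acid of protein length."""
    if protein_length_aa <= 0:
        raise ProteomicsError("protein length must be > 0")
    if spectral_counts < 0:
        raise ProteomicsError("spectral counts must be >= 0")
    return spectral_counts / protein_length_aa


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = REQUIRED_COLUMNS - set(table.columns)
    if missing:
        raise ProteomicsError(f"spectral-count table missing columns: {sorted(missing)}")
    if (table["count"] < 0).any():
        raise ProteomicsError("negative spectral counts")
    if (table["length_aa"] <= 0).any():
        raise ProteomicsError("non-positive protein length")
    return table


def compute_bnsaf(
    table: pd.DataFrame, bait_id: str = "SUA7", counts_only: bool = False
) -> pd.DataFrame:
    """Per-sample bait-normalized SAF for every protein.

    ``counts_only=True`` skips length normalization (bnsaf =
    counts/counts_bait), for tables without protein lengths; the output
    is labeled accordingly in the ``mode`` column.

    Raises when the bait has zero counts in any sample — such a
    purification carries no internal reference and is rejected.
    """
    table = validate_table(table)
    mode = "counts_only" if counts_only else "saf"
    if counts_only:
        table = table.assign(saf=table["count"].astype(float))
    else:
        table = table.assign(saf=table["count"] / table["length_aa"])

    bait = table[table["protein_id"].str.upper() == bait_id.upper()]
    bait_by_sample = bait.set_index("sample_id")["saf"]
    out_rows = []
    for sample_id, grp in table.groupby("sample_id"):
        if sample_id not in bait_by_sample.index:
            raise ProteomicsError(f"bait {bait_id!r} absent from sample {sample_id!r}")
        bait_saf = float(bait_by_sample.loc[sample_id])
        if bait_saf <= 0:
            raise ProteomicsError(
                f"bait {bait_id!r} has zero counts in sample {sample_id!r}; sample rejected"
            )
        g = grp.copy()
        g["bnsaf"] = g["saf"] / bait_saf
        out_rows.append(g)
    out = pd.concat(out_rows, ignore_index=True)
    out["complex"] = out["protein_id"].map(complex_label)
    out["mode"] = mode
    return out[
        ["protein_id", "complex", "sample_id", "genotype", "fraction",
         "replicate", "bnsaf", "mode"]
    ]


def _paired_test(wt: np.ndarray, mut: np.ndarray) -> tuple[float, bool]:
    diffs = mut - wt
    if np.allclose(diffs, 0.0):
        return 1.0, True  # all paired differences zero: no evidence of change
    if np.std(diffs, ddof=1) == 0.0:
        return 0.0, True  # constant nonzero shift: paired-t limit
    return float(stats.ttest_rel(mut, wt).pvalue), False


def compare_genotypes(
    bnsaf: pd.DataFrame,
    wt_label: str = "WT",
    mut_label: str = "mut",
) -> pd.DataFrame:
    """Paired two-sided t-test of per-replicate BNSAF between genotypes.

    Replicate indices must match one-to-one between genotypes within
    each (protein, fraction); an unpaired replicate raises. Returns one
    row per (protein, fraction) with mean BNSAF per genotype, percent
    change (mut vs WT), and the paired p-value.
    """
    rows = []
    for (protein, fraction), grp in bnsaf.groupby(["protein_id", "fraction"]):
        wt = grp[grp["genotype"] == wt_label].set_index("replicate")["bnsaf"].sort_index()
        mut = grp[grp["genotype"] == mut_label].set_index("replicate")["bnsaf"].sort_index()
        if not wt.index.equals(mut.index):
            unpaired = sorted(set(wt.index).symmetric_difference(mut.index))
            raise ProteomicsError(
                f"{protein}/{fraction}: unpaired replicate(s) {unpaired}"
            )
        w, m = wt.to_numpy(float), mut.to_numpy(float)
        mean_wt, mean_mut = float(w.mean()), float(m.mean())
        pct = 100.0 * (mean_mut - mean_wt) / mean_wt if mean_wt > 0 else math.nan
        p, degenerate = _paired_test(w, m)
        rows.append(
            dict(
                protein_id=protein,
                complex=complex_label(protein),
                fraction=fraction,
                mean_bnsaf_wt=mean_wt,
                mean_bnsaf_mut=mean_mut,
                percent_change=pct,
                p_value=p,
                n_pairs=int(w.size),
                degenerate=degenerate,
            )
        )
    return pd.DataFrame(rows)


def complex_summary(per_protein: pd.DataFrame) -> pd.DataFrame:
    """Aggregate member proteins per complex and fraction. The mean
    member decline always lies between the min and max member declines."""
    rows = []
    for (cplx, fraction), grp in per_protein.groupby(["complex", "fraction"]):
        rows.append(
            dict(
                complex=cplx,
                fraction=fraction,
                n_proteins=len(grp),
                mean_percent_change=float(grp["percent_change"].mean()),
                min_percent_change=float(grp["percent_change"].min()),
                max_percent_change=float(grp["percent_change"].max()),
                median_p=float(grp["p_value"].median()),
            )
        )
    return pd.DataFrame(rows)
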