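"""Targeted single-gene assays: ChIP occupancy and transcription run-on
(TRO) quantification with genotype comparison.

ChIP occupancy at an amplicon is the factor's ChIP/input ratio divided
by the RNA polymerase II ChIP/input ratio at the same region — a double
ratio invariant to rescaling either (ChIP, input) pair. TRO nascent
signal is expressed relative to an 18S rRNA control. Genotype declines
are percent changes of group means with a two-tailed Welch t-test by
default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class AssayError(ValueError):
    pass


@dataclass(frozen=True)
class ChIPMeasurement:
    factor: str
    gene_id: str
    amplicon: str
    genotype: str
    replicate: int
    chip_signal: float
    input_signal: float
    polII_chip_signal: float
    polII_input_signal: float


@dataclass(frozen=True)
class TROMeasurement:
    gene_id: str
    primer_id: str
    genotype: str
    replicate: int
    signal: float
    control_18S: float


@dataclass(frozen=True)
class DeclineResult:
    percent_decline: float | None  # None when the WT mean is 0 (undefined)
    p_value: float
    stderr_wt: float
    stderr_mut: float
    mean_wt: float
    mean_mut: float


def chip_occupancy(m: ChIPMeasurement) -> float:
    """(ChIP/input) / (RNAPII ChIP / RNAPII input)."""
    for name in ("chip_signal", "input_signal", "polII_chip_signal", "polII_input_signal"):
        if getattr(m, name) <= 0:
            raise AssayError(
                f"{m.factor}/{m.gene_id}/{m.amplicon} replicate {m.replicate}: "
                f"{name} must be > 0"
            )
    return (m.chip_signal / m.input_signal) / (
        m.polII_chip_signal / m.polII_input_signal
    )


def chip_occupancy_table(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized occupancy over a measurement table (columns as in
    :class:`ChIPMeasurement`)."""
    required = {
        "factor", "gene_id", "amplicon", "genotype", "replicate",
        "chip_signal", "input_signal", "polII_chip_signal", "polII_input_signal",
    }
    missing = required - set(df.columns)
    if missing:
        raise AssayError(f"ChIP table missing columns: {sorted(missing)}")
    bad = df[
        (df["chip_signal"] <= 0) | (df["input_signal"] <= 0)
        | (df["polII_chip_signal"] <= 0) | (df["polII_input_signal"] <= 0)
    ]
    if not bad.empty:
        r = bad.iloc[0]
        raise AssayError(
            f"non-positive signal in {r['factor']}/{r['gene_id']}/{r['amplicon']} "
            f"replicate {r['replicate']}"
        )
    out = df.copy()
    out["occupancy"] = (out["chip_signal"] / out["input_signal"]) / (
        out["polII_chip_signal"] / out["polII_input_signal"]
    )
    return out


def tro_signal(m: TROMeasurement) -> float:
    """Nascent RT-PCR signal relative to the 18S control."""
    if m.control_18S <= 0:
        raise AssayError(f"{m.gene_id}/{m.primer_id}: 18S control must be > 0")
    if m.signal < 0:
        raise AssayError(f"{m.gene_id}/{m.primer_id}: negative signal")
    return m.signal / m.control_18S


def tro_signal_table(df: pd.DataFrame) -> pd.DataFrame:
    required = {"gene_id", "primer_id", "genotype", "replicate", "signal", "control_18S"}
    missing = required - set(df.columns)
    if missing:
        raise AssayError(f"TRO table missing columns: {sorted(missing)}")
    if (df["control_18S"] <= 0).any():
        raise AssayError("non-positive 18S control signal")
    out = df.copy()
    out["normalized"] = out["signal"] / out["control_18S"]
    return out


def genotype_decline(
    values_wt: Sequence[float],
    values_mut: Sequence[float],
    two_sided: bool = True,
) -> DeclineResult:
    """Percent decline of the mutant group mean relative to WT, with a
    Welch t-test (two-tailed by default) and per-group standard errors."""
    w = np.asarray(values_wt, dtype=float)
    m = np.asarray(values_mut, dtype=float)
    if w.size < 2 or m.size < 2:
        raise AssayError("need at least 2 replicates per genotype")
    mean_wt, mean_mut = float(w.mean()), float(m.mean())
    decline = 100.0 * (mean_wt - mean_mut) / mean_wt if mean_wt != 0 else None
    alternative = "two-sided" if two_sided else "greater"
    if np.std(w, ddof=1) == 0 and np.std(m, ddof=1) == 0:
        p = 1.0 if mean_wt == mean_mut else 0.0
    else:
        p = float(stats.ttest_ind(w, m, equal_var=False, alternative=alternative).pvalue)
    return DeclineResult(
        percent_decline=decline,
        p_value=p,
        stderr_wt=float(w.std(ddof=1) / math.sqrt(w.size)),
        stderr_mut=float(m.std(ddof=1) / math.sqrt(m.size)),
        mean_wt=mean_wt,
        mean_mut=mean_mut,
    )


def decline_table(
    df: pd.DataFrame,
    value_col: str,
    group_cols: Sequence[str],
    wt_label: str = "WT",
    mut_label: str = "mut",
    two_sided: bool = True,
) -> pd.DataFrame:
    """Apply :func:`genotype_decline` within each group of a normalized
    measurement table."""
    rows = []
    for keys, grp in df.groupby(list(group_cols)):
        if not isinstance(keys, tuple):
            keys = (keys,)
        wt = grp.loc[grp["genotype"] == wt_label, value_col]
        mut = grp.loc[grp["genotype"] == mut_label, value_col]
        res = genotype_decline(wt, mut, two_sided=two_sided)
        row = dict(zip(group_cols, keys))
        row.update(
            percent_decline=res.percent_decline,
            p_value=res.p_value,
            mean_wt=res.mean_wt,
            mean_mut=res.mean_mut,
            stderr_wt=res.stderr_wt,
            stderr_mut=res.stderr_mut,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def plot_bars(
    table: pd.DataFrame,
    x_col: str,
    path: str,
    title: str = "",
) -> None:
    """Paired WT/mutant bar plot with standard-error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(len(table))
    width = 0.38
    fig, ax = plt.subplots(figsize=(max(4, len(table)), 4))
    ax.bar(x - width / 2, table["mean_wt"], width, yerr=table["stderr_wt"],
           label="WT", color="tab:blue", capsize=3)
    ax.bar(x + width / 2, table["mean_mut"], width, yerr=table["stderr_mut"],
           label="mutant", color="tab:red", capsize=3)
    ax.set_xticks(x)
    ax.set_xticklabels(table[x_col], rotation=45, ha="right")
    ax.set_ylabel("normalized signal")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
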