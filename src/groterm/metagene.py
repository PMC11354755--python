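"""CDS-normalized metagene profiles and readthrough-ordered heat maps.

Each gene's signal in a window around the poly(A) site (default -200 to
+200 nt, transcription sense) is divided by that gene's average read
density in the CDS, so highly expressed genes do not dominate. The
metagene profile is the per-offset mean over all (gene, replicate) pairs
of a genotype, with the standard error computed over the same pool. The
heat-map matrix shows the per-sample normalized densities with genes
ordered top-to-bottom by increasing mutant readthrough (mean mutant
RTI), row order identical across all samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .coverage import CoverageTrack, extract_signal
from .filtering import expression_level


class MetageneError(ValueError):
    pass


@dataclass
class MetageneProfile:
    offsets: np.ndarray  # strandward offsets relative to the poly(A) site
    mean_density: np.ndarray
    stderr: np.ndarray
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean": self.mean_density, "stderr": self.stderr}
        )


def normalize_gene(values: np.ndarray, cds_mean_density: float) -> np.ndarray:
    """Divide a gene's windowed signal by its CDS mean read density."""
    if cds_mean_density <= 0:
        raise MetageneError("cds_mean_density must be > 0 (gene should be excluded)")
    return np.asarray(values, dtype=float) / cds_mean_density


def _gene_window_normalized(
    track: CoverageTrack, gene: GeneModel, window: tuple[int, int]
) -> np.ndarray | None:
    """Full-window CDS-normalized signal, or None when the window is
    truncated or the gene has no CDS signal in this replicate."""
    sig = extract_signal(track, gene, window=window, anchor="polya")
    if sig.truncated:
        return None
    dens = expression_level(track, gene)
    if dens <= 0:
        return None
    return normalize_gene(sig.values, dens)


def metagene_profile(
    tracks: Sequence[CoverageTrack],
    genes: Sequence[GeneModel],
    window: tuple[int, int] = (-200, 200),
) -> MetageneProfile:
    """Average CDS-normalized density around the poly(A) site.

    Pools all (gene, replicate) vectors of the supplied tracks (one
    genotype in typical use); stderr is sample SD / sqrt(count) over that
    pool at each offset.
    """
    if not genes:
        raise MetageneError("empty analyzed gene set")
    vectors = []
    included_genes = set()
    for g in genes:
        for t in tracks:
            v = _gene_window_normalized(t, g, window)
            if v is not None:
                vectors.append(v)
                included_genes.add(g.gene_id)
    if not vectors:
        raise MetageneError("no gene×replicate window passed full-window criteria")
    mat = np.vstack(vectors)
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    stderr = mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(mat.shape[1])
    return MetageneProfile(
        offsets=np.arange(window[0], window[1]),
        mean_density=mean,
        stderr=stderr,
        n_genes=len(included_genes),
    )


def order_genes_by_readthrough(
    genes: Sequence[GeneModel], mutant_rti: Mapping[str, float]
) -> tuple[list[str], list[str]]:
    """Row order for the heat map: ascending mean mutant RTI, ties broken
    lexicographically by gene id; genes with no RTI go last, flagged."""
    with_rti = sorted(
        (g.gene_id for g in genes if g.gene_id in mutant_rti),
        key=lambda gid: (mutant_rti[gid], gid),
    )
    missing = sorted(g.gene_id for g in genes if g.gene_id not in mutant_rti)
    return with_rti + missing, missing


def heatmap_matrix(
    tracks: Sequence[CoverageTrack],
    genes: Sequence[GeneModel],
    mutant_rti: Mapping[str, float],
    window: tuple[int, int] = (-200, 200),
) -> dict[str, pd.DataFrame]:
    """One genes×offsets matrix of CDS-normalized density per sample,
    with an identical row order across all samples."""
    order, _missing = order_genes_by_readthrough(genes, mutant_rti)
    gene_by_id = {g.gene_id: g for g in genes}
    offsets = np.arange(window[0], window[1])
    out: dict[str, pd.DataFrame] = {}
    for t in tracks:
        rows = []
        for gid in order:
            v = _gene_window_normalized(t, gene_by_id[gid], window)
            rows.append(v if v is not None else np.full(offsets.size, np.nan))
        out[t.sample_id] = pd.DataFrame(np.vstack(rows), index=order, columns=offsets)
    return out


def plot_metagene(
    profiles: Mapping[str, MetageneProfile], path: str | Path
) -> None:
    """Line plot with a standard-error band per genotype."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, prof in profiles.items():
        ax.plot(prof.offsets, prof.mean_density, label=label)
        ax.fill_between(
            prof.offsets,
            prof.mean_density - prof.stderr,
            prof.mean_density + prof.stderr,
            alpha=0.3,
        )
    ax.axvline(0, ls="--", c="gray", lw=0.8)
    ax.set_xlabel("distance from poly(A) site (nt)")
    ax.set_ylabel("CDS-normalized read density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(matrix: pd.DataFrame, path: str | Path, vmax: float | None = None) -> None:
    """Red-on-black heat map of one sample's matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list("blackred", ["black", "red", "yellow"])
    fig, ax = plt.subplots(figsize=(4, 6))
    data = matrix.to_numpy()
    if vmax is None:
        vmax = float(np.nanquantile(data, 0.98)) or 1.0
    ax.imshow(data, aspect="auto", cmap=cmap, vmin=0, vmax=vmax, interpolation="nearest")
    ax.set_xlabel("distance from poly(A) site (nt)")
    ax.set_ylabel("genes (increasing readthrough)")
    xt = np.linspace(0, data.shape[1] - 1, 5).astype(int)
    ax.set_xticks(xt)
    ax.set_xticklabels(matrix.columns.to_numpy()[xt])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
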