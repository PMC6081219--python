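"""Depth-profile figures: per-amplicon dosage (blue) + smoothed curve (red).

The profile plots reproduce the working view of the method: normalized
relative depths of one sample in genomic order, grouped per gene, per
chromosome or across the whole panel, with horizontal guides at dosage 1, 2
and 3. The correlation plot shows why pool-wise normalization is needed:
raw depths of two samples split into one trend per primer pool when the
pools are mixed unequally, and collapse onto a single trend after the
relative-depth transform.
"""

from __future__ import annotations

import re
from pathlib import Path

import matplotlib
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .io import chrom_sort_key

POINT_COLOR = "tab:blue"
SMOOTH_COLOR = "tab:red"
GROUPINGS = ("per_gene", "per_chromosome", "whole_panel")


def _slug(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "_", str(text))


def _save(fig, path: Path, dpi: int) -> None:
    kwargs = {"dpi": dpi}
    if path.suffix.lower() == ".svg":
        kwargs["metadata"] = {"Date": None}  # keep output byte-deterministic
    fig.savefig(path, **kwargs)
    plt.close(fig)


def plot_profile(
    norm: pd.DataFrame,
    smoothed: pd.DataFrame,
    design: pd.DataFrame,
    retained: pd.Series,
    sample_id: str,
    grouping: str = "per_gene",
    ylim: tuple[float, float] = (0.0, 4.0),
    outdir: str | Path = ".",
    fmt: str = "png",
    dpi: int = 150,
) -> list[Path]:
    """Write one profile figure per grouping unit for one sample.

    Masked amplicons are omitted. Returns the written paths (one per gene,
    per chromosome, or a single panel-wide file).
    """
    if sample_id not in norm.columns:
        raise ValueError(f"unknown sample {sample_id!r}")
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {GROUPINGS}, got {grouping!r}")
    if not (0 <= ylim[0] < ylim[1]):
        raise ValueError(f"invalid y range {ylim}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    kept = design.loc[retained.reindex(design.index).fillna(False)]
    if grouping == "per_gene":
        units = [
            (f"{chrom}_{gene}", g)
            for (chrom, gene), g in kept.groupby(["chrom", "gene"], sort=False)
        ]
    elif grouping == "per_chromosome":
        units = [(chrom, g) for chrom, g in kept.groupby("chrom", sort=False)]
    else:
        units = [("panel", kept)]
    units.sort(key=lambda u: chrom_sort_key(u[1]["chrom"].iloc[0]))

    paths = []
    for name, group in units:
        ids = group.index
        x = np.arange(len(ids))
        fig, ax = plt.subplots(figsize=(max(4.0, len(ids) / 12), 3.2))
        for ref in (1.0, 2.0, 3.0):
            ax.axhline(ref, color="0.8", lw=0.8, zorder=0)
        ax.plot(x, norm.loc[ids, sample_id], "o", ms=3, color=POINT_COLOR,
                label="normalized depth", zorder=2)
        ax.plot(x, smoothed.loc[ids, sample_id], "-", color=SMOOTH_COLOR,
                lw=1.5, label="5-amplicon smoothing", zorder=3)
        # gene boundaries for multi-gene panels
        if grouping != "per_gene":
            genes = group["gene"].to_numpy()
            bounds = np.flatnonzero(genes[1:] != genes[:-1]) + 1
            for b in bounds:
                ax.axvline(b - 0.5, color="0.6", lw=0.6, ls="--", zorder=1)
            starts = np.concatenate([[0], bounds])
            ends = np.concatenate([bounds, [len(genes)]])
            ax.set_xticks((starts + ends - 1) / 2)
            ax.set_xticklabels(genes[starts], rotation=90, fontsize=6)
        else:
            ax.set_xlabel("amplicon (genomic order)")
        ax.set_ylim(*ylim)
        ax.set_ylabel("normalized relative depth")
        ax.set_title(f"{sample_id} — {name}", fontsize=9)
        ax.legend(loc="upper right", fontsize=6)
        fig.tight_layout()
        path = outdir / f"{_slug(sample_id)}_{_slug(name)}.{fmt}"
        _save(fig, path, dpi)
        paths.append(path)
    return paths


def plot_sample_correlation(
    depths: pd.DataFrame,
    rel: pd.DataFrame,
    design: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    path: str | Path,
    allow_self: bool = False,
    dpi: int = 150,
) -> Path:
    """Two-panel scatter of sample A vs B, before and after pool normalization.

    Left: raw depths colored by primer pool (unequal pool mixing shows up as
    two slopes). Right: relative depths (one trend for a diploid pair).
    """
    if sample_a == sample_b and not allow_self:
        raise ValueError("sample_a and sample_b are identical (pass allow_self=True)")
    for s in (sample_a, sample_b):
        if s not in depths.columns:
            raise ValueError(f"unknown sample {s!r}")
    path = Path(path)
    pools = sorted(design["pool"].unique())
    cmap = matplotlib.colormaps["tab10"]
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.6))
    for ax, mat, title in (
        (axes[0], depths, "raw depth"),
        (axes[1], rel, "relative depth"),
    ):
        for k, pool in enumerate(pools):
            rows = design.index[design["pool"] == pool]
            ax.plot(
                mat.loc[rows, sample_a], mat.loc[rows, sample_b],
                "o", ms=2.5, alpha=0.6, color=cmap(k), label=f"pool {pool}",
            )
        lim = max(float(np.nanmax(mat[[sample_a, sample_b]].to_numpy())), 1.0)
        ax.plot([0, lim], [0, lim], color="0.7", lw=0.8, zorder=0)
        ax.set_xlabel(sample_a)
        ax.set_ylabel(sample_b)
        ax.set_title(title, fontsize=9)
        ax.legend(fontsize=6)
    fig.tight_layout()
    _save(fig, path, dpi)
    return path
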