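"""Static SVG panels for the skew and overlay results."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_skew_panel(obs_topk, ensemble, all_fst, report, path) -> None:
    """ECDF panel: all-SNP F_ST (blue), observed top-k (orange), each
    permutation replicate (translucent black), pooled replicates (green)."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))

    def ecdf(ax, x, **kw):
        x = np.sort(np.asarray(x))
        x = x[np.isfinite(x)]
        ax.step(x, np.arange(1, len(x) + 1) / len(x), where="post", **kw)

    for rep in ensemble.replicates:
        ecdf(ax1, rep["fst"], color="black", alpha=0.05, lw=0.5)
    ecdf(ax1, ensemble.pooled_fst, color="green", lw=1.5, label="permuted (pooled)")
    ecdf(ax1, all_fst, color="tab:blue", lw=1.5, label="all SNPs")
    ecdf(ax1, obs_topk["fst"], color="tab:orange", lw=1.5, label="observed top SNPs")
    ax1.set_xlabel("$F_{ST}$")
    ax1.set_ylabel("cumulative fraction")
    ax1.legend(fontsize=8)
    ax1.set_title(f"skew fdr: {report.fst_skew_fdr.text}")

    ax2.scatter(obs_topk["fst"], obs_topk["neg_log10_p"], s=8, c="tab:orange")
    ax2.set_xlabel("$F_{ST}$")
    ax2.set_ylabel("GWA $-\\log_{10}(p)$")
    sp = report.spearman_fdr.text if report.spearman_fdr else "NA"
    ax2.set_title(f"Spearman fdr: {sp}")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def plot_overlay(windows, top, path) -> None:
    """Windowed mean F_ST (gray) with top GWA SNPs colored by -log10(p)."""
    chroms = list(dict.fromkeys(windows["chrom"]))
    fig, axes = plt.subplots(len(chroms), 1, figsize=(9, 2.2 * len(chroms)), squeeze=False)
    for ax, chrom in zip(axes[:, 0], chroms):
        w = windows[windows["chrom"] == chrom]
        mid = (w["start_pos"] + w["end_pos"]) / 2
        ax.scatter(mid / 1e6, w["mean_fst"], s=6, c="gray", label="10-SNP mean")
        t = top[top["chrom"] == chrom]
        if len(t):
            sc = ax.scatter(
                t["pos"] / 1e6, t["fst"], s=14, c=t["neg_log10_p"], cmap="viridis"
            )
            fig.colorbar(sc, ax=ax, label="$-\\log_{10}(p)$")
        ax.set_ylabel("$F_{ST}$")
        ax.set_title(chrom, fontsize=9)
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
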