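"""Plots: per-chromosome raw/smoothed/control-chart triptych and paired
Manhattan panels for the two detectors."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def chromosome_triptych(scan_results, chromosome: int, path: str | Path) -> None:
    """Raw Fst track, LOWESS-smoothed track, and control chart with dashed
    UCL/LCL for one chromosome (three stacked panels)."""
    trk = scan_results.track
    grp = trk[trk["chromosome"] == chromosome]
    lim = scan_results.limits.set_index("chromosome").loc[chromosome]
    mb = grp["position_bp"] / 1e6

    fig, axes = plt.subplots(3, 1, figsize=(8, 8), sharex=True)
    axes[0].plot(mb, grp["fst"], ".", ms=2, color="grey")
    axes[0].set_ylabel("raw Fst")
    axes[1].plot(mb, grp["smoothed_fst"], "-", color="tab:blue")
    axes[1].set_ylabel(f"smoothed Fst (S={lim['smoothing_s']:.3g})")
    ax = axes[2]
    ax.plot(mb, grp["smoothed_fst"], "-", color="tab:blue")
    ax.axhline(lim["mean"], color="black")
    ax.axhline(lim["ucl"], color="black", ls="--")
    ax.axhline(lim["lcl"], color="black", ls="--")
    out = grp[grp["flag"] != "normal"]
    ax.plot(out["position_bp"] / 1e6, out["smoothed_fst"], "o", ms=4, color="red")
    ax.set_ylabel("control chart")
    ax.set_xlabel(f"chromosome {chromosome} position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def manhattan_pair(scan_results, varld_results, path: str | Path) -> None:
    """Genome-wide smoothed-Fst and standardized varLD panels with their
    3-SD significance thresholds; significant points in black."""
    fig, axes = plt.subplots(2, 1, figsize=(11, 6), sharex=True)

    trk = scan_results.track
    offsets, xticks = {}, []
    run = 0
    for chrom in sorted(trk["chromosome"].unique()):
        offsets[chrom] = run
        span = trk.loc[trk["chromosome"] == chrom, "position_bp"].max()
        xticks.append((run + span / 2, chrom))
        run += span

    for chrom, grp in trk.groupby("chromosome"):
        x = grp["position_bp"] + offsets[chrom]
        color = "tab:blue" if chrom % 2 else "tab:cyan"
        axes[0].plot(x, grp["smoothed_fst"], ".", ms=2, color=color)
        sig = grp[grp["flag"] == "outlier_high"]
        axes[0].plot(sig["position_bp"] + offsets[chrom], sig["smoothed_fst"],
                     ".", ms=4, color="black")
    axes[0].set_ylabel("smoothed Fst")

    w = varld_results.windows
    for chrom, grp in w.groupby("chromosome"):
        if chrom not in offsets:
            continue
        x = grp["central_bp"] + offsets[chrom]
        color = "tab:green" if chrom % 2 else "tab:olive"
        axes[1].plot(x, grp["standardized_score"], ".", ms=2, color=color)
        sig = grp[grp["significant"]]
        axes[1].plot(sig["central_bp"] + offsets[chrom], sig["standardized_score"],
                     ".", ms=4, color="black")
    axes[1].axhline(varld_results.model.config.threshold_sd, color="black", ls="--")
    axes[1].set_ylabel("varLD (SD units)")
    axes[1].set_xticks([t for t, _ in xticks])
    axes[1].set_xticklabels([str(c) for _, c in xticks], fontsize=7)
    axes[1].set_xlabel("chromosome")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
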