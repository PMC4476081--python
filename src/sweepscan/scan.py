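"""Chromosome-wise LOWESS smoothing of the Fst track and control-chart calling.

The scan follows the classic genome-scan recipe: smooth the noisy per-SNP Fst
values separately for each autosome with a locally weighted regression whose
neighborhood always spans the same number of SNPs (default 20, so the
smoothing fraction S varies by chromosome as S = 20 / n_chrom), then treat
the smoothed series as a control chart with limits at mean +/- k*SD (default
k = 3) and flag values beyond the limits as outlier signals.  Runs of
consecutive outlier SNPs collapse to peaks; strong local maxima that stay
below the upper limit are reported as borderline peaks (possible incomplete
sweeps).

The smoother is the standard tricube-weighted local polynomial (degree 1 by
default, no robustness iterations), with the neighborhood being the nearest
``window_snps`` points by physical distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .dataset import GenotypeDataset
from .fst import fst_per_snp, mean_fst

log = logging.getLogger(__name__)


@dataclass
class SmoothingConfig:
    """LOWESS settings: neighborhood size in SNPs, local degree, robustness."""

    window_snps: int = 20
    degree: int = 1
    robustness_iters: int = 0
    x_axis: Literal["position_bp", "snp_index"] = "position_bp"

    def __post_init__(self) -> None:
        if self.window_snps < self.degree + 2:
            raise ValueError("window_snps must be >= degree + 2")


def smoothing_fraction(chrom_snp_count: int, window_snps: int = 20) -> float:
    """Fraction S of a chromosome's SNPs entering each local regression.

    S = window_snps / chrom_snp_count, so every local fit draws on the
    nearest ``window_snps`` points.  Chromosomes with fewer SNPs than the
    window fall back to S = 1 (a single global regression) with a warning.
    """
    if chrom_snp_count < window_snps:
        log.warning(
            "chromosome has %d SNPs < window of %d; using S = 1",
            chrom_snp_count, window_snps,
        )
        return 1.0
    return window_snps / chrom_snp_count


def _strictly_increasing(positions: np.ndarray) -> np.ndarray:
    """Bump duplicate positions by +1 bp until strictly increasing."""
    pos = np.asarray(positions, dtype=float).copy()
    for i in range(1, len(pos)):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1.0
    return pos


def lowess_smooth(
    positions: np.ndarray,
    values: np.ndarray,
    config: SmoothingConfig | None = None,
) -> np.ndarray:
    """Tricube-weighted local polynomial smoother evaluated at every input point.

    ``positions`` must be sorted; duplicates are jittered by +1 bp (warning).
    The neighborhood of each point is its nearest ``window_snps`` points by
    |Δposition| (contiguous on a sorted axis).  Degree 1 uses a closed-form
    weighted least squares fit; higher degrees go through a per-point
    polynomial fit.  Optional robustness iterations reweight by Tukey's
    bisquare on the residuals.
    """
    cfg = config or SmoothingConfig()
    x = np.asarray(positions, dtype=float)
    y = np.asarray(values, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("positions and values must have equal length")
    if n < cfg.degree + 2:
        raise ValueError(f"need at least degree+2 = {cfg.degree + 2} points")
    if not np.isfinite(y).all():
        raise ValueError("values must be finite; drop NaN loci before smoothing")
    if np.any(np.diff(x) < 0):
        raise ValueError("positions must be sorted")
    if np.any(np.diff(x) == 0):
        log.warning("duplicate positions jittered by +1 bp before smoothing")
        x = _strictly_increasing(x)

    k = min(cfg.window_snps, n)
    starts = _neighborhood_starts(x, k)
    idx = starts[:, None] + np.arange(k)[None, :]
    X = x[idx]
    Y = y[idx]
    dist = np.abs(X - x[:, None])
    dmax = dist.max(axis=1)
    dmax = np.where(dmax > 0, dmax, 1.0)
    w = (1.0 - (dist / dmax[:, None]) ** 3) ** 3
    w = np.clip(w, 0.0, None)

    robust = np.ones_like(w)
    smoothed = np.empty(n)
    for _ in range(cfg.robustness_iters + 1):
        smoothed = _wls_fit(X, Y, w * robust, x, cfg.degree)
        if cfg.robustness_iters == 0:
            break
        resid = y - smoothed
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        u = resid / (6.0 * s)
        delta = np.clip(1.0 - u**2, 0.0, None) ** 2
        robust = delta[idx]
    return smoothed


def _neighborhood_starts(x: np.ndarray, k: int) -> np.ndarray:
    """Start index of the nearest-k contiguous neighborhood for each point."""
    n = len(x)
    starts = np.empty(n, dtype=np.int64)
    s = 0
    for i in range(n):
        while s + k < n and x[s + k] - x[i] < x[i] - x[s]:
            s += 1
        starts[i] = s
    return starts


def _wls_fit(X, Y, W, x0, degree: int) -> np.ndarray:
    """Per-row weighted polynomial fit evaluated at x0 (rows are neighborhoods)."""
    Xc = X - x0[:, None]  # center at the evaluation point for stability
    if degree == 1:
        sw = W.sum(axis=1)
        swx = (W * Xc).sum(axis=1)
        swy = (W * Y).sum(axis=1)
        swxx = (W * Xc * Xc).sum(axis=1)
        swxy = (W * Xc * Y).sum(axis=1)
        det = sw * swxx - swx * swx
        scale = sw * swxx + swx * swx
        ok = det > 1e-12 * np.where(scale > 0, scale, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            intercept = (swxx * swy - swx * swxy) / det
            wmean = swy / sw
        return np.where(ok, intercept, wmean)
    out = np.empty(len(x0))
    for i in range(len(x0)):
        wi = W[i]
        pos = wi > 0
        if pos.sum() <= degree:
            out[i] = np.average(Y[i], weights=np.clip(wi, 1e-12, None))
            continue
        coef = np.polyfit(Xc[i][pos], Y[i][pos], degree, w=np.sqrt(wi[pos]))
        out[i] = coef[-1]
    return out


# ---------------------------------------------------------------------------
# Control chart
# ---------------------------------------------------------------------------

FLAG_NORMAL = "normal"
FLAG_HIGH = "outlier_high"
FLAG_LOW = "outlier_low"


def control_chart(smoothed: np.ndarray, k: float = 3.0) -> dict:
    """Mean, sample SD and mean +/- k*SD limits with per-value flags.

    Values strictly above UCL are ``outlier_high``, strictly below LCL
    ``outlier_low``; a value exactly on a limit is normal.  A zero SD
    collapses the limits onto the mean and nothing is flagged.
    """
    v = np.asarray(smoothed, dtype=float)
    if len(v) < 2:
        raise ValueError("control_chart needs at least 2 values")
    mean = float(v.mean())
    sd = 0.0 if np.all(v == v[0]) else float(v.std(ddof=1))
    ucl = mean + k * sd
    lcl = mean - k * sd
    if sd == 0:
        log.info("zero SD: control limits collapse to the mean, no outliers")
        flags = np.full(len(v), FLAG_NORMAL, dtype=object)
    else:
        flags = np.where(v > ucl, FLAG_HIGH, np.where(v < lcl, FLAG_LOW, FLAG_NORMAL))
    return {"mean": mean, "sd": sd, "ucl": ucl, "lcl": lcl, "k": k, "flags": flags}


def classify_peaks(
    chrom_frame: pd.DataFrame,
    chart: dict,
    borderline_fraction: float = 0.9,
) -> pd.DataFrame:
    """Collapse outlier runs into peaks and report strong sub-limit local maxima.

    ``chrom_frame`` needs columns snp_id, position_bp, smoothed_fst (one
    chromosome, map order).  Contiguous runs above UCL become one peak whose
    summit is the maximum smoothed value; local maxima in
    (mean + borderline_fraction*k*sd, UCL] become borderline peaks.
    """
    v = chrom_frame["smoothed_fst"].to_numpy(dtype=float)
    pos = chrom_frame["position_bp"].to_numpy()
    ids = chrom_frame["snp_id"].to_numpy()
    ucl = chart["ucl"]
    border_thr = chart["mean"] + borderline_fraction * chart["k"] * chart["sd"]
    rows = []

    above = v > ucl
    if chart["sd"] > 0 and above.any():
        edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            summit = s + int(np.argmax(v[s:e]))
            rows.append(
                ("outlier", int(pos[s]), int(pos[e - 1]), int(pos[summit]),
                 ids[summit], float(v[summit]), int(e - s))
            )

    if chart["sd"] > 0:
        n = len(v)
        for i in np.flatnonzero((v > border_thr) & ~above):
            left_ok = i == 0 or v[i] >= v[i - 1]
            right_ok = i == n - 1 or v[i] >= v[i + 1]
            if left_ok and right_ok:
                rows.append(
                    ("borderline", int(pos[i]), int(pos[i]), int(pos[i]),
                     ids[i], float(v[i]), 1)
                )

    return pd.DataFrame(
        rows,
        columns=["kind", "start_bp", "end_bp", "summit_bp", "summit_snp_id",
                 "summit_value", "n_snps"],
    )


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class FstScanModel:
    """LOWESS/control-chart selection-signature scan for a two-population panel.

    Parameters
    ----------
    dataset
        QC'd, imputed :class:`GenotypeDataset` (or pass a precomputed Fst
        track via :meth:`from_track`).
    smoothing
        :class:`SmoothingConfig`; default 20-SNP tricube local-linear.
    k_sd
        Control-limit width in standard deviations (default 3).
    chart_scope
        ``"chromosome"`` computes limits per autosome (default);
        ``"genome"`` uses one genome-wide mean/SD for every chromosome.
    borderline_fraction
        Fraction of the mean-to-UCL distance a local maximum must exceed to
        be reported as borderline.
    """

    def __init__(
        self,
        dataset: GenotypeDataset | None = None,
        *,
        track: pd.DataFrame | None = None,
        smoothing: SmoothingConfig | None = None,
        k_sd: float = 3.0,
        chart_scope: Literal["chromosome", "genome"] = "chromosome",
        borderline_fraction: float = 0.9,
    ) -> None:
        if (dataset is None) == (track is None):
            raise ValueError("provide exactly one of dataset or track")
        self.dataset = dataset
        self.track = track if track is not None else fst_per_snp(dataset)
        self.smoothing = smoothing or SmoothingConfig()
        self.k_sd = k_sd
        self.chart_scope = chart_scope
        self.borderline_fraction = borderline_fraction

    @classmethod
    def from_track(cls, track: pd.DataFrame, **kwargs) -> "FstScanModel":
        return cls(track=track, **kwargs)

    def fit(self) -> "FstScanResults":
        track = self.track
        finite = np.isfinite(track["fst"].to_numpy(dtype=float))
        n_dropped = int((~finite).sum())
        if n_dropped:
            log.info("dropping %d NaN-Fst loci before smoothing", n_dropped)
        work = track.loc[finite].reset_index(drop=True)

        pieces = []
        for chrom, grp in work.groupby("chromosome", sort=True):
            grp = grp.reset_index(drop=True)
            if len(grp) < self.smoothing.degree + 2:
                log.warning("chromosome %s has too few SNPs; skipped", chrom)
                continue
            if self.smoothing.x_axis == "snp_index":
                xs = np.arange(len(grp), dtype=float)
            else:
                xs = grp["position_bp"].to_numpy(dtype=float)
            sm = lowess_smooth(xs, grp["fst"].to_numpy(dtype=float), self.smoothing)
            grp = grp.assign(smoothed_fst=sm)
            pieces.append(grp)
        if not pieces:
            raise ValueError("no chromosome had enough SNPs to smooth")
        smoothed = pd.concat(pieces, ignore_index=True)

        limits_rows = []
        flags = np.empty(len(smoothed), dtype=object)
        peak_frames = []
        if self.chart_scope == "genome":
            genome_chart = control_chart(
                smoothed["smoothed_fst"].to_numpy(), self.k_sd
            )
        for chrom, grp in smoothed.groupby("chromosome", sort=True):
            vals = grp["smoothed_fst"].to_numpy()
            if self.chart_scope == "genome":
                chart = dict(genome_chart)
                v = vals
                if chart["sd"] == 0:
                    chart["flags"] = np.full(len(v), FLAG_NORMAL, dtype=object)
                else:
                    chart["flags"] = np.where(
                        v > chart["ucl"], FLAG_HIGH,
                        np.where(v < chart["lcl"], FLAG_LOW, FLAG_NORMAL),
                    )
            else:
                chart = control_chart(vals, self.k_sd)
            flags[grp.index.to_numpy()] = chart["flags"]
            limits_rows.append(
                (chrom, len(grp), smoothing_fraction(len(grp), self.smoothing.window_snps),
                 chart["mean"], chart["sd"], chart["ucl"], chart["lcl"])
            )
            pk = classify_peaks(grp.reset_index(drop=True), chart, self.borderline_fraction)
            pk.insert(0, "chromosome", chrom)
            peak_frames.append(pk)
        smoothed["flag"] = flags
        limits = pd.DataFrame(
            limits_rows,
            columns=["chromosome", "n_snps", "smoothing_s", "mean", "sd", "ucl", "lcl"],
        )
        nonempty = [p for p in peak_frames if len(p)]
        if nonempty:
            peaks = pd.concat(nonempty, ignore_index=True)
        else:
            peaks = peak_frames[0]
        return FstScanResults(self, smoothed, limits, peaks, n_dropped)


class FstScanResults:
    """Fitted scan: smoothed track, per-chromosome limits, peak table."""

    def __init__(self, model, track, limits, peaks, n_dropped_na):
        self.model = model
        self.track = track          # per-SNP: raw fst, smoothed_fst, flag
        self.limits = limits        # per-chromosome chart parameters
        self.peaks = peaks          # collapsed outlier + borderline peaks
        self.n_dropped_na = n_dropped_na

    @property
    def n_outlier_snps(self) -> int:
        return int((self.track["flag"] != FLAG_NORMAL).sum())

    @property
    def outlier_peaks(self) -> pd.DataFrame:
        return self.peaks[self.peaks["kind"] == "outlier"].reset_index(drop=True)

    @property
    def significant_snps(self) -> pd.DataFrame:
        """SNPs above the upper control limit (the annotated signals)."""
        return self.track[self.track["flag"] == FLAG_HIGH].reset_index(drop=True)

    def summary(self) -> str:
        mean, sd = mean_fst(self.track)
        lines = [
            "Fst LOWESS/control-chart scan",
            "=" * 34,
            f"SNPs scanned:        {len(self.track)} (+{self.n_dropped_na} NaN dropped)",
            f"mean Fst:            {mean:.4f} +/- {sd:.4f} SD",
            f"window (SNPs):       {self.model.smoothing.window_snps}",
            f"control limits:      mean +/- {self.model.k_sd:g} SD per "
            f"{self.model.chart_scope}",
            f"outlier SNPs:        {self.n_outlier_snps}",
            f"outlier peaks:       {len(self.outlier_peaks)}",
            f"borderline peaks:    {int((self.peaks['kind'] == 'borderline').sum())}",
        ]
        return "\n".join(lines)

    def to_tsv(self, track_path, limits_path=None, peaks_path=None) -> None:
        self.track.to_csv(track_path, sep="\t", index=False)
        if limits_path:
            self.limits.to_csv(limits_path, sep="\t", index=False)
        if peaks_path:
            self.peaks.to_csv(peaks_path, sep="\t", index=False)
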