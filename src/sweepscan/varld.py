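"""Regional LD comparison between two populations (varLD-style).

For every sliding window of ``window_snps`` consecutive SNPs on a chromosome,
the signed genotype-dosage correlation matrix (composite LD) is formed in each
population; the window's raw score is the sum of absolute differences of the
two matrices' eigenvalues, both sorted in decreasing order:

    raw = sum_i | lambda_A(i) - lambda_B(i) |.

Raw scores are standardized genome-wide (z-score by default, rank-based
inverse-normal as an option), assigned to the window's central SNP, and
windows whose standardized score exceeds ``threshold_sd`` (default 3) are
flagged significant.  Identical LD structure in the two populations gives a
raw score of exactly 0; the score is symmetric in the populations and bounded
by 2k (each spectrum sums to k, the matrix trace).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import special

from .dataset import MISSING, GenotypeDataset

log = logging.getLogger(__name__)


@dataclass
class VarLDConfig:
    """Window length (SNPs), step, significance threshold, standardization."""

    window_snps: int = 20
    step_snps: int = 1
    threshold_sd: float = 3.0
    standardization: Literal["zscore", "rank_normal"] = "zscore"

    def __post_init__(self) -> None:
        if self.window_snps < 2:
            raise ValueError("window_snps must be >= 2")
        if self.step_snps < 1:
            raise ValueError("step_snps must be >= 1")


def window_correlation(dosages: np.ndarray) -> np.ndarray:
    """Signed Pearson correlation matrix of the dosage columns in a window.

    Columns with zero variance (fixed in this population) contribute 0
    off-diagonal and 1 on the diagonal, keeping the matrix well-defined and
    the trace equal to k.  Requires complete (imputed) dosages.
    """
    d = np.asarray(dosages, dtype=float)
    if d.ndim != 2 or d.shape[0] < 3:
        raise ValueError("window_correlation needs a (>=3 samples, k SNPs) matrix")
    if np.any(d == MISSING):
        raise ValueError("missing dosages: impute before computing LD")
    z = d - d.mean(axis=0)
    norm = np.sqrt((z**2).sum(axis=0))
    fixed = norm == 0
    norm = np.where(fixed, 1.0, norm)
    z = z / norm
    corr = z.T @ z
    corr[fixed, :] = 0.0
    corr[:, fixed] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def varld_raw_score(corr_a: np.ndarray, corr_b: np.ndarray) -> float:
    """Sum of absolute differences of the sorted eigenvalues of two
    correlation matrices."""
    a = np.asarray(corr_a, dtype=float)
    b = np.asarray(corr_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("correlation matrices must be square and same size")
    for m in (a, b):
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("correlation matrix is not symmetric")
    ev_a = np.sort(np.linalg.eigvalsh(a))[::-1]
    ev_b = np.sort(np.linalg.eigvalsh(b))[::-1]
    return float(np.abs(ev_a - ev_b).sum())


def rank_inverse_normal(values: np.ndarray) -> np.ndarray:
    """Blom rank-based inverse-normal transform."""
    v = np.asarray(values, dtype=float)
    ranks = pd.Series(v).rank(method="average").to_numpy()
    p = (ranks - 0.375) / (len(v) + 0.25)
    return np.sqrt(2.0) * special.erfinv(2.0 * p - 1.0)


def central_index(window_snps: int) -> int:
    """0-based offset of the central SNP inside a window (ceil(k/2), 1-based)."""
    return math.ceil(window_snps / 2) - 1


def varld_scan(dataset: GenotypeDataset, config: VarLDConfig | None = None) -> pd.DataFrame:
    """Sliding-window varLD scan; returns the per-window table.

    Windows never span chromosomes; chromosomes with fewer SNPs than the
    window are skipped with a warning.  Columns: chromosome, start/end SNP id
    and bp, central_snp_id, central_bp, raw_score, standardized_score,
    significant.
    """
    cfg = config or VarLDConfig()
    labels = dataset.population_labels
    if len(labels) != 2:
        raise ValueError("varld_scan needs exactly two populations")
    subs = [dataset.dosages[dataset.samples_of(lab)].astype(float) for lab in labels]
    if np.any(dataset.dosages == MISSING):
        raise ValueError("missing dosages: impute before the varLD scan")

    k = cfg.window_snps
    coff = central_index(k)
    chroms = dataset.snps["chromosome"].to_numpy()
    ids = dataset.snps["snp_id"].to_numpy()
    pos = dataset.snps["position_bp"].to_numpy()

    rows = []
    for chrom in np.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        if len(sel) < k:
            log.warning("chromosome %s has %d SNPs < window %d; skipped",
                        chrom, len(sel), k)
            continue
        zs = []
        for sub in subs:
            d = sub[:, sel]
            z = d - d.mean(axis=0)
            norm = np.sqrt((z**2).sum(axis=0))
            norm = np.where(norm == 0, np.inf, norm)  # fixed column -> 0 corr
            zs.append(z / norm)
        for s in range(0, len(sel) - k + 1, cfg.step_snps):
            evs = []
            for z in zs:
                zw = z[:, s : s + k]
                corr = zw.T @ zw
                np.fill_diagonal(corr, 1.0)
                evs.append(np.linalg.eigvalsh(corr))
            raw = float(np.abs(evs[0] - evs[1]).sum())
            g = sel[s : s + k]
            rows.append(
                (chrom, ids[g[0]], int(pos[g[0]]), ids[g[-1]], int(pos[g[-1]]),
                 ids[g[coff]], int(pos[g[coff]]), raw)
            )

    out = pd.DataFrame(
        rows,
        columns=["chromosome", "first_snp_id", "first_bp", "last_snp_id",
                 "last_bp", "central_snp_id", "central_bp", "raw_score"],
    )
    if len(out) == 0:
        out["standardized_score"] = []
        out["significant"] = []
        return out
    raw = out["raw_score"].to_numpy()
    if cfg.standardization == "zscore":
        sd = raw.std(ddof=1) if len(raw) > 1 else 0.0
        std = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    else:
        std = rank_inverse_normal(raw)
    out["standardized_score"] = std
    out["significant"] = std > cfg.threshold_sd
    out.attrs["population_labels"] = labels
    return out


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class VarLDModel:
    """Regional LD-divergence scan as a fittable model.

    Parameters mirror :class:`VarLDConfig`; the window length defaults to the
    same 20 SNPs as the LOWESS scan so the two detectors see the same scale.
    """

    def __init__(self, dataset: GenotypeDataset, config: VarLDConfig | None = None,
                 **kwargs) -> None:
        self.dataset = dataset
        self.config = config or VarLDConfig(**kwargs)

    def fit(self) -> "VarLDResults":
        windows = varld_scan(self.dataset, self.config)
        return VarLDResults(self, windows)


class VarLDResults:
    """Fitted varLD scan: per-window scores with significance flags."""

    def __init__(self, model: VarLDModel, windows: pd.DataFrame) -> None:
        self.model = model
        self.windows = windows

    @property
    def significant_windows(self) -> pd.DataFrame:
        return self.windows[self.windows["significant"]].reset_index(drop=True)

    @property
    def significant_snps(self) -> pd.DataFrame:
        """Central SNPs of significant windows, deduplicated."""
        sig = self.significant_windows
        return (
            sig[["chromosome", "central_snp_id", "central_bp", "standardized_score"]]
            .sort_values("standardized_score", ascending=False)
            .drop_duplicates("central_snp_id")
            .reset_index(drop=True)
        )

    def summary(self) -> str:
        w = self.windows
        lines = [
            "varLD regional LD-divergence scan",
            "=" * 34,
            f"windows:             {len(w)} (window {self.model.config.window_snps} "
            f"SNPs, step {self.model.config.step_snps})",
            f"standardization:     {self.model.config.standardization}",
            f"threshold:           > {self.model.config.threshold_sd:g} SD",
            f"significant windows: {int(w['significant'].sum())}",
            f"significant SNPs:    {len(self.significant_snps)}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.windows.to_csv(path, sep="\t", index=False)
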