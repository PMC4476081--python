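"""Data editing: autosome restriction, SNP filters, per-breed modal imputation.

The editing pipeline mirrors standard 50K-array practice for a two-breed
differentiation scan: keep autosomal SNPs only, drop loci monomorphic in both
breeds, loci with more than ``max_missing_rate`` missing calls, and loci with
pooled minor allele frequency below ``min_maf``; finally replace each missing
call with the homozygote of the modal allele within that sample's own breed.

Each removed SNP is counted once, under the first filter that removed it, so
the :class:`QcReport` counts always reconcile with the input SNP count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MISSING, DataError, GenotypeDataset

log = logging.getLogger(__name__)


@dataclass
class QcReport:
    n_input_snps: int = 0
    n_removed_nonautosomal: int = 0
    n_removed_monomorphic_both: int = 0
    n_removed_missingness: int = 0
    n_removed_maf: int = 0
    n_retained: int = 0
    n_imputed_cells: int = 0

    def reconciles(self) -> bool:
        return self.n_input_snps == (
            self.n_retained
            + self.n_removed_nonautosomal
            + self.n_removed_monomorphic_both
            + self.n_removed_missingness
            + self.n_removed_maf
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def _pop_masks(dataset: GenotypeDataset) -> list[np.ndarray]:
    return [dataset.samples_of(lab) for lab in dataset.population_labels]


def allele_b_frequency(dosages: np.ndarray) -> np.ndarray:
    """Per-SNP frequency of allele_b among non-missing calls (NaN if none)."""
    valid = dosages != MISSING
    counts = np.where(valid, dosages, 0).sum(axis=0).astype(float)
    denom = 2.0 * valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, counts / denom, np.nan)


def filter_autosomes(
    dataset: GenotypeDataset, n_autosomes: int = 29
) -> tuple[GenotypeDataset, int]:
    """Keep SNPs on autosomes 1..n_autosomes; returns (dataset, n_removed)."""
    chrom = dataset.snps["chromosome"].to_numpy()
    keep = (chrom >= 1) & (chrom <= n_autosomes)
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        log.warning("autosome filter removed every SNP")
    return dataset.subset_snps(keep), n_removed


def qc_filter(
    dataset: GenotypeDataset,
    max_missing_rate: float = 0.025,
    min_maf: float = 0.01,
) -> tuple[GenotypeDataset, QcReport]:
    """Apply the monomorphic / missingness / MAF filters in that fixed order.

    A SNP is removed as *monomorphic-in-both* only when each breed separately
    shows no variation among its non-missing calls; a SNP fixed in one breed
    but segregating in the other is kept by that filter.  Missingness is the
    pooled per-SNP missing-call fraction; MAF is computed on both breeds
    pooled, from non-missing calls.
    """
    if not 0 <= max_missing_rate < 1:
        raise ValueError("max_missing_rate must be in [0, 1)")
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")

    report = QcReport(n_input_snps=dataset.n_snps)
    d = dataset.dosages
    masks = _pop_masks(dataset)

    mono_each = []
    for m in masks:
        sub = d[m]
        valid = sub != MISSING
        # a population is monomorphic at a locus when all its non-missing calls
        # are the same homozygote (or it has no non-missing calls)
        any_b = (np.where(valid, sub, 0) > 0).any(axis=0)
        all_b2 = np.where(valid, sub, 2).min(axis=0) == 2
        mono_each.append(~any_b | all_b2)
    mono_both = mono_each[0] & mono_each[1]

    miss_rate = (d == MISSING).mean(axis=0)
    high_miss = miss_rate > max_missing_rate

    f = allele_b_frequency(d)
    with np.errstate(invalid="ignore"):
        maf = np.fmin(f, 1.0 - f)
    low_maf = np.nan_to_num(maf, nan=0.0) < min_maf

    removed1 = mono_both
    removed2 = high_miss & ~removed1
    removed3 = low_maf & ~removed1 & ~removed2

    report.n_removed_monomorphic_both = int(removed1.sum())
    report.n_removed_missingness = int(removed2.sum())
    report.n_removed_maf = int(removed3.sum())
    keep = ~(removed1 | removed2 | removed3)
    report.n_retained = int(keep.sum())
    return dataset.subset_snps(keep), report


def impute_missing(dataset: GenotypeDataset) -> tuple[GenotypeDataset, int]:
    """Replace missing calls with the homozygote of the breed-modal allele.

    Within each breed and locus, the allele with the higher frequency among
    non-missing calls fills missing cells as a homozygote (dosage 0 or 2);
    exact 0.5/0.5 ties break toward allele_a (dosage 0), deterministically.
    """
    out = dataset.copy()
    n_imputed = 0
    for lab in dataset.population_labels:
        m = dataset.samples_of(lab)
        sub = out.dosages[m]
        miss = sub == MISSING
        if not miss.any():
            continue
        f = allele_b_frequency(sub)
        fully = np.isnan(f) & miss.any(axis=0)
        if fully.any():
            j = int(np.flatnonzero(fully)[0])
            raise DataError(
                f"locus {dataset.snps['snp_id'].iloc[j]!r} is fully missing in "
                f"population {lab!r}"
            )
        fill = np.where(f > 0.5, 2, 0).astype(np.int8)
        sub = np.where(miss, fill[None, :], sub)
        out.dosages[m] = sub
        n_imputed += int(miss.sum())
    return out, n_imputed


def heterozygosity_summary(dataset: GenotypeDataset) -> pd.DataFrame:
    """Observed and expected heterozygosity per (population, chromosome).

    Returns a tidy frame with rows for every population x chromosome plus a
    genome-wide row (chromosome = 0).  ``h_obs`` is the heterozygote fraction
    among non-missing calls; ``h_exp`` is the mean over SNPs of 2f(1-f) with f
    the within-population allele_b frequency.  Cells with no non-missing calls
    are NaN.
    """
    rows = []
    chroms = dataset.snps["chromosome"].to_numpy()
    for lab in dataset.population_labels:
        m = dataset.samples_of(lab)
        sub = dataset.dosages[m]
        valid = sub != MISSING
        het = sub == 1
        f = allele_b_frequency(sub)
        hexp_snp = 2.0 * f * (1.0 - f)
        for chrom in [0, *sorted(set(chroms.tolist()))]:
            snp_sel = slice(None) if chrom == 0 else (chroms == chrom)
            n_valid = int(valid[:, snp_sel].sum())
            h_obs = float(het[:, snp_sel].sum()) / n_valid if n_valid else np.nan
            he = hexp_snp[snp_sel] if chrom != 0 else hexp_snp
            h_exp = float(np.nanmean(he)) if np.isfinite(he).any() else np.nan
            rows.append((lab, chrom, h_obs, h_exp))
    return pd.DataFrame(rows, columns=["population", "chromosome", "h_obs", "h_exp"])


def run_qc(
    dataset: GenotypeDataset,
    n_autosomes: int = 29,
    max_missing_rate: float = 0.025,
    min_maf: float = 0.01,
    impute: bool = True,
) -> tuple[GenotypeDataset, QcReport]:
    """Full editing pipeline: autosomes -> filters -> (optional) imputation."""
    ds, n_nonauto = filter_autosomes(dataset, n_autosomes)
    ds, report = qc_filter(ds, max_missing_rate=max_missing_rate, min_maf=min_maf)
    report.n_input_snps = dataset.n_snps
    report.n_removed_nonautosomal = n_nonauto
    if impute:
        ds, n_imp = impute_missing(ds)
        report.n_imputed_cells = n_imp
    return ds, report
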