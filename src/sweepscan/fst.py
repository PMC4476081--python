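"""Per-SNP fixation index from pooled allele frequencies.

For two populations with within-population allele_b frequencies f1, f2 and
sample counts n1, n2, the pooled frequency is the chromosome-count weighted
mean

    f_p = [f1 * 2*n1 + f2 * 2*n2] / [2 * (n1 + n2)],      f_q = 1 - f_p,

total expected heterozygosity is H_t = 2 * f_p * f_q, within-population
expected heterozygosity is the matching weighted mean
H_s = w1 * 2*f1*(1-f1) + w2 * 2*f2*(1-f2) with w_i = 2*n_i / (2*n1 + 2*n2),
and

    Fst = (H_t - H_s) / H_t.

With these matched weights H_t >= H_s (concavity of 2p(1-p)), so Fst lies in
[0, 1] wherever H_t > 0; loci monomorphic in the pooled sample (H_t = 0) get
Fst = NaN and are excluded from smoothing.  No finite-sample bias correction
is applied: the statistic is the plain heterozygosity ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset
from .qc import allele_b_frequency

#: Columns of the per-SNP Fst table.
FST_COLUMNS = (
    "snp_id", "chromosome", "position_bp",
    "f_pop1", "f_pop2", "n_pop1", "n_pop2",
    "f_pooled", "h_s", "h_t", "fst",
)


def pooled_frequency(f1: float, n1: int, f2: float, n2: int):
    """Chromosome-count weighted pooled allele frequency.

    Accepts scalars or aligned arrays for the frequencies.
    """
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    if np.any(np.asarray(n1) < 1) or np.any(np.asarray(n2) < 1):
        raise ValueError("population sample counts must be >= 1")
    out = (f1 * (2 * n1) + f2 * (2 * n2)) / (2 * (n1 + n2))
    return float(out) if out.ndim == 0 else out


def fst_from_frequencies(f1, n1, f2, n2, equal_weights: bool = False):
    """(f_p, H_s, H_t, Fst) from within-population frequencies and counts.

    ``equal_weights`` averages the two within-population heterozygosities
    with weight 1/2 each instead of the chromosome-count weights; in that
    case H_t >= H_s is no longer guaranteed for unequal samples.
    """
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    fp = pooled_frequency(f1, n1, f2, n2)
    fp = np.asarray(fp, dtype=float)
    ht = 2.0 * fp * (1.0 - fp)
    if equal_weights:
        w1 = w2 = 0.5
    else:
        w1 = (2.0 * n1) / (2.0 * n1 + 2.0 * n2)
        w2 = (2.0 * n2) / (2.0 * n1 + 2.0 * n2)
    hs = w1 * 2.0 * f1 * (1.0 - f1) + w2 * 2.0 * f2 * (1.0 - f2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(ht > 0, (ht - hs) / ht, np.nan)
    return fp, hs, ht, fst


def fst_per_snp(dataset: GenotypeDataset, equal_weights: bool = False) -> pd.DataFrame:
    """Per-SNP Fst track for a QC'd, imputed two-population dataset.

    Per-locus sample counts are the numbers of non-missing calls in each
    population (equal to the population sizes after imputation).  Returns a
    DataFrame with columns :data:`FST_COLUMNS`, one row per SNP in map order.
    """
    labels = dataset.population_labels
    if len(labels) != 2:
        raise ValueError("fst_per_snp needs exactly two populations")
    masks = [dataset.samples_of(lab) for lab in labels]
    subs = [dataset.dosages[m] for m in masks]
    freqs = [allele_b_frequency(s) for s in subs]
    ns = [(s != MISSING).sum(axis=0) for s in subs]

    fp, hs, ht, fst = fst_from_frequencies(
        freqs[0], ns[0], freqs[1], ns[1], equal_weights=equal_weights
    )
    out = dataset.snps[["snp_id", "chromosome", "position_bp"]].copy()
    out["f_pop1"] = freqs[0]
    out["f_pop2"] = freqs[1]
    out["n_pop1"] = ns[0]
    out["n_pop2"] = ns[1]
    out["f_pooled"] = fp
    out["h_s"] = hs
    out["h_t"] = ht
    out["fst"] = fst
    out.attrs["population_labels"] = labels
    return out


def mean_fst(track: pd.DataFrame) -> tuple[float, float]:
    """Genome-wide mean and sample SD (n-1) of Fst over non-NaN loci.

    The mean times 100 is the percentage of total genetic variation explained
    by between-population differences.
    """
    vals = track["fst"].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("mean_fst needs at least two non-NaN Fst values")
    return float(vals.mean()), float(vals.std(ddof=1))
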