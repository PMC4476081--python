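"""Readers and writers for PLINK text PED/MAP, VCF (GT-only) and population tables.

Allele orientation is fixed at read time: for PED the second-observed allele at a
locus becomes ``allele_b`` (the dosage-counted allele); for VCF, REF -> ``allele_a``
and the first ALT -> ``allele_b``.  Downstream statistics are invariant to the
choice, so orientation is arbitrary but deterministic.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .dataset import MISSING, SNP_COLUMNS, DataError, FormatError, GenotypeDataset

log = logging.getLogger(__name__)

# Non-autosomal labels are retained at read time (removed by qc.filter_autosomes);
# they are coded as integers above any plausible autosome count.
_SPECIAL_CHROM = {"X": 90, "Y": 91, "XY": 92, "MT": 93, "M": 93}
_SPECIAL_CHROM_INV = {90: "X", 91: "Y", 92: "XY", 93: "MT"}


def parse_chromosome(label: str) -> int:
    """Parse a chromosome label to the internal integer code.

    Numeric labels (with an optional ``chr`` prefix) map to themselves;
    X/Y/XY/MT map to reserved codes ≥ 90; anything else (unplaced contigs)
    maps to 0.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() in _SPECIAL_CHROM:
        return _SPECIAL_CHROM[s.upper()]
    try:
        return int(s)
    except ValueError:
        return 0


def chromosome_label(code: int) -> str:
    """Inverse of :func:`parse_chromosome` for writing files."""
    return _SPECIAL_CHROM_INV.get(int(code), str(int(code)))


def read_population_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``sample_id<TAB>population`` into a mapping."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: population table needs 2 columns, found {df.shape[1]}")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_population_table(population_of: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, p in population_of.items():
            fh.write(f"{s}\t{p}\n")


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

def read_plink(
    ped_path: str | Path,
    map_path: str | Path,
    population_of: Mapping[str, str] | None = None,
) -> GenotypeDataset:
    """Read whitespace-delimited PED/MAP genotypes.

    Parameters
    ----------
    population_of
        Mapping sample id -> population label.  If None, the PED family id
        column is used as the population label (the common two-breed layout).

    Notes
    -----
    ``allele_a`` is the first allele observed at a locus scanning samples in
    PED order, ``allele_b`` the second; ``0 0`` is a missing call.  Loci where
    only one allele is ever observed keep ``allele_b == "0"`` and are flagged
    monomorphic-as-read.
    """
    snp_map = _read_map(map_path)
    n_snps = len(snp_map)
    expected_fields = 6 + 2 * n_snps

    samples: list[str] = []
    fids: list[str] = []
    rows: list[np.ndarray] = []
    allele_a = np.full(n_snps, "", dtype="<U1")
    allele_b = np.full(n_snps, "", dtype="<U1")

    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = np.array(line.split())
            if toks.size == 0:
                continue
            if toks.size != expected_fields:
                raise FormatError(
                    f"{ped_path}: line {lineno} has {toks.size} fields, expected {expected_fields}"
                )
            fids.append(str(toks[0]))
            samples.append(str(toks[1]))
            a1 = toks[6::2]
            a2 = toks[7::2]
            miss = (a1 == "0") | (a2 == "0")
            for al in (a1, a2):
                fresh = ~miss & (al != allele_a) & (al != allele_b)
                newa = fresh & (allele_a == "")
                allele_a[newa] = al[newa]
                fresh &= ~newa
                newb = fresh & (allele_b == "")
                allele_b[newb] = al[newb]
                fresh &= ~newb
                if fresh.any():
                    j = int(np.flatnonzero(fresh)[0])
                    raise DataError(
                        f"{ped_path}: locus {snp_map['snp_id'].iloc[j]!r} has a third "
                        f"allele {al[j]!r} (line {lineno})"
                    )
            dose = (a1 == allele_b).astype(np.int8) + (a2 == allele_b).astype(np.int8)
            dose[miss] = MISSING
            rows.append(dose)

    allele_a[allele_a == ""] = "0"
    allele_b[allele_b == ""] = "0"
    snp_map = snp_map.assign(allele_a=allele_a, allele_b=allele_b)[list(SNP_COLUMNS)]

    if population_of is None:
        population_of = dict(zip(samples, fids))
    unknown = [s for s in samples if s not in population_of]
    if unknown:
        raise DataError(f"{ped_path}: samples not in population mapping: {unknown[:5]}")

    ds = GenotypeDataset(
        snp_map,
        samples,
        {s: population_of[s] for s in samples},
        np.vstack(rows) if rows else np.empty((0, n_snps), dtype=np.int8),
    )
    ds.sort_map()
    ds.validate()
    return ds


def _read_map(map_path: str | Path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks:
                continue
            if len(toks) != 4:
                raise FormatError(
                    f"{map_path}: line {lineno} has {len(toks)} fields, expected 4"
                )
            rows.append((toks[1], parse_chromosome(toks[0]), int(toks[3])))
    df = pd.DataFrame(rows, columns=["snp_id", "chromosome", "position_bp"])
    dup = df.duplicated(["chromosome", "position_bp"])
    if dup.any():
        log.warning("%s: %d duplicate (chromosome, position) pairs", map_path, int(dup.sum()))
    return df


def write_plink(dataset: GenotypeDataset, ped_path: str | Path, map_path: str | Path) -> None:
    """Write PED/MAP files that :func:`read_plink` reproduces field-for-field."""
    with open(map_path, "w") as fh:
        for r in dataset.snps.itertuples(index=False):
            fh.write(f"{chromosome_label(r.chromosome)}\t{r.snp_id}\t0\t{r.position_bp}\n")

    a = dataset.snps["allele_a"].to_numpy(dtype="<U1")
    b = dataset.snps["allele_b"].to_numpy(dtype="<U1")
    # genotype strings per dosage value; MISSING -> "0 0"
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(dataset.samples):
            dose = dataset.dosages[i]
            first = np.where(dose >= 1, b, a)
            second = np.where(dose == 2, b, a)
            miss = dose == MISSING
            first = np.where(miss, "0", first)
            second = np.where(miss, "0", second)
            pair = np.char.add(np.char.add(first, " "), second)
            geno = " ".join(pair.tolist())
            pop = dataset.population_of[sample]
            fh.write(f"{pop} {sample} 0 0 0 -9{' ' + geno if geno else ''}\n")


# ---------------------------------------------------------------------------
# VCF (GT only)
# ---------------------------------------------------------------------------

def read_vcf(vcf_path: str | Path, population_of: Mapping[str, str]) -> GenotypeDataset:
    """Read a VCF v4.x with GT calls into a :class:`GenotypeDataset`.

    Only biallelic records are kept; records with two or more ALT alleles are
    skipped with a logged warning (the count is stored in ``meta['n_skipped']``).
    Phased and unphased genotypes are treated identically (dosage = ALT count);
    ``./.`` becomes MISSING.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in population_of]
    if unknown:
        raise DataError(f"{vcf_path}: samples not in population mapping: {unknown[:5]}")

    records = []
    columns = []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_skipped += 1
            continue
        if v.format("GT") is None and not v.genotypes:
            raise FormatError(f"{vcf_path}: record {v.ID or v.POS} lacks a GT field")
        gt = np.array([g[:2] for g in v.genotypes])  # (n_samples, 2) allele indices
        dose = np.where((gt < 0).any(axis=1), MISSING, gt.clip(min=0).sum(axis=1))
        snp_id = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        records.append((snp_id, parse_chromosome(v.CHROM), int(v.POS), v.REF, v.ALT[0]))
        columns.append(dose.astype(np.int8))
    if n_skipped:
        log.warning("%s: skipped %d non-biallelic records", vcf_path, n_skipped)

    snps = pd.DataFrame(records, columns=list(SNP_COLUMNS))
    dosages = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0), dtype=np.int8)
    )
    ds = GenotypeDataset(snps, samples, {s: population_of[s] for s in samples}, dosages)
    ds.meta["n_skipped"] = n_skipped
    ds.sort_map()
    ds.validate()
    return ds


def write_vcf(dataset: GenotypeDataset, vcf_path: str | Path) -> None:
    """Write a minimal VCF v4.2 (GT only) re-readable by :func:`read_vcf`."""
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = dataset.snps["chromosome"].unique()
        for c in chroms:
            fh.write(f"##contig=<ID={chromosome_label(c)}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dataset.samples)
            + "\n"
        )
        gt_of = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, r in enumerate(dataset.snps.itertuples(index=False)):
            ref = r.allele_a if r.allele_a != "0" else "N"
            alt = r.allele_b if r.allele_b != "0" else "."
            gts = "\t".join(gt_of[int(d)] for d in dataset.dosages[:, j])
            fh.write(
                f"{chromosome_label(r.chromosome)}\t{r.position_bp}\t{r.snp_id}\t"
                f"{ref}\t{alt}\t.\t.\t.\tGT\t{gts}\n"
            )
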