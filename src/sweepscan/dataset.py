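"""Shared data model: an ordered SNP map plus a sample x SNP dosage matrix.

Every module in the package consumes :class:`GenotypeDataset`: a biallelic,
two-population genotype panel where each cell counts copies of ``allele_b``
(0, 1, 2) or is :data:`MISSING`.  Coordinates are 1-based physical bp and,
within a chromosome, SNPs are kept sorted by non-decreasing position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in the dosage matrix.
MISSING: int = -1

#: Columns of the SNP map table, in order.
SNP_COLUMNS = ("snp_id", "chromosome", "position_bp", "allele_a", "allele_b")


@dataclass(frozen=True)
class SnpRecord:
    """A single locus of the genetic map.

    ``allele_b`` is the allele whose copies the dosage matrix counts; the
    orientation is fixed when the data are read and never re-polarised
    downstream (Fst and LD statistics are invariant to the choice).
    """

    snp_id: str
    chromosome: int
    position_bp: int
    allele_a: str
    allele_b: str


class DataError(ValueError):
    """Inconsistent genotype content (bad alleles, unknown samples, ...)."""


class FormatError(ValueError):
    """Malformed input file (wrong field counts, missing header keys, ...)."""


@dataclass
class GenotypeDataset:
    """Two-population SNP genotypes with an ordered genetic map.

    Parameters
    ----------
    snps
        DataFrame with columns ``snp_id, chromosome, position_bp, allele_a,
        allele_b``; one row per locus, sorted by (chromosome, position_bp)
        with a stable sort so duplicate positions keep input order.
    samples
        Sample identifiers, one per dosage-matrix row.
    population_of
        Mapping sample id -> population label.  Exactly two labels must be
        present, each with at least two samples (enforced by
        :meth:`validate`, which readers and the simulator call).
    dosages
        ``(n_samples, n_snps)`` integer matrix with entries in
        ``{0, 1, 2, MISSING}`` counting copies of ``allele_b``.
    """

    snps: pd.DataFrame
    samples: list[str]
    population_of: dict[str, str]
    dosages: np.ndarray
    meta: dict = field(default_factory=dict)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[SnpRecord],
        samples: Sequence[str],
        population_of: Mapping[str, str],
        dosages: np.ndarray,
    ) -> "GenotypeDataset":
        snps = pd.DataFrame(
            [(r.snp_id, r.chromosome, r.position_bp, r.allele_a, r.allele_b) for r in records],
            columns=list(SNP_COLUMNS),
        )
        ds = cls(snps, list(samples), dict(population_of), np.asarray(dosages, dtype=np.int8))
        ds.sort_map()
        ds.validate()
        return ds

    def sort_map(self) -> None:
        """Stable-sort SNPs by (chromosome, position_bp), permuting dosages."""
        order = self.snps.sort_values(
            ["chromosome", "position_bp"], kind="stable"
        ).index.to_numpy()
        if not np.array_equal(order, np.arange(len(self.snps))):
            self.snps = self.snps.iloc[order].reset_index(drop=True)
            self.dosages = np.ascontiguousarray(self.dosages[:, order])

    # -- invariants -----------------------------------------------------------

    def validate(self) -> None:
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise DataError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        unknown = [s for s in self.samples if s not in self.population_of]
        if unknown:
            raise DataError(f"samples missing from population mapping: {unknown[:5]}")
        labels = self.population_labels
        if len(labels) != 2:
            raise DataError(f"expected exactly two population labels, found {labels}")
        for lab in labels:
            if int(np.sum(self.population_codes == self._label_index(lab))) < 2:
                raise DataError(f"population {lab!r} has fewer than 2 samples")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise DataError(f"{int(bad.sum())} dosage cells outside {{0,1,2,MISSING}}")

    # -- population bookkeeping ----------------------------------------------

    @property
    def population_labels(self) -> list[str]:
        """The two population labels in first-appearance (sample) order."""
        seen: list[str] = []
        for s in self.samples:
            lab = self.population_of.get(s)
            if lab is not None and lab not in seen:
                seen.append(lab)
        return seen

    def _label_index(self, label: str) -> int:
        return self.population_labels.index(label)

    @property
    def population_codes(self) -> np.ndarray:
        """Per-sample integer code (0/1) following :attr:`population_labels`."""
        labels = self.population_labels
        return np.array([labels.index(self.population_of[s]) for s in self.samples])

    def samples_of(self, label: str) -> np.ndarray:
        """Boolean mask over samples belonging to ``label``."""
        return np.array([self.population_of[s] == label for s in self.samples])

    # -- views ----------------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeDataset":
        """New dataset restricted to SNPs where ``mask`` is True (order kept)."""
        mask = np.asarray(mask, dtype=bool)
        return GenotypeDataset(
            self.snps.loc[mask].reset_index(drop=True),
            list(self.samples),
            dict(self.population_of),
            np.ascontiguousarray(self.dosages[:, mask]),
            dict(self.meta),
        )

    def records(self) -> list[SnpRecord]:
        return [SnpRecord(*row) for row in self.snps.itertuples(index=False, name=None)]

    def equals(self, other: "GenotypeDataset") -> bool:
        """Field-for-field equality (map, samples, populations, dosages)."""
        return (
            self.snps.reset_index(drop=True).equals(other.snps.reset_index(drop=True))
            and self.samples == other.samples
            and {s: self.population_of[s] for s in self.samples}
            == {s: other.population_of[s] for s in other.samples}
            and np.array_equal(self.dosages, other.dosages)
        )

    def polarize_like(self, reference: "GenotypeDataset") -> "GenotypeDataset":
        """Re-orient allele_a/allele_b (flipping dosages) to match a reference.

        Text PED stores no allele order, so a written-then-reread dataset can
        come back with the opposite polarization at loci whose first-observed
        allele differs; all downstream statistics are invariant to this, but
        exact equality checks need the orientation repaired.  Loci where only
        one (or neither) allele was observed adopt the reference labels when
        consistent with the observed allele.
        """
        if len(self.snps) != len(reference.snps):
            raise DataError("polarize_like needs identically sized SNP maps")
        out = self.copy()
        a = out.snps["allele_a"].to_numpy().copy()
        b = out.snps["allele_b"].to_numpy().copy()
        ra = reference.snps["allele_a"].to_numpy()
        rb = reference.snps["allele_b"].to_numpy()
        for j in range(len(a)):
            if a[j] == ra[j] and b[j] == rb[j]:
                continue
            observed = {x for x in (a[j], b[j]) if x != "0"}
            if not observed <= {ra[j], rb[j]}:
                raise DataError(
                    f"locus {out.snps['snp_id'].iloc[j]!r}: alleles "
                    f"{sorted(observed)} not a subset of reference "
                    f"{{{ra[j]}, {rb[j]}}}"
                )
            col = out.dosages[:, j]
            valid = col != MISSING
            # count of reference allele_b = flip iff our allele_b is ref allele_a
            # or our only observed allele is ref allele_b with dosage counted as a
            if b[j] == ra[j] or (b[j] == "0" and a[j] == rb[j]):
                col[valid] = 2 - col[valid]
            a[j], b[j] = ra[j], rb[j]
        out.snps = out.snps.assign(allele_a=a, allele_b=b)
        return out

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(
            self.snps.copy(), list(self.samples), dict(self.population_of),
            self.dosages.copy(), dict(self.meta),
        )
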