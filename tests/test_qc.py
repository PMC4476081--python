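import numpy as np
import pytest

import sweepscan as ss
from sweepscan.dataset import MISSING
from sweepscan.qc import allele_b_frequency
from tests.conftest import build_dataset


class TestFilterAutosomes:
    def test_membership(self):
        ds = build_dataset([[0, 1, 0, 1]] * 4, chromosomes=[1, 30, 29, 0])
        out, n = ss.filter_autosomes(ds)
        assert out.snps["chromosome"].tolist() == [1, 29]
        assert n == 2

    def test_identity_on_autosomal(self, tiny_dataset):
        out, n = ss.filter_autosomes(tiny_dataset)
        assert n == 0
        assert out.equals(tiny_dataset)

    def test_count_by_enumeration(self):
        rng = np.random.default_rng(0)
        chroms = rng.choice([*range(1, 30), 0, 90, 91], size=100,
                            p=[*([0.93 / 29] * 29), 0.03, 0.02, 0.02]).tolist()
        ds = build_dataset([[0, 1, 2, 1]] * 100, chromosomes=chroms,
                           positions=list(range(1000, 101000, 1000)))
        _, n = ss.filter_autosomes(ds)
        assert n == sum(1 for c in chroms if not 1 <= c <= 29)


class TestQcFilter:
    def test_monomorphic_in_both_removed(self):
        ds = build_dataset([[0, 0, 0, 0], [0, 1, 1, 2]], pop_sizes=(2, 2))
        out, rep = ss.qc_filter(ds, min_maf=0.0)
        assert out.snps["snp_id"].tolist() == ["rs2"]
        assert rep.n_removed_monomorphic_both == 1

    def test_monomorphic_in_one_breed_retained(self):
        """Fixed in one breed but segregating in the other: kept."""
        ds = build_dataset([[0, 0, 1, 2]], pop_sizes=(2, 2))
        out, rep = ss.qc_filter(ds, min_maf=0.0)
        assert rep.n_removed_monomorphic_both == 0
        assert out.n_snps == 1

    def test_all_homozygous_opposite_is_polymorphic(self):
        ds = build_dataset([[0, 2, 0, 2]], pop_sizes=(2, 2))
        _, rep = ss.qc_filter(ds, min_maf=0.0)
        assert rep.n_removed_monomorphic_both == 0

    def test_missingness_and_maf_thresholds(self):
        """200 samples: 6/200 = 3% missing is removed; pooled MAF 0.008 is removed."""
        n = 200
        ok = [1] * 20 + [0] * (n - 20)                      # MAF 0.05
        missing6 = [MISSING] * 6 + [1] * 20 + [0] * (n - 26)  # 3% missing
        rare = [1] * 3 + [0] * (n - 3)                      # MAF 3/400 = 0.0075
        cols = [ok, missing6, rare]
        ds = build_dataset(cols, pop_sizes=(100, 100))
        out, rep = ss.qc_filter(ds)
        assert rep.n_removed_missingness == 1
        assert rep.n_removed_maf == 1
        assert rep.n_retained == 1
        assert rep.reconciles()
        assert out.snps["snp_id"].tolist() == ["rs1"]

    def test_first_filter_attribution(self):
        """A SNP hit by several filters is counted once, in the first one."""
        n = 40
        both = [MISSING] * 4 + [0] * (n - 4)  # monomorphic in both AND 10% missing
        ds = build_dataset([both, [0, 1] * (n // 2)], pop_sizes=(20, 20))
        _, rep = ss.qc_filter(ds, min_maf=0.0)
        assert rep.n_removed_monomorphic_both == 1
        assert rep.n_removed_missingness == 0

    def test_idempotent(self, small_sim):
        ds, _ = small_sim
        once, rep1 = ss.qc_filter(ds)
        twice, rep2 = ss.qc_filter(once)
        assert rep2.n_retained == rep1.n_retained
        assert (rep2.n_removed_monomorphic_both + rep2.n_removed_missingness
                + rep2.n_removed_maf) == 0

    def test_counts_match_brute_force(self, small_sim):
        ds, _ = small_sim
        _, rep = ss.qc_filter(ds)
        n_mono = n_miss = n_maf = 0
        for j in range(ds.n_snps):
            col = ds.dosages[:, j]
            mono_both = True
            for lab in ds.population_labels:
                sub = col[ds.samples_of(lab)]
                sub = sub[sub != MISSING]
                if len(sub) and not (all(sub == 0) or all(sub == 2)):
                    mono_both = False
            if mono_both:
                n_mono += 1
                continue
            if (col == MISSING).mean() > 0.025:
                n_miss += 1
                continue
            nm = col[col != MISSING]
            f = nm.sum() / (2 * len(nm))
            if min(f, 1 - f) < 0.01:
                n_maf += 1
        assert (rep.n_removed_monomorphic_both, rep.n_removed_missingness,
                rep.n_removed_maf) == (n_mono, n_miss, n_maf)


class TestImputation:
    def test_modal_allele_a(self):
        ds = build_dataset([[0, 0, 1, MISSING, 0, 1]], pop_sizes=(4, 2))
        out, n = ss.impute_missing(ds)
        assert n == 1
        assert out.dosages[3, 0] == 0

    def test_modal_allele_b(self):
        ds = build_dataset([[2, 2, 1, MISSING, 0, 1]], pop_sizes=(4, 2))
        out, _ = ss.impute_missing(ds)
        assert out.dosages[3, 0] == 2

    def test_exact_tie_breaks_to_allele_a(self):
        # popA non-missing dosages [0, 2, 1, 1]: f_b = 4/8 = 0.5 exactly
        ds = build_dataset([[0, 2, 1, 1, MISSING, 0, 1]], pop_sizes=(5, 2))
        out, _ = ss.impute_missing(ds)
        assert out.dosages[4, 0] == 0

    def test_per_population_mode(self):
        """Each breed fills from its own modal allele."""
        ds = build_dataset([[0, 0, MISSING, 2, 2, MISSING]], pop_sizes=(3, 3))
        out, n = ss.impute_missing(ds)
        assert n == 2
        assert out.dosages[2, 0] == 0
        assert out.dosages[5, 0] == 2

    def test_fully_missing_locus_errors(self):
        ds = build_dataset([[MISSING, MISSING, 0, 1]], pop_sizes=(2, 2))
        with pytest.raises(ss.DataError, match="popA"):
            ss.impute_missing(ds)

    def test_no_missing_left_and_mode_stable(self, small_sim):
        ds, _ = small_sim
        out, _ = ss.impute_missing(ds)
        assert not (out.dosages == MISSING).any()
        # imputation cannot flip the within-population modal allele
        for lab in ds.population_labels:
            m = ds.samples_of(lab)
            f_before = allele_b_frequency(ds.dosages[m])
            f_after = allele_b_frequency(out.dosages[m])
            before_mode = f_before > 0.5
            after_mode = f_after > 0.5
            ok = np.isnan(f_before) | (before_mode == after_mode)
            assert ok.all()


class TestHeterozygosity:
    def test_all_heterozygous(self):
        ds = build_dataset([[1, 1, 1, 1]], pop_sizes=(2, 2))
        het = ss.heterozygosity_summary(ds)
        assert (het["h_obs"] == 1.0).all()

    def test_hand_enumeration(self):
        ds = build_dataset([[0, 1, 1, 2, 0, 0, 0, 0]], pop_sizes=(4, 4))
        het = ss.heterozygosity_summary(ds)
        row = het[(het["population"] == "popA") & (het["chromosome"] == 1)].iloc[0]
        assert row["h_obs"] == 0.5
        assert row["h_exp"] == 0.5  # f = 0.5 -> 2f(1-f) = 0.5

    def test_identical_populations_identical_summaries(self):
        ds = build_dataset([[0, 1, 2, 0, 1, 2], [1, 1, 0, 1, 1, 0]],
                           pop_sizes=(3, 3))
        het = ss.heterozygosity_summary(ds)
        a = het[het["population"] == "popA"].drop(columns="population")
        b = het[het["population"] == "popB"].drop(columns="population")
        assert np.allclose(a.to_numpy(float), b.to_numpy(float), equal_nan=True)

    def test_missing_excluded_from_denominator(self):
        ds = build_dataset([[1, MISSING, 0, 0]], pop_sizes=(2, 2))
        het = ss.heterozygosity_summary(ds)
        row = het[(het["population"] == "popA") & (het["chromosome"] == 0)].iloc[0]
        assert row["h_obs"] == 1.0  # 1 het out of 1 non-missing call


def test_run_qc_report_reconciles(small_sim):
    ds, _ = small_sim
    out, rep = ss.run_qc(ds)
    assert rep.reconciles()
    assert rep.n_retained == out.n_snps
    assert not (out.dosages == MISSING).any()
    assert rep.n_imputed_cells > 0
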