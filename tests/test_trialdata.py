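"""Trial-network data model: SNP QC, imputation, connectivity, folds, IO."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gxesim.trialdata import (
    FoldAssignment,
    GenotypeMatrix,
    TrialDataset,
    assign_folds,
    connectivity_index,
    impute_and_standardize,
    qc_filter_snps,
    read_genotypes_csv,
    read_genotypes_vcf,
    read_phenotypes_csv,
)


def _gm(columns: dict) -> GenotypeMatrix:
    return GenotypeMatrix(pd.DataFrame(columns, dtype=float))


class TestQC:
    def test_low_maf_snp_removed(self):
        # 40 lines, 2 carry one alt allele -> freq 0.025 < 0.05
        rare = [1.0] * 2 + [0.0] * 38
        common = [0.0, 2.0] * 20
        gm = _gm({"rare": rare, "common": common})
        kept = qc_filter_snps(gm)
        assert list(kept.dosages.columns) == ["common"]
        assert not kept.qc_report.loc["rare", "pass_maf"]

    def test_monomorphic_snp_removed(self):
        gm = _gm({"mono": [2.0] * 10, "ok": [0.0, 2.0] * 5})
        kept = qc_filter_snps(gm)
        assert "mono" not in kept.dosages.columns

    def test_call_rate_filter_hand_counted(self):
        base = {f"s{i}": [0.0, 2.0, 2.0, 0.0, 2.0, 0.0, 2.0, 0.0, 0.0, 2.0] for i in range(4)}
        half_missing = [np.nan] * 5 + [0.0, 2.0, 0.0, 2.0, 0.0]
        gm = _gm({**base, "cr50": half_missing})
        kept = qc_filter_snps(gm)
        assert kept.n_snps == 4
        assert "cr50" not in kept.dosages.columns

    def test_heterozygosity_filter(self):
        het = [1.0] * 5 + [0.0, 2.0] * 8  # 5/21 het > 10%
        ok = [0.0, 2.0] * 10 + [1.0]
        gm = _gm({"het": het, "ok": ok})
        kept = qc_filter_snps(gm)
        assert list(kept.dosages.columns) == ["ok"]

    def test_all_filtered_names_binding_filter(self):
        gm = _gm({"a": [2.0] * 8, "b": [0.0] * 8})
        with pytest.raises(ValueError, match="maf"):
            qc_filter_snps(gm)

    def test_invalid_dosage_rejected(self):
        with pytest.raises(ValueError):
            _gm({"a": [0.0, 3.0]})


class TestImputation:
    def test_missing_imputed_to_twice_frequency(self):
        # freq 0.25 -> imputed value 0.5
        col = [0.0, 0.0, 1.0, 1.0, np.nan]
        other = [0.0, 2.0, 0.0, 2.0, 0.0]
        gm = _gm({"x": col, "y": other})
        out = impute_and_standardize(gm)
        freq = np.nanmean(col) / 2
        assert freq == 0.25
        filled = gm.dosages["x"].fillna(2 * freq)
        np.testing.assert_allclose(
            out.X["x"], (filled - filled.mean()) / filled.std(ddof=1)
        )

    def test_columns_standardized(self, tiny_network):
        X = tiny_network.genotypes.X
        np.testing.assert_allclose(X.mean(), 0, atol=1e-8)
        np.testing.assert_allclose(X.std(ddof=1), 1, atol=1e-8)
        assert not X.isna().any().any()

    def test_zero_variance_after_imputation_errors(self):
        gm = _gm({"dead": [2.0, np.nan, 2.0, 2.0], "ok": [0.0, 2.0, 0.0, 2.0]})
        with pytest.raises(ValueError, match="zero-variance"):
            impute_and_standardize(gm)


def _dataset(rows):
    df = pd.DataFrame(rows, columns=["year", "location", "cultivar"])
    df["yield"] = 9.0
    return TrialDataset(df)


class TestConnectivity:
    def test_hand_example(self):
        rows = (
            [(2000, "A", c) for c in ("c1", "c2", "c3")]
            + [(2000, "B", c) for c in ("c1", "c2")]
            + [(2000, "C", c) for c in ("c3",)]
        )
        d = _dataset(rows)
        counts, mean = connectivity_index(d, r=2)
        assert counts[(2000, "A")] == 1  # shares {c1,c2} with B only
        assert counts[(2000, "B")] == 1
        assert counts[(2000, "C")] == 0
        assert mean == pytest.approx(2 / 3)

    def test_common_check_connects_everything_at_r1(self, tiny_network):
        counts, _ = connectivity_index(tiny_network.dataset, r=1)
        n_trials = len(tiny_network.dataset.trial_ids)
        assert (counts == n_trials - 1).all()  # C000 is in every trial

    def test_mean_nonincreasing_in_r(self, tiny_network):
        means = [connectivity_index(tiny_network.dataset, r)[1] for r in range(1, 6)]
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_huge_r_gives_zero_counts(self, tiny_network):
        counts, mean = connectivity_index(tiny_network.dataset, r=10**6)
        assert (counts == 0).all() and mean == 0

    def test_agrees_with_bruteforce_oracle(self, tiny_network):
        d = tiny_network.dataset
        rosters = d.trial_rosters()
        keys = list(rosters)
        for r in (1, 2, 4):
            counts, _ = connectivity_index(d, r)
            for k in keys:
                brute = sum(
                    1 for other in keys if other != k and len(rosters[k] & rosters[other]) >= r
                )
                assert counts[k] == brute


class TestFolds:
    def test_752_trials_k10_sizes(self):
        rows = []
        t = 0
        for y in range(16):
            for l in range(47):
                rows += [(2000 + y, f"L{l}", f"c{i}") for i in range(1)]
                t += 1
                if t == 752:
                    break
            if t == 752:
                break
        d = _dataset(rows)
        fa = assign_folds(d, "by-trial", k=10, seed=0)
        sizes = sorted(fa.fold_sizes())
        assert sizes == [75] * 8 + [76] * 2

    def test_singleton_folds(self, tiny_network):
        units = tiny_network.dataset.trial_ids
        fa = assign_folds(tiny_network.dataset, "by-trial", k=len(units), seed=1)
        assert sorted(fa.fold_sizes()) == [1] * len(units)

    def test_deterministic_under_seed(self, tiny_network):
        a = assign_folds(tiny_network.dataset, "by-cultivar", k=5, seed=3)
        b = assign_folds(tiny_network.dataset, "by-cultivar", k=5, seed=3)
        assert a.assignment == b.assignment

    def test_k_too_large_errors(self, tiny_network):
        with pytest.raises(ValueError):
            assign_folds(tiny_network.dataset, "by-cultivar", k=10**4, seed=0)

    @given(seed=st.integers(0, 10**6), k=st.integers(2, 7))
    @settings(max_examples=25, deadline=None)
    def test_partition_property(self, seed, k):
        rows = [(2000 + y, f"L{l}", "chk") for y in range(4) for l in range(5)]
        d = _dataset(rows)
        fa = assign_folds(d, "by-trial", k=k, seed=seed)
        units = [u for f in range(k) for u in fa.units_in_fold(f)]
        assert sorted(units) == sorted(d.trial_ids)  # each unit exactly once


class TestIO:
    def test_phenotype_csv_roundtrip(self, tmp_path, tiny_network):
        path = tmp_path / "phen.csv"
        tiny_network.dataset.to_csv(path)
        back = read_phenotypes_csv(path)
        pd.testing.assert_frame_equal(back.records, tiny_network.dataset.records)

    def test_duplicate_record_rejected(self):
        df = pd.DataFrame(
            {"year": [2000, 2000], "location": ["A", "A"], "cultivar": ["c", "c"], "yield": [9, 8]}
        )
        with pytest.raises(ValueError, match="un-replicated"):
            TrialDataset(df)

    def test_genotype_csv_roundtrip(self, tmp_path, tiny_network):
        path = tmp_path / "geno.csv"
        tiny_network.genotypes.dosages.to_csv(path)
        back = read_genotypes_csv(path)
        pd.testing.assert_frame_equal(back.dosages, tiny_network.genotypes.dosages)

    def test_vcf_dosages(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
            "1\t100\tsnpA\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\tsnpB\tC\tT\t.\tPASS\t.\tGT\t./.\t0/0\t0/1\n"
        )
        gm = read_genotypes_vcf(vcf)
        assert gm.cultivars == ["S1", "S2", "S3"]
        np.testing.assert_array_equal(gm.dosages["snpA"], [0.0, 1.0, 2.0])
        assert np.isnan(gm.dosages["snpB"].iloc[0])
        np.testing.assert_array_equal(gm.dosages["snpB"].iloc[1:], [0.0, 1.0])

    def test_multiallelic_vcf_rejected(self, tmp_path):
        vcf = tmp_path / "bad.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\tsnpA\tA\tG,T\t.\tPASS\t.\tGT\t0/1\n"
        )
        with pytest.raises(ValueError, match="multi-allelic"):
            read_genotypes_vcf(vcf)

    def test_fold_csv(self, tmp_path, tiny_network):
        fa = assign_folds(tiny_network.dataset, "by-trial", k=4, seed=0)
        path = tmp_path / "folds.csv"
        fa.to_csv(path)
        df = pd.read_csv(path)
        assert set(df.columns) == {"unit", "fold"}
        assert len(df) == len(tiny_network.dataset.trial_ids)
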