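"""QC and per-marker diversity statistics, with an exact-arithmetic
enumeration oracle for the Hardy-Weinberg exact test."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldscape import (
    GenotypeMatrix,
    bonferroni_alpha,
    call_rate_filter,
    conversion_report,
    detect_duplicates,
    diversity_table,
    he_by_lg_comparison,
    hwe_chi2_test,
    hwe_exact_test,
)
from ldscape.io import MISSING, LinkageMap


def hwe_enumeration_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Brute-force exact HWE p-value with rational arithmetic.

    Conditional on allele counts, P(n_ab) = n! / (n_aa! n_ab! n_bb!)
    * 2^n_ab * n_a! n_b! / (2n)!; the p-value sums probabilities of all
    heterozygote counts no more probable than the observed.
    """
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n - n_a

    def prob(h: int) -> Fraction:
        aa = (n_a - h) // 2
        bb = n - aa - h
        num = Fraction(
            comb(n, aa) * comb(n - aa, h) * 2**h
        )
        den = Fraction(comb(2 * n, n_a))
        return num / den

    hets = range(n_a % 2, min(n_a, n_b) + 1, 2)
    probs = {h: prob(h) for h in hets}
    obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= obs))


class TestHWEExact:
    def test_perfect_hwe_chi2_zero(self):
        assert hwe_chi2_test(25, 50, 25) == pytest.approx(1.0)
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    def test_no_heterozygotes_matches_oracle(self):
        assert hwe_exact_test(50, 0, 50) == pytest.approx(
            hwe_enumeration_oracle(50, 0, 50), rel=1e-9
        )
        assert hwe_exact_test(50, 0, 50) < 1e-20

    def test_equal_counts_matches_oracle(self):
        assert hwe_exact_test(10, 10, 10) == pytest.approx(
            hwe_enumeration_oracle(10, 10, 10), rel=1e-9
        )

    def test_all_tables_up_to_n20_match_oracle(self):
        """Exhaustive check against the rational-arithmetic oracle."""
        for n in range(1, 21):
            for n_aa in range(n + 1):
                for n_ab in range(n - n_aa + 1):
                    n_bb = n - n_aa - n_ab
                    got = hwe_exact_test(n_aa, n_ab, n_bb)
                    want = hwe_enumeration_oracle(n_aa, n_ab, n_bb)
                    assert got == pytest.approx(want, rel=1e-8, abs=1e-12), (
                        n_aa, n_ab, n_bb,
                    )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)

    def test_calibration_under_hwe(self, sim_dataset):
        """Under simulated HWE genotypes the rejection rate at nominal 5% is
        at most ~5% (discreteness makes the exact test conservative)."""
        _, gm = sim_dataset
        div = diversity_table(gm)
        rate = (div["hwe_p"] < 0.05).mean()
        assert rate < 0.08
        assert rate >= 0.0


class TestDiversityTable:
    def test_hand_counted_example(self):
        gm = GenotypeMatrix(["m"], ["a", "b", "c", "d"], np.array([[0, 0, 1, 2]]))
        row = diversity_table(gm).iloc[0]
        assert row["p"] == pytest.approx(5 / 8)
        assert row["maf"] == pytest.approx(0.375)
        assert row["ho"] == pytest.approx(0.25)
        assert row["he"] == pytest.approx(0.46875)

    def test_p_half_gives_max_he(self):
        gm = GenotypeMatrix(["m"], ["a", "b"], np.array([[0, 2]]))
        assert diversity_table(gm).iloc[0]["he"] == pytest.approx(0.5)

    def test_monomorphic_boundary(self):
        gm = GenotypeMatrix(["m"], ["a", "b", "c"], np.array([[0, 0, 0]]))
        row = diversity_table(gm).iloc[0]
        assert row["maf"] == 0.0
        assert row["he"] == 0.0
        assert row["hwe_p"] == 1.0

    def test_zero_call_marker_warns_nan(self):
        gm = GenotypeMatrix(
            ["m1", "m2"], ["a", "b"], np.array([[MISSING, MISSING], [0, 1]])
        )
        with pytest.warns(UserWarning, match="zero calls"):
            div = diversity_table(gm)
        assert np.isnan(div.iloc[0]["he"])
        assert not np.isnan(div.iloc[1]["he"])

    @given(st.lists(st.integers(min_value=-1, max_value=2), min_size=2, max_size=40))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_bounds_he_maf(self, dosages):
        if all(d == -1 for d in dosages):
            return
        gm = GenotypeMatrix(
            ["m"], [f"s{i}" for i in range(len(dosages))],
            np.array([dosages], dtype=np.int8),
        )
        row = diversity_table(gm).iloc[0]
        assert row["maf"] <= 0.5 + 1e-12
        assert row["he"] <= 0.5 + 1e-12


class TestQC:
    def test_call_rate_definition(self):
        d = np.zeros((10, 1), dtype=np.int8)
        d[0, 0] = MISSING
        gm = GenotypeMatrix([f"m{i}" for i in range(10)], ["s"], d)
        qc, _ = call_rate_filter(gm, 0.0)
        assert qc.call_rates["s"] == pytest.approx(0.9)

    def test_min_rate_zero_removes_nothing(self, sim_dataset):
        _, gm = sim_dataset
        qc, filtered = call_rate_filter(gm, 0.0)
        assert qc.flagged_samples == []
        assert filtered.n_samples == gm.n_samples

    def test_half_missing_sample_flagged(self, sim_dataset):
        _, gm = sim_dataset
        d = gm.dosage.copy()
        d[::2, 0] = MISSING  # 50% missing in the first sample
        gm2 = GenotypeMatrix(gm.markers, gm.samples, d)
        qc, filtered = call_rate_filter(gm2, 0.8)
        assert qc.flagged_samples == [gm.samples[0]]
        assert filtered.n_samples == gm.n_samples - 1

    def test_independent_samples_no_duplicates(self, sim_dataset):
        _, gm = sim_dataset
        assert detect_duplicates(gm, identity_threshold=0.995) == []

    def test_zero_shared_pair_excluded_with_warning(self):
        d = np.array([[0, MISSING], [MISSING, 1]], dtype=np.int8)
        gm = GenotypeMatrix(["m1", "m2"], ["a", "b"], d)
        with pytest.warns(UserWarning, match="no non-missing"):
            pairs = detect_duplicates(gm, min_shared=1)
        assert pairs == []


class TestBonferroni:
    def test_printed_correction(self):
        # 5% over 2,474 independent tests -> experiment-wise 0.002%
        assert bonferroni_alpha(0.05, 2474) == pytest.approx(2.021e-5, rel=1e-3)

    def test_single_test_identity(self):
        assert bonferroni_alpha(0.05, 1) == 0.05

    def test_large_family(self):
        assert bonferroni_alpha(0.05, 159_814) == pytest.approx(3.129e-7, rel=1e-3)


class TestConversionReport:
    @staticmethod
    def manifest(counts: dict[tuple[str, str], int]) -> pd.DataFrame:
        rows = []
        for (cls, out), k in counts.items():
            rows += [{"marker_id": f"{cls}{out}{i}", "class": cls, "outcome": out}
                     for i in range(k)]
        return pd.DataFrame(rows)

    def test_rates_from_assay_counts(self):
        rep = conversion_report(self.manifest({
            ("snp", "polymorphic"): 2532, ("snp", "failed"): 2605,
            ("snp", "monomorphic"): 1170,
            ("indel", "polymorphic"): 68, ("indel", "failed"): 893,
            ("indel", "monomorphic"): 2011,
        }))
        assert rep.counts.to_numpy().sum() == 9279
        assert rep.overall_rate_pct == pytest.approx(28.0, abs=0.1)
        assert rep.rates_pct["indel"] == pytest.approx(2.3, abs=0.05)
        assert rep.rates_pct["snp"] == pytest.approx(40.2, abs=0.1)

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            conversion_report(pd.DataFrame(columns=["marker_id", "class", "outcome"]))

    def test_unknown_outcome_rejected(self):
        bad = pd.DataFrame(
            [{"marker_id": "x", "class": "snp", "outcome": "exploded"}]
        )
        with pytest.raises(ValueError, match="outcome"):
            conversion_report(bad)


class TestHeByLG:
    @staticmethod
    def _map(n_per_lg: int, n_lg: int) -> LinkageMap:
        return LinkageMap.from_entries(
            [(f"m{lg}_{i}", lg, float(i)) for lg in range(1, n_lg + 1)
             for i in range(n_per_lg)]
        )

    def test_identical_he_one_group(self):
        lmap = self._map(10, 3)
        div = pd.DataFrame({"marker_id": lmap.table["marker_id"], "he": 0.4})
        res = he_by_lg_comparison(div, lmap)
        assert res.anova_f == 0.0
        assert res.anova_p == 1.0
        assert len(set(res.letters.values())) == 1

    def test_shifted_means_two_groups(self):
        rng = np.random.default_rng(0)
        lmap = self._map(40, 2)
        he = np.concatenate([
            rng.normal(0.30, 0.01, 40),  # LG1
            rng.normal(0.45, 0.01, 40),  # LG2: +15 SDs
        ])
        div = pd.DataFrame({"marker_id": lmap.table["marker_id"], "he": he})
        res = he_by_lg_comparison(div, lmap)
        assert res.anova_p < 1e-6
        assert res.letters[1] != res.letters[2]

    def test_letters_consistent_with_pairwise_significance(self):
        rng = np.random.default_rng(1)
        lmap = self._map(30, 4)
        means = {1: 0.30, 2: 0.31, 3: 0.45, 4: 0.46}
        he = np.concatenate([rng.normal(means[lg], 0.02, 30) for lg in range(1, 5)])
        div = pd.DataFrame({"marker_id": lmap.table["marker_id"], "he": he})
        res = he_by_lg_comparison(div, lmap)
        for _, row in res.tukey.iterrows():
            a, b = int(row["group1"]), int(row["group2"])
            share = set(res.letters[a]) & set(res.letters[b])
            if bool(row["reject"]):
                assert not share  # significantly different: no shared letter
            else:
                assert share  # not distinguishable: at least one shared letter

    def test_single_lg_rejected(self):
        lmap = self._map(10, 1)
        div = pd.DataFrame({"marker_id": lmap.table["marker_id"], "he": 0.4})
        with pytest.raises(ValueError):
            he_by_lg_comparison(div, lmap)
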