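"""Rogers-Huff r2, LD scans, the long-distance null model with its audit
bookkeeping, inter-chromosomal testing and the Hill-Weir decay fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldscape import (
    GenotypeMatrix,
    SimulationConfig,
    fit_decay,
    hill_weir_expected_r2,
    interchrom_test,
    ld_scan,
    long_distance_null,
    rogers_huff_r2,
    simulate_decay_pairs,
    simulate_genotypes,
)
from ldscape.io import LinkageMap


class TestRogersHuff:
    def test_identical_vectors_give_one(self):
        assert rogers_huff_r2([0, 1, 2, 1, 0], [0, 1, 2, 1, 0]) == pytest.approx(1.0)

    def test_hand_pearson_example(self):
        # r = 2/sqrt(8) -> r2 = 0.5
        assert rogers_huff_r2([0, 1, 2, 1], [0, 2, 2, 0]) == pytest.approx(0.5)

    def test_monomorphic_undefined(self):
        assert np.isnan(rogers_huff_r2([1, 1, 1, 1], [0, 1, 2, 0]))

    def test_pairwise_complete_missing_handling(self):
        # missing (-1) cells drop that individual for the pair only
        a = [0, 1, 2, -1, 2]
        b = [0, 1, 2, 2, -1]
        want = rogers_huff_r2([0, 1, 2], [0, 1, 2])
        assert rogers_huff_r2(a, b) == pytest.approx(want)

    @given(
        st.lists(
            st.tuples(st.integers(0, 2), st.integers(0, 2)), min_size=4, max_size=30
        )
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_symmetry_and_allele_flip_invariance(self, pairs):
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        r_ab = rogers_huff_r2(a, b)
        if np.isnan(r_ab):
            return
        assert rogers_huff_r2(b, a) == pytest.approx(r_ab)
        assert rogers_huff_r2(2 - a, b) == pytest.approx(r_ab)
        assert rogers_huff_r2(a, 2 - b) == pytest.approx(r_ab)

    def test_converges_to_haplotype_truth(self):
        """On phased simulated data the dosage-correlation estimate approaches
        the haplotype-sample r2 as the sample grows."""
        lmap = LinkageMap.from_entries(
            [(f"m{i}", 1, float(p)) for i, p in enumerate(np.linspace(0, 60, 25))]
        )
        mae = {}
        for n in (50, 400):
            cfg = SimulationConfig(
                n_lg=1, n_individuals=n, n_founder_haplotypes=16,
                missing_rate=0.0, seed=21,
            )
            gm, h1, h2 = simulate_genotypes(
                lmap, cfg, np.random.default_rng(21), return_haplotypes=True
            )
            haps = np.hstack([h1, h2]).astype(float)  # markers x 2n gametes
            errs = []
            for i in range(gm.n_markers):
                for j in range(i + 1, gm.n_markers):
                    est = rogers_huff_r2(gm.dosage[i], gm.dosage[j])
                    if np.isnan(est):
                        continue
                    va, vb = haps[i].var(), haps[j].var()
                    if va == 0 or vb == 0:
                        continue
                    truth = np.corrcoef(haps[i], haps[j])[0, 1] ** 2
                    errs.append(abs(est - truth))
            mae[n] = np.mean(errs)
        assert mae[400] < mae[50]
        assert mae[400] < 0.05


def polymorphic_matrix(markers, samples=8, seed=0):
    rng = np.random.default_rng(seed)
    while True:
        d = rng.integers(0, 3, size=(len(markers), samples)).astype(np.int8)
        if (d.std(axis=1) > 0).all():
            return GenotypeMatrix(markers, [f"s{i}" for i in range(samples)], d)


class TestLDScan:
    def test_single_lg_pair_count(self):
        lmap = LinkageMap.from_entries([("a", 1, 0.0), ("b", 1, 2.0), ("c", 1, 7.0)])
        gm = polymorphic_matrix(["a", "b", "c"], seed=1)
        pairs = ld_scan(gm, lmap)
        assert len(pairs) == 3
        assert pairs["dist_cm"].notna().all()

    def test_two_lg_intra_inter_decomposition(self):
        lmap = LinkageMap.from_entries(
            [("a", 1, 0.0), ("b", 1, 4.0), ("c", 2, 0.0), ("d", 2, 4.0)]
        )
        gm = polymorphic_matrix(["a", "b", "c", "d"], seed=2)
        pairs = ld_scan(gm, lmap)
        intra = pairs[pairs["lg_a"] == pairs["lg_b"]]
        inter = pairs[pairs["lg_a"] != pairs["lg_b"]]
        assert len(pairs) == 6  # C(4,2)
        assert len(intra) == 2
        assert len(inter) == 4
        assert inter["dist_cm"].isna().all()

    def test_colocated_markers_at_zero_cm(self):
        lmap = LinkageMap.from_entries([("a", 1, 3.0), ("b", 1, 3.0)])
        gm = polymorphic_matrix(["a", "b"], seed=3)
        pairs = ld_scan(gm, lmap)
        assert pairs.iloc[0]["dist_cm"] == 0.0

    def test_maf_filter_boundary(self):
        lmap = LinkageMap.from_entries([("a", 1, 0.0), ("b", 1, 2.0)])
        gm = GenotypeMatrix(
            ["a", "b"], ["s1", "s2", "s3", "s4"],
            np.array([[0, 0, 0, 1], [0, 1, 0, 0]], dtype=np.int8),
        )
        assert len(ld_scan(gm, lmap, maf_min=0.5)) == 0

    def test_matches_rogers_huff_per_pair(self, sim_dataset):
        lmap, gm = sim_dataset
        sub_ids = lmap.table["marker_id"].tolist()[:30]
        pairs = ld_scan(gm.subset_markers(sub_ids), lmap.subset(sub_ids))
        idx = {m: i for i, m in enumerate(sub_ids)}
        sub = gm.subset_markers(sub_ids)
        for row in pairs.sample(40, random_state=0).itertuples():
            want = rogers_huff_r2(sub.dosage[idx[row.marker_a]], sub.dosage[idx[row.marker_b]])
            assert row.r2 == pytest.approx(want, rel=1e-9)


def audit_fixture():
    """380 candidate long-distance pairs engineered to reproduce the
    bookkeeping 380 = 238 same-map (102 at 0 cM + 66 near + 70 usable)
    + 142 cross-map, with 5 of the 70 usable pairs failing the MAF filter."""
    rows = []
    comp_a_entries, comp_b_entries = [], []
    comp_pos = 0.0

    def pair_row(a, b, maf_a=0.35, maf_b=0.35):
        return {
            "marker_a": a, "marker_b": b, "lg_a": 1, "lg_b": 1,
            "dist_cm": 10.0, "r2": 0.2, "maf_a": maf_a, "maf_b": maf_b,
            "n_shared": 100,
        }

    groups = [("z", 102, 0.0), ("n", 66, 0.5), ("u", 70, 5.0)]
    k = 0
    for tag, count, comp_dist in groups:
        for i in range(count):
            a, b = f"{tag}{i}_a", f"{tag}{i}_b"
            low_maf = tag == "u" and i < 5
            rows.append(pair_row(a, b, maf_a=0.15 if low_maf else 0.35))
            comp_a_entries.append((a, 1, comp_pos))
            comp_a_entries.append((b, 1, comp_pos + comp_dist))
            comp_pos += 10.0
            k += 1
    for i in range(142):  # cross-map: a only on A, b only on B
        a, b = f"x{i}_a", f"x{i}_b"
        rows.append(pair_row(a, b))
        comp_a_entries.append((a, 1, comp_pos))
        comp_b_entries.append((b, 1, float(i)))
        comp_pos += 10.0
    comp_a_entries.sort(key=lambda e: e[2])
    comp = {
        "A": LinkageMap.from_entries(comp_a_entries),
        "B": LinkageMap.from_entries(comp_b_entries),
    }
    return pd.DataFrame(rows), comp


class TestLongDistanceNull:
    def test_bookkeeping_audit(self):
        pairs, comp = audit_fixture()
        res = long_distance_null(pairs, comp)
        assert res.audit["input_above_r2_min"] == 380
        assert res.audit["same_component_map"] == 238
        assert res.audit["excluded_cross_map"] == 142
        assert res.audit["excluded_zero_cm"] == 102
        assert res.audit["excluded_near_cm"] == 66
        assert res.audit["retained_before_maf"] == 70  # 238 - 102 - 66
        assert res.audit["excluded_maf"] == 5
        assert res.audit["retained"] == 65
        assert len(res.values) == 65

    def test_audit_internally_consistent(self):
        pairs, comp = audit_fixture()
        a = long_distance_null(pairs, comp).audit
        assert (
            a["input_above_r2_min"]
            == a["retained"] + a["excluded_cross_map"] + a["excluded_zero_cm"]
            + a["excluded_near_cm"] + a["excluded_maf"]
        )

    def test_all_colocated_gives_empty_null(self):
        pairs, comp = audit_fixture()
        # move every same-map pair to 0 cM in the component map
        t = comp["A"].table.copy()
        t["position_cm"] = 0.0
        comp0 = {"A": LinkageMap(t), "B": comp["B"]}
        res = long_distance_null(pairs, comp0)
        assert len(res.values) == 0

    def test_without_component_maps_only_maf_filter(self):
        pairs, _ = audit_fixture()
        res = long_distance_null(pairs, None)
        assert res.audit["retained"] == 375  # 380 - 5 low-MAF


class TestInterchromTest:
    @staticmethod
    def inter_frame(r2s):
        return pd.DataFrame(
            {
                "marker_a": [f"a{i}" for i in range(len(r2s))],
                "marker_b": [f"b{i}" for i in range(len(r2s))],
                "lg_a": 1, "lg_b": 2, "r2": r2s,
            }
        )

    def test_no_exceedance_empty(self):
        null = np.linspace(0.1, 0.3, 50)
        res = interchrom_test(self.inter_frame([0.05, 0.1, 0.29]), null)
        assert len(res.significant) == 0

    def test_planted_pair_detected(self):
        null = np.linspace(0.1, 0.3, 50)
        res = interchrom_test(self.inter_frame([0.1, 0.99, 0.2]), null)
        assert res.significant["marker_a"].tolist() == ["a1"]

    def test_threshold_monotone_in_alpha(self):
        null = np.random.default_rng(0).uniform(0.1, 0.4, 200)
        frame = self.inter_frame([0.2] * 10)
        t_strict = interchrom_test(frame, null, alpha=0.01).threshold
        t_loose = interchrom_test(frame, null, alpha=0.10).threshold
        assert t_strict >= t_loose

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            interchrom_test(self.inter_frame([0.2]), np.array([]))


class TestHillWeir:
    def test_no_recombination_large_n_limit(self):
        assert hill_weir_expected_r2(0.0, 10**9) == pytest.approx(10 / 22, rel=1e-6)

    def test_hand_arithmetic_c2_n100(self):
        # (12/52) * (1 + 5*40/5200) = 81/338
        assert hill_weir_expected_r2(2.0, 100) == pytest.approx(81 / 338, rel=1e-12)

    def test_large_c_limit_is_sampling_floor(self):
        # population term vanishes as C grows; the sample-size adjustment
        # leaves the finite-sample floor of 1/n
        assert hill_weir_expected_r2(1e9, 10**9) < 1e-6
        assert hill_weir_expected_r2(1e9, 100) == pytest.approx(0.01, rel=1e-3)


class TestDecayFit:
    def test_noise_free_recovery_exact(self):
        d = np.linspace(1, 5000, 50)
        tbl = simulate_decay_pairs(0.005, 186, d, noise_sd=0.0)
        res = fit_decay(tbl["distance_bp"], tbl["r2"], 186)
        assert res.converged
        assert abs(res.c_per_bp - 0.005) < 1e-6

    def test_noisy_recovery_within_two_se(self):
        """Planted C recovered within +-2 SE in >= 90% of seeds.

        Noise is kept small enough (sd 0.03, distances <= 3000 bp at
        C = 0.005/bp) that [0,1] truncation of the generator's noise is
        negligible; heavy truncation distorts the error model and the
        nominal 2-SE coverage claim with it.
        """
        d = np.linspace(1, 3000, 200)
        hits = 0
        n_seeds = 50
        for s in range(n_seeds):
            tbl = simulate_decay_pairs(0.005, 186, d, noise_sd=0.03, seed=s)
            res = fit_decay(tbl["distance_bp"], tbl["r2"], 186)
            if abs(res.c_per_bp - 0.005) <= 2 * res.bse:
                hits += 1
        assert hits / n_seeds >= 0.90

    def test_flat_data_flagged(self):
        d = np.linspace(1, 5000, 50)
        res = fit_decay(d, np.full(50, 0.5), 186)
        assert res.negative or abs(res.c_per_bp) < 1e-8

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            fit_decay([1, 2, 3], [0.1, 0.2, 0.3], 100)

    def test_binned_means_track_curve_shape(self, sim_dataset):
        """Mean r2 against genetic distance decreases monotonically in broad
        bins on mechanistically simulated data."""
        lmap, gm = sim_dataset
        sub_ids = lmap.markers_on(1)
        pairs = ld_scan(gm.subset_markers(sub_ids), lmap.subset(sub_ids))
        pairs = pairs.dropna(subset=["dist_cm"])
        bins = [0, 5, 20, 60, 200]
        means = pairs.groupby(pd.cut(pairs["dist_cm"], bins), observed=True)["r2"].mean()
        vals = means.to_numpy()
        assert (np.diff(vals) < 0).all()
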