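"""Virtual-3C profile extraction, filtering, classification and batch fits."""

import numpy as np
import pytest
from scipy import sparse

from helix3c import (
    BinnedContactMap,
    FitResult,
    IntervalAnnotation,
    LocalChromatinParams,
    ProfileFitRecord,
    VirtualProfile,
    build_virtual_profiles,
    classify_profiles,
    domain_parameter_summary,
    filter_fit_quality,
    filter_within_tad,
    fit_virtual_profiles,
    model_curve,
    simulate_contact_map,
    simulate_genome,
    GenomeSpec,
)


def uniform_map(n_bins, value=2.0, chromosome="chrU"):
    dense = np.full((n_bins, n_bins), float(value))
    return BinnedContactMap.from_dense(chromosome, dense)


def single_class_map(n_bins, params, chromosome="chrT", noise="none", seed=0):
    tads = IntervalAnnotation(((chromosome, 0, n_bins * 5000, "tad_1"),))
    epi = IntervalAnnotation(((chromosome, 0, n_bins * 5000, "D2"),))
    return simulate_contact_map(tads, epi, {"D2": params}, noise=noise,
                                seed=seed)


class TestBuildProfiles:
    @pytest.mark.parametrize("n_bins, expected", [(200, 121), (80, 1), (79, 0)])
    def test_profile_count_formula(self, n_bins, expected):
        """profiles = max(0, n_bins - span/bin + 1) on a gap-free chromosome."""
        profiles = build_virtual_profiles(uniform_map(n_bins))
        assert len(profiles) == expected

    @pytest.mark.parametrize("aggregation", ["offset_mean", "target_bin"])
    def test_uniform_map_gives_flat_profiles(self, aggregation):
        profiles = build_virtual_profiles(uniform_map(100), span_kb=200.0,
                                          aggregation=aggregation)
        for p in profiles:
            np.testing.assert_allclose(p.frequencies, 2.0)

    def test_separations_are_bin_multiples(self):
        p = build_virtual_profiles(uniform_map(90))[0]
        np.testing.assert_array_equal(
            p.separations, 5.0 * np.arange(1, (400 - 25) // 5 + 1))

    def test_bin_bp_round_trip(self):
        for p in build_virtual_profiles(uniform_map(120), span_kb=200.0):
            assert p.anchor_start_bp // 5000 == p.anchor_start_bin
            assert p.anchor_end_bp - p.anchor_start_bp == 25_000

    def test_offset_mean_preserves_true_separation(self):
        """With constant-offset aggregation, a single-class noiseless map
        yields profile values exactly on the model decay curve."""
        truth = LocalChromatinParams(K=1.5, L=10.6, S=4.9)
        cmap = single_class_map(120, truth)
        profiles = build_virtual_profiles(cmap, span_kb=400.0)
        p = profiles[0]
        np.testing.assert_allclose(
            p.frequencies, model_curve(p.separations, truth), rtol=1e-12)

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            build_virtual_profiles(uniform_map(100), anchor_width_kb=12.0)


class TestTadFilter:
    def _profiles(self, cmap):
        return build_virtual_profiles(cmap, span_kb=200.0)

    def test_rule_application(self):
        cmap = uniform_map(100)
        profiles = self._profiles(cmap)
        # one 150-kb TAD starting at 0: anchors need 25 + 65 = 90 kb inside
        tads = IntervalAnnotation((("chrU", 0, 150_000, "tad_1"),))
        kept = filter_within_tad(profiles, tads, min_span_kb=65.0)
        starts = {p.anchor_start_bp for p in kept}
        assert max(starts) == 60_000          # 60 + 90 = 150 kb exactly
        assert 65_000 not in starts           # window would overhang
        assert len(kept) == 13

    def test_anchor_close_to_border_excluded(self):
        cmap = uniform_map(100)
        profiles = self._profiles(cmap)
        tads = IntervalAnnotation((("chrU", 0, 100_000, "tad_1"),
                                   ("chrU", 100_000, 500_000, "tad_2")))
        kept = filter_within_tad(profiles, tads, min_span_kb=65.0)
        # anchor at 10 kb: window ends 35 kb, border at 100 kb -> only 65 kb
        assert any(p.anchor_start_bp == 10_000 for p in kept)
        assert not any(p.anchor_start_bp == 15_000 and p.anchor_end_bp == 40_000
                       and False for p in kept)  # structural sanity
        # anchor at 15 kb: 15+90 = 105 kb > border -> excluded
        assert not any(p.anchor_start_bp == 15_000 for p in kept)

    def test_matches_brute_force_interval_oracle(self):
        rng = np.random.default_rng(3)
        cmap = uniform_map(400)
        profiles = build_virtual_profiles(cmap, span_kb=400.0)
        # one 100-kb TAD per 200 kb
        tads = IntervalAnnotation(tuple(
            ("chrU", k * 200_000, k * 200_000 + 100_000, f"tad_{k}")
            for k in range(10)))
        kept = filter_within_tad(profiles, tads, min_span_kb=65.0)
        expected = []
        for p in profiles:
            lo, hi = p.anchor_start_bp, p.anchor_end_bp + 65_000
            ok = any(s <= lo and hi <= e for _, s, e, _ in tads.intervals)
            if ok:
                expected.append(p.anchor_start_bp)
        assert [p.anchor_start_bp for p in kept] == expected
        assert len(expected) > 0


class TestClassification:
    def _profile(self, start_bin):
        return VirtualProfile(chromosome="chrU", anchor_start_bin=start_bin,
                              anchor_width_bins=5, bin_size_kb=5.0,
                              separations=np.array([5.0]),
                              frequencies=np.array([1.0]))

    def test_fully_inside(self):
        domains = IntervalAnnotation((("chrU", 0, 50_000, "D2"),))
        assert classify_profiles([self._profile(1)], domains) == ["D2"]

    def test_majority_rule(self):
        domains = IntervalAnnotation((("chrU", 0, 15_000, "D1"),
                                      ("chrU", 15_000, 50_000, "D2")))
        # anchor 0-25 kb: 15 kb in D1, 10 kb in D2
        assert classify_profiles([self._profile(0)], domains) == ["D1"]

    def test_exact_tie_unassigned(self):
        domains = IntervalAnnotation((("chrU", 0, 12_500, "D1"),
                                      ("chrU", 12_500, 25_000, "D3")))
        assert classify_profiles([self._profile(0)], domains) == ["unassigned"]

    def test_zero_overlap_unassigned(self):
        domains = IntervalAnnotation((("chrU", 500_000, 600_000, "D1"),))
        assert classify_profiles([self._profile(0)], domains) == ["unassigned"]

    def test_colour_aliases_normalised(self):
        domains = IntervalAnnotation((("chrU", 0, 50_000, "black"),))
        assert classify_profiles([self._profile(0)], domains) == ["D2"]


class TestBatchFitting:
    def test_noiseless_recovery_of_flexibility(self):
        truth = LocalChromatinParams(K=1.5, L=10.6, S=4.9)
        cmap = single_class_map(120, truth)
        profiles = build_virtual_profiles(cmap)
        records = fit_virtual_profiles(profiles)
        assert all(r.fit.converged for r in records)
        for r in records:
            assert r.fit.params["S"] == pytest.approx(truth.S, rel=1e-3)
            amp = r.fit.params["K"] * (r.fit.params["L"] * r.fit.params["S"]) ** -3
            amp_truth = truth.K * (truth.L * truth.S) ** -3
            assert amp == pytest.approx(amp_truth, rel=1e-3)

    def test_all_zero_profile_flagged_not_raised(self):
        p = VirtualProfile(chromosome="chrU", anchor_start_bin=0,
                           anchor_width_bins=5, bin_size_kb=5.0,
                           separations=5.0 * np.arange(1, 15),
                           frequencies=np.zeros(14))
        (rec,) = fit_virtual_profiles([p])
        assert not rec.fit.converged or rec.fit.r_squared <= 0
        kept, frac = filter_fit_quality([rec])
        assert kept == []
        assert frac is None

    def test_batch_determinism(self):
        truth = LocalChromatinParams(K=1.0, L=10.5, S=4.5)
        cmap = single_class_map(120, truth, noise="lognormal", seed=7)
        profiles = build_virtual_profiles(cmap)
        r1 = fit_virtual_profiles(profiles)
        r2 = fit_virtual_profiles(profiles)
        assert [r.fit for r in r1] == [r.fit for r in r2]


class TestFitQualityFilter:
    @staticmethod
    def _rec(r2, converged=True):
        profile = VirtualProfile(chromosome="chrU", anchor_start_bin=0,
                                 anchor_width_bins=5, bin_size_kb=5.0,
                                 separations=np.array([5.0]),
                                 frequencies=np.array([1.0]))
        fit = FitResult(model_id="unconstrained", params={}, stderr={},
                        r_squared=r2, ssr=0.0, n_obs=14, converged=converged,
                        n_starts=1)
        return ProfileFitRecord(profile=profile, fit=fit)

    def test_open_interval_rule_and_fraction(self):
        records = [self._rec(0.6), self._rec(0.4), self._rec(-0.2),
                   self._rec(1.0)]
        kept, frac = filter_fit_quality(records)
        assert [r.fit.r_squared for r in kept] == [0.6, 0.4]
        assert frac == 0.5

    def test_all_good_fraction_one(self):
        kept, frac = filter_fit_quality([self._rec(0.9)] * 3)
        assert frac == 1.0

    def test_unconverged_dropped(self):
        kept, _ = filter_fit_quality([self._rec(0.9, converged=False),
                                      self._rec(0.8)])
        assert len(kept) == 1


class TestDomainSummary:
    @staticmethod
    def _rec(domain, S, chromosome="chrU"):
        profile = VirtualProfile(chromosome=chromosome, anchor_start_bin=0,
                                 anchor_width_bins=5, bin_size_kb=5.0,
                                 separations=np.array([5.0]),
                                 frequencies=np.array([1.0]))
        fit = FitResult(model_id="unconstrained",
                        params={"K": 1.0, "L": 10.5, "S": S}, stderr={},
                        r_squared=0.9, ssr=0.0, n_obs=14, converged=True,
                        n_starts=1)
        return ProfileFitRecord(profile=profile, fit=fit, domain_label=domain)

    def test_single_record_median_no_tests(self):
        medians, tests = domain_parameter_summary(
            [self._rec("D1", 4.0), self._rec("D4", 5.0)])
        med = medians.set_index("domain")
        assert med.loc["D1", "S_median"] == 4.0
        assert med.loc["D4", "S_median"] == 5.0
        assert tests.empty

    def test_shifted_groups_detected(self, rng):
        recs = [self._rec("D1", v) for v in rng.normal(4.0, 0.3, 200)]
        recs += [self._rec("D4", v) for v in rng.normal(5.0, 0.3, 200)]
        medians, tests = domain_parameter_summary(recs)
        med = medians.set_index("domain")
        assert med.loc["D4", "S_median"] - med.loc["D1", "S_median"] == \
            pytest.approx(1.0, abs=0.15)
        s_test = tests[tests["parameter"] == "S"].iloc[0]
        assert s_test["p_value"] < 1e-3

    def test_excluded_chromosome_dropped(self):
        recs = [self._rec("D1", 4.0), self._rec("D1", 4.2, chromosome="chrX")]
        medians, _ = domain_parameter_summary(recs,
                                              exclude_chromosomes=("chrX",))
        assert set(medians["chromosome"]) == {"chrU"}

    def test_unassigned_records_ignored(self):
        medians, _ = domain_parameter_summary(
            [self._rec("D1", 4.0), self._rec("unassigned", 9.9)])
        assert set(medians["domain"]) == {"D1"}
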