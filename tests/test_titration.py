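import math

import pytest

from nmrdomains.io import Peak, PeakList
from nmrdomains.synthetic import BindingModel, gen_titration
from nmrdomains.titration import (
    CSPEntry,
    CSPProfile,
    assess_fold,
    compare_variant_binding,
    compute_csp,
    match_peaks,
    match_peaks_nearest,
    significance,
    trajectory_similarity,
)


def profile_from_vectors(vectors, first=1):
    """CSPProfile from (d_h, d_n) per consecutive residue."""
    entries = [
        CSPEntry(first + i, dh, dn, math.sqrt((dn / 5) ** 2 + dh**2))
        for i, (dh, dn) in enumerate(vectors)
    ]
    return CSPProfile(entries)


class TestMatchPeaks:
    def test_identical_lists_fully_paired(self, dispersed_peaks):
        res = match_peaks(dispersed_peaks, dispersed_peaks)
        assert len(res.pairs) == len(dispersed_peaks)
        assert res.jumps == [] and res.only_a == [] and res.only_b == []

    def test_large_move_flagged_as_jump(self, make_peaklist):
        a = make_peaklist([(1, "A", 8.0, 120.0), (2, "A", 8.5, 115.0)])
        b = make_peaklist([(1, "A", 8.3, 120.0), (2, "A", 8.5, 115.0)])
        res = match_peaks(a, b, tol=0.15)
        assert res.jumps == [1]
        assert 1 in res.pairs  # jump is reported but still paired

    def test_disjoint_sets_unmatched(self, make_peaklist):
        a = make_peaklist([(1, "A", 8.0, 120.0)])
        b = make_peaklist([(2, "A", 8.0, 120.0)])
        res = match_peaks(a, b)
        assert res.pairs == {} and res.only_a == [1] and res.only_b == [2]

    def test_nonpositive_tolerance_rejected(self, dispersed_peaks):
        with pytest.raises(ValueError):
            match_peaks(dispersed_peaks, dispersed_peaks, tol=0.0)

    def test_nearest_neighbour_mode_pairs_within_tol(self, make_peaklist):
        a = make_peaklist([(1, "A", 8.00, 120.0), (2, "A", 9.00, 130.0)])
        b = make_peaklist([(11, "A", 8.02, 120.1), (12, "A", 7.00, 110.0)])
        res = match_peaks_nearest(a, b, tol=0.15)
        assert list(res.pairs) == [1]
        assert res.pairs[1][1].residue_number == 11
        assert res.only_a == [2] and res.only_b == [12]


class TestComputeCsp:
    def test_no_shift_gives_zero(self, make_peaklist):
        a = make_peaklist([(1, "A", 8.0, 120.0)])
        profile = compute_csp(a, a)
        assert profile.entries[0].csp == 0.0

    def test_hand_worked_equation(self, make_peaklist):
        apo = make_peaklist([(1, "A", 8.0, 120.0)])
        bound = make_peaklist([(1, "A", 8.10, 120.50)])
        csp = compute_csp(apo, bound).entries[0].csp
        assert csp == pytest.approx(0.1414, abs=5e-5)

    def test_nitrogen_scaling_alone(self, make_peaklist):
        apo = make_peaklist([(1, "A", 8.0, 120.0)])
        bound = make_peaklist([(1, "A", 8.0, 121.0)])
        assert compute_csp(apo, bound).entries[0].csp == pytest.approx(0.20)

    def test_global_referencing_offset_invariance(self, make_peaklist):
        apo = make_peaklist([(i, "A", 8.0 + 0.01 * i, 120.0 + i) for i in range(1, 6)])
        bound = make_peaklist([(i, "A", 8.1 + 0.01 * i, 120.5 + i) for i in range(1, 6)])
        off_h, off_n = 0.13, -0.8
        apo2 = PeakList(
            [Peak(p.residue_number, p.residue_type, p.h_ppm + off_h, p.n_ppm + off_n)
             for p in apo.peaks]
        )
        bound2 = PeakList(
            [Peak(p.residue_number, p.residue_type, p.h_ppm + off_h, p.n_ppm + off_n)
             for p in bound.peaks]
        )
        p1, p2 = compute_csp(apo, bound), compute_csp(apo2, bound2)
        for e1, e2 in zip(p1.entries, p2.entries):
            assert e1.csp == pytest.approx(e2.csp, rel=1e-12)

    def test_no_shared_residues_rejected(self, make_peaklist):
        a = make_peaklist([(1, "A", 8.0, 120.0)])
        b = make_peaklist([(2, "A", 8.0, 120.0)])
        with pytest.raises(ValueError):
            compute_csp(a, b)


class TestSignificance:
    def test_hand_worked_mean_plus_two_sd(self):
        vectors = [(0.10, 0.0)] * 9 + [(0.60, 0.0)]
        result = significance(profile_from_vectors(vectors), "mean_plus_two_sd")
        assert result.threshold == pytest.approx(0.45)
        assert result.significant_residues == [10]

    def test_uniform_profile_has_no_outliers(self):
        profile = profile_from_vectors([(0.2, 0.0)] * 5)
        for mode in ("mean", "two_sd", "mean_plus_two_sd"):
            assert significance(profile, mode).significant_residues == []

    def test_too_few_residues_rejected(self):
        with pytest.raises(ValueError):
            significance(profile_from_vectors([(0.1, 0.0)] * 2))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            significance(profile_from_vectors([(0.1, 0.0)] * 5), "median")


class TestTrajectorySimilarity:
    def test_identical_profiles(self):
        a = profile_from_vectors([(0.1, 0.5), (-0.2, 0.3), (0.05, -0.4)])
        comp = trajectory_similarity(a, a)
        assert all(c == pytest.approx(1.0) for c in comp.cosines.values())

    def test_scaled_profile_same_direction(self):
        a = profile_from_vectors([(0.1, 0.5), (-0.2, 0.3), (0.05, -0.4)])
        b = profile_from_vectors([(0.05, 0.25), (-0.1, 0.15), (0.025, -0.2)])
        comp = trajectory_similarity(a, b)
        assert all(c == pytest.approx(1.0) for c in comp.cosines.values())
        assert comp.summary == pytest.approx(1.0)

    def test_opposite_directions(self):
        a = profile_from_vectors([(0.1, 0.5), (-0.2, 0.3), (0.3, 0.1)])
        b = profile_from_vectors([(-0.1, -0.5), (0.2, -0.3), (-0.3, -0.1)])
        comp = trajectory_similarity(a, b)
        assert all(c == pytest.approx(-1.0) for c in comp.cosines.values())

    def test_zero_vectors_skipped(self):
        a = profile_from_vectors([(0.1, 0.5), (0.0, 0.0), (0.3, 0.1)])
        b = profile_from_vectors([(0.1, 0.5), (0.2, 0.1), (0.3, 0.1)])
        comp = trajectory_similarity(a, b)
        assert 2 not in comp.cosines and {1, 3} <= set(comp.cosines)


class TestAssessFold:
    def test_narrow_dispersion_is_collapsed(self, make_peaklist):
        rows = [(i, "A", 7.9 + 0.5 * (i % 10) / 10, 115.0 + i) for i in range(1, 15)]
        result = assess_fold(make_peaklist(rows))
        assert result.verdict == "collapsed"
        assert result.h_range < 1.5

    def test_wide_dispersion_is_folded(self, make_peaklist):
        rows = [(i, "A", 6.5 + 3.7 * (i % 12) / 11, 110.0 + i) for i in range(1, 25)]
        result = assess_fold(make_peaklist(rows))
        assert result.verdict == "folded"
        assert result.h_range > 1.5 and result.h_sd > 0.35

    def test_too_few_peaks_rejected(self, make_peaklist):
        rows = [(i, "A", 7.0 + i / 5, 115.0 + i) for i in range(1, 6)]
        with pytest.raises(ValueError):
            assess_fold(make_peaklist(rows))


class TestCompareVariantBinding:
    def _wt(self):
        vectors = [(0.02, 0.05)] * 8 + [(0.30, 0.80), (0.25, -0.60)]
        return profile_from_vectors(vectors)

    def test_identical_variant_is_wt_like(self):
        wt = self._wt()
        result = compare_variant_binding(wt, wt)
        assert result.extent_ratio == pytest.approx(1.0)
        assert result.verdict == "wt_like"

    def test_half_extent_same_direction_is_reduced(self):
        wt = self._wt()
        half = profile_from_vectors(
            [(dh / 2, dn / 2) for dh, dn in
             [(0.02, 0.05)] * 8 + [(0.30, 0.80), (0.25, -0.60)]]
        )
        result = compare_variant_binding(wt, half)
        assert result.extent_ratio == pytest.approx(0.5)
        assert result.verdict == "reduced"

    def test_flat_variant_is_abolished(self):
        wt = self._wt()
        flat = profile_from_vectors([(1e-4, 1e-4)] * 10)
        assert compare_variant_binding(wt, flat).verdict == "abolished"

    def test_no_significant_wt_residues_rejected(self):
        uniform = profile_from_vectors([(0.1, 0.0)] * 6)
        with pytest.raises(ValueError):
            compare_variant_binding(uniform, uniform)


class TestSyntheticTitration:
    def _series(self, dispersed_peaks, noise=0.0, seed=0):
        model = BindingModel(
            kd_mm=0.05,
            protein_conc_mm=0.5,
            endpoint_shifts={25: (0.25, 0.80), 31: (-0.15, 0.50), 40: (0.10, -1.00)},
        )
        return gen_titration(
            dispersed_peaks, model, [0, 0.5, 1, 1.85, 4, 6],
            noise_ppm=noise, seed=seed,
        )

    def test_fast_exchange_trajectories_collinear(self, dispersed_peaks):
        """Noiseless fast-exchange shifts are collinear across ratios."""
        series = self._series(dispersed_peaks)
        apo = series.apo
        profiles = [
            compute_csp(apo, peaks, endpoint_ratio=r)
            for r, peaks in series.points[1:]
        ]
        for p in profiles[:-1]:
            comp = trajectory_similarity(profiles[-1], p)
            assert all(c >= 0.999 for c in comp.cosines.values())

    def test_planted_binders_recovered(self, dispersed_peaks):
        """mean+2SD significance recovers exactly the planted binding
        residues in >= 90% of 200 seeded noisy titrations."""
        hits = 0
        for seed in range(200):
            series = self._series(dispersed_peaks, noise=0.01, seed=seed)
            profile = compute_csp(series.apo, series.endpoint)
            found = significance(profile, "mean_plus_two_sd").significant_residues
            hits += found == [25, 31, 40]
        assert hits >= 180

    def test_seeded_determinism(self, dispersed_peaks):
        s1 = self._series(dispersed_peaks, noise=0.02, seed=5)
        s2 = self._series(dispersed_peaks, noise=0.02, seed=5)
        for (r1, p1), (r2, p2) in zip(s1.points, s2.points):
            assert r1 == r2 and p1 == p2
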