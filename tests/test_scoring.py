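"""Score formulas: maxC, isotopologue criteria, LIP cut-off, PPS, GRTS/ARTS/RCS,
group reliability, GS and the per-round RGTV normalization."""
import math

import numpy as np
import pytest

from lcmsopt.model import LIP, RP, UNRELIABLE, FeatureGroup
from lcmsopt.scoring import (
    IsotopeCriteria,
    classify_groups,
    classify_lip,
    compute_arts,
    compute_grts,
    compute_pps,
    compute_rcs,
    compute_rgtv,
    compute_gs,
    find_isotopologues,
    max_carbons,
    pps_from_counts,
)

from conftest import make_peak


class TestMaxCarbons:
    @pytest.mark.parametrize(
        "mz,expected",
        [
            (30.04695, 2),  # numerator exactly zero: the minimal two-CH3 chain
            (100.0, 6),  # (100-30.04695)/14.01565 = 4.991 -> floor 4 -> 6
            (200.0, 14),  # 169.95305/14.01565 = 12.126 -> 14
            (20.0, 0),  # below the domain of the hydrocarbon model
        ],
    )
    def test_reference_values(self, mz, expected):
        assert max_carbons(mz) == expected

    def test_nondecreasing_integer_and_at_least_two_on_domain(self):
        mzs = np.linspace(30.05, 1000.0, 400)
        vals = [max_carbons(m) for m in mzs]
        assert all(isinstance(v, int) for v in vals)
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert all(v >= 2 for v in vals)


def brute_force_isotopologues(peaks, criteria):
    """All-pairs oracle applying the three criteria literally."""
    labels = [UNRELIABLE] * len(peaks)
    for i, p in enumerate(peaks):
        for j, q in enumerate(peaks):
            if i == j:
                continue
            if abs(q.mz - (p.mz + criteria.iso_mass_delta)) > criteria.mass_tol_ppm * p.mz * 1e-6:
                continue
            if not (q.rtmin <= p.rtmax and q.rtmax >= p.rtmin):
                continue
            if abs(q.rt - p.rt) > criteria.rt_window_frac * (p.rtmax - p.rtmin):
                continue
            lo = criteria.ia * p.intensity / (1 + criteria.intensity_slack)
            hi = max_carbons(p.mz) * criteria.ia * p.intensity * (1 + criteria.intensity_slack)
            if not (lo <= q.intensity <= hi):
                continue
            labels[i] = RP
            labels[j] = RP
    return labels


def random_peaklist(rng, n):
    """Random peaks with planted isotopologue pairs so RPs actually occur."""
    peaks = []
    for _ in range(n):
        mz = float(rng.uniform(50, 600))
        rt = float(rng.uniform(0, 600))
        width = float(rng.uniform(4, 40))
        inten = float(10 ** rng.uniform(2, 7))
        peaks.append(make_peak(mz=mz, rt=rt, intensity=inten, rt_halfwidth=width / 2))
        if rng.random() < 0.4 and mz > 35:
            nc = max(1, min(max_carbons(mz), int(rng.integers(1, 40))))
            peaks.append(
                make_peak(
                    mz=mz + 1.0033548 * (1 + rng.normal(0, 2e-6)),
                    rt=rt + float(rng.normal(0, width / 8)),
                    intensity=inten * nc * 0.01108 * float(rng.uniform(0.9, 1.1)),
                    rt_halfwidth=width / 2,
                )
            )
    return peaks[:n]


class TestFindIsotopologues:
    def test_hand_checked_pair_is_rp(self):
        parent = make_peak(mz=200.0, rt=100.0, intensity=1e6)
        iso = make_peak(mz=201.00335, rt=100.0, intensity=5e4)
        cls = find_isotopologues([parent, iso])
        # intensity window [11080, 155120] at maxC(200)=14 contains 5e4
        assert list(cls.labels) == [RP, RP]
        assert cls.partners == {0: [1]}

    def test_isotope_too_intense_for_carbon_count_rejected(self):
        parent = make_peak(mz=200.0, rt=100.0, intensity=1e6)
        iso = make_peak(mz=201.00335, rt=100.0, intensity=1e6)
        cls = find_isotopologues([parent, iso])
        assert list(cls.labels) == [UNRELIABLE, UNRELIABLE]

    def test_empty_list(self):
        cls = find_isotopologues([])
        assert cls.n_peaks == 0 and cls.partners == {}

    def test_agrees_with_brute_force_oracle_on_random_lists(self):
        """Exact agreement with the literal all-pairs implementation."""
        criteria = IsotopeCriteria(intensity_slack=0.2)
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(0, 200))
            peaks = random_peaklist(rng, n)
            got = list(find_isotopologues(peaks, criteria).labels)
            expected = brute_force_isotopologues(peaks, criteria)
            assert got == expected

    def test_rp_labels_scale_invariant_in_intensity(self):
        rng = np.random.default_rng(5)
        peaks = random_peaklist(rng, 80)
        base = list(find_isotopologues(peaks).labels)
        scaled = [
            make_peak(mz=p.mz, rt=p.rt, intensity=p.intensity * 137.0,
                      rt_halfwidth=(p.rtmax - p.rtmin) / 2)
            for p in peaks
        ]
        assert list(find_isotopologues(scaled).labels) == base


class TestClassifyLip:
    def test_cutoff_is_mean_of_lowest_three_percent(self):
        # intensities {10, 2..100}: lowest ceil(0.03*100)=3 values are {2,3,4}
        peaks = [make_peak(mz=500.0, intensity=float(i)) for i in range(1, 101)]
        peaks[0] = make_peak(mz=100.0, intensity=10.0)
        cls = classify_lip(peaks, find_isotopologues(peaks))
        assert cls.lip_cutoff == pytest.approx(3.0)

    def test_worked_example(self):
        peaks = [make_peak(mz=500.0, intensity=float(i)) for i in range(1, 101)]
        cls = find_isotopologues(peaks)
        cls = classify_lip(peaks, cls)
        assert cls.lip_cutoff == pytest.approx(2.0)
        probe = make_peak(mz=100.0, intensity=10.0)
        peaks2 = peaks + [probe]
        cls2 = classify_lip(peaks2, find_isotopologues(peaks2))
        # 10 * maxC(100)=6 * 0.01108 = 0.6648 < cutoff -> LIP
        assert cls2.labels[-1] == LIP

    def test_boundary_is_strictly_below(self):
        crit = IsotopeCriteria()
        # two peaks: cutoff = lower intensity; probe predicted exactly at cutoff
        lo = 100.0
        probe_int = lo / (max_carbons(400.0) * crit.ia)
        peaks = [make_peak(mz=600.0, intensity=lo)] * 33 + [make_peak(mz=400.0, intensity=probe_int)]
        cls = classify_lip(peaks, find_isotopologues(peaks), crit)
        assert cls.labels[-1] == UNRELIABLE  # == cutoff, not < cutoff

    def test_rp_peaks_never_relabeled(self):
        parent = make_peak(mz=200.0, rt=100.0, intensity=1e6)
        iso = make_peak(mz=201.00335, rt=100.0, intensity=5e4)
        filler = [make_peak(mz=300.0, intensity=1e9) for _ in range(60)]
        peaks = [parent, iso] + filler
        cls = classify_lip(peaks, find_isotopologues(peaks))
        assert cls.labels[0] == RP and cls.labels[1] == RP


class TestPps:
    @pytest.mark.parametrize(
        "rp,total,lip,expected",
        [
            (4, 10, 2, 2.0),
            (0, 50, 0, 0.0),
            (10, 20, 0, 5.0),
            (5, 5, 0, 5.0),
            (3, 3, 3, 0.0),  # denominator 0
        ],
    )
    def test_formula(self, rp, total, lip, expected):
        assert pps_from_counts(rp, total, lip) == pytest.approx(expected)

    def test_equal_increments_raise_pps(self):
        """The optimization force: +1 RP with +1 total still raises the score."""
        assert pps_from_counts(11, 21, 0) > pps_from_counts(10, 20, 0)


def group_of(rts, run_ids=None):
    run_ids = run_ids or [f"r{i}" for i in range(len(rts))]
    return FeatureGroup([make_peak(rt=t, run_id=rid) for t, rid in zip(rts, run_ids)])


class TestRtScores:
    def test_grts_values(self):
        assert compute_grts(group_of([10, 10, 10])) == 0.0
        assert compute_grts(group_of([9, 10, 11])) == pytest.approx(2.0 / 3.0)
        assert compute_grts(group_of([42.0])) == 0.0

    def test_arts_and_rcs(self):
        groups = [group_of([9, 10, 11, 12]), group_of([100, 103])]
        # GRTS: [1, 0.5, 0.5, 1.5]/4 = 0.875? no: median 10.5 -> |1.5,0.5,0.5,1.5|/4 = 1.0 ; [1.5,1.5]/2
        assert compute_arts(groups) == pytest.approx((1.0 + 1.5) / 2)
        assert compute_rcs(groups) == pytest.approx(1.0 / 1.25)

    def test_rcs_from_grts_example(self):
        # groups engineered to GRTS 0.5 and 1.5 -> ARTS 1.0 -> RCS 1.0
        g1 = group_of([10.0, 11.0])  # GRTS 0.5
        g2 = group_of([10.0, 13.0])  # GRTS 1.5
        assert compute_rcs([g1, g2]) == pytest.approx(1.0)

    def test_perfect_alignment_gives_inf_sentinel(self):
        assert compute_rcs([group_of([5.0, 5.0])]) == math.inf

    def test_zero_groups_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert compute_rcs([]) == 0.0

    def test_rcs_invariant_under_global_rt_shift(self):
        rng = np.random.default_rng(11)
        groups = [group_of(list(rng.uniform(0, 500, size=rng.integers(2, 6)))) for _ in range(10)]
        shifted = [
            FeatureGroup(
                [make_peak(rt=p.rt + 5.0, run_id=p.run_id) for p in g.member_peaks]
            )
            for g in groups
        ]
        assert compute_rcs(shifted) == pytest.approx(compute_rcs(groups))


class TestGroupReliability:
    def test_exactly_one_per_run_is_reliable(self):
        g = group_of([1, 2, 3], ["a", "b", "c"])
        assert classify_groups([g], n_runs=3) == (1, 0)

    def test_duplicate_run_is_nonreliable(self):
        g = group_of([1, 2, 3, 4], ["a", "a", "b", "c"])
        assert classify_groups([g], n_runs=3) == (0, 1)

    def test_missing_run_is_nonreliable(self):
        g = group_of([1, 2], ["a", "b"])
        assert classify_groups([g], n_runs=3) == (0, 1)

    @pytest.mark.parametrize(
        "rel,nonrel,expected", [(10, 4, 25.0), (0, 7, 0.0), (10, 0, 100.0)]
    )
    def test_gs_formula(self, rel, nonrel, expected):
        assert compute_gs(rel, nonrel) == pytest.approx(expected)


class TestRgtv:
    def test_worked_example(self):
        rgtv = compute_rgtv([1.0, 2.0, 3.0], [30.0, 10.0, 20.0])
        np.testing.assert_allclose(rgtv, [1.0, 0.5, 1.5])

    def test_constant_score_contributes_half(self):
        rgtv = compute_rgtv([2.0, 2.0, 2.0], [1.0, 3.0, 2.0])
        np.testing.assert_allclose(rgtv, [0.5, 1.5, 1.0])

    def test_inf_sentinel_maps_to_round_best(self):
        rgtv = compute_rgtv([math.inf, 2.0, 1.0], [5.0, 5.0, 5.0])
        assert rgtv[0] == pytest.approx(1.5)  # inf -> max finite (2.0) -> norm 1
        assert rgtv[2] == pytest.approx(0.5)

    def test_bounds_and_length_check(self):
        rng = np.random.default_rng(0)
        rgtv = compute_rgtv(rng.random(13), rng.random(13))
        assert np.all(rgtv >= 0) and np.all(rgtv <= 2)
        with pytest.raises(ValueError):
            compute_rgtv([1.0, 2.0], [1.0])
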