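import math

import numpy as np
import pytest

from profilesets import (
    ChangePointError,
    ChangePointSettings,
    default_penalty,
    detect_amoc,
    detect_binseg,
    detect_changepoints,
    detect_pelt,
    detect_segneigh,
    segment_cost,
)
from profilesets.changepoint import normalize_method

from helpers import brute_force_optimum, min_seg_len

CHANGE_TYPES = ("mean", "variance", "both")


def random_series(seed, n, steps=True):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    if steps and n >= 6:
        k = rng.integers(0, 3)
        for _ in range(int(k)):
            pos = int(rng.integers(1, n))
            x[pos:] += rng.normal(scale=3)
    return x


class TestSegmentCost:
    def test_constant_segment_mean_cost_zero(self):
        assert segment_cost([2.0] * 6, 1, 6, "mean") == 0.0

    def test_step_segment_mean_cost(self):
        assert segment_cost([0, 0, 6, 6], 1, 4, "mean") == pytest.approx(36.0)

    def test_refinement_never_increases_mean_cost(self):
        x = [0, 0, 0, 5, 5, 5]
        whole = segment_cost(x, 1, 6, "mean")
        split = segment_cost(x, 1, 3, "mean") + segment_cost(x, 4, 6, "mean")
        assert whole >= split

    @pytest.mark.parametrize("ctype", ["variance", "both"])
    def test_minimum_segment_length_enforced(self, ctype):
        with pytest.raises(ChangePointError, match="minimum length"):
            segment_cost([1.0, 2.0, 3.0], 2, 2, ctype)

    def test_bad_bounds_rejected(self):
        with pytest.raises(ChangePointError, match="bounds"):
            segment_cost([1.0, 2.0], 2, 1, "mean")

    def test_variance_cost_uses_global_mean(self):
        # deviations measured around the global series mean (here 3.0)
        x = [0, 0, 6, 6]
        expected = 2 * math.log(9.0)  # first two points: (0-3)^2 each
        assert segment_cost(x, 1, 2, "variance") == pytest.approx(expected)


class TestAmoc:
    def test_clear_step_found(self):
        x = [0.0] * 10 + [5.0] * 10
        settings = ChangePointSettings(
            change_type="mean", method="AMOC", penalty=3 * math.log(20)
        )
        seg = detect_amoc(x, settings)
        assert seg.cpt_indices == (10,)

    def test_constant_series_has_no_change(self):
        settings = ChangePointSettings(change_type="mean", method="AMOC")
        assert detect_amoc([1.0] * 15, settings).cpt_indices == ()

    def test_too_short_series_errors(self):
        settings = ChangePointSettings(change_type="mean", method="AMOC")
        with pytest.raises(ChangePointError, match="too short"):
            detect_amoc([1.0], settings)


class TestBinSeg:
    def test_two_step_series(self):
        x = [0.0] * 8 + [5.0] * 8 + [10.0] * 8
        settings = ChangePointSettings(change_type="mean", method="BinSeg")
        seg = detect_binseg(x, settings)
        assert seg.cpt_indices == (8, 16)

    def test_constant_series(self):
        settings = ChangePointSettings(change_type="mean", method="BinSeg")
        assert detect_binseg([3.0] * 20, settings).cpt_indices == ()

    def test_max_cpts_one_keeps_best_split(self):
        # symmetric two-step series: both splits reduce cost by 300,
        # the tie resolves toward the smaller index
        x = [0.0] * 8 + [5.0] * 8 + [10.0] * 8
        settings = ChangePointSettings(
            change_type="mean", method="BinSeg", max_cpts=1
        )
        seg = detect_binseg(x, settings)
        assert seg.cpt_indices == (8,)

    def test_greedy_cost_never_beats_exact(self):
        for seed in range(10):
            x = random_series(seed, 80)
            for ctype in CHANGE_TYPES:
                s = ChangePointSettings(change_type=ctype, method="BinSeg")
                p = ChangePointSettings(change_type=ctype, method="PELT")
                assert (
                    detect_binseg(x, s).total_cost
                    >= detect_pelt(x, p).total_cost - 1e-8
                )


class TestExactMethods:
    @pytest.mark.parametrize("ctype", CHANGE_TYPES)
    def test_match_brute_force_on_short_series(self, ctype):
        """PELT and SegNeigh attain the exhaustive-enumeration optimum."""
        for seed in range(25):
            rng = np.random.default_rng(1000 + seed)
            n = int(rng.integers(2 * min_seg_len(ctype) + 1, 13))
            x = random_series(seed, n)
            pen = default_penalty(n, ctype)
            expected, _ = brute_force_optimum(x, ctype, pen)
            settings = ChangePointSettings(
                change_type=ctype, method="PELT", max_cpts=n
            )
            assert detect_pelt(x, settings).total_cost == pytest.approx(
                expected, abs=1e-8
            )
            assert detect_segneigh(x, settings).total_cost == pytest.approx(
                expected, abs=1e-8
            )

    @pytest.mark.parametrize("ctype", CHANGE_TYPES)
    def test_pelt_equals_segneigh_on_longer_series(self, ctype):
        for seed in range(5):
            x = random_series(seed, 200)
            settings = ChangePointSettings(change_type=ctype, method="PELT")
            a = detect_pelt(x, settings)
            b = detect_segneigh(x, settings)
            assert a.total_cost == pytest.approx(b.total_cost, abs=1e-8)
            assert a.cpt_indices == b.cpt_indices

    def test_constant_series_no_changes(self):
        for ctype in CHANGE_TYPES:
            settings = ChangePointSettings(change_type=ctype)
            assert detect_pelt([2.0] * 30, settings).cpt_indices == ()
            assert detect_segneigh([2.0] * 30, settings).cpt_indices == ()


class TestProperties:
    def test_penalty_monotonicity(self):
        """A larger penalty never yields more change points."""
        for seed in range(8):
            x = random_series(seed, 120)
            for ctype in CHANGE_TYPES:
                counts = []
                for pen in [0.5, 2.0, 8.0, 32.0, 128.0]:
                    seg = detect_pelt(
                        x, ChangePointSettings(change_type=ctype, penalty=pen)
                    )
                    counts.append(len(seg.cpt_indices))
                assert counts == sorted(counts, reverse=True)

    def test_mean_cost_shift_invariance(self):
        x = random_series(3, 150)
        settings = ChangePointSettings(change_type="mean")
        for method in (detect_amoc, detect_binseg, detect_pelt, detect_segneigh):
            assert (
                method(x, settings).cpt_indices
                == method(x + 123.4, settings).cpt_indices
            )

    def test_detection_is_deterministic(self):
        x = random_series(11, 90)
        settings = ChangePointSettings()
        a = detect_changepoints(x, settings)
        b = detect_changepoints(x.copy(), settings)
        assert a == b


class TestSettings:
    def test_seqneigh_alias_accepted(self):
        assert normalize_method("SeqNeigh") == "SegNeigh"
        assert ChangePointSettings(method="seqneigh").method == "SegNeigh"

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ChangePointError):
            ChangePointSettings(change_type="median")
        with pytest.raises(ChangePointError):
            ChangePointSettings(penalty=-1.0)
        with pytest.raises(ChangePointError):
            ChangePointSettings(max_cpts=0)
        with pytest.raises(ChangePointError):
            normalize_method("wavelet")

    def test_default_penalty_scales_with_log_n(self):
        assert default_penalty(100, "mean") == pytest.approx(3 * math.log(100))
        assert default_penalty(100, "both") == pytest.approx(4 * math.log(100))
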