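"""HDI, KDE mode, ROPE verdicts and syndrome assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from germfire import (
    Interval,
    assign_syndrome,
    classify_control,
    hdi,
    mode_estimate,
    rope_classify,
)
from germfire.decision import DEFAULT_EFFECT_ROPE


def brute_force_hdi(x, mass):
    """Independent oracle: scan every sorted window of the required size."""
    x = np.sort(np.asarray(x, float))
    n = x.size
    k = int(np.ceil(mass * n))
    best = (np.inf, None)
    for i in range(n - k + 1):
        w = x[i + k - 1] - x[i]
        if w < best[0]:
            best = (w, (x[i], x[i + k - 1]))
    return best[1]


class TestHDI:
    def test_matches_bruteforce_exactly(self, rng):
        for dist in (rng.normal, rng.exponential, lambda size: rng.beta(2, 9, size)):
            x = dist(size=1500)
            for mass in (0.5, 0.9, 0.95):
                iv = hdi(x, mass)
                lo, hi = brute_force_hdi(x, mass)
                assert (iv.lower, iv.upper) == (lo, hi)

    def test_beta_8_1_analytic_lower_bound(self, rng):
        # 7/7 successes under a uniform prior: density is monotone increasing
        # so the 95% HDI is [q, 1] with q**8 = 0.05
        x = rng.beta(8, 1, 200_000)
        iv = hdi(x)
        assert iv.lower == pytest.approx(0.05 ** (1 / 8), abs=0.01)
        assert iv.upper > 0.999

    def test_standard_normal(self, rng):
        iv = hdi(rng.standard_normal(200_000))
        assert iv.lower == pytest.approx(-1.96, abs=0.03)
        assert iv.upper == pytest.approx(1.96, abs=0.03)

    def test_constant_draws_zero_width(self):
        iv = hdi(np.full(2000, 3.5))
        assert iv.lower == iv.upper == 3.5

    def test_too_few_draws(self):
        with pytest.raises(ValueError, match="draws"):
            hdi(np.arange(10))


class TestMode:
    def test_beta_4_25(self, rng):
        # analytic density mode 3/27 ~ 0.111
        m = mode_estimate(rng.beta(4, 25, 200_000), bounds=(0, 1))
        assert 0.09 <= m <= 0.13

    def test_symmetric_normal(self, rng):
        assert mode_estimate(rng.normal(5, 1, 50_000)) == pytest.approx(5, abs=0.1)

    def test_beta_8_1_near_boundary(self, rng):
        # monotone density: mode sits just inside the upper boundary
        m = mode_estimate(rng.beta(8, 1, 200_000), bounds=(0, 1))
        assert 0.95 <= m <= 1.0

    def test_constant(self):
        assert mode_estimate(np.full(2000, 2.0)) == 2.0


def _draws_with_hdi(rng, lo, hi, n=20_000):
    """Normal draws whose 95% HDI is approximately [lo, hi]."""
    return rng.normal((lo + hi) / 2, (hi - lo) / (2 * 1.96), n)


class TestRopeClassify:
    def test_nontrivial_outside(self, rng):
        c = rope_classify(_draws_with_hdi(rng, 14, 28))
        assert c.verdict == "non_trivial"
        assert c.mass_outside_rope > 0.95

    def test_trivial_inside(self, rng):
        c = rope_classify(_draws_with_hdi(rng, -3, 4))
        assert c.verdict == "trivial"

    def test_uncertain_overlap_high_mass_outside(self, rng):
        c = rope_classify(_draws_with_hdi(rng, 6, 33))
        assert c.verdict == "uncertain"
        assert c.mass_outside_rope > 0.8
        assert 0.8 < c.hdi_mass_outside_rope <= 1.0

    def test_invariant_to_draw_order(self, rng):
        x = _draws_with_hdi(rng, 5, 25)
        a = rope_classify(x)
        b = rope_classify(rng.permutation(x))
        assert a.verdict == b.verdict
        assert a.mass_outside_rope == b.mass_outside_rope

    def test_invariant_to_shared_affine_rescaling(self, rng):
        x = _draws_with_hdi(rng, 4, 18)
        base = rope_classify(x, DEFAULT_EFFECT_ROPE, bounds=None)
        for a, b in ((2.0, 5.0), (0.5, -3.0)):
            scaled = rope_classify(
                a * x + b,
                Interval(
                    a * DEFAULT_EFFECT_ROPE.lower + b,
                    a * DEFAULT_EFFECT_ROPE.upper + b,
                    mass=1.0,
                ),
                bounds=None,
            )
            assert scaled.verdict == base.verdict
            assert scaled.mass_outside_rope == pytest.approx(
                base.mass_outside_rope, abs=1e-12
            )

    @given(
        mu=st.floats(-40, 40),
        sd=st.floats(0.5, 15),
        widen=st.floats(0, 30),
        seed=st.integers(0, 2**20),
    )
    @settings(max_examples=60, deadline=None)
    def test_widening_rope_is_monotone(self, mu, sd, widen, seed):
        """A wider ROPE can only move a verdict toward trivial, never mint a
        new non-trivial call."""
        x = np.random.default_rng(seed).normal(mu, sd, 2000)
        narrow = rope_classify(x, Interval(-10, 10, mass=1.0)).verdict
        wide = rope_classify(x, Interval(-10 - widen, 10 + widen, mass=1.0)).verdict
        rank = {"non_trivial": 0, "uncertain": 1, "trivial": 2}
        assert rank[wide] >= rank[narrow]


class TestControl:
    def test_high_control(self, rng):
        c = classify_control(np.clip(rng.normal(0.97, 0.01, 20_000), 0, 1))
        assert c.p_ge_50 > 0.99
        assert c.verdict == "non_trivial"  # HDI above the [0, 50] ROPE

    def test_likely_sufficient(self, rng):
        c = classify_control(rng.normal(0.62, 0.105, 200_000))
        assert 0.84 <= c.p_ge_50 <= 0.90

    def test_low_control(self, rng):
        c = classify_control(np.clip(rng.normal(0.1, 0.04, 20_000), 0, 1))
        assert c.p_ge_50 < 0.01
        assert c.verdict == "trivial"  # inside [0, 50]


def _effect(rng, lo, hi, name="S-C"):
    return rope_classify(_draws_with_hdi(rng, lo, hi), name=name)


def _pi(rng, means):
    return {
        t: np.clip(rng.normal(m, 0.02, 5000), 0, 1) for t, m in means.items()
    }


class TestSyndrome:
    def test_fire_dependent(self, rng):
        control = classify_control(np.clip(rng.normal(0.05, 0.02, 5000), 0, 1))
        call = assign_syndrome(
            control,
            [_effect(rng, 80, 95)],
            _pi(rng, {"C": 0.05, "S": 0.91}),
        )
        assert call.label == "FD"

    def test_fire_enhanced(self, rng):
        control = classify_control(rng.normal(0.62, 0.105, 5000))
        call = assign_syndrome(
            control,
            [_effect(rng, 15, 40)],
            _pi(rng, {"C": 0.62, "S": 0.95}),
        )
        assert call.label == "FE"

    def test_fire_independent(self, rng):
        control = classify_control(np.clip(rng.normal(0.99, 0.005, 5000), 0, 1))
        call = assign_syndrome(
            control,
            [_effect(rng, -4, 3), _effect(rng, -3, 4, "H-C")],
            _pi(rng, {"C": 0.99, "H": 0.99, "S": 0.99}),
        )
        assert call.label == "FI"

    def test_uncertain_effect_blocks_fi(self, rng):
        control = classify_control(np.clip(rng.normal(0.9, 0.03, 5000), 0, 1))
        call = assign_syndrome(
            control,
            [_effect(rng, 5, 15)],
            _pi(rng, {"C": 0.9, "S": 0.97}),
        )
        assert call.label == "FU"

    def test_low_overall_germination_annotated(self, rng):
        control = classify_control(np.clip(rng.normal(0.05, 0.02, 5000), 0, 1))
        call = assign_syndrome(
            control,
            [_effect(rng, -2, 14)],
            _pi(rng, {"C": 0.05, "S": 0.15}),
        )
        assert call.label == "FU"
        assert "low overall germination" in call.annotations

    @given(
        cm=st.floats(0.02, 0.98),
        e_lo=st.floats(-30, 20),
        width=st.floats(1, 60),
        seed=st.integers(0, 2**20),
    )
    @settings(max_examples=40, deadline=None)
    def test_every_species_gets_exactly_one_label(self, cm, e_lo, width, seed):
        r = np.random.default_rng(seed)
        control = classify_control(np.clip(r.normal(cm, 0.05, 2000), 0, 1))
        effects = [_effect(r, e_lo, e_lo + width)]
        call = assign_syndrome(
            control, effects, _pi(r, {"C": cm, "S": min(cm + 0.2, 1.0)})
        )
        assert call.label in {"FD", "FE", "FI", "FU"}

    def test_missing_classifications_error(self, rng):
        control = classify_control(np.clip(rng.normal(0.5, 0.1, 2000), 0, 1))
        with pytest.raises(ValueError, match="no effect"):
            assign_syndrome(control, [], {"C": np.full(100, 0.5)})
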