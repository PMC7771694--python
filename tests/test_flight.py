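"""Flight dynamics: response function, resistance, Brownian steps, drift, reflection."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import repelsim as rs
from repelsim.flight import MEAN_CHI3, drift_gain


def make_source(kind="attractant", threshold=0.01):
    return rs.SourceSpec(location=(0.0, 0.0, 0.0), kind=kind, threshold=threshold)


class TestResponseStrength:
    @pytest.mark.parametrize(
        "c,a,rho,expected",
        [
            (0.0, 1.0, 1.0, 0.0),
            (1e9, 1.0, 1.0, 1.0),
            (np.log(2.0), 1.0, 2.0, 1.0),
        ],
    )
    def test_closed_form_values(self, c, a, rho, expected):
        assert rs.response_strength(c, a, rho) == pytest.approx(expected, abs=1e-12)

    @given(c1=st.floats(0.0, 50.0), c2=st.floats(0.0, 50.0))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_and_bounded(self, c1, c2):
        lo, hi = sorted((c1, c2))
        k_lo, k_hi = (rs.response_strength(c, 1.0, 0.8) for c in (lo, hi))
        assert 0.0 <= k_lo <= k_hi < 0.8 + 1e-12

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            rs.response_strength(-1.0, 1.0, 1.0)


class TestEffectiveConcentration:
    @pytest.mark.parametrize(
        "phen,kind,expected",
        [
            (rs.SUSCEPTIBLE, "repellent", 4.0),
            (rs.RESISTANT, "repellent", 2.0),
            (rs.RESISTANT, "attractant", 4.0),
        ],
    )
    def test_tolerance_division(self, phen, kind, expected):
        assert rs.effective_concentration(4.0, phen, kind) == expected

    def test_efficiency_mode_leaves_concentration(self):
        phen = rs.Phenotype("resistant", 2.0, mode="efficiency")
        assert rs.effective_concentration(4.0, phen, "repellent") == 4.0
        # tolerance applies to the repellency gain instead
        p = rs.FlightParams()
        assert drift_gain("repellent", p, phen) == pytest.approx(p.gamma2 * p.beta / 2.0)

    def test_susceptible_requires_unit_tolerance(self):
        with pytest.raises(ValueError):
            rs.Phenotype("susceptible", 2.0)


class TestBrownianStep:
    def test_zero_mean_and_unit_mean_length(self, rng):
        p = rs.FlightParams()
        steps = p.sigma * p.step_scale * rng.standard_normal((100_000, 3))
        per_axis = steps.mean(axis=0)
        se = p.sigma * p.step_scale / np.sqrt(len(steps))
        assert np.all(np.abs(per_axis) < 3.0 * se)
        mean_len = np.linalg.norm(steps, axis=1).mean()
        assert mean_len == pytest.approx(1.0, rel=0.01)  # 10 m per 30 s at 1000 steps/30 s

    def test_default_scale_is_inverse_chi3_mean(self):
        assert rs.FlightParams().step_scale == pytest.approx(1.0 / MEAN_CHI3)
        assert MEAN_CHI3 == pytest.approx(2.0 * np.sqrt(2.0 / np.pi))

    def test_msd_additivity(self, rng):
        # n-step MSD equals n * 3 * (sigma*step_scale)^2: brute-force simulation
        p = rs.FlightParams()
        n_steps, n_walkers = 200, 2000
        steps = p.sigma * p.step_scale * rng.standard_normal((n_walkers, n_steps, 3))
        msd = (steps.sum(axis=1) ** 2).sum(axis=1).mean()
        expected = n_steps * 3.0 * (p.sigma * p.step_scale) ** 2
        assert msd == pytest.approx(expected, rel=0.1)


class TestDriftDisplacement:
    def test_below_threshold_is_zero(self):
        src = make_source(threshold=0.5)
        d = rs.drift_displacement(np.array([300.0, 0, 0]), src, 0.4, rs.FlightParams())
        assert np.all(d == 0.0)

    def test_attractive_drift_toward_source(self):
        # K = 0.8 at c = -ln(0.2), gain = gamma1*alpha = 0.5: drift (-0.4, 0, 0)
        src = make_source()
        c = -np.log(0.2)
        d = rs.drift_displacement(np.array([300.0, 0, 0]), src, c, rs.FlightParams())
        np.testing.assert_allclose(d, [-0.4, 0.0, 0.0], atol=1e-12)

    def test_repulsive_drift_away_from_source(self):
        src = make_source(kind="repellent")
        c = -np.log(0.2)
        d = rs.drift_displacement(np.array([300.0, 0, 0]), src, c, rs.FlightParams())
        np.testing.assert_allclose(d, [+0.4, 0.0, 0.0], atol=1e-12)

    def test_coincident_position_gives_zero(self):
        src = make_source()
        d = rs.drift_displacement(src.location, src, 1.0, rs.FlightParams())
        assert np.all(d == 0.0)

    def test_magnitude_bounded_by_gain_times_rho(self):
        src = make_source(kind="repellent")
        p = rs.FlightParams(rho=0.7, rho_repellent=0.9)
        d = rs.drift_displacement(np.array([10.0, 5.0, 2.0]), src, 1e9, p)
        assert np.linalg.norm(d) <= p.gamma2 * p.beta * 0.9 + 1e-12

    def test_resistant_drift_weaker_than_susceptible(self):
        src = make_source(kind="repellent")
        p = rs.FlightParams()
        x = np.array([100.0, 0, 0])
        c = 2.0
        d_sus = rs.drift_displacement(x, src, rs.effective_concentration(c, rs.SUSCEPTIBLE, "repellent"), p)
        d_res = rs.drift_displacement(x, src, rs.effective_concentration(c, rs.RESISTANT, "repellent"), p)
        assert np.linalg.norm(d_res) < np.linalg.norm(d_sus)

    def test_opposing_equal_sources_cancel(self):
        attract = make_source("attractant")
        repel = make_source("repellent")
        p = rs.FlightParams()  # alpha == beta, shared rho and a
        x = np.array([123.0, 45.0, 6.0])
        total = rs.drift_displacement(x, attract, 1.7, p) + rs.drift_displacement(x, repel, 1.7, p)
        np.testing.assert_allclose(total, 0.0, atol=1e-14)


class TestReflection:
    CAGE = rs.CageGeometry()

    @pytest.mark.parametrize(
        "x,expected",
        [
            ((-3.0, 100.0, 100.0), (3.0, 100.0, 100.0)),
            ((503.0, 100.0, 100.0), (497.0, 100.0, 100.0)),
            ((250.0, 250.0, 150.0), (250.0, 250.0, 150.0)),
        ],
    )
    def test_mirror_examples(self, x, expected):
        np.testing.assert_allclose(rs.reflect_into_cage(np.array(x), self.CAGE), expected)

    @given(
        x=st.floats(-2000.0, 2000.0),
        y=st.floats(-2000.0, 2000.0),
        z=st.floats(-2000.0, 2000.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_always_inside_and_idempotent(self, x, y, z):
        pt = np.array([x, y, z])
        folded = rs.reflect_into_cage(pt, self.CAGE)
        assert np.all(folded >= 0.0) and np.all(folded <= self.CAGE.lengths)
        np.testing.assert_allclose(rs.reflect_into_cage(folded, self.CAGE), folded)


class TestAdvanceMosquito:
    def test_without_sources_is_pure_random_walk(self):
        p = rs.FlightParams()
        state = rs.MosquitoState(0, np.array([250.0, 250.0, 150.0]))
        out1 = rs.advance_mosquito(state, [], p, rs.SUSCEPTIBLE, 10.0, np.random.default_rng(5), rs.CageGeometry())
        expected = state.position + p.sigma * p.step_scale * np.random.default_rng(5).standard_normal(3)
        np.testing.assert_allclose(out1.position, expected)

    def test_deterministic_under_same_seed(self):
        p = rs.FlightParams()
        src = rs.make_scenario("attractant_only").attractant
        state = rs.MosquitoState(0, np.array([100.0, 50.0, 20.0]))
        outs = [
            rs.advance_mosquito(state, [src], p, rs.RESISTANT, 60.0, np.random.default_rng(9), rs.CageGeometry())
            for _ in range(2)
        ]
        np.testing.assert_array_equal(outs[0].position, outs[1].position)

    def test_rejects_non_flying_state(self):
        state = rs.MosquitoState(0, np.array([1.0, 1.0, 1.0]), status="landed", event_time=5.0)
        with pytest.raises(ValueError):
            rs.advance_mosquito(state, [], rs.FlightParams(), rs.SUSCEPTIBLE, 0.0, np.random.default_rng(0))
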