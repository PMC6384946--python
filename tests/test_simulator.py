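"""Retention surface, gradient-elution solver and synthetic dataset generator."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import gradret as g


def neutral_solute(ln_kw: float, S: float, solute_id: str = "s") -> g.IsocraticRetentionParams:
    """pH-independent solute: ionized species identical to the neutral one."""
    return g.IsocraticRetentionParams(solute_id, ln_kw, S, ln_kw, S, 7.0, "acid", 0.0)


def lss_retention_time(t0: float, k0: float, b: float) -> float:
    """Closed-form linear-solvent-strength gradient solution: elution during
    the ramp of a neutral solute with ln k = ln k0 - b t gives
    t_R = t0 + ln(1 + b t0 k0) / b.  Implemented independently of the solver."""
    return t0 + math.log1p(b * t0 * k0) / b


@st.composite
def acid_params_strategy(draw):
    """Random acids whose ionized species is weaker than the neutral one at
    every composition (the constraint the parameter class enforces)."""
    ln_kw = draw(st.floats(1.5, 7.0))
    S = draw(st.floats(6.0, 15.0))
    return g.IsocraticRetentionParams(
        solute_id="h",
        ln_kw_neutral=ln_kw,
        S_neutral=S,
        ln_kw_ion=ln_kw - draw(st.floats(0.5, 4.0)),
        S_ion=S + draw(st.floats(0.0, 2.0)),
        pKa=draw(st.floats(3.0, 9.0)),
        charge_type="acid",
        pKa_phi_shift=draw(st.floats(0.0, 2.0)),
    )


acid_params = acid_params_strategy()


class TestIsocraticK:
    def test_half_ionization_with_retentionless_ion(self):
        """At pH = pKa_eff with k_ion ~ 0 the surface halves the neutral k."""
        p = g.IsocraticRetentionParams("s", 2.0, 10.0, -30.0, 10.5, 5.0, "acid", 1.5)
        phi = 0.2
        k = g.isocratic_k(p, phi, pH=5.0 + 1.5 * phi)
        assert k == pytest.approx(0.5 * math.exp(2.0 - 10.0 * phi), rel=1e-9)

    def test_fully_neutral_limit(self):
        p = g.IsocraticRetentionParams("s", 3.0, 9.0, 0.5, 9.5, 8.0, "acid", 0.0)
        assert g.isocratic_k(p, 0.1, pH=2.0) == pytest.approx(
            math.exp(3.0 - 0.9), rel=1e-5
        )

    def test_exponent_cancellation(self):
        p = neutral_solute(2.0, 10.0)
        assert g.isocratic_k(p, 0.2, pH=2.0) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(params=acid_params, phi=st.floats(0.05, 0.6), pH=st.floats(2.0, 11.0))
    def test_k_positive_and_monotone(self, params, phi, pH):
        """k > 0, decreasing in phi, and decreasing in pH for acids."""
        k = g.isocratic_k(params, phi, pH)
        assert k > 0
        assert g.isocratic_k(params, phi + 0.05, pH) <= k * (1 + 1e-12)
        assert g.isocratic_k(params, phi, pH + 0.5) <= k * (1 + 1e-12)

    def test_base_retention_rises_with_pH(self):
        p = g.IsocraticRetentionParams("b", 3.0, 9.0, 0.0, 9.5, 6.0, "base", 0.0)
        assert g.isocratic_k(p, 0.2, 8.5) > g.isocratic_k(p, 0.2, 3.5)

    def test_ion_must_not_outretain_neutral(self):
        with pytest.raises(ValueError):
            g.IsocraticRetentionParams("s", 2.0, 10.0, 3.0, 10.0, 5.0, "acid", 0.0)


class TestGradientRetentionTime:
    def test_constant_composition_closed_form(self):
        """With zero slopes the fundamental equation gives t_R = t0 (1 + k)."""
        phi = 0.25
        p = g.GradientProfile("iso", "B", phi, phi, 3.0, 3.0, 10.0)
        params = neutral_solute(math.log(4.0) + 10.0 * phi, 10.0)  # k = 4 exactly
        t_r = g.gradient_retention_time(p, params, g.SimulatorConfig(t0=2.0))
        assert t_r == pytest.approx(10.0, rel=1e-6)

    def test_matches_lss_closed_form_over_sweep(self):
        """Numeric solver vs. the analytic LSS gradient formula, 20 settings."""
        rng = np.random.default_rng(42)
        cfg = g.SimulatorConfig(t0=2.0)
        for _ in range(20):
            ln_kw = rng.uniform(2.0, 6.0)
            S = rng.uniform(6.0, 14.0)
            phi_i = rng.uniform(0.1, 0.3)
            slope = rng.uniform(0.005, 0.05)
            t_g = 200.0  # ramp long enough that elution happens inside it
            profile = g.GradientProfile(
                "lss", "C", phi_i, min(phi_i + slope * t_g, 0.95), 3.0, 3.0,
                (min(phi_i + slope * t_g, 0.95) - phi_i) / slope,
            )
            params = neutral_solute(ln_kw, S)
            k0 = float(g.isocratic_k(params, phi_i, 3.0))
            expected = lss_retention_time(cfg.t0, k0, S * slope)
            assert expected - cfg.t0 < profile.t_g  # oracle's validity condition
            t_r = g.gradient_retention_time(profile, params, cfg)
            assert t_r == pytest.approx(expected, rel=1e-6)

    def test_elution_residual_bounded(self, design_b, library):
        """The returned t_R satisfies the defining integral to tolerance."""
        cfg = g.SimulatorConfig(t0=2.0, integration_tol=1e-9)
        profile = design_b["1B"]
        params = library[10]
        t_r = g.gradient_retention_time(profile, params, cfg)
        F, _ = quad(
            lambda t: 1.0 / (cfg.t0 * g.isocratic_k(params, *g.composition_at(profile, t))),
            0.0, t_r - cfg.t0, points=[profile.t_g], limit=500,
        )
        assert abs(F - 1.0) <= 10 * cfg.integration_tol

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(
        params=acid_params,
        slopes=st.tuples(st.floats(0.005, 0.05), st.floats(0.005, 0.05)),
    )
    def test_steeper_phi_gradient_never_elutes_later(self, params, slopes):
        """Monotonicity in gradient steepness: more organic sooner, never
        a later peak."""
        steep, shallow = max(slopes), min(slopes)
        cfg = g.SimulatorConfig(t0=2.0)
        t_rs = []
        for slope in (steep, shallow):
            profile = g.GradientProfile(
                "m", "A", 0.2, 0.5, 3.0, 3.0, 0.3 / slope, dphi_dt=slope,
            )
            t_rs.append(g.gradient_retention_time(profile, params, cfg))
        assert t_rs[0] <= t_rs[1] * (1 + 1e-9)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(params=acid_params)
    def test_retention_never_below_holdup(self, params, design_a):
        t_r = g.gradient_retention_time(design_a["1A"], params, g.SimulatorConfig(t0=2.0))
        assert t_r >= 2.0

    def test_non_elution_raises(self):
        """A base that ionizes away its retention at low pH but regains a huge
        neutral k as the pH ramp passes its pKa never reaches the outlet."""
        profile = g.GradientProfile("ne", "B", 0.25, 0.25, 3.0, 9.0, 2.0)
        params = g.IsocraticRetentionParams("stuck", 8.0, 10.0, 5.5, 10.5, 5.0, "base", 0.0)
        with pytest.raises(g.NonElutionError):
            g.gradient_retention_time(profile, params, g.SimulatorConfig(t0=2.0))

    def test_unretained_start_warns_but_solves(self):
        profile = g.GradientProfile("w", "B", 0.25, 0.25, 8.0, 9.0, 5.0)
        params = g.IsocraticRetentionParams("fast", 1.0, 10.0, -6.0, 10.5, 4.0, "acid", 0.0)
        with pytest.warns(UserWarning, match="unretained"):
            t_r = g.gradient_retention_time(profile, params, g.SimulatorConfig(t0=2.0))
        assert t_r > 2.0


class TestDatasetGeneration:
    def test_cardinality_and_determinism(self, design_a, library):
        cfg1 = g.SimulatorConfig(noise_cv=0.0, seed=1)
        cfg2 = g.SimulatorConfig(noise_cv=0.0, seed=99)
        d1 = g.generate_retention_dataset(design_a, library, cfg1)
        d2 = g.generate_retention_dataset(design_a, library, cfg2)
        assert len(d1) == 19 * 16
        assert (d1["tR_min"] == d2["tR_min"]).all()  # noise-free: seed irrelevant

    def test_seeded_noise_reproducible(self, design_a, library):
        cfg = g.SimulatorConfig(noise_cv=0.01, seed=7)
        d1 = g.generate_retention_dataset(design_a, library, cfg)
        d2 = g.generate_retention_dataset(design_a, library, cfg)
        assert (d1["tR_min"] == d2["tR_min"]).all()

    def test_noise_perturbs_but_preserves_scale(self, design_a, library, records_a):
        cfg = g.SimulatorConfig(noise_cv=0.01, seed=7)
        noisy = g.generate_retention_dataset(design_a, library, cfg)
        ratio = noisy["tR_min"].to_numpy() / records_a["tR_min"].to_numpy()
        assert (ratio != 1.0).any()
        assert np.abs(np.log(ratio)).max() < 0.1

    def test_simulated_retention_above_holdup(self, records_a, records_b, records_c, sim_cfg):
        for recs in (records_a, records_b, records_c):
            assert (recs["tR_min"] > sim_cfg.t0).all()


class TestSoluteLibrary:
    def test_roster_and_labels(self, library):
        ids = [p.solute_id for p in library]
        assert len(library) == 16
        assert ids == list(g.ROSTER)
        assert {"Dopa", "GABA"} <= set(ids)
        assert "Glu" not in ids

    def test_elution_order_matches_roster_on_steep_phi_gradient(
        self, design_a, library, sim_cfg
    ):
        t_rs = [g.gradient_retention_time(design_a["1A"], p, sim_cfg) for p in library]
        assert t_rs == sorted(t_rs)
        assert t_rs[0] < t_rs[-1]  # Arg elutes before Leu

    def test_retention_window_is_realistic(self, records_a, records_b, records_c):
        """Simulated retention spans roughly 2-60 min over the three designs."""
        lo = min(r["tR_min"].min() for r in (records_a, records_b, records_c))
        hi = max(r["tR_min"].max() for r in (records_a, records_b, records_c))
        assert 2.0 <= lo <= 6.0
        assert 25.0 <= hi <= 60.0
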