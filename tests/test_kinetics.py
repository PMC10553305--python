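"""Closed-form encounter kinetics: worked examples and algebraic invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zooencounter import (DegenerateMotionError, EncounterRate, ParticleField,
                          Swimmer, ValidationError, effective_speed, gs_rate,
                          ro_rate, taxon_registry, turbulence_multiplier)

speeds = st.floats(min_value=1e-6, max_value=1.0)
radii = st.floats(min_value=1e-5, max_value=0.1)
densities = st.floats(min_value=0.0, max_value=1e6)


class TestGSRate:
    @pytest.mark.parametrize("y, conc, expected_per_s, expected_per_h", [
        (0.04, 13.5, 0.67858, 2442.9),    # chaetognath, June mean concentration
        (0.016, 13.5, 0.27143, 977.2),    # luciferid, June
    ])
    def test_stationary_prey_examples(self, y, conc, expected_per_s, expected_per_h):
        """Surface rates for a stationary particle field match the swept-cylinder
        values the published means are built on."""
        rate = gs_rate(Swimmer("t", speed=y, radius=0.02),
                       ParticleField.from_per_liter(conc))
        assert rate.value == pytest.approx(expected_per_s, rel=1e-4)
        assert rate.to_per_hour().value == pytest.approx(expected_per_h, rel=1e-4)

    def test_no_particles_no_encounters(self):
        rate = gs_rate(Swimmer("t", speed=0.04, radius=0.02), ParticleField(0.0))
        assert rate.value == 0.0

    @given(speed=speeds, radius=radii, density=densities)
    @settings(max_examples=50, deadline=None)
    def test_stationary_prey_closed_form_exact(self, speed, radius, density):
        """For x = 0 the GS rate is exactly pi R^2 N y (swept cylinder)."""
        rate = gs_rate(Swimmer("t", speed=speed, radius=radius),
                       ParticleField(density))
        assert rate.value == math.pi * radius ** 2 * density * speed

    @given(v=speeds, radius=radii, density=densities)
    @settings(max_examples=50, deadline=None)
    def test_symmetric_speeds_closed_form(self, v, radius, density):
        """At x = y = v the bracket simplifies to (4/3) pi R^2 N v."""
        rate = gs_rate(Swimmer("t", speed=v, radius=radius),
                       ParticleField(density, speed=v))
        assert rate.value == pytest.approx(
            (4.0 / 3.0) * math.pi * radius ** 2 * density * v, rel=1e-12)

    @given(y=speeds, x=speeds, radius=radii, density=st.floats(1.0, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_linear_in_density_and_quadratic_in_radius(self, y, x, radius, density):
        base = gs_rate(Swimmer("t", y, radius), ParticleField(density, x)).value
        doubled_n = gs_rate(Swimmer("t", y, radius),
                            ParticleField(2 * density, x)).value
        doubled_r = gs_rate(Swimmer("t", y, 2 * radius),
                            ParticleField(density, x)).value
        assert doubled_n == pytest.approx(2 * base, rel=1e-12)
        assert doubled_r == pytest.approx(4 * base, rel=1e-12)

    def test_continuous_across_stationary_limit(self):
        """The analytic limit used at x ~ 0 joins the full bracket smoothly."""
        swimmer = Swimmer("t", speed=0.04, radius=0.02)
        limit = gs_rate(swimmer, ParticleField(13500.0, speed=0.0)).value
        near = gs_rate(swimmer, ParticleField(13500.0, speed=1e-9)).value
        assert near == pytest.approx(limit, rel=1e-9)

    def test_both_stationary_is_degenerate(self):
        with pytest.raises(DegenerateMotionError):
            gs_rate(Swimmer("t", speed=0.0, radius=0.02), ParticleField(100.0))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            Swimmer("t", speed=-1.0, radius=0.02)
        with pytest.raises(ValidationError):
            Swimmer("t", speed=0.01, radius=0.0)
        with pytest.raises(ValidationError):
            ParticleField(-5.0)

    def test_accepts_density_arrays(self):
        dens = np.array([0.0, 1000.0, 13500.0])
        rate = gs_rate(Swimmer("t", 0.04, 0.02), ParticleField(dens))
        assert rate.value == pytest.approx(math.pi * 0.02 ** 2 * 0.04 * dens)


class TestEffectiveSpeed:
    def test_pythagorean_triple(self):
        assert effective_speed(0.03, 0.04) == pytest.approx(0.05)

    @given(v=speeds)
    @settings(max_examples=25, deadline=None)
    def test_identity_without_turbulence(self, v):
        assert effective_speed(v, 0.0) == v
        assert effective_speed(0.0, v) == v

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            effective_speed(-0.1, 0.0)
        with pytest.raises(ValidationError):
            effective_speed(0.1, -0.1)


class TestRORate:
    def test_reduces_to_gs_at_zero_turbulence(self):
        swimmer = Swimmer("t", 0.04, 0.02)
        field = ParticleField(13500.0)
        assert (ro_rate(swimmer, field, 0.0).value
                == gs_rate(swimmer, field).value)

    def test_continuity_as_w_vanishes(self):
        swimmer = Swimmer("t", 0.04, 0.02)
        field = ParticleField(13500.0)
        assert ro_rate(swimmer, field, 1e-12).value == pytest.approx(
            gs_rate(swimmer, field).value, rel=1e-9)

    @given(y=speeds, x=st.floats(0.0, 1.0), w=st.floats(0.0, 1.0),
           radius=radii, density=st.floats(1.0, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_turbulence_never_decreases_encounters(self, y, x, w, radius, density):
        swimmer = Swimmer("t", y, radius)
        field = ParticleField(density, x)
        assert (ro_rate(swimmer, field, w).value
                >= gs_rate(swimmer, field).value * (1 - 1e-12))

    @pytest.mark.parametrize("y, w, expected", [
        (0.04, 0.03, 1.400),    # chaetognath, June wind
        (0.016, 0.04, 3.466),   # luciferid, October wind (direct bracket value)
    ])
    def test_ratio_examples(self, y, w, expected):
        swimmer = Swimmer("t", y, 0.02)
        field = ParticleField(13500.0)
        ratio = ro_rate(swimmer, field, w).value / gs_rate(swimmer, field).value
        assert ratio == pytest.approx(expected, abs=5e-4)


class TestTurbulenceMultiplier:
    @pytest.mark.parametrize("y, w, expected", [
        (0.062, 0.03, 1.181),   # copepod, June
        (0.04, 0.03, 1.400),    # chaetognath, June
        (0.016, 0.03, 2.676),   # luciferid, June
        (0.062, 0.04, 1.307),   # copepod, October
        (0.04, 0.04, 1.650),    # chaetognath, October
    ])
    def test_published_wind_conditions(self, y, w, expected):
        assert turbulence_multiplier(y, 0.0, w) == pytest.approx(expected, abs=5e-4)

    def test_unity_without_wind(self):
        assert turbulence_multiplier(0.04, 0.0, 0.0) == 1.0

    @given(y=speeds, x=st.floats(0.0, 1.0), w=st.floats(0.0, 1.0),
           r1=radii, r2=radii, n1=st.floats(1.0, 1e6), n2=st.floats(1.0, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_independent_of_radius_and_density(self, y, x, w, r1, r2, n1, n2):
        """R and N cancel in the RO/GS ratio, whatever their values."""
        ratios = [ro_rate(Swimmer("t", y, r), ParticleField(n, x), w).value
                  / gs_rate(Swimmer("t", y, r), ParticleField(n, x)).value
                  for r, n in [(r1, n1), (r2, n2)]]
        assert ratios[0] == pytest.approx(ratios[1], rel=1e-9)
        assert ratios[0] == pytest.approx(turbulence_multiplier(y, x, w), rel=1e-9)

    def test_monotone_in_turbulence_for_stationary_prey(self):
        ws = np.linspace(0.0, 0.2, 50)
        mults = [turbulence_multiplier(0.04, 0.0, w) for w in ws]
        assert all(b >= a for a, b in zip(mults, mults[1:]))
        assert all(m >= 1.0 for m in mults)


class TestRegistryAndUnits:
    def test_three_study_taxa(self, registry):
        assert set(registry) == {"copepod", "chaetognath", "luciferid"}
        assert registry["chaetognath"] == Swimmer("chaetognath", 0.04, 0.02)
        assert registry["luciferid"] == Swimmer("luciferid", 0.016, 0.02)
        assert registry["copepod"].radius == pytest.approx(4.0e-4)
        assert registry["copepod"].speed == pytest.approx(0.062)

    def test_literal_copepod_speed_flag(self):
        assert taxon_registry(copepod_speed_as_printed=True)["copepod"].speed \
            == pytest.approx(0.0062)

    def test_registry_is_read_only_but_copyable(self, registry):
        with pytest.raises(TypeError):
            registry["krill"] = Swimmer("krill", 0.01, 0.01)
        copy = dict(registry)
        copy["krill"] = Swimmer("krill", 0.01, 0.01)
        assert "krill" in copy and "krill" not in registry

    def test_unknown_taxon_lookup(self, registry):
        with pytest.raises(KeyError):
            registry["krill"]

    def test_unit_conversions_exact(self):
        assert ParticleField.from_per_liter(13.5).density == 13500.0
        assert EncounterRate(0.5, "per-second").to_per_hour().value == 1800.0
        assert EncounterRate(3600.0, "per-hour").to_per_second().value == 1.0
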