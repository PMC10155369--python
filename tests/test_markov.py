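"""Generator construction, propagation and absorption of the fate chain.

The independent oracle here is the closed-form cascade (Bateman-style)
solution of the transient linear chain: with distinct total exit rates
per state the occupancies are explicit sums of exponentials, and the
absorbing-state masses are their term-by-term integrals.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subdos import (
    ExpressionScenario,
    GeneArchitecture,
    InvalidParameterError,
    ModelSpec,
    SelectionParams,
    StateDistribution,
    Variant,
    absorption_probabilities,
    build_generator,
    mutation_rates,
    propagate,
    trajectory,
)


def cascade_occupancies(q: np.ndarray, z: int, t: float) -> np.ndarray:
    """Closed-form state occupancies at time t for the 0->1->...->z-1 cascade.

    Requires pairwise-distinct exit rates (true for these generators).
    Transient state k:  p_k(t) = (prod of forward rates) * sum_j
    exp(-lam_j t) / prod_{m != j}(lam_m - lam_j).  Absorbing masses are
    the inflow-rate-weighted integrals of those exponentials.
    """
    lam = -np.diag(q)[:z]
    fwd = [q[i, i + 1] for i in range(z - 1)]

    def transient(k: int, tt: float) -> float:
        coef = math.prod(fwd[:k])
        total = 0.0
        for j in range(k + 1):
            denom = math.prod(lam[m] - lam[j] for m in range(k + 1) if m != j)
            total += math.exp(-lam[j] * tt) / denom
        return coef * total

    def transient_integral(k: int, tt: float) -> float:
        coef = math.prod(fwd[:k])
        total = 0.0
        for j in range(k + 1):
            denom = math.prod(lam[m] - lam[j] for m in range(k + 1) if m != j)
            total += (1.0 - math.exp(-lam[j] * tt)) / (lam[j] * denom)
        return coef * total

    p = np.zeros(z + 2)
    for k in range(z):
        p[k] = transient(k, t)
    for k in range(z):
        p[z] += q[k, z] * transient_integral(k, t)  # inflow to S
        p[z + 1] += q[k, z + 1] * transient_integral(k, t)  # inflow to Y
    return p


class TestMutationRates:
    def test_region_rates_from_reference_parameters(self, architecture):
        u_c, u_r = mutation_rates(architecture)
        assert u_c == pytest.approx(1.25e-3, rel=1e-12)
        assert u_r == pytest.approx(1.9375e-5, rel=1e-12)

    def test_rates_scale_linearly_with_region_length(self, architecture):
        doubled = GeneArchitecture(
            z=4, l_c=architecture.l_c, l_r=2 * architecture.l_r,
            u_b=architecture.u_b, u_h=architecture.u_h,
        )
        assert mutation_rates(doubled)[1] == pytest.approx(
            2 * mutation_rates(architecture)[1], rel=1e-12
        )


class TestBuildGenerator:
    def test_neutral_generator_entries(self, sub_only_spec):
        q = build_generator(sub_only_spec).q
        u_c, u_r = mutation_rates(sub_only_spec.architecture)
        assert q[0, 1] == pytest.approx(8 * u_r, rel=1e-12)  # 2z * u_r
        assert q[0, 5] == pytest.approx(2 * u_c, rel=1e-12)
        assert q[1, 2] == pytest.approx(3 * u_r, rel=1e-12)
        assert q[1, 4] == pytest.approx(3 * u_r, rel=1e-12)
        assert q[1, 5] == pytest.approx(u_c, rel=1e-12)
        assert q[3, 4] == pytest.approx(u_r, rel=1e-12)
        assert q[3, 5] == pytest.approx(u_c + u_r, rel=1e-12)

    def test_zero_pattern_and_absorbing_rows(self, sub_dos_spec):
        gen = build_generator(sub_dos_spec)
        q, z = gen.q, gen.z
        assert np.all(q[z:] == 0.0)  # S and Y rows
        assert q[0, gen.s_index] == 0.0  # no direct 0 -> S route
        for i in range(z):
            for j in range(z):
                if j not in (i, i + 1):
                    assert q[i, j] == 0.0

    def test_rows_sum_to_zero(self, sub_only_spec, sub_dos_spec, sub_dos_ssd_spec):
        for spec in (sub_only_spec, sub_dos_spec, sub_dos_ssd_spec):
            q = build_generator(spec).q
            scale = np.abs(q).max()
            assert np.abs(q.sum(axis=1)).max() <= 1e-15 * scale
            off_diag = q - np.diag(np.diag(q))
            assert np.all(off_diag >= 0.0)

    def test_dosage_model_without_selection_reduces_to_neutral(
        self, architecture, wgd
    ):
        sel = SelectionParams(w=0.0, n_e=1.4e5)
        q_dos = build_generator(
            ModelSpec(Variant.SUB_DOS, architecture, sel, wgd, 1e10)
        ).q
        q_only = build_generator(
            ModelSpec(Variant.SUB_ONLY, architecture, sel, wgd, 1e10)
        ).q
        np.testing.assert_array_equal(q_dos, q_only)

    def test_wgd_selection_slows_every_transition(self, sub_only_spec, sub_dos_spec):
        q_only = build_generator(sub_only_spec).q
        q_dos = build_generator(sub_dos_spec).q
        mask = ~np.eye(6, dtype=bool) & (q_only > 0)
        assert np.all(q_dos[mask] < q_only[mask])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        z=st.integers(2, 8),
        n_e=st.floats(1e2, 1e7),
        keq=st.floats(1e4, 1e12),
        ssd=st.booleans(),
    )
    def test_generator_invariants_across_architectures(self, z, n_e, keq, ssd):
        arch = GeneArchitecture(z=z, l_c=5e4, l_r=775, u_b=2.5e-8, u_h=2.5e-8)
        scenario = ExpressionScenario.ssd() if ssd else ExpressionScenario.wgd()
        spec = ModelSpec(Variant.SUB_DOS, arch, SelectionParams(1.0, n_e), scenario, keq)
        gen = build_generator(spec)
        q = gen.q
        assert q.shape == (z + 2, z + 2)
        assert np.abs(q.sum(axis=1)).max() <= 1e-13 * max(np.abs(q).max(), 1e-300)
        assert np.all(q[z:] == 0.0)
        assert np.all(q - np.diag(np.diag(q)) >= 0.0)


class TestPropagate:
    def test_zero_time_returns_initial(self, sub_only_spec):
        gen = build_generator(sub_only_spec)
        start = StateDistribution.point_mass(0, 6)
        assert propagate(gen, 0.0, start) is start

    def test_negative_time_rejected(self, sub_only_spec):
        gen = build_generator(sub_only_spec)
        with pytest.raises(InvalidParameterError):
            propagate(gen, -1.0, StateDistribution.point_mass(0, 6))

    def test_matches_closed_form_cascade(self, sub_only_spec, sub_dos_spec):
        for spec in (sub_only_spec, sub_dos_spec):
            gen = build_generator(spec)
            start = StateDistribution.point_mass(0, 6)
            for t in (50.0, 400.0, 3000.0):
                expected = cascade_occupancies(gen.q, gen.z, t)
                got = propagate(gen, t, start).p
                np.testing.assert_allclose(got, expected, rtol=1e-9, atol=1e-15)

    def test_distribution_stays_simplex_valued(self, sub_dos_spec):
        gen = build_generator(sub_dos_spec)
        start = StateDistribution.point_mass(0, 6)
        for t in (1.0, 400.0, 1e5, 4e6):
            p = propagate(gen, t, start).p
            assert abs(p.sum() - 1.0) < 1e-12
            assert np.all(p >= 0.0)


class TestTrajectory:
    def test_absorbing_mass_monotone_and_state0_decreasing(self, sub_dos_spec):
        times = [0.0, 100.0, 500.0, 1000.0, 5000.0]
        dists = trajectory(sub_dos_spec, times)
        s = [d.p[4] for d in dists]
        y = [d.p[5] for d in dists]
        p0 = [d.p[0] for d in dists]
        assert all(a <= b for a, b in zip(s, s[1:]))
        assert all(a <= b for a, b in zip(y, y[1:]))
        assert all(a >= b for a, b in zip(p0, p0[1:]))

    def test_unsorted_times_rejected(self, sub_only_spec):
        with pytest.raises(InvalidParameterError):
            trajectory(sub_only_spec, [100.0, 50.0])
        with pytest.raises(InvalidParameterError):
            trajectory(sub_only_spec, [-1.0, 50.0])


class TestAbsorption:
    def test_probabilities_sum_to_one(self, sub_only_spec, sub_dos_spec, sub_dos_ssd_spec):
        for spec in (sub_only_spec, sub_dos_spec, sub_dos_ssd_spec):
            gen = build_generator(spec)
            p_s, p_y = absorption_probabilities(gen, StateDistribution.point_mass(0, 6))
            assert p_s + p_y == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_long_time_exponential(self, sub_dos_spec):
        gen = build_generator(sub_dos_spec)
        start = StateDistribution.point_mass(0, 6)
        p_s, p_y = absorption_probabilities(gen, start)
        long_run = propagate(gen, 4e6, start).p
        assert p_s == pytest.approx(long_run[4], abs=1e-6)
        assert p_y == pytest.approx(long_run[5], abs=1e-6)

    def test_neutral_absorption_invariant_to_population_size(self, architecture, wgd):
        values = []
        for n_e in (1e2, 1e4, 1e6):
            spec = ModelSpec(
                Variant.SUB_ONLY, architecture, SelectionParams(1.0, n_e), wgd, 1e10
            )
            gen = build_generator(spec)
            values.append(absorption_probabilities(gen, StateDistribution.point_mass(0, 6)))
        for got in values[1:]:
            assert got == pytest.approx(values[0], rel=1e-12)


class TestNeutralInvariance:
    def test_sub_only_trajectory_invariant_to_population_size(self, architecture, wgd):
        reference = None
        for n_e in (1e2, 1e5, 1e7):
            spec = ModelSpec(
                Variant.SUB_ONLY, architecture, SelectionParams(1.0, n_e), wgd, 1e10
            )
            dists = trajectory(spec, [400.0, 2000.0])
            p = np.stack([d.p for d in dists])
            if reference is None:
                reference = p
            else:
                np.testing.assert_allclose(p, reference, rtol=1e-12)
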