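"""Γ phonons, mode decomposition, free energies and torsion profiles."""

import math

import numpy as np
import pytest

import crysvib as cv
from crysvib.constants import CM1_TO_EV, KB_EV, SQRT_EV_A2_AMU_TO_CM1
from crysvib.errors import ConfigurationError
from crysvib.harmonic import (
    PolymorphRecord,
    TorsionProfile,
    analyze_torsion_profile,
    enforce_acoustic_sum_rule,
    gamma_phonons,
)
from crysvib.structures import Crystal


def _diatomic_fc(k):
    """3N×3N force constants of two atoms joined by a spring along x."""
    fc = np.zeros((6, 6))
    block = np.diag([k, 0.0, 0.0])
    fc[0:3, 3:6] = -block
    fc[3:6, 0:3] = -block
    fc[0:3, 0:3] = block
    fc[3:6, 3:6] = block
    return fc


class TestGammaPhonons:
    def test_diatomic_closed_form(self):
        k, m1, m2 = 5.0, 12.011, 1.008
        modes = gamma_phonons(_diatomic_fc(k), [m1, m2])
        want = SQRT_EV_A2_AMU_TO_CM1 * math.sqrt(k * (1 / m1 + 1 / m2))
        nonzero = modes.frequencies[np.abs(modes.frequencies) > 1.0]
        assert len(nonzero) == 1
        assert nonzero[0] == pytest.approx(want, rel=1e-10)

    def test_three_acoustic_modes(self, toy_system):
        modes = toy_system.phonons()
        assert int(modes.acoustic.sum()) == 3
        assert np.abs(modes.frequencies[:3]).max() < 0.1

    def test_matches_independent_diagonalization(self, rng):
        """Random 12-site toy matrix vs a from-scratch eigen-decomposition."""
        n = 12
        masses = rng.uniform(1.0, 30.0, n)
        a = rng.standard_normal((3 * n, 3 * n))
        fc = a @ a.T  # symmetric PSD
        modes = gamma_phonons(fc, masses, enforce_sum_rule=False)
        # oracle: explicit M^-1/2 K M^-1/2 eigenvalues
        minv = np.diag(1.0 / np.sqrt(np.repeat(masses, 3)))
        lam = np.linalg.eigvalsh(minv @ fc @ minv)
        want = np.sort(np.sign(lam) * SQRT_EV_A2_AMU_TO_CM1 * np.sqrt(np.abs(lam)))
        np.testing.assert_allclose(modes.frequencies, want, rtol=1e-8, atol=1e-8)

    def test_eigenvectors_orthonormal(self, toy_system):
        e = toy_system.phonons().eigenvectors
        np.testing.assert_allclose(e @ e.T, np.eye(len(e)), atol=1e-8)

    def test_asymmetric_matrix_rejected(self):
        fc = _diatomic_fc(3.0)
        fc[0, 5] += 1.0
        with pytest.raises(ConfigurationError):
            gamma_phonons(fc, [1.0, 2.0])

    def test_negative_eigenvalues_flagged_not_dropped(self):
        fc = -_diatomic_fc(2.0)  # unstable spring
        modes = gamma_phonons(fc, [1.0, 1.0], enforce_sum_rule=False)
        assert int(modes.imaginary.sum()) == 1
        assert len(modes.frequencies) == 6

    def test_sum_rule_enforcement_touches_only_self_blocks(self, rng):
        """On a random pair-spring network (symmetric 3×3 pair blocks, the
        physical class), enforcement changes only self-terms and leaves
        exactly three near-zero acoustic modes."""
        n = 5
        fc = np.zeros((3 * n, 3 * n))
        for i in range(n):
            for j in range(i + 1, n):
                nhat = rng.standard_normal(3)
                nhat /= np.linalg.norm(nhat)
                kl = rng.uniform(0.5, 5.0)
                block = kl * np.outer(nhat, nhat) + 0.2 * kl * np.eye(3)
                fc[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = -block
                fc[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = -block
        # garbage on the diagonal that enforcement must overwrite
        for i in range(n):
            fc[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = rng.standard_normal((3, 3))
        fc = 0.5 * (fc + fc.T)
        out = enforce_acoustic_sum_rule(fc)
        for i in range(n):
            for j in range(n):
                if i != j:
                    np.testing.assert_array_equal(
                        out[3 * i : 3 * i + 3, 3 * j : 3 * j + 3],
                        fc[3 * i : 3 * i + 3, 3 * j : 3 * j + 3],
                    )
        modes = gamma_phonons(out, rng.uniform(1, 20, n), enforce_sum_rule=False)
        assert np.abs(np.sort(np.abs(modes.frequencies))[:3]).max() < 0.1
        assert np.sort(np.abs(modes.frequencies))[3] > 1.0


class TestDecomposeModes:
    def test_uniform_translation_is_pure_translational(self, toy_system):
        modes = toy_system.phonons()
        pct = cv.decompose_modes(modes, toy_system.crystal)
        for k in np.nonzero(modes.acoustic)[0]:
            assert pct[k, 0] == pytest.approx(100.0, abs=1e-6)

    def test_diatomic_stretch_is_pure_internal(self):
        c = Crystal(np.eye(3) * 12, ["C", "O"],
                    np.array([[0.3, 0.3, 0.3], [0.42, 0.3, 0.3]]))
        modes = gamma_phonons(_diatomic_fc(4.0), c.masses)
        pct = cv.decompose_modes(modes, c)
        stretch = np.argmax(modes.frequencies)
        # the optical stretch of an isolated diatomic is orthogonal to the
        # rigid-body space of the two-atom "molecule" except for rotation:
        # for a diatomic the bond-stretch is orthogonal to both rotations
        assert pct[stretch, 2] == pytest.approx(100.0, abs=1e-6)

    def test_percentages_sum_to_100(self, toy_system):
        pct = cv.decompose_modes(toy_system.phonons(), toy_system.crystal)
        np.testing.assert_allclose(pct.sum(axis=1), 100.0, atol=1e-8)
        assert np.all(pct >= -1e-10) and np.all(pct <= 100 + 1e-10)

    def test_matches_explicit_projector_oracle(self, toy_system, rng):
        """Random orthonormal vectors: percentages equal squared projections
        onto an independently constructed projector."""
        from crysvib.harmonic import _rigid_body_basis

        crystal = toy_system.crystal
        masses = crystal.masses
        t_basis, r_basis = _rigid_body_basis(crystal, masses)
        pt_proj = t_basis @ t_basis.T
        pr_proj = r_basis @ r_basis.T
        n3 = 3 * crystal.n_sites
        q, _ = np.linalg.qr(rng.standard_normal((n3, n3)))
        modes = cv.PhononModes(np.arange(n3, dtype=float) + 1.0, q.T, masses)
        pct = cv.decompose_modes(modes, crystal)
        for k in range(0, n3, 5):
            v = q[:, k]
            assert pct[k, 0] == pytest.approx(100 * v @ pt_proj @ v, abs=1e-10)
            assert pct[k, 1] == pytest.approx(100 * v @ pr_proj @ v, abs=1e-10)

    def test_completeness_of_rigid_body_fraction(self, toy_system):
        """Σ_modes translational% / (100·3N) equals the translational
        subspace dimension fraction."""
        crystal = toy_system.crystal
        pct = cv.decompose_modes(toy_system.phonons(), crystal)
        n3 = 3 * crystal.n_sites
        n_trans = 3 * len(crystal.get_molecules())
        assert pct[:, 0].sum() / 100.0 == pytest.approx(n_trans, abs=1e-8)


class TestVibrationalFreeEnergy:
    def test_empty_mode_list_is_zero(self):
        assert cv.vibrational_free_energy([], 300.0) == 0.0

    def test_zero_temperature_is_zpe(self):
        f, zpe = cv.vibrational_free_energy([100.0], 0.0, return_zpe=True)
        assert f == zpe == pytest.approx(0.5 * 100.0 * CM1_TO_EV, rel=1e-12)

    def test_closed_form_single_mode_300K(self):
        """Independent evaluation of ħω/2 + kT ln(1−e^(−ħω/kT))."""
        nu, t = 100.0, 300.0
        hw = nu * CM1_TO_EV
        want = 0.5 * hw + KB_EV * t * math.log(1.0 - math.exp(-hw / (KB_EV * t)))
        got = cv.vibrational_free_energy([nu], t)
        assert got == pytest.approx(want, rel=1e-12)

    def test_monotonically_decreasing_in_temperature(self):
        freqs = [30.0, 120.0, 850.0]
        temps = np.linspace(1.0, 900.0, 40)
        vals = [cv.vibrational_free_energy(freqs, t) for t in temps]
        assert np.all(np.diff(vals) < 0)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ConfigurationError):
            cv.vibrational_free_energy([-5.0, 100.0], 300.0)


class TestStabilityCurves:
    def test_reference_vs_itself_is_zero(self):
        rec = PolymorphRecord("a", -100.0, 500.0, [50.0, 120.0], 4)
        curve = cv.relative_stability_curves(
            [rec], "a", np.linspace(0, 7, 15), 300.0
        )
        np.testing.assert_array_equal(curve.delta_g["a"], 0.0)

    def test_analytic_crossover_pressure(self):
        """ΔE = δ with constant ΔV crosses at P* = −δ/ΔV exactly."""
        from crysvib.constants import GPA_A3_TO_EV

        delta_e = 0.10   # eV
        dv = -25.0       # Å³ (denser polymorph, higher energy)
        p_star = -delta_e / (dv * GPA_A3_TO_EV)
        recs = [
            PolymorphRecord("ref", 0.0, 500.0, [60.0], 1),
            PolymorphRecord("hp", delta_e, 500.0 + dv, [60.0], 1),
        ]
        grid = np.linspace(0.0, 2 * p_star, 201)
        curve = cv.relative_stability_curves(recs, "ref", grid, 300.0)
        assert len(curve.crossovers) == 1
        assert curve.crossovers[0][2] == pytest.approx(p_star, rel=1e-6)

    def test_phonon_term_additivity(self):
        """Curves with/without phonons differ by exactly ΔF_vib."""
        recs = [
            PolymorphRecord("ref", 0.0, 500.0, [60.0, 200.0], 2),
            PolymorphRecord("b", 0.02, 480.0, [80.0, 260.0], 2),
        ]
        grid = np.linspace(0, 5, 11)
        t = 300.0
        with_ph = cv.relative_stability_curves(recs, "ref", grid, t)
        without = cv.relative_stability_curves(
            recs, "ref", grid, t, include_phonons=False
        )
        from crysvib.constants import EV_TO_KJMOL

        df = (
            cv.vibrational_free_energy([80.0, 260.0], t)
            - cv.vibrational_free_energy([60.0, 200.0], t)
        ) * EV_TO_KJMOL / 2
        np.testing.assert_allclose(
            with_ph.delta_g["b"] - without.delta_g["b"], df, atol=1e-12
        )

    def test_identical_records_give_zero_curves(self):
        recs = [
            PolymorphRecord("a", -5.0, 400.0, [75.0], 2),
            PolymorphRecord("b", -5.0, 400.0, [75.0], 2),
        ]
        curve = cv.relative_stability_curves(recs, "a", np.linspace(0, 7, 8), 300.0)
        np.testing.assert_allclose(curve.delta_g["b"], 0.0, atol=1e-12)


class TestTorsionProfile:
    def test_single_cosine_closed_form(self):
        """V = K(1 − cos(τ − τ0)) at 10° steps: one minimum at τ0, barrier
        2K at τ0 + 180°."""
        k_amp, tau0 = 3.1, 40.0
        angles = np.arange(-180.0, 180.0, 10.0)
        energies = k_amp * (1 - np.cos(np.radians(angles - tau0)))
        minima, barriers = analyze_torsion_profile(TorsionProfile(angles, energies))
        assert len(minima) == 1
        assert minima[0].angle == pytest.approx(tau0)
        assert len(barriers) == 1
        assert barriers[0].height == pytest.approx(2 * k_amp, rel=1e-12)
        assert barriers[0].at_angle == pytest.approx(tau0 - 180.0)

    def test_two_well_matches_brute_force_scan(self, rng):
        from crysvib.synthetic import cosine_series, two_well_coefficients

        co = two_well_coefficients()
        angles = np.arange(-180.0, 180.0, 10.0)
        e = cosine_series(co, np.radians(angles))
        e = e - e.min()
        minima, barriers = analyze_torsion_profile(TorsionProfile(angles, e))
        # oracle: exhaustive scan over every grid path between each pair
        n = len(e)
        min_idx = [
            i for i in range(n)
            if e[i] <= e[(i - 1) % n] and e[i] <= e[(i + 1) % n]
        ]
        assert sorted(m.angle for m in minima) == sorted(
            angles[i] for i in min_idx
        )
        # each ordered pair is reported once per connecting arc; the set of
        # heights must equal the brute-force arc maxima above the departure
        for a0, a1 in [(minima[0].angle, minima[1].angle),
                       (minima[1].angle, minima[0].angle)]:
            i0 = int(np.where(angles == a0)[0][0])
            i1 = int(np.where(angles == a1)[0][0])
            fwd = [(i0 + s) % n for s in range((i1 - i0) % n + 1)]
            bwd = [(i1 + s) % n for s in range((i0 - i1) % n + 1)]
            want = {
                round(max(e[fwd]) - e[i0], 9),
                round(max(e[bwd]) - e[i0], 9),
            }
            got = {
                round(b.height, 9)
                for b in barriers
                if b.from_angle == a0 and b.to_angle == a1
            }
            assert got == want

    def test_constructed_profile_with_offset_and_barrier(self):
        """A profile built with minima at +75° and −70°, offset 1.9 kJ/mol
        and ~4.8 kJ/mol barrier, reports exactly that geometry."""
        from crysvib.synthetic import cosine_series, two_well_coefficients

        co = two_well_coefficients(min_a=75.0, min_b=-70.0, offset=1.9,
                                   barrier=4.8, barrier_angle=0.0)
        angles = np.arange(-180.0, 181.0, 5.0)  # closed grid incl. +180
        e = cosine_series(co, np.radians(angles))
        e = e - e.min()
        prof = TorsionProfile(angles, e)
        minima, barriers = analyze_torsion_profile(prof)
        by_angle = {round(m.angle): m for m in minima}
        assert 75 in by_angle and -70 in by_angle
        assert by_angle[75].energy == pytest.approx(0.0, abs=1e-12)
        assert by_angle[-70].energy == pytest.approx(1.9, abs=0.05)
        up = [b for b in barriers if b.from_angle == 75.0 and b.to_angle == -70.0]
        assert up and min(b.height for b in up) == pytest.approx(4.8, abs=0.2)

    def test_flat_profile_reports_no_minima(self):
        angles = np.arange(-180.0, 180.0, 10.0)
        minima, barriers = analyze_torsion_profile(
            TorsionProfile(angles, np.zeros_like(angles))
        )
        assert minima == [] and barriers == []

    def test_periodic_closure_violation_rejected(self):
        angles = np.arange(-180.0, 181.0, 10.0)
        e = np.linspace(0, 5, len(angles))  # endpoints disagree
        with pytest.raises(ConfigurationError):
            TorsionProfile(angles, e)
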