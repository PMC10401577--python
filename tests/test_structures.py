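"""Crystal model, torsion geometry, motif classification and disorder builds."""

import math

import numpy as np
import pytest
from scipy.stats import chisquare

import crysvib as cv
from crysvib.errors import (
    ConfigurationError,
    InvalidDonorError,
    TopologyError,
    UndefinedDihedralError,
)
from crysvib.structures import (
    Crystal,
    TorsionSpec,
    wrap_angle,
    _dihedral_from_points,
)


def _chain_crystal(points, symbols=None, box=20.0):
    """Open-boundary-ish crystal: a big box so minimum image is trivial."""
    points = np.asarray(points, dtype=float)
    lattice = np.eye(3) * box
    return Crystal(lattice, symbols or ["C"] * len(points), points / box)


def _oracle_dihedral(p0, p1, p2, p3):
    """Independent signed-dihedral oracle via plane normals:
    τ = atan2((n1×n2)·b̂, n1·n2) — cross-checked against mdtraj's
    compute_dihedrals convention."""
    n1 = np.cross(p1 - p0, p2 - p1)
    n2 = np.cross(p2 - p1, p3 - p2)
    bu = (p2 - p1) / np.linalg.norm(p2 - p1)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), bu)
    return math.degrees(math.atan2(y, x))


class TestLattice:
    def test_parameter_round_trip(self, rng):
        for _ in range(20):
            a, b, c = rng.uniform(3, 15, 3)
            al, be, ga = rng.uniform(70, 110, 3)
            m = cv.lattice_from_parameters(a, b, c, al, be, ga)
            back = cv.lattice_parameters(m)
            np.testing.assert_allclose(back, (a, b, c, al, be, ga), atol=1e-9)

    def test_closed_form_volume_matches_determinant(self, rng):
        for _ in range(20):
            a, b, c = rng.uniform(3, 15, 3)
            al, be, ga = rng.uniform(70, 110, 3)
            m = cv.lattice_from_parameters(a, b, c, al, be, ga)
            assert cv.cell_volume(a, b, c, al, be, ga) == pytest.approx(
                abs(np.linalg.det(m)), rel=1e-12
            )


class TestCrystal:
    def test_coordinates_wrapped(self):
        c = Crystal(np.eye(3) * 10, ["C"], [[1.25, -0.5, 0.999]])
        assert np.all(c.frac_coords >= 0) and np.all(c.frac_coords < 1)
        np.testing.assert_allclose(c.frac_coords[0], [0.25, 0.5, 0.999])

    def test_unknown_element_rejected(self):
        with pytest.raises(Exception, match="unknown element"):
            Crystal(np.eye(3) * 10, ["Xq"], [[0, 0, 0]])

    def test_partition_must_cover_sites(self):
        with pytest.raises(ConfigurationError):
            Crystal(np.eye(3) * 10, ["C", "C"], [[0, 0, 0], [0.1, 0, 0]],
                    molecules=[[0]])

    def test_molecular_partition_matches_bfs_oracle(self, toy_system):
        """Inferred molecules equal connected components of a hand-built
        covalent-bond adjacency, found by breadth-first search."""
        crystal = toy_system.crystal.copy()
        crystal.molecules = None
        from crysvib.elements import BOND_TOLERANCE, COVALENT_RADIUS

        n = crystal.n_sites
        adj = {i: [] for i in range(n)}
        for i in range(n):
            for j in range(i + 1, n):
                cut = BOND_TOLERANCE * (
                    COVALENT_RADIUS[crystal.symbols[i]]
                    + COVALENT_RADIUS[crystal.symbols[j]]
                )
                if crystal.distance(i, j) < cut:
                    adj[i].append(j)
                    adj[j].append(i)
        seen, comps = set(), []
        for s in range(n):
            if s in seen:
                continue
            comp, queue = [], [s]
            seen.add(s)
            while queue:
                i = queue.pop(0)
                comp.append(i)
                for j in adj[i]:
                    if j not in seen:
                        seen.add(j)
                        queue.append(j)
            comps.append(sorted(comp))
        assert sorted(crystal.infer_molecules()) == sorted(comps)
        assert len(comps) == 2


class TestMeasureTorsion:
    def test_planar_eclipsed_chain_is_cis_zero(self):
        pts = [[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]]
        c = _chain_crystal(pts)
        assert cv.measure_torsion(c, TorsionSpec(0, 1, 2, 3)) == pytest.approx(0.0)

    def test_constructed_rotation_round_trip(self):
        """A geometry built by explicit rotation to 77.6° measures 77.6°."""
        base = np.array([[0, 1.0, 0], [0, 0, 0], [1.5, 0, 0], [1.5, 1.0, 0]])
        tau = math.radians(77.6)
        rot = np.array(
            [[1, 0, 0], [0, math.cos(tau), -math.sin(tau)],
             [0, math.sin(tau), math.cos(tau)]]
        )
        base[3] = base[2] + rot @ (base[3] - base[2])
        c = _chain_crystal(base)
        assert cv.measure_torsion(c, TorsionSpec(0, 1, 2, 3)) == pytest.approx(
            77.6, abs=1e-6
        )

    def test_agrees_with_plane_normal_oracle(self, rng):
        for _ in range(50):
            pts = rng.uniform(2.0, 8.0, (4, 3))
            try:
                got = cv.measure_torsion(_chain_crystal(pts), TorsionSpec(0, 1, 2, 3))
            except UndefinedDihedralError:
                continue
            want = _oracle_dihedral(*pts)
            assert abs(wrap_angle(got - want)) < 1e-9

    def test_invariant_under_lattice_translation(self, rng):
        pts = np.array([[0, 1.0, 0], [0, 0, 0], [1.5, 0, 0], [1.8, 1.0, 0.7]])
        c = _chain_crystal(pts, box=12.0)
        ref = cv.measure_torsion(c, TorsionSpec(0, 1, 2, 3))
        for _ in range(10):
            shifted = c.copy()
            i = rng.integers(0, 4)
            shifted.frac_coords[i] = (shifted.frac_coords[i] + rng.integers(-2, 3, 3)) % 1.0
            assert cv.measure_torsion(shifted, TorsionSpec(0, 1, 2, 3)) == pytest.approx(
                ref, abs=1e-9
            )

    def test_collinear_raises(self):
        pts = [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]]
        with pytest.raises(UndefinedDihedralError):
            cv.measure_torsion(_chain_crystal(pts), TorsionSpec(0, 1, 2, 3))


class TestSetTorsion:
    def _thiol(self):
        from crysvib.synthetic import _molecule_template

        return _chain_crystal(_molecule_template(77.6) + 8.0,
                              symbols=["C", "C", "S", "H"])

    def test_set_to_current_is_identity(self):
        c = self._thiol()
        spec = TorsionSpec(0, 1, 2, 3)
        cur = cv.measure_torsion(c, spec)
        out = cv.set_torsion(c, spec, cur)
        np.testing.assert_allclose(out.frac_coords, c.frac_coords, atol=1e-12)

    def test_motif_swap_moves_only_the_thiol_hydrogen(self):
        """77.6° → −85.4° (the SH···S → SH···O swap) displaces only H."""
        c = self._thiol()
        spec = TorsionSpec(0, 1, 2, 3)
        out = cv.set_torsion(c, spec, -85.4)
        assert cv.measure_torsion(out, spec) == pytest.approx(-85.4, abs=1e-6)
        moved = np.abs(out.frac_coords - c.frac_coords).sum(axis=1) > 1e-10
        assert list(np.nonzero(moved)[0]) == [3]

    def test_bond_lengths_and_angles_preserved(self):
        c = self._thiol()
        out = cv.set_torsion(c, TorsionSpec(0, 1, 2, 3), -85.4)
        for i, j in [(0, 1), (1, 2), (2, 3)]:
            assert out.distance(i, j) == pytest.approx(c.distance(i, j), abs=1e-9)
        # the C–S–H angle (involves the rotated atom but not the torsion value)
        def angle(cr, i, j, k):
            v1, v2 = cr.mic_vector(j, i), cr.mic_vector(j, k)
            return math.degrees(
                math.acos(np.dot(v1, v2) / np.linalg.norm(v1) / np.linalg.norm(v2))
            )
        assert angle(out, 1, 2, 3) == pytest.approx(angle(c, 1, 2, 3), abs=1e-7)

    def test_set_then_set_back_restores_coordinates(self):
        c = self._thiol()
        spec = TorsionSpec(0, 1, 2, 3)
        orig = cv.measure_torsion(c, spec)
        there = cv.set_torsion(c, spec, -123.4)
        back = cv.set_torsion(there, spec, orig)
        np.testing.assert_allclose(back.frac_coords, c.frac_coords, atol=1e-9)

    def test_round_trip_many_random_targets(self, rng):
        c = self._thiol()
        spec = TorsionSpec(0, 1, 2, 3)
        for target in rng.uniform(-180.0, 180.0, 300):
            target = wrap_angle(target)
            out = cv.set_torsion(c, spec, target)
            assert abs(wrap_angle(cv.measure_torsion(out, spec) - target)) < 1e-6

    def test_ring_rotation_raises_topology_error(self):
        # a 4-ring: rotating any ring bond would tear it
        pts = np.array([[0, 0, 0], [1.4, 0, 0], [1.4, 1.4, 0], [0, 1.4, 0]])
        c = _chain_crystal(pts + 8.0, symbols=["C"] * 4, box=20.0)
        with pytest.raises(TopologyError):
            cv.set_torsion(c, TorsionSpec(0, 1, 2, 3), 30.0)


class TestSupercell:
    def test_identity(self, toy_system):
        out = cv.build_supercell(toy_system.crystal, (1, 1, 1))
        np.testing.assert_allclose(out.lattice, toy_system.crystal.lattice)
        np.testing.assert_allclose(out.frac_coords, toy_system.crystal.frac_coords)

    def test_2x2x2_of_four_molecules_gives_32(self):
        sys4 = cv.make_toy_molecular_crystal(4, seed=7)
        sc = cv.build_supercell(sys4.crystal, (2, 2, 2))
        assert len(sc.get_molecules()) == 32
        assert sc.volume == pytest.approx(8 * sys4.crystal.volume, rel=1e-12)
        assert sc.n_sites == 8 * sys4.crystal.n_sites

    def test_all_parent_images_present_by_enumeration(self, toy_system):
        """Exhaustive coordinate enumeration oracle for a (2,1,3) supercell."""
        parent = toy_system.crystal
        sc = cv.build_supercell(parent, (2, 1, 3))
        mults = np.array([2, 1, 3], dtype=float)
        expected = set()
        for fr in parent.frac_coords:
            for i in range(2):
                for j in range(1):
                    for k in range(3):
                        img = (fr + [i, j, k]) / mults
                        expected.add(tuple(np.round(img % 1.0, 8)))
        got = {tuple(np.round(fr, 8)) for fr in sc.frac_coords}
        assert got == expected


class TestMotifClassification:
    def _host(self, extra_sites, box=14.0):
        """A thiol fragment plus explicitly placed acceptor atoms."""
        from crysvib.synthetic import _molecule_template

        pts = list(_molecule_template(87.0) + 5.0)
        symbols = ["C", "C", "S", "H"]
        for sym, p in extra_sites:
            symbols.append(sym)
            pts.append(np.asarray(p, dtype=float))
        return _chain_crystal(np.array(pts), symbols, box=box)

    def test_nearest_acceptor_by_construction(self):
        c = self._host([])
        h = c.frac_coords[3] * 14.0
        c2 = self._host(
            [("S", h + [2.0, 0, 0]), ("O", h + [0, 3.5, 0])]
        )
        res = cv.classify_sh_motif(c2, 3, cutoff=4.0)
        assert res.motif == "SH...S"
        assert res.distance == pytest.approx(2.0, abs=0.05)

    def test_no_acceptor_within_cutoff_is_none(self):
        res = cv.classify_sh_motif(self._host([]), 3, cutoff=3.0)
        assert res.motif == "none"

    def test_invalid_donor_raises(self):
        c = self._host([])
        with pytest.raises(InvalidDonorError):
            cv.classify_sh_motif(c, 0)

    def test_matches_brute_force_periodic_image_scan(self, rng):
        """20 random acceptor placements vs an exhaustive all-images oracle."""
        for trial in range(20):
            extra = []
            for _ in range(3):
                sym = "S" if rng.random() < 0.5 else "O"
                extra.append((sym, rng.uniform(0.0, 14.0, 3)))
            c = self._host(extra, box=14.0)
            cutoff = 6.0
            res = cv.classify_sh_motif(c, 3, cutoff=cutoff)
            # oracle: scan every acceptor over a generous image block
            h = c.frac_coords[3] @ c.lattice
            best = (np.inf, None)
            for j, sym in enumerate(c.symbols):
                if sym not in ("S", "O") or j == 2:
                    continue
                for na in range(-2, 3):
                    for nb in range(-2, 3):
                        for nc in range(-2, 3):
                            p = (c.frac_coords[j] + [na, nb, nc]) @ c.lattice
                            d = np.linalg.norm(p - h)
                            if d <= cutoff and d < best[0]:
                                best = (d, sym)
            want = (
                "none" if best[1] is None
                else ("SH...S" if best[1] == "S" else "SH...O")
            )
            assert res.motif == want
            if best[1] is not None:
                assert res.distance == pytest.approx(best[0], abs=1e-9)


class TestDisorderModel:
    def _supercell_with_torsions(self, n_parent=4, mult=(2, 2, 2)):
        sys4 = cv.make_toy_molecular_crystal(n_parent, seed=7)
        sc = cv.build_supercell(sys4.crystal, mult)
        specs = [TorsionSpec(*m[:4]) for m in sc.get_molecules()]
        return sc, specs

    def test_half_half_assignment_is_exact(self):
        sc, specs = self._supercell_with_torsions()
        out, plan = cv.generate_disorder_model(
            sc, specs, angles=(-78.4, 87.0), fraction=0.5, seed=0
        )
        assert plan.n_at == {-78.4: 16, 87.0: 16}
        for spec, ang in plan.assignments:
            assert cv.measure_torsion(out, spec) == pytest.approx(ang, abs=1e-6)

    def test_fraction_zero_gives_single_motif_cell(self):
        sys2 = cv.make_toy_molecular_crystal(2, seed=3)
        specs = [TorsionSpec(*m[:4]) for m in sys2.crystal.get_molecules()]
        out, plan = cv.generate_disorder_model(
            sys2.crystal, specs, angles=(-78.4, 87.0), fraction=0.0, seed=5
        )
        assert plan.n_at == {87.0: len(specs)}
        angles = [cv.measure_torsion(out, s) for s in specs]
        assert np.allclose(angles, 87.0, atol=1e-6)

    def test_duplicate_specs_rejected(self):
        sc, specs = self._supercell_with_torsions(2, (1, 1, 1))
        with pytest.raises(ConfigurationError):
            cv.generate_disorder_model(sc, specs + [specs[0]], fraction=0.5, seed=0)

    def test_reproducible_for_fixed_seed(self):
        sc, specs = self._supercell_with_torsions(2, (2, 1, 1))
        _, p1 = cv.generate_disorder_model(sc, specs, fraction=0.5, seed=42)
        _, p2 = cv.generate_disorder_model(sc, specs, fraction=0.5, seed=42)
        assert p1 == p2

    def test_selection_uniform_over_subsets(self):
        """4 torsions, fraction 0.5: the chosen pair covers all C(4,2)=6
        subsets uniformly over seeds (chi-square p > 0.01)."""
        sys4 = cv.make_toy_molecular_crystal(4, seed=7)
        specs = [TorsionSpec(*m[:4]) for m in sys4.crystal.get_molecules()]
        counts = {}
        for seed in range(600):
            _, plan = cv.generate_disorder_model(
                sys4.crystal, specs, fraction=0.5, seed=seed
            )
            key = tuple(sorted(
                i for i, (_, ang) in enumerate(plan.assignments) if ang == -78.4
            ))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        stat, p = chisquare(list(counts.values()))
        assert p > 0.01
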