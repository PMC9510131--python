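import itertools

import numpy as np
import pytest

import oracles
from cma import assembly, fixtures
from cma.assembly import (
    ClashCriterion,
    align_axes,
    compose_hybrid,
    detect_c2_axis,
    detect_clashes,
    min_separation,
    scan_dihedral,
)
from cma.errors import InfeasibleAssemblyError, NoAxisError, UsageError
from cma.geometry import RigidTransform, kabsch, rotation_about_axis
from cma.structio import DomainSpec, StructureModel


def angle_between(u, v):
    """Unsigned angle between two axis directions, in degrees."""
    c = abs(float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(min(c, 1.0))))


def pairwise_distances(coords, k=200, seed=0):
    rng = np.random.default_rng(seed)
    n = len(coords)
    i = rng.integers(0, n, size=k)
    j = rng.integers(0, n, size=k)
    return np.linalg.norm(coords[i] - coords[j], axis=1)


class TestDetectC2Axis:
    def test_exact_fixture(self):
        model, truth = fixtures.make_c2_dimer(fixtures.FixtureSpec(seed=0))
        axis = detect_c2_axis(model, "A", "B")
        assert axis.rotation_angle == pytest.approx(180.0, abs=1e-6)
        assert angle_between(axis.direction, truth.direction) < np.degrees(1e-6)
        assert axis.residual_rmsd < 1e-9

    def test_noisy_fixture_within_half_degree(self):
        spec = fixtures.FixtureSpec(noise_sigma=0.2, seed=7)
        model, truth = fixtures.make_c2_dimer(spec)
        axis = detect_c2_axis(model, "A", "B")
        assert angle_between(axis.direction, truth.direction) < 0.5

    @pytest.mark.parametrize("sigma", [0.2, 0.3])
    def test_20_seeds_recovery(self, sigma):
        """(direction, angle) recovered within (0.5, 0.5) degrees across
        20 seeds; needs a fixture with 3-D spread (a thin helical rod is
        weakly constrained against rotation about its own axis)."""
        for seed in range(20):
            spec = fixtures.FixtureSpec(
                geometry="blob",
                n_residues_per_domain=200,
                noise_sigma=sigma,
                seed=seed,
                separation=20.0,
                axis_direction=(0.3, -0.5, 0.81),
            )
            model, truth = fixtures.make_c2_dimer(spec)
            axis = detect_c2_axis(model, "A", "B")
            assert angle_between(axis.direction, truth.direction) < 0.5
            assert abs(axis.rotation_angle - 180.0) < 0.5

    def test_brute_force_grid_cross_check(self):
        """Axis direction agrees with an exhaustive orientation search
        minimising post-rotation RMSD of chain A onto chain B."""
        spec = fixtures.FixtureSpec(noise_sigma=0.2, seed=7, n_residues_per_domain=12)
        model, truth = fixtures.make_c2_dimer(spec)
        axis = detect_c2_axis(model, "A", "B")

        ca = np.array(
            [r.get_atom("CA").coords for r in model.get_chain("A").residues]
        )
        cb = np.array(
            [r.get_atom("CA").coords for r in model.get_chain("B").residues]
        )
        center = np.vstack([ca, cb]).mean(axis=0)

        best_dir, best_rmsd = None, np.inf
        for theta in np.linspace(0, np.pi, 60):
            for phi in np.linspace(0, 2 * np.pi, 120, endpoint=False):
                d = np.array(
                    [
                        np.sin(theta) * np.cos(phi),
                        np.sin(theta) * np.sin(phi),
                        np.cos(theta),
                    ]
                )
                rot = rotation_about_axis(d, center, 180.0)
                r = np.sqrt(np.mean(np.sum((rot.apply(ca) - cb) ** 2, axis=1)))
                if r < best_rmsd:
                    best_rmsd, best_dir = r, d
        assert angle_between(axis.direction, best_dir) < 3.0  # grid resolution

    def test_involution(self):
        model, _ = fixtures.make_c2_dimer(fixtures.FixtureSpec(seed=3))
        axis = detect_c2_axis(model, "A", "B")
        t = axis.transform()
        coords = model.coords()
        twice = t.apply(t.apply(coords))
        assert np.abs(twice - coords).max() < 1e-6

    def test_too_few_pairs(self):
        pts = [(0.0, 0.0, 0.0), (3.8, 0.0, 0.0)]
        a = fixtures.model_from_points(pts, "A", atom_name="CA").chains[0]
        b = fixtures.model_from_points(pts, "B", atom_name="CA").chains[0]
        with pytest.raises(NoAxisError):
            detect_c2_axis(StructureModel([a, b]), "A", "B")

    def test_near_identity_rotation(self):
        chain_a = fixtures.build_helix_chain(10, "A")
        chain_b = fixtures.build_helix_chain(10, "B", origin=(30.0, 0.0, 0.0))
        with pytest.raises(NoAxisError):
            detect_c2_axis(StructureModel([chain_a, chain_b]), "A", "B")


class TestAlignAxes:
    def _parts(self):
        part_a, _ = fixtures.make_c2_dimer(fixtures.FixtureSpec(seed=1))
        part_b, _ = fixtures.make_c2_dimer(
            fixtures.FixtureSpec(
                seed=2, axis_direction=(1.0, 1.0, 0.2), axis_point=(7.0, -4.0, 2.0)
            )
        )
        return part_a, part_b

    def test_axes_collinear_after_alignment(self):
        part_a, part_b = self._parts()
        axis_a = detect_c2_axis(part_a, "A", "B")
        axis_b = detect_c2_axis(part_b, "A", "B")
        moved, _ = align_axes(part_a, axis_a, part_b, axis_b)
        axis_b2 = detect_c2_axis(moved, "A", "B")
        assert angle_between(axis_b2.direction, axis_a.direction) < np.degrees(1e-6)
        offset = axis_b2.point - axis_a.point
        perp = offset - np.dot(offset, axis_a.direction) * axis_a.direction
        assert np.linalg.norm(perp) < 1e-6

    def test_already_aligned_is_identity(self):
        part_a, _ = self._parts()
        axis_a = detect_c2_axis(part_a, "A", "B")
        moved, transform = align_axes(part_a, axis_a, part_a.copy(), axis_a)
        assert transform.is_identity(atol=1e-9)
        assert np.allclose(moved.coords(), part_a.coords(), atol=1e-9)

    def test_rigidity(self):
        part_a, part_b = self._parts()
        axis_a = detect_c2_axis(part_a, "A", "B")
        axis_b = detect_c2_axis(part_b, "A", "B")
        moved, _ = align_axes(part_a, axis_a, part_b, axis_b)
        before = pairwise_distances(part_b.coords())
        after = pairwise_distances(moved.coords())
        assert np.abs(before - after).max() < 1e-6


class TestDetectClashes:
    def test_two_carbons_clash_arithmetic(self):
        a = fixtures.model_from_points([(0.0, 0.0, 0.0)], "A")
        b = fixtures.model_from_points([(2.0, 0.0, 0.0)], "B")
        model = StructureModel([a.chains[0], b.chains[0]])
        report = detect_clashes(model, ["A"], ["B"])
        assert report.clash_count == 1  # 2.0 < 1.7 + 1.7 - 0.4
        assert report.min_distance == pytest.approx(2.0)

    def test_two_carbons_no_clash(self):
        a = fixtures.model_from_points([(0.0, 0.0, 0.0)], "A")
        b = fixtures.model_from_points([(3.2, 0.0, 0.0)], "B")
        model = StructureModel([a.chains[0], b.chains[0]])
        assert detect_clashes(model, ["A"], ["B"]).clash_count == 0

    def test_matches_brute_force_on_500_atoms(self):
        model, _ = fixtures.make_topology_dimer(
            "crossed",
            fixtures.FixtureSpec(
                geometry="blob", n_residues_per_domain=125, noise_sigma=0.8, seed=13
            ),
        )
        assert model.n_atoms == 500
        report = detect_clashes(model, ["A"], ["B"])
        brute = oracles.brute_clashes(model, ["A"], ["B"])
        mine = {
            (ra.key, na, rb.key, nb) for (ra, na), (rb, nb), _ in report.clash_pairs
        }
        assert mine == {(ka, na, kb, nb) for ka, na, kb, nb, _ in brute}

    def test_symmetric(self, bound_blob_dimer):
        model, _ = bound_blob_dimer
        ab = detect_clashes(model, ["A"], ["B"])
        ba = detect_clashes(model, ["B"], ["A"])
        assert ab.clash_count == ba.clash_count
        assert ab.min_distance == pytest.approx(ba.min_distance)


class TestMinSeparation:
    def test_two_single_atoms_analytic(self):
        a = fixtures.model_from_points([(0.0, 0.0, 0.0)], "A")
        b = fixtures.model_from_points([(0.0, 0.0, 10.0)], "B")
        axis = assembly.SymmetryAxis((0, 0, 1), (0, 0, 0), 180.0, 0.0)
        criterion = ClashCriterion(fixed_cutoff=3.0)
        result = min_separation(a, b, axis, criterion)
        assert result.separation == pytest.approx(3.0, abs=0.1)
        assert result.clash_report.clash_count == 0

    def test_rings_match_fine_brute_force(self):
        theta = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        ring = np.column_stack((4 * np.cos(theta), 4 * np.sin(theta), np.zeros(10)))
        a = fixtures.model_from_points(ring, "A")
        # second ring rotated half a step so the atoms interleave
        ring_b = np.column_stack(
            (
                4 * np.cos(theta + np.pi / 10),
                4 * np.sin(theta + np.pi / 10),
                np.full(10, 20.0),
            )
        )
        b = fixtures.model_from_points(ring_b, "B")
        axis = assembly.SymmetryAxis((0, 0, 1), (0, 0, 0), 180.0, 0.0)
        result = min_separation(a, b, axis, step=0.1)
        brute = oracles.brute_min_separation(a, b, (0, 0, 1), step=0.01)
        assert result.separation == pytest.approx(brute, abs=0.1)

    def test_never_clashing_gives_zero(self):
        """Parts offset laterally never clash at any axial separation."""
        a = fixtures.model_from_points([(0.0, 0.0, 0.0)], "A")
        b = fixtures.model_from_points([(50.0, 0.0, 10.0)], "B")
        axis = assembly.SymmetryAxis((0, 0, 1), (0, 0, 0), 180.0, 0.0)
        result = min_separation(a, b, axis)
        assert result.separation == 0.0

    def test_monotone_in_tolerance(self):
        part_a, _ = fixtures.make_c2_dimer(fixtures.FixtureSpec(seed=1))
        part_b, _ = fixtures.make_c2_dimer(fixtures.FixtureSpec(seed=2))
        axis = detect_c2_axis(part_a, "A", "B")
        seps = []
        for tol in (0.8, 0.4, 0.0):  # decreasing tolerance = stricter
            result = min_separation(
                part_a, part_b, axis, ClashCriterion(tolerance=tol)
            )
            seps.append(result.separation)
        assert seps == sorted(seps)  # stricter never smaller

    def test_assembly_is_clash_free_and_rigid(self):
        part_a, _ = fixtures.make_c2_dimer(fixtures.FixtureSpec(seed=1))
        part_b, _ = fixtures.make_c2_dimer(fixtures.FixtureSpec(seed=2))
        axis = detect_c2_axis(part_a, "A", "B")
        result = min_separation(part_a, part_b, axis)
        assert result.clash_report.clash_count == 0
        merged_b = StructureModel(
            [
                result.model.get_chain(result.chain_mapping[c])
                for c in part_b.chain_ids
            ]
        )
        before = pairwise_distances(part_b.coords())
        after = pairwise_distances(merged_b.coords())
        assert np.abs(before - after).max() < 1e-6


def ring_with_gap(gap_start, gap_end, radius=20.0, z=0.0, every=5.0, chain="B"):
    """Atoms on a circle except inside the gap arc (degrees)."""
    pts = []
    ang = 0.0
    while ang < 360.0:
        inside = (
            gap_start <= ang <= gap_end
            if gap_start <= gap_end
            else ang >= gap_start or ang <= gap_end
        )
        if not inside:
            pts.append(
                (
                    radius * np.cos(np.deg2rad(ang)),
                    radius * np.sin(np.deg2rad(ang)),
                    z,
                )
            )
        ang += every
    return fixtures.model_from_points(pts, chain)


class TestScanDihedral:
    AXIS = assembly.SymmetryAxis((0, 0, 1), (0, 0, 0), 180.0, 0.0)

    def test_intersection_midpoint(self):
        """Variant 1 feasible everywhere, variant 2 only on an arc around
        [40, 80]: the chosen angle is the arc midpoint (~60)."""
        blocker = fixtures.model_from_points([(20.0, 0.0, 0.0)], "A")
        free = fixtures.model_from_points([(0.0, 0.0, 5.0)], "B")  # on axis: never hits
        # ring with its gap initially at azimuth [-80, -40]: rotating the
        # variant by theta moves the gap to [theta-80, theta-40], so the
        # blocker (azimuth 0) escapes through it for theta in ~[40, 80]
        gapped = ring_with_gap(280.0, 320.0, chain="B")
        scan = scan_dihedral(blocker, [free, gapped], self.AXIS, angular_step=1.0)
        assert 50.0 <= scan.chosen_angle <= 70.0
        # variant arcs: free variant feasible on the full circle, gapped
        # variant only on one arc around [40, 80]
        assert scan.per_variant_arcs[0] == ((0.0, 360.0),)
        assert len(scan.per_variant_arcs[1]) == 1
        (lo, hi), = scan.per_variant_arcs[1]
        assert 35.0 <= lo <= 55.0 and 65.0 <= hi <= 85.0

    def test_single_fully_feasible_variant_gives_180(self):
        part_a = fixtures.model_from_points([(0.0, 0.0, 0.0)], "A")
        variant = fixtures.model_from_points([(0.0, 0.0, 30.0)], "B")
        scan = scan_dihedral(part_a, [variant], self.AXIS)
        assert scan.chosen_angle == pytest.approx(180.0)
        assert scan.feasible_arcs == ((0.0, 360.0),)

    def test_mask_matches_quarter_degree_brute_force(self):
        blocker = fixtures.model_from_points(
            [(8.0, 0.0, 0.0), (0.0, 8.0, 0.0)], "A"
        )
        probe = fixtures.model_from_points([(8.0, 0.0, 1.0)], "B")
        coarse = scan_dihedral(blocker, [probe], self.AXIS, angular_step=1.0)
        # brute force at 0.25 deg: recompute feasibility by direct rotation
        angles = np.arange(0.0, 360.0, 0.25)
        feas = []
        for ang in angles:
            rot = rotation_about_axis((0, 0, 1), (0, 0, 0), float(ang))
            moved = probe.transformed(rot)
            merged = StructureModel([blocker.chains[0].copy(), moved.chains[0].copy()])
            feas.append(detect_clashes(merged, ["A"], ["B"]).clash_count == 0)
        # compare at shared grid points (multiples of 1 degree)
        shared = {a: f for a, f in zip(angles, feas) if a == int(a)}
        mask_from_arcs = {}
        for a in shared:
            inside = any(
                (lo <= a <= hi) if lo <= hi else (a >= lo or a <= hi)
                for lo, hi in coarse.per_variant_arcs[0]
            )
            mask_from_arcs[a] = inside
        assert mask_from_arcs == shared

    def test_empty_intersection_reports_arcs(self):
        blocker = fixtures.model_from_points([(20.0, 0.0, 0.0)], "A")
        # two variants whose gaps are on opposite sides and too narrow to
        # overlap: feasible sets are disjoint
        v1 = ring_with_gap(-10.0, 10.0, chain="B")
        v2 = ring_with_gap(170.0, 190.0, chain="B")
        with pytest.raises(InfeasibleAssemblyError) as err:
            scan_dihedral(blocker, [v1, v2], self.AXIS, angular_step=1.0)
        assert err.value.per_variant_arcs is not None
        assert len(err.value.per_variant_arcs) == 2
        assert all(arcs for arcs in err.value.per_variant_arcs)

    def test_assemblies_clash_free(self):
        part_a, _ = fixtures.make_c2_dimer(fixtures.FixtureSpec(seed=1))
        part_b, _ = fixtures.make_c2_dimer(fixtures.FixtureSpec(seed=2))
        axis = detect_c2_axis(part_a, "A", "B")
        placed = min_separation(part_a, part_b, axis)
        shifted = part_b.transformed(
            RigidTransform(
                np.eye(3),
                placed.separation * axis.direction
                - (part_b.centroid() - part_a.centroid()),
            )
        )
        scan = scan_dihedral(part_a, [shifted], axis, angular_step=5.0)
        for result in scan.assemblies:
            assert result.clash_report.clash_count == 0


class TestComposeHybrid:
    def test_identity_when_closed_equals_open(self, bound_blob_dimer):
        model, domains = bound_blob_dimer
        partner_specs = [d for d in domains if d.label != "FMNd"]
        hybrid, fit = compose_hybrid(model, model.copy(), partner_specs)
        assert fit < 1e-9
        assert np.allclose(hybrid.coords(), model.coords(), atol=1e-9)

    def test_mobile_domains_from_each_parent(self):
        closed, domains = fixtures.make_topology_dimer(
            "closed", fixtures.FixtureSpec(geometry="blob")
        )
        crossed, _ = fixtures.make_topology_dimer(
            "crossed", fixtures.FixtureSpec(geometry="blob")
        )
        partner_specs = [d for d in domains if d.label != "FMNd"]
        hybrid, fit = compose_hybrid(closed, crossed, partner_specs)
        assert fit < 1e-9  # partner domains coincide by construction

        def mobile_coords(model, chain):
            return np.array(
                [
                    r.atoms[0].coords
                    for r in model.get_chain(chain).residues
                    if r.ref.res_number >= 101
                ]
            )

        assert np.allclose(
            mobile_coords(hybrid, "A"), mobile_coords(closed, "A"), atol=1e-9
        )
        assert np.allclose(
            mobile_coords(hybrid, "B"), mobile_coords(crossed, "B"), atol=1e-9
        )

    def test_each_domain_once_per_monomer(self, bound_blob_dimer):
        model, domains = bound_blob_dimer
        partner_specs = [d for d in domains if d.label != "FMNd"]
        hybrid, _ = compose_hybrid(model, model.copy(), partner_specs)
        for chain in hybrid.chains:
            numbers = [r.ref.res_number for r in chain.residues]
            assert len(numbers) == len(set(numbers))
        assert hybrid.chain_ids == model.chain_ids

    def test_restricted_fit_beats_all_atom_fit_on_selection(self):
        closed, domains = fixtures.make_topology_dimer(
            "closed", fixtures.FixtureSpec(geometry="blob", noise_sigma=0.3, seed=21)
        )
        crossed, _ = fixtures.make_topology_dimer(
            "crossed", fixtures.FixtureSpec(geometry="blob", noise_sigma=0.3, seed=22)
        )
        partner_specs = [d for d in domains if d.label != "FMNd"]
        _, fit_restricted = compose_hybrid(closed, crossed, partner_specs)

        # all-atom fit, evaluated on the partner-domain selection
        all_closed = closed.coords()
        all_crossed = crossed.coords()
        t_all = kabsch(all_crossed, all_closed)

        def partner_coords(model):
            return np.array(
                [
                    a.coords
                    for ref, a in model.iter_atoms()
                    if ref.res_number <= 100 and a.name == "CA"
                ]
            )

        moved = t_all.apply(partner_coords(crossed))
        fit_all = np.sqrt(np.mean(np.sum((moved - partner_coords(closed)) ** 2, axis=1)))
        assert fit_restricted <= fit_all + 1e-12

    def test_missing_domain_errors(self, bound_blob_dimer):
        model, _ = bound_blob_dimer
        with pytest.raises(UsageError):
            compose_hybrid(
                model, model.copy(), [DomainSpec("nope", "A", 900, 950)]
            )
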