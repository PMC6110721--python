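"""Solvent accessibility: analytic sphere oracles, partition and invariances."""

import math

import numpy as np
import pytest

from saapqa.surface import (AccessibilityProfile, ResidueAccessibility, accessible_mask,
                            atom_sasa, compute_sasa, sidechain_reference)


def two_sphere_exposed_areas(r1: float, r2: float, d: float, probe: float):
    """Closed-form exposed areas of two intersecting solvent-expanded spheres.

    For spheres of expanded radii R1 = r1 + probe, R2 = r2 + probe at
    centre distance d < R1 + R2, each sphere loses a spherical cap of
    height h_i; exposed area_i = 4*pi*Ri^2 - 2*pi*Ri*h_i.
    """
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 4 * math.pi * R1 ** 2, 4 * math.pi * R2 ** 2
    h1 = (R2 - R1 + d) * (R2 + R1 - d) / (2 * d)
    h2 = (R1 - R2 + d) * (R1 + R2 - d) / (2 * d)
    return (4 * math.pi * R1 ** 2 - 2 * math.pi * R1 * h1,
            4 * math.pi * R2 ** 2 - 2 * math.pi * R2 * h2)


class TestAtomOracles:
    def test_isolated_atom_matches_analytic_sphere(self):
        area = atom_sasa(np.zeros((1, 3)), np.array([1.90]), probe=1.4, n_points=960)
        assert area[0] == pytest.approx(4 * math.pi * 3.30 ** 2, rel=0.005)

    def test_distant_atoms_unoccluded(self):
        r = 1.87
        coords = np.array([[0.0, 0.0, 0.0], [2 * (r + 1.4) + 1.0, 0.0, 0.0]])
        areas = atom_sasa(coords, np.array([r, r]), probe=1.4, n_points=960)
        iso = 4 * math.pi * (r + 1.4) ** 2
        np.testing.assert_allclose(areas, iso, rtol=0.005)

    @pytest.mark.parametrize("r1,r2,d", [(1.87, 1.87, 3.0), (1.65, 1.40, 2.4),
                                         (1.90, 1.52, 3.3)])
    def test_two_overlapping_spheres_match_cap_formula(self, r1, r2, d):
        coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        areas = atom_sasa(coords, np.array([r1, r2]), probe=1.4, n_points=5000)
        a1, a2 = two_sphere_exposed_areas(r1, r2, d, probe=1.4)
        assert areas[0] == pytest.approx(a1, rel=0.01)
        assert areas[1] == pytest.approx(a2, rel=0.01)


def shrake_rupley_reference(coords: np.ndarray, radii: np.ndarray,
                            probe: float, n_points: int = 960) -> np.ndarray:
    """Independent brute-force Shrake-Rupley (golden-spiral points, numpy)."""
    k = np.arange(n_points)
    golden = math.pi * (3 - math.sqrt(5))
    z = 1 - 2 * (k + 0.5) / n_points
    r = np.sqrt(1 - z ** 2)
    pts = np.stack([r * np.cos(golden * k), r * np.sin(golden * k), z], axis=1)
    expanded = radii + probe
    out = np.zeros(len(coords))
    for i, (c, R) in enumerate(zip(coords, expanded)):
        surf = c + R * pts
        free = np.ones(n_points, dtype=bool)
        for j, (c2, R2) in enumerate(zip(coords, expanded)):
            if j == i:
                continue
            free &= np.linalg.norm(surf - c2, axis=1) >= R2
        out[i] = 4 * math.pi * R ** 2 * free.mean()
    return out


def test_against_independent_shrake_rupley(small_benchmark):
    """Per-atom SASA agrees with a brute-force implementation on a real fold."""
    s = small_benchmark[0].reference
    coords = np.vstack([r.coords() for r in s.residues])[:120]
    radii = np.full(len(coords), 1.8)
    ours = atom_sasa(coords, radii, probe=1.4, n_points=2000)
    ref = shrake_rupley_reference(coords, radii, probe=1.4, n_points=2000)
    # point-set orientations differ; compare per-atom with a small tolerance
    np.testing.assert_allclose(ours, ref, atol=3.0)
    assert abs(ours.sum() - ref.sum()) / ref.sum() < 0.01


class TestResidueProfiles:
    def test_partition_property(self, small_benchmark):
        s = small_benchmark[0].reference
        prof = compute_sasa(s)
        arr_total = prof.total_sasa()
        coords = np.vstack([r.coords() for r in s.residues])
        from saapqa.surface import atom_radius
        radii = np.array([atom_radius(r.name, a[0], a[1])
                          for r in s.residues for a in r.atoms])
        whole = atom_sasa(coords, radii).sum()
        assert arr_total == pytest.approx(whole, rel=1e-6)

    def test_rigid_motion_invariance(self, small_benchmark):
        from scipy.spatial.transform import Rotation
        s = small_benchmark[0].reference
        before = compute_sasa(s)
        rot = Rotation.from_euler("xyz", [31, -54, 117], degrees=True).as_matrix()
        import copy
        s2 = copy.deepcopy(s)
        for r in s2.residues:
            r.atoms = [(n, e, *(rot @ np.array([x, y, z]) + np.array([5.0, -3.0, 9.0])))
                       for n, e, x, y, z in r.atoms]
        after = compute_sasa(s2)
        a = np.array([r.abs_total_sasa for r in before.per_residue])
        b = np.array([r.abs_total_sasa for r in after.per_residue])
        np.testing.assert_allclose(a, b, rtol=0.02, atol=2.0)

    def test_sampling_convergence(self, small_benchmark):
        import biotite.structure as struc
        from saapqa.core import to_atom_array
        from saapqa.surface import atom_radius
        s = small_benchmark[0].reference
        arr = to_atom_array(s)
        radii = np.array([atom_radius(arr.res_name[i], arr.atom_name[i],
                                      arr.element[i])
                          for i in range(arr.array_length())])
        a = np.asarray(struc.sasa(arr, probe_radius=1.4, point_number=960,
                                  vdw_radii=radii, ignore_ions=False))
        b = np.asarray(struc.sasa(arr, probe_radius=1.4, point_number=1920,
                                  vdw_radii=radii, ignore_ions=False))
        # doubling the sampling changes any atom by <= 2%, up to the
        # discretisation floor (one point covers 4*pi*(r+probe)^2/960 Å²;
        # a few quanta of shot noise are unavoidable for buried atoms)
        quantum = 4 * math.pi * (radii + 1.4) ** 2 / 960
        assert np.all(np.abs(a - b) <= np.maximum(0.02 * b, 8 * quantum))
        # and the structure total converges well below 1%
        assert abs(a.sum() - b.sum()) / b.sum() < 0.01

    def test_buried_core_vs_exposed_surface(self, small_benchmark):
        """The hydrophobic central helix is buried; solvent faces are not."""
        pool = small_benchmark[0]
        prof = compute_sasa(pool.reference)
        from saapqa.aggregation import profile_sequence
        agg = profile_sequence(pool.sequence)
        rel = np.array([r.rel_sidechain_sasa for r in prof.per_residue])
        flagged = agg.is_aggregation_prone
        assert np.nanmean(rel[flagged]) < np.nanmean(rel[~flagged])
        mask = accessible_mask(prof)
        assert mask[flagged].mean() < 0.3


class TestAccessibleMask:
    def test_threshold_strictness(self):
        rels = [10.0, 50.0, 50.01, 90.0]
        prof = AccessibilityProfile(
            structure_id="t",
            per_residue=[ResidueAccessibility(i + 1, "", "ALA", 0.0, rel, 0.0, True)
                         for i, rel in enumerate(rels)],
            probe_radius=1.4, n_points=960)
        assert accessible_mask(prof).tolist() == [False, False, True, True]

    def test_all_buried(self):
        prof = AccessibilityProfile(
            structure_id="t",
            per_residue=[ResidueAccessibility(i + 1, "", "ALA", 0.0, 0.0, 0.0, True)
                         for i in range(5)],
            probe_radius=1.4, n_points=960)
        assert not accessible_mask(prof).any()


def test_reference_table_covers_20_types_and_is_positive():
    ref = sidechain_reference()
    assert len(ref) == 20
    assert all(v > 0 for v in ref.values())
    # bulky aromatics expose more side-chain surface than small residues
    assert ref["TRP"] > ref["ALA"]
    assert ref["GLY"] < ref["ALA"]


def test_fully_extended_residue_scores_near_100():
    from saapqa.surface import build_tripeptide
    tri = build_tripeptide("LEU")
    prof = compute_sasa(tri)
    centre = [r for r in prof.per_residue if r.seq_number == 2][0]
    assert centre.rel_sidechain_sasa == pytest.approx(100.0, abs=1e-6)
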