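"""Shrake-Rupley SASA against analytic and independent-library oracles."""

import numpy as np
import pytest

from macrodissect.ensemble_io import Atom, AtomClassTable, ConformerEnsemble
from macrodissect.surfaces import (
    ensemble_surface,
    partition_sasa,
    shrake_rupley,
    sphere_points,
)


def two_sphere_analytic(r1: float, r2: float, probe: float, d: float) -> tuple[float, float]:
    """Closed-form accessible areas of two intersecting solvent-expanded
    spheres (spherical-cap subtraction)."""
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 4 * np.pi * R1**2, 4 * np.pi * R2**2
    # cap height on sphere 1 buried inside sphere 2 and vice versa
    h1 = R1 - (d**2 + R1**2 - R2**2) / (2 * d)
    h2 = R2 - (d**2 + R2**2 - R1**2) / (2 * d)
    a1 = 4 * np.pi * R1**2 - 2 * np.pi * R1 * h1
    a2 = 4 * np.pi * R2**2 - 2 * np.pi * R2 * h2
    return a1, a2


class TestSpherePoints:
    def test_unit_norm_and_determinism(self):
        pts = sphere_points(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        np.testing.assert_array_equal(pts, sphere_points(960))

    def test_quasi_uniform_centroid(self):
        assert np.linalg.norm(sphere_points(960).mean(axis=0)) < 1e-3


class TestShrakeRupley:
    def test_isolated_sphere_exact(self):
        area = shrake_rupley(np.zeros((1, 3)), np.array([1.6]), probe_radius=1.4, n_points=96)
        assert area[0] == pytest.approx(4 * np.pi * 3.0**2, rel=1e-12)

    def test_distant_atoms_full_spheres(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        radii = np.array([1.7, 1.52])
        areas = shrake_rupley(coords, radii)
        for a, r in zip(areas, radii):
            assert a == pytest.approx(4 * np.pi * (r + 1.4) ** 2, rel=1e-12)

    @pytest.mark.parametrize("n_points, rel_tol", [(960, 0.02), (10000, 0.005)])
    def test_two_sphere_cap_oracle(self, n_points, rel_tol):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        radii = np.array([1.7, 1.7])
        areas = shrake_rupley(coords, radii, probe_radius=1.4, n_points=n_points)
        exact = two_sphere_analytic(1.7, 1.7, 1.4, 3.0)
        assert areas.sum() == pytest.approx(sum(exact), rel=rel_tol)

    def test_convergence_toward_analytic_value(self):
        coords = np.array([[0.0, 0, 0], [2.4, 0.3, -0.2]])
        radii = np.array([1.7, 1.52])
        d = float(np.linalg.norm(coords[1] - coords[0]))
        exact = sum(two_sphere_analytic(1.7, 1.52, 1.4, d))
        errors = [
            abs(shrake_rupley(coords, radii, n_points=n).sum() - exact) / exact
            for n in (96, 960, 9600)
        ]
        assert errors[0] > errors[1] > errors[2]

    def test_distant_atom_leaves_others_unchanged(self):
        rng = np.random.default_rng(8)
        coords = rng.normal(scale=2.0, size=(8, 3))
        radii = np.full(8, 1.6)
        base = shrake_rupley(coords, radii)
        extended = shrake_rupley(
            np.vstack([coords, [50.0, 0, 0]]), np.append(radii, 1.6)
        )
        np.testing.assert_allclose(extended[:8], base, rtol=1e-3)

    def test_overlapping_atom_never_increases_sasa(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(scale=2.0, size=(8, 3))
        radii = np.full(8, 1.6)
        base = shrake_rupley(coords, radii)
        extended = shrake_rupley(
            np.vstack([coords, coords.mean(axis=0)]), np.append(radii, 1.6)
        )
        assert (extended[:8] <= base + 1e-9).all()

    def test_agrees_with_biotite_on_random_fixtures(self):
        """Independent reference implementation cross-check: 10 random
        20-atom clusters, total SASA within 2%."""
        struc = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(10)
        for _ in range(10):
            coords = rng.normal(scale=3.0, size=(20, 3))
            radii = rng.uniform(1.4, 1.9, size=20)
            ours = shrake_rupley(coords, radii, probe_radius=1.4, n_points=960)
            arr = struc.AtomArray(20)
            arr.coord = coords.astype(np.float32)
            arr.element = np.array(["C"] * 20)
            theirs = struc.sasa(arr, probe_radius=1.4, point_number=960, vdw_radii=radii)
            assert ours.sum() == pytest.approx(float(theirs.sum()), rel=0.02)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            shrake_rupley(np.zeros((2, 3)), np.array([1.0]))
        with pytest.raises(ValueError):
            shrake_rupley(np.zeros((1, 3)), np.array([-1.0]))


class TestPartition:
    def test_all_polar(self):
        table = AtomClassTable(classes=["polar", "polar"], radii=np.array([1.5, 1.5]))
        psa, npsa = partition_sasa(np.array([10.0, 5.0]), table)
        assert (psa, npsa) == (15.0, 0.0)

    def test_all_nonpolar(self):
        table = AtomClassTable(classes=["nonpolar"] * 2, radii=np.array([1.7, 1.7]))
        psa, npsa = partition_sasa(np.array([10.0, 5.0]), table)
        assert (psa, npsa) == (0.0, 15.0)

    def test_mixed_partition_conserves_total(self):
        rng = np.random.default_rng(11)
        coords = rng.normal(scale=2.0, size=(6, 3))
        radii = np.full(6, 1.6)
        per_atom = shrake_rupley(coords, radii)
        table = AtomClassTable(
            classes=["polar", "nonpolar", "polar", "nonpolar", "polar", "nonpolar"],
            radii=radii,
        )
        psa, npsa = partition_sasa(per_atom, table)
        assert psa + npsa == pytest.approx(per_atom.sum(), abs=1e-9)

    def test_length_mismatch_raises(self):
        table = AtomClassTable(classes=["polar"], radii=np.array([1.5]))
        with pytest.raises(ValueError):
            partition_sasa(np.array([1.0, 2.0]), table)


def _linear_chain(n: int, spacing: float) -> np.ndarray:
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * spacing
    coords[:, 1] = 0.01 * np.arange(n) ** 2  # break collinearity slightly
    return coords


class TestEnsembleSurface:
    def _ensemble(self, frames):
        n = frames.shape[1]
        atoms = [Atom(f"C{i + 1}", "C", 0) for i in range(n)]
        return ConformerEnsemble(ligand_id="chain", atoms=atoms, bonds=[], frames=frames)

    def _classes(self, n):
        return AtomClassTable(
            classes=["polar" if i % 2 else "nonpolar" for i in range(n)],
            radii=np.full(n, 1.7),
        )

    def test_identical_frames_zero_sigma(self):
        frame = _linear_chain(5, 2.0)
        ens = self._ensemble(np.repeat(frame[None], 3, axis=0))
        surf = ensemble_surface(ens, self._classes(5), n_points=240)
        assert surf.sigma_psa == 0.0
        single = shrake_rupley(frame, np.full(5, 1.7), n_points=240)
        assert surf.mean_total == pytest.approx(single.sum(), abs=1e-9)

    def test_two_frame_mean(self):
        compact = _linear_chain(5, 1.0)
        extended = _linear_chain(5, 4.0)
        ens = self._ensemble(np.stack([compact, extended]))
        surf = ensemble_surface(ens, self._classes(5), n_points=240)
        a = shrake_rupley(compact, np.full(5, 1.7), n_points=240)
        b = shrake_rupley(extended, np.full(5, 1.7), n_points=240)
        assert surf.mean_total == pytest.approx((a.sum() + b.sum()) / 2, abs=1e-9)

    def test_mixture_lies_between_pure_conformers(self):
        compact = _linear_chain(6, 1.2)
        extended = _linear_chain(6, 4.0)
        frames = np.stack([compact] * 3 + [extended] * 3)
        surf = ensemble_surface(self._ensemble(frames), self._classes(6), n_points=240)
        lo = shrake_rupley(compact, np.full(6, 1.7), n_points=240).sum()
        hi = shrake_rupley(extended, np.full(6, 1.7), n_points=240).sum()
        assert lo < surf.mean_total < hi

    def test_block_sigma_option(self):
        rng = np.random.default_rng(12)
        frames = _linear_chain(4, 2.0)[None] + rng.normal(scale=0.1, size=(8, 4, 3))
        ens = self._ensemble(frames)
        surf = ensemble_surface(ens, self._classes(4), n_points=96, n_blocks=4)
        assert surf.sigma_kind == "blocks"
        assert surf.sigma_psa >= 0.0

    def test_frame_subset_restriction(self):
        compact = _linear_chain(5, 1.0)
        extended = _linear_chain(5, 4.0)
        ens = self._ensemble(np.stack([compact, extended]))
        surf = ensemble_surface(
            ens, self._classes(5), n_points=240, frame_indices=np.array([1])
        )
        only = shrake_rupley(extended, np.full(5, 1.7), n_points=240)
        assert surf.mean_total == pytest.approx(only.sum(), abs=1e-9)
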