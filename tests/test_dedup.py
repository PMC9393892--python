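import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from vcdkit.constants import ROTCONST_CM
from vcdkit.dedup import (
    DedupThresholds,
    atomic_masses,
    is_duplicate,
    kabsch_rmsd,
    prune_duplicates,
    rotational_constants,
)
from vcdkit.ensemble import Conformer, EnergyRecord, Ensemble
from vcdkit.errors import DegenerateGeometryError, EnergyUnavailableError, InputError
from .conftest import random_conformer


def brute_force_min_rmsd(a: np.ndarray, b: np.ndarray, n_grid=13, n_refine=8) -> float:
    """Independent oracle: nested grid search over Euler angles."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    center = np.zeros(3)
    widths = np.array([np.pi, np.pi / 2, np.pi])
    best_val = np.inf
    for _ in range(n_refine):
        axes = [np.linspace(c - w, c + w, n_grid) for c, w in zip(center, widths)]
        for al in axes[0]:
            for be in axes[1]:
                for ga in axes[2]:
                    rot = Rotation.from_euler("zyx", [al, be, ga])
                    d = a - rot.apply(b)
                    val = np.sqrt((d * d).sum() / len(a))
                    if val < best_val:
                        best_val, best_ang = val, np.array([al, be, ga])
        center = best_ang
        widths = widths * (2.0 / (n_grid - 1))
    return best_val


class TestKabschRmsd:
    def test_self_rmsd_is_zero(self, rng):
        c = random_conformer(rng)
        assert kabsch_rmsd(c, c) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        c = random_conformer(rng)
        rot = Rotation.from_euler("z", 90, degrees=True)
        moved = c.with_coords(rot.apply(c.coords) + np.array([5.0, 5.0, 5.0]))
        assert kabsch_rmsd(c, moved) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self, rng):
        a, b = random_conformer(rng), random_conformer(rng)
        assert kabsch_rmsd(a, b) == pytest.approx(kabsch_rmsd(b, a), abs=1e-12)

    def test_independent_rigid_motions_leave_rmsd_unchanged(self, rng):
        a, b = random_conformer(rng), random_conformer(rng)
        ref = kabsch_rmsd(a, b)
        a2 = a.with_coords(Rotation.random(rng=rng).apply(a.coords) + rng.normal(size=3))
        b2 = b.with_coords(Rotation.random(rng=rng).apply(b.coords) + rng.normal(size=3))
        assert kabsch_rmsd(a2, b2) == pytest.approx(ref, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_against_rotation_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_conformer(rng, n_atoms=4, label="a")
        b = random_conformer(rng, n_atoms=4, label="b")
        assert kabsch_rmsd(a, b) == pytest.approx(
            brute_force_min_rmsd(a.coords, b.coords), abs=1e-3
        )

    def test_mass_weighting_changes_result(self, rng):
        a, b = random_conformer(rng), random_conformer(rng)
        assert kabsch_rmsd(a, b, use_mass_weighting=True) != pytest.approx(
            kabsch_rmsd(a, b), abs=1e-12
        )


class TestRotationalConstants:
    def test_homonuclear_diatomic_closed_form(self):
        r = 1.2  # A
        c = Conformer(atoms=["C", "C"], coords=np.array([[-r / 2, 0, 0], [r / 2, 0, 0]]))
        m = atomic_masses(["C"])[0]
        expected = ROTCONST_CM / (m * r**2 / 2.0)
        consts = rotational_constants(c)
        assert consts[0] == np.inf  # rotation about the molecular axis
        assert consts[1] == pytest.approx(expected, rel=1e-6)
        assert consts[2] == pytest.approx(expected, rel=1e-6)

    def test_rotation_invariance(self, rng):
        c = random_conformer(rng)
        rot = Rotation.random(rng=rng)
        moved = c.with_coords(rot.apply(c.coords) + np.array([1.0, -2.0, 3.0]))
        assert np.allclose(rotational_constants(c), rotational_constants(moved), rtol=1e-8)

    def test_equilateral_triangle_hand_eigen_oracle(self):
        # three H atoms at the vertices of an equilateral triangle, side a:
        # planar symmetric top with I_z = m a^2 and I_x = I_y = m a^2 / 2
        a = 1.5
        r = a / np.sqrt(3.0)
        theta = np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
        coords = np.stack([r * np.cos(theta), r * np.sin(theta), np.zeros(3)], axis=1)
        c = Conformer(atoms=["H", "H", "H"], coords=coords)
        m = atomic_masses(["H"])[0]
        in_plane = ROTCONST_CM / (m * a**2 / 2.0)
        out_of_plane = ROTCONST_CM / (m * a**2)
        assert np.allclose(
            rotational_constants(c), [in_plane, in_plane, out_of_plane], rtol=1e-9
        )

    def test_positive_for_nonlinear_geometry(self, rng):
        consts = rotational_constants(random_conformer(rng))
        assert np.all(consts > 0) and np.all(np.isfinite(consts))

    def test_coincident_atoms_degenerate(self):
        c = Conformer(atoms=["C", "C"], coords=np.zeros((2, 3)))
        with pytest.raises(DegenerateGeometryError):
            rotational_constants(c)


class TestIsDuplicate:
    def _pair(self, rng, de_kcal=0.0, geom_shift=0.0):
        from vcdkit.constants import HARTREE_TO_KCAL

        a = random_conformer(rng, label="a", energy=EnergyRecord(electronic=-100.0))
        b = Conformer(
            atoms=list(a.atoms),
            coords=a.coords + geom_shift,
            energy=EnergyRecord(electronic=-100.0 + de_kcal / HARTREE_TO_KCAL),
            label="b",
        )
        return a, b

    def test_exact_copy_is_duplicate_with_zero_metrics(self, rng):
        a, b = self._pair(rng)
        verdict, m = is_duplicate(a, b)
        assert verdict
        assert m.delta_e == pytest.approx(0.0, abs=1e-9)
        assert m.rmsd == pytest.approx(0.0, abs=1e-9)
        assert m.max_rel_rotconst == pytest.approx(0.0, abs=1e-12)

    def test_energy_criterion_alone_fails_pair(self, rng):
        a, b = self._pair(rng, de_kcal=5.0)
        verdict, m = is_duplicate(a, b)
        assert not verdict
        assert m.rmsd == pytest.approx(0.0, abs=1e-9)  # geometry identical
        assert m.delta_e == pytest.approx(5.0, abs=1e-6)

    def test_geometry_criterion_alone_fails_pair(self, rng):
        # a large perturbation of one atom: energies equal, geometry not
        a = random_conformer(rng, label="a", energy=EnergyRecord(electronic=-100.0))
        coords = a.coords.copy()
        coords[0] += np.array([3.0, 0.0, 0.0])
        b = Conformer(list(a.atoms), coords, EnergyRecord(electronic=-100.0), "b")
        verdict, m = is_duplicate(a, b)
        assert not verdict and m.delta_e == 0.0 and m.rmsd > 0.125

    def test_missing_energy_field_raises(self, rng):
        a = random_conformer(rng, label="a", energy=EnergyRecord(gibbs=-1.0))
        b = random_conformer(rng, label="b", energy=EnergyRecord(gibbs=-1.0))
        with pytest.raises(EnergyUnavailableError):
            is_duplicate(a, b, energy_field="electronic")

    def test_thresholds_must_be_positive(self):
        with pytest.raises(InputError):
            DedupThresholds(energy_thr=-1.0)


class TestPruneDuplicates:
    def test_no_duplicates_keeps_everything(self, toy_ensemble):
        pruned, report = prune_duplicates(toy_ensemble)
        assert len(pruned) == len(toy_ensemble)
        assert report.removed == []

    def test_k_exact_copies_keep_one(self, rng):
        base = random_conformer(rng, label="c1", energy=EnergyRecord(electronic=-50.0))
        copies = [
            Conformer(list(base.atoms), base.coords.copy(), base.energy, f"c{k}")
            for k in range(1, 5)
        ]
        pruned, report = prune_duplicates(Ensemble(conformers=copies))
        assert len(pruned) == 1
        assert len(report.removed) == 3

    def test_planted_pairs_recovered(self):
        from vcdkit.synthetic import FixtureSpec, make_ensemble

        spec = FixtureSpec(seed=11, n_conformers=6, n_duplicate_pairs=2)
        ens, groups = make_ensemble(spec)
        pruned, report = prune_duplicates(ens)
        assert len(pruned) == len(groups)  # one representative per group
        group_of = {lab: k for k, g in enumerate(groups) for lab in g}
        assert sorted(group_of[lab] for lab in report.kept) == list(range(len(groups)))
        for lab, match, _ in report.removed:
            assert group_of[lab] == group_of[match]

    def test_idempotent(self):
        from vcdkit.synthetic import FixtureSpec, make_ensemble

        ens, _ = make_ensemble(FixtureSpec(seed=3))
        pruned, _ = prune_duplicates(ens)
        pruned2, report2 = prune_duplicates(pruned)
        assert report2.removed == []
        assert pruned2.labels == pruned.labels

    def test_injected_copy_does_not_change_kept_set(self):
        from vcdkit.synthetic import FixtureSpec, make_ensemble

        ens, _ = make_ensemble(FixtureSpec(seed=5))
        pruned, _ = prune_duplicates(ens)
        victim = pruned[0]
        clone = Conformer(list(victim.atoms), victim.coords.copy(), victim.energy, "clone")
        augmented = Ensemble(conformers=ens.conformers + [clone])
        pruned2, report2 = prune_duplicates(augmented)
        assert sorted(pruned2.labels) == sorted(pruned.labels)
        assert "clone" in report2.removed_labels

    def test_output_sorted_by_energy(self):
        from vcdkit.synthetic import FixtureSpec, make_ensemble

        ens, _ = make_ensemble(FixtureSpec(seed=9))
        pruned, _ = prune_duplicates(ens)
        energies = [c.energy.get("electronic") for c in pruned]
        assert energies == sorted(energies)
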