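import numpy as np
import pytest

from lamella import md_structure as mdst
from lamella.datatypes import ATOMIC_MASS, COHERENT_B
from lamella.md_structure import DensityProfile, DeuterationSpec, MolecularSystem


def _toy_system(positions, elements, mol_ids, classes, box=(5, 5, 20), **kw):
    n = len(elements)
    defaults = dict(
        chain_label=np.array(kw.pop("chain", ["none"] * n), object),
        site_label=np.array(kw.pop("site", [""] * n), object),
        chain_position=np.array(kw.pop("cpos", [-1] * n)),
        headgroup=np.array(kw.pop("head", [False] * n)),
    )
    return MolecularSystem(np.asarray(positions, float),
                           np.array(elements, object), np.asarray(mol_ids),
                           np.array(classes, object), defaults["chain_label"],
                           defaults["site_label"], np.asarray(box, float),
                           defaults["chain_position"], defaults["headgroup"])


def _headgroup_stack(plane_zs, per_plane=10, jitter=0.0, seed=0):
    """FFA headgroup reference atoms on well-separated planes."""
    rng = np.random.default_rng(seed)
    pos, els, mids, classes, head = [], [], [], [], []
    mid = 0
    for z in plane_zs:
        for k in range(per_plane):
            pos.append([rng.uniform(0, 5), rng.uniform(0, 5),
                        z + (rng.normal(0, jitter) if jitter else 0.0)])
            els.append("C")
            mids.append(mid)
            classes.append("FFA")
            head.append(True)
            mid += 1
    return _toy_system(pos, els, mids, classes, head=head)


class TestAssignLeaflets:
    def test_six_leaflet_stack(self):
        planes = [1.0, 6.3, 6.5, 11.7, 11.9, 17.2]
        sys6 = _headgroup_stack(planes, per_plane=8, jitter=0.02)
        leaf = mdst.assign_leaflets(sys6, 6)
        assert list(leaf.counts()) == [8] * 6
        assert leaf.inner_mask.sum() == 32  # four inner leaflets
        assert np.all(np.diff(leaf.leaflet_z) > 0)

    def test_two_leaflet_system_has_no_inner(self):
        sys2 = _headgroup_stack([2.0, 7.0], per_plane=6)
        leaf = mdst.assign_leaflets(sys2, 2)
        assert leaf.inner_mask.sum() == 0

    def test_jitter_does_not_change_assignment(self):
        planes = [1.0, 4.0, 7.0, 10.0, 13.0, 16.0]  # separation >> sigma
        clean = mdst.assign_leaflets(_headgroup_stack(planes, seed=3), 6)
        noisy = mdst.assign_leaflets(
            _headgroup_stack(planes, jitter=0.1, seed=3), 6)
        for k in range(6):
            assert set(clean.members(k)) == set(noisy.members(k))

    def test_too_few_headgroups_rejected(self):
        sys1 = _headgroup_stack([1.0], per_plane=3)
        with pytest.raises(ValueError):
            mdst.assign_leaflets(sys1, 6)


class TestDensityProfile:
    def test_single_atom_single_bin(self):
        s = _toy_system([[1, 1, 3.13]], ["C"], [0], ["FFA"])
        prof = mdst.density_profile(s, kind="mass")
        assert np.count_nonzero(prof.value) == 1
        assert prof.value.sum() == pytest.approx(ATOMIC_MASS["C"])

    def test_h_to_d_flips_sign_contribution(self):
        sH = _toy_system([[1, 1, 3.0]], ["H"], [0], ["FFA"])
        sD = _toy_system([[1, 1, 3.0]], ["D"], [0], ["FFA"])
        pH = mdst.density_profile(sH, kind="neutron_sld")
        pD = mdst.density_profile(sD, kind="neutron_sld")
        assert pH.value.sum() < 0 < pD.value.sum()
        assert pH.value.sum() == pytest.approx(COHERENT_B["H"])
        assert pD.value.sum() == pytest.approx(COHERENT_B["D"])

    def test_mass_conservation(self, rng):
        n = 500
        els = rng.choice(["C", "H", "O", "N"], n)
        s = _toy_system(rng.uniform(0, 5, (n, 3)), els, np.arange(n),
                        ["WATER"] * n)
        prof = mdst.density_profile(s, kind="mass")
        total = sum(ATOMIC_MASS[e] for e in els)
        assert prof.value.sum() == pytest.approx(total, rel=1e-9)

    def test_headgroup_plane_separation(self, rng):
        zs = np.concatenate([rng.normal(2.675, 0.05, 400),
                             rng.normal(-2.675, 0.05, 400)]) + 10.0
        pos = np.column_stack([rng.uniform(0, 5, 800), rng.uniform(0, 5, 800), zs])
        s = _toy_system(pos, ["N"] * 800, np.arange(800), ["CER_NS"] * 800)
        prof = mdst.density_profile(s, kind="mass")
        thick = mdst.bilayer_thickness(prof)
        assert thick == pytest.approx(5.35, abs=prof.bin_width)

    def test_empty_selection_rejected(self):
        s = _toy_system([[1, 1, 1]], ["C"], [0], ["FFA"])
        with pytest.raises(ValueError):
            mdst.density_profile(s, selection=np.array([False]))


class TestBilayerThickness:
    def _two_gaussian_profile(self, sep, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        z = np.arange(-4, 4, 0.05)
        v = (np.exp(-((z - sep / 2) / 0.3) ** 2)
             + np.exp(-((z + sep / 2) / 0.3) ** 2))
        if noise:
            v = v + rng.normal(0, noise * v.max(), z.size)
        return DensityProfile(z, v, "mass", 0.05)

    def test_constructed_separation(self):
        prof = self._two_gaussian_profile(5.4)
        assert mdst.bilayer_thickness(prof) == pytest.approx(5.4, abs=0.05)

    def test_reflection_invariance(self):
        prof = self._two_gaussian_profile(5.0)
        flipped = DensityProfile(prof.z, prof.value[::-1], "mass", 0.05)
        assert mdst.bilayer_thickness(flipped) == pytest.approx(
            mdst.bilayer_thickness(prof))

    def test_noisy_recovery_within_one_bin(self):
        for seed in range(20):
            prof = self._two_gaussian_profile(5.4, noise=0.01, seed=seed)
            assert mdst.bilayer_thickness(prof) == pytest.approx(5.4, abs=0.05 + 1e-9)

    def test_single_peak_rejected(self):
        z = np.arange(-2, 2, 0.05)
        prof = DensityProfile(z, np.exp(-z**2), "mass", 0.05)
        with pytest.raises(ValueError):
            mdst.bilayer_thickness(prof)


class TestAreaPerLipid:
    def test_simple_ratio(self):
        assert mdst.area_per_lipid(100.0, 300) == pytest.approx(1.0 / 3, rel=1e-12)

    def test_intensive_under_duplication(self):
        assert mdst.area_per_lipid(200.0, 600) == mdst.area_per_lipid(100.0, 300)

    def test_mean_over_leaflets(self):
        assert mdst.area_per_lipid(100.0, [290, 310]) == pytest.approx(1.0 / 3)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            mdst.area_per_lipid(100.0, 0)


def _zigzag(axis, n=12, origin=(0, 0, 0)):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    perp = np.cross(axis, [1.0, 0, 0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0, 1.0, 0])
    perp /= np.linalg.norm(perp)
    return np.array([np.asarray(origin) + i * 0.125 * axis
                     + ((-1) ** i) * 0.05 * perp for i in range(n)])


class TestChainGeometry:
    def test_straight_chain_along_z(self):
        coords = np.column_stack([np.zeros(10), np.zeros(10),
                                  np.arange(10) * 0.125])
        assert mdst.chain_tilt(coords) == pytest.approx(0.0, abs=1e-9)

    def test_45_degree_chain(self):
        t = np.arange(10) * 0.125
        coords = np.column_stack([t / np.sqrt(2), np.zeros(10), t / np.sqrt(2)])
        assert mdst.chain_tilt(coords) == pytest.approx(45.0, abs=1e-9)

    def test_zigzag_12_degrees_within_one(self):
        axis = [np.sin(np.radians(12)), 0.0, np.cos(np.radians(12))]
        assert mdst.chain_tilt(_zigzag(axis, 24)) == pytest.approx(12.0, abs=1.0)

    def test_degenerate_flagged(self):
        # perfectly isotropic arrangement: regular tetrahedron
        coords = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                          float)
        with pytest.raises(ValueError, match="degenerate"):
            mdst.chain_tilt(coords)

    def test_rotation_about_z_invariance(self):
        axis = [np.sin(0.3), 0.0, np.cos(0.3)]
        coords = _zigzag(axis, 18)
        ang = np.radians(73.0)
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        assert mdst.chain_tilt(coords @ R.T) == pytest.approx(
            mdst.chain_tilt(coords), abs=1e-9)


class TestNematicOrder:
    def test_perfect_alignment(self):
        u = np.tile([0.0, 0.0, 1.0], (50, 1))
        assert mdst.nematic_order(u) == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_set_near_zero(self, rng):
        v = rng.normal(size=(100_000, 3))
        assert mdst.nematic_order(v) < 0.02

    def test_92_percent_aligned_mixture(self, rng):
        n = 50_000
        n_iso = int(0.08 * n)
        u = np.tile([0.0, 0.0, 1.0], (n - n_iso, 1))
        v = rng.normal(size=(n_iso, 3))
        s2 = mdst.nematic_order(np.vstack([u, v]))
        assert s2 == pytest.approx(0.92, abs=0.01)

    def test_zero_director_rejected(self):
        with pytest.raises(ValueError):
            mdst.nematic_order(np.array([[0, 0, 1], [0, 0, 0]], float))


class TestConformation:
    def test_opposite_directions_linear(self):
        acyl = _zigzag([0, 0, 1], 10)
        sph = _zigzag([0, 0, -1], 10)
        assert mdst.classify_conformation(acyl, sph) == "linear"

    def test_parallel_directions_hairpin(self):
        acyl = _zigzag([0, 0, -1], 10, origin=(0.3, 0, 0))
        sph = _zigzag([0, 0, -1], 10)
        assert mdst.classify_conformation(acyl, sph) == "hairpin"

    def test_constructed_fraction_recovered_exactly(self):
        from lamella import synth
        build = synth.build_stack(synth.StackSpec(
            seed=5, lipids_per_leaflet=20, linear_fraction=0.35,
            bulk_water_layers=False))
        conf = mdst.conformation_fractions(build.system)
        assert conf["linear"] == build.ground_truth["linear_fraction"]
        assert conf["n"] == build.ground_truth["n_cer"]


class TestDeuteration:
    def test_nsd7_replaces_exactly_seven_h_per_cer(self, small_stack):
        system = small_stack.system
        deut = mdst.apply_deuteration(system, [mdst.NSD7])
        n_d = int(np.sum(deut.element == "D"))
        n_ns = int(np.unique(
            system.molecule_id[system.molecule_class == "CER_NS"]).size)
        assert n_d == 7 * n_ns
        # only sphingosine hydrogens of CER NS changed
        changed = (deut.element == "D") & (system.element == "H")
        assert set(system.molecule_class[changed]) == {"CER_NS"}
        assert set(system.chain_label[changed]) == {"sphingoid"}

    def test_empty_spec_identity(self, small_stack):
        prof0 = mdst.simulated_sld_profile(small_stack.system, None)
        prof1 = mdst.simulated_sld_profile(small_stack.system, [])
        assert np.array_equal(prof0.value, prof1.value)

    def test_unmatched_spec_rejected(self, small_stack):
        bad = DeuterationSpec("WATER", "acyl", 3)
        with pytest.raises(ValueError):
            mdst.apply_deuteration(small_stack.system, [bad])


class TestSymmetrizeAndScale:
    def test_symmetric_profile_scaled_to_0_100(self):
        z = np.linspace(-2.7, 2.7, 109)
        v = np.cos(2 * np.pi * z / 5.4)
        from lamella.datatypes import SLDProfile
        out = mdst.symmetrize_and_scale(SLDProfile(z, v, 5.4))
        assert out.rho.min() == pytest.approx(0.0, abs=1e-12)
        assert out.rho.max() == pytest.approx(100.0, abs=1e-12)
        # shape preserved up to the affine map
        rescaled = (v - v.min()) / (v.max() - v.min()) * 100
        assert np.allclose(out.rho, rescaled, atol=1e-9)

    def test_mirror_gives_identical_output(self):
        z = np.linspace(-2.0, 2.0, 81)
        v = np.exp(-((z - 0.7) / 0.3) ** 2) + 0.3 * z
        from lamella.datatypes import SLDProfile
        a = mdst.symmetrize_and_scale(SLDProfile(z, v, 4.0))
        b = mdst.symmetrize_and_scale(SLDProfile(z, v[::-1], 4.0))
        assert np.allclose(a.rho, b.rho, atol=1e-9)

    def test_linear_ramp_degenerates(self):
        z = np.linspace(-1, 1, 41)
        from lamella.datatypes import SLDProfile
        with pytest.raises(ValueError):
            mdst.symmetrize_and_scale(SLDProfile(z, 3.0 * z, 2.0))


class TestStackInvariances:
    def test_xy_duplication_leaves_metrics_unchanged(self, small_stack):
        """Doubling the box in x with a copied image is an intensive no-op."""
        s = small_stack.system
        shifted = s.positions + np.array([s.box[0], 0.0, 0.0])
        pos = np.vstack([s.positions, shifted])
        dup = MolecularSystem(
            pos, np.concatenate([s.element] * 2),
            np.concatenate([s.molecule_id, s.molecule_id + s.molecule_id.max() + 1]),
            np.concatenate([s.molecule_class] * 2),
            np.concatenate([s.chain_label] * 2),
            np.concatenate([s.site_label] * 2),
            np.array([2 * s.box[0], s.box[1], s.box[2]]),
            np.concatenate([s.chain_position] * 2),
            np.concatenate([s.headgroup] * 2))
        n_leaf = small_stack.ground_truth["n_leaflets"]
        leaf1 = mdst.assign_leaflets(s, n_leaf)
        leaf2 = mdst.assign_leaflets(dup, n_leaf)
        apl1 = mdst.area_per_lipid(float(s.box[0] * s.box[1]),
                                   leaf1.counts()[1:-1])
        apl2 = mdst.area_per_lipid(float(dup.box[0] * dup.box[1]),
                                   leaf2.counts()[1:-1])
        assert apl2 == pytest.approx(apl1, rel=1e-12)
        p1 = mdst.density_profile(s, kind="mass")
        p2 = mdst.density_profile(dup, kind="mass")
        w = mdst.central_bilayer_window(leaf1)
        assert mdst.bilayer_thickness(p2, w) == pytest.approx(
            mdst.bilayer_thickness(p1, w))
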