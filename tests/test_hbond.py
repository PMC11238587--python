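import numpy as np
import pytest

from lamella import hbond
from lamella.hbond import HBond, HBondSiteTaxonomy, Site, census, default_taxonomy
from lamella.md_structure import MolecularSystem


def _system(rows, box=(6.0, 6.0, 6.0)):
    """rows: (xyz, element, mol_id, mol_class, site)"""
    pos = np.array([r[0] for r in rows], float)
    el = np.array([r[1] for r in rows], object)
    mid = np.array([r[2] for r in rows])
    cls = np.array([r[3] for r in rows], object)
    site = np.array([r[4] for r in rows], object)
    n = len(rows)
    return MolecularSystem(pos, el, mid, cls,
                           np.array(["none"] * n, object), site,
                           np.array(box, float))


def brute_force_hbonds(system, taxonomy=None, d_cut=0.35, angle_cut=30.0):
    """Independent all-pairs oracle: direct loops, no neighbor structure."""
    if taxonomy is None:
        taxonomy = default_taxonomy()
    donors = {s.name for s in taxonomy.sites if s.donor}
    acceptors = {s.name for s in taxonomy.sites if s.acceptor}
    box = system.box
    out = set()
    n = system.n_atoms
    for di in range(n):
        if system.element[di] not in ("N", "O") or system.site_label[di] not in donors:
            continue
        for hi in range(n):
            if (system.element[hi] not in ("H", "D")
                    or system.molecule_id[hi] != system.molecule_id[di]
                    or system.site_label[hi] != system.site_label[di]):
                continue
            for ai in range(n):
                if (system.element[ai] not in ("N", "O")
                        or system.site_label[ai] not in acceptors
                        or system.molecule_id[ai] == system.molecule_id[di]):
                    continue
                v_da = system.positions[ai] - system.positions[di]
                v_da -= box * np.round(v_da / box)
                d = np.linalg.norm(v_da)
                if d >= d_cut or d == 0:
                    continue
                v_dh = system.positions[hi] - system.positions[di]
                v_dh -= box * np.round(v_dh / box)
                nh = np.linalg.norm(v_dh)
                if nh == 0:
                    continue
                cosang = np.dot(v_da, v_dh) / (d * nh)
                ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if ang < angle_cut:
                    out.add((di, hi, ai))
    return out


def random_hbond_box(seed, n_molecules):
    """Random box of single-site molecules drawn from the full taxonomy."""
    rng = np.random.default_rng(seed)
    site_defs = [("CER_NH", "N", "CER_NS"), ("CER_CO", "O", "CER_NS"),
                 ("CER_O1H", "O", "CER_NS"), ("CER_O3H", "O", "CER_NP"),
                 ("CER_O88H", "O", "CER_NP"), ("FFA_CO", "O", "FFA"),
                 ("FFA_OH", "O", "FFA"), ("CHOL_OH", "O", "CHOL"),
                 ("WAT", "O", "WATER")]
    has_h = {"CER_NH", "CER_O1H", "CER_O3H", "CER_O88H", "FFA_OH",
             "CHOL_OH", "WAT"}
    box = 3.0
    rows = []
    for mid in range(n_molecules):
        name, el, cls = site_defs[rng.integers(len(site_defs))]
        p = rng.uniform(0, box, 3)
        rows.append((p, el, mid, cls, name))
        if name in has_h:
            for _ in range(2 if name == "WAT" else 1):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                rows.append((p + 0.1 * u, "H", mid, cls, name))
    return _system(rows, box=(box, box, box))


class TestEnumeratePairTypes:
    def test_default_lipid_taxonomy_gives_33(self):
        c = hbond.enumerate_pair_types(default_taxonomy(include_water=False))
        assert c["lipid_lipid"] == 33
        assert c["total"] == 33

    def test_with_water_gives_8_1_42(self):
        c = hbond.enumerate_pair_types(default_taxonomy())
        assert c["lipid_lipid"] == 33
        assert c["lipid_water"] == 8
        assert c["water_water"] == 1
        assert c["total"] == 42

    def test_pure_acceptor_site_alone_gives_zero(self):
        tax = HBondSiteTaxonomy([Site("X_CO", ("FFA",), False, True)])
        assert hbond.enumerate_pair_types(tax)["total"] == 0

    def test_site_must_have_a_role(self):
        with pytest.raises(ValueError):
            Site("inert", ("FFA",), False, False)


class TestDetectHBonds:
    def _pair(self, d, angle_deg):
        """CHOL O-H donating towards an FFA carbonyl along +x."""
        a = np.radians(angle_deg)
        rows = [((1.0, 1.0, 1.0), "O", 0, "CHOL", "CHOL_OH"),
                ((1.0 + 0.1 * np.cos(a), 1.0 + 0.1 * np.sin(a), 1.0),
                 "H", 0, "CHOL", "CHOL_OH"),
                ((1.0 + d, 1.0, 1.0), "O", 1, "FFA", "FFA_CO")]
        return _system(rows)

    def test_linear_short_contact_is_bond(self):
        bonds = hbond.detect_hbonds(self._pair(0.28, 0.0))
        assert len(bonds) == 1
        assert bonds[0].donor_site == "CHOL_OH"
        assert bonds[0].acceptor_site == "FFA_CO"
        assert bonds[0].distance == pytest.approx(0.28)

    def test_distance_cutoff(self):
        assert hbond.detect_hbonds(self._pair(0.40, 0.0)) == []

    def test_angle_cutoff(self):
        assert hbond.detect_hbonds(self._pair(0.30, 45.0)) == []

    def test_intramolecular_excluded(self):
        rows = [((1, 1, 1), "O", 0, "CER_NS", "CER_O1H"),
                ((1.1, 1, 1), "H", 0, "CER_NS", "CER_O1H"),
                ((1.3, 1, 1), "O", 0, "CER_NS", "CER_CO")]
        assert hbond.detect_hbonds(_system(rows)) == []

    def test_missing_donor_hydrogen_named_in_error(self):
        rows = [((1, 1, 1), "O", 0, "CHOL", "CHOL_OH"),
                ((2, 1, 1), "O", 1, "FFA", "FFA_CO")]
        with pytest.raises(ValueError, match="CHOL_OH"):
            hbond.detect_hbonds(_system(rows))

    def test_periodic_image_bond(self):
        rows = [((0.05, 1, 1), "O", 0, "CHOL", "CHOL_OH"),
                ((5.95, 1, 1), "H", 0, "CHOL", "CHOL_OH"),
                ((5.80, 1, 1), "O", 1, "FFA", "FFA_CO")]
        bonds = hbond.detect_hbonds(_system(rows))
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        system = random_hbond_box(seed, n_molecules=120)
        fast = {(b.donor_atom, b.h_atom, b.acceptor_atom)
                for b in hbond.detect_hbonds(system)}
        assert fast == brute_force_hbonds(system)

    def test_monotone_in_cutoffs(self):
        system = random_hbond_box(99, n_molecules=150)
        tight = {(b.donor_atom, b.h_atom, b.acceptor_atom)
                 for b in hbond.detect_hbonds(system, d_cut=0.30, angle_cut=20.0)}
        loose = {(b.donor_atom, b.h_atom, b.acceptor_atom)
                 for b in hbond.detect_hbonds(system, d_cut=0.35, angle_cut=30.0)}
        assert tight <= loose


def _mk_bond(dm, am, ds, as_):
    return HBond(0, 1, 2, dm, am, ds, as_, 0.28, 5.0)


class TestCensus:
    def _ten_cer_system(self):
        rows = []
        for mid in range(10):
            p = (0.5 * mid % 6, 1.0, 1.0)
            rows.append((p, "N", mid, "CER_NS", "CER_NH"))
            rows.append(((p[0] + 0.1, 1.0, 1.0), "H", mid, "CER_NS", "CER_NH"))
        return _system(rows)

    def test_n1_o4_counted_once_in_combined_amide(self):
        system = _system([
            ((1, 1, 1), "N", 0, "CER_NS", "CER_NH"),
            ((1.1, 1, 1), "H", 0, "CER_NS", "CER_NH"),
            ((1.3, 1, 1), "O", 1, "CER_NP", "CER_CO"),
        ])
        bonds = [_mk_bond(0, 1, "CER_NH", "CER_CO")]
        cen = census(bonds, system)
        assert cen.class_total("amideI") == 1
        assert cen.class_total("amideII") == 1
        assert cen.class_total("amideI+II") == 1  # footnote-style subtraction
        assert cen.total == 1

    def test_per_cer_normalization(self):
        system = self._ten_cer_system()
        bonds = [_mk_bond(i, j, "CER_NH", "CER_NH") for i, j in
                 [(0, 1), (2, 3), (4, 5), (6, 7)]]
        cen = census(bonds, system)
        assert cen.normalized[("CER", "lipid", "amideII")] == pytest.approx(0.4)

    def test_class_additivity_identity(self):
        system = random_hbond_box(7, n_molecules=200)
        bonds = hbond.detect_hbonds(system)
        cen = census(bonds, system)
        total = (cen.class_total("amideI") + cen.class_total("amideII")
                 + cen.class_total("other") - cen.class_total("both"))
        assert total == pytest.approx(cen.total)

    def test_frame_averaging(self):
        system = self._ten_cer_system()
        f1 = [_mk_bond(0, 1, "CER_NH", "CER_NH")]
        f2 = [_mk_bond(0, 1, "CER_NH", "CER_NH"),
              _mk_bond(2, 3, "CER_NH", "CER_NH")]
        cen = census([f1, f2], system)
        assert cen.frames == 2
        assert cen.total == pytest.approx(1.5)

    def test_inner_only_requires_leaflets(self):
        system = self._ten_cer_system()
        with pytest.raises(ValueError):
            census([], system, inner_only=True)

    def test_inner_only_restricts_to_inner_leaflets(self, small_stack):
        from lamella import md_structure as mdst
        s = small_stack.system
        leaf = mdst.assign_leaflets(s, small_stack.ground_truth["n_leaflets"])
        bonds = hbond.detect_hbonds(s)
        cen_all = census(bonds, s)
        cen_in = census(bonds, s, inner_only=True, leaflets=leaf)
        assert cen_in.total <= cen_all.total
        n_lip_in = sum(v for k, v in cen_in.molecule_counts.items()
                       if k != "WATER")
        assert n_lip_in == int(leaf.inner_mask.sum())
        # bulk water excluded from the inner region
        assert cen_in.molecule_counts.get("WATER", 0) == \
            small_stack.ground_truth["water_inner"]


class TestReplicateStats:
    def test_identical_replicates_flagged(self):
        res = hbond.replicate_stats({"m": [1.0, 1.0, 1.0]},
                                    {"m": [1.0, 1.0, 1.0]})
        assert res["a"]["m"]["sd"] == 0.0
        assert res["tests"]["m"]["defined"] is False

    def test_true_shift_detected_one_tailed(self, rng):
        a = list(0.66 + rng.normal(0, 0.01, 3))
        b = list(0.60 + rng.normal(0, 0.01, 3))
        res = hbond.replicate_stats({"m": a}, {"m": b})
        assert res["tests"]["m"]["p_one_sided_a_greater"] < 0.05

    def test_swapping_conditions_flips_direction(self, rng):
        a = list(rng.normal(1.0, 0.05, 3))
        b = list(rng.normal(0.8, 0.05, 3))
        r1 = hbond.replicate_stats({"m": a}, {"m": b})
        r2 = hbond.replicate_stats({"m": b}, {"m": a})
        assert (r1["tests"]["m"]["p_one_sided_a_greater"]
                + r2["tests"]["m"]["p_one_sided_a_greater"]) == pytest.approx(1.0)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            hbond.replicate_stats({"m": [1.0]})
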