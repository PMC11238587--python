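"""Geometric hydrogen-bond analysis for stratum-corneum lipid systems.

The lipid headgroups expose eight bonding sites — four on CER NS (amide
N-H, carbonyl C=O, hydroxyls O1-H and O3-H), those four plus the extra
phytosphingosine hydroxyl O88-H on CER NP, two on FFA (carbonyl, acid
O-H) and one on CHOL (hydroxyl) — plus water.  Hydroxyl/amine sites
donate; nitrogen and oxygen atoms accept.  A bond is counted when the
donor-acceptor distance is below 0.35 nm and the donor-centered
H-deviation angle below 30 degrees, intermolecular pairs only.

Bond pairs touching the CER carbonyl map to the amide I FTIR shift and
pairs touching the CER amide N-H to amide II; the one pair in both
classes (CER N-H donating to a CER C=O, the N1-O4 pair) is subtracted
once from the combined amide I+II total.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import ttest_ind

from .md_structure import LeafletAssignment, MolecularSystem

__all__ = [
    "Site",
    "HBondSiteTaxonomy",
    "default_taxonomy",
    "HBond",
    "HBondCensus",
    "enumerate_pair_types",
    "detect_hbonds",
    "census",
    "replicate_stats",
    "AMIDE_I_SITE",
    "AMIDE_II_SITE",
]

AMIDE_I_SITE = "CER_CO"   # ceramide carbonyl C=O
AMIDE_II_SITE = "CER_NH"  # ceramide amide N-H

_CER_CLASSES = ("CER_NS", "CER_NP")


@dataclass(frozen=True)
class Site:
    """One hydrogen-bonding site: host classes and donor/acceptor roles."""

    name: str
    classes: tuple
    donor: bool
    acceptor: bool

    def __post_init__(self) -> None:
        if not (self.donor or self.acceptor):
            raise ValueError(f"site {self.name}: must donate or accept")


@dataclass
class HBondSiteTaxonomy:
    sites: list[Site]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sites]
        if len(set(names)) != len(names):
            raise ValueError("duplicate site names")
        for s in self.sites:
            if s.name == "CER_O88H" and tuple(s.classes) != ("CER_NP",):
                raise ValueError("O88 is specific to CER NP")

    def site(self, name: str) -> Site:
        for s in self.sites:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sites]

    def is_water_site(self, name: str) -> bool:
        return "WATER" in self.site(name).classes

    def with_water(self) -> "HBondSiteTaxonomy":
        if any("WATER" in s.classes for s in self.sites):
            return self
        return HBondSiteTaxonomy(self.sites
                                 + [Site("WAT", ("WATER",), True, True)])


def default_taxonomy(include_water: bool = True) -> HBondSiteTaxonomy:
    """The 8 lipid sites of the CER NS / CER NP / CHOL / FFA system.

    Carbonyls are acceptor-only; every hydroxyl and the amide N-H both
    donate and accept (their N/O heavy atoms are acceptors).
    """
    sites = [
        Site("CER_NH", _CER_CLASSES, donor=True, acceptor=True),
        Site("CER_CO", _CER_CLASSES, donor=False, acceptor=True),
        Site("CER_O1H", _CER_CLASSES, donor=True, acceptor=True),
        Site("CER_O3H", _CER_CLASSES, donor=True, acceptor=True),
        Site("CER_O88H", ("CER_NP",), donor=True, acceptor=True),
        Site("FFA_CO", ("FFA",), donor=False, acceptor=True),
        Site("FFA_OH", ("FFA",), donor=True, acceptor=True),
        Site("CHOL_OH", ("CHOL",), donor=True, acceptor=True),
    ]
    tax = HBondSiteTaxonomy(sites)
    return tax.with_water() if include_water else tax


def enumerate_pair_types(taxonomy: HBondSiteTaxonomy) -> dict:
    """Count distinct unordered site pairs able to form a hydrogen bond.

    A pair (self-pairs allowed) qualifies when one member donates and the
    other accepts.  Partitioned into lipid-lipid, lipid-water and
    water-water by the hosts' classes.  The default 8-site lipid taxonomy
    yields 33 lipid-lipid pairs; adding water gives 8 lipid-water, 1
    water-water, 42 in total.
    """
    counts = {"lipid_lipid": 0, "lipid_water": 0, "water_water": 0}
    pairs = []
    for a, b in itertools.combinations_with_replacement(taxonomy.sites, 2):
        if not ((a.donor and b.acceptor) or (b.donor and a.acceptor)):
            continue
        wa = "WATER" in a.classes
        wb = "WATER" in b.classes
        key = ("water_water" if wa and wb
               else "lipid_water" if wa or wb
               else "lipid_lipid")
        counts[key] += 1
        pairs.append(tuple(sorted((a.name, b.name))))
    counts["total"] = sum(counts.values())
    counts["pairs"] = pairs
    return counts


@dataclass(frozen=True)
class HBond:
    donor_atom: int
    h_atom: int
    acceptor_atom: int
    donor_mol: int
    acceptor_mol: int
    donor_site: str
    acceptor_site: str
    distance: float
    angle: float  # degrees, donor-centered deviation


def _min_image(vec: np.ndarray, box: np.ndarray) -> np.ndarray:
    return vec - box * np.round(vec / box)


def detect_hbonds(system: MolecularSystem,
                  taxonomy: HBondSiteTaxonomy | None = None,
                  d_cut: float = 0.35, angle_cut: float = 30.0) -> list[HBond]:
    """Geometric hydrogen bonds between molecules.

    Criteria: donor-heavy-atom to acceptor distance < ``d_cut`` (nm,
    minimum image) and the angle at the donor between the D->H and D->A
    directions < ``angle_cut`` (degrees).  Intramolecular pairs are
    skipped.  Bonds are counted once per donor-H/acceptor pair, so
    bifurcated bonds each count.  Neighbor search uses a periodic k-d
    tree on the acceptor positions.
    """
    if taxonomy is None:
        taxonomy = default_taxonomy()
    if d_cut <= 0 or angle_cut <= 0:
        raise ValueError("cutoffs must be positive")
    donor_names = {s.name for s in taxonomy.sites if s.donor}
    acceptor_names = {s.name for s in taxonomy.sites if s.acceptor}

    sl = system.site_label
    el = system.element
    heavy = np.isin(el, ("N", "O"))
    hyd = np.isin(el, ("H", "D"))
    don_idx = np.flatnonzero(heavy & np.isin(sl, list(donor_names)))
    acc_idx = np.flatnonzero(heavy & np.isin(sl, list(acceptor_names)))
    if don_idx.size == 0 or acc_idx.size == 0:
        return []

    # map each donor heavy atom to its hydrogens (same molecule, same site)
    h_idx = np.flatnonzero(hyd & np.isin(sl, list(donor_names)))
    h_by_key: dict[tuple, list[int]] = {}
    for i in h_idx:
        h_by_key.setdefault((system.molecule_id[i], sl[i]), []).append(int(i))
    for i in don_idx:
        if (system.molecule_id[i], sl[i]) not in h_by_key:
            raise ValueError(
                f"donor site {sl[i]!r} on molecule {system.molecule_id[i]} "
                "has no hydrogen atoms")

    box = system.box
    pos = np.mod(system.positions, box)  # wrap for the periodic tree
    tree = cKDTree(pos[acc_idx], boxsize=box)
    cos_cut = np.cos(np.radians(angle_cut))

    bonds: list[HBond] = []
    neighbor_lists = tree.query_ball_point(pos[don_idx], r=d_cut)
    for di, neighbors in zip(don_idx, neighbor_lists):
        d_mol = int(system.molecule_id[di])
        hs = h_by_key[(d_mol, sl[di])]
        for k in neighbors:
            ai = int(acc_idx[k])
            a_mol = int(system.molecule_id[ai])
            if a_mol == d_mol:
                continue
            v_da = _min_image(system.positions[ai] - system.positions[di], box)
            dist = float(np.linalg.norm(v_da))
            if dist >= d_cut or dist == 0.0:
                continue
            for hi in hs:
                v_dh = _min_image(system.positions[hi] - system.positions[di], box)
                nh = np.linalg.norm(v_dh)
                if nh == 0:
                    continue
                cosang = float(np.dot(v_da, v_dh) / (dist * nh))
                if cosang > cos_cut:
                    ang = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                    bonds.append(HBond(int(di), int(hi), ai, d_mol, a_mol,
                                       str(sl[di]), str(sl[ai]), dist, ang))
    return bonds


def _pair_class(s1: str, s2: str) -> str:
    has_i = AMIDE_I_SITE in (s1, s2)
    has_ii = AMIDE_II_SITE in (s1, s2)
    if has_i and has_ii:
        return "both"
    if has_i:
        return "amideI"
    if has_ii:
        return "amideII"
    return "other"


@dataclass
class HBondCensus:
    """Per-pair-type bond counts (mean/frame) with amide bookkeeping.

    ``pair_counts`` keys are sorted site-name pairs.  ``molecule_counts``
    holds the molecules actually inside the census region, used for the
    per-molecule normalizations; CER lumps CER NS and CER NP.
    """

    pair_counts: dict
    pair_class: dict
    molecule_counts: dict
    frames: int
    normalized: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.pair_counts.values()))

    def class_total(self, cls: str) -> float:
        """Mean bonds/frame in one amide class ('both' pairs count in each)."""
        if cls == "amideI":
            keys = {"amideI", "both"}
        elif cls == "amideII":
            keys = {"amideII", "both"}
        elif cls in ("other", "both"):
            keys = {cls}
        elif cls == "amideI+II":
            return (self.class_total("amideI") + self.class_total("amideII")
                    - self.class_total("both"))
        else:
            raise ValueError(f"unknown class {cls!r}")
        return float(sum(v for k, v in self.pair_counts.items()
                         if self.pair_class[k] in keys))


def _mol_class_of(system: MolecularSystem) -> dict:
    ids, idx = np.unique(system.molecule_id, return_index=True)
    return {int(i): str(system.molecule_class[j]) for i, j in zip(ids, idx)}


def _norm_group(cls: str) -> str:
    return "CER" if cls in _CER_CLASSES else cls


def census(bonds, system: MolecularSystem, inner_only: bool = False,
           leaflets: LeafletAssignment | None = None,
           water_margin: float = 0.5) -> HBondCensus:
    """Aggregate detected bonds into the pair-type/amide-class census.

    ``bonds`` is one frame's bond list or a list of per-frame lists; the
    counts are averaged over frames.  With ``inner_only`` the census is
    restricted to lipids of the inner leaflets (leaflet assignment
    required) and waters within ``water_margin`` nm of the inner
    headgroup planes' z-extent, mirroring the headgroup-region restriction
    that keeps bulk water out.  Both bond partners must be in the region.

    Normalizations divide by the molecule counts actually present in the
    region; a class with zero molecules is reported as nan.
    """
    if bonds and isinstance(bonds[0], HBond):
        frames_bonds = [bonds]
    else:
        frames_bonds = list(bonds) if bonds else [[]]
    nframes = len(frames_bonds)

    mol_class = _mol_class_of(system)
    if inner_only:
        if leaflets is None:
            raise ValueError("inner_only census requires a leaflet assignment")
        allowed = set(int(m) for m in leaflets.molecule_ids[leaflets.inner_mask])
        inner_z = leaflets.leaflet_z[1:-1]
        zlo, zhi = inner_z.min() - water_margin, inner_z.max() + water_margin
        wmask = system.molecule_class == "WATER"
        for mid in np.unique(system.molecule_id[wmask]):
            zmol = system.positions[(system.molecule_id == mid) & wmask, 2]
            if zlo <= float(zmol.mean()) <= zhi:
                allowed.add(int(mid))
        in_region = lambda m: m in allowed  # noqa: E731
    else:
        in_region = lambda m: True  # noqa: E731

    pair_counts: dict = {}
    norm_counts: dict = {}
    for frame in frames_bonds:
        for b in frame:
            if not (in_region(b.donor_mol) and in_region(b.acceptor_mol)):
                continue
            key = tuple(sorted((b.donor_site, b.acceptor_site)))
            pair_counts[key] = pair_counts.get(key, 0) + 1
            cls = _pair_class(*key)
            groups = {_norm_group(mol_class[b.donor_mol]),
                      _norm_group(mol_class[b.acceptor_mol])}
            for g in groups:
                partner = (groups - {g} or {g}).pop()
                pgroup = "water" if partner == "WATER" else "lipid"
                norm_counts[(g, pgroup, cls)] = norm_counts.get((g, pgroup, cls), 0) + 1

    pair_counts = {k: v / nframes for k, v in pair_counts.items()}
    pair_class = {k: _pair_class(*k) for k in pair_counts}

    molecule_counts: dict = {}
    for mid, cls in mol_class.items():
        if in_region(mid):
            g = _norm_group(cls)
            molecule_counts[g] = molecule_counts.get(g, 0) + 1

    normalized: dict = {}
    for (g, pgroup, cls), n in norm_counts.items():
        denom = molecule_counts.get(g, 0)
        normalized[(g, pgroup, cls)] = (n / nframes / denom if denom
                                        else float("nan"))
    return HBondCensus(pair_counts, pair_class, molecule_counts, nframes,
                       normalized)


def replicate_stats(cond_a: dict, cond_b: dict | None = None) -> dict:
    """Mean +- SD per metric over replicates, with unpaired t-tests.

    ``cond_a`` (and optionally ``cond_b``) map metric names to lists of
    per-replicate values.  With two conditions, one- and two-tailed
    unpaired t-tests are reported per shared metric (one-tailed in the
    direction a > b; swapping the conditions flips it).  Zero-variance
    comparisons are flagged undefined.
    """
    def summarize(cond):
        out = {}
        for k, vals in cond.items():
            v = np.asarray(vals, float)
            if v.size < 2:
                raise ValueError(f"metric {k!r}: need >= 2 replicates")
            out[k] = {"mean": float(v.mean()), "sd": float(v.std(ddof=1)),
                      "n": int(v.size)}
        return out

    result = {"a": summarize(cond_a)}
    if cond_b is None:
        return result
    result["b"] = summarize(cond_b)
    tests = {}
    for k in set(cond_a) & set(cond_b):
        va = np.asarray(cond_a[k], float)
        vb = np.asarray(cond_b[k], float)
        if va.std(ddof=1) == 0 and vb.std(ddof=1) == 0:
            tests[k] = {"t": float("nan"), "p_two_sided": float("nan"),
                        "p_one_sided_a_greater": float("nan"),
                        "defined": False}
            continue
        two = ttest_ind(va, vb, equal_var=True)
        one = ttest_ind(va, vb, equal_var=True, alternative="greater")
        tests[k] = {"t": float(two.statistic),
                    "p_two_sided": float(two.pvalue),
                    "p_one_sided_a_greater": float(one.pvalue),
                    "defined": True}
    result["tests"] = tests
    return result
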