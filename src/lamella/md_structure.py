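"""Structural metrics and simulated SLD profiles from labeled coordinate
snapshots of lipid multilayer stacks.

The membrane normal is z.  Metrics follow the conventions used for
multilayer stratum-corneum models: area per lipid from the box
cross-section and the headgroup count of the four inner leaflets of a
six-leaflet stack; bilayer thickness from the headgroup peak-to-peak
distance of the central bilayer's mass density profile; chain tilt from
the minimum-inertia eigenvector; nematic order S2 from the largest
eigenvalue of the nematic tensor; and neutron SLD profiles from
scattering-length-weighted z-histograms with optional in-silico H->D
substitution (e.g. the NSd7 label: the last three sphingosine carbons).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from .datatypes import ATOMIC_MASS, COHERENT_B, SLDProfile

__all__ = [
    "MolecularSystem",
    "LeafletAssignment",
    "DensityProfile",
    "DeuterationSpec",
    "assign_leaflets",
    "density_profile",
    "bilayer_thickness",
    "central_bilayer_window",
    "area_per_lipid",
    "chain_tilt",
    "chain_director",
    "nematic_order",
    "classify_conformation",
    "conformation_fractions",
    "apply_deuteration",
    "simulated_sld_profile",
    "symmetrize_and_scale",
]

MOLECULE_CLASSES = ("CER_NS", "CER_NP", "CHOL", "FFA", "WATER")
CHAIN_LABELS = ("acyl", "sphingoid", "sterol", "ffa_chain", "none")


@dataclass
class MolecularSystem:
    """Labeled coordinate snapshot.

    Per-atom arrays: positions (N,3) in nm; element symbols (H, D, C, N,
    O); molecule id and class; chain label; hydrogen-bond site label (''
    when none); ``chain_position``: 1-based carbon index along the chain
    counted from the headgroup (hydrogens inherit their parent carbon's
    index; -1 elsewhere); ``headgroup``: the per-molecule reference atom
    used for leaflet assignment and APL counting.
    """

    positions: np.ndarray
    element: np.ndarray
    molecule_id: np.ndarray
    molecule_class: np.ndarray
    chain_label: np.ndarray
    site_label: np.ndarray
    box: np.ndarray
    chain_position: np.ndarray | None = None
    headgroup: np.ndarray | None = None
    frame_id: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        n = self.positions.shape[0]
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        self.element = np.asarray(self.element, dtype=object)
        self.molecule_id = np.asarray(self.molecule_id, dtype=int)
        self.molecule_class = np.asarray(self.molecule_class, dtype=object)
        self.chain_label = np.asarray(self.chain_label, dtype=object)
        self.site_label = np.asarray(self.site_label, dtype=object)
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")
        if self.chain_position is None:
            self.chain_position = np.full(n, -1, dtype=int)
        else:
            self.chain_position = np.asarray(self.chain_position, dtype=int)
        if self.headgroup is None:
            self.headgroup = np.zeros(n, dtype=bool)
        else:
            self.headgroup = np.asarray(self.headgroup, dtype=bool)
        for name in ("element", "molecule_id", "molecule_class", "chain_label",
                     "site_label", "chain_position", "headgroup"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length mismatch")
        bad = set(np.unique(self.molecule_class)) - set(MOLECULE_CLASSES)
        if bad:
            raise ValueError(f"unknown molecule classes: {sorted(bad)}")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "MolecularSystem":
        return MolecularSystem(self.positions.copy(), self.element.copy(),
                               self.molecule_id.copy(), self.molecule_class.copy(),
                               self.chain_label.copy(), self.site_label.copy(),
                               self.box.copy(), self.chain_position.copy(),
                               self.headgroup.copy(), self.frame_id)

    def lipid_molecules(self) -> tuple[np.ndarray, np.ndarray]:
        """(molecule ids, classes) of non-water molecules, id-sorted."""
        mask = self.molecule_class != "WATER"
        ids, idx = np.unique(self.molecule_id[mask], return_index=True)
        return ids, self.molecule_class[mask][idx]


@dataclass
class LeafletAssignment:
    """Leaflet index per lipid molecule, ordered by mean z."""

    molecule_ids: np.ndarray
    leaflet_index: np.ndarray
    inner_mask: np.ndarray          # per lipid: True away from bulk water
    leaflet_z: np.ndarray           # mean headgroup z per leaflet

    def members(self, leaflet: int) -> np.ndarray:
        return self.molecule_ids[self.leaflet_index == leaflet]

    def counts(self) -> np.ndarray:
        return np.bincount(self.leaflet_index, minlength=self.leaflet_z.size)


@dataclass
class DensityProfile:
    """z-histogram of mass or coherent scattering length."""

    z: np.ndarray       # bin centers, nm
    value: np.ndarray   # summed weight per bin
    kind: str           # mass | neutron_sld
    bin_width: float
    meta: dict = field(default_factory=dict)


def assign_leaflets(system: MolecularSystem, n_leaflets: int = 6) -> LeafletAssignment:
    """Group lipids into leaflets by 1D clustering of headgroup z.

    Headgroup reference z values are sorted and split at the
    ``n_leaflets - 1`` largest gaps — deterministic and exact when the
    headgroup planes are separated by more than their width.  The two
    outermost leaflets (contacting bulk water in a stack) are excluded
    from ``inner_mask``.
    """
    hg = system.headgroup & (system.molecule_class != "WATER")
    mol_ids = system.molecule_id[hg]
    z = system.positions[hg, 2]
    if mol_ids.size < n_leaflets:
        raise ValueError("fewer headgroup reference atoms than leaflets")
    order = np.argsort(z, kind="stable")
    z_sorted, ids_sorted = z[order], mol_ids[order]
    gaps = np.diff(z_sorted)
    cut_idx = np.sort(np.argsort(gaps)[::-1][: n_leaflets - 1]) + 1
    leaflet_sorted = np.zeros(z_sorted.size, dtype=int)
    for c in cut_idx:
        leaflet_sorted[c:] += 1
    # leaflets already ordered by mean z because z_sorted is ascending
    leaflet_z = np.array([z_sorted[leaflet_sorted == k].mean()
                          for k in range(n_leaflets)])
    inner = np.ones(mol_ids.size, dtype=bool)
    inner &= (leaflet_sorted != 0) & (leaflet_sorted != n_leaflets - 1)
    if n_leaflets <= 2:
        inner[:] = False
    return LeafletAssignment(ids_sorted, leaflet_sorted, inner, leaflet_z)


def _weights(system: MolecularSystem, kind: str) -> np.ndarray:
    table = ATOMIC_MASS if kind == "mass" else COHERENT_B
    try:
        return np.array([table[e] for e in system.element], dtype=float)
    except KeyError as exc:
        raise ValueError(f"unknown element {exc.args[0]!r}") from None


def density_profile(system: MolecularSystem, selection: np.ndarray | None = None,
                    kind: str = "mass", bin_width: float = 0.05,
                    z_range: tuple[float, float] | None = None) -> DensityProfile:
    """Histogram along z weighted by atomic mass or coherent scattering length.

    Default bin width 0.05 nm (0.5 Angstrom).  ``selection`` is a boolean
    atom mask (e.g. lipids only, excluding water, for the protiated SLD
    profile).  The sum over bins equals the summed weights of the
    selection.
    """
    if kind not in ("mass", "neutron_sld"):
        raise ValueError("kind must be 'mass' or 'neutron_sld'")
    if selection is None:
        selection = np.ones(system.n_atoms, dtype=bool)
    if not np.any(selection):
        raise ValueError("empty selection")
    z = system.positions[selection, 2]
    w = _weights(system, kind)[selection]
    if z_range is None:
        z_range = (float(z.min()), float(z.max()) + bin_width)
    lo, hi = z_range
    nbins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(nbins + 1)
    hist, _ = np.histogram(z, bins=edges, weights=w)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(centers, hist, kind, bin_width)


def central_bilayer_window(assignment: LeafletAssignment,
                           margin: float = 0.6) -> tuple[float, float]:
    """z-window covering the middle two leaflets' headgroup planes.

    ``margin`` (nm) pads beyond the two planes so the full headgroup
    peaks fall inside the window.
    """
    n = assignment.leaflet_z.size
    if n < 2:
        raise ValueError("need at least two leaflets")
    mid = assignment.leaflet_z[n // 2 - 1], assignment.leaflet_z[n // 2]
    return (float(min(mid) - margin), float(max(mid) + margin))


def bilayer_thickness(profile: DensityProfile,
                      window: tuple[float, float] | None = None) -> float:
    """Headgroup peak-to-peak distance (nm) of the central bilayer.

    Finds local maxima of the (mass) density profile inside ``window``
    and returns the separation of the two most prominent ones.
    """
    z, v = profile.z, profile.value
    if window is not None:
        lo, hi = min(window), max(window)
        m = (z >= lo) & (z <= hi)
        z, v = z[m], v[m]
    idx, props = find_peaks(v, prominence=0.0)
    if idx.size < 2:
        raise ValueError("fewer than two density maxima in the window")
    top2 = idx[np.argsort(props["prominences"])[::-1][:2]]
    return float(abs(z[top2[0]] - z[top2[1]]))


def area_per_lipid(box_xy_area: float, headgroups_per_leaflet) -> float:
    """Box cross-section divided by the mean headgroup count per leaflet.

    For a stack, pass the per-leaflet counts of the four inner leaflets;
    the mean count is used.
    """
    if box_xy_area <= 0:
        raise ValueError("box area must be positive")
    counts = np.atleast_1d(np.asarray(headgroups_per_leaflet, dtype=float))
    if np.any(counts <= 0):
        raise ValueError("headgroup counts must be positive")
    return float(box_xy_area / counts.mean())


def _inertia_axis(coords: np.ndarray) -> np.ndarray:
    """Minimum-eigenvalue eigenvector of the inertia tensor (unit masses)."""
    r = coords - coords.mean(axis=0)
    r2 = np.sum(r * r, axis=1)
    inertia = np.eye(3) * r2.sum() - r.T @ r
    w, v = np.linalg.eigh(inertia)
    if (w[1] - w[0]) <= 1e-10 * max(w[-1], 1e-300):
        raise ValueError("degenerate inertia tensor; chain axis undefined")
    return v[:, 0]


def chain_tilt(chain_coords: np.ndarray) -> float:
    """Angle (degrees, folded to [0, 90]) between the chain director and z.

    The director is the eigenvector of the minimum eigenvalue of the
    chain's inertia tensor; its sign is irrelevant for the tilt.
    """
    coords = np.asarray(chain_coords, dtype=float)
    if coords.shape[0] < 3:
        raise ValueError("need at least three atoms for a chain director")
    axis = _inertia_axis(coords)
    cosang = abs(axis[2]) / np.linalg.norm(axis)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def chain_director(chain_coords: np.ndarray) -> np.ndarray:
    """Unit director of a chain, oriented head (first atom) -> tail (last)."""
    coords = np.asarray(chain_coords, dtype=float)
    if coords.shape[0] < 3:
        raise ValueError("need at least three atoms for a chain director")
    axis = _inertia_axis(coords)
    span = coords[-1] - coords[0]
    if np.dot(axis, span) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def nematic_order(directors: np.ndarray) -> float:
    """S2: largest eigenvalue of Q = <(3/2) u u^T - (1/2) I>.

    1 for perfect alignment, ~0 for an isotropic set (up to finite-N
    fluctuation).
    """
    u = np.asarray(directors, dtype=float)
    if u.ndim != 2 or u.shape[1] != 3 or u.shape[0] < 2:
        raise ValueError("directors must be an (N>=2, 3) array")
    norms = np.linalg.norm(u, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-length director")
    u = u / norms[:, None]
    Q = 1.5 * (u.T @ u) / u.shape[0] - 0.5 * np.eye(3)
    return float(np.linalg.eigvalsh(Q)[-1])


def classify_conformation(acyl_coords: np.ndarray,
                          sphingoid_coords: np.ndarray) -> str:
    """'linear' when the two chain directors point to opposite sides.

    Directors are oriented head -> tail; an inter-director angle above
    90 degrees means the sphingoid and acyl tails extend in opposite
    directions (linear/extended ceramide), otherwise the molecule is in
    the hairpin conformation.
    """
    da = chain_director(acyl_coords)
    ds = chain_director(sphingoid_coords)
    return "linear" if float(np.dot(da, ds)) < 0.0 else "hairpin"


def conformation_fractions(system: MolecularSystem,
                           molecule_ids: np.ndarray | None = None) -> dict:
    """Linear/hairpin fractions over the ceramides of the system.

    Restricts to ``molecule_ids`` when given (e.g. the inner-leaflet
    ceramides).  Only carbons define the chain geometry.
    """
    is_cer = np.isin(system.molecule_class, ("CER_NS", "CER_NP"))
    ids = np.unique(system.molecule_id[is_cer])
    if molecule_ids is not None:
        ids = ids[np.isin(ids, molecule_ids)]
    n_linear = 0
    n_total = 0
    carbons = system.element == "C"
    for mid in ids:
        mol = system.molecule_id == mid
        ac = system.positions[mol & carbons & (system.chain_label == "acyl")]
        sp = system.positions[mol & carbons & (system.chain_label == "sphingoid")]
        if ac.shape[0] < 3 or sp.shape[0] < 3:
            raise ValueError(f"ceramide {mid} is missing a chain")
        n_total += 1
        if classify_conformation(ac, sp) == "linear":
            n_linear += 1
    if n_total == 0:
        return {"linear": float("nan"), "hairpin": float("nan"), "n": 0}
    return {"linear": n_linear / n_total, "hairpin": 1.0 - n_linear / n_total,
            "n": n_total}


@dataclass(frozen=True)
class DeuterationSpec:
    """In-silico H -> D substitution on chain-terminal carbons.

    ``n_terminal_carbons`` counts from the chain end; e.g. NSd7 is
    (CER_NS, sphingoid, 3): the hydrogens on the last three sphingosine
    carbons (2+2+3 = 7 per molecule) become deuterium.
    """

    molecule_class: str
    chain: str
    n_terminal_carbons: int

    def __post_init__(self) -> None:
        if self.molecule_class not in MOLECULE_CLASSES:
            raise ValueError(f"unknown molecule class {self.molecule_class!r}")
        if self.chain not in CHAIN_LABELS:
            raise ValueError(f"unknown chain label {self.chain!r}")
        if self.n_terminal_carbons < 1:
            raise ValueError("n_terminal_carbons must be >= 1")


NSD7 = DeuterationSpec("CER_NS", "sphingoid", 3)


def apply_deuteration(system: MolecularSystem,
                      specs: list[DeuterationSpec]) -> MolecularSystem:
    """Return a copy with the specified hydrogens replaced by deuterium."""
    out = system.copy()
    for spec in specs:
        chain_mask = ((out.molecule_class == spec.molecule_class)
                      & (out.chain_label == spec.chain))
        if not np.any(chain_mask):
            raise ValueError(f"deuteration spec matches no atoms: {spec}")
        carbons = chain_mask & (out.element == "C")
        hit_any = False
        for mid in np.unique(out.molecule_id[chain_mask]):
            mol = chain_mask & (out.molecule_id == mid)
            cpos = out.chain_position[mol & carbons]
            if cpos.size == 0:
                continue
            first = int(cpos.max()) - spec.n_terminal_carbons + 1
            target = mol & (out.element == "H") & (out.chain_position >= first)
            out.element[target] = "D"
            hit_any = hit_any or bool(np.any(target))
        if not hit_any:
            raise ValueError(f"deuteration spec replaced no hydrogens: {spec}")
    return out


def simulated_sld_profile(system: MolecularSystem,
                          deuteration: list[DeuterationSpec] | None = None,
                          bin_width: float = 0.05, lipids_only: bool = True,
                          z_range: tuple[float, float] | None = None) -> DensityProfile:
    """Neutron SLD z-profile, optionally after in-silico deuteration.

    The protiated reference profile uses ``deuteration=None`` (or an
    empty list).  ``lipids_only`` excludes water, matching the
    experimental lipid-only reference profile.
    """
    sys_d = apply_deuteration(system, deuteration) if deuteration else system
    sel = (sys_d.molecule_class != "WATER") if lipids_only else None
    prof = density_profile(sys_d, selection=sel, kind="neutron_sld",
                           bin_width=bin_width, z_range=z_range)
    prof.meta["deuteration"] = [str(s) for s in (deuteration or [])]
    return prof


def symmetrize_and_scale(profile: DensityProfile | SLDProfile,
                         center: float | None = None,
                         d: float | None = None) -> SLDProfile:
    """Symmetrize a one-unit-cell profile about its center and map to [0, 100].

    rho'(x) = (rho(x) + rho(-x)) / 2 on the centered axis, then an affine
    map puts min at 0 and max at 100 exactly.  A constant profile has no
    defined scale and raises.
    """
    if isinstance(profile, SLDProfile):
        x, v = profile.x, profile.rho
        d_out = profile.d
    else:
        z = profile.z
        if center is None:
            center = float(0.5 * (z.min() + z.max()))
        x, v = z - center, profile.value
        d_out = d if d is not None else float(z.max() - z.min() + profile.bin_width)
    mirrored = np.interp(-x, x, v)
    sym = 0.5 * (v + mirrored)
    lo, hi = float(sym.min()), float(sym.max())
    if hi - lo <= 1e-12 * max(abs(hi), 1.0):
        raise ValueError("profile symmetrizes to a constant; 0-100 scale undefined")
    scaled = (sym - lo) / (hi - lo) * 100.0
    return SLDProfile(x, scaled, d_out, scale_tag="scaled_0_100")
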