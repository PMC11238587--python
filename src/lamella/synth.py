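"""Synthetic ground-truth generators for every pipeline input.

Three generators cover the three experimental arms:

* :func:`build_stack` — an idealized multilayer coordinate stack (three
  bilayers / six leaflets by default) of CER NS / CER NP / CHOL / FFA C24
  with headgroups at the unit-cell borders, all-trans zigzag chains
  (0.125 nm C-C axial projection), a chosen linear/hairpin ceramide split
  and tilt, inner-leaflet water and optional bulk water, plus deuterium
  labels.  It is a geometric construction with full ground-truth labels,
  not a simulator.
* :func:`forward_diffraction` — Bragg amplitudes of a band-limited SLD
  model at several D2O contrasts, with the water layer at the unit-cell
  border (contrast-matched near 8% D2O), seeded noise and known signs.
* :func:`forward_ftir` helpers — Lorentzian band spectra and logistic
  thermotropic curves with stored ground truth.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import ContrastSeries, SLDProfile, Spectrum1D, StructureFactorSet
from .ftir import ThermotropicCurve
from .md_structure import DeuterationSpec, MolecularSystem, apply_deuteration
from .neutron import absorption_correction

__all__ = [
    "StackSpec",
    "StackBuild",
    "build_stack",
    "DiffractionSpec",
    "ForwardDiffraction",
    "forward_diffraction",
    "default_diffraction_spec",
    "scissoring_spectrum",
    "amide_spectrum",
    "thermotropic_curve",
    "flat_spectrum",
]

_CC = 0.125       # nm, axial C-C projection of an all-trans chain
_ZIGZAG = 0.05    # nm, lateral zigzag offset
_CH = 0.10        # nm, C-H / O-H / N-H placement distance

# default simulated composition: CER:CHOL:FFA = 1:0.5:1, CER NS:NP = 2:1
_DEFAULT_COMPOSITION = {"CER_NS": 0.2667, "CER_NP": 0.1333,
                        "CHOL": 0.2, "FFA": 0.4}


@dataclass
class StackSpec:
    """Construction parameters of a synthetic multilayer stack.

    Defaults mirror the modeled short-periodicity phase: three bilayers
    with a 5.4 nm repeat, APL 0.334 nm^2, CER:CHOL:FFA 1:0.5:1 with
    CER NS:NP 2:1, ~35% linear ceramides, ~12 degree chain tilt and 0.4
    inner-leaflet waters per lipid.
    """

    n_bilayers: int = 3
    d: float = 5.4
    apl: float = 0.334
    composition: dict = field(default_factory=lambda: dict(_DEFAULT_COMPOSITION))
    linear_fraction: float = 0.35
    tilt: float = 12.0
    water_per_lipid_inner: float = 0.4
    bulk_water_layers: bool = True
    bulk_water_per_nm2: float = 8.0
    lipids_per_leaflet: int = 60
    deuteration: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d <= 0 or self.apl <= 0 or self.n_bilayers < 1:
            raise ValueError("d, apl and n_bilayers must be positive")
        total = sum(self.composition.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError("composition molar ratios must sum to 1")
        if not (0.0 <= self.linear_fraction <= 1.0):
            raise ValueError("linear_fraction must lie in [0, 1]")
        if self.apl < 0.25:
            raise ValueError("APL below 0.25 nm^2 cannot pack two chains; "
                             "infeasible stack")


@dataclass
class StackBuild:
    """A built stack together with its ground truth."""

    system: MolecularSystem
    ground_truth: dict


class _Builder:
    def __init__(self) -> None:
        self.pos: list = []
        self.el: list = []
        self.mol: list = []
        self.cls: list = []
        self.chain: list = []
        self.site: list = []
        self.cpos: list = []
        self.head: list = []
        self.next_mol = 0

    def atom(self, p, el, cls, chain="none", site="", cpos=-1, head=False):
        self.pos.append(np.asarray(p, float))
        self.el.append(el)
        self.mol.append(self.next_mol)
        self.cls.append(cls)
        self.chain.append(chain)
        self.site.append(site)
        self.cpos.append(cpos)
        self.head.append(head)

    def end_molecule(self):
        self.next_mol += 1

    def system(self, box) -> MolecularSystem:
        return MolecularSystem(np.array(self.pos), np.array(self.el, object),
                               np.array(self.mol), np.array(self.cls, object),
                               np.array(self.chain, object),
                               np.array(self.site, object), np.asarray(box, float),
                               np.array(self.cpos), np.array(self.head, bool))


def _chain_atoms(b: _Builder, origin, axis, n_carbons, cls, chain_label,
                 with_h=True, n_flat=0, cpos_offset=0):
    """All-trans zigzag chain of ``n_carbons`` along a unit ``axis``.

    The first ``n_flat`` carbons stay in the headgroup plane (lateral
    offsets only), mimicking chain carbons buried in the headgroup
    region; the rest advance axially by the 0.125 nm C-C projection.
    """
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    # lateral zigzag direction perpendicular to the axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    perp1 = np.cross(axis, ref)
    perp1 /= np.linalg.norm(perp1)
    perp2 = np.cross(axis, perp1)
    for i in range(n_carbons):
        adv = max(i + 1 - n_flat, 0)
        lat = (0.12 * (n_flat - i) if i < n_flat else 0.0)
        c = (np.asarray(origin, float) + adv * _CC * axis
             + ((-1) ** i) * _ZIGZAG * perp1 + lat * perp2)
        b.atom(c, "C", cls, chain_label, cpos=i + 1 + cpos_offset)
        if not with_h:
            continue
        n_h = 3 if i == n_carbons - 1 else 2
        for k in range(n_h):
            off = perp2 if k == 0 else -perp2 if k == 1 else axis
            b.atom(c + _CH * off, "H", cls, chain_label,
                   cpos=i + 1 + cpos_offset)


def _tilt_axis(direction: float, tilt_deg: float, azimuth: float) -> np.ndarray:
    t = np.radians(tilt_deg)
    return np.array([np.sin(t) * np.cos(azimuth),
                     np.sin(t) * np.sin(azimuth),
                     direction * np.cos(t)])


def _largest_remainder(fracs: dict, total: int) -> dict:
    raw = {k: v * total for k, v in fracs.items()}
    out = {k: int(np.floor(v)) for k, v in raw.items()}
    rem = total - sum(out.values())
    order = sorted(raw, key=lambda k: raw[k] - np.floor(raw[k]), reverse=True)
    for k in order[:rem]:
        out[k] += 1
    return out


def _place_cer(b, x, y, z0, direction, cls, axis_a, axis_s, linear):
    """Ceramide: headgroup sites at the border, acyl 24 C, sphingoid 18 C."""
    up = direction
    b.atom((x, y, z0 + 0.05 * up), "N", cls, site="CER_NH", head=True)
    b.atom((x + _CH, y, z0 + 0.05 * up), "H", cls, site="CER_NH")
    b.atom((x - 0.12, y, z0 + 0.10 * up), "C", cls)            # carbonyl carbon
    b.atom((x - 0.12, y + _CH, z0 + 0.12 * up), "O", cls, site="CER_CO")
    b.atom((x + 0.12, y, z0 + 0.10 * up), "O", cls, site="CER_O1H")
    b.atom((x + 0.12, y + _CH, z0 + 0.10 * up), "H", cls, site="CER_O1H")
    b.atom((x, y - 0.15, z0 + 0.08 * up), "O", cls, site="CER_O3H")
    b.atom((x, y - 0.15 - _CH, z0 + 0.08 * up), "H", cls, site="CER_O3H")
    if cls == "CER_NP":
        b.atom((x, y + 0.15, z0 + 0.08 * up), "O", cls, site="CER_O88H")
        b.atom((x, y + 0.15 + _CH, z0 + 0.08 * up), "H", cls, site="CER_O88H")
    _chain_atoms(b, (x - 0.12, y, z0 + 0.1 * up), axis_a, 24, cls, "acyl")
    # the first two sphingoid carbons sit in the headgroup; the remaining
    # 16 extend axially, so the C18 terminus lies ~2 nm from the border
    s_origin = (x + 0.12, y, z0 + 0.1 * up if not linear else z0 - 0.1 * up)
    s_axis = axis_s if not linear else -axis_s
    _chain_atoms(b, s_origin, s_axis, 18, cls, "sphingoid", n_flat=2)
    b.end_molecule()


def _place_chol(b, x, y, z0, direction, axis):
    b.atom((x, y, z0 + 0.05 * direction), "O", "CHOL", site="CHOL_OH", head=True)
    b.atom((x + _CH, y, z0 + 0.05 * direction), "H", "CHOL", site="CHOL_OH")
    _chain_atoms(b, (x, y, z0 + 0.05 * direction), axis, 17, "CHOL", "sterol")
    b.end_molecule()


def _place_ffa(b, x, y, z0, direction, axis):
    b.atom((x, y, z0 + 0.05 * direction), "C", "FFA", "ffa_chain",
           cpos=1, head=True)
    b.atom((x - _CH, y, z0 + 0.03 * direction), "O", "FFA", site="FFA_CO")
    b.atom((x + _CH, y, z0 + 0.03 * direction), "O", "FFA", site="FFA_OH")
    b.atom((x + 2 * _CH, y, z0 + 0.03 * direction), "H", "FFA", site="FFA_OH")
    _chain_atoms(b, (x, y, z0 + 0.05 * direction), axis, 23, "FFA",
                 "ffa_chain", cpos_offset=1)  # carboxyl carbon is C1
    b.end_molecule()


def _place_water(b, p):
    p = np.asarray(p, float)
    b.atom(p, "O", "WATER", site="WAT")
    b.atom(p + (_CH, 0, 0), "H", "WATER", site="WAT")
    b.atom(p + (-0.033, 0.094, 0), "H", "WATER", site="WAT")
    b.end_molecule()


def build_stack(spec: StackSpec) -> StackBuild:
    """Construct the labeled multilayer stack described by ``spec``.

    Bilayer k occupies z in [k d, (k+1) d] (plus a bulk-water offset);
    leaflet 2k's headgroups sit on the lower border with chains pointing
    up, leaflet 2k+1 mirrors it from the upper border.  Linear ceramides
    extend their sphingoid chain across the border instead.  Lipids are
    laid out on a per-leaflet square lattice whose cross-section realises
    the requested APL exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n_lip = spec.lipids_per_leaflet
    n_leaflets = 2 * spec.n_bilayers
    box_l = float(np.sqrt(n_lip * spec.apl))
    w_pad = 1.0 if spec.bulk_water_layers else 0.3
    box_z = spec.n_bilayers * spec.d + 2 * w_pad
    z_off = w_pad

    counts = _largest_remainder(spec.composition, n_lip)
    n_cer_per_leaflet = counts.get("CER_NS", 0) + counts.get("CER_NP", 0)
    n_cer_total = n_cer_per_leaflet * n_leaflets
    n_linear_total = int(round(spec.linear_fraction * n_cer_total))

    # lattice positions, lipid classes shuffled deterministically per leaflet
    nx = int(np.ceil(np.sqrt(n_lip)))
    sx = box_l / nx
    # spread the linear ceramides evenly over the whole stack so each
    # leaflet carries close to the requested fraction and the global
    # count is exact
    linear_flags = [(i + 1) * n_linear_total // max(n_cer_total, 1)
                    - i * n_linear_total // max(n_cer_total, 1) > 0
                    for i in range(n_cer_total)]

    b = _Builder()
    cer_seen = 0
    for leaflet in range(n_leaflets):
        bilayer = leaflet // 2
        lower = leaflet % 2 == 0
        z0 = z_off + bilayer * spec.d + (0.0 if lower else spec.d)
        direction = 1.0 if lower else -1.0
        classes = ([c for c, n in sorted(counts.items()) for _ in range(n)])
        rng.shuffle(classes)
        cells = [(i, j) for i in range(nx) for j in range(nx)][:n_lip]
        offset = 0.25 * sx if lower else 0.75 * sx  # stagger opposing leaflets
        for (i, j), cls in zip(cells, classes):
            x = (i + 0.5) * sx % box_l
            y = ((j + 0.5) * sx + offset) % box_l
            az = rng.uniform(0, 2 * np.pi)
            axis = _tilt_axis(direction, spec.tilt, az)
            if cls in ("CER_NS", "CER_NP"):
                linear = linear_flags[cer_seen]
                cer_seen += 1
                _place_cer(b, x, y, z0, direction, cls, axis, axis, linear)
            elif cls == "CHOL":
                _place_chol(b, x, y, z0, direction, axis)
            else:
                _place_ffa(b, x, y, z0, direction, axis)

    # inner-leaflet water at the interior borders
    n_inner_lipids = (n_leaflets - 2) * n_lip
    n_water_inner = int(round(spec.water_per_lipid_inner * n_inner_lipids))
    inner_borders = [z_off + k * spec.d for k in range(1, spec.n_bilayers)]
    for w in range(n_water_inner):
        zb = inner_borders[w % len(inner_borders)]
        _place_water(b, (rng.uniform(0, box_l), rng.uniform(0, box_l),
                         zb + rng.uniform(-0.15, 0.15)))

    n_bulk = 0
    if spec.bulk_water_layers:
        n_bulk = int(round(spec.bulk_water_per_nm2 * box_l**2))
        for side in (0, 1):
            zlo = 0.1 if side == 0 else box_z - w_pad + 0.1
            for _ in range(n_bulk):
                _place_water(b, (rng.uniform(0, box_l), rng.uniform(0, box_l),
                                 zlo + rng.uniform(0, w_pad - 0.2)))

    system = b.system((box_l, box_l, box_z))
    if spec.deuteration:
        system = apply_deuteration(system, list(spec.deuteration))

    # ground-truth NSd7 label position: |z - central unit-cell center| of
    # the hydrogens on the last three sphingoid carbons of CER NS
    nsd7_truth = float("nan")
    label = ((system.molecule_class == "CER_NS")
             & (system.chain_label == "sphingoid")
             & (system.element == "H") & (system.chain_position >= 16))
    if np.any(label):
        center = z_off + (spec.n_bilayers // 2) * spec.d + spec.d / 2
        zc = np.abs(system.positions[label, 2] - center)
        in_cell = zc <= spec.d / 2
        if np.any(in_cell):
            nsd7_truth = float(np.mean(zc[in_cell]))

    truth = {
        "d": spec.d,
        "apl": spec.apl,
        "tilt": spec.tilt,
        "n_leaflets": n_leaflets,
        "lipids_per_leaflet": n_lip,
        "counts_per_leaflet": counts,
        "linear_fraction": n_linear_total / max(n_cer_total, 1),
        "n_linear": n_linear_total,
        "n_cer": n_cer_total,
        "nsd7_mean_abs_z": nsd7_truth,
        "water_inner": n_water_inner,
        "water_bulk": 2 * n_bulk,
        "box": [box_l, box_l, box_z],
        "z_offset": z_off,
        "seed": spec.seed,
    }
    return StackBuild(system, truth)


# ---------------------------------------------------------------------------
# forward diffraction


@dataclass
class DiffractionSpec:
    """Band-limited forward model of a lamellar contrast series.

    The lipid unit cell is the cosine series with coefficients
    ``lipid_coeffs`` (signed F_n of orders 1..N at the water match point)
    plus ``F0``.  Water sits in a Gaussian layer of width ``water_sigma``
    at the unit-cell border; its scattering vanishes at
    ``match_fraction`` D2O and grows linearly with the D2O fraction, so
    order n acquires a slope with sign (-1)^n.  Intensities are
    I_n = F_n^2 A_n / L with multiplicative Gaussian noise.
    """

    d: float = 5.4
    lipid_coeffs: np.ndarray = None
    F0: float = 0.0
    contrasts: tuple = (0.08, 0.5, 1.0)
    noise_sd: float = 0.0
    mu: float = 0.0
    l: float = 0.1
    water_amplitude: float = 1.5
    water_sigma: float = 0.35
    match_fraction: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lipid_coeffs is None:
            raise ValueError("lipid_coeffs required")
        self.lipid_coeffs = np.asarray(self.lipid_coeffs, dtype=float)
        self.contrasts = tuple(float(c) for c in self.contrasts)
        if any(not 0 <= c <= 1 for c in self.contrasts):
            raise ValueError("contrasts must lie in [0, 1]")

    @property
    def orders(self) -> np.ndarray:
        return np.arange(1, self.lipid_coeffs.size + 1)

    def water_coeffs(self, fraction: float) -> np.ndarray:
        """Signed water contribution to each order at a D2O fraction."""
        n = self.orders
        damp = np.exp(-2.0 * (np.pi * n * self.water_sigma / self.d) ** 2)
        return (self.water_amplitude * (fraction - self.match_fraction)
                * (-1.0) ** n * damp)

    def signed_F(self, fraction: float) -> np.ndarray:
        return self.lipid_coeffs + self.water_coeffs(fraction)

    def truth_profile(self, fraction: float, npoints: int = 512) -> SLDProfile:
        """Band-limited ground-truth SLD profile at one contrast."""
        x = np.linspace(-self.d / 2, self.d / 2, npoints)
        rho = np.full(npoints, self.F0)
        for n, F in zip(self.orders, self.signed_F(fraction)):
            rho += (2.0 / self.d) * F * np.cos(2 * np.pi * n * x / self.d)
        return SLDProfile(x, rho, self.d)


@dataclass
class ForwardDiffraction:
    series: ContrastSeries
    intensities: dict          # fraction -> I_n array (Lorentz/absorption applied)
    true_signs: dict           # fraction -> sign array
    spec: DiffractionSpec


def forward_diffraction(spec: DiffractionSpec) -> ForwardDiffraction:
    """Generate the unsigned contrast series plus its ground truth."""
    rng = np.random.default_rng(spec.seed)
    q_n = 2 * np.pi * spec.orders / spec.d
    sets, intensities, true_signs = [], {}, {}
    for f in spec.contrasts:
        F = spec.signed_F(f)
        noise = rng.normal(1.0, spec.noise_sd, F.size) if spec.noise_sd else 1.0
        F_obs = np.abs(F) * noise
        theta = np.arcsin(np.clip(q_n * 0.1 / (4 * np.pi), -1, 1)) + 0.05
        A = np.array([absorption_correction(t, spec.mu, spec.l) for t in theta])
        intensities[f] = F_obs**2 * A / q_n
        true_signs[f] = np.sign(F).astype(int)
        true_signs[f][true_signs[f] == 0] = 1
        sets.append(StructureFactorSet(spec.d, spec.orders, F_obs, F0=spec.F0))
    series = ContrastSeries(np.array(spec.contrasts), sets)
    return ForwardDiffraction(series, intensities, true_signs, spec)


def default_diffraction_spec(seed: int = 0, noise_sd: float = 0.0,
                             n_orders: int = 4) -> DiffractionSpec:
    """Paper-like system: headgroups at the border, water matched at 8% D2O.

    The border-headgroup cosine coefficients alternate as (-1)^n, so the
    phased signs at the 8% reference come out - + - + for orders 1-4.
    """
    d, sigma_h = 5.4, 0.40
    n = np.arange(1, n_orders + 1)
    amp_h = 3.0
    coeffs = amp_h * (-1.0) ** n * np.exp(-2.0 * (np.pi * n * sigma_h / d) ** 2)
    return DiffractionSpec(d=d, lipid_coeffs=coeffs, F0=1.0, seed=seed,
                           noise_sd=noise_sd)


# ---------------------------------------------------------------------------
# forward FTIR


def _lorentz(x, center, height, fwhm):
    return height / (1.0 + 4.0 * ((x - center) / fwhm) ** 2)


def scissoring_spectrum(splitting: float, or_mid_ratio: float | None,
                        band: str = "dCH2", outer_height: float = 2.0,
                        fwhm: float = 2.0, noise_sd: float = 0.0,
                        seed: int = 0, dx: float = 0.1) -> tuple[Spectrum1D, dict]:
    """Scissoring band: orthorhombic doublet plus optional central peak.

    ``or_mid_ratio=None`` omits the central (hexagonal) component.
    Returns the spectrum and its ground truth.
    """
    center = {"dCH2": 1467.5, "dCD2": 1090.0}[band]
    lo, hi = {"dCH2": (1450.0, 1485.0), "dCD2": (1072.0, 1108.0)}[band]
    rng = np.random.default_rng(seed)
    x = np.arange(lo, hi + dx / 2, dx)
    c1, c2 = center - splitting / 2, center + splitting / 2
    y = _lorentz(x, c1, outer_height, fwhm) + _lorentz(x, c2, outer_height, fwhm)
    truth = {"centers": [c1, c2], "splitting": splitting,
             "or_mid_ratio": or_mid_ratio, "outer_height": outer_height}
    if or_mid_ratio is not None:
        h_mid = outer_height / or_mid_ratio
        y += _lorentz(x, center, h_mid, fwhm)
        truth["centers"] = [c1, center, c2]
    if noise_sd:
        y = y + rng.normal(0, noise_sd, x.size)
    return Spectrum1D(x, y, "cm^-1", "absorbance"), truth


def amide_spectrum(centers, heights=None, fwhm: float = 12.0,
                   noise_sd: float = 0.0, seed: int = 0,
                   dx: float = 0.25) -> tuple[Spectrum1D, dict]:
    """Amide-window spectrum (1480-1700 cm^-1) of Lorentzian bands."""
    centers = list(centers)
    if heights is None:
        heights = [1.0] * len(centers)
    rng = np.random.default_rng(seed)
    x = np.arange(1480.0, 1700.0 + dx / 2, dx)
    y = np.zeros_like(x)
    for c, h in zip(centers, heights):
        y += _lorentz(x, c, h, fwhm)
    if noise_sd:
        y = y + rng.normal(0, noise_sd, x.size)
    return Spectrum1D(x, y, "cm^-1", "absorbance"), {"centers": centers,
                                                     "heights": heights}


def flat_spectrum(lo: float = 1480.0, hi: float = 1700.0, level: float = 0.1,
                  dx: float = 0.25) -> Spectrum1D:
    x = np.arange(lo, hi + dx / 2, dx)
    return Spectrum1D(x, np.full(x.size, level), "cm^-1", "absorbance")


def thermotropic_curve(steps, base: float = 2848.3, band: str = "vsCH2",
                       t_range: tuple = (10.0, 90.0), n_points: int = 81,
                       noise_sd: float = 0.0,
                       seed: int = 0) -> tuple[ThermotropicCurve, dict]:
    """Logistic thermotropic curve with one or more transition steps.

    ``steps`` is a list of (midpoint degC, amplitude cm^-1, width degC).
    The defaults mimic ordered chains (< 2849 cm^-1) stepping up through
    the orthorhombic-hexagonal and hexagonal-liquid (> 2853 cm^-1)
    transitions.
    """
    rng = np.random.default_rng(seed)
    T = np.linspace(*t_range, n_points)
    w = np.full(T.size, float(base))
    for tm, amp, width in steps:
        w = w + amp / (1.0 + np.exp(-(T - tm) / width))
    if noise_sd:
        w = w + rng.normal(0, noise_sd, T.size)
    return (ThermotropicCurve(T, w, band),
            {"steps": list(steps), "base": base})
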