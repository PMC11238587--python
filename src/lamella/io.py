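"""File formats and run configuration.

1D data (patterns, spectra, profiles) travel as two-column numeric text
with ``#`` metadata headers; structure factors as TSV; coordinates as
GRO/PDB through MDAnalysis with the molecule-class / chain / site labels
encoded in residue and atom names; configuration as YAML with explicit
units on physical parameters.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .datatypes import ContrastSeries, SLDProfile, Spectrum1D, StructureFactorSet
from .md_structure import MolecularSystem

__all__ = [
    "read_spectrum", "write_spectrum",
    "read_sld_profile", "write_sld_profile",
    "read_structure_factors", "write_structure_factors",
    "read_coordinates", "write_coordinates",
    "write_ground_truth", "read_ground_truth",
    "RunConfig", "load_config", "save_config",
]


# --------------------------------------------------------------------- 1D data

def read_spectrum(path) -> Spectrum1D:
    """Two-column whitespace/CSV numeric text; '#' header lines ignored."""
    xs, ys, meta = [], [], {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*(\w+)\s*[:=]\s*(.+)", line)
                if m:
                    meta[m.group(1)] = m.group(2).strip()
                continue
            parts = re.split(r"[,\s]+", line)
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
    if not xs:
        raise ValueError(f"no data rows in {path}")
    return Spectrum1D(np.array(xs), np.array(ys),
                      meta.pop("x_unit", ""), meta.pop("y_unit", ""), meta)


def write_spectrum(spectrum: Spectrum1D, path, **extra_meta) -> None:
    with open(path, "w") as fh:
        if spectrum.x_unit:
            fh.write(f"# x_unit: {spectrum.x_unit}\n")
        if spectrum.y_unit:
            fh.write(f"# y_unit: {spectrum.y_unit}\n")
        for k, v in {**spectrum.meta, **extra_meta}.items():
            fh.write(f"# {k}: {v}\n")
        for x, y in zip(spectrum.x, spectrum.y):
            fh.write(f"{x:.10g}\t{y:.10g}\n")


def write_sld_profile(profile: SLDProfile, path, **extra_meta) -> None:
    with open(path, "w") as fh:
        fh.write(f"# d: {profile.d:.10g}\n")
        fh.write(f"# scale_tag: {profile.scale_tag}\n")
        for k, v in {**profile.meta, **extra_meta}.items():
            fh.write(f"# {k}: {v}\n")
        for x, r in zip(profile.x, profile.rho):
            fh.write(f"{x:.12g}\t{r:.12g}\n")


def read_sld_profile(path) -> SLDProfile:
    sp = read_spectrum(path)
    meta = dict(sp.meta)
    d = float(meta.pop("d"))
    tag = meta.pop("scale_tag", "arbitrary")
    return SLDProfile(sp.x, sp.y, d, scale_tag=tag, meta=meta)


# ---------------------------------------------------------- structure factors

def write_structure_factors(obj, path) -> None:
    """TSV: contrast, order, q, F_abs, sign (0 while unsigned), F0, d."""
    if isinstance(obj, StructureFactorSet):
        series = [(float("nan"), obj)]
    elif isinstance(obj, ContrastSeries):
        series = list(zip(obj.d2o_fractions, obj.sets))
    else:
        raise TypeError("expected StructureFactorSet or ContrastSeries")
    with open(path, "w") as fh:
        fh.write("contrast\torder\tq\tF_abs\tsign\tF0\td\n")
        for frac, sf in series:
            q = 2 * np.pi * sf.orders / sf.d
            signs = sf.signs if sf.signs is not None else np.zeros(sf.orders.size, int)
            for n, qn, F, s in zip(sf.orders, q, sf.F_abs, signs):
                fh.write(f"{frac:.6g}\t{n}\t{qn:.10g}\t{F:.10g}\t{s}"
                         f"\t{sf.F0:.10g}\t{sf.d:.10g}\n")


def read_structure_factors(path):
    """Inverse of :func:`write_structure_factors`.

    Returns a StructureFactorSet for single-contrast files, otherwise a
    ContrastSeries.
    """
    rows = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        for line in fh:
            if line.strip():
                rows.append(dict(zip(header, line.split())))
    if not rows:
        raise ValueError(f"no data rows in {path}")
    by_contrast: dict = {}
    for r in rows:
        by_contrast.setdefault(r["contrast"], []).append(r)
    sets, fracs = [], []
    for frac, group in by_contrast.items():
        orders = np.array([int(r["order"]) for r in group])
        F = np.array([float(r["F_abs"]) for r in group])
        signs = np.array([int(r["sign"]) for r in group])
        d = float(group[0]["d"])
        F0 = float(group[0]["F0"])
        sf = StructureFactorSet(d, orders, F,
                                signs=signs if np.all(signs != 0) else None,
                                F0=F0)
        sets.append(sf)
        fracs.append(float(frac))
    if len(sets) == 1:
        return sets[0]
    return ContrastSeries(np.array(fracs), sets)


# --------------------------------------------------------------- coordinates

_RESNAME = {"CER_NS": "CNS", "CER_NP": "CNP", "CHOL": "CHL", "FFA": "FFA",
            "WATER": "SOL"}
_RESNAME_INV = {v: k for k, v in _RESNAME.items()}
_CHAIN_LETTER = {"acyl": "A", "sphingoid": "S", "sterol": "T", "ffa_chain": "F"}
_CHAIN_INV = {v: k for k, v in _CHAIN_LETTER.items()}

# (resname, atom name) -> (element, site, headgroup flag) for non-chain atoms
_SITE_ATOMS = {}
for _res in ("CNS", "CNP"):
    _SITE_ATOMS.update({
        (_res, "N1"): ("N", "CER_NH", True),
        (_res, "HN1"): ("H", "CER_NH", False),
        (_res, "C1"): ("C", "", False),
        (_res, "O4"): ("O", "CER_CO", False),
        (_res, "O1"): ("O", "CER_O1H", False),
        (_res, "HO1"): ("H", "CER_O1H", False),
        (_res, "O3"): ("O", "CER_O3H", False),
        (_res, "HO3"): ("H", "CER_O3H", False),
    })
_SITE_ATOMS[("CNP", "O88")] = ("O", "CER_O88H", False)
_SITE_ATOMS[("CNP", "HO88")] = ("H", "CER_O88H", False)
_SITE_ATOMS.update({
    ("FFA", "OC1"): ("O", "FFA_CO", False),
    ("FFA", "OH1"): ("O", "FFA_OH", False),
    ("FFA", "HO1"): ("H", "FFA_OH", False),
    ("CHL", "OH1"): ("O", "CHOL_OH", True),
    ("CHL", "HO1"): ("H", "CHOL_OH", False),
    ("SOL", "OW"): ("O", "WAT", False),
    ("SOL", "HW1"): ("H", "WAT", False),
    ("SOL", "HW2"): ("H", "WAT", False),
})

_CHAIN_RE = re.compile(r"^([HD]?)([ASTF])(\d+)$")


def _atom_name(system: MolecularSystem, i: int) -> str:
    chain = system.chain_label[i]
    if chain in _CHAIN_LETTER and system.chain_position[i] >= 1:
        letter = _CHAIN_LETTER[chain]
        el = system.element[i]
        prefix = "" if el == "C" else el  # H or D
        return f"{prefix}{letter}{system.chain_position[i]}"
    res = _RESNAME[system.molecule_class[i]]
    site, el = system.site_label[i], system.element[i]
    for (r, name), (e, s, _h) in _SITE_ATOMS.items():
        if r == res and s == site and e == ("H" if el == "D" else el):
            if res == "SOL" and s == "WAT" and el in ("H", "D"):
                break  # handled below, two H names
            return name
    if res == "SOL":
        return "OW" if el == "O" else "HW1"
    if site == "" and el == "C":
        return "C1"
    raise ValueError(f"cannot encode atom {i} ({res}, site={site!r}, {el})")


def write_coordinates(system: MolecularSystem, path) -> None:
    """Write GRO or PDB (by extension) with labels encoded in the names."""
    import warnings

    import MDAnalysis as mda

    n = system.n_atoms
    _, resindex = np.unique(system.molecule_id, return_inverse=True)
    names = []
    water_h_seen: dict = {}
    for i in range(n):
        name = _atom_name(system, i)
        if name == "HW1":
            k = water_h_seen.get(system.molecule_id[i], 0)
            water_h_seen[system.molecule_id[i]] = k + 1
            name = f"HW{k + 1}"
        names.append(name)
    res_first = np.searchsorted(resindex, np.arange(resindex.max() + 1),
                                side="left")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, n_residues=int(resindex.max()) + 1,
                               atom_resindex=resindex, trajectory=True)
        u.add_TopologyAttr("names", names)
        u.add_TopologyAttr("resnames", [_RESNAME[system.molecule_class[j]]
                                        for j in res_first])
        u.add_TopologyAttr("resids", np.arange(resindex.max() + 1) + 1)
        u.atoms.positions = system.positions * 10.0  # nm -> Angstrom
        u.dimensions = [*(system.box * 10.0), 90.0, 90.0, 90.0]
        u.atoms.write(str(path))


def read_coordinates(path) -> MolecularSystem:
    """Read a GRO/PDB file written with this package's label encoding."""
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    n = len(u.atoms)
    pos = u.atoms.positions / 10.0
    box = u.dimensions[:3] / 10.0
    el = np.empty(n, dtype=object)
    cls = np.empty(n, dtype=object)
    chain = np.full(n, "none", dtype=object)
    site = np.full(n, "", dtype=object)
    cpos = np.full(n, -1, dtype=int)
    head = np.zeros(n, dtype=bool)
    for i, atom in enumerate(u.atoms):
        res = atom.resname
        if res not in _RESNAME_INV:
            raise ValueError(f"unknown residue name {res!r}")
        cls[i] = _RESNAME_INV[res]
        name = atom.name
        m = _CHAIN_RE.match(name)
        if m:
            prefix, letter, idx = m.groups()
            el[i] = prefix or "C"
            chain[i] = _CHAIN_INV[letter]
            cpos[i] = int(idx)
            if cls[i] == "FFA" and cpos[i] == 1 and el[i] == "C":
                head[i] = True
            continue
        if res == "SOL" and name.startswith("HW"):
            el[i], site[i] = "H", "WAT"
            continue
        key = (res, name)
        if key not in _SITE_ATOMS:
            raise ValueError(f"unknown atom name {name!r} in residue {res!r}")
        el[i], site[i], head[i] = _SITE_ATOMS[key]
    mol_id = u.atoms.resindices.astype(int)
    return MolecularSystem(pos, el, mol_id, cls, chain, site, box, cpos, head)


# ------------------------------------------------------------- ground truth

def write_ground_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(truth), fh, sort_keys=True)


def read_ground_truth(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ------------------------------------------------------------- configuration

# key -> (unit or "" for dimensionless, default)
_CONFIG_SCHEMA = {
    "seed": ("", 0),
    "output_dir": ("", "lamella_out"),
    "log_level": ("", "INFO"),
    "d_cut": ("nm", 0.35),
    "angle_cut": ("deg", 30.0),
    "bin_width": ("nm", 0.05),
    "fsd_gamma": ("cm^-1", 2.2),
    "fsd_smoothing": ("", 76.7),
    "d_guess": ("nm", 5.4),
    "order_tolerance": ("", 0.1),
    "n_bilayers": ("", 3),
    "lipids_per_leaflet": ("", 24),
    "apl": ("nm^2", 0.334),
    "repeat_distance": ("nm", 5.4),
    "tilt": ("deg", 12.0),
    "linear_fraction": ("", 0.35),
    "water_per_lipid_inner": ("", 0.4),
}


@dataclass
class RunConfig:
    """Validated run parameters with explicit units on physical values."""

    values: dict = field(default_factory=dict)

    def __getitem__(self, key):
        if key in self.values:
            return self.values[key]
        return _CONFIG_SCHEMA[key][1]

    def as_dict(self) -> dict:
        return {k: self[k] for k in _CONFIG_SCHEMA}

    def content_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        payload = {k: v for k, v in self.as_dict().items()
                   if k not in ("output_dir", "log_level")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _parse_quantity(key: str, raw, unit: str):
    if unit == "":
        return raw
    if isinstance(raw, dict):
        if set(raw) != {"value", "unit"}:
            raise ValueError(f"{key}: expected {{value, unit}}")
        got_unit, value = raw["unit"], raw["value"]
    elif isinstance(raw, str):
        parts = raw.split()
        if len(parts) != 2:
            raise ValueError(f"{key}: physical parameter must carry a unit "
                             f"(e.g. '0.35 {unit}')")
        value, got_unit = float(parts[0]), parts[1]
    else:
        raise ValueError(f"{key}: physical parameter given without a unit; "
                         f"write '<value> {unit}'")
    if got_unit != unit:
        raise ValueError(f"{key}: expected unit {unit!r}, got {got_unit!r}")
    return float(value)


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; unknown keys are rejected."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(p) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    values = {}
    for key, v in raw.items():
        if key not in _CONFIG_SCHEMA:
            raise ValueError(f"unknown config key {key!r}")
        values[key] = _parse_quantity(key, v, _CONFIG_SCHEMA[key][0])
    return RunConfig(values)


def save_config(config: RunConfig, path) -> None:
    out = {}
    for key, (unit, _default) in _CONFIG_SCHEMA.items():
        v = config[key]
        out[key] = f"{v:.10g} {unit}" if unit else v
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=True)
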