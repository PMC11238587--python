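"""End-to-end pipeline: synthesize inputs, run every analysis stage,
write versioned outputs and a machine-readable JSON summary."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import __version__, ftir, hbond, md_structure as mdst, neutron, saxd, synth
from .io import RunConfig, write_ground_truth, write_sld_profile

log = logging.getLogger("lamella")

__all__ = ["run_pipeline", "PipelineError", "stack_metrics"]


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are preserved in the output dir."""


def stack_metrics(build: synth.StackBuild, d_cut: float = 0.35,
                  angle_cut: float = 30.0, bin_width: float = 0.05) -> dict:
    """All structural metrics of one built stack.

    APL over the four inner leaflets; thickness, tilt and S2 for the
    central bilayer; conformation fractions over the inner-leaflet
    ceramides; the NSd7 difference-profile peak positions; and the
    inner-leaflet hydrogen-bond census.
    """
    system = build.system
    truth = build.ground_truth
    leaflets = mdst.assign_leaflets(system, truth["n_leaflets"])

    box_area = float(system.box[0] * system.box[1])
    inner_counts = leaflets.counts()[1:-1]
    apl = mdst.area_per_lipid(box_area, inner_counts)

    window = mdst.central_bilayer_window(leaflets)
    mass = mdst.density_profile(system, kind="mass", bin_width=bin_width)
    thickness = mdst.bilayer_thickness(mass, window=window)

    n = truth["n_leaflets"]
    central_ids = np.concatenate([leaflets.members(n // 2 - 1),
                                  leaflets.members(n // 2)])
    carbons = system.element == "C"
    tilts, directors = [], []
    for mid in central_ids:
        mol = system.molecule_id == mid
        for chain in ("acyl", "sphingoid", "sterol", "ffa_chain"):
            coords = system.positions[mol & carbons
                                      & (system.chain_label == chain)]
            if coords.shape[0] >= 3:
                tilts.append(mdst.chain_tilt(coords))
                directors.append(mdst.chain_director(coords))
    s2_directors = np.array([d if d[2] >= 0 else -d for d in directors])
    s2 = mdst.nematic_order(s2_directors)

    inner_ids = leaflets.molecule_ids[leaflets.inner_mask]
    conf = mdst.conformation_fractions(system, molecule_ids=inner_ids)

    prot = mdst.simulated_sld_profile(system, None, bin_width=bin_width)
    deut = mdst.simulated_sld_profile(system, [mdst.NSD7], bin_width=bin_width)
    diff = mdst.DensityProfile(prot.z, deut.value - prot.value, "neutron_sld",
                               bin_width)
    z_off = truth["z_offset"]
    d = truth["d"]
    center = z_off + truth["n_leaflets"] // 4 * d + d / 2  # central unit cell
    lo, hi = center - d / 2, center + d / 2
    m = (diff.z >= lo) & (diff.z <= hi)
    cell = mdst.DensityProfile(diff.z[m], diff.value[m], "neutron_sld", bin_width)
    scaled = mdst.symmetrize_and_scale(cell, center=center, d=d)
    half = scaled.x > 0
    peak_pos = float(scaled.x[half][np.argmax(scaled.rho[half])])

    bonds = hbond.detect_hbonds(system, d_cut=d_cut, angle_cut=angle_cut)
    cen = hbond.census(bonds, system, inner_only=True, leaflets=leaflets)
    n_water_inner = cen.molecule_counts.get("WATER", 0)
    n_lipid_inner = sum(v for k, v in cen.molecule_counts.items()
                        if k != "WATER")

    return {
        "apl_nm2": float(apl),
        "bilayer_thickness_nm": float(thickness),
        "tilt_deg_mean": float(np.mean(tilts)),
        "s2": float(s2),
        "linear_fraction": conf["linear"],
        "nsd7_peak_nm": peak_pos,
        "hbond_total_per_frame": cen.total,
        "waters_per_lipid_inner": (n_water_inner / n_lipid_inner
                                   if n_lipid_inner else float("nan")),
        "hbond_molecule_counts": dict(cen.molecule_counts),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run synth -> analysis end-to-end; returns the summary dict.

    Outputs (profiles, ground truth, summary.json, log) land in the
    configured output directory; every file records the package version,
    the config hash and the seed.  A stage failure raises PipelineError
    after writing whatever completed.
    """
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    provenance = {"version": __version__, "config_hash": config.content_hash(),
                  "seed": seed}
    summary: dict = {"provenance": provenance}

    def finalize(failed_stage: str | None = None, error: str | None = None):
        if failed_stage:
            summary["failed_stage"] = failed_stage
            summary["error"] = error
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=float)

    try:
        spec = synth.StackSpec(
            n_bilayers=int(config["n_bilayers"]),
            d=float(config["repeat_distance"]),
            apl=float(config["apl"]),
            tilt=float(config["tilt"]),
            linear_fraction=float(config["linear_fraction"]),
            water_per_lipid_inner=float(config["water_per_lipid_inner"]),
            lipids_per_leaflet=int(config["lipids_per_leaflet"]),
            seed=seed)
        build = synth.build_stack(spec)
        write_ground_truth({**build.ground_truth, **provenance},
                           outdir / "stack_truth.yaml")
        summary["stack"] = stack_metrics(
            build, d_cut=float(config["d_cut"]),
            angle_cut=float(config["angle_cut"]),
            bin_width=float(config["bin_width"]))
    except Exception as exc:  # pragma: no cover - error path
        finalize("stack", str(exc))
        raise PipelineError(f"stack stage failed: {exc}") from exc

    try:
        dspec = synth.default_diffraction_spec(seed=seed)
        fwd = synth.forward_diffraction(dspec)
        phasing = neutron.determine_phase_signs(fwd.series)
        profile = neutron.fourier_reconstruct(phasing.sf)
        write_sld_profile(profile, outdir / "sld_profile.dat", **provenance)
        q_obs = 2 * np.pi * dspec.orders / dspec.d
        assignment = saxd.assign_orders(q_obs, float(config["d_guess"]),
                                        float(config["order_tolerance"]))
        summary["diffraction"] = {
            "phase_signs": phasing.sf.signs.tolist(),
            "repeat_distance_nm": assignment.d,
            "reconstruction_points": int(profile.x.size),
        }
    except Exception as exc:  # pragma: no cover
        finalize("diffraction", str(exc))
        raise PipelineError(f"diffraction stage failed: {exc}") from exc

    try:
        curve, truth_tm = synth.thermotropic_curve(
            steps=[(32.6, 1.2, 1.0), (70.8, 4.0, 1.5)], seed=seed)
        tm1 = ftir.transition_midpoint(curve, window=(10, 50))
        tm2 = ftir.transition_midpoint(curve, window=(50, 90))
        spectrum, truth_sc = synth.scissoring_spectrum(10.3, 2.3, seed=seed)
        sc = ftir.scissoring_analysis(spectrum)
        summary["ftir"] = {
            "tm_orthorhombic_hexagonal_C": tm1.t_m,
            "tm_hexagonal_liquid_C": tm2.t_m,
            "scissoring_splitting_cm1": sc.splitting,
            "or_mid_ratio": sc.or_mid_ratio,
        }
    except Exception as exc:  # pragma: no cover
        finalize("ftir", str(exc))
        raise PipelineError(f"ftir stage failed: {exc}") from exc

    finalize()
    log.info("pipeline complete: %s", outdir / "summary.json")
    return summary
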