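"""End-to-end pipeline: trajectory → clusters → GRASP → PMM → shift table.

One YAML config drives every stage; each stage writes its artifact
(CSV / extended-XYZ / point-charge file) into the output directory with
the config hash and seed embedded, so a rerun with the same config and
seeds is bit-identical and any stage output can be inspected or reused.

Stages, in order:

1. load (or synthesize) the trajectory and topology;
2. subsample to the decorrelation stride;
3. extract the six solute–solvent interaction distances per frame;
4. PCA to the explained-variance target;
5. PAM scan over k with the 3-of-4 vote;
6. proportional GRASP selection per cluster;
7. collective-frame construction and point-charge export;
8. PMM excitation energies per frame and Gaussian-broadened,
   population-weighted spectra;
9. shift-table assembly (externally computed QM band positions enter
   here from the config, mirroring the composition rule).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .cluster import cluster_scan
from .core import CybospecError, Trajectory
from .features import extract_features, pca_fit_transform
from .pmm import (
    build_perturbed_hamiltonian,
    diagonalize_pmm,
    read_qm_reference,
    site_potentials,
)
from .selection import allocate_frames, build_collective_frame, grasp_select
from .spectra import Spectrum, average_spectra, broaden, build_shift_table
from .structure import subsample
from .synthetic import Regime, RegimeSpec, gen_qm_reference, gen_trajectory
from .units import hartree_to_wavenumber

__all__ = ["PipelineError", "load_config", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(CybospecError):
    """A stage failed; the message names the stage and its input."""


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise CybospecError("workflow config must be a YAML mapping")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _stamp(path: Path, cfg_hash: str, seed: int) -> None:
    """Prefix an artifact with its provenance comment line."""
    text = path.read_text()
    path.write_text(f"# config={cfg_hash} seed={seed}\n{text}")


def _validate(cfg: dict) -> None:
    """Fail fast on missing inputs before any expensive stage runs."""
    traj_cfg = cfg.get("trajectory", {})
    if "synthetic" not in traj_cfg:
        for key in ("path", "topology"):
            if key not in traj_cfg:
                raise PipelineError(f"stage validate: trajectory.{key} missing from config")
            if not Path(traj_cfg[key]).exists():
                raise PipelineError(f"stage validate: {traj_cfg[key]} does not exist")
    pmm_cfg = cfg.get("pmm", {})
    ref = pmm_cfg.get("qm_reference")
    if isinstance(ref, str) and not Path(ref).exists():
        raise PipelineError(f"stage validate: QM reference file {ref} does not exist")
    if isinstance(ref, list):
        for r in ref:
            if not Path(r).exists():
                raise PipelineError(f"stage validate: QM reference file {r} does not exist")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage {name} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("trajectory")
def _load_trajectory(cfg: dict, seed: int) -> tuple[Trajectory, np.ndarray | None]:
    traj_cfg = cfg.get("trajectory", {})
    if "synthetic" in traj_cfg:
        syn = traj_cfg["synthetic"]
        regimes = tuple(
            Regime(
                hb_count=int(r["hb_count"]),
                dwell=float(r["dwell"]),
                r_mean=float(r.get("r_mean", 1.85)),
                r_sd=float(r.get("r_sd", 0.05)),
                angle_sd=float(r.get("angle_sd", 4.0)),
            )
            for r in syn["regimes"]
        )
        spec = RegimeSpec(
            regimes=regimes,
            n_frames=int(syn.get("n_frames", 100)),
            seed=int(syn.get("seed", seed)),
            n_bulk=int(syn.get("n_bulk", 12)),
            sphere_radius=float(syn.get("sphere_radius", 12.0)),
        )
        return gen_trajectory(None, None, spec)
    topology = cio.read_topology(traj_cfg["topology"])
    return cio.read_trajectory(traj_cfg["path"], topology), None


@_stage("features")
def _features(traj: Trajectory, cfg: dict):
    site_names = cfg.get("sites", {"N": "N", "O": "O", "LP1": "LP1", "LP2": "LP2"})
    sites = {k: traj.topology.index_of(v) for k, v in site_names.items()}
    elements = cfg.get("candidate_elements", ["O"])
    cand = [i for i, a in enumerate(traj.topology.atoms)
            if a.role == "solvent" and a.element in elements]
    return extract_features(traj, sites, np.asarray(cand, dtype=int))


def run_pipeline(cfg: dict, output_dir: str | Path | None = None) -> dict:
    """Execute the full workflow; return all stage results in a dict.

    Artifacts are written under ``output_dir`` (default: the config's
    ``output_dir``, default ``./cybospec_out``). The returned dict
    holds the trajectory, feature matrix, clustering, GRASP selection,
    per-cluster spectra, the averaged spectrum, and the shift table
    (when the config supplies the external QM band positions).
    """
    _validate(cfg)
    seed = int(cfg.get("seed", 0))
    cfg_hash = _config_hash(cfg)
    outdir = Path(output_dir or cfg.get("output_dir", "cybospec_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"config_hash": cfg_hash, "seed": seed}

    traj, planted = _load_trajectory(cfg, seed)
    results["trajectory"] = traj
    results["planted_labels"] = planted

    stride = float(cfg.get("stride_ps", 10.0))
    if stride > traj.stride:
        traj_s = subsample(traj, stride)
    else:
        traj_s = traj
    results["subsampled"] = traj_s

    fm = _features(traj_s, cfg)
    pd.DataFrame(fm.values, columns=list(fm.feature_labels)).to_csv(
        outdir / "features.csv", index=False
    )
    _stamp(outdir / "features.csv", cfg_hash, seed)

    model, reduced = pca_fit_transform(fm, float(cfg.get("pca_variance", 0.90)))
    results["pca"] = model
    results["reduced"] = reduced

    kcfg = cfg.get("clustering", {})
    clustering = cluster_scan(
        reduced,
        k_min=int(kcfg.get("k_min", 2)),
        k_max=int(kcfg.get("k_max", 8)),
        seed=seed,
    )
    results["clustering"] = clustering
    pd.DataFrame(
        {"frame": np.arange(len(clustering.labels)), "label": clustering.labels}
    ).to_csv(outdir / "clusters.csv", index=False)
    _stamp(outdir / "clusters.csv", cfg_hash, seed)
    score_rows = [{"k": k, **sc} for k, sc in sorted(clustering.scores.items())]
    pd.DataFrame(score_rows).to_csv(outdir / "k_scores.csv", index=False)
    _stamp(outdir / "k_scores.csv", cfg_hash, seed)

    gcfg = cfg.get("grasp", {})
    sizes = [int(np.sum(clustering.labels == c)) for c in range(clustering.k)]
    budget = int(gcfg.get("budget", max(clustering.k, round(0.05 * len(clustering.labels)))))
    counts = allocate_frames(sizes, budget)
    selections = []
    objectives = []
    for c in range(clustering.k):
        members = np.flatnonzero(clustering.labels == c)
        sel, J = grasp_select(
            reduced[members],
            min(counts[c], len(members)),
            alpha=float(gcfg.get("alpha", 0.3)),
            n_restarts=int(gcfg.get("restarts", 20)),
            seed=seed + c,
        )
        selections.append(members[sel])
        objectives.append(J)
    results["grasp"] = {
        "counts": counts,
        "frames": selections,
        "objectives": objectives,
    }
    rows = [
        {"cluster": c, "frame": int(f)}
        for c, sel in enumerate(selections) for f in sel
    ]
    pd.DataFrame(rows).to_csv(outdir / "selection.csv", index=False)
    _stamp(outdir / "selection.csv", cfg_hash, seed)

    # collective frames: solvent charges of the selected frames at 1/N
    medoid_frames = [traj_s.frames[int(m)] for m in clustering.medoid_indices]
    collectives = []
    for c in range(clustering.k):
        frames = [traj_s.frames[int(f)] for f in selections[c]]
        cf = build_collective_frame(frames, traj_s.topology, medoid_frames[c])
        collectives.append(cf)
        pc_path = outdir / f"cframe_cluster{c + 1}.pc"
        cio.write_point_charges(cf.solvent_charges, cf.solvent_coordinates, pc_path)
        _stamp(pc_path, cfg_hash, seed)
    results["collective_frames"] = collectives

    # PMM spectra (per cluster, reference anchored at the medoid frame)
    pmm_cfg = cfg.get("pmm", {})
    if pmm_cfg:
        results.update(_pmm_stage(cfg, pmm_cfg, traj_s, clustering, sizes, outdir,
                                  cfg_hash, seed))

    shift_cfg = cfg.get("shift_table")
    if shift_cfg:
        table = build_shift_table(shift_cfg["solvents"], shift_cfg["reference"])
        table.to_csv(outdir / "shift_table.csv", index=False)
        _stamp(outdir / "shift_table.csv", cfg_hash, seed)
        results["shift_table"] = table

    return results


@_stage("pmm")
def _pmm_stage(cfg, pmm_cfg, traj_s, clustering, sizes, outdir, cfg_hash, seed):
    top = traj_s.topology
    solute_mol = top.atoms[0].molecule_id
    solute_idx = [i for i, a in enumerate(top.atoms)
                  if a.molecule_id == solute_mol and a.role != "virtual_site"]
    solvent_idx = [i for i, a in enumerate(top.atoms) if a.molecule_id != solute_mol]
    charges = top.charges

    ref_spec = pmm_cfg.get("qm_reference", {"synthetic": {}})
    refs = []
    for c in range(clustering.k):
        if isinstance(ref_spec, str):
            refs.append(read_qm_reference(ref_spec))
        elif isinstance(ref_spec, list):
            refs.append(read_qm_reference(ref_spec[c]))
        else:
            syn = ref_spec.get("synthetic", {})
            ref = gen_qm_reference(
                n_states=int(syn.get("n_states", 11)),
                n_atoms=len(solute_idx),
                coupling_scale=float(syn.get("coupling_scale", 0.02)),
                seed=int(syn.get("seed", seed)) + c,
            )
            # anchor the reference potentials at the cluster medoid so the
            # perturbation vanishes there, as in a real reference computation
            medoid = traj_s.frames[int(clustering.medoid_indices[c])]
            vref = site_potentials(
                medoid.coordinates[solvent_idx], charges[solvent_idx],
                medoid.coordinates[solute_idx],
            )
            ref = dataclasses.replace(ref, reference_potentials=vref)
            refs.append(ref)

    hwhm = float(pmm_cfg.get("hwhm", 600.0))
    grid_cfg = pmm_cfg.get("grid", {})
    grid = np.arange(
        float(grid_cfg.get("min", 200.0)),
        float(grid_cfg.get("max", 800.0)) + 1e-9,
        float(grid_cfg.get("step", 0.1)),
    )

    energy_rows = []
    per_cluster_spectra: list[Spectrum] = []
    for c in range(clustering.k):
        members = np.flatnonzero(clustering.labels == c)
        sticks: list[tuple[float, float]] = []
        for f in members:
            fr = traj_s.frames[int(f)]
            V = site_potentials(
                fr.coordinates[solvent_idx], charges[solvent_idx],
                fr.coordinates[solute_idx],
            )
            res = diagonalize_pmm(build_perturbed_hamiltonian(refs[c], V), refs[c])
            nu = hartree_to_wavenumber(res.excitation_energies)
            for state, (nu_k, f_k) in enumerate(
                zip(nu, res.oscillator_strengths), start=1
            ):
                energy_rows.append(
                    {"cluster": c, "frame": int(f), "state": state,
                     "wavenumber_cm1": float(nu_k), "oscillator_strength": float(f_k)}
                )
                sticks.append((float(nu_k), float(f_k) / len(members)))
        per_cluster_spectra.append(broaden(sticks, hwhm=hwhm, grid=grid))

    pd.DataFrame(energy_rows).to_csv(outdir / "pmm_energies.csv", index=False)
    _stamp(outdir / "pmm_energies.csv", cfg_hash, seed)

    weights = np.asarray(sizes, dtype=float)
    weights /= weights.sum()
    averaged = average_spectra(per_cluster_spectra, weights)
    pd.DataFrame(
        {"wavelength_nm": averaged.grid, "epsilon": averaged.epsilon}
    ).to_csv(outdir / "spectrum.csv", index=False)
    _stamp(outdir / "spectrum.csv", cfg_hash, seed)

    return {
        "qm_references": refs,
        "cluster_spectra": per_cluster_spectra,
        "spectrum": averaged,
        "cluster_weights": weights,
    }
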