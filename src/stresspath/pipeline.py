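"""The two-condition comparison pipeline.

``run_compare`` realises the full workflow: obtain an ensemble per
condition (synthetic, from files, or a precomputed force matrix),
compute the structural observables (RMSD, RMSF, gate distances), build
the mean force matrices, difference them, derive the punctual-stress
profile, export it onto a B-factor PDB, extract maximin pathways
between the configured regions, and write a run manifest.  All outputs
are plain TSV/PDB/JSON; the run is a pure function of (config, seeds,
inputs).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig, ConditionSpec, frames_bookkeeping
from .fda import (
    ForceMatrix,
    align_force_matrices,
    force_difference,
    mean_force_matrix,
    punctual_stress,
)
from .metrics import AtomSelection, gate_distances, rmsd_series, \
    rmsf_per_residue
from .pathways import (
    DisconnectedError,
    build_graph,
    extract_pathways,
    max_connectivity_cutoff,
)
from .structure_io import (
    Structure,
    Trajectory,
    read_structure,
    read_trajectory,
    write_bfactor_pdb,
)
from .synthetic import (
    ElasticNetwork,
    build_enm,
    default_plant_spec,
    make_toy_structure,
    plant_perturbation,
    sample_ensemble,
)

log = logging.getLogger("stresspath")


@dataclass
class ConditionData:
    name: str
    force: ForceMatrix
    trajectory: Trajectory | None = None
    network: ElasticNetwork | None = None
    reference: Structure | None = None


def _realize_condition(spec: ConditionSpec, config: RunConfig
                       ) -> ConditionData:
    syn = config.synthetic
    if spec.mode == "synthetic":
        structure = make_toy_structure(
            syn.n_residues, syn.n_chains, seed=syn.structure_seed,
        )
        net = build_enm(structure, cutoff=syn.enm_cutoff, k=syn.k, kT=syn.kT)
        if spec.plant:
            plant = default_plant_spec(syn.n_residues)
            plant = type(plant)(
                site_residues=plant.site_residues,
                pathway_residues=plant.pathway_residues,
                stiffening=syn.stiffening, ligand_k=syn.k,
            )
            net = plant_perturbation(net, plant)
        seed = spec.seed if spec.seed is not None else config.seed
        traj = sample_ensemble(net, syn.n_frames, seed=seed)
        return ConditionData(spec.name, mean_force_matrix(traj, net),
                             trajectory=traj, network=net,
                             reference=net.to_structure())
    if spec.mode == "trajectory":
        structure = read_structure(spec.structure)
        traj = read_trajectory(spec.trajectory, structure,
                               format=spec.trajectory_format)
        net = ElasticNetwork.read_tsv(spec.network)
        return ConditionData(spec.name, mean_force_matrix(traj, net),
                             trajectory=traj, network=net,
                             reference=structure)
    if spec.mode == "force_matrix":
        return ConditionData(spec.name, ForceMatrix.read_tsv(
            spec.force_matrix))
    raise ValueError(f"unknown condition mode {spec.mode!r}")


def _condition_metrics(data: ConditionData, config: RunConfig,
                       out: Path) -> None:
    traj = data.trajectory
    if traj is None:
        return
    cdir = out / data.name
    cdir.mkdir(parents=True, exist_ok=True)
    sel = AtomSelection.calpha()
    rmsd = rmsd_series(traj, data.reference, fit_sel=sel)
    with open(cdir / "rmsd.tsv", "w") as fh:
        fh.write("frame\trmsd_A\n")
        for f, v in enumerate(rmsd):
            fh.write(f"{f}\t{v:.6f}\n")
    rmsf = rmsf_per_residue(traj, sel=sel)
    rmsf.write_tsv(cdir / "rmsf.tsv")
    gates = [g for g in config.gates
             if _gate_resolves(g, traj.topology)]
    if gates:
        jp = config.joint_pair
        names = {g.name for g in gates}
        if jp is not None and not set(jp) <= names:
            jp = None
        dist = gate_distances(traj, gates, joint_pair=jp)
        dist.write_tsv(cdir / "gate_samples.tsv", cdir / "gate_hist.tsv")
    data.force.write_tsv(cdir / "force_matrix.tsv")


def _gate_resolves(gate, topology) -> bool:
    try:
        gate.resolve(topology)
        return True
    except ValueError:
        return False


def run_compare(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Execute the full comparison; returns the output directory.

    Writes, per condition, RMSD/RMSF/gate tables and the mean force
    matrix; then the difference matrix, punctual-stress profile and its
    B-factor PDB, the pathway graph and ranked pathway report, and a
    manifest recording config hash, seeds and versions.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    by_name: dict[str, ConditionData] = {}
    for spec in config.conditions:
        log.info("realizing condition %s (%s)", spec.name, spec.mode)
        by_name[spec.name] = _realize_condition(spec, config)
        _condition_metrics(by_name[spec.name], config, out)

    name_a, name_b = config.compare
    fa, fb = align_force_matrices(by_name[name_a].force,
                                  by_name[name_b].force)
    dF = force_difference(fa, fb)
    dF.write_tsv(out / "delta_force.tsv")
    stress = punctual_stress(dF)
    stress.write_tsv(out / "stress.tsv")

    ref = by_name[name_b].reference or by_name[name_a].reference
    if ref is not None:
        keys = set(ref.residue_keys())
        sub = type(stress)(
            {k: v for k, v in stress.items() if k in keys}, units="pN")
        write_bfactor_pdb(ref, sub, out / "stress_bfactor.pdb")

    pathway_note = None
    try:
        g = build_graph(dF, config.floor, config.source, config.sink)
        g.write_graphml(out / "pathway_graph.graphml")
        cutoff = max_connectivity_cutoff(g)
        g.write_edge_tsv(out / "pathway_edges.tsv", cutoff=cutoff)
        result = extract_pathways(g, cutoff, max_paths=config.max_paths)
        result.write_tsv(out / "pathways.tsv")
    except (DisconnectedError, ValueError) as exc:
        pathway_note = "no perturbation connectivity"
        log.warning("pathway stage: %s (%s)", pathway_note, exc)
        with open(out / "pathways.tsv", "w") as fh:
            fh.write(f"# {pathway_note}\n")
        cutoff = None

    manifest = {
        "package": "stresspath",
        "version": __version__,
        "numpy": np.__version__,
        "config_sha256": hashlib.sha256(
            json.dumps(config.raw, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.seed,
        "condition_seeds": {c.name: c.seed for c in config.conditions},
        "compare": list(config.compare),
        "cutoff_pN": cutoff,
        "pathway_note": pathway_note,
    }
    if config.duration_ns and config.save_interval_ps:
        manifest["frames"] = frames_bookkeeping(
            config.duration_ns, config.save_interval_ps, config.n_runs)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
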