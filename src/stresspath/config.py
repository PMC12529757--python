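"""Run configuration: TOML parsing, cross-reference validation, defaults.

A run compares two (or more) *conditions*.  Each condition is either
generated synthetically (an elastic-network ensemble, optionally with a
planted ligand perturbation), loaded as a trajectory plus spring
network, or loaded directly as a precomputed force-matrix TSV.  The
config also names the gate distances to monitor, the source/sink
residue regions for pathway extraction, and bookkeeping metadata.

The module ships the default SULT1A1 residue profile — the loop
definitions, gate endpoints and region seeds in 2D06 numbering — so a
user supplying real sulfotransferase structures gets the canonical
gates without writing them out.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .metrics import GateDefinition
from .structure_io import ResidueKey, Structure


class ConfigError(ValueError):
    """Aggregated, human-readable configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("\n".join(errors))


# Default SULT1A1 profile (2D06 numbering).  Loops: L1 "Lip" 83-91,
# L2 141-158, L3 241-255, cL3 256-262, nL3 236-240, a14nL3 228-240,
# a3L4 66-78, KTVE dimerisation motif 265-274.
SULT1A1_LOOPS: dict[str, tuple[int, int]] = {
    "L1": (83, 91),
    "L2": (141, 158),
    "L3": (241, 255),
    "cL3": (256, 262),
    "nL3": (236, 240),
    "a14nL3": (228, 240),
    "a3L4": (66, 78),
    "KTVE": (265, 274),
}

SULT1A1_GATES: list[dict[str, Any]] = [
    {"name": "L1-L2", "a": ["A", 87, "CA"], "b": ["A", 148, "CA"]},
    {"name": "L1-L3", "a": ["A", 87, "CA"], "b": ["A", 247, "CA"]},
    {"name": "cL3", "a": ["A", 197, "CA"], "b": ["A", 260, "CA"]},
]

# Pathway endpoint regions in SULT1A1 numbering: the PAPS-binding
# residues (anchors K48, R130, S138, R257 among others) as source and
# the dimerisation pair K265(A)/E274(B) as sink.
SULT1A1_REGIONS: dict[str, list[str]] = {
    "source": ["A:48", "A:130", "A:138", "A:257"],
    "sink": ["A:265", "B:274"],
}


@dataclass
class SyntheticSpec:
    n_residues: int = 32          # per chain
    n_chains: int = 2
    n_frames: int = 2000
    k: float = 100.0              # pN/A
    enm_cutoff: float = 8.0       # A
    kT: float = 41.4              # pN*A (300 K)
    stiffening: float = 4.0
    structure_seed: int = 0


@dataclass
class ConditionSpec:
    name: str
    mode: str                     # synthetic | trajectory | force_matrix
    plant: bool = False           # synthetic: apply the default PlantSpec
    seed: int | None = None       # synthetic sampling seed
    structure: str | None = None  # trajectory mode: PDB path
    trajectory: str | None = None
    trajectory_format: str = "xyz-frames"
    network: str | None = None    # spring-network TSV path
    force_matrix: str | None = None


@dataclass
class RunConfig:
    conditions: list[ConditionSpec]
    compare: tuple[str, str]
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    gates: list[GateDefinition] = field(default_factory=list)
    joint_pair: tuple[str, str] | None = None
    source: list[ResidueKey] = field(default_factory=list)
    sink: list[ResidueKey] = field(default_factory=list)
    floor: float = 0.0
    max_paths: int = 3
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"
    # bookkeeping metadata (trajectory provenance, optional)
    duration_ns: float | None = None
    save_interval_ps: float | None = None
    n_runs: int = 1
    raw: dict = field(default_factory=dict)


def _parse_residue_key(tok: str) -> ResidueKey:
    ch, rid = tok.rsplit(":", 1)
    return ch, int(rid)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML run configuration.

    Raises :class:`ConfigError` with one line per problem.
    """
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return config_from_dict(data)


def config_from_dict(data: dict) -> RunConfig:
    errors: list[str] = []

    cond_block = data.get("conditions", {})
    conditions: list[ConditionSpec] = []
    if not cond_block:
        errors.append("no conditions defined")
    for name, c in cond_block.items():
        mode = c.get("mode", "synthetic")
        if mode not in ("synthetic", "trajectory", "force_matrix"):
            errors.append(f"condition {name!r}: unknown mode {mode!r}")
            continue
        spec = ConditionSpec(
            name=name, mode=mode, plant=bool(c.get("plant", False)),
            seed=c.get("seed"), structure=c.get("structure"),
            trajectory=c.get("trajectory"),
            trajectory_format=c.get("trajectory_format", "xyz-frames"),
            network=c.get("network"), force_matrix=c.get("force_matrix"),
        )
        if mode == "trajectory":
            for fld in ("structure", "trajectory", "network"):
                if getattr(spec, fld) is None:
                    errors.append(
                        f"condition {name!r}: trajectory mode needs {fld!r}"
                    )
        if mode == "force_matrix" and spec.force_matrix is None:
            errors.append(
                f"condition {name!r}: force_matrix mode needs a path"
            )
        conditions.append(spec)

    names = [c.name for c in conditions]
    compare = tuple(data.get("compare", names[:2]))
    if len(compare) != 2:
        errors.append("'compare' must name exactly two conditions")
    else:
        for nm in compare:
            if nm not in names:
                errors.append(f"compare names unknown condition {nm!r}")

    syn_raw = data.get("synthetic", {})
    synthetic = SyntheticSpec(
        n_residues=int(syn_raw.get("n_residues", 32)),
        n_chains=int(syn_raw.get("n_chains", 2)),
        n_frames=int(syn_raw.get("n_frames", 2000)),
        k=float(syn_raw.get("k", 100.0)),
        enm_cutoff=float(syn_raw.get("enm_cutoff", 8.0)),
        kT=float(syn_raw.get("kT", 41.4)),
        stiffening=float(syn_raw.get("stiffening", 4.0)),
        structure_seed=int(syn_raw.get("structure_seed", 0)),
    )
    if any(c.mode == "synthetic" and c.seed is None and "seed" not in data
           for c in conditions):
        errors.append(
            "synthetic conditions need a 'seed' (per condition or global)"
        )

    gates = []
    for graw in data.get("gates", []):
        try:
            gates.append(GateDefinition(
                graw["name"],
                (graw["a"][0], int(graw["a"][1]), graw["a"][2]),
                (graw["b"][0], int(graw["b"][1]), graw["b"][2]),
            ))
        except (KeyError, IndexError, ValueError):
            errors.append(f"malformed gate entry: {graw!r}")
    joint_pair = data.get("metrics", {}).get("joint_pair")
    if joint_pair is not None:
        joint_pair = tuple(joint_pair)
        gnames = {g.name for g in gates}
        for nm in joint_pair:
            if nm not in gnames:
                errors.append(f"joint_pair names unknown gate {nm!r}")

    pw = data.get("pathways", {})
    source = [_parse_residue_key(t) for t in pw.get("source", [])]
    sink = [_parse_residue_key(t) for t in pw.get("sink", [])]
    if not source or not sink:
        errors.append("pathways.source and pathways.sink must be non-empty")
    elif set(source) & set(sink):
        errors.append("pathways source and sink regions overlap")

    run = data.get("run", {})
    book = data.get("bookkeeping", {})
    if errors:
        raise ConfigError(errors)
    return RunConfig(
        conditions=conditions, compare=compare, synthetic=synthetic,
        gates=gates, joint_pair=joint_pair, source=source, sink=sink,
        floor=float(pw.get("floor", 0.0)),
        max_paths=int(pw.get("max_paths", 3)),
        out_dir=run.get("out", "results"),
        seed=int(data.get("seed", run.get("seed", 0))),
        log_level=run.get("log_level", "INFO"),
        duration_ns=book.get("duration_ns"),
        save_interval_ps=book.get("save_interval_ps"),
        n_runs=int(book.get("n_runs", 1)),
        raw=data,
    )


def validate_against_structure(config: RunConfig,
                               structure: Structure) -> list[str]:
    """Resolve all residue cross-references against a topology.

    Returns a list of problems (empty when everything resolves).
    """
    problems: list[str] = []
    keys = set(structure.residue_keys())
    for gate in config.gates:
        for ep in (gate.endpoint_a, gate.endpoint_b):
            if (ep[0], ep[1]) not in keys:
                problems.append(
                    f"gate {gate.name!r}: residue {ep[0]}:{ep[1]} "
                    "not in structure"
                )
    for label, region in (("source", config.source),
                          ("sink", config.sink)):
        for key in region:
            if key not in keys:
                problems.append(
                    f"pathways.{label}: residue {key[0]}:{key[1]} "
                    "not in structure"
                )
    return problems


def frames_bookkeeping(duration_ns: float, save_interval_ps: float,
                       n_runs: int = 1) -> dict[str, int]:
    """Saved-frame counts implied by run duration and save interval.

    A 1000 ns run saved every 20 ps yields 50,000 frames; three parallel
    runs of one system, 150,000.
    """
    if duration_ns <= 0 or save_interval_ps <= 0 or n_runs < 1:
        raise ValueError("duration, interval and run count must be positive")
    per_run = int(round(duration_ns * 1000.0 / save_interval_ps))
    return {"frames_per_run": per_run,
            "frames_per_system": per_run * n_runs}


def default_synthetic_config(n_frames: int = 2000, seed: int = 0,
                             n_residues: int = 32) -> RunConfig:
    """Ready-made apo-vs-planted comparison on the toy dimer.

    Source region = the ligand-site residues, sink = residues just past
    the dimer-interface bridge on chain B, so the extracted pathway must
    cross between the subunits.
    """
    n = n_residues
    data = {
        "seed": seed,
        "conditions": {
            "apo": {"mode": "synthetic", "plant": False, "seed": seed},
            "bound": {"mode": "synthetic", "plant": True, "seed": seed + 1},
        },
        "compare": ["apo", "bound"],
        "synthetic": {"n_residues": n, "n_chains": 2, "n_frames": n_frames},
        "gates": [
            {"name": "site-interface",
             "a": ["A", n - 3, "CA"], "b": ["A", n, "CA"]},
            {"name": "interface",
             "a": ["A", n, "CA"], "b": ["B", n, "CA"]},
        ],
        "pathways": {
            "floor": 0.0, "max_paths": 3,
            "source": [f"A:{n - 3}", f"A:{n - 2}"],
            "sink": [f"B:{n - 1}"],
        },
        "bookkeeping": {"duration_ns": 1000, "save_interval_ps": 20,
                        "n_runs": 3},
    }
    return config_from_dict(data)
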