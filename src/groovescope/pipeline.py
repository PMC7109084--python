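"""Stage orchestration: run protonation, electrostatics, pocket, mode and
geometry stages from one YAML config, with a checksummed run manifest.

Stages execute in dependency order; each stage records its parameters and
the SHA-256 checksum of every file it wrote. A stage failure is recorded in
the manifest, downstream dependents are skipped, and run_pipeline raises
PipelineError after writing the manifest (the CLI converts this to a
nonzero exit).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .conformational_modes import build_kirchhoff, gnm_modes, mode_profile
from .electrostatics import SolverConfig, compute_field, solve_lpb, write_dx, write_vector_dx
from .groove_geometry import AperturePair, aperture_trace
from .pocket_dynamics import PocketConfig, occupancy_grid, occupancy_shell, volume_trace
from .protonation import (assign_charges_radii, assign_protonation, consensus_pka,
                          net_charge, read_pka_table, write_pka_table)
from .structure_io import align_frames, read_pqr, read_structure, write_pdb, write_pqr
from .synthetic_data import make_breathing_trajectory, make_pka_scenario, make_portal_scaffold

log = logging.getLogger("groovescope")

STAGE_ORDER = ["scenario", "simulate", "protonate", "pbsolve", "field",
               "pockets", "occupancy", "gnm", "geometry"]
STAGE_DEPS = {
    "protonate": ["scenario"],
    "pbsolve": ["protonate"],
    "field": ["pbsolve"],
    "pockets": ["simulate"],
    "occupancy": ["simulate"],
    "geometry": ["simulate"],
}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    outdir: Path
    stages: list[str]
    seed: int = 0
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        stages = raw.get("stages", [])
        unknown = [s for s in stages if s not in STAGE_ORDER]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {STAGE_ORDER}")
        params = {k: v for k, v in raw.items() if k not in ("stages", "outdir", "seed")}
        for ph in params.get("protonate", {}).get("ph", []):
            if not 0 < float(ph) < 14:
                raise ValueError(f"pH {ph} outside (0, 14)")
        for key in ("pdb", "pka_table", "pqr"):
            for block in params.values():
                if isinstance(block, dict) and key in block:
                    p = Path(block[key])
                    if not p.exists():
                        raise FileNotFoundError(f"referenced input {p} does not exist")
        return cls(outdir=Path(raw.get("outdir", "groovescope_run")),
                   stages=stages, seed=int(raw.get("seed", 0)), params=params)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed, "stages": {}}
    state: dict = {}
    failed: set[str] = set()
    ordered = [s for s in STAGE_ORDER if s in cfg.stages]

    for stage in ordered:
        deps = STAGE_DEPS.get(stage, [])
        if any(d in failed for d in deps if d in cfg.stages):
            manifest["stages"][stage] = {"status": "skipped (failed dependency)"}
            failed.add(stage)
            continue
        t0 = time.monotonic()
        entry: dict = {"params": cfg.params.get(stage, {})}
        try:
            outputs = _STAGE_FUNCS[stage](cfg, state, entry)
            entry["outputs"] = {str(p.relative_to(cfg.outdir)): _sha256(p) for p in outputs}
            entry["status"] = "ok"
        except Exception as exc:  # noqa: BLE001 — failure is a manifest fact
            entry["status"] = f"failed: {exc}"
            failed.add(stage)
            log.error("stage %s failed: %s", stage, exc)
        entry["wall_s"] = round(time.monotonic() - t0, 3)
        manifest["stages"][stage] = entry
        log.info("stage %s: %s (%.2fs)", stage, entry["status"], entry["wall_s"])

    manifest["files"] = {
        str(p.relative_to(cfg.outdir)): _sha256(p)
        for p in sorted(cfg.outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    (cfg.outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if failed:
        raise PipelineError(f"stages failed: {sorted(failed & set(cfg.stages))}")
    return manifest


# ---------------------------------------------------------------------------
# stage implementations: each returns the list of files it wrote

def _stage_scenario(cfg: RunConfig, state: dict, entry: dict) -> list[Path]:
    p = cfg.params.get("scenario", {})
    preset = p.get("preset", "CD1d_a1a2")
    structure, table = make_pka_scenario(preset, seed=cfg.seed)
    state["structure"] = structure
    state["pka_table"] = table
    pdb = cfg.outdir / f"{preset}.pdb"
    pdb.write_text(write_pdb(structure))
    tab = cfg.outdir / f"{preset}_pka.tsv"
    tab.write_text(write_pka_table(table))
    entry["preset"] = preset
    return [pdb, tab]


def _stage_simulate(cfg: RunConfig, state: dict, entry: dict) -> list[Path]:
    p = cfg.params.get("simulate", {})
    scaffold = make_portal_scaffold(
        separation=float(p.get("separation", 14.0)),
        n_res_per_helix=int(p.get("n_res_per_helix", 15)),
        composition=p.get("composition"),
    )
    traj = make_breathing_trajectory(
        scaffold,
        d0=float(p.get("d0", 14.3)), d_inf=float(p.get("d_inf", 11.9)),
        tau=float(p.get("tau", 200.0)), noise_sd=float(p.get("noise_sd", 0.5)),
        n_frames=int(p.get("n_frames", 100)), seed=cfg.seed,
    )
    state["trajectory"] = traj
    out = cfg.outdir / "breathing.pdb"
    out.write_text(write_pdb(traj))
    return [out]


def _stage_protonate(cfg: RunConfig, state: dict, entry: dict) -> list[Path]:
    p = cfg.params.get("protonate", {})
    if "pka_table" in p:
        table = read_pka_table(p["pka_table"])
    else:
        table = state.get("pka_table")
    structure = state.get("structure")
    if "pdb" in p:
        structure = read_structure(Path(p["pdb"]).read_text()).topology
    if table is None or structure is None:
        raise PipelineError("protonate needs a scenario stage or pdb/pka_table inputs")
    cons = consensus_pka(table, agreement_tol=float(p.get("tol", 0.5)))
    written: list[Path] = []
    charges: dict[str, int] = {}
    state["assignments"] = {}
    for ph in p.get("ph", [7.0, 4.5]):
        ph = float(ph)
        st = assign_protonation(cons, ph, margin=float(p.get("margin", 0.1)))
        q = net_charge(st)
        charges[f"{ph:g}"] = q
        asg = assign_charges_radii(structure, st)
        state["assignments"][ph] = asg
        pqr = cfg.outdir / f"protonated_ph{ph:g}.pqr"
        pqr.write_text(write_pqr(structure, asg.charges, asg.radii))
        written.append(pqr)
    entry["net_charges"] = charges
    return written


def _stage_pbsolve(cfg: RunConfig, state: dict, entry: dict) -> list[Path]:
    p = cfg.params.get("pbsolve", {})
    scfg = SolverConfig(
        fine_dim=int(p.get("fine_dim", 65)),
        fine_spacing=float(p.get("fine_spacing", 1.0)),
        coarse_dim=int(p.get("coarse_dim", 33)),
        ionic_strength=float(p.get("ionic_strength", 0.150)),
    )
    assignments = state.get("assignments")
    if "pqr" in p:
        s, q, r = read_pqr(Path(p["pqr"]).read_text())
        from .protonation import ChargeRadiusAssignment
        assignments = {None: ChargeRadiusAssignment(s, q, r)}
    if not assignments:
        raise PipelineError("pbsolve needs a protonate stage or a pqr input")
    written = []
    state["grids"] = {}
    for ph, asg in assignments.items():
        grid = solve_lpb(asg, scfg)
        state["grids"][ph] = grid
        tag = "" if ph is None else f"_ph{ph:g}"
        out = cfg.outdir / f"potential{tag}.dx"
        out.write_text(write_dx(grid, comment=f"linearized PB potential, {grid.units}"))
        written.append(out)
    return written


def _stage_field(cfg: RunConfig, state: dict, entry: dict) -> list[Path]:
    grids = state.get("grids")
    if not grids:
        raise PipelineError("field needs a pbsolve stage")
    written = []
    for ph, grid in grids.items():
        tag = "potential" if ph is None else f"potential_ph{ph:g}"
        vec = compute_field(grid)
        for fname, text in write_vector_dx(vec, tag).items():
            out = cfg.outdir / fname
            out.write_text(text)
            written.append(out)
    return written


def _aligned_traj(state: dict):
    traj = state.get("trajectory")
    if traj is None:
        raise PipelineError("stage needs a simulate stage (trajectory)")
    if not traj.aligned:
        sel = traj.topology.select_indices(names=("CA",))
        traj = align_frames(traj, sel)
        state["trajectory"] = traj
    return traj


def _stage_pockets(cfg: RunConfig, state: dict, entry: dict) -> list[Path]:
    p = cfg.params.get("pockets", {})
    traj = _aligned_traj(state)
    pcfg = PocketConfig(spacing=float(p.get("spacing", 0.8)))
    ts = volume_trace(traj, pcfg)
    out = cfg.outdir / "pocket_volumes.csv"
    import pandas as pd
    pd.DataFrame({"frame": np.arange(ts.values.size), "time_ns": ts.time,
                  "volume_A3": ts.values}).to_csv(out, index=False)
    return [out]


def _stage_occupancy(cfg: RunConfig, state: dict, entry: dict) -> list[Path]:
    p = cfg.params.get("occupancy", {})
    traj = _aligned_traj(state)
    pcfg = PocketConfig(spacing=float(p.get("spacing", 0.8)))
    og = occupancy_grid(traj, pcfg)
    from .electrostatics import ScalarGrid
    grid = ScalarGrid(og.lattice.origin, np.full(3, og.lattice.spacing),
                      og.occupancy.astype(float), units="occupancy")
    out = cfg.outdir / "occupancy.dx"
    out.write_text(write_dx(grid, comment="pocket occupancy fraction"))
    shells = p.get("shells", [[0.6, 0.8], [0.8, 1.0]])
    entry["shell_volumes_A3"] = {
        f"{lo}:{hi}": occupancy_shell(og, float(lo), float(hi))[1] for lo, hi in shells
    }
    return [out]


def _stage_gnm(cfg: RunConfig, state: dict, entry: dict) -> list[Path]:
    p = cfg.params.get("gnm", {})
    if "pdb" in p:
        structure = read_structure(Path(p["pdb"]).read_text()).topology
    elif state.get("trajectory") is not None:
        structure = state["trajectory"].topology
    elif state.get("structure") is not None:
        structure = state["structure"]
    else:
        raise PipelineError("gnm needs a pdb input or an upstream structure")
    K = build_kirchhoff(structure, cutoff=float(p.get("cutoff", 7.3)))
    modes = gnm_modes(K)
    indices = p.get("modes", [1, 2, 3])
    labels, amp = mode_profile(modes, list(indices), chain=p.get("chain"))
    out = cfg.outdir / "gnm_profile.csv"
    import pandas as pd
    pd.DataFrame({"chain": [c for c, _ in labels], "res_seq": [r for _, r in labels],
                  "amplitude": amp}).to_csv(out, index=False)
    entry["modes"] = list(indices)
    return [out]


def _stage_geometry(cfg: RunConfig, state: dict, entry: dict) -> list[Path]:
    p = cfg.params.get("geometry", {})
    traj = _aligned_traj(state)
    if "pair" in p:
        ca, cb = p["pair"].split(",")
        pair = AperturePair(ca.split(":")[0], int(ca.split(":")[1]),
                            cb.split(":")[0], int(cb.split(":")[1]))
    else:
        from .synthetic_data import portal_aperture_indices
        n_res = max(a.res_seq for a in traj.topology.atoms if a.chain_id == "A")
        (c1, r1), (c2, r2) = portal_aperture_indices(n_res)
        pair = AperturePair(c1, r1, c2, r2)
    ts = aperture_trace(traj, pair)
    out = cfg.outdir / "aperture.csv"
    import pandas as pd
    pd.DataFrame({"frame": np.arange(ts.values.size), "time_ns": ts.time,
                  "distance_A": ts.values}).to_csv(out, index=False)
    entry["mean_A"] = round(ts.mean(), 3)
    entry["std_A"] = round(ts.std(), 3)
    return [out]


_STAGE_FUNCS = {
    "scenario": _stage_scenario,
    "simulate": _stage_simulate,
    "protonate": _stage_protonate,
    "pbsolve": _stage_pbsolve,
    "field": _stage_field,
    "pockets": _stage_pockets,
    "occupancy": _stage_occupancy,
    "gnm": _stage_gnm,
    "geometry": _stage_geometry,
}
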