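"""End-to-end orchestration over one or more systems.

A study is a list of systems (each either generated from a config or
loaded from PDB/DCD/sidecar files), a reference system, and per-stage
parameter blocks.  Every constant of the analysis protocol (310 K, 4.5 Å /
75% network edges, 6 Å pocket, 30% report threshold, 2 Å RMSF gate, 60%
flux rule, 1.4 Å probe, 0.0072 kcal/(mol Å²) surface tension) is an
explicit, named configuration key so the protocol is auditable.

``run_pipeline`` produces, per system: geometry series, an MM/GBSA energy
ledger, a Markov-model + flux-pathway summary, a 2D PMF with basins and
metastate projections, an interaction-fingerprint table, and a dynamic
network with communities and allosteric paths; across systems it adds the
affinity table (with ΔΔG_cal and r² against experiment), fingerprint
deltas, and per-node path-count deltas, all relative to the reference
system.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dynet, energetics, fingerprints, geomcore, msmtpt, pmf2d, toytraj
from ._constants import T_DEFAULT

log = logging.getLogger("switchscope")


@dataclass
class SystemSpec:
    name: str
    path: str | None = None              # directory with system.pdb/traj.dcd/params.json
    generator: dict = field(default_factory=dict)   # GeneratorConfig overrides
    ic50_nM: float | None = None


@dataclass
class StudyConfig:
    systems: list
    reference: str
    seed: int = 0
    n_frames: int = 2000
    temperature: float = T_DEFAULT
    # geometry
    rmsf_threshold: float = 2.0          # Å gate for flexible-residue selection
    # energetics
    energy_stride: int = 100             # score every Nth frame
    entropy_frames: int = 3              # frames for normal-mode entropy
    sasa_points: int = 480
    # msm
    msm_k: int = 100
    msm_lag: int = 1
    n_metastates: int = 2
    flux_threshold: float = 0.60         # dominant-pathway cumulative flux rule
    # pmf
    pmf_bins: int = 40
    basin_depth: float = 1.0             # kcal/mol
    # fingerprints
    pocket_cutoff: float = 6.0           # Å
    report_threshold: float = 30.0       # %
    fingerprint_stride: int = 1
    # network
    network_cutoff: float = 4.5          # Å
    network_persistence: float = 0.75
    network_stride: int = 5
    path_source: str = "R58"
    path_sink: str = "NUC"
    path_tolerance: float = 0.2

    def __post_init__(self):
        self.systems = [
            s if isinstance(s, SystemSpec) else SystemSpec(**s) for s in self.systems
        ]
        if self.reference not in {s.name for s in self.systems}:
            raise ValueError(f"reference system {self.reference!r} not in system list")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_or_generate(spec: SystemSpec, config: StudyConfig, index: int):
    if spec.path:
        structure, traj = toytraj.read_system(spec.path)
        manifest = None
        mpath = Path(spec.path) / "manifest.json"
        if mpath.exists():
            manifest = toytraj.TruthManifest.from_json(mpath.read_text())
        return structure, traj, manifest
    gen = toytraj.GeneratorConfig(**spec.generator)
    seed = int(
        np.random.SeedSequence(config.seed, spawn_key=(index,)).generate_state(1)[0]
        % (2**31)
    )
    return toytraj.generate_system(gen, n_frames=config.n_frames, seed=seed)


def analyze_system(structure, traj, config: StudyConfig, name: str = "system") -> dict:
    """Run every analysis stage on one system; returns the per-system bundle."""
    t0 = time.time()
    out: dict = {"name": name}
    beads = structure.beads()

    # --- geometry ------------------------------------------------------
    rmsf = geomcore.rmsf_profile(traj, sel=beads)
    rmsf_by_resid = dict(zip(structure.resids[beads].tolist(), rmsf.tolist()))
    flexible = geomcore.select_flexible_residues(rmsf_by_resid, config.rmsf_threshold)
    loop_rmsd = {}
    for region in structure.regions:
        sel = structure.region_atoms(region)
        fit = np.setdiff1d(beads, sel)
        loop_rmsd[region] = geomcore.rmsd_series(traj, traj.ref_frame, sel, fit)
    out["geometry"] = {
        "rmsf": rmsf_by_resid,
        "flexible_residues": flexible,
        "loop_rmsd": loop_rmsd,
    }
    log.info("[%s] geometry done (%.1fs): %d flexible residues", name, time.time() - t0, len(flexible))

    # --- energetics ----------------------------------------------------
    receptor = np.flatnonzero(structure.roles != "ligand")
    ligand = structure.atoms_by_role("ligand")
    report = None
    if ligand.size:
        report = energetics.mmgbsa_binding(
            traj, structure, receptor, ligand,
            stride=config.energy_stride, T=config.temperature,
            entropy_frames=config.entropy_frames, sasa_points=config.sasa_points,
        )
    out["energy"] = report
    log.info("[%s] energetics done (%.1fs)", name, time.time() - t0)

    # --- MSM + TPT -----------------------------------------------------
    feats = msmtpt.featurize(traj, structure, flexible)
    k = min(config.msm_k, max(2, traj.n_frames // 20))
    dtraj, centers = msmtpt.cluster_microstates(feats, k, seed=0)
    model = msmtpt.estimate_msm(dtraj, config.msm_lag, centers=centers)
    msmtpt.coarse_grain_metastates(model, config.n_metastates)
    region_names = list(structure.regions)
    reps, start_meta, end_meta = msmtpt.metastate_representatives(
        model, feats,
        loop_rmsd={r: loop_rmsd[r] for r in region_names},
        n_rep=min(10, traj.n_frames),
    )
    T_meta, pi_meta = msmtpt.coarse_grained_T(model)
    tpt = None
    dominant = None
    if start_meta != end_meta:
        tpt = msmtpt.tpt_flux_pathways(T_meta, pi_meta, [start_meta], [end_meta])
        dominant = msmtpt.select_dominant_states(tpt, config.flux_threshold)
    out["msm"] = {
        "model": model, "representatives": reps, "start": start_meta, "end": end_meta,
        "T_meta": T_meta, "pi_meta": pi_meta, "tpt": tpt, "dominant": dominant,
    }
    log.info("[%s] msm/tpt done (%.1fs): %d microstates", name, time.time() - t0, len(model.active))

    # --- 2D PMF --------------------------------------------------------
    r1, r2 = (loop_rmsd[r] for r in region_names[:2])
    grid = pmf2d.compute_pmf2d(r1, r2, bins=config.pmf_bins, T=config.temperature)
    basins = pmf2d.locate_basins(grid, config.basin_depth, x=r1, y=r2)
    labels = {
        m: (reps[m]["labels"][region_names[0]], reps[m]["labels"][region_names[1]])
        for m in reps
    }
    out["pmf"] = {
        "grid": grid, "basins": basins,
        "projections": pmf2d.project_states_on_pmf(grid, labels),
    }

    # --- fingerprints --------------------------------------------------
    table = None
    if ligand.size:
        rules = fingerprints.InteractionRules(pocket_cutoff=config.pocket_cutoff)
        table = fingerprints.interaction_frequencies(
            traj, structure, ligand, rules=rules,
            report_threshold=config.report_threshold, system=name,
            stride=config.fingerprint_stride,
        )
    out["fingerprints"] = table
    log.info("[%s] fingerprints done (%.1fs)", name, time.time() - t0)

    # --- dynamic network ----------------------------------------------
    net = dynet.build_network(
        traj, structure,
        dist_cutoff=config.network_cutoff, persistence=config.network_persistence,
        stride=config.network_stride,
    )
    communities, modularity = dynet.detect_communities(net)
    paths = None
    if config.path_source in net.graph and config.path_sink in net.graph:
        try:
            paths = dynet.suboptimal_paths(
                net, config.path_source, config.path_sink, config.path_tolerance
            )
        except dynet.NetworkError as exc:
            log.warning("[%s] path analysis skipped: %s", name, exc)
    out["network"] = {
        "net": net, "communities": communities, "modularity": modularity, "paths": paths,
    }
    log.info("[%s] network done (%.1fs): %d edges, %d communities",
             name, time.time() - t0, net.graph.number_of_edges(), len(communities))
    return out


def run_pipeline(config: StudyConfig) -> dict:
    """Run every stage over every system plus the cross-system comparisons."""
    bundle: dict = {
        "manifest": {
            "config_digest": config.digest(),
            "seed": config.seed,
            "temperature": config.temperature,
        },
        "systems": {},
        "status": {},
    }
    for i, spec in enumerate(config.systems):
        try:
            structure, traj, truth = _load_or_generate(spec, config, i)
            res = analyze_system(structure, traj, config, name=spec.name)
            res["truth"] = truth
            bundle["systems"][spec.name] = res
            bundle["status"][spec.name] = "ok"
        except Exception as exc:  # partial bundle with per-stage status
            log.error("[%s] failed: %s", spec.name, exc)
            bundle["status"][spec.name] = f"failed: {exc}"

    ok = {n: r for n, r in bundle["systems"].items() if r.get("energy") is not None}
    reports = {n: r["energy"] for n, r in ok.items()}
    ic50s = {s.name: s.ic50_nM for s in config.systems}
    if config.reference in reports:
        records = energetics.assemble_affinity_table(
            reports, ic50s, config.reference, T=config.temperature, require_ic50=False
        )
        for rec in records:
            if rec.ic50_nM is None:
                log.warning("system %s has no IC50; dG_exp left blank", rec.system)
        bundle["affinity"] = records
        with_exp = [r for r in records if r.dg_exp is not None]
        if len(with_exp) >= 3:
            bundle["r_squared"] = energetics.r_squared(
                [r.dg_cal for r in with_exp], [r.dg_exp for r in with_exp]
            )
    # fingerprint + path deltas against the reference
    ref = bundle["systems"].get(config.reference)
    if ref is not None:
        deltas, path_deltas = {}, {}
        for nsys, res in bundle["systems"].items():
            if nsys == config.reference:
                continue
            if ref.get("fingerprints") is not None and res.get("fingerprints") is not None:
                deltas[nsys] = fingerprints.compare_fingerprints(
                    ref["fingerprints"], res["fingerprints"]
                )
            rp, rq = ref["network"].get("paths"), res["network"].get("paths")
            if rp is not None and rq is not None:
                path_deltas[nsys] = dynet.allosteric_path_delta(rp, rq)
        bundle["fingerprint_deltas"] = deltas
        bundle["path_deltas"] = path_deltas
    return bundle


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def render_tables(bundle: dict) -> dict[str, pd.DataFrame]:
    """Publication-style report tables from a pipeline bundle."""
    out: dict[str, pd.DataFrame] = {}
    if "affinity" in bundle:
        rows = {}
        for rec in bundle["affinity"]:
            rep = bundle["systems"][rec.system]["energy"]
            col = rep.as_series()
            col["ddG_cal"] = np.nan if rec.ddg_cal is None else rec.ddg_cal
            col["dG_exp"] = np.nan if rec.dg_exp is None else rec.dg_exp
            col["IC50(nM)"] = np.nan if rec.ic50_nM is None else rec.ic50_nM
            rows[rec.system] = col
        out["energy_ledger"] = pd.DataFrame(rows)
    freq_tables = [
        r["fingerprints"].frequencies
        for r in bundle["systems"].values()
        if r.get("fingerprints") is not None
    ]
    if freq_tables:
        merged = pd.concat(freq_tables, axis=1).fillna(0.0)
        thresh = next(
            r["fingerprints"].report_threshold
            for r in bundle["systems"].values()
            if r.get("fingerprints") is not None
        )
        out["fingerprint_frequencies"] = merged[merged.max(axis=1) > thresh]
    if bundle.get("path_deltas"):
        rows = []
        for nsys, d in bundle["path_deltas"].items():
            for node, delta in d["delta"].items():
                rows.append({"system": nsys, "node": node, "delta": delta})
        out["path_count_deltas"] = pd.DataFrame(rows)
    return out


def save_bundle(bundle: dict, outdir) -> None:
    """Write CSV/JSON report artifacts for a pipeline bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = render_tables(bundle)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv")
    summary = {
        "manifest": bundle["manifest"],
        "status": bundle["status"],
        "r_squared": bundle.get("r_squared"),
        "systems": {
            n: {
                "flexible_residues": r["geometry"]["flexible_residues"],
                "n_basins": len(r["pmf"]["basins"]),
                "n_communities": len(r["network"]["communities"]),
                "modularity": r["network"]["modularity"],
                "dG_cal": None if r.get("energy") is None else r["energy"].g_cal,
            }
            for n, r in bundle["systems"].items()
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
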