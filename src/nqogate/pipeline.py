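"""Configuration-driven orchestration of the full gate analysis.

A single human-editable config (YAML or dict) names the systems to
simulate or load, the selections and thresholds for each structural stage,
and the kinetic datasets to fit.  ``run`` executes the requested stages in
dependency order, writes every artifact under the output directory, and
returns a machine-readable report.  Identical config + seed produces
identical artifacts (timestamps excluded).

Config schema (all keys optional unless noted)::

    seed: 0
    outdir: "out"                     # required
    stages: [simulate, distances, pca, contacts, kinetics]
    systems:                          # name -> source (required for
      WT:                             #   structural stages)
        generate: {closed_mean_distance: 11.6, ...}   # EnsembleSpec kwargs
      P78G:
        topology: path.pdb            # or load from files
        trajectory: path.dcd
        format: dcd
    equilibration_fraction: 1.0       # keep the last fraction of frames
    selection: "name CA"              # atoms for superposition / PCA
    gate:
      atom_a: "resid 10 and name CA"
      atom_b: "resid 30 and name CA"
    contacts:
      cutoff: 4.5                     # A
      min_separation: 3
      stable_threshold: 0.7           # occupancy for community edges
      df_threshold: 0.5               # |df| for significant edges
      n_blocks: 4
      reference_system: WT            # df = P(other) - P(reference)
    pca:
      n_components: 2
      bins: 60
    kinetics:
      rates: {simulate: {...}}        # KineticsSimSpec kwargs, or {csv: path}
      model: both                     # pingpong | pingpong_si | both
      traces: {simulate: {...}, concentrations: [90, 150, ...]}
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, contacts, gate, kinetics, pca, synthetic, trajectory

__all__ = ["RunConfig", "RunReport", "validate", "run"]

log = logging.getLogger("nqogate.pipeline")

STRUCTURAL_STAGES = ("simulate", "distances", "pca", "contacts")
ALL_STAGES = STRUCTURAL_STAGES + ("kinetics",)


@dataclass
class RunConfig:
    raw: dict

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            return cls(raw=yaml.safe_load(fh))

    def get(self, key, default=None):
        return self.raw.get(key, default)

    def hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)   # name -> status record

    def record(self, stage: str, status: str, outputs=(), params=None,
               error: str | None = None):
        self.stages[stage] = {
            "status": status,
            "outputs": [str(p) for p in outputs],
            "parameters": params or {},
            **({"error": error} if error else {}),
        }

    def to_dict(self) -> dict:
        return {"config_hash": self.config_hash, "version": self.version,
                "stages": self.stages}

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         sort_keys=True) + "\n")


def validate(config: RunConfig) -> list[str]:
    """Exhaustive non-throwing validation; returns human-readable findings."""
    findings: list[str] = []
    raw = config.raw if isinstance(config.raw, dict) else None
    if raw is None:
        return ["config: not a mapping"]
    if not raw.get("outdir"):
        findings.append("outdir: missing required output directory")
    stages = raw.get("stages", list(ALL_STAGES))
    for s in stages:
        if s not in ALL_STAGES:
            findings.append(f"stages: unknown stage {s!r}")
    needs_structures = any(s in STRUCTURAL_STAGES for s in stages)
    systems = raw.get("systems", {})
    if needs_structures and not systems:
        findings.append("systems: structural stages requested but no systems "
                        "configured")
    for name, src in systems.items():
        if "generate" in src:
            try:
                synthetic.EnsembleSpec(**src["generate"]).validate()
            except (TypeError, synthetic.SpecError) as exc:
                findings.append(f"systems.{name}.generate: {exc}")
        else:
            for key in ("topology", "trajectory"):
                p = src.get(key)
                if not p:
                    findings.append(f"systems.{name}: missing {key} path")
                elif not Path(p).exists():
                    findings.append(f"systems.{name}.{key}: path not found: {p}")
    frac = raw.get("equilibration_fraction", 1.0)
    if not 0 < frac <= 1:
        findings.append(f"equilibration_fraction: must be in (0, 1], got {frac}")
    ccfg = raw.get("contacts", {})
    if ccfg.get("cutoff", contacts.DEFAULT_CUTOFF) <= 0:
        findings.append(f"contacts.cutoff: must be > 0 A, got {ccfg['cutoff']}")
    if not 0 < ccfg.get("stable_threshold", 0.7) <= 1:
        findings.append("contacts.stable_threshold: must be in (0, 1]")
    if ccfg.get("df_threshold", 0.5) < 0:
        findings.append("contacts.df_threshold: must be >= 0")
    kcfg = raw.get("kinetics", {})
    rates = kcfg.get("rates", {})
    if "csv" in rates and not Path(rates["csv"]).exists():
        findings.append(f"kinetics.rates.csv: path not found: {rates['csv']}")
    if "simulate" in rates:
        try:
            synthetic.KineticsSimSpec(**rates["simulate"]).validate()
        except (TypeError, synthetic.SpecError) as exc:
            findings.append(f"kinetics.rates.simulate: {exc}")
    return findings


def _load_systems(config: RunConfig, outdir: Path, report: RunReport):
    """Simulate or read every configured system; returns name -> Trajectory."""
    seed = int(config.get("seed", 0))
    systems = {}
    outputs = []
    for k, (name, src) in enumerate(config.get("systems", {}).items()):
        if "generate" in src:
            kwargs = dict(src["generate"])
            kwargs.setdefault("rng_seed", seed + k)
            spec = synthetic.EnsembleSpec(**kwargs)
            top, traj = synthetic.simulate_gate_ensemble(spec)
            top_path = outdir / f"{name}_topology.pdb"
            trj_path = outdir / f"{name}_trajectory.dcd"
            trajectory.write_structure(top, top_path)
            trajectory.write_trajectory(traj, trj_path, format="dcd")
            outputs += [top_path, trj_path]
        else:
            top = trajectory.read_structure(src["topology"])
            traj = trajectory.read_trajectory(src["trajectory"], top,
                                              src.get("format"))
        frac = float(config.get("equilibration_fraction", 1.0))
        systems[name] = trajectory.trim_equilibration(traj, frac)
    report.record("simulate", "completed", outputs,
                  {"systems": list(systems), "seed": seed})
    return systems


def _stage_distances(config, systems, outdir: Path, report: RunReport):
    gcfg = config.get("gate")
    if not gcfg:
        report.record("distances", "skipped", params={"reason": "no gate config"})
        return
    outputs, stats_all = [], {}
    for name, traj in systems.items():
        series = gate.distance_series(traj, gcfg["atom_a"], gcfg["atom_b"],
                                      system_label=name)
        st = gate.gate_stats(series)
        csv_path = outdir / f"{name}_gate_distance.csv"
        gate.write_series_csv(series, csv_path)
        outputs.append(csv_path)
        stats_all[name] = {"mean_A": st.mean, "sd_A": st.sd,
                           "n_frames": st.n_frames}
    stats_path = outdir / "gate_stats.json"
    stats_path.write_text(json.dumps(stats_all, indent=2) + "\n")
    outputs.append(stats_path)
    report.record("distances", "completed", outputs, gcfg)


def _stage_pca(config, systems, outdir: Path, report: RunReport):
    pcfg = config.get("pca", {})
    expr = config.get("selection", "name CA")
    names = list(systems)
    first = systems[names[0]]
    sel = trajectory.select_atoms(first.topology, expr)
    model = pca.fit_pca(list(systems.values()), sel)
    ncomp = min(int(pcfg.get("n_components", 2)),
                model.eigenvectors.shape[0])
    projections = [pca.project(systems[n], model, sel, ncomp, system_label=n)
                   for n in names]
    outputs = []
    for proj in projections:
        p = outdir / f"{proj.system_label}_pc_scores.csv"
        pd.DataFrame(proj.scores,
                     columns=[f"PC{i+1}" for i in range(ncomp)]).to_csv(
            p, index=False)
        outputs.append(p)
    scree_path = outdir / "scree.csv"
    pd.DataFrame({"component": np.arange(1, len(model.eigenvalues) + 1),
                  "eigenvalue_A2": model.eigenvalues,
                  "cumulative_variance_fraction": pca.scree(model)}).to_csv(
        scree_path, index=False)
    outputs.append(scree_path)
    if ncomp >= 2:
        maps = pca.density2d(projections, bins=int(pcfg.get("bins", 60)))
        modes = {}
        for proj, dmap in zip(projections, maps):
            dens_path = outdir / f"{proj.system_label}_pc_density.csv"
            np.savetxt(dens_path, dmap.density, delimiter=",")
            outputs.append(dens_path)
            modes[proj.system_label] = {
                "most_probable_frame": pca.most_probable_frame(proj, dmap),
                "mode_center": dmap.mode_center().tolist()}
        modes_path = outdir / "pc_modes.json"
        modes_path.write_text(json.dumps(modes, indent=2) + "\n")
        outputs.append(modes_path)
    report.record("pca", "completed", outputs,
                  {"selection": expr, "n_components": ncomp})


def _stage_contacts(config, systems, outdir: Path, report: RunReport):
    ccfg = config.get("contacts", {})
    cutoff = float(ccfg.get("cutoff", contacts.DEFAULT_CUTOFF))
    min_sep = int(ccfg.get("min_separation", contacts.DEFAULT_MIN_SEPARATION))
    stable = float(ccfg.get("stable_threshold", 0.7))
    df_thr = float(ccfg.get("df_threshold", 0.5))
    n_blocks = int(ccfg.get("n_blocks", 4))
    seed = int(config.get("seed", 0))
    names = list(systems)
    outputs = []
    probs = {}
    for name, traj in systems.items():
        p = contacts.contact_probabilities(traj, cutoff, min_sep)
        probs[name] = p
        path = outdir / f"{name}_contact_probability.csv"
        p.to_frame().to_csv(path)
        outputs.append(path)
    if len(names) >= 2:
        ref = ccfg.get("reference_system", names[0])
        other = next(n for n in names if n != ref)
        diff = contacts.difference_network(probs[ref], probs[other],
                                           labels=(ref, other))
        df_path = outdir / f"df_{ref}_to_{other}.csv"
        pd.DataFrame(diff.df).to_csv(df_path)
        edges = contacts.significant_edges(diff, df_thr)
        edges_path = outdir / "significant_edges.csv"
        contacts.edges_to_frame(diff, edges).to_csv(edges_path, index=False)
        outputs += [df_path, edges_path]
        # consensus communities over equal trajectory blocks of the reference
        ref_traj = systems[ref]
        bounds = np.linspace(0, ref_traj.n_frames, n_blocks + 1).astype(int)
        blocks = []
        for b in range(n_blocks):
            sub = trajectory.Trajectory(topology=ref_traj.topology,
                                        xyz=ref_traj.xyz[bounds[b]:bounds[b + 1]])
            if sub.n_frames:
                blocks.append(contacts.contact_probabilities(sub, cutoff,
                                                             min_sep))
        partition = contacts.consensus_communities(blocks, stable, seed=seed)
        part_path = outdir / "communities.csv"
        pd.DataFrame({
            "residue": [f"{c}{r}" for c, r in partition.residue_labels],
            "community": partition.labels,
            "stability": partition.stability}).to_csv(part_path, index=False)
        cdg = contacts.community_difference(diff, partition)
        cdg_path = outdir / "community_difference.json"
        cdg_path.write_text(json.dumps({
            "sizes": cdg.sizes,
            "edges": {f"{a}-{b}": v for (a, b), v in cdg.edges.items()},
            "intra": cdg.intra}, indent=2) + "\n")
        outputs += [part_path, cdg_path]
    report.record("contacts", "completed", outputs,
                  {"cutoff_A": cutoff, "min_separation": min_sep,
                   "stable_threshold": stable, "df_threshold": df_thr,
                   "n_blocks": n_blocks})


def _stage_kinetics(config, outdir: Path, report: RunReport):
    kcfg = config.get("kinetics", {})
    if not kcfg:
        report.record("kinetics", "skipped",
                      params={"reason": "no kinetics config"})
        return
    seed = int(config.get("seed", 0))
    outputs = []
    results: dict = {}
    rates_cfg = kcfg.get("rates")
    if rates_cfg:
        if "csv" in rates_cfg:
            data = synthetic.read_rates_csv(rates_cfg["csv"])
        else:
            kwargs = dict(rates_cfg.get("simulate", {}))
            kwargs.setdefault("rng_seed", seed)
            data = synthetic.simulate_rates(synthetic.KineticsSimSpec(**kwargs))
            rates_path = outdir / "rates.csv"
            synthetic.write_rates_csv(data, rates_path)
            outputs.append(rates_path)
        model = kcfg.get("model", "both")
        fits = {}
        if model in ("pingpong", "both"):
            fits["pingpong"] = kinetics.fit_pingpong(data)
        if model in ("pingpong_si", "both"):
            fits["pingpong_si"] = kinetics.fit_pingpong_substrate_inhibition(data)
        for mid, f in fits.items():
            results[mid] = {"kcat": f.kcat, "Ka": f.Ka, "Kb": f.Kb,
                            "Kis": f.Kis, "se": f.se,
                            "r_squared": f.r_squared}
        if len(fits) == 2:
            sel = kinetics.select_model(fits["pingpong"], fits["pingpong_si"],
                                        data)
            results["model_selection"] = {
                "choice": sel.choice, "aicc": sel.aicc,
                "f_statistic": sel.f_statistic, "p_value": sel.p_value}
    traces_cfg = kcfg.get("traces")
    if traces_cfg:
        conc = traces_cfg.get("concentrations", [90, 150, 250, 350, 500])
        kwargs = dict(traces_cfg.get("simulate", {}))
        kwargs.setdefault("rng_seed", seed + 1)
        spec = synthetic.KineticsSimSpec(**kwargs)
        traces = synthetic.simulate_traces(spec, conc)
        sat_points, biexp_out = [], {}
        for tr in traces:
            bi = kinetics.fit_biexponential(tr)
            sat_points.append((tr.substrate_concentration, bi.kobs1))
            biexp_out[str(tr.substrate_concentration)] = {
                "kobs1": bi.kobs1, "kobs2": bi.kobs2,
                "amplitude_fraction_fast": bi.amplitude_fraction_fast}
            p = outdir / f"trace_{tr.substrate_concentration:g}uM.csv"
            synthetic.write_trace_csv(tr, p)
            outputs.append(p)
        sat = kinetics.fit_saturation(sat_points)
        results["transient"] = {
            "per_trace": biexp_out,
            "kred": sat.kred, "Kd": sat.Kd, "se": sat.se,
            "kd_unconstrained": sat.kd_unconstrained}
    fits_path = outdir / "kinetic_fits.json"
    fits_path.write_text(json.dumps(results, indent=2, default=float) + "\n")
    outputs.append(fits_path)
    report.record("kinetics", "completed", outputs, {"seed": seed})


def run(config: RunConfig) -> RunReport:
    """Execute the configured stages in dependency order.

    Validation failures abort before any compute; a stage failure aborts
    only its downstream dependents and is recorded with context.
    """
    findings = validate(config)
    if findings:
        raise ValueError("invalid config:\n" + "\n".join(findings))
    outdir = Path(config.get("outdir"))
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.hash(), version=__version__)
    stages = config.get("stages", list(ALL_STAGES))

    systems = None
    structural = [s for s in stages if s in STRUCTURAL_STAGES]
    if structural:
        try:
            systems = _load_systems(config, outdir, report)
        except Exception as exc:          # abort all structural dependents
            log.exception("system preparation failed")
            report.record("simulate", "failed", error=str(exc))
            for s in structural:
                if s != "simulate":
                    report.record(s, "aborted",
                                  params={"reason": "system preparation failed"})
            systems = None
    for stage, fn in (("distances", _stage_distances),
                      ("pca", _stage_pca),
                      ("contacts", _stage_contacts)):
        if stage not in stages:
            report.stages.setdefault(stage, {"status": "skipped",
                                             "outputs": [], "parameters": {}})
            continue
        if systems is None:
            continue
        try:
            fn(config, systems, outdir, report)
        except Exception as exc:
            log.exception("stage %s failed", stage)
            report.record(stage, "failed", error=str(exc))
    if "kinetics" in stages:
        try:
            _stage_kinetics(config, outdir, report)
        except Exception as exc:
            log.exception("kinetics stage failed")
            report.record("kinetics", "failed", error=str(exc))
    else:
        report.record("kinetics", "skipped",
                      params={"reason": "stage not requested"})
    if not structural:
        for s in STRUCTURAL_STAGES:
            report.stages.setdefault(s, {"status": "skipped", "outputs": [],
                                         "parameters": {"reason":
                                                        "stage not requested"}})
    report.write(outdir / "report.json")
    return report


def demo_config(outdir: str | Path, seed: int = 0,
                n_frames: int = 300) -> RunConfig:
    """A small end-to-end WT-vs-mutant configuration on synthetic data."""
    return RunConfig(raw={
        "seed": seed,
        "outdir": str(outdir),
        "stages": list(ALL_STAGES),
        "systems": {
            "WT": {"generate": {"n_frames": n_frames,
                                "fluctuation_sd": 1.4,
                                "p_closed_to_open": 0.0,
                                "p_open_to_closed": 0.0,
                                "start_state": "closed"}},
            "P78G": {"generate": {"n_frames": n_frames,
                                  "fluctuation_sd": 2.9,
                                  "p_closed_to_open": 0.0,
                                  "p_open_to_closed": 0.0,
                                  "start_state": "open"}},
        },
        "equilibration_fraction": 0.8,
        "selection": "name CA",
        "gate": {"atom_a": "resid 10 and name CA",
                 "atom_b": "resid 30 and name CA"},
        "contacts": {"cutoff": 4.5, "min_separation": 3,
                     "stable_threshold": 0.7, "df_threshold": 0.5,
                     "n_blocks": 4},
        "pca": {"n_components": 2, "bins": 40},
        "kinetics": {
            "rates": {"simulate": {"true_kcat": 5.4, "true_Ka": 130.0,
                                   "true_Kb": 10.0}},
            "model": "both",
            "traces": {"simulate": {"true_kred": 4.8, "true_Kd": 450.0},
                       "concentrations": [90, 150, 250, 350, 500]},
        },
    })
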