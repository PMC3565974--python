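"""End-to-end study orchestration: simulate -> fit-mri -> fit-mech -> analyze.

A :class:`StudyConfig` fully determines a run; rerunning with the same
config and seed reproduces every output table byte-identically.  Each
stage writes plain CSV/Newick files into its own subdirectory so stages
can also be run (and inspected) independently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, qmri, stats
from .biomech import (Geometry, RampSchedule, darcy_permeability,
                      fit_confined, fit_unconfined)
from .synthetic import (GROUPS, MECH_VARS, MRI_VARS, MechGroundTruth, REGIONS,
                        TissueGroundTruth, default_cohort_spec,
                        simulate_cohort, simulate_confined_test,
                        simulate_darcy_test, simulate_phantom,
                        simulate_unconfined_test, tensor_from_md_fa)
from .acquisition import default_protocol

__all__ = ["StudyConfig", "run_study", "write_report"]


@dataclass
class StudyConfig:
    """Configuration of one reproducible study run."""
    seed: int = 0
    n_per_group: int = 15
    #: zero the residual SD of the MRI -> mechanics linkage (exact linear cohort)
    noiseless_linkage: bool = False
    # imaging demo stage (small phantom per region)
    phantom_voxels_per_roi: int = 4
    mri_noise_sigma: float = 0.0
    # mechanical demo stage
    mech_demo: bool = True
    force_noise_sd: float = 0.0
    unconfined_schedule: dict = field(default_factory=lambda: {
        "n_ramps": 2, "strain_increment": 0.05,
        "ramp_duration": 60.0, "hold_duration": 1200.0})
    confined_schedule: dict = field(default_factory=lambda: {
        "n_ramps": 2, "strain_increment": 0.05,
        "ramp_duration": 60.0, "hold_duration": 900.0})
    # analysis options
    vif_threshold: float = 10.0
    power_convention: str = "n*f2"
    cluster_k_override: int | None = None

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _analyze(cohort: pd.DataFrame, config: StudyConfig, out: Path,
             tag: str) -> dict:
    """The statistics stage for one run; returns a summary dict."""
    summary: dict = {}
    tag_cmt = f"discmech {tag}"
    # per-group mean +/- SD summary table
    rows = []
    for reg in REGIONS:
        for grp in GROUPS:
            cell = cohort[(cohort.region == reg) & (cohort.group == grp)]
            row = {"region": reg, "group": grp, "n": len(cell)}
            for v in (*MRI_VARS, *MECH_VARS):
                row[f"{v}_mean"] = cell[v].mean()
                row[f"{v}_sd"] = cell[v].std(ddof=1)
            rows.append(row)
    io.write_csv(pd.DataFrame(rows), out / "group_summary.csv", tag_cmt)

    # ANOVA + Dunn-Sidak pairwise p-values per variable and region
    anova_rows = []
    for reg in REGIONS:
        sub = cohort[cohort.region == reg]
        for v in (*MECH_VARS, *MRI_VARS):
            groups = [sub[sub.group == g][v].dropna().to_numpy() for g in GROUPS]
            f, p = stats.one_way_anova(groups)
            row = {"region": reg, "variable": v, "F": f, "p_global": p}
            post = stats.dunn_sidak_pairwise(groups)
            for _, r in post.iterrows():
                row[f"p_{GROUPS[int(r.i)]}_vs_{GROUPS[int(r.j)]}"] = r.p_adj
            anova_rows.append(row)
    io.write_csv(pd.DataFrame(anova_rows), out / "anova.csv", tag_cmt)

    # multilinear regressions: per group and pooled
    reg_rows = []
    for reg in REGIONS:
        sub = cohort[cohort.region == reg]
        for resp in MECH_VARS:
            slices = [("all", sub)] + [(g, sub[sub.group == g]) for g in GROUPS]
            for name, sl in slices:
                if len(sl) <= len(stats.MRI_PREDICTORS) + 1:
                    continue
                res = stats.fit_multilinear(sl, resp,
                                            power_convention=config.power_convention)
                reduced, trace = stats.vif_eliminate(sl, resp,
                                                     config.vif_threshold)
                reg_rows.append({
                    "region": reg, "response": resp, "group": name,
                    "n": res.n, "r2": res.r2, "see": res.see,
                    "power": res.power_alpha05,
                    "max_vif": max(res.vif.values()),
                    "removed": ";".join(t["removed"] for t in trace),
                    "r2_reduced": reduced.r2,
                    **{f"a{i}": c for i, c in enumerate(res.coefficients)},
                })
    io.write_csv(pd.DataFrame(reg_rows), out / "regressions.csv", tag_cmt)
    summary["n_regression_blocks"] = len(REGIONS) * len(MECH_VARS)

    # PCA per mechanical property (correlation circles) and clustering
    pca_rows, circle_frames = [], []
    cluster_summary = {}
    for reg in REGIONS:
        sub = cohort[cohort.region == reg].reset_index(drop=True)
        for resp in MECH_VARS:
            pca = stats.run_pca(sub, (resp, *MRI_VARS))
            pca_rows.append({"region": reg, "variables": f"{resp}+MRI",
                             **{f"F{k+1}_cum": c for k, c in
                                enumerate(pca.cumulative_variability[:3])}})
            cc = stats.correlation_circle(pca)
            cc.insert(0, "variable", cc.index)
            cc.insert(0, "set", resp)
            cc.insert(0, "region", reg)
            circle_frames.append(cc)
        for label, varset in (("mech", MECH_VARS), ("mri", MRI_VARS)):
            pca = stats.run_pca(sub, tuple(varset))
            pcs = pca.scores[:, :3]
            dendro = stats.ward_cluster(pcs, tuple(sub.sample_id))
            division = stats.natural_division(dendro)
            k = config.cluster_k_override or division["k"]
            assign = dendro.cut(k)
            io.write_newick(dendro, out / f"dendrogram_{reg}_{label}.nwk")
            io.write_csv(pd.DataFrame({"sample_id": sub.sample_id,
                                       "group": sub.group,
                                       "cluster": assign}),
                         out / f"clusters_{reg}_{label}.csv", tag_cmt)
            pca_rows.append({"region": reg, "variables": label,
                             **{f"F{k2+1}_cum": c for k2, c in
                                enumerate(pca.cumulative_variability[:3])}})
            cluster_summary[f"{reg}_{label}"] = {
                "k_natural": division["k"], "k_used": k}
    io.write_csv(pd.DataFrame(pca_rows), out / "pca_variability.csv", tag_cmt)
    io.write_csv(pd.concat(circle_frames, ignore_index=True),
                 out / "correlation_circles.csv", tag_cmt)
    summary["clusters"] = cluster_summary
    return summary


def run_study(config: StudyConfig, out_dir) -> dict:
    """Execute all stages and write a report bundle; returns the manifest.

    Stage failures abort with the stage name; partial outputs persist.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        raise FileExistsError(f"run directory {out} is not empty")
    out.mkdir(parents=True, exist_ok=True)
    tag = f"run {config.config_hash} seed={config.seed}"
    manifest = {"config_hash": config.config_hash, "seed": config.seed,
                "version": __version__, "stages": {}}
    stage = "simulate"
    try:
        sim = out / "simulate"
        spec = default_cohort_spec(config.n_per_group, seed=config.seed)
        if config.noiseless_linkage:
            spec.noise_sd = {reg: {p: 0.0 for p in MECH_VARS}
                             for reg in REGIONS}
        cohort = simulate_cohort(spec)
        io.write_cohort_csv(cohort, sim / "cohort.csv", f"discmech {tag}")
        manifest["stages"][stage] = {"cohort_rows": len(cohort),
                                     "clipped": cohort.attrs["n_clipped"]}

        proto = default_protocol()
        npv = config.phantom_voxels_per_roi
        labels = np.array(["NP"] * npv + ["AF"] * npv + ["background"])
        truths = {
            "NP": TissueGroundTruth(1140.0, 124.0, 0.34,
                                    tensor_from_md_fa(15.04e-4, 0.0803)),
            "AF": TissueGroundTruth(706.0, 70.0, 0.44,
                                    tensor_from_md_fa(15.89e-4, 0.1583)),
        }
        phantom = simulate_phantom(labels, truths, proto,
                                   noise_sigma=config.mri_noise_sigma,
                                   seed=config.seed)
        io.write_csv(io.phantom_to_voxel_table(phantom),
                     sim / "phantom_voxels.csv", f"discmech {tag}")

        mech_truth = MechGroundTruth()
        curves = {}
        if config.mech_demo:
            curves["unconfined"] = simulate_unconfined_test(
                mech_truth, schedule=RampSchedule(**config.unconfined_schedule),
                noise_sd_n=config.force_noise_sd, seed=config.seed)
            curves["confined"] = simulate_confined_test(
                mech_truth, schedule=RampSchedule(**config.confined_schedule),
                noise_sd_n=config.force_noise_sd, seed=config.seed + 1)
            for kind, c in curves.items():
                io.write_mech_curve(c, sim / f"{kind}.csv")
        darcy = simulate_darcy_test(mech_truth.k_a)

        stage = "fit-mri"
        maps = qmri.fit_voxelwise(phantom)
        roi = qmri.roi_aggregate(maps, phantom.roi_labels)
        rows = [{"region": r, **{k: v[0] for k, v in s.items() if k != "excluded_fraction"},
                 **{f"{k}_sd": v[1] for k, v in s.items() if k != "excluded_fraction"},
                 "excluded_fraction": s["excluded_fraction"]}
                for r, s in roi.items()]
        io.write_csv(pd.DataFrame(rows), out / "fit_mri" / "roi_summary.csv",
                     f"discmech {tag}")
        manifest["stages"][stage] = {"voxels_fit": int(maps["converged"].sum())}

        stage = "fit-mech"
        mech_rows = []
        if config.mech_demo:
            pu = fit_unconfined(curves["unconfined"])
            pc = fit_confined(curves["confined"])
            mech_rows.append({"test": "unconfined", "E": pu.e_young,
                              "mu": pu.mu_visc, "k_r": pu.k_r, "nu": pu.nu,
                              "c": pu.c_visc})
            mech_rows.append({"test": "confined", "H_A0": pc.h_a0,
                              "k_0": pc.k_0, "beta": pc.beta, "M": pc.m_perm})
        mech_rows.append({"test": "darcy", "k_a": darcy_permeability(darcy)})
        io.write_csv(pd.DataFrame(mech_rows),
                     out / "fit_mech" / "mech_params.csv", f"discmech {tag}")
        manifest["stages"][stage] = {"fits": len(mech_rows)}

        stage = "analyze"
        manifest["stages"][stage] = _analyze(cohort, config,
                                             out / "analyze", tag)
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    stage = "report"
    write_report(out, manifest)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest


def write_report(run_dir, manifest: dict | None = None) -> Path:
    """Render a markdown report from a run directory's stage outputs."""
    run_dir = Path(run_dir)
    required = {
        "cohort": run_dir / "simulate" / "cohort.csv",
        "group summary": run_dir / "analyze" / "group_summary.csv",
        "ANOVA": run_dir / "analyze" / "anova.csv",
        "regressions": run_dir / "analyze" / "regressions.csv",
        "PCA": run_dir / "analyze" / "pca_variability.csv",
    }
    for name, p in required.items():
        if not p.exists():
            raise FileNotFoundError(f"missing stage output: {name} ({p})")
    cohort = io.read_cohort_csv(required["cohort"])
    if cohort.empty:
        raise ValueError("cohort table is empty")
    lines = ["# discmech study report", ""]
    if manifest:
        lines += [f"Run `{manifest['config_hash']}`, seed {manifest['seed']}, "
                  f"discmech {manifest['version']}.", ""]
    summary = pd.read_csv(required["group summary"], comment="#")
    lines += ["## Group means (mean +/- SD)", ""]
    for _, r in summary.iterrows():
        vals = ", ".join(f"{v}={r[f'{v}_mean']:.3g}+/-{r[f'{v}_sd']:.3g}"
                         for v in (*MECH_VARS, *MRI_VARS))
        lines.append(f"- **{r.region}/{r.group}** (n={r.n}): {vals}")
    anova = pd.read_csv(required["ANOVA"], comment="#")
    lines += ["", "## One-way ANOVA (global p per variable)", ""]
    for _, r in anova.iterrows():
        lines.append(f"- {r.region}/{r.variable}: p={r.p_global:.3g}")
    regs = pd.read_csv(required["regressions"], comment="#")
    lines += ["", "## Multilinear regressions (MRI -> mechanics)", ""]
    for (reg, resp), block in regs.groupby(["region", "response"]):
        lines.append(f"### {reg}: {resp}")
        for _, r in block.iterrows():
            lines.append(f"- {r.group} (n={r.n}): R2={r.r2:.3f}, "
                         f"SEE={r.see:.3g}, power={r.power:.2f}, "
                         f"maxVIF={r.max_vif:.1f}")
        lines.append("")
    pca = pd.read_csv(required["PCA"], comment="#")
    lines += ["## PCA cumulative variability", ""]
    for _, r in pca.iterrows():
        lines.append(f"- {r.region}/{r.variables}: F1 {r.F1_cum:.2f}, "
                     f"F2 {r.F2_cum:.2f}, F3 {r.F3_cum:.2f}")
    path = run_dir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
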