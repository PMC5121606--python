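"""Config-driven end-to-end orchestration.

A single YAML config names either input files (genotypes, coordinates,
environment) or a simulation block; the pipeline then runs the requested
stages (diversity, isotropic and anisotropic SGS, sPCA, SAR) with one master
seed fanned out into independent per-stage streams, writes plain TSV/JSON
artifacts per stage, and consolidates headline numbers into report.json and
a human-readable report.md. Every headline number is read back from a stage
artifact, so regenerating the report from the artifact files is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import time
import traceback
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import anisotropic, diversity, isotropic, sar, spca
from .data_model import (AnalysisConfig, GenotypeTable, SpatialFrame,
                         pairwise_geometry, read_coordinates, read_environment,
                         read_genotypes, write_genotypes_csv,
                         write_genotypes_genepop)
from .kinship import kinship_matrix
from .synthetic import SimulationConfig, simulate

__all__ = ["run_pipeline", "PipelineError", "DEFAULT_STAGES"]

DEFAULT_STAGES = ("diversity", "sgs", "anisotropy", "spca", "sar")

# fixed substream index per stage so adding a stage never perturbs another
_STAGE_STREAM = {"simulate": 0, "diversity": 1, "sgs": 2, "anisotropy": 3,
                 "spca": 4, "sar": 5}


class PipelineError(RuntimeError):
    pass


def _stage_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(master) % (2 ** 31), _STAGE_STREAM[stage]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _json_default(o: Any):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _dump_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True,
                               default=_json_default) + "\n")


def _distogram_frame(d: isotropic.Distogram) -> pd.DataFrame:
    return pd.DataFrame({
        "d_lo": d.class_edges[:-1], "d_hi": d.class_edges[1:],
        "F_D": d.F_D, "n_pairs": d.n_pairs,
        "envelope_lo": d.envelope_lo, "envelope_hi": d.envelope_hi,
        "p": d.p_per_class,
    })


def run_pipeline(config: str | Path | dict, out_dir: str | Path | None = None,
                 dry_run: bool = False) -> dict:
    """Execute the configured stages; returns the report dict.

    The YAML config has keys ``seed``, ``output_dir``, ``stages`` (optional
    subset of diversity/sgs/anisotropy/spca/sar), an ``analysis`` block of
    :class:`AnalysisConfig` fields, and either a ``simulation`` block of
    :class:`SimulationConfig` fields or an ``inputs`` block naming
    ``genotypes``/``coords``/``environment`` CSV paths. With ``dry_run`` the
    config and inputs are validated and no computation runs. A failed stage
    is recorded and its dependents are skipped; the report's ``ok`` flag is
    False in that case.
    """
    if isinstance(config, (str, Path)):
        cfg = yaml.safe_load(Path(config).read_text())
    else:
        cfg = dict(config)
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("output_dir", "finesgs_out"))
    stages = tuple(cfg.get("stages", DEFAULT_STAGES))
    unknown = set(stages) - set(DEFAULT_STAGES)
    if unknown:
        raise PipelineError(f"unknown stages {sorted(unknown)}")
    acfg_fields = dict(cfg.get("analysis", {}))
    acfg = AnalysisConfig(**acfg_fields)

    sim_cfg = cfg.get("simulation")
    inputs = cfg.get("inputs")
    if (sim_cfg is None) == (inputs is None):
        raise PipelineError("config must name exactly one of "
                            "'simulation' or 'inputs'")
    if inputs is not None:
        for key in ("genotypes", "coords"):
            if key not in inputs:
                raise PipelineError(f"inputs block missing {key!r}")
            if not Path(inputs[key]).exists():
                raise PipelineError(f"input file not found: {inputs[key]}")
        if "sar" in stages and "environment" not in inputs:
            raise PipelineError("the sar stage needs inputs.environment")
    if dry_run:
        if sim_cfg is not None:
            SimulationConfig(**{**sim_cfg, "rng_seed": seed})
        return {"ok": True, "dry_run": True, "stages": list(stages)}

    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": cfg, "seed": seed, "stages": {}, "ok": True,
                    "headline": {}}
    artifacts: dict[str, str] = {}
    timings: dict[str, float] = {}

    def record(stage: str, t0: float, **extra) -> None:
        timings[stage] = round(time.time() - t0, 3)
        report["stages"][stage] = {"status": "ok", **extra}

    def fail(stage: str, exc: Exception) -> None:
        report["ok"] = False
        report["stages"][stage] = {
            "status": "failed", "error": f"{type(exc).__name__}: {exc}",
            "traceback": traceback.format_exc(),
        }

    # ---- load or simulate -------------------------------------------------
    t0 = time.time()
    try:
        if sim_cfg is not None:
            scfg = SimulationConfig(**{**sim_cfg,
                                       "rng_seed": _stage_seed(seed, "simulate")})
            sim = simulate(scfg)
            g, frame, env_table = sim.genotypes, sim.frame, sim.environment
            write_genotypes_csv(g, out / "genotypes.csv")
            write_genotypes_genepop(g, out / "genotypes.gen")
            pd.DataFrame({"individual_id": frame.ids, "x": frame.x,
                          "y": frame.y}).to_csv(out / "coords.csv", index=False)
            env_table.data.to_csv(out / "environment.csv", index=False)
            truth = {k: v for k, v in sim.truth.items()}
            _dump_json(truth, out / "truth.json")
            artifacts["simulate"] = "truth.json"
            record("simulate", t0,
                   realized_migrants=sim.truth["realized_migrant_count"])
        else:
            g = read_genotypes(inputs["genotypes"],
                               format=inputs.get("format", "csv"))
            frame = read_coordinates(inputs["coords"]).align_to(g.ids)
            env_table = (read_environment(inputs["environment"]).align_to(g.ids)
                         if inputs.get("environment") else None)
            record("load", t0, n_individuals=g.n_individuals)
    except Exception as exc:
        fail("simulate" if sim_cfg is not None else "load", exc)
        _finalize(report, out, artifacts, timings)
        return report

    cohorts = g.cohort_labels
    D, A = pairwise_geometry(frame)

    # ---- diversity --------------------------------------------------------
    if "diversity" in stages:
        t0 = time.time()
        try:
            rng = np.random.default_rng(_stage_seed(seed, "diversity"))
            summaries = diversity.locus_summaries(g, hwe_perm=acfg.n_perm_fst,
                                                  rng=rng)
            pd.DataFrame([dataclasses.asdict(s) for s in summaries]).to_csv(
                out / "locus_summaries.tsv", sep="\t", index=False)
            diff = diversity.fst_between_cohorts(g, n_perm=acfg.n_perm_fst,
                                                 rng=rng)
            am = diversity.amova_chord(g, n_perm=acfg.n_perm_fst, rng=rng)
            payload = {"fst": diff.fst, "fst_p": diff.fst_p,
                       "fst_per_locus": diff.fst_per_locus,
                       "amova_sigma2": am.amova_sigma2,
                       "amova_sigma2_raw": am.amova_sigma2_raw,
                       "amova_p": am.amova_p}
            _dump_json(payload, out / "differentiation.json")
            artifacts["diversity"] = "differentiation.json"
            report["headline"]["fst"] = payload["fst"]
            report["headline"]["fst_p"] = payload["fst_p"]
            report["headline"]["amova_sigma2"] = payload["amova_sigma2"]
            report["headline"]["amova_p"] = payload["amova_p"]
            record("diversity", t0)
        except Exception as exc:
            fail("diversity", exc)

    # ---- kinship once, shared by sgs/anisotropy ---------------------------
    kin = None
    if {"sgs", "anisotropy"} & set(stages):
        try:
            kin = kinship_matrix(g, marker="ssr", freq_scope="pooled")
        except Exception as exc:
            fail("sgs", exc)

    if "sgs" in stages and kin is not None:
        t0 = time.time()
        try:
            sp_results = {}
            modes = [f"within_{c}" for c in cohorts] + ["between"]
            sgs_cfg = dataclasses.replace(acfg,
                                          rng_seed=_stage_seed(seed, "sgs"))
            for mode in modes:
                dg = isotropic.distogram(kin, D, mode, sgs_cfg)
                _distogram_frame(dg).to_csv(out / f"distogram_{mode}.tsv",
                                            sep="\t", index=False)
                sp = isotropic.sp_statistic(kin, D, mode, sgs_cfg)
                sp_results[mode] = sp.as_dict()
            if len(cohorts) == 2:
                a = isotropic.sp_statistic(kin, D, f"within_{cohorts[0]}",
                                           sgs_cfg, n_perm=0)
                b = isotropic.sp_statistic(kin, D, f"within_{cohorts[1]}",
                                           sgs_cfg, n_perm=0)
                sp_results["t_test_between_cohorts"] = \
                    isotropic.compare_cohorts(a, b, kin.n_loci)
            _dump_json(sp_results, out / "sp_results.json")
            artifacts["sgs"] = "sp_results.json"
            for mode in modes:
                report["headline"][f"Sp_{mode}"] = sp_results[mode]["Sp"]
            record("sgs", t0)
        except Exception as exc:
            fail("sgs", exc)

    if "anisotropy" in stages and kin is not None:
        t0 = time.time()
        try:
            ani_cfg = dataclasses.replace(acfg,
                                          rng_seed=_stage_seed(seed, "anisotropy"))
            ani: dict = {}
            for c in cohorts:
                mode = f"within_{c}"
                bc = anisotropic.bearing_correlogram(kin, (D, A), ani_cfg,
                                                     mode=mode)
                pd.DataFrame({"angle": bc.angles, "r": bc.r, "p": bc.p}).to_csv(
                    out / f"bearing_correlogram_{c}.tsv", sep="\t", index=False)
                entry = {"theta_s": bc.theta_s, "theta_w": bc.theta_w,
                         "r_s": bc.r_s, "r_w": bc.r_w}
                for label, theta in (("theta_s", bc.theta_s),
                                     ("theta_w", bc.theta_w)):
                    try:
                        sp = anisotropic.sector_sp(kin, (D, A), theta, ani_cfg,
                                                   mode=mode, n_perm=0)
                        entry[f"sp_{label}"] = sp.as_dict()
                    except ValueError as e:
                        entry[f"sp_{label}"] = {"error": str(e)}
                ani[c] = entry
                report["headline"][f"theta_s_{c}"] = bc.theta_s
                report["headline"][f"theta_w_{c}"] = bc.theta_w
            _dump_json(ani, out / "anisotropy.json")
            artifacts["anisotropy"] = "anisotropy.json"
            record("anisotropy", t0)
        except Exception as exc:
            fail("anisotropy", exc)

    # ---- sPCA -------------------------------------------------------------
    spca_scores: dict[str, np.ndarray] = {}
    nets: dict[str, spca.ConnectionNetwork] = {}
    if {"spca", "sar"} & set(stages):
        t0 = time.time()
        try:
            rng = np.random.default_rng(_stage_seed(seed, "spca"))
            results: dict = {}
            eig_rows, score_frames = [], []
            for c in cohorts:
                sub = g.cohort_subset(c)
                idx = np.where(g.cohorts.astype(str) == c)[0]
                sub_frame = SpatialFrame([frame.ids[i] for i in idx],
                                         frame.x[idx], frame.y[idx],
                                         frame.plot_bounds)
                net_raw = spca.build_network(sub_frame, style="raw")
                fit = spca.spca_fit(sub, net_raw)
                spca_scores[c] = fit.scores
                nets[c] = spca.build_network(sub_frame, style="row")
                gt, gp = spca.global_local_test(sub, net_raw, which="global",
                                               n_perm=acfg.n_perm_mantel,
                                               rng=rng)
                lt, lp = spca.global_local_test(sub, net_raw, which="local",
                                               n_perm=acfg.n_perm_mantel,
                                               rng=rng)
                results[c] = {"eigenvalues": fit.eigenvalues[:5].tolist(),
                              "global_max_t": gt, "global_p": gp,
                              "local_max_t": lt, "local_p": lp}
                eig_rows.append(pd.DataFrame({
                    "cohort": c,
                    "component": np.arange(1, len(fit.eigenvalues) + 1),
                    "eigenvalue": fit.eigenvalues}))
                score_frames.append(pd.DataFrame({
                    "individual_id": sub.ids, "cohort": c,
                    "x": sub_frame.x, "y": sub_frame.y,
                    "PC1": fit.scores[:, 0],
                    "PC2": fit.scores[:, 1] if fit.scores.shape[1] > 1
                    else np.nan}))
                report["headline"][f"spca_lambda1_{c}"] = float(fit.eigenvalues[0])
                report["headline"][f"spca_global_p_{c}"] = gp
            pd.concat(eig_rows).to_csv(out / "spca_eigenvalues.tsv", sep="\t",
                                       index=False)
            pd.concat(score_frames).to_csv(out / "spca_scores.tsv", sep="\t",
                                           index=False)
            _dump_json(results, out / "spca_tests.json")
            artifacts["spca"] = "spca_tests.json"
            record("spca", t0)
        except Exception as exc:
            fail("spca", exc)
            spca_scores = {}

    # ---- SAR --------------------------------------------------------------
    if "sar" in stages:
        t0 = time.time()
        if env_table is None:
            fail("sar", PipelineError("no environment table available"))
        elif not spca_scores:
            fail("sar", PipelineError("sPCA stage did not produce scores"))
        else:
            try:
                rng = np.random.default_rng(_stage_seed(seed, "sar"))
                tables, models = [], {}
                for c in cohorts:
                    sub_ids = [i for i, lab in zip(g.ids, g.cohorts.astype(str))
                               if lab == c]
                    env_sub = env_table.align_to(sub_ids)
                    preds = sar.build_env_predictors(env_sub)
                    for pc in (0, 1):
                        if spca_scores[c].shape[1] <= pc:
                            continue
                        ma = sar.model_select_average(
                            spca_scores[c][:, pc], preds, nets[c],
                            moran_perm=min(acfg.n_perm_mantel, 199), rng=rng)
                        tab = ma.table.assign(cohort=c, response=f"PC{pc + 1}")
                        tables.append(tab)
                        models[f"{c}_PC{pc + 1}"] = {
                            "rho": ma.rho_estimate, "rho_se": ma.rho_se,
                            "selected": ma.selected_models}
                        report["headline"][f"sar_rho_{c}_PC{pc + 1}"] = \
                            ma.rho_estimate
                pd.concat(tables).to_csv(out / "sar_averages.tsv", sep="\t",
                                         index=False)
                _dump_json(models, out / "sar_models.json")
                artifacts["sar"] = "sar_models.json"
                record("sar", t0)
            except Exception as exc:
                fail("sar", exc)

    _finalize(report, out, artifacts, timings)
    return report


def _finalize(report: dict, out: Path, artifacts: dict[str, str],
              timings: dict[str, float] | None = None) -> None:
    report["artifacts"] = artifacts
    _dump_json(report, out / "report.json")
    _dump_json(timings or {}, out / "timings.json")
    lines = ["# finesgs pipeline report", ""]
    for stage, info in report["stages"].items():
        mark = "ok" if info.get("status") == "ok" else "FAILED"
        secs = (timings or {}).get(stage, "-")
        lines.append(f"- **{stage}**: {mark} ({secs} s)")
    if report["headline"]:
        lines += ["", "## Headline numbers", ""]
        for key, val in report["headline"].items():
            if isinstance(val, float):
                lines.append(f"- {key}: {val:.6g}")
            else:
                lines.append(f"- {key}: {val}")
    (out / "report.md").write_text("\n".join(lines) + "\n")
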