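"""End-to-end orchestration: simulate -> behavior -> GLM -> decode ->
DCM inversion -> BMS/BMA -> swap test -> report.

Every stage writes its artifacts as documented text formats (TSV/CSV/JSON)
into the output directory, and stages can be re-run individually against
previously written artifacts.  All randomness flows through named seed
streams derived from the config seed, so a rerun with the same config is
bit-identical.

The default "desk" profile runs the whole chain at reduced scale (smaller
runs, cohort, model subset and permutation counts) so a complete pass
finishes in minutes on one CPU; the "full" profile mirrors the original
study dimensions (28 behavioral participants, 26 DCM participants, 5-block
runs of 552 volumes, the full 72-model space).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayes, behavior, dcm, generative, glm, inversion, model_space, predictive, synthetic
from .constants import HORIZONTAL, NODES, VERTICAL

logger = logging.getLogger(__name__)

STAGES = ("simulate", "behavior", "glm", "decode", "dcm-invert", "bms", "swap-test")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    profile: str = "desk"  # "desk" or "full"
    scenario: str = "null-direction"  # or "direction-effect", "custom"
    cohort_behavior: int | None = None  # defaults per profile
    cohort_dcm: int | None = None
    stages: tuple[str, ...] = STAGES
    out_dir: str = "meridian_out"
    n_perm_decode: int = 99
    n_null_swap: int = 199
    bf_iterations: int = 10_000
    b_strength: float = 0.4
    b3_strength: float | None = None  # None -> equal to b_strength
    direction_effect_ms: float = 0.0
    snr: float = 1.0
    model_subset: tuple | None = None  # None -> profile default
    write_raw: bool = False

    def __post_init__(self) -> None:
        if self.profile not in ("desk", "full"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.scenario not in ("null-direction", "direction-effect", "custom"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.cohort_behavior is None:
            self.cohort_behavior = 12 if self.profile == "desk" else 28
        if self.cohort_dcm is None:
            self.cohort_dcm = 6 if self.profile == "desk" else 26
        if self.scenario == "direction-effect":
            if self.b3_strength is None:
                self.b3_strength = 0.0
            if self.direction_effect_ms == 0.0:
                self.direction_effect_ms = 30.0
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @property
    def design_spec(self) -> synthetic.DesignSpec:
        return synthetic.DESK_SPEC if self.profile == "desk" else synthetic.DesignSpec()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


def _stage_seed(seed: int, name: str, k: int = 0) -> int:
    # stable (not hash-randomized) per-stage seed below 2**31
    base = sum(ord(c) * 131**i for i, c in enumerate(name)) % (2**20)
    return (seed * (2**20) + base + k) % (2**31)


def default_model_subset(profile: str) -> list[model_space.ModulationStructure]:
    """Models inverted by the dcm stage.

    desk: one TPJ->dorsal model per laterality x IPS-direction cell (9
    models), enough for the two-level family selection; full: all 72.
    """
    models = model_space.enumerate_models()
    if profile == "full":
        return models
    chosen = [
        m
        for m in models
        if m.tpj_ips == "tpj_to_dorsal" and m.tpj_fef == "tpj_to_dorsal"
    ]
    return chosen


def ground_truth_for(config: RunConfig) -> synthetic.GroundTruthNetwork:
    return synthetic.default_ground_truth(
        b_strength=config.b_strength,
        b3_strength=config.b3_strength,
        snr=config.snr,
    )


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------


def stage_simulate(config: RunConfig, out: Path) -> dict:
    spec = config.design_spec
    truth = ground_truth_for(config)
    behav_params = synthetic.BehaviorParams(
        direction_effect_ms=config.direction_effect_ms,
        seed=_stage_seed(config.seed, "behavior-params"),
    )
    records = {}
    bolds = {}
    inputs = {}
    events = {}
    for pid in range(config.cohort_behavior):
        s = _stage_seed(config.seed, "design", pid)
        seq_h, seq_v = synthetic.generate_design_pair(spec, seed=s)
        seq = pd.concat([seq_h, seq_v], ignore_index=True)
        params = replace(behav_params, seed=_stage_seed(config.seed, "rt", pid))
        records[pid] = synthetic.generate_behavior(seq, params)
        if pid < config.cohort_dcm:
            bold, inp = synthetic.generate_bold(
                (seq_h, seq_v), truth, spec=spec, seed=_stage_seed(config.seed, "bold", pid)
            )
            bolds[pid], inputs[pid], events[pid] = bold, inp, (seq_h, seq_v)
    if config.write_raw:
        raw = out / "raw"
        raw.mkdir(exist_ok=True)
        for pid, rec in records.items():
            synthetic.write_events(rec, raw / f"sub-{pid:02d}_events.tsv")
        for pid, bold in bolds.items():
            synthetic.write_timeseries(bold, raw / f"sub-{pid:02d}_bold.tsv")
    truth.model.save(out / "ground_truth_model.json")
    return {
        "records": records,
        "bolds": bolds,
        "inputs": inputs,
        "events": events,
        "truth": truth,
        "spec": spec,
    }


def stage_behavior(config: RunConfig, ctx: dict, out: Path) -> dict:
    table = behavior.summarize_cohort(ctx["records"])
    table.to_csv(out / "behavior_summary.csv", index=False)
    rt_table = table.rename(columns={"median_rt_ms": "value"})
    bf_rt = bayes.bf_anova(
        rt_table[["participant", "cueing", "direction", "value"]],
        iterations=config.bf_iterations,
        seed=_stage_seed(config.seed, "bf-rt"),
    )
    err_table = table.rename(columns={"error_rate": "value"})
    bf_err = bayes.bf_anova(
        err_table[["participant", "cueing", "direction", "value"]],
        iterations=config.bf_iterations,
        seed=_stage_seed(config.seed, "bf-err"),
    )
    result = {"rt": bf_rt.to_dict(), "error_rate": bf_err.to_dict(),
              "best_rt_model": bf_rt.best_model(), "best_error_model": bf_err.best_model()}
    (out / "behavior_bf.json").write_text(json.dumps(result, indent=1))
    return {"behavior_table": table, "bf_rt": bf_rt, "bf_err": bf_err}


def stage_glm(config: RunConfig, ctx: dict, out: Path) -> dict:
    spec = ctx["spec"]
    results = {}
    for pid, bold in ctx["bolds"].items():
        seq_h, seq_v = ctx["events"][pid]
        events = pd.concat([seq_h, seq_v], ignore_index=True)
        design = glm.build_design_matrix(
            events, n_volumes=spec.volumes_per_run, tr=spec.tr_seconds
        )
        results[pid] = glm.fit_glm(bold, design)
    table = glm.beta_table(results)
    glm.write_beta_table(table, out / "beta_table.tsv")
    # VOI Bayes-factor ANOVAs on direction-collapsed betas
    voi_bf = {}
    for node in NODES:
        rows = []
        for pid, res in results.items():
            coll = glm.collapse_betas(res.betas).loc[node]
            for name, val in coll.items():
                cueing, direction = name.split("_")
                rows.append(
                    {"participant": pid, "cueing": cueing, "direction": direction, "value": val}
                )
        bf = bayes.bf_anova(
            pd.DataFrame(rows),
            iterations=config.bf_iterations,
            seed=_stage_seed(config.seed, f"bf-voi-{node}"),
        )
        voi_bf[node] = {"best_model": bf.best_model(), **bf.to_dict()}
    # group-level contrast tests (sign-flip permutation on per-participant values)
    contrasts = {}
    for cname in ("main_cueing", "horiz_reorient", "vert_reorient", "main_direction", "interaction"):
        vals = {
            node: [float(glm.apply_contrast(results[pid].betas, cname)[node]) for pid in results]
            for node in NODES
        }
        contrasts[cname] = {
            node: {
                "mean": float(np.mean(v)),
                "p_signflip": glm.signflip_ttest(
                    v, n_permutations=5000, seed=_stage_seed(config.seed, f"sf-{cname}-{node}")
                ),
            }
            for node, v in vals.items()
        }
    (out / "glm_report.json").write_text(
        json.dumps({"voi_bf_anova": voi_bf, "contrasts": contrasts}, indent=1)
    )
    return {"glm_results": results, "beta_table": table, "voi_bf": voi_bf, "contrasts": contrasts}


def stage_decode(config: RunConfig, ctx: dict, out: Path) -> dict:
    table = ctx["beta_table"]
    ds_h = predictive.decode_dataset_from_betas(table, HORIZONTAL)
    ds_v = predictive.decode_dataset_from_betas(table, VERTICAL)
    seed = _stage_seed(config.seed, "decode")
    n_perm = config.n_perm_decode
    if n_perm > 0:
        within_h = predictive.permutation_p_nested(ds_h, n_perm=n_perm, seed=seed)
        within_v = predictive.permutation_p_nested(ds_v, n_perm=n_perm, seed=seed + 1)
        cross_hv = predictive.permutation_p_cross(ds_h, ds_v, n_perm=n_perm, seed=seed + 2)
        cross_vh = predictive.permutation_p_cross(ds_v, ds_h, n_perm=n_perm, seed=seed + 3)
        res = {
            "within_horizontal": {"accuracy": within_h.observed, "p": within_h.p_value},
            "within_vertical": {"accuracy": within_v.observed, "p": within_v.p_value},
            "cross_h_to_v": {"accuracy": cross_hv.observed, "p": cross_hv.p_value},
            "cross_v_to_h": {"accuracy": cross_vh.observed, "p": cross_vh.p_value},
        }
    else:  # accuracies only (permutation tests skipped)
        res = {
            "within_horizontal": {
                "accuracy": predictive.nested_cv_accuracy(ds_h, seed=seed), "p": None
            },
            "within_vertical": {
                "accuracy": predictive.nested_cv_accuracy(ds_v, seed=seed + 1), "p": None
            },
            "cross_h_to_v": {
                "accuracy": predictive.cross_run_generalization(ds_h, ds_v, seed=seed + 2)[0],
                "p": None,
            },
            "cross_v_to_h": {
                "accuracy": predictive.cross_run_generalization(ds_v, ds_h, seed=seed + 3)[0],
                "p": None,
            },
        }
    res["n_permutations"] = n_perm
    (out / "decode_report.json").write_text(json.dumps(res, indent=1))
    return {"decode": res}


def stage_dcm_invert(config: RunConfig, ctx: dict, out: Path) -> dict:
    subset = config.model_subset
    models = (
        default_model_subset(config.profile)
        if subset is None
        else [model_space.enumerate_models()[i] for i in subset]
    )
    models = [replace(m, index=i) for i, m in enumerate(models)]
    posteriors: dict[int, list] = {}
    lme = np.zeros((len(ctx["bolds"]), len(models)))
    for row, (pid, bold) in enumerate(sorted(ctx["bolds"].items())):
        posts = []
        for m in models:
            post = inversion.invert(m, bold, ctx["inputs"][pid])
            posts.append(post)
            lme[row, m.index] = post.free_energy
        posteriors[pid] = posts
    pd.DataFrame(lme, columns=[f"m{m.index}" for m in models]).to_csv(
        out / "log_evidence.tsv", sep="\t", index=False
    )
    mean_r2 = float(np.mean([p.r2_pooled for posts in posteriors.values() for p in posts]))
    (out / "inversion_report.json").write_text(
        json.dumps({"n_models": len(models), "mean_r2_percent": mean_r2}, indent=1)
    )
    return {"models": models, "posteriors": posteriors, "lme": lme}


def stage_bms(config: RunConfig, ctx: dict, out: Path) -> dict:
    models, lme = ctx["models"], ctx["lme"]
    sel = model_space.hierarchical_family_selection(
        lme, models, seed=_stage_seed(config.seed, "bms")
    )
    # per-participant BMA over the winning family
    win = sel["winning_family_models"]
    bma_params = {}
    for row, (pid, posts) in enumerate(sorted(ctx["posteriors"].items())):
        means = [posts[i].means for i in win]
        fs = [posts[i].free_energy for i in win]
        bma_params[pid] = model_space.bma(means, np.array(fs))
    # Bayesian paired t-tests on each B1/B3 parameter pair
    b_names = sorted(
        {n[3:] for params in bma_params.values() for n in params if n.startswith("B1[")}
    )
    ttests = {}
    for suffix in b_names:
        x = [bma_params[pid].get("B1[" + suffix, 0.0) for pid in sorted(bma_params)]
        y = [bma_params[pid].get("B3[" + suffix, 0.0) for pid in sorted(bma_params)]
        d = np.asarray(x) - np.asarray(y)
        bf = bayes.bf_paired_ttest(np.asarray(x), np.asarray(y))
        ttests["B[" + suffix] = {
            "mean_diff": float(d.mean()), "sd_diff": float(d.std(ddof=1)), "bf10": bf
        }
    result = {
        "level1": sel["level1"].to_dict(),
        "level2": sel["level2"].to_dict(),
        "laterality_winner": sel["laterality_winner"],
        "ips_winner": sel["ips_winner"],
        "paired_bf": ttests,
    }
    (out / "bms_report.json").write_text(json.dumps(result, indent=1))
    return {"selection": sel, "bma_params": bma_params, "paired_bf": ttests}


def stage_swap_test(config: RunConfig, ctx: dict, out: Path) -> dict:
    results = []
    per_participant = {}
    for pid, bold in sorted(ctx["bolds"].items()):
        params = ctx["bma_params"][pid]
        model = inversion.model_from_means(params)
        inputs = ctx["inputs"][pid]
        projectors, _ = inversion.build_confound_projector(inputs.volumes_per_run, inputs.tr)
        observed = inversion._project(bold[list(NODES)].to_numpy(dtype=float), projectors)
        res = generative.generative_permutation_test(
            model,
            observed + 0.0,
            inputs,
            n_null=config.n_null_swap,
            seed=_stage_seed(config.seed, "swap", pid),
        )
        results.append(res)
        per_participant[pid] = res.to_dict()
    prop = generative.swap_success_proportion(results)
    report = {
        "per_participant": per_participant,
        "proportion_swapped_p_below_05": prop,
        "n_null": config.n_null_swap,
    }
    (out / "swap_report.json").write_text(json.dumps(report, indent=1))
    return {"swap_results": results, "swap_proportion": prop}


# --------------------------------------------------------------------------
# Orchestration
# --------------------------------------------------------------------------

_STAGE_FUNCS = {
    "behavior": stage_behavior,
    "glm": stage_glm,
    "decode": stage_decode,
    "dcm-invert": stage_dcm_invert,
    "bms": stage_bms,
    "swap-test": stage_swap_test,
}

_STAGE_DEPS = {
    "behavior": ("simulate",),
    "glm": ("simulate",),
    "decode": ("glm",),
    "dcm-invert": ("simulate",),
    "bms": ("dcm-invert",),
    "swap-test": ("simulate", "bms"),
}


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and write the aggregated report.

    Returns the report dict; artifacts land in ``config.out_dir``.  A stage
    failure raises with the stage name; artifacts of completed stages
    remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    requested = [s for s in STAGES if s in config.stages]
    # pull in dependencies (in-memory pipeline: upstream stages must run)
    needed: list[str] = []

    def add(stage: str) -> None:
        for dep in _STAGE_DEPS.get(stage, ()):
            add(dep)
        if stage not in needed:
            needed.append(stage)

    for s in requested:
        add(s)
    ctx: dict = {}
    for stage in STAGES:
        if stage not in needed:
            continue
        logger.info("running stage %s", stage)
        try:
            if stage == "simulate":
                ctx.update(stage_simulate(config, out))
            else:
                ctx.update(_STAGE_FUNCS[stage](config, ctx, out))
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    report = build_summary(config, ctx)
    (out / "summary.json").write_text(json.dumps(report, indent=1))
    (out / "summary.txt").write_text(format_summary(report))
    return report


def build_summary(config: RunConfig, ctx: dict) -> dict:
    """Aggregate the per-stage outputs into one report dict."""
    summary: dict = {"config": {"seed": config.seed, "profile": config.profile,
                                "scenario": config.scenario}}
    if "bf_rt" in ctx:
        summary["behavior"] = {
            "best_rt_model": ctx["bf_rt"].best_model(),
            "rt_log_bf10": ctx["bf_rt"].log_bf10,
            "best_error_model": ctx["bf_err"].best_model(),
            "error_log_bf10": ctx["bf_err"].log_bf10,
        }
    if "voi_bf" in ctx:
        summary["voi"] = {node: d["best_model"] for node, d in ctx["voi_bf"].items()}
    if "decode" in ctx:
        summary["decode"] = ctx["decode"]
    if "selection" in ctx:
        sel = ctx["selection"]
        summary["bms"] = {
            "laterality_winner": sel["laterality_winner"],
            "laterality_ep": dict(zip(sel["level1"].names, sel["level1"].exceedance_p.tolist())),
            "ips_winner": sel["ips_winner"],
            "ips_ep": dict(zip(sel["level2"].names, sel["level2"].exceedance_p.tolist())),
        }
        bfs = [d["bf10"] for d in ctx["paired_bf"].values()]
        summary["paired_bf_median"] = float(np.median(bfs)) if bfs else None
    if "swap_proportion" in ctx:
        summary["swap_proportion_p_below_05"] = ctx["swap_proportion"]
    return summary


def _direction_verdict(summary: dict) -> list[str]:
    lines = []
    beh = summary.get("behavior")
    if beh:
        verdict = "no direction effect" if "direction" not in beh["best_rt_model"] else "direction effect"
        lines.append(f"behavior: best RT model = {beh['best_rt_model']} -> {verdict}")
    if "paired_bf_median" in summary and summary["paired_bf_median"] is not None:
        m = summary["paired_bf_median"]
        verdict = "no direction effect" if m < 1 else "direction effect"
        lines.append(f"connectivity: median paired BF10 (B1 vs B3) = {m:.3g} -> {verdict}")
    if "swap_proportion_p_below_05" in summary:
        p = summary["swap_proportion_p_below_05"]
        verdict = "no direction effect" if p >= 0.5 else "direction effect"
        lines.append(
            f"generative: swapped inputs beat the random null for {100 * p:.0f}% of "
            f"participants -> {verdict}"
        )
    return lines


def format_summary(summary: dict) -> str:
    """Human-readable run summary, one evidence line per analysis."""
    lines = [
        "meridian pipeline summary",
        f"profile={summary['config']['profile']} scenario={summary['config']['scenario']} "
        f"seed={summary['config']['seed']}",
        "",
    ]
    if "behavior" in summary:
        lines.append("Behavioral BF-ANOVA:")
        for mdl, lbf in summary["behavior"]["rt_log_bf10"].items():
            lines.append(f"  RT {mdl}: log BF10 = {lbf:.2f}")
    if "voi" in summary:
        lines.append("VOI BF-ANOVA best models: " + ", ".join(
            f"{n}={m}" for n, m in summary["voi"].items()))
    if "decode" in summary:
        d = summary["decode"]
        for key in ("within_horizontal", "within_vertical", "cross_h_to_v", "cross_v_to_h"):
            p = d[key]["p"]
            p_txt = f"p = {p:.3f}" if p is not None else "no permutation test"
            lines.append(
                f"  decode {key}: accuracy = {d[key]['accuracy']:.3f} ({p_txt})"
            )
    if "bms" in summary:
        b = summary["bms"]
        lines.append(
            f"BMS: laterality winner = {b['laterality_winner']} "
            f"(ep = {b['laterality_ep'][b['laterality_winner']]:.2f}); "
            f"IPS winner = {b['ips_winner']} (ep = {b['ips_ep'][b['ips_winner']]:.2f})"
        )
    lines.append("")
    lines.extend(_direction_verdict(summary))
    return "\n".join(lines) + "\n"
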