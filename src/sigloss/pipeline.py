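"""End-to-end orchestration: simulate/load -> preprocess -> derive signature
-> score cohorts -> survival -> meta-analysis -> enrichment.

The pipeline is driven by a YAML config (see ``example_config``) and writes
all intermediates (TSV/GMT/JSON) plus a ``RunReport`` JSON into the output
directory. Given fixed seeds the report is fully regenerable from config +
inputs, modulo wall-times.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import de as de_mod
from . import gsea as gsea_mod
from . import meta as meta_mod
from . import scoring, survival
from .io import (ExpressionMatrix, SiglossError, read_clinical, read_expression,
                 read_gmt, signature_to_gmt, write_expression, write_rnk)
from .preprocess import filter_low_counts, tmm_normalize
from .simulate import SimConfig, simulate_cohort, write_cohort


def example_config(outdir: str = "sigloss_out", seed: int = 7) -> dict:
    """A paper-shaped demo config: one discovery and three validation cohorts."""
    return {
        "outdir": outdir,
        "seed": seed,
        "simulate": {
            "discovery": {"n_samples": 120, "n_genes": 1000, "n_planted_up": 50,
                          "n_planted_down": 50, "effect_log2": 2.0},
            "validation": [
                {"name": "cohort_A", "n_samples": 100},
                {"name": "cohort_B", "n_samples": 140},
                {"name": "cohort_C", "n_samples": 90},
            ],
        },
        "de": {"anchor": "ZFP36", "rule": "quartile_low_vs_rest", "B": 1000,
               "q_max": 0.05, "lmr_min": 0.58},
        "score": {"rule": "median"},
        "survival": {"adjust": []},
        "meta": {"model": "random"},
        "gsea": {"enabled": True, "mode": "gene_set_perm", "n_perm": 1000,
                 "min_size": 10, "max_size": 500},
    }


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise SiglossError("pipeline config must be a YAML mapping")
    return cfg


def validate_inputs(expr_paths: dict[str, str], clinical_paths: dict[str, str]) -> dict:
    """Cross-check expression/clinical pairs; returns an issue report.

    Fatal issues (duplicate ids, unreadable tables) set ``fatal``; sample-id
    mismatches are listed per cohort but only fatal when no sample overlaps.
    """
    report: dict = {"fatal": [], "mismatches": {}, "cohorts": {}}
    for name, epath in expr_paths.items():
        try:
            expr = read_expression(epath)
        except Exception as err:  # duplicate ids, NaNs, bad scale
            report["fatal"].append(f"{name}: {err}")
            continue
        cpath = clinical_paths.get(name)
        if cpath is None:
            report["mismatches"][name] = "no clinical table"
            continue
        try:
            clin = read_clinical(cpath)
        except Exception as err:
            report["fatal"].append(f"{name}: {err}")
            continue
        only_clin = sorted(set(clin.index) - set(expr.sample_ids))
        only_expr = sorted(set(expr.sample_ids) - set(clin.index))
        shared = set(clin.index) & set(expr.sample_ids)
        if only_clin or only_expr:
            report["mismatches"][name] = {"clinical_only": only_clin,
                                          "expression_only": only_expr}
        if not shared:
            report["fatal"].append(f"{name}: no shared samples between tables")
        report["cohorts"][name] = {"n_genes": expr.n_genes,
                                   "n_shared_samples": len(shared)}
    report["ok"] = not report["fatal"]
    return report


def _load_or_simulate(cfg: dict, outdir: Path, seed: int, report: dict
                      ) -> tuple[dict[str, ExpressionMatrix], dict[str, pd.DataFrame], dict]:
    cohorts_expr: dict[str, ExpressionMatrix] = {}
    cohorts_clin: dict[str, pd.DataFrame] = {}
    truths: dict = {}
    if "simulate" in cfg:
        sim = cfg["simulate"]
        specs = [("discovery", sim.get("discovery", {}))]
        for i, v in enumerate(sim.get("validation", [])):
            v = dict(v)
            specs.append((v.pop("name", f"validation_{i + 1}"), v))
        for i, (name, params) in enumerate(specs):
            params = dict(params)
            params.setdefault("seed", seed + 101 * (i + 1))
            sc = SimConfig(**params)
            expr, clin, truth = simulate_cohort(sc)
            write_cohort(expr, clin, truth, outdir / "cohorts" / name)
            cohorts_expr[name], cohorts_clin[name], truths[name] = expr, clin, truth
            report["stages"].setdefault("simulate", {})[name] = {
                "config": asdict(sc), "n_genes": expr.n_genes,
                "n_samples": expr.n_samples,
            }
    else:
        cohort_cfg = cfg.get("cohorts")
        if not cohort_cfg or "discovery" not in cohort_cfg:
            raise SiglossError("config needs either 'simulate' or 'cohorts.discovery'")
        entries = [("discovery", cohort_cfg["discovery"])]
        for i, v in enumerate(cohort_cfg.get("validation", [])):
            entries.append((v.get("name", f"validation_{i + 1}"), v))
        for name, entry in entries:
            expr = read_expression(entry["expression"], scale=entry.get("scale", "normalized"))
            cohorts_expr[name] = expr
            if "clinical" in entry:
                cohorts_clin[name] = read_clinical(entry["clinical"])
    return cohorts_expr, cohorts_clin, truths


def run_pipeline(cfg: dict | str | Path) -> dict:
    """Execute the configured stages in dependency order; returns the RunReport."""
    if not isinstance(cfg, dict):
        cfg = load_config(cfg)
    outdir = Path(cfg.get("outdir", "sigloss_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    report: dict = {"config": cfg, "stages": {}, "wall_time_s": {}}

    def timed(stage):
        t0 = time.perf_counter()
        return lambda: report["wall_time_s"].__setitem__(
            stage, round(time.perf_counter() - t0, 3))

    done = timed("inputs")
    cohorts_expr, cohorts_clin, truths = _load_or_simulate(cfg, outdir, seed, report)
    done()

    discovery = cohorts_expr["discovery"]
    pp_cfg = cfg.get("preprocess", {})
    if pp_cfg.get("enabled", discovery.scale == "raw_counts") and \
            discovery.scale == "raw_counts":
        done = timed("preprocess")
        for name in list(cohorts_expr):
            m = cohorts_expr[name]
            if m.scale != "raw_counts":
                continue
            filtered = filter_low_counts(m, pp_cfg.get("min_total", 2),
                                         pp_cfg.get("mode", "total"))
            normalized, tf = tmm_normalize(filtered)
            cohorts_expr[name] = normalized
            tf.factors.to_csv(outdir / f"tmm_factors_{name}.tsv", sep="\t")
            report["stages"].setdefault("preprocess", {})[name] = {
                "genes_before": m.n_genes, "genes_after": filtered.n_genes,
                "reference_sample": tf.reference_sample,
            }
        discovery = cohorts_expr["discovery"]
        done()

    de_cfg = cfg.get("de", {})
    if de_cfg.get("enabled", True):
        done = timed("de")
        groups = de_mod.assign_groups(discovery, de_cfg.get("anchor", "ZFP36"),
                                      de_cfg.get("rule", "quartile_low_vs_rest"))
        perm = de_mod.PermutationConfig(B=int(de_cfg.get("B", 10_000)),
                                        seed=seed)
        stats = de_mod.integrated_de(discovery, groups, perm,
                                     null_mode=de_cfg.get("null_mode", "pooled"),
                                     lam=de_cfg.get("storey_lambda", 0.5))
        criteria = de_mod.DegCriteria(q_max=de_cfg.get("q_max", 0.05),
                                      lmr_min=de_cfg.get("lmr_min", 0.58))
        signature = de_mod.call_degs(stats, criteria, name="loss_signature")
        stats.rename_axis("gene_id").to_csv(outdir / "de_stats.tsv", sep="\t")
        signature_to_gmt(signature, outdir / "signature.gmt")
        write_rnk(gsea_mod.rank_genes(stats["lmr"]), outdir / "ranked.rnk")
        report["stages"]["de"] = {
            "n_low": len(groups.low), "n_high": len(groups.high),
            "B": perm.B, "n_up": len(signature.up_genes),
            "n_down": len(signature.down_genes),
        }
        done()
    else:
        raise SiglossError("scoring requires the DE stage (no signature file support "
                           "in run_pipeline; use the `sigloss score` subcommand)")

    done = timed("score_survival")
    score_cfg = cfg.get("score", {})
    surv_cfg = cfg.get("survival", {})
    study_rows = []
    for name, expr in cohorts_expr.items():
        scores = scoring.score_activation(expr, signature,
                                          aggregate=score_cfg.get("aggregate", "mean"))
        labels = scoring.dichotomize(scores, rule=score_cfg.get("rule", "median"))
        scores.assign(group=labels).rename_axis("sample_id").to_csv(
            outdir / f"scores_{name}.tsv", sep="\t")
        clin = cohorts_clin.get(name)
        if clin is None:
            continue
        clin = clin.loc[clin.index.intersection(labels.index)]
        curves = survival.km_fit(clin, labels)
        for g, curve in curves.items():
            curve.as_frame().to_csv(outdir / f"km_{name}_{g}.tsv", sep="\t",
                                    index=False)
        lr = survival.logrank(clin, labels)
        cox = survival.cox_fit_groups(clin, labels, reference="low",
                                      adjust=surv_cfg.get("adjust", []))
        hr = cox.hr("group_high")
        ci = cox.ci("group_high")
        study_rows.append({"study_id": name, "hr": hr, "ci_low": ci[0],
                           "ci_high": ci[1]})
        report["stages"].setdefault("survival", {})[name] = {
            "logrank_chi2": lr.chi2, "logrank_p": lr.p, "hr_high_vs_low": hr,
            "ci": list(ci), "n": cox.n, "n_events": cox.n_events,
        }
    done()

    if study_rows:
        done = timed("meta")
        studies = [meta_mod.StudyEffect(r["study_id"], r["hr"], r["ci_low"],
                                        r["ci_high"]) for r in study_rows]
        pooled = meta_mod.pool(studies)
        model = cfg.get("meta", {}).get("model", "random")
        table = meta_mod.forest_table(studies, pooled, model=model)
        table.to_csv(outdir / "forest.tsv", sep="\t", index=False)
        report["stages"]["meta"] = {
            "model": model, "pooled_hr_fixed": pooled.pooled_hr_fixed,
            "pooled_hr_random": pooled.pooled_hr_random, "Q": pooled.Q,
            "I2": pooled.I2, "tau2": pooled.tau2, "k": len(studies),
        }
        done()

    gsea_cfg = cfg.get("gsea", {})
    if gsea_cfg.get("enabled", True):
        done = timed("gsea")
        ranked = gsea_mod.rank_genes(stats["lmr"])
        if gsea_cfg.get("gmt"):
            sets = read_gmt(gsea_cfg["gmt"])
        elif "discovery" in truths:
            truth = truths["discovery"]
            sets = {"PLANTED_UP": sorted(truth.planted_up),
                    "PLANTED_DOWN": sorted(truth.planted_down)}
        else:
            sets = {}
        if sets:
            coll = gsea_mod.GeneSetCollection(sets,
                                              min_size=gsea_cfg.get("min_size", 15),
                                              max_size=gsea_cfg.get("max_size", 500))
            enr = gsea_mod.es_significance(
                ranked, coll, mode=gsea_cfg.get("mode", "gene_set_perm"),
                n_perm=int(gsea_cfg.get("n_perm", 1000)), seed=seed)
            enr.to_csv(outdir / "enrichment.tsv", sep="\t")
            report["stages"]["gsea"] = {
                "n_sets": len(enr),
                "n_significant_q25": int(enr["significant"].sum()),
            }
        done()

    (outdir / "run_report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
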