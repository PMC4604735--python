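"""End-to-end analysis workflow.

Mirrors the validation-study design: simulate (or read) a Glasgow-like and
a London-like cohort, apply the complete-case exclusion, compute the
severity-score panel, run the univariate battery, build the per-cohort ROC
table with Youden cut points, select logistic models by stepwise AIC,
transport each cohort's model cut point to the other cohort, compare the
two best scores on the combined cohort with the paired DeLong test, and
quantify the effect of the encephalopathy-handling mode on CTP / CTP+L.

All report numbers come from module operations; this layer only arranges
inputs and serializes outputs (CSV/JSON plus a text summary), so a run is a
pure function of (inputs, configuration, seed).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import __version__
from .cohort import Cohort, exclude_incomplete, read_cohort, write_cohort
from .logistic_models import (
    LogisticModelResult,
    stepwise_aic,
    transport_cut_point,
)
from .roc_analysis import (
    clinically_useful,
    delong_paired_test,
    roc_curve,
    youden_cut_point,
)
from .scores import builtin_definitions, compute_panel
from .stats_univariate import (
    default_variable_plan,
    format_p,
    results_to_csv,
    univariate_table,
)
from .synthetic_data import default_configs, simulate_cohort

logger = logging.getLogger("liverscore")

DEFAULT_CANDIDATES = ("lactate", "bilirubin", "pf_ratio", "pt_ratio",
                      "urea", "creatinine", "sodium", "albumin")


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    seed: int = 0
    out_dir: str | Path = "reports"
    cohort_paths: dict[str, str] = dc_field(default_factory=dict)
    encephalopathy_modes: dict[str, str] = dc_field(
        default_factory=lambda: {"glasgow": "observed", "london": "presumed_2"})
    required_fields: tuple[str, ...] = DEFAULT_CANDIDATES
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES


def _cohort_seeds(seed: int, n: int = 2) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2 ** 31)) for s in state]


def load_cohorts(config: RunConfig) -> dict[str, Cohort]:
    """Simulated default cohorts, or cohorts read from configured files."""
    if config.cohort_paths:
        return {label: read_cohort(path, label=label)
                for label, path in config.cohort_paths.items()}
    sim = default_configs()
    seeds = _cohort_seeds(config.seed, len(sim))
    return {label: simulate_cohort(cfg, seed=s)
            for (label, cfg), s in zip(sim.items(), seeds)}


def simulate_to_csv(out_dir: str | Path, seed: int) -> list[Path]:
    """Write the default simulated cohorts as CSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    cohorts = load_cohorts(RunConfig(seed=seed))
    for label, cohort in cohorts.items():
        path = out / f"cohort_{label}.csv"
        write_cohort(cohort, path)
        logger.info("wrote %s (%d records)", path, len(cohort))
        paths.append(path)
    return paths


def roc_table(cohort: Cohort, encephalopathy_mode: str) -> list[dict]:
    """Per-score ROC rows: AUC, 95 % CI, Youden cut point, sens/spec."""
    panel = compute_panel(cohort, encephalopathy_mode=encephalopathy_mode)
    labels = [1 if r.icu_outcome == "died" else 0 for r in cohort]
    rows = []
    for score in panel.columns:
        values = [None if np.isnan(v) else float(v) for v in panel[score]]
        roc = roc_curve(values, labels, name=score)
        cut = youden_cut_point(roc)
        rows.append({
            "score": score, "auc": round(roc.auc, 4),
            "ci_low": round(roc.auc_ci95[0], 4),
            "ci_high": round(roc.auc_ci95[1], 4),
            "cut_point": round(cut.cut_point, 4),
            "sensitivity": round(cut.sensitivity, 4),
            "specificity": round(cut.specificity, 4),
            "n_positive": roc.n_positive, "n_negative": roc.n_negative,
            "clinically_useful": clinically_useful(roc.auc),
        })
    rows.sort(key=lambda r: -r["auc"])
    return rows


def _model_report(model: LogisticModelResult) -> dict:
    return {"variables": model.variables,
            "n_used": model.n_used,
            "log_likelihood": round(model.log_likelihood, 6),
            "aic": round(model.aic, 6),
            "terms": [{k: (round(v, 6) if isinstance(v, float) else v)
                       for k, v in row.items()}
                      for row in model.summary_rows()]}


def encephalopathy_mode_comparison(cohort: Cohort) -> dict:
    """AUCs of CTP / CTP+L under each encephalopathy-handling mode, with the
    paired DeLong comparison of the observed vs excluded variants."""
    labels = [1 if r.icu_outcome == "died" else 0 for r in cohort]
    out: dict = {"modes": {}}
    panels = {mode: compute_panel(cohort, definitions={},
                                  encephalopathy_mode=mode)
              for mode in ("observed", "presumed_2", "excluded")}
    for mode, panel in panels.items():
        out["modes"][mode] = {}
        for score in ("CTP", "CTP+L"):
            vals = [None if np.isnan(v) else float(v) for v in panel[score]]
            roc = roc_curve(vals, labels, name=f"{score}[{mode}]")
            out["modes"][mode][score] = {"auc": round(roc.auc, 4)}
    for score in ("CTP", "CTP+L"):
        a = panels["observed"][score].to_numpy()
        b = panels["excluded"][score].to_numpy()
        z, p = delong_paired_test(
            [None if np.isnan(v) else v for v in a],
            [None if np.isnan(v) else v for v in b], labels)
        out[f"{score}_observed_vs_excluded"] = {"z": round(z, 4),
                                                "p": round(p, 4)}
    return out


def run_analysis(config: RunConfig) -> dict:
    """Run every stage and write the report bundle under ``config.out_dir``.

    Any stage failure removes the partially written outputs and re-raises
    with the stage name. Returns a dict of the key results.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    results: dict = {"seed": config.seed, "version": __version__}
    stage = "setup"

    def emit_json(name: str, payload) -> None:
        path = out / name
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(path)

    try:
        stage = "load"
        cohorts = load_cohorts(config)

        stage = "exclusion"
        analysed: dict[str, Cohort] = {}
        exclusions: dict[str, list[str]] = {}
        for label, cohort in cohorts.items():
            kept, dropped = exclude_incomplete(cohort,
                                               list(config.required_fields))
            logger.info("%s: %d records, %d excluded for missing values",
                        label, len(cohort), len(dropped))
            analysed[label] = kept
            exclusions[label] = dropped
        emit_json("exclusions.json",
                  {k: {"n_initial": len(cohorts[k]), "n_retained": len(v),
                       "excluded_ids": exclusions[k]}
                   for k, v in analysed.items()})
        results["exclusions"] = {k: len(v) for k, v in exclusions.items()}

        stage = "univariate"
        for label, cohort in cohorts.items():
            plan = default_variable_plan(
                include_encephalopathy=(
                    config.encephalopathy_modes.get(label) == "observed"))
            table = univariate_table(cohort, plan)
            path = out / f"univariate_{label}.csv"
            results_to_csv(table, path)
            written.append(path)

        stage = "roc"
        roc_rows: dict[str, list[dict]] = {}
        for label, cohort in cohorts.items():
            mode = config.encephalopathy_modes.get(label, "observed")
            rows = roc_table(cohort, mode)
            roc_rows[label] = rows
            path = out / f"roc_{label}.csv"
            with open(path, "w", newline="", encoding="utf-8") as fh:
                writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
                writer.writeheader()
                writer.writerows(rows)
            written.append(path)
        results["roc"] = roc_rows

        stage = "models"
        models: dict[str, LogisticModelResult] = {}
        for label, cohort in analysed.items():
            model = stepwise_aic(cohort, list(config.candidates))
            logger.info("%s stepwise model: %s (AIC %.2f)", label,
                        model.variables or ["intercept only"], model.aic)
            models[label] = model
            emit_json(f"model_{label}.json", _model_report(model))
        results["models"] = {k: m.variables for k, m in models.items()}

        stage = "crossval"
        labels_list = list(analysed)
        crossval = {}
        for src in labels_list:
            for tgt in labels_list:
                if src == tgt:
                    continue
                cv = transport_cut_point(models[src], analysed[src],
                                         analysed[tgt])
                crossval[f"{src}_to_{tgt}"] = {
                    "cut_point": round(cv.cut_point, 6),
                    "table": cv.table,
                    "chi2": None if cv.chi2 is None else round(cv.chi2, 4),
                    "p": None if cv.p_value is None else round(cv.p_value, 4),
                    "phi": None if cv.phi is None else round(cv.phi, 4),
                    "n_used": cv.n_used,
                }
        emit_json("crossval.json", crossval)
        results["crossval"] = crossval

        stage = "combined"
        combined_records = []
        combined_ctpl: list[float | None] = []
        combined_rfh: list[float | None] = []
        rfh_def = {"RFH": builtin_definitions()["RFH"]}
        for label, cohort in cohorts.items():
            mode = config.encephalopathy_modes.get(label, "observed")
            panel = compute_panel(cohort, definitions=rfh_def,
                                  encephalopathy_mode=mode)
            combined_ctpl += [None if np.isnan(v) else float(v)
                              for v in panel["CTP+L"]]
            combined_rfh += [None if np.isnan(v) else float(v)
                             for v in panel["RFH"]]
            combined_records += [1 if r.icu_outcome == "died" else 0
                                 for r in cohort]
        roc_ctpl = roc_curve(combined_ctpl, combined_records, name="CTP+L")
        roc_rfh = roc_curve(combined_rfh, combined_records, name="RFH")
        z, p = delong_paired_test(combined_ctpl, combined_rfh,
                                  combined_records)
        combined = {"n": len(combined_records),
                    "ctp_plus_l_auc": round(roc_ctpl.auc, 4),
                    "rfh_auc": round(roc_rfh.auc, 4),
                    "delong_z": round(z, 4), "delong_p": round(p, 4)}
        emit_json("combined_delong.json", combined)
        results["combined"] = combined

        stage = "encephalopathy"
        glasgow_like = cohorts[labels_list[0]]
        enc = encephalopathy_mode_comparison(glasgow_like)
        emit_json("encephalopathy_modes.json", enc)
        results["encephalopathy"] = enc

        stage = "summary"
        _write_summary(out / "summary.txt", config, cohorts, exclusions,
                       roc_rows, models, crossval, combined, enc)
        written.append(out / "summary.txt")
    except Exception as err:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"analysis stage {stage!r} failed: {err}") from err
    return results


def _write_summary(path: Path, config: RunConfig, cohorts, exclusions,
                   roc_rows, models, crossval, combined, enc) -> None:
    lines = [f"liverscore {__version__} analysis (seed={config.seed})", ""]
    for label, cohort in cohorts.items():
        died = sum(1 for r in cohort if r.icu_outcome == "died")
        lines.append(f"{label}: n={len(cohort)}, ICU mortality "
                     f"{100 * died / len(cohort):.1f} %, "
                     f"{len(exclusions[label])} excluded for missing values")
    lines.append("")
    for label, rows in roc_rows.items():
        lines.append(f"ROC ({label}):")
        for r in rows:
            flag = " *" if r["clinically_useful"] else ""
            lines.append(f"  {r['score']:<10} AUC {r['auc']:.2f} "
                         f"({r['ci_low']:.2f}-{r['ci_high']:.2f}) "
                         f"cut {r['cut_point']:g} sens {r['sensitivity']:.2f} "
                         f"spec {r['specificity']:.2f}{flag}")
        lines.append("")
    for label, model in models.items():
        lines.append(f"stepwise model ({label}): "
                     f"{' + '.join(model.variables) or 'intercept only'} "
                     f"(AIC {model.aic:.1f})")
        for row in model.summary_rows()[1:]:
            lines.append(f"  {row['term']:<12} OR {row['odds_ratio']:.2f} "
                         f"({row['ci_low']:.2f}-{row['ci_high']:.2f}) "
                         f"p {format_p(row['p'])}")
    lines.append("")
    for key, cv in crossval.items():
        lines.append(f"cut-point transport {key}: phi "
                     f"{'NA' if cv['phi'] is None else format(cv['phi'], '.2f')}, "
                     f"p {format_p(cv['p'])}")
    lines.append("")
    lines.append(f"combined cohort (n={combined['n']}): CTP+L AUC "
                 f"{combined['ctp_plus_l_auc']:.2f} vs RFH AUC "
                 f"{combined['rfh_auc']:.2f}, DeLong p "
                 f"{format_p(combined['delong_p'])}")
    lines.append("encephalopathy handling (first cohort): "
                 + ", ".join(
                     f"{s} observed-vs-excluded p {format_p(enc[f'{s}_observed_vs_excluded']['p'])}"
                     for s in ("CTP", "CTP+L")))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
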