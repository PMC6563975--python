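"""End-to-end validation runs: cohort -> proxies -> reference standard ->
availability gate -> multiple imputation -> per-imputation predictions and
ORC -> pooling -> threshold harm/benefit analysis -> report.

The pipeline order is fixed and every random draw descends from one master
seed, so a run is fully reproducible from its :class:`RunConfig`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_io import Cohort, apply_proxy_map, read_cohort
from .decision_analysis import DEFAULT_THRESHOLDS, threshold_report
from .metrics import ORC_CRITERION, PerformanceSummary, orc, round_half_away, rule_class_crosstab
from .missing_data import PooledEstimate, impute_multiple, pool_results
from .model_zoo import (
    ModelSpec,
    builtin_model_names,
    evaluate_logistic_model_frame,
    evaluate_rule_model_frame,
    load_builtin_model,
    load_model_spec,
    predictor_availability,
    _DERIVED_SOURCES,
)
from .reference_standard import (
    DiagnosisMap,
    bacterial_flag,
    classify_cohort,
    default_diagnosis_map,
)
from .schema import DATA_DICTIONARY
from .synthetic_cohort import generate_cohort, preset

log = logging.getLogger("ordival")

#: Default proxy substitutions for predictors that are wholly unrecorded in
#: one of the source databases: retractions stand in for dyspnoea, and the
#: clinician's ill-appearance judgement for the "something is wrong" gestalt.
DEFAULT_PROXY_MAP = {"dyspnoea": "retractions", "something_wrong": "ill_appearance"}


@dataclass
class RunConfig:
    """Everything needed to reproduce one validation run."""

    cohort_path: str | None = None
    profile_name: str | None = None
    profile_n: int | None = None
    effect_size: float = 1.0
    dx_map_path: str | None = None
    model_names: tuple[str, ...] = ()
    model_paths: tuple[str, ...] = ()
    proxy_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PROXY_MAP))
    m_imputations: int = 10
    imputation_method: str = "chained_equations"
    seed: int = 0
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    orc_weighting: str = "unweighted_pairs"
    force_thresholds: bool = False

    def __post_init__(self):
        if (self.cohort_path is None) == (self.profile_name is None):
            raise ValueError("specify exactly one of cohort_path / profile_name")
        for t in self.thresholds:
            if not 0 < t < 1:
                raise ValueError(f"threshold {t} outside (0,1)")


@dataclass
class ModelResult:
    spec: ModelSpec
    availability: float
    included: bool
    exclusion_reason: str = ""
    performance: PerformanceSummary | None = None
    rule_crosstab: dict | None = None
    thresholds: dict[float, dict] | None = None


@dataclass
class ValidationReport:
    config: RunConfig
    cohort_name: str
    n: int
    category_counts: list[int]
    observed_rx: int
    models: list[ModelResult]
    software: dict

    def to_dict(self) -> dict:
        out = {
            "software": self.software,
            "cohort": {
                "name": self.cohort_name,
                "n": self.n,
                "category_counts": self.category_counts,
                "observed_rx": self.observed_rx,
                "observed_rx_pct": int(
                    round_half_away(100.0 * self.observed_rx / self.n)
                ),
            },
            "settings": {
                "m_imputations": self.config.m_imputations,
                "imputation_method": self.config.imputation_method,
                "seed": self.config.seed,
                "orc_weighting": self.config.orc_weighting,
                "thresholds": list(self.config.thresholds),
                "orc_criterion": ORC_CRITERION,
                "proxy_map": self.config.proxy_map,
            },
            "models": {},
        }
        for mr in sorted(self.models, key=lambda r: r.spec.name):
            entry: dict = {
                "label": mr.spec.label,
                "form": mr.spec.form,
                "availability": round(mr.availability, 4),
                "included": mr.included,
            }
            if not mr.included:
                entry["exclusion_reason"] = mr.exclusion_reason
            if mr.performance is not None:
                perf = mr.performance
                entry["orc"] = {
                    "mean": round(perf.orc.mean, 4),
                    "sd": round(perf.orc.sd, 4),
                    "per_imputation": [round(v, 6) for v in perf.orc.per_imputation_values],
                }
                entry["pairwise_auc"] = {
                    f"{i}-{j}": round(v, 4) for (i, j), v in perf.pairwise_auc.items()
                }
                entry["meets_orc_criterion"] = perf.orc.mean >= ORC_CRITERION
                if perf.is_rule_model:
                    entry["note"] = "binary high/low score; ORC is coarse"
            if mr.rule_crosstab is not None:
                entry["category_by_class"] = mr.rule_crosstab
            if mr.thresholds is not None:
                entry["threshold_analysis"] = {
                    f"{t:.2f}": rep for t, rep in mr.thresholds.items()
                }
            out["models"][mr.spec.name] = entry
        return out


def _load_models(config: RunConfig) -> list[ModelSpec]:
    specs = [load_builtin_model(n) for n in (config.model_names or ())]
    specs += [load_model_spec(p) for p in config.model_paths]
    if not specs:
        specs = [load_builtin_model(n) for n in builtin_model_names()]
    return specs


def _imputation_targets(specs: list[ModelSpec], cohort: Cohort) -> list[str]:
    wanted: set[str] = set()
    for spec in specs:
        for var in spec.predictor_variables:
            if var in _DERIVED_SOURCES:
                wanted.update({_DERIVED_SOURCES[var], "age_months"})
            elif var in spec.derivation_constants:
                continue
            else:
                wanted.add(var)
        for term in spec.predictors:
            if term.when is not None:
                wanted.add(term.when[0])
    targets = []
    for var in sorted(wanted):
        kind = DATA_DICTIONARY[var].kind
        if kind not in ("number", "boolean"):
            continue
        col = cohort.data[var]
        if col.notna().any() and col.isna().any():
            targets.append(var)
    return targets


def _effective_spec(spec: ModelSpec, cohort: Cohort) -> ModelSpec:
    """Drop rule predicates whose variable is wholly unobserved.

    A rule model that passes the >50% availability gate is validated on the
    predicates that can actually be assessed in the cohort; a predicate on a
    variable no record carries can never fire and would otherwise block
    evaluation. Logistic models are untouched (their wholly missing
    predictors go through proxies or derivation-constant mean imputation).
    """
    if not spec.is_rule:
        return spec
    import dataclasses

    def observable(var: str) -> bool:
        if var in _DERIVED_SOURCES:
            return bool(cohort.data[_DERIVED_SOURCES[var]].notna().any())
        return bool(cohort.data[var].notna().any())

    kept = tuple(t for t in spec.predictors if observable(t.variable))
    if len(kept) < len(spec.predictors):
        dropped = [t.variable for t in spec.predictors if t not in kept]
        log.info("%s: dropping unobservable predicates %s", spec.name, dropped)
    if not kept:
        raise ValueError(f"model {spec.name!r} has no observable predicates")
    return dataclasses.replace(spec, predictors=kept)


def run_validation(config: RunConfig) -> ValidationReport:
    """Execute the full validation pipeline for one cohort."""
    ss = np.random.SeedSequence(config.seed)
    seed_gen, seed_imp = (
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2)
    )

    if config.profile_name is not None:
        profile = preset(
            config.profile_name, n=config.profile_n, effect_size=config.effect_size
        )
        cohort, _truth = generate_cohort(profile, seed=seed_gen)
    else:
        cohort = read_cohort(config.cohort_path)

    cohort = apply_proxy_map(cohort, config.proxy_map)
    n_proxied = int((cohort.provenance.apply(lambda s: s.str.startswith("proxy:"))).sum().sum())
    log.info("proxy substitutions: %d cells via %s", n_proxied, config.proxy_map)

    dx_map = (
        DiagnosisMap.from_yaml(config.dx_map_path)
        if config.dx_map_path
        else default_diagnosis_map()
    )
    categories, counts = classify_cohort(cohort, dx_map)
    if (counts > 0).sum() < 2:
        raise ValueError("cohort has a single outcome category; ORC undefined")
    bacterial = categories.map(bacterial_flag).to_numpy(dtype=bool)
    rx = cohort.data["antibiotics_prescribed"].fillna(False).to_numpy(dtype=bool)

    specs = _load_models(config)
    results: list[ModelResult] = []
    included_specs: list[ModelSpec] = []
    for spec in specs:
        fraction, include = predictor_availability(spec, cohort)
        if include:
            included_specs.append(spec)
            results.append(ModelResult(spec, fraction, True))
        else:
            reason = (
                f"only {fraction:.0%} of predictors available "
                f"(gate requires strictly more than 50%)"
            )
            log.info("excluding %s: %s", spec.name, reason)
            results.append(ModelResult(spec, fraction, False, exclusion_reason=reason))
    if not included_specs:
        raise ValueError("no model passes the predictor-availability gate")

    targets = _imputation_targets(included_specs, cohort)
    imp = impute_multiple(
        cohort,
        targets,
        m=config.m_imputations,
        seed=seed_imp,
        method=config.imputation_method,
    )

    for mr in results:
        if not mr.included:
            continue
        spec = _effective_spec(mr.spec, cohort)
        orc_values, pairwise_acc = [], {}
        risk_stack = []
        for completed in imp.completed_cohorts:
            if spec.is_rule:
                classes = evaluate_rule_model_frame(spec, completed.data)
                scores = (classes == "high").astype(float).to_numpy()
            else:
                scores = evaluate_logistic_model_frame(spec, completed.data).to_numpy()
            risk_stack.append(scores)
            value, pairwise = orc(scores, categories, weighting=config.orc_weighting)
            orc_values.append(value)
            for key, v in pairwise.items():
                pairwise_acc.setdefault(key, []).append(v)
        pooled = pool_results(orc_values)
        mr.performance = PerformanceSummary(
            model_name=spec.name,
            orc=pooled,
            pairwise_auc={k: float(np.mean(v)) for k, v in pairwise_acc.items()},
            n_per_category=counts,
            is_rule_model=spec.is_rule,
        )
        if spec.is_rule:
            # Average the category-by-class table across imputations.
            tabs = [
                rule_class_crosstab(
                    np.where(s > 0.5, "high", "low"), categories.to_numpy()
                )
                for s in risk_stack
            ]
            mr.rule_crosstab = {
                cat: {
                    cls: round(float(np.mean([t[cat][cls] for t in tabs])), 1)
                    for cls in ("high", "low")
                }
                for cat in range(1, 6)
            }
        qualifies = pooled.mean >= ORC_CRITERION and not spec.is_rule
        if qualifies or (config.force_thresholds and not spec.is_rule):
            mr.thresholds = {}
            for t in config.thresholds:
                per_imp = [
                    threshold_report(spec.name, s, rx, bacterial, thresholds=[t])[0]
                    for s in risk_stack
                ]
                mr.thresholds[t] = {
                    "n_low_risk": pool_results([r.n_low_risk for r in per_imp]).mean,
                    "expected_rx": pool_results([r.expected_rx for r in per_imp]).mean,
                    "undertreated": pool_results([r.undertreated for r in per_imp]).mean,
                    "pct_low_risk": round_half_away(
                        np.mean([r.pct_low_risk for r in per_imp])
                    ),
                    "pct_expected_rx": round_half_away(
                        np.mean([r.pct_expected_rx for r in per_imp])
                    ),
                    "pct_undertreated": round_half_away(
                        np.mean([r.pct_undertreated for r in per_imp])
                    ),
                }

    return ValidationReport(
        config=config,
        cohort_name=cohort.name,
        n=len(cohort),
        category_counts=[int(c) for c in counts],
        observed_rx=int(rx.sum()),
        models=results,
        software={"package": "ordival", "version": __version__},
    )


def render_report(report: ValidationReport, out_dir: str | Path, formats=("json",)) -> list[Path]:
    """Write the report in one or more formats; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    d = report.to_dict()
    for fmt in formats:
        if fmt == "json":
            path = out_dir / "validation_report.json"
            path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
        elif fmt == "markdown":
            path = out_dir / "validation_report.md"
            path.write_text(_markdown(d))
        elif fmt == "csv":
            path = out_dir / "model_performance.csv"
            rows = []
            for name, entry in d["models"].items():
                row = {
                    "model": name,
                    "form": entry["form"],
                    "availability": entry["availability"],
                    "included": entry["included"],
                    "orc_mean": entry.get("orc", {}).get("mean"),
                    "orc_sd": entry.get("orc", {}).get("sd"),
                }
                rows.append(row)
            pd.DataFrame(rows).to_csv(path, index=False)
        else:
            raise ValueError(f"unknown report format {fmt!r}")
        written.append(path)
    return written


def _markdown(d: dict) -> str:
    lines = [
        f"# Validation report: {d['cohort']['name']}",
        "",
        f"n = {d['cohort']['n']}, observed antibiotic prescription "
        f"{d['cohort']['observed_rx']} ({d['cohort']['observed_rx_pct']}%)",
        "",
        "category counts (bacterial -> viral): "
        + ", ".join(str(c) for c in d["cohort"]["category_counts"]),
        "",
        "| model | form | availability | ORC mean | ORC sd |",
        "|---|---|---|---|---|",
    ]
    for name, e in d["models"].items():
        o = e.get("orc", {})
        lines.append(
            f"| {name} | {e['form']} | {e['availability']:.2f} | "
            f"{o.get('mean', '—')} | {o.get('sd', '—')} |"
        )
    for name, e in d["models"].items():
        if "threshold_analysis" not in e:
            continue
        lines += ["", f"## Threshold analysis: {name}", ""]
        lines.append("| threshold | low risk (%) | expected rx (%) | under-treated (%) |")
        lines.append("|---|---|---|---|")
        for t, rep in e["threshold_analysis"].items():
            lines.append(
                f"| {t} | {rep['n_low_risk']:.1f} ({rep['pct_low_risk']:.0f}%) "
                f"| {rep['expected_rx']:.1f} ({rep['pct_expected_rx']:.0f}%) "
                f"| {rep['undertreated']:.1f} ({rep['pct_undertreated']:.0f}%) |"
            )
    return "\n".join(lines) + "\n"
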