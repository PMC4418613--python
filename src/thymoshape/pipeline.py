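"""The three-model discrimination analysis, end to end.

Given a cohort table, the analysis (i) screens every candidate covariate
univariately, (ii) builds three backward-stepwise logistic models —
clinical + CT features alone, shape features alone, and their combination
— from the covariates passing the screen, (iii) checks collinearity of
each final model by VIF, (iv) scores every subject by leave-one-out
cross-validation, and (v) compares the models' LOOCV ROC curves pairwise
with the DeLong test.  The three-model structure is the default but the
variable lists are fully configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation, stats

__all__ = ["AnalysisConfig", "run_analysis", "report_to_markdown",
           "phantom_study_cohort"]

CLINICAL_CT_VARIABLES = ["age", "symptoms", "myasthenia", "cystic_change",
                         "calcification", "diameter"]
SHAPE_VARIABLES = ["log_volume", "surface_area_cm2", "sphericity",
                   "discrete_compactness", "roundness"]


@dataclass
class AnalysisConfig:
    """Thresholds and variable lists of the discrimination analysis.

    Defaults follow the study protocol: covariates enter a model's
    candidate set when their univariate p < 0.1; stepwise removal drops a
    variable when its LRT p > 0.10 and re-enters one at p < 0.05; VIF
    above 10 flags collinearity.
    """

    model_variables: dict = field(default_factory=lambda: {
        "clinical_ct": list(CLINICAL_CT_VARIABLES),
        "shape": list(SHAPE_VARIABLES),
        "combined": list(CLINICAL_CT_VARIABLES) + list(SHAPE_VARIABLES),
    })
    screen_threshold: float = 0.10
    p_enter: float = 0.05
    p_remove: float = 0.10
    vif_limit: float = 10.0
    selection_in_fold: bool = False
    seed: int = 0

    def __post_init__(self):
        for thr in (self.screen_threshold, self.p_enter, self.p_remove):
            if not (0 < thr < 1):
                raise ValueError(f"threshold {thr} outside (0, 1)")
        for name, cols in self.model_variables.items():
            if not cols:
                raise ValueError(f"model '{name}' has no variables")


def run_analysis(cohort: pd.DataFrame,
                 config: AnalysisConfig | None = None) -> dict:
    """Run screen -> stepwise models -> VIF -> LOOCV -> ROC -> DeLong.

    Returns a report dict with keys ``screen`` (DataFrame), ``models``
    (per-model dict: candidates, selected variables, odds-ratio table,
    VIF, LOOCV AUC with CI), and ``comparisons`` (pairwise DeLong).  A
    model whose screen leaves no candidates is reported intercept-only.
    """
    config = config or AnalysisConfig()
    all_vars = sorted({v for cols in config.model_variables.values()
                       for v in cols})
    missing = [v for v in all_vars if v not in cohort.columns]
    if missing:
        raise KeyError(f"cohort lacks configured variables: {missing}")

    screen = stats.univariate_screen(cohort, all_vars)
    passed = set(screen.loc[screen["p"] < config.screen_threshold,
                            "variable"])

    y = cohort["label"].to_numpy(int)
    models: dict[str, dict] = {}
    probs: dict[str, np.ndarray] = {}
    for name, cols in config.model_variables.items():
        candidates = [v for v in cols if v in passed]
        entry: dict = {"candidates": candidates}
        if not candidates:
            entry.update(selected=[], intercept_only=True,
                         warning="no covariate passed the univariate screen")
            probs[name] = np.full(len(y), y.mean())
            models[name] = entry
            continue
        sw = stats.backward_stepwise(
            cohort[candidates], y, p_enter=config.p_enter,
            p_remove=config.p_remove, on_separation="keep")
        entry["selected"] = sw.selected
        entry["intercept_only"] = sw.intercept_only
        entry["trace"] = sw.trace
        entry["or_table"] = sw.fit.summary_table()
        entry["separated"] = sw.fit.separated
        if len(sw.selected) >= 2:
            entry["vif"] = stats.vif(cohort[sw.selected])
            entry["vif_ok"] = bool((entry["vif"] < config.vif_limit).all())
        if sw.selected:
            probs[name] = evaluation.loocv_probabilities(
                cohort, sw.selected,
                selection_in_fold=config.selection_in_fold,
                p_enter=config.p_enter, p_remove=config.p_remove)
        else:
            probs[name] = np.full(len(y), y.mean())
        models[name] = entry

    for name in models:
        roc = evaluation.roc_auc(probs[name], y)
        models[name]["roc"] = roc
        models[name]["auc"] = roc.auc
        models[name]["auc_ci"] = (roc.ci_low, roc.ci_high)

    comparisons = {}
    names = list(models)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            comparisons[f"{a}_vs_{b}"] = evaluation.delong_ci_and_compare(
                probs[a], probs[b], y)

    return {"screen": screen, "models": models, "comparisons": comparisons,
            "config": config, "n": len(y),
            "class_counts": (int((y == 0).sum()), int((y == 1).sum()))}


def phantom_study_cohort(n_enc: int = 12, n_inv: int = 12,
                         lobulation_gap: float = 0.6,
                         seed: int = 0,
                         feature_config=None) -> pd.DataFrame:
    """A full cohort table whose shape features come from digital phantoms.

    Encapsulated subjects get low-lobulation phantoms, invasive ones
    high-lobulation (gap = ``lobulation_gap``); shape features are
    extracted from the masks with the standard pipeline, while the
    clinical covariates are drawn from the published class rates.  This
    ties every stage together: geometry drives the shape columns, so a
    model given those columns should beat the clinical covariates alone.
    """
    from .features import FeatureConfig, extract_features
    from .synthetic import (DEFAULT_COHORT_SPEC, _rng,
                            simulate_phantom_cohort)

    masks, labels = simulate_phantom_cohort(
        n_enc=n_enc, n_inv=n_inv, lobulation_gap=lobulation_gap, seed=seed)
    fc = feature_config or FeatureConfig()
    feats = [extract_features(m, fc) for m in masks]
    rng = _rng(seed, 30)
    params = {0: DEFAULT_COHORT_SPEC.encapsulated,
              1: DEFAULT_COHORT_SPEC.invasive}
    rows = []
    for i, (label, f) in enumerate(zip(labels, feats)):
        p = params[label]
        rows.append({
            "subject_id": f"P{i:03d}", "label": int(label),
            "age": float(rng.normal(*p.age)),
            "symptoms": int(rng.random() < p.p_symptoms),
            "myasthenia": int(rng.random() < p.p_myasthenia),
            "cystic_change": int(rng.random() < p.p_cystic),
            "calcification": int(rng.random() < p.p_calcification),
            "diameter": float(max(rng.normal(*p.diameter), 0.5)),
            **f.as_row(),
        })
    return pd.DataFrame(rows)


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def report_to_markdown(report: dict) -> str:
    """Render the analysis report as a human-readable markdown summary."""
    lines = ["# Discrimination analysis report", ""]
    n0, n1 = report["class_counts"]
    lines += [f"Subjects: {report['n']} (encapsulated {n0}, invasive {n1})",
              ""]
    lines += ["## Univariate screen", ""]
    scr = report["screen"]
    lines += ["| Variable | Encapsulated | Invasive | Test | P |",
              "|---|---|---|---|---|"]
    for _, r in scr.iterrows():
        lines.append(f"| {r.variable} | {r.encapsulated} | {r.invasive} "
                     f"| {r.test} | {_fmt_p(r.p)} |")
    lines.append("")
    for name, m in report["models"].items():
        lines += [f"## Model: {name}", "",
                  f"Candidates: {', '.join(m['candidates']) or 'none'}  "]
        if m.get("intercept_only"):
            lines += ["Intercept-only model "
                      f"({m.get('warning', 'no variable retained')})", ""]
        else:
            lines += [f"Selected: {', '.join(m['selected'])}", "",
                      "| Variable | Adjusted OR | 95% CI | P |",
                      "|---|---|---|---|"]
            tab = m["or_table"]
            for var in m["selected"]:
                r = tab.loc[var]
                lines.append(
                    f"| {var} | {r.odds_ratio:.3f} "
                    f"| {r.ci_low:.3f}–{r.ci_high:.3f} | {_fmt_p(r.p)} |")
            lines.append("")
        if "vif" in m:
            worst = m["vif"].max()
            lines += [f"Max VIF: {worst:.2f} "
                      f"({'ok' if m['vif_ok'] else 'collinearity!'})", ""]
        if "auc" in m:
            lo, hi = m["auc_ci"]
            lines += [f"LOOCV AUC: {m['auc']:.3f} "
                      f"(95% CI {lo:.3f}–{hi:.3f})", ""]
    lines += ["## Model comparisons (DeLong)", "",
              "| Pair | ΔAUC | 95% CI | P |", "|---|---|---|---|"]
    for pair, c in report["comparisons"].items():
        lines.append(f"| {pair} | {c.delta:+.3f} "
                     f"| {c.delta_ci_low:.3f}–{c.delta_ci_high:.3f} "
                     f"| {_fmt_p(c.p)} |")
    lines.append("")
    return "\n".join(lines)


def report_to_json(report: dict) -> str:
    """Serialize the report (numeric content only) to JSON."""
    out = {
        "n": report["n"],
        "class_counts": report["class_counts"],
        "screen": report["screen"].to_dict(orient="records"),
        "models": {},
        "comparisons": {},
    }
    for name, m in report["models"].items():
        entry = {k: m[k] for k in ("candidates", "selected",
                                   "intercept_only") if k in m}
        if "or_table" in m:
            entry["or_table"] = m["or_table"].reset_index(
                names="variable").to_dict(orient="records")
        if "vif" in m:
            entry["vif"] = {k: (None if not np.isfinite(v) else float(v))
                            for k, v in m["vif"].items()}
        if "auc" in m:
            entry["auc"] = m["auc"]
            entry["auc_ci"] = list(m["auc_ci"])
        out["models"][name] = entry
    for pair, c in report["comparisons"].items():
        out["comparisons"][pair] = {
            "auc_a": c.auc_a, "auc_b": c.auc_b, "delta": c.delta,
            "z": c.z, "p": c.p,
            "delta_ci": [c.delta_ci_low, c.delta_ci_high]}
    return json.dumps(out, indent=2, default=float)
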