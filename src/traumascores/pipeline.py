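"""End-to-end orchestration: simulate/read -> screen -> score -> evaluate.

One :class:`RunConfig` drives the full analysis: cohort acquisition
(synthetic or CSV), eligibility screening, score-panel computation, group
summaries, AUROC/AUPRC with bootstrap CIs, all-pairs DeLong comparisons,
Youden and sensitivity-floor cutoffs, and the 6x3 model-comparison grid.
A single top-level seed deterministically derives per-stage sub-seeds so
stages can be rerun in isolation and the whole run is byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import cohort as cohort_io
from . import discrimination as disc
from . import riskmodels
from . import thresholds as thr
from .scores import ORIENTATION, SCORE_NAMES, score_panel
from .simulate import GeneratorConfig, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "report_tables", "score_cohort",
           "derive_subseeds"]

log = logging.getLogger("traumascores")


@dataclass
class RunConfig:
    """Parameters of one full evaluation run."""

    n_patients: int = 20_000          # used when simulating
    patients_path: Optional[str] = None
    injuries_path: Optional[str] = None
    outcome: str = "death7"           # primary; death30 is the secondary
    n_boot: int = 2000
    folds: int = 5
    alpha_fw: float = 0.05
    se_floor: float = 0.95
    out_dir: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def validate(self) -> None:
        if self.outcome not in ("death7", "death30"):
            raise ValueError(f"outcome must be death7/death30, got {self.outcome!r}")
        if not 0.0 < self.alpha_fw < 1.0:
            raise ValueError("alpha_fw must be in (0,1)")
        if not 0.0 < self.se_floor <= 1.0:
            raise ValueError("se_floor must be in (0,1]")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def derive_subseeds(seed: int) -> dict:
    """Stage sub-seeds derived deterministically from the top-level seed."""
    state = np.random.SeedSequence(seed).generate_state(3)
    return {
        "generator": int(state[0] % (2**31)),
        "bootstrap": int(state[1] % (2**31)),
        "cv": int(state[2] % (2**31)),
    }


def score_cohort(cohort: cohort_io.CohortTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every (eligible) patient.

    Returns (scores, risks): raw score values and oriented larger-is-worse
    risks, one row per patient, indexed by patient_id.
    """
    rows = []
    for p in cohort:
        panel = score_panel(p)
        rows.append({"patient_id": p.patient_id, **panel.as_dict()})
    scores = pd.DataFrame(rows).set_index("patient_id")
    risks = scores.copy()
    for name in SCORE_NAMES:
        if ORIENTATION[name] == "lower_worse":
            risks[name] = -risks[name]
    return scores, risks


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole analysis; returns the metric bundle as a plain dict.

    When ``config.out_dir`` is set the bundle is also written as
    ``metrics.json`` plus one CSV per report table.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    seeds = derive_subseeds(config.seed)

    # --- acquire ---------------------------------------------------------
    if config.patients_path is not None:
        cohort = cohort_io.read_cohort(config.patients_path, config.injuries_path)
        log.info("stage=read n_in=%d", len(cohort))
    else:
        gen = GeneratorConfig(**{**config.generator.__dict__,
                                 "n_patients": config.n_patients,
                                 "seed": seeds["generator"]})
        cohort = generate_cohort(gen)
        log.info("stage=simulate n_out=%d seed=%d", len(cohort), seeds["generator"])

    # --- screen ----------------------------------------------------------
    eligible, elig_report = cohort_io.apply_eligibility(cohort)
    log.info("stage=eligibility n_in=%d n_out=%d excluded_mechanism=%d "
             "excluded_missing=%d", elig_report.n_input, elig_report.n_eligible,
             elig_report.n_excluded_mechanism, elig_report.n_excluded_missing)

    # --- score -----------------------------------------------------------
    scores, risks = score_cohort(eligible)
    labels = np.array([getattr(p, config.outcome) for p in eligible], dtype=int)
    prevalence = float(labels.mean())
    log.info("stage=score n=%d outcome=%s prevalence=%.4f",
             len(eligible), config.outcome, prevalence)

    # --- summaries -------------------------------------------------------
    cohort_summary = cohort_io.summarize_groups(eligible, outcome=config.outcome)
    score_summary = cohort_io.summarize_groups(
        eligible, outcome=config.outcome, scores=scores)
    score_summary = score_summary[score_summary["variable"].isin(SCORE_NAMES)]

    # --- discrimination --------------------------------------------------
    degenerate = [c for c in risks.columns if risks[c].nunique() <= 1]
    active = [c for c in risks.columns if c not in degenerate]
    results = disc.evaluate_scores(risks[active], labels, n_boot=config.n_boot,
                                   seed=seeds["bootstrap"])
    pairwise = disc.delong_test_all_pairs(
        risks[active].to_numpy(), labels, names=active, alpha_fw=config.alpha_fw)
    log.info("stage=discrimination scores=%d pairs=%d", len(active), len(pairwise))

    # --- cutoffs ---------------------------------------------------------
    threshold_reports = []
    for name in active:
        r = risks[name].to_numpy(dtype=float)
        threshold_reports.append(
            thr.youden_cutoff(r, labels, score=name, orientation=ORIENTATION[name]))
        threshold_reports.append(
            thr.se_floor_cutoff(r, labels, floor=config.se_floor, score=name,
                                orientation=ORIENTATION[name]))
    log.info("stage=thresholds reports=%d", len(threshold_reports))

    # --- risk models -----------------------------------------------------
    comparison = riskmodels.compare_models(risks[active], labels,
                                           k=config.folds, seed=seeds["cv"])
    log.info("stage=riskmodels grid=%d", len(comparison.losses))

    bundle = {
        "config": {
            "outcome": config.outcome, "n_boot": config.n_boot,
            "folds": config.folds, "alpha_fw": config.alpha_fw,
            "se_floor": config.se_floor, "seed": config.seed,
            "subseeds": seeds,
        },
        "eligibility": elig_report.as_dict(),
        "prevalence": prevalence,
        "degenerate_scores": degenerate,
        "discrimination": [{
            "score": r.name, "auroc": r.auroc, "auprc": r.auprc,
            "ci_auroc": list(r.ci_auroc), "ci_auprc": list(r.ci_auprc),
            "n_boot": r.n_boot, "prevalence": r.prevalence,
        } for r in results],
        "pairwise": [{
            "score_a": c.score_a, "score_b": c.score_b,
            "auc_a": c.auc_a, "auc_b": c.auc_b, "auc_diff": c.auc_diff,
            "z": c.z, "p": c.p, "significant": c.significant,
            "alpha": c.alpha, "degenerate": c.degenerate,
        } for c in pairwise],
        "thresholds": [{
            "score": t.score, "rule": t.rule, "cutoff": t.cutoff,
            "native_cutoff": t.native_cutoff, "native_label": t.native_label(),
            "se": t.se, "sp": t.sp, "ppv": t.ppv, "npv": t.npv,
            "accuracy": t.accuracy, "npv_defined": t.npv_defined,
            "youden_j": t.youden_j,
        } for t in threshold_reports],
        "model_comparison": {
            "losses": {f"{s}:{f}": v for (s, f), v in comparison.losses.items()},
            "best_family": comparison.best_family,
            "folds": comparison.folds,
        },
        "cohort_summary": cohort_summary.to_dict(orient="records"),
        "score_summary": score_summary.to_dict(orient="records"),
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "metrics.json").write_text(
            json.dumps(bundle, indent=2, sort_keys=True, allow_nan=True))
        report_tables(bundle, out)
        log.info("stage=report out_dir=%s", out)
    return bundle


def _fmt(x, nd=1):
    return "" if x is None else f"{x:.{nd}f}"


def report_tables(bundle: dict, out_dir) -> None:
    """Write the human-readable CSV tables from a metric bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(bundle["cohort_summary"]).to_csv(out / "cohort_summary.csv",
                                                  index=False)
    pd.DataFrame(bundle["score_summary"]).to_csv(out / "score_summary.csv",
                                                 index=False)

    ci = {d["score"]: d for d in bundle["discrimination"]}
    rows = []
    for t in bundle["thresholds"]:
        d = ci[t["score"]]
        rows.append({
            "score": t["score"],
            "auroc": f"{d['auroc']:.2f}",
            "auroc_ci": f"({d['ci_auroc'][0]:.2f}-{d['ci_auroc'][1]:.2f})",
            "auprc": f"{d['auprc']:.2f}",
            "auprc_ci": f"({d['ci_auprc'][0]:.2f}-{d['ci_auprc'][1]:.2f})",
            "method": t["rule"],
            "cutoff": t["native_label"],
            "se": _fmt(t["se"]), "sp": _fmt(t["sp"]),
            "ppv": _fmt(t["ppv"]),
            "npv": _fmt(t["npv"]) if t["npv_defined"] else "-",
            "accuracy": _fmt(t["accuracy"]),
        })
    pd.DataFrame(rows).to_csv(out / "discrimination.csv", index=False)

    names = [d["score"] for d in bundle["discrimination"]]
    mat = pd.DataFrame("-", index=names, columns=names)
    for c in bundle["pairwise"]:
        p = "<0.001" if c["p"] < 0.001 else f"{c['p']:.2f}"
        mat.loc[c["score_a"], c["score_b"]] = p
    mat.to_csv(out / "pairwise_delong.csv")

    losses = bundle["model_comparison"]["losses"]
    grid = pd.DataFrame(
        {s: {f: round(losses[f"{s}:{f}"], 4) for f in riskmodels.FAMILIES}
         for s in names})
    grid.index.name = "model"
    grid.to_csv(out / "model_comparison.csv")

    with open(out / "eligibility.json", "w") as fh:
        json.dump(bundle["eligibility"], fh, indent=2, sort_keys=True)
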