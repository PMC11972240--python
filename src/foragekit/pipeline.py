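"""End-to-end analysis: indicators → rates → composites → ROC → combination.

Per analysis stratum (by default condition × age group, pooled across
participants within the stratum):

1. build the stay/leave decision set (every collected target from the
   third onward is a decision; the last pick of a trial is the leave);
2. compute the trial-so-far indicator and RIAIR series;
3. standardize indicators over all trial-so-far instances in the
   stratum, run parallel analysis and PCA on the end-of-trial values,
   and build the weighted and unweighted composites;
4. one ROC curve per predictor with its conventional polarity, plus the
   maximum-likelihood combined curve for each configured pair;
5. emit a results table (predictor × stratum: AUC, CI, optimal
   threshold or compound rule, sensitivity, specificity) with full
   provenance.

Deterministic given the configured seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import composite as cb
from . import roc as rocmod
from .io import Trial, extract_decisions, read_event_log
from .organization import indicator_series
from .rates import riair_series
from .simulate import DesignCell, simulate_session

log = logging.getLogger("foragekit")

#: Direction in which each predictor signals an imminent leave: the
#: composites, best-r and RIAIR drop before leaving; mean ITD, PAO and
#: the intersection rate rise.
DEFAULT_POLARITY = {
    "best_r": "below",
    "mean_itd": "above",
    "pao": "above",
    "intersection_rate": "above",
    "composite_weighted": "below",
    "composite_unweighted": "below",
    "riair": "below",
}

DEFAULT_PREDICTORS = list(DEFAULT_POLARITY)


@dataclass
class AnalysisConfig:
    """Everything needed to rerun an analysis end to end."""

    input_logs: list[str] = field(default_factory=list)
    design: list[DesignCell] = field(default_factory=list)
    strata: list[str] = field(default_factory=lambda: ["condition", "age_group"])
    predictors: list[str] = field(default_factory=lambda: list(DEFAULT_PREDICTORS))
    polarity: dict = field(default_factory=lambda: dict(DEFAULT_POLARITY))
    combination_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [("composite_weighted", "riair")]
    )
    combination_mode: str = "independence"
    min_picks: int = 3
    tsp_method: str = "auto"
    value_mode: str = "items"
    include_travel: bool = False
    pa_reps: int = 500
    seed: int = 0
    out_dir: str | None = None


def build_decision_table(
    trials: list[Trial],
    min_picks: int = 3,
    tsp_method: str = "auto",
    value_mode: str = "items",
    include_travel: bool = False,
) -> pd.DataFrame:
    """Labeled decision records with trial-so-far indicators and RIAIR.

    One row per collected target from the ``min_picks``-th onward; the
    indicator columns hold the values computed on the first n picks only,
    and ``riair`` the intake-rate ratio at that pick.  Degenerate
    indicator evaluations become NaN with ``degenerate`` set, not errors.
    """
    rows = []
    for trial in trials:
        decisions = extract_decisions(trial, min_picks=min_picks)
        if not decisions:
            continue
        series = indicator_series(trial, method=tsp_method)
        by_n = {s.n: s for s in series}
        rates = {
            r.n: r
            for r in riair_series(
                trial, value_mode=value_mode, include_travel=include_travel
            )
        }
        for dec in decisions:
            ind = by_n[dec.n]
            rows.append(
                {
                    "participant_id": dec.participant_id,
                    "condition": dec.condition,
                    "age_group": dec.age_group,
                    "trial_id": dec.trial_id,
                    "n": dec.n,
                    "label": dec.label,
                    "t": dec.t,
                    "best_r": ind.best_r,
                    "mean_itd": ind.mean_itd,
                    "pao": ind.pao,
                    "intersection_rate": ind.intersection_rate,
                    "riair": rates[dec.n].riair,
                    "degenerate": ind.degenerate,
                    "depleted": dec.depleted,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class StratumResult:
    stratum: str
    table: pd.DataFrame  # Table-2-shaped rows
    curves: dict
    pca: cb.PcaResult
    stats: cb.StandardizationStats
    weights: cb.CompositeWeights
    decisions: pd.DataFrame


def analyze_stratum(
    decisions: pd.DataFrame,
    stratum: str,
    config: AnalysisConfig,
) -> StratumResult | None:
    """Full analysis of one stratum's pooled decision set; returns None
    (with a logged reason) when the stratum cannot support a ROC."""
    labels = decisions["label"]
    if labels.nunique() < 2:
        log.warning("stratum %s skipped: single decision class", stratum)
        return None
    clean = decisions[~decisions["degenerate"]]
    try:
        stats = cb.StandardizationStats.fit(clean, stratum=stratum)
    except ValueError as err:
        log.warning("stratum %s skipped: %s", stratum, err)
        return None
    z = cb.standardize(decisions, stats)
    end_of_trial = clean[clean["label"] == "leave"]
    pca = cb.parallel_analysis(end_of_trial, reps=config.pa_reps, seed=config.seed)
    weights = cb.CompositeWeights.from_pca(pca)
    z = cb.add_composites(z, weights)

    rows, curves = [], {}
    for pred in config.predictors:
        sub = z.dropna(subset=[pred])
        if sub["label"].nunique() < 2:
            log.warning("stratum %s: predictor %s skipped (one class)", stratum, pred)
            continue
        pol = config.polarity.get(pred, "auto")
        curve = rocmod.roc_curve(sub[pred], sub["label"], polarity=pol, predictor=pred)
        signed = -sub[pred] if curve.polarity == "below" else sub[pred]
        _, ci = rocmod.delong_ci(signed, sub["label"])
        curve.ci, curve.ci_method = ci, "delong"
        best = rocmod.youden_optimal(curve)
        curves[pred] = curve
        rows.append(
            {
                "stratum": stratum,
                "predictor": pred,
                "auc": curve.auc,
                "ci_low": ci[0],
                "ci_high": ci[1],
                "rule": f"{pred} {'<' if curve.polarity == 'below' else '>'} "
                f"{best.point.threshold:.4g}",
                "threshold": best.point.threshold,
                "sensitivity": best.point.sensitivity,
                "specificity": best.point.specificity,
                "n_leave": curve.n_leave,
                "n_stay": curve.n_stay,
            }
        )

    for name_a, name_b in config.combination_pairs:
        if name_a not in curves or name_b not in curves:
            continue
        sub = z.dropna(subset=[name_a, name_b])
        curve_a = rocmod.roc_curve(
            sub[name_a], sub["label"], config.polarity.get(name_a, "auto"), name_a
        )
        curve_b = rocmod.roc_curve(
            sub[name_b], sub["label"], config.polarity.get(name_b, "auto"), name_b
        )
        combined = rocmod.combine_roc_ml(
            curve_a,
            curve_b,
            mode=config.combination_mode,
            values_a=sub[name_a],
            values_b=sub[name_b],
            labels=sub["label"],
        )
        best = rocmod.youden_optimal_rule(combined)
        curves[combined.predictor] = combined
        rows.append(
            {
                "stratum": stratum,
                "predictor": f"combined {name_a}+{name_b}",
                "auc": combined.auc,
                "ci_low": combined.ci[0],
                "ci_high": combined.ci[1],
                "rule": str(best.rule) if best.rule else "",
                "threshold": float("nan"),
                "sensitivity": best.point.sensitivity,
                "specificity": best.point.specificity,
                "n_leave": combined.n_leave,
                "n_stay": combined.n_stay,
            }
        )

    return StratumResult(
        stratum=stratum,
        table=pd.DataFrame(rows),
        curves=curves,
        pca=pca,
        stats=stats,
        weights=weights,
        decisions=z,
    )


@dataclass
class PipelineResult:
    results: pd.DataFrame
    strata: dict[str, StratumResult]
    provenance: dict


def run_pipeline(config: AnalysisConfig) -> PipelineResult:
    """Run the full analysis from event logs and/or a simulation design."""
    trials: list[Trial] = []
    for path in config.input_logs:
        trials.extend(read_event_log(path))
    if config.design:
        session = simulate_session(config.design, seed=config.seed)
        trials.extend(session.trials)
    if not trials:
        raise ValueError("no input: provide input_logs or a simulation design")

    decisions = build_decision_table(
        trials,
        min_picks=config.min_picks,
        tsp_method=config.tsp_method,
        value_mode=config.value_mode,
        include_travel=config.include_travel,
    )
    if decisions.empty:
        raise ValueError(
            "no decisions: every trial has fewer than min_picks targets"
        )

    strata_results: dict[str, StratumResult] = {}
    tables = []
    keys = config.strata
    if keys:
        present = {
            tuple(str(getattr(t, k)) for k in keys) for t in trials
        }
        with_decisions = {
            tuple(map(str, row))
            for row in decisions[keys].drop_duplicates().itertuples(index=False)
        }
        for missing in sorted(present - with_decisions):
            log.warning(
                "stratum %s skipped: no trial reaches min_picks=%d targets",
                " / ".join(missing),
                config.min_picks,
            )
    grouped = decisions.groupby(keys) if keys else [((), decisions)]
    for key, sub in grouped:
        label = " / ".join(map(str, key if isinstance(key, tuple) else (key,)))
        res = analyze_stratum(sub, label, config)
        if res is not None:
            strata_results[label] = res
            tables.append(res.table)

    results = (
        pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    )
    provenance = {
        "seed": config.seed,
        "n_trials": len(trials),
        "n_decisions": int(len(decisions)),
        "strata": {
            name: {
                "eigenvalues": res.pca.eigenvalues.tolist(),
                "adjusted_eigenvalues": res.pca.adjusted_eigenvalues.tolist(),
                "n_retained": res.pca.n_retained,
                "variance_explained_pct": res.pca.variance_explained_pct,
                "loadings": res.pca.loadings,
                "weights": res.weights.weights,
                "standardization": {
                    "mean": res.stats.mean,
                    "sd": res.stats.sd,
                    "n_instances": res.stats.n_instances,
                },
            }
            for name, res in strata_results.items()
        },
        "config": {
            k: v
            for k, v in asdict(config).items()
            if k not in ("design",)
        },
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.csv", index=False)
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, default=float)
        for name, res in strata_results.items():
            safe = name.replace(" / ", "_").replace(" ", "-") or "all"
            dump = pd.DataFrame(
                [
                    {
                        "predictor": pname,
                        "threshold": p.threshold,
                        "sensitivity": p.sensitivity,
                        "specificity": p.specificity,
                    }
                    for pname, curve in res.curves.items()
                    for p in curve.points
                ]
            )
            dump.to_csv(out / f"curves_{safe}.csv", index=False)

    return PipelineResult(results=results, strata=strata_results, provenance=provenance)
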