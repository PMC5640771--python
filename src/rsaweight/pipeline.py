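"""End-to-end study replica: simulate -> predictors -> fit -> evaluate -> compare.

`run_analysis` reproduces the full analysis sequence on synthetic data:
subject judgment RDMs (optionally reconstructed from simulated
multi-arrangement sessions), predictor sets for every model in the
roster (conceptual feature/category models, layered activation sources,
and a combined category+late-layer model), cross-validated non-negative
reweighting of each, tau-a evaluation per subject with a noise ceiling,
and Wilcoxon/FDR inference over models — writing a report bundle whose
manifest suffices to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import EvaluationResult, evaluate_model, noise_ceiling
from .fit import (
    CrossValidationSpec,
    WeightedModelFit,
    audit_fold_log,
    crossval_predict_rdm,
    unfitted_prediction,
)
from .inference import ComparisonMatrix, compare_models_pairwise
from .io import write_rdm_csv
from .multiarrangement import iterative_scale_average, trial_consistency
from .predictors import (
    CATEGORY_GROUPS,
    FEATURE_GROUPS,
    PredictorRDMSet,
    build_predictor_set,
    combine_predictor_sets,
    merge_correlated_dimensions,
)
from .rdm import RDM, average_rdms, percentile_transform, rdm_correlation_matrix
from .synthetic import (
    SyntheticScenario,
    default_scenario,
    generate_conceptual_model,
    generate_layer_activations,
    generate_multiarrangement_session,
    generate_subject_judgments,
    toy_scenario,
)

__all__ = ["AnalysisConfig", "ReportBundle", "run_analysis"]

log = logging.getLogger("rsaweight")


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one full analysis run."""

    scenario: SyntheticScenario = field(default_factory=default_scenario)
    cv: CrossValidationSpec | None = None     # None -> scaled default
    q: float = 0.05
    seed: int = 0
    out_dir: str | Path | None = None
    use_sessions: bool = True                 # reconstruct subject RDMs from trials
    include_layers: bool = True
    include_combined: bool = True
    merge_threshold: float = 0.9
    roster: list[str] | None = None           # None -> full default roster

    @classmethod
    def from_preset(cls, preset: str, seed: int = 0, **kw) -> "AnalysisConfig":
        if preset == "toy":
            scenario = toy_scenario(seed)
        elif preset == "paper-scale":
            scenario = default_scenario(seed)
        else:
            raise ValueError(f"unknown preset {preset!r}")
        return cls(scenario=scenario, seed=seed, **kw)

    def resolved_cv(self, model_index: int) -> CrossValidationSpec:
        """CV spec with a per-model seed derived from the run seed."""
        n = self.scenario.n_images
        base = self.cv or CrossValidationSpec(
            n_heldout_images=max(2, round(n * 8 / 92)))
        seed = int(np.random.SeedSequence([self.seed, 100 + model_index])
                   .generate_state(1)[0] % (2 ** 31))
        return dataclasses.replace(base, seed=seed)


@dataclass
class ReportBundle:
    """In-memory results of a run plus the directory they were written to."""

    config: AnalysisConfig
    target: RDM
    subject_rdms: list[RDM]
    evaluation: pd.DataFrame            # model, variant, subject, tau_a
    summary: pd.DataFrame
    result: EvaluationResult
    comparison: ComparisonMatrix
    model_correlations: pd.DataFrame
    fits: dict[str, WeightedModelFit]
    trial_consistency_r: float | None
    out_dir: Path | None
    manifest: dict


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    log.info("stage %s: start", name)
    try:
        yield
    except Exception as e:
        raise RuntimeError(f"analysis stage {name!r} failed: {e}") from e
    log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)


def _default_roster(conceptual, layers, include_layers, include_combined):
    names = [g for g in FEATURE_GROUPS
             if any(d[1] == g for d in conceptual.dimensions)]
    names.append("all_features")
    names.extend(g for g in CATEGORY_GROUPS
                 if any(d[1] == g for d in conceptual.dimensions))
    names.append("all_categories")
    names.append("features_and_categories")
    if include_layers:
        names.extend(layer.name for layer in layers)
        if include_combined and layers:
            names.append(f"all_categories+{layers[-1].name}")
    return names


def _build_roster_sets(roster, conceptual, layers) -> dict[str, PredictorRDMSet]:
    by_layer = {layer.name: layer for layer in layers}
    sets = {}
    for name in roster:
        if name in FEATURE_GROUPS or name in CATEGORY_GROUPS:
            sets[name] = build_predictor_set(conceptual.subset(name), name=name)
        elif name == "all_features":
            sets[name] = build_predictor_set(conceptual.subset(FEATURE_GROUPS), name=name)
        elif name == "all_categories":
            sets[name] = build_predictor_set(conceptual.subset(CATEGORY_GROUPS), name=name)
        elif name == "features_and_categories":
            sets[name] = build_predictor_set(
                conceptual.subset(FEATURE_GROUPS + CATEGORY_GROUPS), name=name)
        elif name in by_layer:
            sets[name] = build_predictor_set(by_layer[name], name=name)
        elif "+" in name:
            a, b = name.split("+", 1)
            base = sets.get(a) or _build_roster_sets([a], conceptual, layers)[a]
            other = sets.get(b) or _build_roster_sets([b], conceptual, layers)[b]
            sets[name] = combine_predictor_sets(base, other, name=name)
        else:
            raise ValueError(f"roster model {name!r} not resolvable")
    return sets


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """Run the full synthetic-study analysis and write the report bundle."""
    sc = config.scenario

    with _stage("simulate"):
        conceptual = merge_correlated_dimensions(
            generate_conceptual_model(sc), config.merge_threshold)
        layers = generate_layer_activations(sc, conceptual) if config.include_layers else []
        subject_truths, truth, gen_weights = generate_subject_judgments(sc, conceptual)
        consistency = None
        if config.use_sessions:
            subject_rdms = []
            rs = []
            for s, subj_rdm in enumerate(subject_truths):
                sess_seed = int(np.random.SeedSequence([sc.seed, 4, s])
                                .generate_state(1)[0] % (2 ** 31))
                session = generate_multiarrangement_session(
                    subj_rdm, sc.trial_spec, sess_seed, subject_id=f"s{s:02d}")
                rdm, _ = iterative_scale_average(session)
                subject_rdms.append(rdm)
                rs.append(trial_consistency(session))
            consistency = float(np.mean(rs))
        else:
            subject_rdms = subject_truths
        target = average_rdms(subject_rdms, metric_tag="judged_distance")

    with _stage("build-predictors"):
        roster = config.roster or _default_roster(
            conceptual, layers, config.include_layers, config.include_combined)
        sets = _build_roster_sets(roster, conceptual, layers)

    fits: dict[str, WeightedModelFit] = {}
    unfitted: dict[str, RDM] = {}
    with _stage("fit"):
        for k, name in enumerate(roster):
            cv = config.resolved_cv(k)
            fits[name] = crossval_predict_rdm(sets[name], target, cv, model_name=name)
            audit_fold_log(fits[name])
            unfitted[name] = unfitted_prediction(sets[name])
            log.info("fitted %-28s K=%3d folds=%4d lambda~%.3g", name,
                     len(fits[name].column_ids), len(fits[name].fold_log),
                     float(np.median(fits[name].lambda_chosen)))

    with _stage("evaluate"):
        rows = []
        columns = []
        taus = []
        for name in roster:
            for variant, rdm in (("fitted", fits[name].predicted_rdm),
                                 ("unfitted", unfitted[name])):
                t = evaluate_model(rdm, subject_rdms)
                taus.append(t)
                columns.append(f"{name} ({variant})")
                rows.extend({"model": name, "variant": variant,
                             "subject": f"s{s:02d}",
                             "tau_a": float(t[s])} for s in range(len(subject_rdms)))
        tau_matrix = np.column_stack(taus)
        lower, upper = noise_ceiling(subject_rdms)
        result = EvaluationResult(columns, tau_matrix, lower, upper)
        evaluation = pd.DataFrame(rows)

    with _stage("compare"):
        comparison = compare_models_pairwise(tau_matrix, columns, q=config.q)
        summary = pd.DataFrame({
            "model": columns,
            "mean_tau": result.mean_tau,
            "sem": result.sem,
            "p_vs_zero": comparison.per_model_p,
            "significant": comparison.per_model_significant,
        })
        corr = rdm_correlation_matrix([fits[n].predicted_rdm for n in roster])
        model_corr = pd.DataFrame(corr, index=roster, columns=roster)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "q": config.q,
        "scenario": _jsonable(dataclasses.asdict(sc)),
        "cv": _jsonable(dataclasses.asdict(config.resolved_cv(0))),
        "roster": roster,
        "use_sessions": config.use_sessions,
        "merge_threshold": config.merge_threshold,
        "generating_weights": gen_weights,
        "numpy_version": np.__version__,
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()).hexdigest()[:16]

    out_dir = Path(config.out_dir) if config.out_dir else None
    bundle = ReportBundle(config, target, subject_rdms, evaluation, summary, result,
                          comparison, model_corr, fits, consistency, out_dir, manifest)
    if out_dir is not None:
        with _stage("report"):
            _write_bundle(bundle)
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_bundle(bundle: ReportBundle) -> None:
    out = bundle.out_dir
    out.mkdir(parents=True, exist_ok=True)
    bundle.evaluation.to_csv(out / "evaluation.tsv", sep="\t", index=False,
                             float_format="%.10g")
    bundle.summary.to_csv(out / "summary.tsv", sep="\t", index=False,
                          float_format="%.10g")
    with open(out / "ceiling.json", "w") as f:
        json.dump({"lower": bundle.result.ceiling_lower,
                   "upper": bundle.result.ceiling_upper}, f, indent=2)
    cmp_df = pd.DataFrame(bundle.comparison.p_values,
                          index=bundle.comparison.model_names,
                          columns=bundle.comparison.model_names)
    cmp_df.to_csv(out / "comparisons_p.tsv", sep="\t", float_format="%.10g")
    pd.DataFrame(bundle.comparison.significant_at_q,
                 index=bundle.comparison.model_names,
                 columns=bundle.comparison.model_names).to_csv(
        out / "comparisons_significant.tsv", sep="\t")
    with open(out / "comparisons_meta.json", "w") as f:
        json.dump({"q": bundle.comparison.q,
                   "n_pairwise": int(len(bundle.comparison.model_names)
                                     * (len(bundle.comparison.model_names) - 1) / 2),
                   "families": ["pairwise", "model_vs_zero"]}, f, indent=2)
    bundle.model_correlations.to_csv(out / "model_correlations.tsv", sep="\t",
                                     float_format="%.10g")
    weights = {
        name: {
            "weights": dict(zip(fit.column_ids, fit.weights.tolist())),
            "intercept": fit.intercept,
            "lambda_per_fold": fit.lambda_chosen,
            "n_folds": len(fit.fold_log),
            "coverage_min": int(fit.coverage_counts.min()),
            "coverage_max": int(fit.coverage_counts.max()),
            "seed": fit.seed,
        } for name, fit in bundle.fits.items()
    }
    with open(out / "weights.json", "w") as f:
        json.dump(weights, f, indent=2)
    with open(out / "manifest.json", "w") as f:
        json.dump(bundle.manifest, f, indent=2)
    pct = out / "percentile_rdms"
    pct.mkdir(exist_ok=True)
    write_rdm_csv(percentile_transform(bundle.target), pct / "judgments.csv")
    for name, fit in bundle.fits.items():
        safe = name.replace("+", "_plus_")
        write_rdm_csv(percentile_transform(fit.predicted_rdm), pct / f"{safe}.csv")
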