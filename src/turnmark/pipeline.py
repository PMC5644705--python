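"""End-to-end per-attempt analysis and batch orchestration.

`run_attempt` composes the stages in analysis order: data filters, significant
-carer classification, validity checks, sequence statistics, the three nested
rate models with likelihood-ratio tests, turn-taking ratios, the ordering
diagnostic, the IVI randomization test, and the bout-clustering check.  The
result is a JSON-serializable report validated against the schema shipped
with the package.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from . import alternation as alt
from . import carers as cr
from . import ctmc
from .ingest import apply_filters
from .randomization import STATISTICS, randomization_test
from .types import ProvisioningAttempt

__all__ = [
    "PipelineConfig",
    "run_attempt",
    "run_batch",
    "load_report_schema",
    "validate_report",
]

log = logging.getLogger(__name__)

RATE_UNITS = {"hour": 3600.0, "minute": 60.0, "second": 1.0}


@dataclass
class PipelineConfig:
    """Tunable knobs of the full analysis (defaults follow the standard protocol)."""

    apply_data_filters: bool = True
    min_brood_age: float = 10.0
    allow_missing_metadata: bool = True
    threshold_frac: float = 0.2  # significant-carer exclusion fraction
    min_visits: int = 10
    max_carers: int = 6
    rate_unit: str = "hour"
    n_reps: int = 1000  # randomization replicates
    n_perm: int = 999  # permutation p-values (ordering, reciprocity)
    statistics: tuple = STATISTICS
    seed: int | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if isinstance(cfg.statistics, list):
            cfg.statistics = tuple(cfg.statistics)
        return cfg


def _scale(q: np.ndarray, unit: str) -> np.ndarray:
    return q * RATE_UNITS[unit]


def _fit_entry(fit: ctmc.FitResult, unit: str) -> dict:
    entry = {
        "model": fit.model,
        "logLik": fit.logLik,
        "n_params": fit.n_params,
        "rates_per_" + unit: _scale(fit.rates.q, unit).tolist(),
        "flags": fit.flags,
    }
    if fit.lambda_i is not None:
        entry["lambda_i"] = _scale(fit.lambda_i, unit).tolist()
        entry["mu_i"] = _scale(fit.mu_i, unit).tolist()
    if fit.lambda0 is not None:
        entry["lambda0"] = float(_scale(np.array(fit.lambda0), unit))
        entry["mu0"] = float(_scale(np.array(fit.mu0), unit))
    return entry


def _lrt_entry(r: ctmc.LRTResult) -> dict:
    return {
        "general": r.general,
        "constrained": r.constrained,
        "stat": r.stat,
        "df": r.df,
        "p": r.p,
        "flags": r.flags,
    }


def _runs_entry(r: alt.RunsTestResult) -> dict:
    return {
        "R_obs": r.R_obs,
        "E_R": r.E_R,
        "Var_R": r.Var_R,
        "z": r.z,
        "p": r.p,
        "alternative": r.alternative,
        "method": r.method,
        "degenerate": r.degenerate,
    }


def _sanitize(obj):
    """Make report JSON-safe: numpy scalars to python, non-finite to strings."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else repr(v)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def run_attempt(
    attempt: ProvisioningAttempt, config: PipelineConfig | None = None
) -> dict:
    """Full analysis of one breeding attempt; returns the attempt report."""
    cfg = config or PipelineConfig()
    warnings: list[str] = []
    report: dict = {"attempt_id": attempt.attempt_id, "skipped": False, "warnings": warnings}
    # independent seed streams per randomized stage: adding reps to one stage
    # never perturbs the draws of another
    ss = np.random.SeedSequence(cfg.seed)
    seed_ordering, seed_recip, seed_rand = ss.spawn(3)

    if cfg.apply_data_filters:
        attempt = apply_filters(
            attempt,
            min_brood_age=cfg.min_brood_age,
            allow_missing_metadata=cfg.allow_missing_metadata,
        )
        report["filter_report"] = attempt.filter_report
    report["n_visits"] = attempt.n_visits
    report["n_days"] = len(attempt.days)

    counts = attempt.visit_counts()
    if not counts:
        report["skipped"] = True
        report["skip_reason"] = "no visits after filtering"
        return report
    carer_set = cr.classify_significant(
        counts,
        threshold_frac=cfg.threshold_frac,
        attempt_id=attempt.attempt_id,
        carer_classes=attempt.metadata.carer_class,
    )
    cr.rank_helpers(carer_set)
    report["carer_set"] = {
        "c": carer_set.c,
        "carers": [
            {
                "carer_id": e.carer_id,
                "visit_count": e.visit_count,
                "carer_class": e.carer_class,
                "helper_rank": e.helper_rank,
                "terminal": e.terminal,
            }
            for e in carer_set.carers
        ],
        "excluded": [
            {"carer_id": cid, "visit_count": n, "round": r}
            for cid, n, r in carer_set.excluded
        ],
    }

    stats = ctmc.sufficient_stats(attempt, carer_set)
    validity = cr.validate_for_fitting(
        carer_set, min_visits=cfg.min_visits, max_carers=cfg.max_carers,
        transition_counts=stats.n,
    )
    report["validity"] = validity
    warnings.extend(validity["warnings"])
    if not validity["valid"]:
        report["skipped"] = True
        report["skip_reason"] = "; ".join(validity["warnings"]) or "invalid for fitting"
        return _sanitize(report)

    sequences = alt.attempt_sequences(attempt, carer_set)
    prop = alt.proportion_alternated(sequences)
    report["proportion_alternated"] = prop
    concat = np.concatenate([s for s in sequences if len(s)]) if sequences else np.empty(0)
    report["runs_test"] = _runs_entry(
        alt.k_category_runs_test(concat, alternative="more_runs")
    )

    fits = {
        "full": ctmc.fit_full(stats),
        "per_individual": ctmc.fit_per_individual(stats),
        "pooled": ctmc.fit_pooled(stats),
    }
    report["models"] = {name: _fit_entry(f, cfg.rate_unit) for name, f in fits.items()}
    report["lrt"] = [
        _lrt_entry(ctmc.lrt(fits["full"], fits["per_individual"])),
        _lrt_entry(ctmc.lrt(fits["per_individual"], fits["pooled"])),
    ]
    ratio = ctmc.turn_taking_ratio(fits["per_individual"])
    report["turn_taking"] = ratio
    warnings.extend(ratio["flags"])
    report["turn_taking"]["pooled_ratio"] = (
        fits["pooled"].lambda0 / fits["pooled"].mu0 if fits["pooled"].mu0 > 0 else None
    )
    report["wilcoxon_lambda_mu"] = ctmc.wilcoxon_lambda_mu(fits["per_individual"])
    report["reciprocity"] = ctmc.reciprocity_correlation(
        fits["full"].rates, n_perm=cfg.n_perm, seed=seed_recip
    )

    report["ivi_summaries"] = alt.ivi_summaries(attempt, carer_set)

    ordering = alt.ordering_score(
        alt.per_carer_ivis(attempt, carer_set), n_perm=cfg.n_perm, seed=seed_ordering
    )
    report["ordering"] = {
        "carers": ordering.carers,
        "p_scores": ordering.p_scores,
        "mean": ordering.mean,
        "sd": ordering.sd,
        "flags": ordering.flags,
    }
    if ordering.mean is not None and not (0.05 <= ordering.mean <= 0.95):
        warnings.append(
            f"ordering diagnostic mean p-score {ordering.mean:.3f}: "
            "IVIs may be temporally ordered, randomization null may be biased"
        )

    rand = randomization_test(
        attempt, carer_set, n_reps=cfg.n_reps, statistics=cfg.statistics,
        seed=seed_rand,
    )
    report["randomization"] = [r.summary() for r in rand]

    givs = alt.group_ivis(attempt, carer_set, first_day_only=True)
    if givs and len(givs[0]) >= 4:
        report["bout_test"] = _runs_entry(alt.ww_bout_test(givs[0]))
    else:
        report["bout_test"] = None
        warnings.append("too few group IVIs on the first day for the bout test")

    return _sanitize(report)


def run_batch(
    attempts: list[ProvisioningAttempt], config: PipelineConfig | None = None
) -> dict:
    """Analyze many attempts; per-attempt reports plus cross-attempt summary."""
    cfg = config or PipelineConfig()
    reports, failures = [], []
    if not attempts:
        log.warning("run_batch: empty manifest")
    for i, attempt in enumerate(attempts):
        acfg = cfg
        if cfg.seed is not None:
            acfg = PipelineConfig(**{**cfg.__dict__, "seed": cfg.seed + i})
        try:
            reports.append(run_attempt(attempt, acfg))
        except Exception as exc:  # a hard failure must not sink the batch
            log.exception("attempt %s failed", attempt.attempt_id)
            failures.append({"attempt_id": attempt.attempt_id, "error": str(exc)})
    analyzed = [r for r in reports if not r.get("skipped")]
    ratios_by_c: dict[int, list[float]] = {}
    n_passive = n_active = 0
    for r in analyzed:
        g = r["turn_taking"]["group_ratio"]
        if isinstance(g, float):
            ratios_by_c.setdefault(r["carer_set"]["c"], []).append(g)
        for rnd in r.get("randomization", []):
            if rnd["statistic"] == "group_lambda_mu_ratio":
                n_passive += bool(rnd["passive_flag"])
                n_active += rnd["p_active"] <= 0.05
    return {
        "n_attempts": len(attempts),
        "n_analyzed": len(analyzed),
        "n_skipped": len(reports) - len(analyzed),
        "n_failed": len(failures),
        "failures": failures,
        "group_ratio_by_c": {
            str(c): {
                "n": len(v),
                "mean": float(np.mean(v)),
                "median": float(np.median(v)),
            }
            for c, v in sorted(ratios_by_c.items())
        },
        "n_passive_flag": n_passive,
        "n_active_significant": n_active,
        "reports": reports,
    }


# -- report schema ----------------------------------------------------------

def load_report_schema() -> dict:
    with resources.files("turnmark").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "boolean": bool,
    "integer": int,
    "null": type(None),
}


def _check(instance, schema: dict, path: str, errors: list[str]) -> None:
    typ = schema.get("type")
    if typ is not None:
        types = typ if isinstance(typ, list) else [typ]
        ok = False
        for t in types:
            if t == "number":
                ok |= isinstance(instance, (int, float)) and not isinstance(instance, bool)
            elif t == "integer":
                ok |= isinstance(instance, int) and not isinstance(instance, bool)
            else:
                ok |= isinstance(instance, _TYPES[t])
        if not ok:
            errors.append(f"{path}: expected {typ}, got {type(instance).__name__}")
            return
    if isinstance(instance, dict):
        for req in schema.get("required", []):
            if req not in instance:
                errors.append(f"{path}: missing required key {req!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                _check(instance[key], sub, f"{path}.{key}", errors)
    if isinstance(instance, list) and "items" in schema:
        for i, item in enumerate(instance):
            _check(item, schema["items"], f"{path}[{i}]", errors)


def validate_report(report: dict, schema: dict | None = None) -> list[str]:
    """Check a report against the shipped schema (type/required/properties
    /items subset); returns a list of violations, empty when valid."""
    errors: list[str] = []
    _check(report, schema or load_report_schema(), "$", errors)
    return errors
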