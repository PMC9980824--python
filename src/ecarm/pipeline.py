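"""End-to-end orchestration of the six cohort-construction phases.

query -> greedy screening -> empirical baseline-window calibration ->
informatics ascertainment + concordance -> random-forest imputation with a
two-variant sensitivity comparison -> cohort finalisation and endpoints.
Every stage is a pure function of (inputs, config, seed); the manifest
records a config hash and per-artifact content hashes, so identical runs
produce identical manifests.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import ascertainment, endpoints, imputation, screening, synthetic_ehr, temporal
from .bundle import EhrBundle
from .cdai import CdaiThresholds

log = logging.getLogger("ecarm")


@dataclass
class PipelineConfig:
    generator: synthetic_ehr.GeneratorConfig = field(
        default_factory=synthetic_ehr.GeneratorConfig
    )
    bundle_dir: str | None = None  # read an existing bundle instead of generating
    seed: int = 0
    max_lookback_weeks: int = 16
    plateau_tolerance: float = 0.05
    thresholds: CdaiThresholds = field(default_factory=CdaiThresholds)
    variant_a: dict = field(default_factory=lambda: dict(imputation.VARIANT_A))
    variant_b: dict = field(default_factory=lambda: dict(imputation.VARIANT_B))
    run_sensitivity: bool = True
    concordance_fraction: float = 0.25  # share of eligible patients manually reviewed
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = synthetic_ehr.GeneratorConfig(**raw.pop("generator", {}))
        thr = CdaiThresholds(**raw.pop("thresholds", {}))
        return cls(generator=gen, thresholds=thr, **raw)


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory artifacts of a full run (also written to disk when out_dir set)."""

    bundle: EhrBundle
    truth: synthetic_ehr.GroundTruth | None
    attrition: screening.AttritionReport
    eligible: set[str]
    lookback_weeks: int
    windows: dict[str, temporal.WindowSpec]
    concordance: ascertainment.ConcordanceReport | None
    matrix: imputation.CohortMatrix | None
    completed: imputation.CohortMatrix | None
    trace: imputation.ConvergenceTrace | None
    sensitivity: dict | None
    cohort: set[str]
    scores: pd.DataFrame | None
    steroid: pd.DataFrame | None
    summary: endpoints.EndpointSummary | None
    characterization: pd.DataFrame | None
    manifest: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    cfg = config
    ident = cfg.to_dict()
    ident.pop("out_dir", None)  # output location is not part of the run identity
    manifest: dict = {"config_hash": _hash(ident), "seed": cfg.seed,
                      "stages": {}}

    # --- data -------------------------------------------------------------
    if cfg.bundle_dir:
        bundle, truth = EhrBundle.read(cfg.bundle_dir), None
    else:
        gen = dataclasses.replace(cfg.generator, seed=cfg.seed)
        bundle, truth = synthetic_ehr.generate_bundle(gen)

    empty = PipelineResult(
        bundle=bundle, truth=truth,
        attrition=screening.AttritionReport([("candidates", 0)], {}),
        eligible=set(), lookback_weeks=12, windows={}, concordance=None,
        matrix=None, completed=None, trace=None, sensitivity=None, cohort=set(),
        scores=None, steroid=None, summary=None, characterization=None,
        manifest=manifest,
    )
    if not len(bundle.patients):
        manifest["status"] = "empty cohort"
        manifest["stages"]["query"] = {"candidates": 0}
        _write_artifacts(cfg, empty)
        return empty

    # --- phase 1-2: query + greedy screening -------------------------------
    candidates = screening.query_candidates(bundle)
    log.info("query: %d candidates of %d patients", len(candidates), len(bundle.patients))
    eligible, attrition, results = screening.screen_greedy(bundle, candidates)
    manifest["stages"]["query"] = {"candidates": len(candidates)}
    manifest["stages"]["screen"] = {"in": len(candidates), "out": len(eligible)}
    log.info("screen: %d eligible", len(eligible))
    if not eligible:
        manifest["status"] = "empty cohort"
        empty.attrition = attrition
        _write_artifacts(cfg, empty)
        return empty

    # --- phase 3: baseline-window calibration ------------------------------
    curve = temporal.availability_curve(bundle, eligible, cfg.max_lookback_weeks)
    lookback = temporal.select_baseline_window(curve, cfg.plateau_tolerance)
    windows = {
        "baseline": temporal.baseline_window(lookback),
        "week12": temporal.WEEK12_WINDOW,
        "week24": temporal.WEEK24_WINDOW,
    }
    manifest["stages"]["calibrate"] = {"lookback_weeks": lookback}
    log.info("calibrate: baseline lookback = %d weeks", lookback)

    # --- phase 4: concordance on the reviewed subset ------------------------
    reviewed = sorted(eligible)[:: max(int(round(1 / cfg.concordance_fraction)), 1)]
    concordance = None
    if reviewed and len(bundle.abstraction):
        concordance = ascertainment.concordance_report(bundle, reviewed, windows)
        manifest["stages"]["ascertain"] = {"reviewed": len(reviewed)}

    # --- phase 5: matrix + imputation --------------------------------------
    matrix = ascertainment.build_cohort_matrix(bundle, eligible, windows)
    completed, trace = imputation._run_variant(matrix, cfg.variant_a, cfg.seed)
    sensitivity = None
    if cfg.run_sensitivity:
        sensitivity = imputation.sensitivity_compare(
            matrix, cfg.variant_a, cfg.variant_b, cfg.thresholds, base_seed=cfg.seed
        )
    manifest["stages"]["impute"] = {
        "n": len(matrix.values), "iterations": len(trace.deltas),
    }

    # --- phase 6: finalisation + endpoints ----------------------------------
    cohort = imputation.finalize_cohort(eligible, completed, cfg.thresholds)
    log.info("finalize: %d cohort members", len(cohort))
    ids = sorted(cohort)
    summary = characterization = scores = steroid = None
    if ids:
        scores = pd.DataFrame(
            {p: ascertainment.cdai_scores(completed.values.loc[ids], p)
             for p in ("baseline", "week12", "week24")}
        )
        steroid = pd.DataFrame(
            {p: completed.values.loc[ids, f"steroid__{p}"].astype(float) > 0.5
             for p in ("baseline", "week12", "week24")}
        )
        summary = endpoints.summarize_endpoints(scores, steroid, cfg.thresholds)
        characterization = endpoints.characterize_cohort(bundle, cohort, completed.values)
    manifest["stages"]["endpoints"] = {"cohort": len(cohort)}
    manifest["status"] = "ok" if ids else "empty cohort"

    result = PipelineResult(
        bundle=bundle, truth=truth, attrition=attrition, eligible=eligible,
        lookback_weeks=lookback, windows=windows, concordance=concordance,
        matrix=matrix, completed=completed, trace=trace, sensitivity=sensitivity,
        cohort=cohort, scores=scores, steroid=steroid, summary=summary,
        characterization=characterization, manifest=manifest,
    )
    result.manifest["curve"] = _hash(curve.fractions.round(9).to_dict())
    result.manifest["screen_results"] = _hash(
        screening.results_frame(results).to_dict("records")
    )
    _write_artifacts(cfg, result)
    return result


def _write_artifacts(cfg: PipelineConfig, result: PipelineResult) -> None:
    if cfg.out_dir is None:
        return
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "attrition.json").write_text(
        json.dumps(result.attrition.to_dict(), indent=2, sort_keys=True)
    )
    if result.concordance is not None:
        result.concordance.write(out)
    else:
        ascertainment.ConcordanceReport().write(out)
    (out / "sensitivity.json").write_text(
        json.dumps(result.sensitivity or {}, indent=2, sort_keys=True)
    )
    summary = result.summary.to_dict() if result.summary else {"status": "empty cohort"}
    (out / "endpoint_summary.json").write_text(json.dumps(summary, indent=2,
                                                          sort_keys=True))
    traj_rows = []
    if result.scores is not None:
        bio = {}
        if "prior_biologic" in result.bundle.patients.columns:
            bio = result.bundle.patients.set_index("id")["prior_biologic"].to_dict()
        for pid in result.scores.index:
            for period in ("baseline", "week12", "week24"):
                traj_rows.append(
                    {"id": pid, "period": period,
                     "cdai": float(result.scores.loc[pid, period]),
                     "steroid": bool(result.steroid.loc[pid, period]),
                     "prior_biologic": int(bio.get(pid, 0))}
                )
    pd.DataFrame(traj_rows, columns=["id", "period", "cdai", "steroid",
                                     "prior_biologic"]).to_csv(
        out / "trajectories.csv", index=False
    )
    if result.characterization is not None:
        result.characterization.to_csv(out / "characterization.csv", index=False)
    artifacts = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    result.manifest["artifacts"] = {
        name: _file_hash(out / name) for name in artifacts
    }
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2,
                                                  sort_keys=True))
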