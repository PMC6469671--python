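"""End-to-end study orchestration: simulate -> classify -> match ->
ascertain -> compare -> validate, with one config, structured logging and
reproducible seeds.

Every stage writes its artifact under the output directory, and a
``manifest.json`` records the config hash, the per-stage seeds and row
counts, so two runs with identical config and seeds produce identical
manifests (and byte-identical comparison files).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field

from .classify import CohortResult, build_ms_cohort
from .codelist import Codelist, default_codelist
from .matching import MatchedSet, match_cohort
from .outcomes import ascertain_cohort
from .ppv import compute_ppv, sample_for_adjudication
from .records import Bundle, Dialect, age_years_at, format_day
from .synth import GeneratorConfig, GroundTruth, default_configs, generate_population, write_ground_truth
from .tables import build_tables

__all__ = ["RunConfig", "run_full_study", "StageError"]

logger = logging.getLogger("msphen")


class StageError(RuntimeError):
    def __init__(self, stage: str, artifact: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed writing {artifact!r}: {cause}")
        self.stage = stage
        self.artifact = artifact


class RunConfig(BaseModel):
    dialect: str = "dod"  # "dod" | "cprd"
    generator: Optional[GeneratorConfig] = None  # packaged default when None
    n_patients: int = Field(default=50_000, gt=0)
    ratio: int = Field(default=10, ge=1)
    suppress_below: int = Field(default=5, ge=0)
    n_per_tier: int = Field(default=50, ge=1)
    adjudication_error: float = Field(default=0.0, ge=0, le=1)
    simulate_seed: int = 0
    match_seed: int = 0
    validate_seed: int = 0
    out_dir: str = "msphen_run"

    def resolved_generator(self) -> GeneratorConfig:
        if self.generator is not None:
            return self.generator
        key = "dod_like" if self.dialect == "dod" else "cprd_like"
        return default_configs(self.n_patients, seed=self.simulate_seed)[key]

    def resolved_dialect(self) -> Dialect:
        return Dialect.CLAIMS_DOD if self.dialect == "dod" else Dialect.EMR_CPRD


def classifications_frame(cohort: CohortResult) -> pd.DataFrame:
    rows = []
    for cls in cohort.classifications.values():
        rows.append(
            {
                "patient_id": cls.patient_id,
                "tier": cls.tier.value,
                "first_ms_date": format_day(cls.first_ms_date)
                if cls.first_ms_date is not None
                else "",
                "n_ms_dx_dates": cls.n_ms_dx_dates,
                "n_demyelinating_dx_dates": cls.n_demyelinating_dx_dates,
                "n_dmt_rx": cls.n_dmt_rx,
                "excluded": cls.excluded,
                "exclusion_reason": cls.exclusion_reason.value,
                "incident": cls.incident,
            }
        )
    return pd.DataFrame(rows).sort_values("patient_id").reset_index(drop=True)


def matched_sets_frame(matched: list[MatchedSet]) -> pd.DataFrame:
    rows = []
    for s in matched:
        for cid in s.control_ids:
            rows.append(
                {
                    "case_id": s.case_id,
                    "control_id": cid,
                    "index_date": format_day(s.index_date),
                    "set_size": len(s.control_ids),
                }
            )
        if not s.control_ids:
            rows.append(
                {
                    "case_id": s.case_id,
                    "control_id": "",
                    "index_date": format_day(s.index_date),
                    "set_size": 0,
                }
            )
    return pd.DataFrame(rows)


def demographics_frame(
    bundle: Bundle, cohort: CohortResult, matched: list[MatchedSet]
) -> pd.DataFrame:
    """Per-patient arm, sex and age band at the (shared) index date."""
    rows = []

    def band(age: int) -> str:
        if age < 40:
            return "<40"
        if age < 60:
            return "40-59"
        return "60+"

    for m in cohort.members:
        p = bundle[m.patient_id].patient
        rows.append(
            {
                "patient_id": m.patient_id,
                "arm": "ms",
                "sex": p.sex,
                "age_band": band(age_years_at(p.birth_day, m.first_ms_date)),
            }
        )
    for s in matched:
        for cid in s.control_ids:
            p = bundle[cid].patient
            rows.append(
                {
                    "patient_id": cid,
                    "arm": "nonms",
                    "sex": p.sex,
                    "age_band": band(age_years_at(p.birth_day, s.index_date)),
                }
            )
    return pd.DataFrame(rows)


def run_full_study(config: RunConfig, codelist: Optional[Codelist] = None) -> dict:
    """Execute all stages and return the run manifest."""
    codelist = codelist or default_codelist()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": hashlib.sha256(
            config.model_dump_json().encode()
        ).hexdigest(),
        "seeds": {
            "simulate": config.simulate_seed,
            "match": config.match_seed,
            "validate": config.validate_seed,
        },
        "stages": {},
    }

    def _stage(name: str, artifact: str, fn):
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - abort with stage context
            raise StageError(name, str(out / artifact), exc) from exc
        logger.info("stage %s complete", name)
        return result

    gen_cfg = config.resolved_generator()
    dialect = config.resolved_dialect()

    def _simulate():
        from .records import write_bundle

        bundle, truths = generate_population(gen_cfg, dialect)
        write_bundle(bundle, out / "records")
        write_ground_truth(truths, out / "records" / "ground_truth.csv")
        return bundle, truths

    bundle, truths = _stage("simulate", "records", _simulate)
    manifest["stages"]["simulate"] = {"n_patients": len(bundle)}

    def _classify():
        cohort = build_ms_cohort(bundle, codelist)
        classifications_frame(cohort).to_csv(out / "classifications.csv", index=False)
        return cohort

    cohort = _stage("classify", "classifications.csv", _classify)
    manifest["stages"]["classify"] = {
        "cohort_n": len(cohort.members),
        "tiers": {t.value: int(n) for t, n in sorted(cohort.tier_counts.items())},
        "excluded": {
            r.value: int(n) for r, n in sorted(cohort.exclusion_counts.items())
        },
    }

    def _match():
        matched = match_cohort(
            cohort.members,
            bundle,
            cohort.classifications,
            codelist,
            ratio=config.ratio,
            seed=config.match_seed,
        )
        matched_sets_frame(matched).to_csv(out / "matched_sets.csv", index=False)
        return matched

    matched = _stage("match", "matched_sets.csv", _match)
    n_controls = sum(len(s.control_ids) for s in matched)
    manifest["stages"]["match"] = {
        "cases": len(matched),
        "controls": n_controls,
        "fully_matched": sum(
            1 for s in matched if len(s.control_ids) == config.ratio
        ),
    }

    def _ascertain():
        df = ascertain_cohort(bundle, cohort.members, matched, codelist)
        df.to_csv(out / "outcomes.csv", index=False)
        return df

    outcome_df = _stage("ascertain", "outcomes.csv", _ascertain)
    manifest["stages"]["ascertain"] = {"rows": len(outcome_df)}

    def _compare():
        demo = demographics_frame(bundle, cohort, matched)
        tables = build_tables(
            outcome_df, codelist, demo, suppress_below=config.suppress_below
        )
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        return tables

    tables = _stage("compare", "comparisons.csv", _compare)
    manifest["stages"]["compare"] = {"outcomes": len(tables["comparisons"])}

    def _validate():
        truth_map = {t.patient_id: t.true_ms for t in truths}
        samples = sample_for_adjudication(
            cohort.classifications.values(),
            truth_map,
            config.n_per_tier,
            seed=config.validate_seed,
            adjudication_error=config.adjudication_error,
        )
        if not samples:
            return None
        result = compute_ppv(samples)
        rows = [
            {
                "tier": t,
                "n_sampled": result.n_sampled[t],
                "n_true": result.n_true[t],
                "ppv": f"{result.by_tier[t]:.4f}",
                "ci_low": f"{result.ci_by_tier[t][0]:.4f}",
                "ci_high": f"{result.ci_by_tier[t][1]:.4f}",
            }
            for t in sorted(result.by_tier)
        ]
        rows.append(
            {
                "tier": "overall",
                "n_sampled": sum(result.n_sampled.values()),
                "n_true": sum(result.n_true.values()),
                "ppv": f"{result.overall:.4f}",
                "ci_low": "",
                "ci_high": "",
            }
        )
        pd.DataFrame(rows).to_csv(out / "ppv.csv", index=False)
        return result

    ppv_result = _stage("validate", "ppv.csv", _validate)
    manifest["stages"]["validate"] = (
        {"overall_ppv": ppv_result.overall} if ppv_result else {"overall_ppv": None}
    )

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
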