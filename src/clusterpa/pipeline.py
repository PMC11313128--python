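"""End-to-end pipeline: simulate -> filter -> estimate -> design.

A :class:`PipelineConfig` (usually loaded from YAML) names the stages
to run; each stage's outputs are written as CSV/JSON under the run
directory, row counts and filter decisions are logged to standard
error, and the whole run is deterministic for a fixed seed (the global
seed is expanded into per-stage substreams so stages can be rerun in
isolation).  Stage failures abort with a stage-labelled error; outputs
of completed stages are retained.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from importlib.metadata import version as pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import autocorr as ac
from . import icc as icc_mod
from ._errors import ClusterPAError, ConfigurationError
from .design import DesignSpec, required_schools
from .simulate import (
    SimulationConfig,
    filter_valid,
    generate_population,
    read_observations,
    write_observations,
)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("clusterpa")


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run.

    A stage runs when its block is present (an empty mapping means
    "run with defaults").  When the design block supplies its own
    icc / sd_total (and cac / iac for stepped wedge cells), the
    estimation stages may be omitted entirely.
    """

    seed: int = 0
    out_dir: str | Path = "clusterpa_run"
    data_in: str | None = None
    simulation: dict | None = None
    estimation: dict | None = None
    autocorrelation: dict | None = None
    design: dict | None = None
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown pipeline field(s): {sorted(unknown)}")
        return cls(**raw)


def _stage_seed(seed: int, stage: str) -> int:
    """Independent 31-bit substream seed for a named stage."""
    tag = zlib.crc32(stage.encode()) % 2**31
    ss = np.random.SeedSequence([int(seed), tag])
    return int(ss.generate_state(1)[0] % 2**31)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "versions": {"clusterpa": _version()}}
    data = None
    stage = "setup"
    try:
        # ---- data ----------------------------------------------------
        if config.data_in is not None:
            stage = "load"
            data = read_observations(config.data_in)
            log.info("load: %d rows from %s", len(data), config.data_in)
        elif config.simulation is not None:
            stage = "simulate"
            sim_raw = dict(config.simulation)
            sim_raw.setdefault("seed", _stage_seed(config.seed, "simulate"))
            sim = SimulationConfig.from_dict(sim_raw)
            data = generate_population(sim)
            write_observations(data, out / "data.csv")
            log.info("simulate: %d rows -> %s", len(data), out / "data.csv")
            summary["simulate"] = {"n_rows": len(data), "seed": sim.seed}

        needs_data = config.estimation is not None or config.autocorrelation is not None
        if needs_data and data is None:
            raise ConfigurationError(
                "estimation stages need data: give data_in or a simulation block"
            )

        # ---- inclusion filter ---------------------------------------
        if data is not None and needs_data:
            stage = "filter"
            est = config.estimation or {}
            min_days = int(est.get("min_valid_days", 2))
            data, n_removed = filter_valid(data, min_days)
            log.info(
                "filter: removed %d rows with < %d valid days (%d remain)",
                n_removed, min_days, len(data),
            )
            summary["filter"] = {
                "min_valid_days": min_days,
                "n_removed": n_removed,
                "n_remaining": len(data),
            }

        # ---- ICC estimation -----------------------------------------
        est_inputs: dict = {}
        if config.estimation is not None:
            stage = "icc"
            est = config.estimation
            outcome = est.get("outcome", "mvpa_weekday")
            ests = icc_mod.estimate_iccs(
                data,
                outcome=outcome,
                stratify_by_gender=bool(est.get("stratify_by_gender", False)),
            )
            pooled_vc = icc_mod.fit_variance_components(
                data, outcome=outcome, by_yeargroup=False
            )
            pooled = icc_mod.icc_from_components(pooled_vc, outcome=outcome)
            table = icc_mod.icc_table(ests + [pooled])
            table.to_csv(out / "icc_estimates.csv", index=False)
            (out / "icc_estimates.json").write_text(
                table.to_json(orient="records", indent=2)
            )
            est_inputs["icc"] = pooled.icc
            est_inputs["sd_total"] = pooled.sd_total
            log.info(
                "icc: %d estimates (pooled icc=%.3f, sd=%.1f, converged=%s)",
                len(ests), pooled.icc, pooled.sd_total, pooled_vc.converged,
            )
            summary["icc"] = {
                "n_estimates": len(ests),
                "pooled_icc": pooled.icc,
                "pooled_sd_total": pooled.sd_total,
                "converged": pooled_vc.converged,
            }

        # ---- autocorrelations ---------------------------------------
        if config.autocorrelation is not None:
            stage = "autocorr"
            blk = config.autocorrelation
            outcome = (config.estimation or {}).get("outcome", "mvpa_weekday")
            records = ac.correlation_records(
                data, outcome=outcome, min_pupils=int(blk.get("min_pupils", 5))
            )
            method = blk.get("method", "dl")
            pooled_bins = ac.pool_correlations(
                records, bin_by_followup=True, method=method
            )
            pooled_all = ac.pool_correlations(
                records, bin_by_followup=False, method=method
            )
            ac.pooled_table(pooled_bins + pooled_all).to_csv(
                out / "autocorrelations.csv", index=False
            )
            for p in pooled_all:
                est_inputs["cac" if p.level == "school" else "iac"] = p.r
            log.info(
                "autocorr: %d records pooled -> %s",
                len(records), out / "autocorrelations.csv",
            )
            summary["autocorr"] = {
                "n_records": len(records),
                "pooled": {p.level: p.r for p in pooled_all},
            }

        # ---- trial design -------------------------------------------
        if config.design is not None:
            stage = "design"
            blk = dict(config.design)
            params = {
                "delta": float(blk.get("delta", 5.0)),
                "alpha": float(blk.get("alpha", 0.05)),
                "power": float(blk.get("power", 0.80)),
                "m": int(blk.get("m", 25)),
            }
            for key in ("icc", "sd_total", "cac", "iac"):
                if blk.get(key) is not None:
                    params[key] = float(blk[key])
                elif key in est_inputs:
                    params[key] = float(est_inputs[key])
            for key in ("icc", "sd_total"):
                if key not in params:
                    raise ConfigurationError(
                        f"design stage needs {key}: supply it or run estimation"
                    )
            params.setdefault("cac", 1.0)
            params.setdefault("iac", 0.0)
            cells = blk.get(
                "designs",
                [
                    {"design": "crct"},
                    {"design": "sw_cross_sectional", "steps": 2},
                    {"design": "sw_cohort", "steps": 2},
                    {"design": "sw_cross_sectional", "steps": 3},
                    {"design": "sw_cohort", "steps": 3},
                ],
            )
            rows = []
            for cell in cells:
                spec = DesignSpec(**{**params, **cell})
                res = required_schools(spec)
                rows.append(
                    {
                        "design": spec.design,
                        "steps": spec.steps if spec.design.startswith("sw") else None,
                        "icc": spec.icc,
                        "sd_total": spec.sd_total,
                        "m": spec.m,
                        "total_schools": res.total_schools,
                        "achieved_power": res.achieved_power,
                    }
                )
            table = pd.DataFrame(rows)
            table.to_csv(out / "design_table.csv", index=False)
            log.info("design: %d cells -> %s", len(rows), out / "design_table.csv")
            summary["design"] = {"inputs": params, "n_cells": len(rows)}

    except ClusterPAError as err:
        raise type(err)(f"[stage: {stage}] {err}") from err

    (out / "run_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return out


def _version() -> str:
    try:
        return pkg_version("clusterpa")
    except Exception:
        return "unknown"
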