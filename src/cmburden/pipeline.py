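"""End-to-end pipeline driver: simulate -> prevalence -> RR -> PAF -> burden
-> uncertainty, with stages skippable when pre-computed tables are supplied.

Supplying ``prevalence_csv`` and ``rr_csv`` together runs the attribution
chain in "spreadsheet-equivalent" mode directly from external tables (no
microdata); supplying ``burden_csv`` replaces the synthetic burden envelope.
Every output CSV carries the run seed and a configuration hash in comment
headers, and a ``manifest.json`` records versions, seed, hash and outputs so
any run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .burden import (
    attribute_anxiety,
    attribute_cause,
    attribute_self_harm,
    attribute_smoking,
    summarise,
)
from .io import config_hash, read_table, write_table
from .paf import aggregate_paf, paf_table
from .patterns import COUNT_CODING, SIX_PATTERN_CODING
from .prevalence import PrevalenceModelSpec, fit_joint_prevalence
from .relative_risks import OUTCOME_LABELS, fit_log_binomial
from .synthetic import SimulationConfig, simulate_burden_table, simulate_microdata
from .uncertainty import UncertaintySpec, run_monte_carlo

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    out_dir: str = "cmburden_out"
    coding: str = "count_of_types"  # or "six_common_patterns"
    adjustment: str = "simply"
    iterations: int = 2000
    ptsd_share: float = 0.28
    n_respondents: int = 8377
    # optional pre-computed inputs (stages are skipped when supplied)
    prevalence_csv: str | None = None
    rr_csv: str | None = None
    burden_csv: str | None = None
    run_uncertainty: bool = True
    simulation: SimulationConfig | None = None

    def resolved_simulation(self) -> SimulationConfig:
        sim = self.simulation or SimulationConfig()
        return dataclasses.replace(sim, n_respondents=self.n_respondents)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _coding(name: str):
    return {"count_of_types": COUNT_CODING, "six_common_patterns": SIX_PATTERN_CODING}[name]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline, writing all outputs under ``config.out_dir``.

    Returns a dict of in-memory results (prevalence, rr, paf, attributable,
    summary, uncertainty, manifest).  On stage failure a ``<stage>.partial``
    marker is left in the output directory and the error re-raised.
    """
    for p in (config.prevalence_csv, config.rr_csv, config.burden_csv):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(p)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hash_cfg = {k: v for k, v in config.as_dict().items() if k != "out_dir"}
    meta = {
        "seed": config.seed,
        "config_hash": config_hash(hash_cfg),
        "cmburden_version": __version__,
    }
    coding = _coding(config.coding)
    ss = np.random.SeedSequence(config.seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss]
    results: dict = {}
    stage = "setup"
    try:
        skip_estimation = config.prevalence_csv is not None and config.rr_csv is not None

        stage = "simulate"
        if not skip_estimation:
            sim = config.resolved_simulation()
            microdata = simulate_microdata(sim, seed=seeds[0])
            write_table(microdata, out / "microdata.csv", meta)
            results["microdata"] = microdata

        stage = "burden_table"
        if config.burden_csv:
            burden = read_table(config.burden_csv, "burden")
        else:
            burden = simulate_burden_table(config.resolved_simulation(), seed=seeds[1])
            write_table(burden, out / "burden_table.csv", meta)
        results["burden_table"] = burden

        stage = "prevalence"
        if config.prevalence_csv:
            prevalence = read_table(config.prevalence_csv, "prevalence")
        else:
            fit = fit_joint_prevalence(microdata, PrevalenceModelSpec())
            prevalence = fit.table
            results["prevalence_fit"] = fit
        if "effective_n" not in prevalence.columns:
            prevalence = prevalence.assign(effective_n=np.inf)
        write_table(prevalence, out / "prevalence.csv", meta)
        results["prevalence"] = prevalence

        stage = "relative_risks"
        if config.rr_csv:
            rrset = read_table(config.rr_csv, "rr")
        else:
            rrset = pd.concat(
                [
                    fit_log_binomial(microdata, o, coding, config.adjustment)
                    for o in OUTCOME_LABELS
                ],
                ignore_index=True,
            )
        write_table(rrset, out / "rr.csv", meta)
        results["rr"] = rrset

        stage = "paf"
        paf = paf_table(prevalence, rrset, coding)
        write_table(paf, out / "paf.csv", meta)
        results["paf"] = paf

        stage = "burden_attribution"
        attributables = []
        causes = set(burden["cause"])
        outcomes = set(rrset["outcome"])
        if "mdd" in outcomes and "mdd" in causes:
            attributables.append(attribute_cause(paf, burden, "mdd"))
        if {"ptsd", "gad"} <= outcomes and "anxiety_total" in causes:
            attributables.append(
                attribute_anxiety(
                    paf[paf["outcome"] == "ptsd"],
                    paf[paf["outcome"] == "gad"],
                    burden[burden["cause"] == "anxiety_total"],
                    config.ptsd_share,
                )
            )
        if "suicide_attempt" in outcomes and "self_harm" in causes:
            attributables.append(
                attribute_self_harm(paf, burden[burden["cause"] == "self_harm"])
            )
        if "aud" in outcomes and "aud" in causes:
            attributables.append(attribute_cause(paf, burden, "aud"))
        if "smoking" in outcomes and "smoking_attributable" in causes:
            attributables.append(
                attribute_smoking(paf, burden[burden["cause"] == "smoking_attributable"])
            )
        attributable = (
            pd.concat(attributables, ignore_index=True) if attributables else pd.DataFrame()
        )
        write_table(attributable, out / "attributable_burden.csv", meta)
        summary = summarise(attributables, burden)
        results["attributable"] = attributable
        results["summary"] = summary
        write_table(summary["by_cause"], out / "summary_by_cause.csv", meta)
        write_table(summary["totals"], out / "summary_totals.csv", meta)
        # all-ages PAF weighted by each outcome's cause DALYs
        cause_of = {
            "mdd": "mdd", "aud": "aud", "suicide_attempt": "self_harm",
            "smoking": "smoking_attributable", "ptsd": "anxiety_total",
            "gad": "anxiety_total",
        }
        agg_parts = []
        for o in outcomes:
            cause = cause_of.get(o)
            if cause not in causes:
                continue
            weights = (
                burden[burden["cause"] == cause][["gender", "age_group", "daly"]]
                .rename(columns={"daly": "weight"})
            )
            agg_parts.append(aggregate_paf(paf[paf["outcome"] == o], weights))
        if agg_parts:
            results["paf_all_ages"] = pd.concat(agg_parts, ignore_index=True)
            write_table(results["paf_all_ages"], out / "paf_all_ages.csv", meta)

        stage = "uncertainty"
        if config.run_uncertainty:
            uspec = UncertaintySpec(iterations=config.iterations, seed=seeds[2])
            unc = run_monte_carlo(
                prevalence, rrset, coding, burden, config.ptsd_share, uspec
            )
            write_table(unc.paf, out / "paf_ui.csv", meta)
            write_table(unc.attributable_daly, out / "attributable_daly_ui.csv", meta)
            write_table(unc.share_all_dalys, out / "share_all_dalys_ui.csv", meta)
            results["uncertainty"] = unc

        stage = "manifest"
        manifest = {
            **meta,
            "config": config.as_dict(),
            "outputs": sorted(p.name for p in out.glob("*.csv")),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        results["manifest"] = manifest
    except Exception:
        (out / f"{stage}.partial").touch()
        raise
    return results
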