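"""Orchestration of the full factorial simulation study.

One study = scenarios x outcomes x methods x replicates.  For each scenario
a single target population is generated, the true marginal effects are
computed once on a large independent draw, and every replicate sample is
analyzed by the configured methods on all three outcomes.  Replicate seeds
are derived counter-style from the master seed, so any subset of replicates
reproduces exactly without running its predecessors, and the whole report
is a deterministic function of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .coefficients import ScenarioCoefficients, load_frozen
from .dgp import confounder_summary, draw_samples, generate_population
from .estimators import (
    OUTCOMES,
    compute_weights,
    estimate_gcomputation,
    estimate_raw,
    estimate_weighted,
    fit_propensity,
)
from .tmle import estimate_tmle
from .truth import TrueEffects, true_effects_counterfactual

__all__ = ["StudyConfig", "StudyReport", "run_replicates", "run_study", "write_report"]

ALL_METHODS = ("raw", "GC", "IPTW", "SMR", "OW", "TMLE")
_OUTCOME_KEY = {"continuous": "ate_continuous", "binary": "ate_binary", "survival": "ate_survival"}


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one simulation study."""

    scenarios: tuple = (1, 2, 3)
    population_size: int = 20_000
    n_replicates: int = 3000
    sample_size: int = 200
    methods: tuple = ALL_METHODS
    outcomes: tuple = OUTCOMES
    gc_bootstrap_reps: int = 200
    master_seed: int = 20230117
    truth_size: int = 200_000
    coefficient_sets: dict | None = None  # scenario_id -> ScenarioCoefficients

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.sample_size < 20:
            raise ValueError("sample_size must be >= 20")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    def coefficients(self, scenario_id: int) -> ScenarioCoefficients:
        if self.coefficient_sets and scenario_id in self.coefficient_sets:
            return self.coefficient_sets[scenario_id]
        return load_frozen(scenario_id)

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        if self.coefficient_sets:
            payload["coefficient_sets"] = {
                k: v.to_dict() for k, v in self.coefficient_sets.items()
            }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class StudyReport:
    """Everything a study produces, traceable to its replicate records."""

    config: StudyConfig
    truths: dict                      # scenario_id -> TrueEffects
    records: pd.DataFrame             # one row per replicate x method x outcome
    summary: pd.DataFrame             # performance table
    confounders: dict                 # scenario_id -> ConfounderSummary
    failures: list = field(default_factory=list)


def _replicate_seed(master_seed: int, scenario_id: int, replicate_index: int):
    return [master_seed, scenario_id, replicate_index]


def run_replicates(
    pop: pd.DataFrame,
    scenario_id: int,
    n_replicates: int,
    sample_size: int,
    methods=ALL_METHODS,
    outcomes=OUTCOMES,
    gc_bootstrap_reps: int = 200,
    master_seed: int = 0,
    gc_bootstrap_outcomes=OUTCOMES,
) -> pd.DataFrame:
    """Run the configured estimators over replicate samples of one population.

    ``gc_bootstrap_outcomes`` limits which outcomes get a bootstrap CI for
    g-computation (the survival bootstrap refits many Cox models and can be
    switched off when only point estimates are needed).

    Returns the replicate-level record table.  Deterministic given seeds;
    replicates are mutually independent, so results do not depend on
    execution order.
    """
    rows = []
    sampler = draw_samples(pop, n_replicates, sample_size, seed=master_seed)
    for i, sample in sampler:
        rng = np.random.default_rng(_replicate_seed(master_seed, scenario_id, i))
        estimates = []
        if "raw" in methods:
            estimates += [estimate_raw(sample, oc) for oc in outcomes]
        if "GC" in methods:
            for oc in outcomes:
                reps = gc_bootstrap_reps if oc in gc_bootstrap_outcomes else 0
                estimates.append(
                    estimate_gcomputation(sample, oc, ci_bootstrap_reps=reps, rng=rng)
                )
        needs_ps = any(m in methods for m in ("IPTW", "SMR", "OW", "TMLE"))
        if needs_ps:
            ps = fit_propensity(sample)
            a = sample["A"].to_numpy(dtype=float)
            for m in ("IPTW", "SMR", "OW"):
                if m not in methods:
                    continue
                if ps.converged:
                    w = compute_weights(ps.scores, a, m)
                    estimates += [estimate_weighted(sample, oc, w, method=m) for oc in outcomes]
                else:
                    from .estimators import _failed

                    estimates += [_failed(m, oc) for oc in outcomes]
            if "TMLE" in methods:
                estimates += [estimate_tmle(sample, oc, ps=ps) for oc in outcomes]
        for est in estimates:
            rec = est.as_record()
            rec["scenario"] = scenario_id
            rec["replicate_index"] = i
            rows.append(rec)
    return pd.DataFrame(rows)


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full study described by ``config``."""
    truths: dict[int, TrueEffects] = {}
    confounders = {}
    failures = []
    all_records = []
    for sid in config.scenarios:
        coeffs = config.coefficients(sid)
        pop = generate_population(
            coeffs, config.population_size, seed=[config.master_seed, sid, 900_000]
        )
        truths[sid] = true_effects_counterfactual(
            coeffs, size=config.truth_size, seed=[config.master_seed, sid, 900_001]
        )
        confounders[sid] = confounder_summary(pop)
        try:
            rec = run_replicates(
                pop,
                sid,
                config.n_replicates,
                config.sample_size,
                methods=config.methods,
                outcomes=config.outcomes,
                gc_bootstrap_reps=config.gc_bootstrap_reps,
                master_seed=config.master_seed,
            )
            all_records.append(rec)
        except Exception as exc:  # partial report with failure manifest
            failures.append({"scenario": sid, "error": repr(exc)})

    records = (
        pd.concat(all_records, ignore_index=True)
        if all_records
        else pd.DataFrame(
            columns=["scenario", "outcome", "method", "replicate_index",
                     "point", "ci_low", "ci_high", "converged"]
        )
    )
    truth_map = {
        (sid, oc): getattr(truths[sid], _OUTCOME_KEY[oc])
        for sid in truths
        for oc in config.outcomes
    }
    summary = (
        _metrics.summarize(records, truth_map) if len(records) else pd.DataFrame()
    )
    return StudyReport(
        config=config,
        truths=truths,
        records=records,
        summary=summary,
        confounders=confounders,
        failures=failures,
    )


def write_report(report: StudyReport, outdir) -> list:
    """Write the report as plain CSV / key-value text files.

    Emits ``summary.csv`` (performance table), ``replicates.csv``
    (density-plot source), ``confounders.csv``, ``truths.csv`` and
    ``provenance.json``.  Writes are atomic (temp file + rename) and the
    CSV payloads are byte-identical across re-runs of the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not outdir.is_dir():
        raise ValueError(f"{outdir} is not a writable directory")
    written = []

    def atomic_write(name: str, text: str):
        tmp = outdir / (name + ".tmp")
        tmp.write_text(text)
        tmp.replace(outdir / name)
        written.append(outdir / name)

    if len(report.summary):
        atomic_write("summary.csv", report.summary.to_csv(index=False))
    if len(report.records):
        atomic_write("replicates.csv", report.records.to_csv(index=False))

    conf_rows = []
    for sid, cs in report.confounders.items():
        t = cs.arm_stats.reset_index()
        t.insert(0, "scenario", sid)
        for key, val in cs.correlations.items():
            t[key] = val
        t["adjusted_or_u"] = cs.adjusted_or_u
        conf_rows.append(t)
    if conf_rows:
        atomic_write("confounders.csv", pd.concat(conf_rows, ignore_index=True).to_csv(index=False))

    truth_rows = [
        {"scenario": sid, **te.as_dict()} for sid, te in sorted(report.truths.items())
    ]
    if truth_rows:
        atomic_write("truths.csv", pd.DataFrame(truth_rows).to_csv(index=False))

    provenance = {
        "config": {
            k: v
            for k, v in dataclasses.asdict(report.config).items()
            if k != "coefficient_sets"
        },
        "config_digest": report.config.digest(),
        "coefficient_versions": {
            sid: report.config.coefficients(sid).version for sid in report.config.scenarios
        },
        "failures": report.failures,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
    written.append(outdir / "provenance.json")
    return written
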