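"""Orchestrate simulate -> scrape -> estimate -> model -> report.

Each stage reads the previous stage's CSV outputs from one output
directory, writes its own, and appends a manifest entry (config
snapshot, seed, input hashes, row counts) so a run can be reproduced
exactly.  All randomness derives from the single configured seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import estimator, journal_model, scraper, synthetic

logger = logging.getLogger(__name__)

STAGES = ("simulate", "scrape", "estimate", "model", "report")


@dataclass
class PipelineConfig:
    """One source of truth for a pipeline run (YAML-loadable)."""

    outdir: str = "litfdr_out"
    seed: int = 0
    alpha: float = 0.05
    # simulate: panel scale (demo-sized by default) and reporting mix
    n_oncology: int = 10
    n_medicine: int = 8
    years: tuple[int, int] = (2011, 2015)
    pvalues_per_journal_year: int = 120
    abstract_size: int = 5
    p_exact: float = 0.3
    p_round: float = 0.4
    p_truncate: float = 0.3
    mixture_a: float = 0.7
    mixture_b: float = 30.0
    oa_switch_prob: float = 0.0
    # estimate
    tol: float = 1e-6
    max_iter: int = 2000
    n_multistart: int = 1
    min_count: int = 10
    # model
    dataset: str = "all"
    zero_tol: float = 1e-4
    screen_alpha: float = 0.05
    bootstrap_B: int = 0
    jif_grid_n: int = 25
    # optional external inputs (skip simulate / scrape)
    medline_path: Optional[str] = None
    meta_path: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "years" in raw:
            raw["years"] = tuple(raw["years"])
        return cls(**raw)

    def estimator_config(self) -> estimator.EstimatorConfig:
        return estimator.EstimatorConfig(
            alpha=self.alpha, tol=self.tol, max_iter=self.max_iter,
            n_multistart=self.n_multistart, min_count=self.min_count,
        )

    def policy(self) -> synthetic.ReportingPolicy:
        return synthetic.ReportingPolicy(self.p_exact, self.p_round, self.p_truncate)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest_path(outdir: str) -> str:
    return os.path.join(outdir, "manifest.json")


def _update_manifest(outdir: str, stage: str, entry: dict) -> None:
    path = _manifest_path(outdir)
    manifest = {}
    if os.path.exists(path):
        with open(path, encoding="utf-8") as fh:
            manifest = json.load(fh)
    manifest[stage] = entry
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _record(outdir: str, stage: str, config: PipelineConfig,
            inputs: dict[str, str], outputs: dict[str, dict]) -> None:
    entry = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "seed": config.seed,
        "inputs": {p: _sha256(p) for p in inputs.values()},
        "outputs": outputs,
    }
    _update_manifest(outdir, stage, entry)


def _out(outdir: str, name: str) -> str:
    return os.path.join(outdir, name)


def _write_csv(df: pd.DataFrame, path: str) -> dict:
    df.to_csv(path, index=False)
    return {"sha256": _sha256(path), "rows": int(len(df))}


def _require(path: str, stage: str) -> str:
    if not os.path.exists(path):
        raise FileNotFoundError(
            f"stage {stage!r} requires {path}; run the upstream stage first"
        )
    return path


# -- stages -----------------------------------------------------------------


def stage_simulate(config: PipelineConfig) -> dict:
    os.makedirs(config.outdir, exist_ok=True)
    panel_cfg = synthetic.PanelConfig(
        n_oncology=config.n_oncology, n_medicine=config.n_medicine,
        years=config.years, oa_switch_prob=config.oa_switch_prob,
        pvalues_per_journal_year=config.pvalues_per_journal_year,
        seed=config.seed,
    )
    meta, truth, coefs = synthetic.generate_journal_panel(panel_cfg)
    corpus = _out(config.outdir, "corpus.medline")
    gt = synthetic.generate_corpus(
        meta, truth, corpus, policy=config.policy(),
        mixture_shapes=(config.mixture_a, config.mixture_b),
        alpha=config.alpha, pvalues_per_cell=config.pvalues_per_journal_year,
        abstract_size=config.abstract_size, seed=config.seed + 1,
    )
    outputs = {
        "meta.csv": _write_csv(meta, _out(config.outdir, "meta.csv")),
        "truth.csv": _write_csv(truth, _out(config.outdir, "truth.csv")),
        "ground_truth_reports.csv": _write_csv(
            gt, _out(config.outdir, "ground_truth_reports.csv")),
        "corpus.medline": {"sha256": _sha256(corpus)},
    }
    with open(_out(config.outdir, "true_coefficients.json"), "w", encoding="utf-8") as fh:
        json.dump(coefs, fh, indent=2, sort_keys=True)
        fh.write("\n")
    outputs["true_coefficients.json"] = {
        "sha256": _sha256(_out(config.outdir, "true_coefficients.json"))}
    _record(config.outdir, "simulate", config, {}, outputs)
    return outputs


def stage_scrape(config: PipelineConfig) -> dict:
    corpus = config.medline_path or _require(
        _out(config.outdir, "corpus.medline"), "scrape")
    pvals = scraper.scrape_file(corpus)
    outputs = {"pvalues.csv": _write_csv(pvals, _out(config.outdir, "pvalues.csv"))}
    _record(config.outdir, "scrape", config, {"corpus": corpus}, outputs)
    return outputs


def stage_estimate(config: PipelineConfig) -> dict:
    path = _require(_out(config.outdir, "pvalues.csv"), "estimate")
    pvals = pd.read_csv(path)
    records = [
        scraper.ReportedPValue(
            value=float(r.value), comparator=r.comparator,
            decimals=None if pd.isna(r.decimals) else int(r.decimals),
            cls=r.cls, abstract_id=str(r.abstract_id),
            journal=r.journal, year=int(r.year),
        )
        for r in pvals.itertuples(index=False)
    ]
    kept = scraper.filter_significant(records, config.alpha)
    kept_df = pd.DataFrame(
        [{"journal": r.journal, "year": r.year, "value": r.value,
          "comparator": r.comparator,
          "decimals": r.decimals if r.decimals is not None else np.nan,
          "cls": r.cls} for r in kept],
        columns=["journal", "year", "value", "comparator", "decimals", "cls"],
    )
    estimates, removals = estimator.estimate_journal_years(
        kept_df, config.estimator_config())
    logger.info("estimate: %d journal-year fits, %d journals flagged for removal",
                len(estimates), len(removals))
    outputs = {
        "estimates.csv": _write_csv(estimates, _out(config.outdir, "estimates.csv")),
        "removals.csv": _write_csv(removals, _out(config.outdir, "removals.csv")),
    }
    _record(config.outdir, "estimate", config, {"pvalues": path}, outputs)
    return outputs


def _fit_and_table(frame, terms, screen_alpha):
    final_terms, log = journal_model.screen_interactions(
        frame, terms, alpha=screen_alpha)
    fit = journal_model.fit_lmm(frame, final_terms)
    table = fit.table.reset_index(names="term").rename(columns={
        "estimate": "Estimate", "se": "Std. Error", "tvalue": "T-Value",
        "pvalue": "p value", "ci_low": "CI low", "ci_high": "CI high",
    })
    return fit, table, final_terms, log


def stage_model(config: PipelineConfig) -> dict:
    est_path = _require(_out(config.outdir, "estimates.csv"), "model")
    meta_path = config.meta_path or _require(_out(config.outdir, "meta.csv"), "model")
    estimates = pd.read_csv(est_path)
    removals = pd.read_csv(_require(_out(config.outdir, "removals.csv"), "model"))
    meta = pd.read_csv(meta_path)
    est = estimator.modeling_table(estimates, removals)
    est_f, meta_f = journal_model.apply_dataset_filter(
        est, meta, config.dataset, config.zero_tol)
    frame = journal_model.build_model_frame(est_f, meta_f)

    outputs: dict[str, dict] = {}
    screen_lines: list[str] = []
    fits = {}
    for name, sub, terms in (
        ("global", frame, list(journal_model.GLOBAL_TERMS)),
        ("oncology", frame[frame["oncology"] == 1], list(journal_model.STRATIFIED_TERMS)),
        ("medicine", frame[frame["oncology"] == 0], list(journal_model.STRATIFIED_TERMS)),
    ):
        fit, table, final_terms, log = _fit_and_table(sub, terms, config.screen_alpha)
        fits[name] = (fit, sub, final_terms)
        fname = f"model_{name}.csv"
        outputs[fname] = _write_csv(table, _out(config.outdir, fname))
        screen_lines.append(f"[{name}] final terms: {', '.join(final_terms)}")
        for entry in log:
            screen_lines.append(
                f"[{name}] step {entry['step']}: terms={entry['terms']} "
                f"testable p={entry['testable_pvalues']} removed={entry['removed']}"
            )
        if config.bootstrap_B >= 2 and name in ("oncology", "medicine"):
            grid = np.linspace(sub["log_jif"].min(), sub["log_jif"].max(),
                               config.jif_grid_n)
            bands = journal_model.bootstrap_bands(
                sub, final_terms, grid, B=config.bootstrap_B,
                seed=config.seed + 100)
            bname = f"bands_{name}.csv"
            outputs[bname] = _write_csv(bands, _out(config.outdir, bname))
    log_path = _out(config.outdir, "screening_log.txt")
    with open(log_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(screen_lines) + "\n")
    outputs["screening_log.txt"] = {"sha256": _sha256(log_path)}
    entry_inputs = {"estimates": est_path, "meta": meta_path}
    _record(config.outdir, "model", config, entry_inputs, outputs)
    manifest_extra = {
        "dataset": config.dataset, "zero_tol": config.zero_tol,
        "n_journals": int(frame["journal"].nunique()), "n_obs": int(len(frame)),
    }
    _update_manifest(config.outdir, "model_filters", manifest_extra)
    return outputs


def stage_report(config: PipelineConfig) -> dict:
    tables = {}
    for name in ("global", "oncology", "medicine"):
        path = _require(_out(config.outdir, f"model_{name}.csv"), "report")
        tables[name] = pd.read_csv(path).set_index("term")
    rows = []
    for name, tab in tables.items():
        beta = float(tab.loc["log_jif", "Estimate"])
        rows.append({"model": name, "quantity": "twofold_jif_effect",
                     "value": journal_model.twofold_jif_effect(beta)})
    # adjusted means need the fitted frame; refit from stored outputs
    estimates = pd.read_csv(_require(_out(config.outdir, "estimates.csv"), "report"))
    removals = pd.read_csv(_require(_out(config.outdir, "removals.csv"), "report"))
    meta = pd.read_csv(config.meta_path or _require(_out(config.outdir, "meta.csv"), "report"))
    est = estimator.modeling_table(estimates, removals)
    est_f, meta_f = journal_model.apply_dataset_filter(
        est, meta, config.dataset, config.zero_tol)
    frame = journal_model.build_model_frame(est_f, meta_f)
    gterms = [t for t in tables["global"].index if t != "Intercept"]
    gfit = journal_model.fit_lmm(frame, gterms)
    if "oncology" in gterms and not any(
            "oncology" in t.split(":") for t in gterms if t != "oncology"):
        means = journal_model.adjusted_means(gfit, frame, "oncology")
        rows.append({"model": "global", "quantity": "adjusted_mean_medicine",
                     "value": means[0]})
        rows.append({"model": "global", "quantity": "adjusted_mean_oncology",
                     "value": means[1]})
        rows.append({"model": "global", "quantity": "percent_excess_oncology",
                     "value": journal_model.percent_excess(means[1], means[0])})
    derived = pd.DataFrame(rows, columns=["model", "quantity", "value"])
    outputs = {"derived_effects.csv": _write_csv(
        derived, _out(config.outdir, "derived_effects.csv"))}
    _record(config.outdir, "report", config,
            {"global": _out(config.outdir, "model_global.csv")}, outputs)
    return outputs


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "scrape": stage_scrape,
    "estimate": stage_estimate,
    "model": stage_model,
    "report": stage_report,
}


def run_stage(stage: str, config: PipelineConfig) -> dict:
    """Run one named stage; writes outputs plus a manifest entry."""
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    logger.info("running stage %s -> %s", stage, config.outdir)
    return _STAGE_FUNCS[stage](config)


def run_all(config: PipelineConfig) -> dict[str, dict]:
    """Full pipeline in order; returns outputs per stage."""
    results = {}
    for stage in STAGES:
        if stage == "simulate" and config.medline_path:
            continue  # external corpus provided
        results[stage] = run_stage(stage, config)
    return results
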