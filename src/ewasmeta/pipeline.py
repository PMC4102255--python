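"""End-to-end orchestration: simulate -> qc -> normalize -> probeset ->
association / survival -> meta -> summary tables.

Each stage writes its outputs under the run directory plus a manifest
line (stage, parameters, output file SHA-256 hashes), halting downstream
stages on failure. A stage re-run from disk loads whatever upstream
outputs it needs; a missing input raises a stage-labelled error naming
the file. Reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import meta as meta_mod
from . import qc as qc_mod
from .assoc import run_batch_association
from .containers import BetaMatrix
from .normalize import adjust_batch_effects
from .probeset import assemble_analysis_set, read_annotation
from .survmod import run_survival_association
from .synthio import (
    SimConfig,
    simulate_annotation,
    simulate_beta,
    simulate_cohort,
    simulate_survival,
    write_outputs,
)

__all__ = ["RunConfig", "StageError", "run_all", "summarize"]

ALL_STEPS = ("simulate", "qc", "normalize", "probeset", "assoc", "survival", "meta", "summarize")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "pipeline_out"
    sim: SimConfig = field(default_factory=SimConfig)
    detp_cut: float = 0.05
    min_detection_rate: float = 0.70
    negctrl_k_sd: float = 4.0
    call_rate_min: float = 0.95
    bisulfite_min: float = 0.90
    significance: float = 5e-6
    steps: tuple = ALL_STEPS

    def __post_init__(self) -> None:
        unknown = set(self.steps) - set(ALL_STEPS)
        if unknown:
            raise ValueError(f"unknown steps: {sorted(unknown)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _manifest_line(out: Path, stage: str, params: dict, files: list[Path]) -> None:
    rec = {
        "stage": stage,
        "params": params,
        "outputs": {f.name: _sha256(f) for f in files if f.exists()},
    }
    with open(out / "manifest.jsonl", "a") as fh:
        fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageError(f"{stage}: required input file {path} is missing")
    return path


def _load_beta(out: Path, stage: str) -> dict[int, BetaMatrix]:
    return {
        b: BetaMatrix(
            pd.read_csv(_require(out / f"beta_batch{b}.tsv", stage), sep="\t", index_col=0),
            pd.read_csv(_require(out / f"detp_batch{b}.tsv", stage), sep="\t", index_col=0),
        )
        for b in (1, 2, 3)
    }


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages in fixed order; return the state dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    for step in ALL_STEPS:
        if step in config.steps:
            _STAGES[step](config, out, state)
    return state


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> None:
    sheet, truth = simulate_cohort(config.sim)
    beta = simulate_beta(sheet, truth, config.sim)
    sheet = simulate_survival(sheet, truth, beta, config.sim)
    ann = simulate_annotation(truth, config.sim)
    write_outputs(out, config.sim, sheet, truth, beta, ann)
    state.update(sheet=sheet, truth=truth, beta=beta, ann=ann)
    _manifest_line(out, "simulate", {"seed": config.sim.seed},
                   sorted(out.glob("*.tsv")) + [out / "sample_sheet.csv", out / "config.yaml"])


def _stage_qc(config: RunConfig, out: Path, state: dict) -> None:
    if "sheet" not in state:
        state["sheet"] = pd.read_csv(_require(out / "sample_sheet.csv", "qc"))
        state["beta"] = _load_beta(out, "qc")
        state["ann"] = read_annotation(_require(out / "probe_annotation.tsv", "qc"))
    sheet, beta, ann = state["sheet"], state["beta"], state["ann"]

    # QC is done jointly for the two small-panel batches, then for batch 3
    def _panel_qc(batches: tuple) -> tuple[set, set]:
        bm = BetaMatrix(
            pd.concat([beta[b].beta for b in batches], axis=1),
            pd.concat([beta[b].detp for b in batches], axis=1),
        )
        in_panel = sheet[sheet["sample_id"].isin(bm.sample_ids)]
        neg = in_panel.loc[in_panel["role"] == "negative_bsm", "sample_id"]
        study = in_panel.loc[in_panel["role"] == "study", "sample_id"]
        probe_rep = qc_mod.run_probe_qc(
            bm, ann, neg, study, detp_cut=config.detp_cut,
            min_rate=config.min_detection_rate, k_sd=config.negctrl_k_sd,
        )
        sample_rep = qc_mod.run_sample_qc(
            bm, sheet, call_rate_min=config.call_rate_min,
            bisulfite_min=config.bisulfite_min, detp_cut=config.detp_cut,
        )
        passing = set(bm.probe_ids) - probe_rep.excluded_probe_ids
        state.setdefault("qc_reports", []).append((batches, probe_rep, sample_rep))
        return passing, sample_rep.excluded_sample_ids

    pass_small, bad_small = _panel_qc((1, 2))
    pass_large, bad_large = _panel_qc((3,))
    bad_samples = bad_small | bad_large
    state["qc_pass_small"], state["qc_pass_large"] = pass_small, pass_large
    state["excluded_samples"] = bad_samples

    frames = []
    for batches, prep, srep in state["qc_reports"]:
        f = prep.excluded_probes.copy()
        f["panel"] = "+".join(map(str, batches))
        frames.append(f.rename(columns={"probe_id": "id"}).assign(kind="probe"))
        g = srep.excluded_samples.copy()
        g["panel"] = "+".join(map(str, batches))
        frames.append(g.rename(columns={"sample_id": "id"}).assign(kind="sample"))
        srep.concordance.assign(panel="+".join(map(str, batches))).to_csv(
            out / f"concordance_panel{batches[0]}.tsv", sep="\t", index=False
        )
    pd.concat(frames, ignore_index=True).to_csv(out / "qc_exclusions.tsv", sep="\t", index=False)
    _manifest_line(out, "qc", {"detp_cut": config.detp_cut, "min_rate": config.min_detection_rate},
                   [out / "qc_exclusions.tsv"])


def _stage_normalize(config: RunConfig, out: Path, state: dict) -> None:
    if "beta" not in state:
        raise StageError("normalize: qc state missing; run simulate+qc first")
    sheet, beta = state["sheet"], state["beta"]
    excluded = state.get("excluded_samples", set())
    adjusted = {}
    for batch in (1, 2, 3):
        sub = sheet[
            (sheet["batch"] == batch)
            & (sheet["role"] == "study")
            & ~sheet["sample_id"].isin(excluded)
        ]
        bm = beta[batch].subset_samples(sub["sample_id"])
        factor_col = "chip" if batch in (1, 2) else "plate"
        factor = sub.set_index("sample_id")[factor_col]
        adjusted[batch] = adjust_batch_effects(bm, factor)
        adjusted[batch].beta.to_csv(out / f"adjusted_beta_batch{batch}.tsv", sep="\t")
    state["adjusted"] = adjusted
    _manifest_line(out, "normalize", {"factors": {1: "chip", 2: "chip", 3: "plate"}},
                   [out / f"adjusted_beta_batch{b}.tsv" for b in (1, 2, 3)])


def _stage_probeset(config: RunConfig, out: Path, state: dict) -> None:
    if "qc_pass_small" not in state:
        raise StageError("probeset: qc state missing; run qc first")
    final, book = assemble_analysis_set(
        state["ann"], state["qc_pass_small"], state["qc_pass_large"]
    )
    state["analysis_set"], state["bookkeeping"] = final, book
    pd.Series(sorted(final), name="probe_id").to_csv(out / "analysis_probes.txt", index=False, header=False)
    (out / "probeset_bookkeeping.json").write_text(json.dumps(dataclasses.asdict(book), indent=1))
    _manifest_line(out, "probeset", {}, [out / "analysis_probes.txt", out / "probeset_bookkeeping.json"])


def _stage_assoc(config: RunConfig, out: Path, state: dict) -> None:
    if "adjusted" not in state:
        raise StageError("assoc: normalized matrices missing; run normalize first")
    res = run_batch_association(state["adjusted"], state["sheet"], state["analysis_set"])
    res.to_csv(out / "assoc_batch_results.tsv", sep="\t", index=False)
    state["assoc_results"] = res
    _manifest_line(out, "assoc", {}, [out / "assoc_batch_results.tsv"])


def _stage_survival(config: RunConfig, out: Path, state: dict) -> None:
    if "adjusted" not in state:
        raise StageError("survival: normalized matrices missing; run normalize first")
    res = run_survival_association(state["adjusted"], state["sheet"], state["analysis_set"])
    res.to_csv(out / "survival_batch_results.tsv", sep="\t", index=False)
    state["survival_results"] = res
    _manifest_line(out, "survival", {}, [out / "survival_batch_results.tsv"])


def _stage_meta(config: RunConfig, out: Path, state: dict) -> None:
    if "assoc_results" not in state:
        raise StageError("meta: per-batch association results missing")
    risk = meta_mod.meta_table(
        state["assoc_results"], estimate_col="beta_hat", scale="linear",
        threshold=config.significance,
    )
    risk.to_csv(out / "meta_risk.tsv", sep="\t", index=False)
    state["meta_risk"] = risk
    files = [out / "meta_risk.tsv"]
    surv = state.get("survival_results")
    if surv is not None and len(surv):
        meta_surv = meta_mod.meta_table(
            surv, estimate_col="log_hr", scale="log", threshold=config.significance
        )
        meta_surv.to_csv(out / "meta_survival.tsv", sep="\t", index=False)
        state["meta_survival"] = meta_surv
        files.append(out / "meta_survival.tsv")
    _manifest_line(out, "meta", {"significance": config.significance}, files)


def summarize(meta_results: pd.DataFrame, ann: pd.DataFrame,
              batch_results: pd.DataFrame | None = None,
              estimate_col: str = "estimate", n_top: int | None = None) -> pd.DataFrame:
    """Top-table report sorted by meta p (stable tie-break on probe id).

    Mirrors the published result-table layout: probe, chromosome,
    position, nearest gene, island relation, then combined and per-batch
    estimate/p columns.
    """
    cols = ["probe_id", "chromosome", "position", "nearest_gene", "island_relation",
            estimate_col, "p", "q_p", "significant"]
    if len(meta_results) == 0:
        return pd.DataFrame(columns=cols)
    tab = meta_results.merge(
        ann.reset_index()[["probe_id", "chromosome", "position", "nearest_gene", "island_relation"]],
        on="probe_id", how="left",
    )
    if batch_results is not None:
        bcol = "beta_hat" if "beta_hat" in batch_results.columns else "hr"
        wide = batch_results.pivot(index="probe_id", columns="batch", values=[bcol, "p"])
        wide.columns = [f"batch{b}_{v}" for v, b in wide.columns]
        tab = tab.merge(wide.reset_index(), on="probe_id", how="left")
    tab = tab.sort_values(["p", "probe_id"], kind="mergesort").reset_index(drop=True)
    keep = [c for c in cols if c in tab.columns] + [c for c in tab.columns if c.startswith("batch")]
    tab = tab[keep + [c for c in ("hr",) if c in tab.columns]]
    return tab.head(n_top) if n_top else tab


def _stage_summarize(config: RunConfig, out: Path, state: dict) -> None:
    if "meta_risk" not in state:
        raise StageError("summarize: meta results missing")
    top = summarize(state["meta_risk"], state["ann"], state.get("assoc_results"))
    top.to_csv(out / "top_table_risk.tsv", sep="\t", index=False)
    files = [out / "top_table_risk.tsv"]
    if "meta_survival" in state:
        top_s = summarize(state["meta_survival"], state["ann"], state.get("survival_results"))
        top_s.to_csv(out / "top_table_survival.tsv", sep="\t", index=False)
        files.append(out / "top_table_survival.tsv")
    _manifest_line(out, "summarize", {}, files)


_STAGES = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "normalize": _stage_normalize,
    "probeset": _stage_probeset,
    "assoc": _stage_assoc,
    "survival": _stage_survival,
    "meta": _stage_meta,
    "summarize": _stage_summarize,
}
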