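"""End-to-end orchestration of the four pipeline phases.

A run takes three training tables (activity, descriptors, ADMET labels)
plus a test descriptor table — either read from disk or drawn from the
synthetic generator — and produces:

* ``selection_report.json`` / ``selection_report.csv`` — phase-1 screen;
* ``ERα_activity_test.csv`` — predicted pIC50 and IC50 for the test
  compounds (phase 2);
* ``ADMET_test.csv`` — predicted binary ADMET labels (phase 3);
* ``results.csv`` — per-descriptor optimal value ranges from the swarm
  search, plus ``convergence_trace.csv`` (phase 4);
* ``admet_evaluation.json`` and per-property ROC point CSVs;
* ``run_manifest.json`` — config echo, per-stage seeds, artifact list
  with content hashes, timings, and evaluation summaries.

One master seed is fanned out deterministically to per-stage seeds by
hashing the stage name, so a stage can be rerun in isolation and a whole
run is bit-reproducible.
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

from . import __version__
from .activity import (FusionSpec, SplitSpec, ic50_to_pic50, pic50_to_ic50,
                       train_activity_model)
from .admet import predict_admet, train_admet_property
from .datasets import (ADMET_COLUMNS, ID_COLUMN, GeneratorConfig,
                       SyntheticDataset, config_to_dict, generate_dataset,
                       prevalence_report)
from .names import normalize_names
from .optimize import (ConstrainedObjective, RewardSpec, assemble_decision_space,
                       derive_ranges, run_pso)
from .selection import run_selection

ACTIVITY_OUT = "ERα_activity_test.csv"
ADMET_OUT = "ADMET_test.csv"
RESULTS_OUT = "results.csv"


@dataclass
class RunConfig:
    """Everything a reproducible run needs.

    ``generator`` may be ``None`` when the three input tables are read
    from ``input_dir`` instead of being synthesized.
    """

    generator: GeneratorConfig | None = None
    input_dir: str | None = None
    seed: int = 0
    gra_k: int = 200
    spearman_cut: float = 0.85
    shap_k: int = 20
    rfe_keep: int = 25
    split: SplitSpec = field(default_factory=SplitSpec)
    fusion: FusionSpec = field(default_factory=FusionSpec)
    swarm_size: int = 50
    pso_iters: int = 80
    pso_w: float = 0.8
    pso_c1: float = 0.5
    pso_c2: float = 0.5
    penalty: float = 10.0
    top_fraction: float = 0.1
    reward_threshold: int = 3
    outdir: str = "qsaropt_out"

    def __post_init__(self) -> None:
        if not (0 < self.spearman_cut < 1):
            raise ValueError(f"spearman_cut must be in (0, 1), got {self.spearman_cut}")
        if self.gra_k < 1 or self.shap_k < 1 or self.rfe_keep < 1:
            raise ValueError("gra_k, shap_k and rfe_keep must be >= 1")
        if not (0 < self.top_fraction <= 1):
            raise ValueError(f"top_fraction must be in (0, 1], got {self.top_fraction}")
        if self.generator is None and self.input_dir is None:
            self.generator = GeneratorConfig(seed=stage_seed(self.seed, "generate"))


def small_config(seed: int = 0, outdir: str = "qsaropt_out") -> RunConfig:
    """Reduced-scale preset: same structure, desk-scale problem sizes."""
    gen = GeneratorConfig(n_train=300, n_test=50, n_descriptors=120, n_zero_cols=37,
                          n_signal=8, n_collinear_pairs=5,
                          seed=stage_seed(seed, "generate"))
    return RunConfig(generator=gen, seed=seed, gra_k=60, swarm_size=30, pso_iters=30,
                     outdir=outdir)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from a master seed."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def read_tables(input_dir: str | Path):
    """Read and validate the four tables from a directory.

    Expects ``Molecular_Descriptor``, ``ERa_activity`` (or
    ``ERα_activity``), ``ADMET`` and ``Molecular_Descriptor_test`` as
    .csv (or .xlsx); first column is the compound key.  Descriptor names
    are normalized, row keys aligned across tables, the pIC50/IC50
    relationship and binary ADMET domain validated.
    """
    input_dir = Path(input_dir)

    def load(stem: str, alt: str | None = None) -> pd.DataFrame:
        for name in filter(None, (stem, alt)):
            for suffix, reader in ((".csv", pd.read_csv), (".xlsx", pd.read_excel)):
                path = input_dir / f"{name}{suffix}"
                if path.exists():
                    df = reader(path)
                    return df.set_index(df.columns[0]).rename_axis(ID_COLUMN)
        raise FileNotFoundError(f"no {stem}.csv/.xlsx under {input_dir}")

    desc = load("Molecular_Descriptor")
    activity = load("ERa_activity", "ERα_activity")
    admet = load("ADMET")
    desc_test = load("Molecular_Descriptor_test")

    for name, df in (("descriptors", desc), ("test descriptors", desc_test)):
        bad = df.columns[~df.dtypes.map(lambda d: np.issubdtype(d, np.number))]
        if len(bad):
            raise ValueError(f"non-numeric {name} column(s): {list(bad)}")
        if df.isna().any().any():
            rows, cols = np.where(df.isna())
            raise ValueError(f"missing {name} value at row {df.index[rows[0]]!r}, "
                             f"column {df.columns[cols[0]]!r}")
    desc.columns = normalize_names(desc.columns)
    desc_test.columns = normalize_names(desc_test.columns)
    if desc.columns.duplicated().any():
        raise ValueError("duplicate descriptor names after normalization")

    for key_df, name in ((activity, "activity"), (admet, "ADMET")):
        mismatch = key_df.index.symmetric_difference(desc.index)
        if len(mismatch):
            raise ValueError(f"compound keys differ between descriptor and {name} "
                             f"tables: {list(mismatch[:5])}...")

    act_cols = {c.lower(): c for c in activity.columns}
    ic_col = next((act_cols[c] for c in act_cols if "ic50" in c and not c.startswith("p")), None)
    pic_col = next((act_cols[c] for c in act_cols if c.startswith("pic50")), None)
    if ic_col is None or pic_col is None:
        raise ValueError(f"activity table must carry IC50 and pIC50 columns, "
                         f"got {list(activity.columns)}")
    activity = activity.rename(columns={ic_col: "IC50_nM", pic_col: "pIC50"})
    if (activity["IC50_nM"] <= 0).any():
        raise ValueError("IC50 values must be positive")
    implied = np.array([ic50_to_pic50(v) for v in activity["IC50_nM"]])
    if np.max(np.abs(implied - activity["pIC50"].to_numpy(dtype=float))) > 1e-6:
        raise ValueError("pIC50 is not consistent with 9 - log10(IC50 in nM)")

    admet = admet[[c for c in admet.columns if c in ADMET_COLUMNS]]
    if list(admet.columns) != ADMET_COLUMNS:
        raise ValueError(f"ADMET table must carry columns {ADMET_COLUMNS}")
    if not admet.isin([0, 1]).all().all():
        raise ValueError("ADMET labels must be binary (0/1)")
    admet = admet.loc[desc.index]
    activity = activity.loc[desc.index]
    return desc, activity, admet, desc_test


@dataclass
class RunManifest:
    """Record of one pipeline run, serializable to JSON."""

    config: dict
    versions: dict
    stage_seeds: dict
    artifacts: dict = field(default_factory=dict)   # name -> {path, sha256}
    timings: dict = field(default_factory=dict)     # stage -> seconds
    summaries: dict = field(default_factory=dict)

    def record_artifact(self, name: str, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.artifacts[name] = {"path": str(path), "sha256": digest}

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.generator is not None:
        d["generator"] = config_to_dict(config.generator)
    return d


def run_all(config: RunConfig) -> RunManifest:
    """Execute phases 1-4 and write every artifact; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {s: stage_seed(config.seed, s)
             for s in ("generate", "selection", "activity", "admet", "pso")}
    manifest = RunManifest(
        config=_config_dict(config),
        versions={"qsaropt": __version__, "numpy": np.__version__,
                  "pandas": pd.__version__},
        stage_seeds=seeds,
    )

    t0 = time.perf_counter()
    if config.input_dir is not None:
        desc, activity, admet_labels, desc_test = read_tables(config.input_dir)
        truth = None
    else:
        data: SyntheticDataset = generate_dataset(config.generator)
        desc, activity = data.descriptors, data.activity
        admet_labels, desc_test = data.admet, data.test_descriptors
        truth = data.truth
    manifest.timings["load"] = time.perf_counter() - t0
    manifest.summaries["admet_prevalence"] = prevalence_report(admet_labels)

    # ---- phase 1: descriptor screen -------------------------------------
    t0 = time.perf_counter()
    pic50 = activity["pIC50"].to_numpy(dtype=float)
    report, norm, params = run_selection(
        desc, pic50, gra_k=config.gra_k, spearman_cut=config.spearman_cut,
        shap_k=config.shap_k, seed=seeds["selection"],
    )
    sel_json = outdir / "selection_report.json"
    sel_json.write_text(json.dumps(report.as_dict(), indent=2))
    sel_csv = outdir / "selection_report.csv"
    report.to_frame().to_csv(sel_csv, index=False)
    manifest.record_artifact("selection_report.json", sel_json)
    manifest.record_artifact("selection_report.csv", sel_csv)
    manifest.timings["selection"] = time.perf_counter() - t0
    manifest.summaries["selection"] = {
        "n_removed_constant": len(report.removed_zero_variance),
        "n_after_gra": len(report.gra_top),
        "n_after_spearman": len(report.retained_after_spearman),
        "n_final": len(report.shap_top),
    }

    # normalize the test table with the training bounds
    norm_test = (desc_test[norm.columns] - params.x_min) / (params.x_max - params.x_min)

    # ---- phase 2: activity model ----------------------------------------
    t0 = time.perf_counter()
    act_result = train_activity_model(
        norm[report.shap_top].to_numpy(dtype=float), pic50, report.shap_top,
        config.split, config.fusion, seeds["activity"],
    )
    pred_pic50 = act_result.surrogate.predict(norm_test[report.shap_top].to_numpy(dtype=float))
    act_out = outdir / ACTIVITY_OUT
    pd.DataFrame({
        ID_COLUMN: desc_test.index,
        "predicted_pIC50": pred_pic50,
        "predicted_IC50_nM": [pic50_to_ic50(v) for v in pred_pic50],
    }).to_csv(act_out, index=False)
    manifest.record_artifact(ACTIVITY_OUT, act_out)
    manifest.timings["activity"] = time.perf_counter() - t0
    manifest.summaries["activity"] = {
        "family_r2_test": {f: e.r2 for f, e in act_result.family_evals.items()},
        "base_families": act_result.surrogate.base_families,
        "fusion_strategy": config.fusion.strategy,
        "fusion_r2_validation": {s: e.r2 for s, e in act_result.fusion_evals_val.items()},
        "fusion_r2_test": act_result.fusion_eval_test.r2,
        "split_sizes": act_result.split_sizes,
        "n_features": len(act_result.surrogate.feature_list),
    }

    # ---- phase 3: ADMET classifiers -------------------------------------
    t0 = time.perf_counter()
    surrogates = {}
    admet_summary = {}
    for prop in ADMET_COLUMNS:
        res = train_admet_property(
            norm, admet_labels[prop].to_numpy(), prop,
            split=config.split, seed=stage_seed(seeds["admet"], prop),
            n_keep=config.rfe_keep,
        )
        surrogates[prop] = res.surrogate
        winner = res.surrogate.best_family
        admet_summary[prop] = {
            "best_family": winner,
            "f1": {f: e.f1 for f, e in res.family_evals.items()},
            "auc": {f: e.auc for f, e in res.family_evals.items()},
            "failed": res.failed_families,
            "prevalence": res.prevalence,
            "features": res.surrogate.feature_list,
        }
        roc_csv = outdir / f"roc_{prop.replace('-', '')}.csv"
        pd.DataFrame(res.family_evals[winner].roc_points,
                     columns=["fpr", "tpr"]).to_csv(roc_csv, index=False)
        manifest.record_artifact(roc_csv.name, roc_csv)
    admet_pred = predict_admet(surrogates, norm_test)
    admet_out = outdir / ADMET_OUT
    admet_pred.reset_index().to_csv(admet_out, index=False)
    admet_eval_json = outdir / "admet_evaluation.json"
    admet_eval_json.write_text(json.dumps(admet_summary, indent=2))
    manifest.record_artifact(ADMET_OUT, admet_out)
    manifest.record_artifact("admet_evaluation.json", admet_eval_json)
    manifest.timings["admet"] = time.perf_counter() - t0
    manifest.summaries["admet"] = {p: {"best_family": s["best_family"],
                                       "best_f1": s["f1"][s["best_family"]]}
                                   for p, s in admet_summary.items()}

    # ---- phase 4: constrained swarm search ------------------------------
    t0 = time.perf_counter()
    space = assemble_decision_space(
        report.shap_top, {p: surrogates[p].feature_list for p in ADMET_COLUMNS},
        bounds_source=params,
    )
    reward_spec = RewardSpec(threshold=config.reward_threshold)
    objective = ConstrainedObjective(space, act_result.surrogate, surrogates,
                                     reward_spec=reward_spec, penalty=config.penalty)
    opt = run_pso(space, objective, m=config.swarm_size, iters=config.pso_iters,
                  w=config.pso_w, c1=config.pso_c1, c2=config.pso_c2,
                  seed=seeds["pso"])
    ranges = derive_ranges(opt, space, top_fraction=config.top_fraction)
    results_out = outdir / RESULTS_OUT
    ranges.to_csv(results_out, index=False)
    trace_out = outdir / "convergence_trace.csv"
    pd.DataFrame({"iteration": np.arange(opt.trace.size),
                  "best_objective": opt.trace}).to_csv(trace_out, index=False)
    manifest.record_artifact(RESULTS_OUT, results_out)
    manifest.record_artifact("convergence_trace.csv", trace_out)
    manifest.timings["pso"] = time.perf_counter() - t0
    manifest.summaries["optimization"] = {
        "decision_dim": space.dim,
        "duplicate_count": space.duplicate_count,
        "best_objective": opt.best_value,
        "best_predicted_pic50": opt.best_pic50,
        "n_feasible_points": int(opt.feasible_positions.shape[0]),
    }
    if truth is not None:
        recovered = set(report.shap_top) & set(truth.signal_names)
        manifest.summaries["signal_recovery"] = {
            "n_signal": len(truth.signal_names),
            "n_recovered_in_panel": len(recovered),
        }

    manifest_path = outdir / "run_manifest.json"
    manifest.write(manifest_path)
    missing = [a["path"] for a in manifest.artifacts.values() if not Path(a["path"]).exists()]
    if missing:
        raise RuntimeError(f"manifest lists missing artifacts: {missing}")
    return manifest
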