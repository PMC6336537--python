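"""End-to-end screen pipeline: design -> rasterize -> descriptors ->
simulate -> morphometry -> hit selection -> tree model -> recovery report.

Every stage writes its table to the output directory; the run manifest
records the configuration, all seeds and the SHA-256 of every artifact, so
two runs of the same configuration are bit-identical.  Table mode (cell
tables straight from the simulator) is the default; image mode renders a
subsample of units and pushes them through segmentation instead, which is
slower but exercises the imaging stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import descriptors as desc
from . import hits as hits_mod
from . import library as lib
from . import morphometry as morpho
from . import screen_sim as sim
from . import tree as tree_mod

#: imputation sentinels for descriptors that are undefined when a design has
#: no qualifying primitives.  The sentinel sits on the side of the feature
#: range where the stimulating property is absent: a design without line
#: elements behaves like one with very long lines, one without circles like
#: one with vanishing circle diameter, and one without orientable primitives
#: is perfectly regular.
ABSENT_SENTINELS = {"line_len": 999.0, "circ_diam": 0.0, "rot_sd": 0.0}


@dataclass
class RunConfig:
    """All knobs of one screen run.  Seeds are per stage so stages can be
    re-randomized independently."""

    n_designs: int = 2175
    grid_rows: int = 66
    grid_cols: int = 66
    resolution: float = 0.5
    mfi_cutoff: float = 270.0
    library_seed: int = 1
    layout_seed: int = 1
    sim_seed: int = 1
    split_seed: int = 1
    tree_seed: int = 1
    # hit selection for the modelled metric
    hit_metric: str = "pct_pos"
    k_top: float = 2.0
    bottom_quantile: float | None = 0.25
    k_bottom: float | None = None
    # tree hyperparameters
    min_leaf: int = 8
    max_depth: int = 5
    cv_folds: int = 10
    r2_max: float = 0.75
    train_frac: float = 0.75
    # planted model: None -> package default
    planted_model_path: str | None = None
    # image mode
    images: bool = False
    image_units: int = 200
    noise_sd: float = 10.0
    out_dir: str = "toposcreen_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_planted_model(config: RunConfig) -> sim.PlantedModel:
    if config.planted_model_path is None:
        return sim.default_planted_model()
    path = Path(config.planted_model_path)
    if not path.exists():
        raise FileNotFoundError(f"planted-model file not found: {path}")
    return sim.PlantedModel.from_json(path)


def build_feature_table(descriptor_table: pd.DataFrame) -> pd.DataFrame:
    """Impute absent descriptor values with their sentinels (see
    :data:`ABSENT_SENTINELS`) so trees can route every design."""
    out = descriptor_table.copy()
    for col, sentinel in ABSENT_SENTINELS.items():
        if col in out.columns:
            out[col] = out[col].fillna(sentinel)
    return out


def units_from_cells(cells: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Table mode: classify and summarize the simulator's cell table."""
    classified = morpho.classify_tgm1(cells, cutoff=cutoff)
    return morpho.summarize_units(classified)


def units_from_images(cells: pd.DataFrame, masks: dict[str, lib.UnitMask],
                      cutoff: float, noise_sd: float,
                      seed: int) -> pd.DataFrame:
    """Image mode: render each unit, segment, measure, classify, summarize."""
    rows = []
    for (row, col, design_id), grp in cells.groupby(["row", "col", "design_id"]):
        stack = sim.render_unit(grp, masks[design_id], noise_sd=noise_sd,
                                seed=[seed, int(row), int(col)])
        measured = morpho.analyze_stack(stack, cutoff=cutoff)
        rec = {"row": row, "col": col, "design_id": design_id}
        rec.update(morpho.summarize_unit(measured))
        rows.append(rec)
    return pd.DataFrame(rows, columns=["row", "col", "design_id",
                                       *morpho.SUMMARY_COLUMNS])


def model_stage(
    descriptor_table: pd.DataFrame,
    labels: pd.DataFrame,
    planted: sim.PlantedModel,
    config: RunConfig,
) -> tuple[tree_mod.TreeModel, dict]:
    """Feature filtering, split, tree induction and held-out evaluation."""
    features = build_feature_table(descriptor_table)
    label_ser = labels.set_index("design_id")["label"]
    features = features.loc[label_ser.index]
    reduced, drop_log = tree_mod.filter_correlated(features, r2_max=config.r2_max)
    train_idx, test_idx = tree_mod.split_train_test(
        reduced, label_ser, frac=config.train_frac, seed=config.split_seed)
    model = tree_mod.fit_tree(
        reduced.loc[train_idx], label_ser.loc[train_idx],
        min_leaf=config.min_leaf, max_depth=config.max_depth,
        cv_folds=config.cv_folds, seed=config.tree_seed)
    scores = tree_mod.predict(model, reduced.loc[test_idx])
    roc = tree_mod.roc_auc(scores, label_ser.loc[test_idx])
    recovery = tree_mod.evaluate_recovery(model, planted.feature_names(),
                                          auc=roc["auc"])
    report = {
        "retained_features": list(reduced.columns),
        "dropped_features": drop_log,
        "n_train": int(len(train_idx)),
        "n_test": int(len(test_idx)),
        "train_ids": sorted(map(str, train_idx)),
        "test_ids": sorted(map(str, test_idx)),
        "cp": model.cp,
        "n_leaves": model.n_leaves(),
        "auc": roc["auc"],
        "roc": {"fpr": roc["fpr"], "tpr": roc["tpr"]},
        "recovery": recovery,
    }
    return model, report


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    planted = load_planted_model(config)  # validate config before any compute
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    library = lib.generate_library(config.n_designs, seed=config.library_seed)
    lib.write_designs(library, out / "lib.json")

    descriptor_table = desc.library_descriptors(
        library, resolution=config.resolution, seed=config.library_seed)
    descriptor_table.to_csv(out / "features.csv")

    layout = lib.layout_chip(library, rows=config.grid_rows,
                             cols=config.grid_cols, seed=config.layout_seed)
    cells, truth = sim.simulate_screen(library, layout, planted,
                                       seed=config.sim_seed,
                                       descriptors=descriptor_table)
    truth_cols = ["true_diff", "true_morph"]
    cells.drop(columns=truth_cols).to_csv(out / "cells.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)

    if config.images:
        sub_units = truth[["row", "col", "design_id"]].head(config.image_units)
        keys = set(map(tuple, sub_units.to_numpy()))
        sub_cells = cells[[tuple(k) in keys for k in
                           zip(cells["row"], cells["col"], cells["design_id"])]]
        masks = {d: lib.rasterize(next(x for x in library if x.design_id == d),
                                  config.resolution)
                 for d in sub_units["design_id"].unique()}
        units = units_from_images(sub_cells, masks, config.mfi_cutoff,
                                  config.noise_sd, config.sim_seed)
    else:
        units = units_from_cells(cells, config.mfi_cutoff)
    units.to_csv(out / "units.csv", index=False)

    hit_result = hits_mod.select_hits(
        units, config.hit_metric, k_top=config.k_top,
        k_bottom=config.k_bottom, bottom_quantile=config.bottom_quantile)
    hit_result.table.to_csv(out / "hits.csv", index=False)
    labels = hits_mod.make_labels(hit_result, hit_result)
    labels.to_csv(out / "labels.csv", index=False)

    model, report = model_stage(descriptor_table, labels, planted, config)
    model.to_json(out / "model.json")
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    pd.DataFrame({"fpr": report["roc"]["fpr"],
                  "tpr": report["roc"]["tpr"]}).to_csv(out / "roc.csv",
                                                       index=False)

    artifacts = ["lib.json", "features.csv", "cells.csv", "truth.csv",
                 "units.csv", "hits.csv", "labels.csv", "model.json",
                 "report.json", "roc.csv"]
    manifest = {
        "config": dataclasses.asdict(config),
        "hashes": {name: _sha256(out / name) for name in artifacts},
        "hit_counts": {k: int(v) for k, v in hit_result.counts.items()},
        "recovery": report["recovery"],
        "auc": report["auc"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest


def recovery_experiment(
    n_seeds: int = 20,
    base_seed: int = 1,
    config: RunConfig | None = None,
    library=None,
    descriptor_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Repeat the screen's stochastic stages over ``n_seeds`` seeds.

    The library and its descriptors are deterministic given the config, so
    they are computed once and shared; layout, simulation, splitting and tree
    induction are re-randomized per seed.  Returns one row per seed with the
    recovery verdict and held-out AUC.
    """
    config = config or RunConfig()
    planted = load_planted_model(config)
    if library is None:
        library = lib.generate_library(config.n_designs, seed=config.library_seed)
    if descriptor_table is None:
        descriptor_table = desc.library_descriptors(
            library, resolution=config.resolution, seed=config.library_seed)
    rows = []
    for i in range(n_seeds):
        seed = base_seed + i
        layout = lib.layout_chip(library, rows=config.grid_rows,
                                 cols=config.grid_cols, seed=seed)
        cells, _ = sim.simulate_screen(library, layout, planted, seed=seed,
                                       descriptors=descriptor_table)
        units = units_from_cells(cells, config.mfi_cutoff)
        hit_result = hits_mod.select_hits(
            units, config.hit_metric, k_top=config.k_top,
            k_bottom=config.k_bottom, bottom_quantile=config.bottom_quantile)
        labels = hits_mod.make_labels(hit_result, hit_result)
        run_cfg = dataclasses.replace(config, split_seed=seed, tree_seed=seed)
        _, report = model_stage(descriptor_table, labels, planted, run_cfg)
        rows.append({
            "seed": seed,
            "auc": report["auc"],
            "recovered": report["recovery"]["recovered"],
            "top_level_features": ",".join(report["recovery"]["top_level_features"]),
            "n_high": int((labels["label"] == "high").sum()),
            "n_low": int((labels["label"] == "low").sum()),
        })
    return pd.DataFrame(rows)


def plot_roc(report: dict, path: str | Path) -> None:
    """Static ROC plot of a model report."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(report["roc"]["fpr"], report["roc"]["tpr"], lw=2,
            label=f"AUC = {report['auc']:.2f}")
    ax.plot([0, 1], [0, 1], "k--", lw=1)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
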