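"""Reproducible end-to-end runs: config, stage orchestration, manifest, report.

A run executes simulate -> preprocess -> unmix -> stats -> train -> evaluate in
order, writing every artifact under one output directory and recording paths,
SHA-256 checksums and per-stage seeds in ``manifest.json``.  Stage seeds are
derived from the global seed by a counter scheme: stage i uses
``SeedSequence([global_seed, i])``, so archived config + seed reproduces all
outputs bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, io as hsio, preprocess, simulate, stats
from .exceptions import DependencyError
from .spectral import FLUOROPHORES, WavelengthGrid, build_synthetic_basis, unmix_many

__all__ = ["RunConfig", "run_pipeline", "make_report", "stage_seed", "DEFAULT_STAGES"]

DEFAULT_STAGES = ("simulate", "preprocess", "unmix", "stats", "train", "evaluate")

logger = logging.getLogger("hsfluor")


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    task: str = "margin"
    delta: float = 1.0
    seed: int = 0
    outdir: str = "hsfluor_run"
    stages: tuple[str, ...] = DEFAULT_STAGES
    n_biopsies_per_class: int | None = 8
    n_cubes: int = 1
    cube_field_px: int = 352
    cube_grid_step_nm: float = 5.0
    pixels_per_sample: int = 1
    samples_per_class: int | str = 300
    grid: str = "compact"  # "compact" or "table1"
    group_split_by_biopsy: bool = False
    format_version: str = "1"

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        payload["stages"] = tuple(payload.get("stages", DEFAULT_STAGES))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def stage_seed(global_seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    return int(np.random.SeedSequence([global_seed, stage_index]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _setup_logging(outdir: Path) -> None:
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        logger.setLevel(logging.INFO)
        logger.addHandler(logging.StreamHandler())
    for h in [h for h in logger.handlers if isinstance(h, logging.FileHandler)]:
        logger.removeHandler(h)
        h.close()
    fh = logging.FileHandler(outdir / "pipeline.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(fh)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns (and writes) the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    config.to_yaml(outdir / "config.yaml")
    manifest: dict = {"config": str(outdir / "config.yaml"), "stages": {}}
    state: dict = {}

    runners = {
        "simulate": _stage_simulate,
        "preprocess": _stage_preprocess,
        "unmix": _stage_unmix,
        "stats": _stage_stats,
        "train": _stage_train,
        "evaluate": _stage_evaluate,
    }
    for name in config.stages:
        if name not in runners:
            raise ValueError(f"unknown stage {name!r}")
        idx = DEFAULT_STAGES.index(name)
        seed = stage_seed(config.seed, idx)
        t0 = time.perf_counter()
        logger.info("stage %s (seed %d) ...", name, seed)
        artifacts = runners[name](config, outdir, seed, state)
        dt = time.perf_counter() - t0
        manifest["stages"][name] = {
            "seed": seed,
            "elapsed_s": round(dt, 3),
            "artifacts": {
                key: {"path": str(p), "sha256": _sha256(Path(p))}
                for key, p in artifacts.items()
            },
        }
        logger.info("stage %s done in %.2fs", name, dt)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _require(state: dict, key: str, stage: str, needed_by: str):
    if key not in state:
        raise DependencyError(
            f"stage {needed_by!r} requires output of stage {stage!r}, which has not run"
        )
    return state[key]


def _coarse_basis(config: RunConfig):
    grid = WavelengthGrid.from_step(420.0, 729.0, config.cube_grid_step_nm)
    return build_synthetic_basis(grid)


def _stage_simulate(config, outdir, seed, state):
    ds = simulate.simulate_dataset(
        config.task, n_biopsies_per_class=config.n_biopsies_per_class,
        seed=seed, delta=config.delta,
    )
    dataset_path = outdir / "dataset.csv"
    ds.to_csv(dataset_path)
    manifest_path = outdir / "dataset_manifest.csv"
    ds.manifest().to_csv(manifest_path, index=False)
    state["dataset"] = ds
    artifacts = {"dataset": dataset_path, "dataset_manifest": manifest_path}

    basis = _coarse_basis(config)
    profiles = simulate.class_profiles(config.task, delta=config.delta)
    cube_dir = outdir / "cubes"
    state["cube_stems"] = []
    for i in range(config.n_cubes):
        profile = profiles[i % len(profiles)]
        phantom = simulate.make_phantom(
            f"CUBE{i:02d}", profile,
            diameter_px=min(288.0, config.cube_field_px - 8.0), seed=seed + i,
            field_shape=(config.cube_field_px, config.cube_field_px),
        )
        triplet = simulate.simulate_biopsy_cube(phantom, basis, seed=seed + 100 + i)
        paths = hsio.write_cube_triplet(
            triplet, cube_dir, phantom.biopsy_id, seed=seed + i, labels=phantom.labels
        )
        state["cube_stems"].append(phantom.biopsy_id)
        for phase, p in paths.items():
            artifacts[f"{phantom.biopsy_id}_{phase}"] = p
    state["cube_dir"] = cube_dir
    return artifacts


def _stage_preprocess(config, outdir, seed, state):
    cube_dir = state.get("cube_dir", Path(outdir) / "cubes")
    stems = state.get("cube_stems")
    if stems is None:
        if not cube_dir.exists():
            raise DependencyError(
                "stage 'preprocess' requires cubes from stage 'simulate', which has not run"
            )
        stems = sorted({p.name.rsplit("_", 1)[0] for p in cube_dir.glob("*_blue.tif")})
    artifacts = {}
    state["block_spectra"] = {}
    for stem in stems:
        blue, dark, white = hsio.read_cube_triplet(cube_dir, stem)
        blocks = preprocess.preprocess_triplet(blue, dark, white)
        path = outdir / f"block_spectra_{stem}.csv"
        hsio.write_block_spectra_csv(blocks, path, biopsy_id=stem)
        state["block_spectra"][stem] = blocks
        artifacts[stem] = path
    return artifacts


def _stage_unmix(config, outdir, seed, state):
    blocks_by_stem = _require(state, "block_spectra", "preprocess", "unmix")
    artifacts = {}
    frames = []
    for stem, blocks in blocks_by_stem.items():
        basis = _coarse_basis(config)
        if blocks.grid != basis.grid:
            basis = build_synthetic_basis(blocks.grid)
        ab, resid = unmix_many(blocks.values, basis)
        frame = pd.DataFrame(ab, columns=[f"c_{n}" for n in FLUOROPHORES])
        frame.insert(0, "biopsy_id", stem)
        frame["residual_norm"] = resid
        frames.append(frame)
    path = outdir / "cube_abundances.csv"
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.9g")
    artifacts["cube_abundances"] = path
    return artifacts


def _stage_stats(config, outdir, seed, state):
    ds = _require(state, "dataset", "simulate", "stats")
    ab = ds.abundances()
    ve = {}
    for n in range(2, 6):
        ve[n] = stats.pca_variance_explained(ab, n).variance_explained
    pca_path = outdir / "pca_variance_explained.json"
    pca_path.write_text(json.dumps(
        {str(n): round(100.0 * v, 3) for n, v in ve.items()}, indent=1, sort_keys=True
    ))
    report = stats.ks_battery(ab, ds.blocks["label"].to_numpy(), task=ds.task)
    ks_path = outdir / "ks_battery.csv"
    stats.ks_report_frame(report).to_csv(ks_path, index=False, float_format="%.6g")
    state["ks_report"] = report
    state["pca_variance_explained"] = ve
    return {"pca": pca_path, "ks": ks_path}


def _stage_train(config, outdir, seed, state):
    ds = _require(state, "dataset", "simulate", "train")
    table = classify.build_feature_table(
        ds, pixels_per_sample=config.pixels_per_sample,
        samples_per_class=config.samples_per_class, seed=seed,
    )
    train, test = classify.split_train_test(
        table, seed=seed, group_by_biopsy=config.group_split_by_biopsy
    )
    grids = classify.table1_grids() if config.grid == "table1" else classify.compact_grids()
    ranked = classify.cross_validate_grid(train, grids, seed=seed)
    rank_path = outdir / "cv_ranking.csv"
    pd.DataFrame(
        [dict(model=e.spec.describe(), mean_cv_accuracy=e.mean_cv_accuracy,
              std_cv_accuracy=e.std_cv_accuracy) for e in ranked]
    ).to_csv(rank_path, index=False, float_format="%.6g")
    model = classify.select_and_fit(train, ranked, seed=seed)
    state.update(model=model, train=train, test=test, best=ranked[0])
    best_path = outdir / "best_model.json"
    best_path.write_text(json.dumps(
        {"model": ranked[0].spec.describe(),
         "mean_cv_accuracy": ranked[0].mean_cv_accuracy,
         "included_classes": list(table.included_classes),
         "excluded_classes": list(table.excluded_classes)},
        indent=1, sort_keys=True,
    ))
    return {"cv_ranking": rank_path, "best_model": best_path}


def _stage_evaluate(config, outdir, seed, state):
    model = _require(state, "model", "train", "evaluate")
    report = classify.evaluate(
        model, state["test"], model_desc=state["best"].spec.describe(), split_seed=seed
    )
    path = outdir / "evaluation_report.json"
    path.write_text(json.dumps(report.to_json_dict(), indent=1, sort_keys=True))
    roc_path = outdir / "roc_points.csv"
    rows = []
    for cls, (fpr, tpr) in report.roc_curves.items():
        for f, t in zip(fpr, tpr):
            rows.append(dict(class_label=cls, fpr=f, tpr=t))
    pd.DataFrame(rows).to_csv(roc_path, index=False, float_format="%.6g")
    state["evaluation"] = report
    return {"evaluation_report": path, "roc_points": roc_path}


def make_report(manifest: dict | str | Path, outdir: str | Path | None = None) -> Path:
    """Render a static report (markdown + figures) from a run's artifacts.

    Figures: confusion matrix, per-class ROC, 2-component PCA scatter of the
    dataset abundances and a PpIX634 abundance overlay of the first simulated
    cube; plus the KS exception table (or a statement that all pairs were
    significant).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    run_dir = Path(manifest["config"]).parent
    report_dir = Path(outdir) if outdir is not None else run_dir / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    lines = ["# Pipeline run report", ""]

    eval_art = manifest["stages"].get("evaluate", {}).get("artifacts", {})
    if "evaluation_report" in eval_art:
        rep = json.loads(Path(eval_art["evaluation_report"]["path"]).read_text())
        classes = rep["classes"]
        cm = np.array(rep["confusion_matrix"])
        fig, ax = plt.subplots(figsize=(4.5, 4))
        im = ax.imshow(cm, cmap="Blues")
        ax.set_xticks(range(len(classes)), classes, rotation=45, ha="right")
        ax.set_yticks(range(len(classes)), classes)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        for i in range(cm.shape[0]):
            for j in range(cm.shape[1]):
                ax.text(j, i, str(cm[i, j]), ha="center", va="center", fontsize=8)
        fig.colorbar(im, shrink=0.8)
        fig.tight_layout()
        fig.savefig(report_dir / "confusion_matrix.png", dpi=120)
        plt.close(fig)
        lines += [f"Test accuracy: **{rep['accuracy']:.3f}**, macro AUC: "
                  f"**{rep['macro_auc']:.3f}** ({rep['model']})", "",
                  "![confusion](confusion_matrix.png)", ""]
        roc = pd.read_csv(eval_art["roc_points"]["path"])
        fig, ax = plt.subplots(figsize=(4.5, 4))
        for cls, grp in roc.groupby("class_label"):
            ax.plot(grp["fpr"], grp["tpr"],
                    label=f"{cls} (AUC {rep['auc_per_class'].get(str(cls), float('nan')):.2f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(report_dir / "roc.png", dpi=120)
        plt.close(fig)
        lines += ["![roc](roc.png)", ""]

    stats_art = manifest["stages"].get("stats", {}).get("artifacts", {})
    if "ks" in stats_art:
        ks = pd.read_csv(stats_art["ks"]["path"])
        exceptions = ks[~ks["significant"]]
        if len(exceptions) == 0:
            lines += ["All class pairs were significantly different for all "
                      "fluorophores (p < 0.01).", ""]
        else:
            lines += ["KS exceptions (pairs not significant at alpha):", "",
                      exceptions.to_string(index=False), ""]
    if "pca" in stats_art:
        ve = json.loads(Path(stats_art["pca"]["path"]).read_text())
        lines += ["PCA variance explained (%) by component count: "
                  + ", ".join(f"n={k}: {v}" for k, v in sorted(ve.items())), ""]

    sim_art = manifest["stages"].get("simulate", {}).get("artifacts", {})
    if "dataset" in sim_art:
        ds = pd.read_csv(sim_art["dataset"]["path"])
        ab_cols = [f"c_{n}" for n in FLUOROPHORES]
        res = stats.pca_variance_explained(ds[ab_cols].to_numpy(), 2)
        proj = res.transform(ds[ab_cols].to_numpy())
        fig, ax = plt.subplots(figsize=(4.5, 4))
        for cls, grp in pd.DataFrame(
            dict(x=proj[:, 0], y=proj[:, 1], label=ds["label"])
        ).groupby("label"):
            ax.scatter(grp["x"], grp["y"], s=2, alpha=0.4, label=cls)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend(fontsize=7, markerscale=3)
        fig.tight_layout()
        fig.savefig(report_dir / "pca_scatter.png", dpi=120)
        plt.close(fig)
        lines += ["![pca](pca_scatter.png)", ""]

    # PpIX634 abundance overlay of the first simulated cube
    blue_arts = sorted(k for k in sim_art if k.endswith("_blue"))
    if blue_arts:
        stem = blue_arts[0][: -len("_blue")]
        cube_dir = Path(sim_art[blue_arts[0]]["path"]).parent
        blue, dark, white = hsio.read_cube_triplet(cube_dir, stem)
        corrected = preprocess.dark_correct(blue, dark)
        mask = preprocess.segment_tumor(corrected)
        blocks = preprocess.extract_block_spectra(corrected, mask)
        basis = build_synthetic_basis(blocks.grid)
        ab, _ = unmix_many(blocks.values, basis)
        overlay = np.full(mask.mask.shape, np.nan)
        ppix = ab[:, list(FLUOROPHORES).index("PpIX634")]
        for (r, c), v in zip(blocks.block_origin, ppix):
            overlay[r : r + blocks.block_size, c : c + blocks.block_size] = v
        fig, ax = plt.subplots(figsize=(4.5, 4))
        ax.imshow(corrected.band_image(634.0), cmap="gray")
        im = ax.imshow(overlay, cmap="inferno", alpha=0.7)
        fig.colorbar(im, shrink=0.8, label="PpIX634 abundance")
        ax.set_axis_off()
        fig.tight_layout()
        fig.savefig(report_dir / "ppix_overlay.png", dpi=120)
        plt.close(fig)
        lines += ["![overlay](ppix_overlay.png)", ""]

    report_path = report_dir / "report.md"
    report_path.write_text("\n".join(lines))
    return report_path
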