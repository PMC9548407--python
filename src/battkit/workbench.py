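"""Orchestration: run the whole battery analysis end-to-end and report.

A :class:`RunConfig` (usually loaded from YAML) names either a synthetic
preset or user-supplied delimited-text tables, and fixes every analysis
knob plus one master seed.  :func:`run_pipeline` executes the stages in
order — standardise, cross-validated component count, varimax PCA, factor
scores, leave-one-out generalisability, proxy selection and item halving,
reduced-battery rescoring and matching, normative comparison, and (when
lesion data are present) VBCM and RVR — writing every artefact and a
machine-readable manifest into a run directory.  Rerunning with the same
config and seed reproduces all numeric outputs.

The delimited-text dialect is fixed: comma separator, UTF-8, "." decimal,
"NA" for missing; tables carry one header row and an ID column.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dimension as dim
from . import lesionmap as lm
from . import normcompare as nc
from . import reduction as red
from . import synthgen as sg

logger = logging.getLogger("battkit")

__all__ = ["RunConfig", "load_tables", "run_pipeline", "make_report", "child_seed"]


def child_seed(master: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) from the master seed.

    Stages can thereby be rerun in isolation with the same randomness as in
    the full pipeline.
    """
    tag = zlib.crc32(stage.encode("utf-8"))  # stable across processes
    ss = np.random.SeedSequence([int(master), int(tag)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    preset: str | None = "extensive"        # synthetic preset, or None
    scores_path: str | None = None          # user score table (CSV)
    controls_path: str | None = None
    n_patients: int = 75
    n_controls: int = 30
    n_factors: int = 4
    folds: int = 5
    k_max: int | None = None
    cutoff_k: float = 2.0
    reduction: red.ReductionSpec = field(default_factory=red.ReductionSpec)
    run_lesions: bool = True
    grid_shape: tuple[int, int, int] = (14, 14, 14)
    vbcm_n_perm: int = 500
    rvr_n_perm: int = 100
    seed: int = 0
    out_dir: str = "battkit_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        redspec = red.ReductionSpec(**raw.pop("reduction", {}))
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        cfg = cls(**raw, reduction=redspec)
        for p in (cfg.scores_path, cfg.controls_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d


def load_tables(path) -> dim.ScoreMatrix:
    """Read a delimited score table (header row + patient-ID column).

    Unparseable cells become missing, with a logged count; duplicate IDs or
    a table without numeric columns are errors.
    """
    df = pd.read_csv(path, index_col=0, na_values=["NA"],
                     float_precision="round_trip")
    if df.index.duplicated().any():
        raise ValueError(f"duplicate patient IDs in {path}")
    num = df.apply(pd.to_numeric, errors="coerce")
    n_bad = int((num.isna() & df.notna()).sum().sum())
    if n_bad:
        logger.warning("%d unparseable cells in %s set to missing", n_bad, path)
    if num.shape[1] == 0 or num.isna().all().all():
        raise ValueError(f"no numeric columns in {path}")
    return dim.ScoreMatrix.from_frame(num)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    return _Ctx()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}

    with _stage("inputs"):
        if config.preset is not None:
            spec = (sg.extensive_battery_preset() if config.preset == "extensive"
                    else sg.shallow_battery_preset())
            latent, scores, items = sg.simulate_cohort(
                spec, config.n_patients, config.n_factors,
                child_seed(config.seed, "cohort"))
            controls = sg.simulate_controls(spec, config.n_controls,
                                            child_seed(config.seed, "controls"))
        else:
            scores = load_tables(config.scores_path)
            controls = load_tables(config.controls_path) if config.controls_path else None
            latent, items = None, {}
        scores.write_csv(out / "scores.csv")
        if controls is not None:
            controls.write_csv(out / "controls.csv")

    with _stage("dimension"):
        z = dim.standardize(scores)
        z.values = dim.impute_test_means(z.values)
        curve = dim.crossval_component_count(
            scores, folds=config.folds, k_max=config.k_max,
            seed=child_seed(config.seed, "cv"))
        model = dim.fit_rotated_pca(z, curve.k_selected)
        comp = dim.component_scores(model, z)
        loo_r = dim.loo_generalizability(scores, curve.k_selected)
        model.loading_frame().to_csv(out / "loadings.csv")
        comp.to_frame().to_csv(out / "component_scores.csv")
        pd.Series(curve.rmse_by_k, name="rmse").rename_axis("k").to_csv(out / "cv_curve.csv")
        manifest["stages"]["dimension"] = {
            "k_selected": curve.k_selected,
            "loo_generalizability_r": loo_r,
            "variance_explained_pct": [float(v) for v in model.variance_explained],
        }

    reduced_info: dict = {}
    if items:
        with _stage("reduction"):
            proxies = red.select_proxy_tests(model, config.reduction)
            retained: dict[str, list[str]] = {}
            manifests = []
            for tests in proxies.values():
                for t in tests:
                    irm = items[t]
                    if irm.n_items > config.reduction.long_test_threshold:
                        ids, man = red.reduce_items(irm, config.reduction)
                        retained[t] = ids
                        manifests.append(man)
            reduced_scores = red.score_reduced_battery(items, retained, proxies)
            if manifests:
                pd.concat(manifests).to_csv(out / "item_manifest.csv", index=False)
            reduced_scores.write_csv(out / "reduced_scores.csv")
            z_red = dim.standardize(reduced_scores)
            z_red.values = dim.impute_test_means(z_red.values)
            model_red = dim.fit_rotated_pca(z_red, min(curve.k_selected,
                                                       reduced_scores.n_tests - 1))
            comp_red = dim.component_scores(model_red, z_red)
            matching, cm = dim.match_components(comp, comp_red)
            cm.to_csv(out / "component_matching.csv")
            reduced_info = {
                "proxies": proxies,
                "matched_abs_r": {f"{a}~{b}": abs(r) for a, b, r in matching},
            }
            manifest["stages"]["reduction"] = reduced_info

    if config.preset is not None and controls is not None:
        with _stage("normcompare"):
            cutoffs = nc.cutoffs_from_controls(controls, k=config.cutoff_k)
            flags = nc.classify_impairment(scores, cutoffs)
            flags.to_csv(out / "impairment_flags.csv", na_rep="NA")
            manifest["stages"]["normcompare"] = {
                "pct_impaired_mean": float(np.nanmean(flags.to_numpy()) * 100)}

    if config.run_lesions and latent is not None:
        with _stage("lesionmap"):
            atlas = sg.default_atlas(config.grid_shape, config.n_factors)
            vols, lesion_vol = sg.simulate_abnormality(
                latent, atlas, child_seed(config.seed, "lesions"))
            mask = lm.build_mask(vols)
            lm.save_volume(mask.mask.astype(float), out / "analysis_mask.nii")
            maps = lm.vbcm(vols, comp, n_perm=config.vbcm_n_perm,
                           seed=child_seed(config.seed, "vbcm"), mask=mask)
            rows = []
            for comp_name, sm in maps.items():
                for c in sm.clusters:
                    rows.append({"component": comp_name, **{k: v for k, v in c.items()
                                                            if k != "peak_voxel"},
                                 "peak_x": c["peak_voxel"][0],
                                 "peak_y": c["peak_voxel"][1],
                                 "peak_z": c["peak_voxel"][2]})
            pd.DataFrame(rows).to_csv(out / "cluster_table.csv", index=False)
            feats = lm.volumes_to_matrix(vols, mask.mask)
            rvr_rows = []
            for ci, comp_name in enumerate(comp.component_names):
                fit = lm.rvr_predict_loocv(feats, comp.values[:, ci],
                                           n_perm=config.rvr_n_perm,
                                           seed=child_seed(config.seed, f"rvr{ci}"))
                rvr_rows.append({"component": comp_name, "cv_r": fit.cv_r,
                                 "permutation_p": fit.permutation_p})
            pd.DataFrame(rvr_rows).to_csv(out / "rvr_table.csv", index=False)
            manifest["stages"]["lesionmap"] = {
                "mask_voxels": mask.n_voxels,
                "n_clusters": len(rows),
                "mean_lesion_volume": float(lesion_vol.mean()),
            }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def make_report(run_dir) -> str:
    """Assemble a human-readable summary of a completed run."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {run_dir}; run the pipeline first")
    manifest = json.loads(manifest_path.read_text())
    lines = ["# Battery analysis report", ""]

    def section(title, filename, formatter=None):
        lines.append(f"## {title}")
        path = run_dir / filename
        if not path.exists():
            lines.append("_not run_")
        else:
            df = pd.read_csv(path)
            lines.append(df.round(3).to_string(index=False) if formatter is None
                         else formatter(df))
        lines.append("")

    dim_info = manifest["stages"].get("dimension", {})
    lines.append(f"Selected components: {dim_info.get('k_selected', 'n/a')}; "
                 f"LOO generalisability r = "
                 f"{round(dim_info.get('loo_generalizability_r', float('nan')), 3)}")
    lines.append("")
    section("Component loadings", "loadings.csv")
    section("Reduced vs full battery component correlations", "component_matching.csv")
    section("Impairment flags (head)", "impairment_flags.csv",
            lambda df: df.head(10).to_string(index=False))
    section("VBCM cluster table", "cluster_table.csv")
    section("RVR cross-validated prediction", "rvr_table.csv")
    text = "\n".join(lines)
    (run_dir / "report.md").write_text(text)
    return text
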