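"""Orchestration of the full workflow: simulate -> design/calibrate ->
predict -> phenotype / QTL.

A run is driven by a :class:`PipelineConfig` (YAML on disk), a single global
seed, and an output directory.  The global seed fans out to per-stage seeds
by hashing ``"<seed>:<stage>"``, so any stage can be rerun in isolation and
still reproduce.  Every output file is listed in a JSON manifest with its
SHA-256 hash; rerunning the same config and seed reproduces identical
hashes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemometrics as chem
from . import io as nio
from . import synthetic as syn
from .phenotype import variance_components
from .preprocess import PreprocessConfig, msc_apply, msc_fit, preprocess
from .qtl import ScanConfig, map_qtl
from .quality import CalibrationReport, build_report, reports_to_table
from .selection import SelectionPlan, rank_split, select_diverse, select_extremes

__all__ = [
    "PipelineConfig",
    "DesignConfig",
    "develop_calibration",
    "run_pipeline",
    "make_table1",
    "make_table2",
    "stage_seed",
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) from the global seed and stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class DesignConfig:
    """Calibration-set design settings (diversity + extremes + 3:1 split)."""

    n_diverse: int = 100
    n_extreme: int = 48
    pca_components: int = 3
    pca_axes: tuple[int, int] = (1, 3)
    split_ratio: tuple[int, int] = (3, 1)
    preliminary_max_factors: int = 10


_ALLOWED_KEYS = {
    "seed",
    "outdir",
    "simulate",
    "preprocess",
    "design",
    "calibrate",
    "predict",
    "phenotype",
    "qtl",
    "inputs",
}
_ALLOWED = {
    "simulate": {"n_samples", "n_lines", "oil_protein_corr", "noise_sd",
                 "scatter_slope_sd", "scatter_offset_sd"},
    "preprocess": {"msc", "derivative", "windows"},
    "design": {"n_diverse", "n_extreme", "pca_components", "pca_axes",
               "split_ratio", "preliminary_max_factors"},
    "calibrate": {"components", "max_factors", "sep_convention"},
    "predict": set(),
    "phenotype": {"n_genotypes", "n_cultures", "n_replicates", "genotype_sd",
                  "culture_sd", "interaction_sd", "residual_sd"},
    "qtl": {"trait", "qtl_spec", "residual_sd", "n_lines", "step",
            "n_permutations", "alpha", "cofactor_window", "lod_drop"},
    "inputs": {"spectra", "reference", "map", "genotypes", "phenotypes"},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    outdir: str = "nirseed_run"
    simulate: dict | None = None
    preprocess: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)
    calibrate: dict = field(default_factory=dict)
    predict: dict = field(default_factory=dict)
    phenotype: dict | None = None
    qtl: dict | None = None
    inputs: dict | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for block, allowed in _ALLOWED.items():
            sub = d.get(block)
            if isinstance(sub, dict):
                bad = set(sub) - allowed
                if bad:
                    raise ValueError(f"unknown keys in '{block}': {sorted(bad)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def develop_calibration(
    spectra: nio.SpectraSet,
    refs: nio.ReferenceTable,
    component: str,
    design: DesignConfig = DesignConfig(),
    preprocess_cfg: PreprocessConfig = PreprocessConfig(),
    max_factors: int = 10,
    sep_convention: str = "bias-corrected",
) -> dict:
    """Full calibration development for one component.

    1. PCA on MSC-corrected (non-derivative) spectra of the whole pool;
       greedy max--min selection of ``n_diverse`` samples on the PC1/PC3
       plane.
    2. A preliminary PLS model on the diverse samples predicts the whole
       pool; ``n_extreme`` samples with extreme predictions extend the
       concentration range.
    3. The combined set is rank-split 3:1 into calibration and validation.
    4. The final model is calibrated with leave-one-out PRESS factor
       selection and externally validated.

    Returns a dict with the fitted model, the selection plan, the PRESS
    curve and the :class:`CalibrationReport`.
    """
    # -- 1: spectral-diversity selection in PC space
    ref_msc = msc_fit(spectra)
    corrected = nio.SpectraSet(
        spectra.grid,
        msc_apply(spectra.absorbance, ref_msc),
        list(spectra.sample_ids),
    )
    pca = chem.pca_fit(corrected, design.pca_components)
    diverse = select_diverse(
        pca.scores, spectra.sample_ids, design.pca_axes, design.n_diverse
    )
    # -- 2: preliminary model -> extremes
    ref_vals = refs.values_for(component)
    div_with_ref = [s for s in diverse if s in ref_vals.index]
    prelim_set = spectra.subset(div_with_ref)
    y_prelim = ref_vals.loc[div_with_ref].to_numpy(float)
    curve0 = chem.loo_press(
        prelim_set, y_prelim,
        min(design.preliminary_max_factors, len(div_with_ref) - 2),
        preprocess_cfg,
    )
    k0 = chem.select_factors(curve0)
    pp0, msc0 = preprocess(prelim_set, preprocess_cfg)
    prelim = chem.pls_fit(
        pp0.absorbance, y_prelim, k0,
        preprocess_config=preprocess_cfg, msc_ref=msc0,
        training_ids=div_with_ref, component=component,
    )
    pool_pred = pd.Series(
        chem.pls_predict(prelim, spectra), index=spectra.sample_ids
    )
    candidates = pool_pred[[s in ref_vals.index for s in pool_pred.index]]
    extremes = select_extremes(candidates, design.n_extreme, exclude=diverse)
    # -- 3: ranked 3:1 split on reference values
    chosen = div_with_ref + extremes
    split_values = ref_vals.loc[chosen]
    cal_ids, val_ids = rank_split(split_values, design.split_ratio)
    plan = SelectionPlan(diverse, extremes, cal_ids, val_ids, design.pca_axes)
    # -- 4: final calibration + external validation
    cal_set = spectra.subset(cal_ids)
    y_cal = ref_vals.loc[cal_ids].to_numpy(float)
    curve = chem.loo_press(
        cal_set, y_cal, min(max_factors, len(cal_ids) - 2), preprocess_cfg
    )
    k = chem.select_factors(curve)
    pp, msc_ref_final = preprocess(cal_set, preprocess_cfg)
    model = chem.pls_fit(
        pp.absorbance, y_cal, k,
        preprocess_config=preprocess_cfg, msc_ref=msc_ref_final,
        training_ids=cal_ids, component=component,
    )
    cal_pred = chem.pls_predict(model, cal_set)
    val_set = spectra.subset(val_ids)
    y_val = ref_vals.loc[val_ids].to_numpy(float)
    val_pred = chem.pls_predict(model, val_set)
    report = build_report(
        component, y_cal, cal_pred, k, curve.loo_residuals[:, k - 1],
        y_val, val_pred, sep_convention,
    )
    return {
        "model": model,
        "report": report,
        "plan": plan,
        "press": curve,
        "validation_predictions": pd.Series(val_pred, index=val_ids),
    }


def make_table1(reports) -> pd.DataFrame:
    """Combine per-component calibration reports into one summary table."""
    if not reports:
        raise ValueError("need at least one report")
    return reports_to_table(reports)


def make_table2(qtl_by_trait: dict) -> pd.DataFrame:
    """Combine per-trait QTL results, appending a per-trait R^2 totals row."""
    if not qtl_by_trait:
        raise ValueError("need at least one trait")
    rows = []
    for trait, results in qtl_by_trait.items():
        if not results:
            rows.append({"name": "no QTL detected", "trait": trait})
            continue
        for i, q in enumerate(results, start=1):
            rows.append(
                {
                    "name": f"{trait}.{i}",
                    "trait": trait,
                    "chr": q.chrom,
                    "position_cM": q.pos_cM,
                    "lod": q.lod,
                    "ci_lo": q.ci_lo,
                    "ci_hi": q.ci_hi,
                    "additive_effect": q.additive_effect,
                    "r2_pct": q.r2_pct,
                }
            )
        total = round(sum(q.r2_pct for q in results if q.r2_pct is not None), 1)
        rows.append({"name": f"{trait} total", "trait": trait, "r2_pct": total})
    cols = ["name", "trait", "chr", "position_cM", "lod", "ci_lo", "ci_hi",
            "additive_effect", "r2_pct"]
    return pd.DataFrame(rows).reindex(columns=cols)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages in dependency order; return the manifest.

    Stages: simulate (or load declared inputs), design + calibrate per
    component, predict the pool, phenotype variance decomposition, QTL
    mapping.  Aborts with the failing stage's name on error.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}

    def record(stage: str, *paths: Path):
        for p in paths:
            manifest["files"][str(p.relative_to(out))] = _sha256(p)
        manifest["stages"].setdefault(stage, []).extend(
            str(p.relative_to(out)) for p in paths
        )

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            manifest["error"] = {"stage": name, "message": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc

    # ---- acquire inputs
    if config.simulate is not None:
        def do_simulate():
            sim = config.simulate or {}
            seed = stage_seed(config.seed, "simulate")
            n = sim.get("n_samples", 500)
            refs, _ = syn.simulate_concentrations(
                n, oil_protein_corr=sim.get("oil_protein_corr",
                                            syn.DEFAULT_OIL_PROTEIN_CORR),
                seed=seed,
            )
            spectra, _ = syn.simulate_spectra(
                refs,
                noise_sd=sim.get("noise_sd", syn.DEFAULT_NOISE_SD),
                scatter_slope_sd=sim.get("scatter_slope_sd",
                                         syn.DEFAULT_SCATTER_SLOPE_SD),
                scatter_offset_sd=sim.get("scatter_offset_sd",
                                          syn.DEFAULT_SCATTER_OFFSET_SD),
                seed=stage_seed(config.seed, "simulate-spectra"),
            )
            nio.write_spectra(spectra, out / "spectra.csv")
            nio.write_reference(refs, out / "reference.csv")
            record("simulate", out / "spectra.csv", out / "reference.csv")
            return spectra, refs

        spectra, refs = run_stage("simulate", do_simulate)
    elif config.inputs:
        def do_load():
            return (
                nio.read_spectra(config.inputs["spectra"]),
                nio.read_reference(config.inputs["reference"]),
            )

        if "spectra" not in config.inputs or "reference" not in config.inputs:
            raise RuntimeError(
                "stage 'preflight' failed: no simulate block and inputs "
                "missing spectra/reference paths"
            )
        spectra, refs = run_stage("load", do_load)
    else:
        raise RuntimeError(
            "stage 'preflight' failed: config needs a simulate block or inputs"
        )

    # ---- design + calibrate + validate per component
    def do_calibrate():
        pre = PreprocessConfig.from_dict(config.preprocess) if config.preprocess else PreprocessConfig()
        design = DesignConfig(**config.design) if config.design else DesignConfig()
        comps = config.calibrate.get("components", list(nio.COMPONENTS))
        reports, models = [], {}
        for comp in comps:
            res = develop_calibration(
                spectra, refs, comp, design, pre,
                max_factors=config.calibrate.get("max_factors", 10),
                sep_convention=config.calibrate.get("sep_convention",
                                                    "bias-corrected"),
            )
            reports.append(res["report"])
            models[comp] = res["model"]
            chem.save_model(res["model"], out / f"model_{comp}.json")
            res["plan"].to_frame().to_csv(out / f"design_{comp}.csv", index=False)
            record("calibrate", out / f"model_{comp}.json", out / f"design_{comp}.csv")
        table1 = make_table1(reports)
        table1.to_csv(out / "calibration_table.csv", index=False)
        record("calibrate", out / "calibration_table.csv")
        return reports, models

    reports, models = run_stage("calibrate", do_calibrate)

    # ---- predict the whole pool with the final models
    def do_predict():
        pred = pd.DataFrame({"sample_id": spectra.sample_ids})
        for comp, model in models.items():
            pred[comp] = chem.pls_predict(model, spectra)
        pred.to_csv(out / "predictions.csv", index=False)
        record("predict", out / "predictions.csv")

    run_stage("predict", do_predict)

    # ---- phenotype variance decomposition on a simulated trial
    if config.phenotype is not None:
        def do_phenotype():
            ph = config.phenotype or {}
            trial = syn.simulate_culture_trial(
                seed=stage_seed(config.seed, "phenotype"), **ph
            )
            comp = variance_components(trial)
            pd.DataFrame([{"trait": "simulated", **comp.as_dict()}]).to_csv(
                out / "variance_components.csv", index=False
            )
            record("phenotype", out / "variance_components.csv")

        run_stage("phenotype", do_phenotype)

    # ---- QTL mapping on a simulated RIL study
    if config.qtl is not None:
        def do_qtl():
            q = config.qtl or {}
            gmap = syn.default_map()
            pop = syn.simulate_ril_population(
                gmap, q.get("n_lines", 164), seed=stage_seed(config.seed, "ril")
            )
            qtl_spec = [tuple(x) for x in q.get(
                "qtl_spec", [("4", 36.7, 1.61), ("3", 63.6, 1.28)]
            )]
            phen, truth = syn.simulate_ril_phenotypes(
                pop, qtl_spec, q.get("residual_sd", 3.7),
                seed=stage_seed(config.seed, "ril-phenotype"),
                trait=q.get("trait", "oil"),
            )
            scan = ScanConfig(
                step=q.get("step", 1.0),
                n_permutations=q.get("n_permutations", 1000),
                alpha=q.get("alpha", 0.05),
                cofactor_window=q.get("cofactor_window", 10.0),
                lod_drop=q.get("lod_drop", 1.5),
                seed=stage_seed(config.seed, "permutations"),
            )
            nio.write_map(gmap, out / "map.csv")
            nio.write_genotypes(pop, out / "genotypes.csv")
            nio.write_phenotypes(phen, out / "phenotypes.csv")
            result = map_qtl(pop, phen, scan)
            result["im"].to_frame().to_csv(out / "lod_curve_im.csv", index=False)
            result["mqm"].to_frame().to_csv(out / "lod_curve_mqm.csv", index=False)
            trait = q.get("trait", "oil")
            table2 = make_table2({trait: result["qtl"]})
            table2.to_csv(out / "qtl_table.csv", index=False)
            sidecar = {
                "threshold": result["threshold"],
                "n_permutations": scan.n_permutations,
                "alpha": scan.alpha,
                "seed": scan.seed,
                "planted_qtl": [
                    {"chr": c, "pos_cM": p, "effect": e} for c, p, e in qtl_spec
                ],
                "truth_variance_fractions": truth.qtl_variance_fractions,
            }
            (out / "qtl_threshold.json").write_text(json.dumps(sidecar, indent=2))
            record(
                "qtl", out / "map.csv", out / "genotypes.csv",
                out / "phenotypes.csv", out / "lod_curve_im.csv",
                out / "lod_curve_mqm.csv", out / "qtl_table.csv",
                out / "qtl_threshold.json",
            )

        run_stage("qtl", do_qtl)

    # settings actually used, so a run is self-describing
    manifest["settings"] = {
        "preprocess_order": "msc -> derivative -> windows",
        "sep_convention": config.calibrate.get("sep_convention", "bias-corrected"),
        "lod_drop": (config.qtl or {}).get("lod_drop", 1.5),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
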