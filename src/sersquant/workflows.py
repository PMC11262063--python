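"""End-to-end workflows chaining the pipeline the way the study did:

* :func:`run_lod_study` — per-analyte dilution series; PCA-guided peak
  selection; univariate calibration-curve LoDs; PLS with
  leave-one-concentration-out double CV and the capability-of-detection LoD.
* :func:`run_multiplex_study` — 120-sample Latin hypercube mixtures; PLS-1
  (one model per thiol) and PLS-2 (one joint model) with bootstrap
  out-of-bag validation.
* :func:`run_blind_test` — frozen multiplex models predicting a fresh
  random-design set measured as a separate batch.
* :func:`run_mcr_study` — MCR-ALS on the mixtures in SNV-only and
  SNV+first-derivative domains, with profile-vs-known regressions.

Every workflow is a pure function of (config, seed); all randomness flows
from the root seed split per stage.
"""

from __future__ import annotations

import time
import zlib
from contextlib import contextmanager
from dataclasses import dataclass, field, replace as _replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .design import lhs_design, random_design
from .io import write_spectra_csv
from .lod import fit_calibration, lod_blank_criterion, lod_from_calibration, peak_heights
from .mcr import assign_components, fit_mcr_als, initialize_from_pure, regress_profiles
from .pca import fit_pca, select_peaks_from_loadings
from .pls import (
    bootstrap_validate,
    compute_metrics,
    double_cv_loco,
    fit_pls,
    load_model,
    pls_lod,
    predict,
    save_model,
)
from .preprocess import PreprocessingChain, apply_chain, mcr_chain, pca_chain, pls_chain
from .synthetic import (
    NoiseModel,
    apply_batch_effect,
    default_thiol_library,
    simulate_dilution_series,
    simulate_mixture_set,
)

__all__ = [
    "RunReport",
    "run_lod_study",
    "run_multiplex_study",
    "run_blind_test",
    "run_mcr_study",
]

METRIC_COLUMNS = ["family", "analyte", "n_lv", "R2", "Q2_cv", "Q2_test",
                  "RMSEC_ppm", "RMSECV_ppm", "RMSEP_ppm"]
FLOAT_FORMAT = "%.10g"


def stage_seed(root: int, *labels) -> int:
    """Deterministic per-stage seed derived from the root seed (< 2^31)."""
    key = [int(root)] + [zlib.crc32(str(l).encode()) for l in labels]
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2**31))


@dataclass
class RunReport:
    workflow: str
    seed: int
    tables: dict = field(default_factory=dict)       # name -> DataFrame
    models: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)        # name -> written path
    timings: dict = field(default_factory=dict)      # stage -> seconds
    version: str = __version__


@contextmanager
def _stage(report: RunReport, name: str):
    t0 = time.perf_counter()
    yield
    report.timings[name] = time.perf_counter() - t0


def _axis(config: RunConfig) -> np.ndarray:
    g = config.generator
    return np.linspace(g.axis_start, g.axis_stop, g.n_channels)


def _noise(config: RunConfig, seed: int) -> NoiseModel:
    g = config.generator
    return NoiseModel(
        additive_sd=g.additive_sd,
        multiplicative_sd=g.multiplicative_sd,
        baseline_amplitude=g.baseline_amplitude,
        baseline_smoothness=g.baseline_smoothness,
        baseline_variation=g.baseline_variation,
        seed=seed,
    )


def _write_report(report: RunReport, config: RunConfig, outdir, extra_writers=()) -> None:
    if outdir is None:
        return
    out = Path(outdir) / report.workflow
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    report.files["config"] = str(out / "config.yaml")
    for name, table in report.tables.items():
        p = out / f"{name}.csv"
        table.to_csv(p, index=False, float_format=FLOAT_FORMAT)
        report.files[name] = str(p)
    for writer in extra_writers:
        writer(out)
    log = out / "run.log"
    lines = [f"workflow={report.workflow} seed={report.seed} version={report.version}"]
    lines += [f"stage {k}: {v:.3f} s" for k, v in report.timings.items()]
    log.write_text("\n".join(lines) + "\n")
    report.files["log"] = str(log)


# ---------------------------------------------------------------------------
# LoD study

def run_lod_study(config: RunConfig, outdir=None) -> RunReport:
    """Per-analyte LoD study: dilution series -> PCA peak selection ->
    univariate calibration LoDs (and the blank criterion at the dominant
    band) -> PLS double CV and capability-of-detection LoD on the lowest
    five concentration levels."""
    report = RunReport("lod_study", config.seed)
    lib = default_thiol_library(_axis(config))
    lcfg = config.lod
    uni_rows, pls_rows = [], []
    sets = {}
    with _stage(report, "lod_all_analytes"):
        for analyte in lib.names:
            noise = _noise(config, stage_seed(config.seed, "lod", analyte))
            # single-session acquisition: constant background, lower noise
            noise = _replace(noise, additive_sd=lcfg.additive_sd,
                             baseline_variation=lcfg.baseline_variation)
            series = simulate_dilution_series(
                lib, analyte, lcfg.levels_ppm, noise,
                replicates=lcfg.replicates, include_blank=True,
            )
            sets[analyte] = series
            conc = series.concentrations[analyte].to_numpy(dtype=float)

            # PCA chain -> PC-1 loading extrema nominate bands
            processed = apply_chain(series, pca_chain())
            pca = fit_pca(processed, n_components=min(5, series.n_samples - 1))
            sel = select_peaks_from_loadings(
                pca, component=0, max_peaks=lcfg.max_peaks,
                min_prominence=lcfg.min_prominence,
            )
            # univariate: raw spectra, local baseline-corrected peak heights.
            # Keep positive-sign extrema (the direction associated with
            # increasing concentration under the fixed sign convention) and
            # skip any nominated band with no positive calibration slope.
            for wn, sign in zip(sel.wavenumbers, sel.signs):
                if sign <= 0:
                    continue
                h = peak_heights(series, wn, lcfg.half_width_cm1)
                curve = fit_calibration(conc, h, n_lowest=lcfg.n_lowest)
                if curve.slope <= 0:
                    continue
                est = lod_from_calibration(curve, k=lcfg.k, analyte=analyte,
                                           peak_wavenumber=wn)
                uni_rows.append(
                    {"analyte": analyte, "wavenumber_cm1": round(float(wn), 1),
                     "R2": curve.r2, "LoD_ppm": est.value, "method": est.method}
                )
            dom = lib.dominant_band(analyte).center
            blank = lod_blank_criterion(series, analyte, dom,
                                        half_width=lcfg.half_width_cm1, k=lcfg.k)
            uni_rows.append(
                {"analyte": analyte, "wavenumber_cm1": dom,
                 "R2": float("nan"),
                 "LoD_ppm": blank.value, "method": blank.method}
            )

            # PLS on the same lowest five levels, leave-one-level-out double CV
            levels = np.unique(conc[conc > 0])[: lcfg.n_lowest]
            rows = np.flatnonzero(np.isin(conc, levels))
            low = series.subset(rows)
            X = apply_chain(low, pls_chain()).intensities
            y = low.concentrations[analyte].to_numpy(dtype=float)
            n_levels = levels.size
            max_lv = min(lcfg.max_candidate_lv, len(rows) - len(rows) // n_levels - 1)
            cv = double_cv_loco(
                X, y, range(1, max_lv + 1),
                seed=stage_seed(config.seed, "lod_cv", analyte),
            )
            est = pls_lod(y, cv.predictions[:, 0], analyte=analyte)
            pls_rows.append(
                {"analyte": analyte, "LoD_ppm": est.value,
                 "Q2_cv": float(cv.q2_cv[0]), "RMSECV_ppm": float(cv.rmsecv[0]),
                 "n_lv": cv.selected_lv, "method": est.method}
            )
    report.tables["univariate_lod"] = pd.DataFrame(uni_rows)
    report.tables["pls_lod"] = pd.DataFrame(pls_rows)
    _write_report(report, config, outdir)
    report.models["series"] = sets
    return report


# ---------------------------------------------------------------------------
# multiplex study

def _fit_family(X, Y, analytes, candidates, max_outer, max_inner, n_boot, seed):
    """CV-select LVs, fit the full model, bootstrap-validate; returns
    (model, cv, boot)."""
    cv = double_cv_loco(
        X, Y, candidates,
        max_outer_folds=max_outer, max_inner_folds=max_inner,
        seed=stage_seed(seed, "cv"),
    )
    model = fit_pls(X, Y, cv.selected_lv, analytes=analytes)
    boot = bootstrap_validate(X, Y, model.n_lv, n_resamples=n_boot,
                              seed=stage_seed(seed, "bootstrap"))
    return model, cv, boot


def run_multiplex_study(config: RunConfig, outdir=None) -> RunReport:
    """LHS design -> simulated mixtures -> vector-normalised PLS-1 and PLS-2
    with bootstrap out-of-bag validation; emits the per-analyte metric table
    and the per-sample out-of-bag prediction export."""
    report = RunReport("multiplex_study", config.seed)
    mcfg, pcfg = config.multiplex, config.pls
    lib = default_thiol_library(_axis(config))
    with _stage(report, "simulate"):
        design = lhs_design(
            mcfg.n_samples, mcfg.analytes,
            (mcfg.conc_min_ppm, mcfg.conc_max_ppm),
            seed=stage_seed(config.seed, "design"),
        )
        noise = _noise(config, stage_seed(config.seed, "noise"))
        sset = simulate_mixture_set(
            lib, design, noise, replicates=mcfg.replicates,
            capacity=config.generator.capacity_ppm,
        )
    with _stage(report, "preprocess"):
        proc = apply_chain(sset, pls_chain())
    X = proc.intensities
    Y = proc.concentrations[list(mcfg.analytes)].to_numpy(dtype=float)

    rows, pred_rows = [], []
    models = {"pls1": {}, "pls2": None}
    with _stage(report, "pls1"):
        for j, analyte in enumerate(mcfg.analytes):
            fixed = (pcfg.fixed_lvs or {}).get(analyte)
            cands = [fixed] if fixed else range(1, pcfg.max_candidate_lv + 1)
            model, cv, boot = _fit_family(
                X, Y[:, j], [analyte], cands,
                pcfg.max_outer_folds, pcfg.max_inner_folds,
                pcfg.n_bootstrap, stage_seed(config.seed, "pls1", analyte),
            )
            r2, rmsec = compute_metrics(Y[:, j], predict(model, X)[:, 0], "train")
            model.chain = "pls_chain"
            models["pls1"][analyte] = model
            rows.append({
                "family": "PLS-1", "analyte": analyte, "n_lv": model.n_lv,
                "R2": float(r2[0]), "Q2_cv": float(cv.q2_cv[0]),
                "Q2_test": float(boot.q2_test[0]), "RMSEC_ppm": float(rmsec[0]),
                "RMSECV_ppm": float(cv.rmsecv[0]), "RMSEP_ppm": float(boot.rmsep[0]),
            })
            pred_rows += _prediction_rows(proc, "PLS-1", analyte, Y[:, j], boot, 0)
    with _stage(report, "pls2"):
        cands = [pcfg.fixed_lv_pls2] if pcfg.fixed_lv_pls2 else range(1, pcfg.max_candidate_lv + 1)
        model2, cv2, boot2 = _fit_family(
            X, Y, list(mcfg.analytes), cands,
            pcfg.max_outer_folds, pcfg.max_inner_folds,
            pcfg.n_bootstrap, stage_seed(config.seed, "pls2"),
        )
        r2, rmsec = compute_metrics(Y, predict(model2, X), "train")
        model2.chain = "pls_chain"
        models["pls2"] = model2
        for j, analyte in enumerate(mcfg.analytes):
            rows.append({
                "family": "PLS-2", "analyte": analyte, "n_lv": model2.n_lv,
                "R2": float(r2[j]), "Q2_cv": float(cv2.q2_cv[j]),
                "Q2_test": float(boot2.q2_test[j]), "RMSEC_ppm": float(rmsec[j]),
                "RMSECV_ppm": float(cv2.rmsecv[j]), "RMSEP_ppm": float(boot2.rmsep[j]),
            })
            pred_rows += _prediction_rows(proc, "PLS-2", analyte, Y[:, j], boot2, j)

    report.tables["metrics"] = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    report.tables["oob_predictions"] = pd.DataFrame(pred_rows)
    report.tables["design"] = design.concentrations.copy()
    report.models = models
    report.models["library"] = lib
    report.models["train_set"] = sset

    def _write_models(out: Path):
        mdir = out / "models"
        mdir.mkdir(exist_ok=True)
        for analyte, mdl in models["pls1"].items():
            save_model(mdl, mdir / f"pls1_{analyte}.json")
        save_model(models["pls2"], mdir / "pls2.json")
        write_spectra_csv(sset, out / "spectra.csv", out / "concentrations.csv")
        report.files["models"] = str(mdir)

    _write_report(report, config, outdir, extra_writers=[_write_models])
    return report


def _prediction_rows(proc, family, analyte, known, boot, col):
    out = []
    for i in range(len(known)):
        out.append({
            "spectrum_id": proc.metadata["spectrum_id"].iloc[i],
            "family": family, "analyte": analyte,
            "known_ppm": float(known[i]),
            "oob_mean_ppm": float(boot.oob_mean[i, col]),
            "oob_sd_ppm": float(boot.oob_sd[i, col]),
            "n_oob": int(boot.oob_count[i]),
        })
    return out


# ---------------------------------------------------------------------------
# blind test

def load_models(model_dir, analytes) -> dict:
    mdir = Path(model_dir)
    return {
        "pls1": {a: load_model(mdir / f"pls1_{a}.json") for a in analytes},
        "pls2": load_model(mdir / "pls2.json"),
    }


def run_blind_test(config: RunConfig, models: dict | None = None,
                   model_dir=None, outdir=None, batch_gain: float | None = None) -> RunReport:
    """Predict a fresh 15-sample random-design batch with frozen multiplex
    models at their training latent-variable counts.

    ``models`` is the dict returned by :func:`run_multiplex_study`; if absent
    it is loaded from ``model_dir`` or the multiplex study is (re)run from
    the config.
    """
    report = RunReport("blind_test", config.seed)
    mcfg, bcfg = config.multiplex, config.blind
    if batch_gain is None:
        batch_gain = bcfg.batch_gain
    if models is None:
        if model_dir is not None:
            models = load_models(model_dir, mcfg.analytes)
        else:
            models = run_multiplex_study(config).models
    lib = default_thiol_library(_axis(config))
    with _stage(report, "simulate_blind"):
        design = random_design(
            bcfg.n_samples, mcfg.analytes,
            (mcfg.conc_min_ppm, mcfg.conc_max_ppm),
            seed=stage_seed(config.seed, "blind_design"),
        )
        noise = _noise(config, stage_seed(config.seed, "blind_noise"))
        blind = simulate_mixture_set(
            lib, design, noise, replicates=bcfg.replicates, batch="blind",
            capacity=config.generator.capacity_ppm, sample_prefix="b",
        )
        blind = apply_batch_effect(blind, batch_gain,
                                   seed=stage_seed(config.seed, "batch"))
    with _stage(report, "predict"):
        proc = apply_chain(blind, pls_chain())
        X = proc.intensities
        Y = proc.concentrations[list(mcfg.analytes)].to_numpy(dtype=float)
        rows, pred_rows = [], []
        for j, analyte in enumerate(mcfg.analytes):
            mdl = models["pls1"][analyte]
            pred = predict(mdl, X)[:, 0]
            q2, rmsep = compute_metrics(Y[:, j], pred, "test")
            rows.append({"family": "PLS-1", "analyte": analyte, "n_lv": mdl.n_lv,
                         "Q2_test": float(q2[0]), "RMSEP_ppm": float(rmsep[0])})
            for i in range(len(pred)):
                pred_rows.append({
                    "spectrum_id": proc.metadata["spectrum_id"].iloc[i],
                    "family": "PLS-1", "analyte": analyte,
                    "known_ppm": float(Y[i, j]), "predicted_ppm": float(pred[i]),
                })
        mdl2 = models["pls2"]
        pred2 = predict(mdl2, X)
        q2, rmsep = compute_metrics(Y, pred2, "test")
        for j, analyte in enumerate(mcfg.analytes):
            rows.append({"family": "PLS-2", "analyte": analyte, "n_lv": mdl2.n_lv,
                         "Q2_test": float(q2[j]), "RMSEP_ppm": float(rmsep[j])})
            for i in range(pred2.shape[0]):
                pred_rows.append({
                    "spectrum_id": proc.metadata["spectrum_id"].iloc[i],
                    "family": "PLS-2", "analyte": analyte,
                    "known_ppm": float(Y[i, j]), "predicted_ppm": float(pred2[i, j]),
                })
    report.tables["blind_metrics"] = pd.DataFrame(rows)
    report.tables["blind_predictions"] = pd.DataFrame(pred_rows)
    report.tables["blind_design"] = design.concentrations.copy()
    report.models = models
    _write_report(report, config, outdir)
    return report


# ---------------------------------------------------------------------------
# MCR study

def run_mcr_study(config: RunConfig, outdir=None, train_set=None) -> RunReport:
    """MCR-ALS on the multiplex mixtures in two domains — SNV only ('raw')
    and SNV + first derivative — with component-to-analyte assignment and
    profile-vs-known regressions.

    One extra background component (initialised from the mean processed
    spectrum) absorbs the background/offset term that survives
    normalisation.
    """
    report = RunReport("mcr_study", config.seed)
    mcfg = config.multiplex
    lib = default_thiol_library(_axis(config))
    if train_set is None:
        with _stage(report, "simulate"):
            design = lhs_design(
                mcfg.n_samples, mcfg.analytes,
                (mcfg.conc_min_ppm, mcfg.conc_max_ppm),
                seed=stage_seed(config.seed, "design"),
            )
            noise = _noise(config, stage_seed(config.seed, "noise"))
            train_set = simulate_mixture_set(
                lib, design, noise, replicates=mcfg.replicates,
                capacity=config.generator.capacity_ppm,
            )
    chains = {
        "raw_snv": PreprocessingChain("snv_only", [("snv", {})]),
        "derivative": mcr_chain(),
    }
    rows = []
    traces = []
    results = {}
    for mode, chain in chains.items():
        with _stage(report, f"mcr_{mode}"):
            proc = apply_chain(train_set, chain)
            X = proc.intensities
            ref = initialize_from_pure(lib, chain)
            extras = None
            if config.mcr.extra_components > 0:
                extras = np.tile(X.mean(axis=0), (config.mcr.extra_components, 1))
            S_init = initialize_from_pure(lib, chain, extra=extras)
            res = fit_mcr_als(X, S_init, nonneg_c=True, nonneg_s=False,
                              tol=config.mcr.tol, max_iter=config.mcr.max_iter)
            res.assignment = assign_components(res.S, ref, list(lib.names))
            C_reg = res.C
            corrected = False
            if config.mcr.reference_correction:
                # SNV divides each spectrum by its own sd; that per-sample
                # scale re-emerges as a common factor on all profile
                # coefficients.  It is known exactly from the raw data, so
                # multiplying it back restores a shared concentration scale.
                sd = train_set.intensities.std(axis=1, ddof=1)
                C_reg = res.C * sd[:, None]
                corrected = True
            res.regressions = regress_profiles(
                C_reg, train_set.concentrations, res.assignment
            )
            results[mode] = res
            for analyte in lib.names:
                comp, corr = res.assignment[analyte]
                slope, intercept, r2 = res.regressions[analyte]
                rows.append({
                    "mode": mode, "analyte": analyte, "component": comp,
                    "matched_correlation": corr, "slope": slope,
                    "intercept": intercept, "R2": r2,
                    "lof_pct": res.lof, "converged": res.converged,
                    "n_iter": res.n_iter, "reference_corrected": corrected,
                })
            for it, lof in enumerate(res.lof_trace):
                traces.append({"mode": mode, "iteration": it, "lof_pct": lof})
    report.tables["mcr_metrics"] = pd.DataFrame(rows)
    report.tables["lof_trace"] = pd.DataFrame(traces)
    report.models = results
    _write_report(report, config, outdir)
    return report
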