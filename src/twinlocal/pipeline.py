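"""End-to-end orchestration: simulate -> metrics -> twin models -> associations.

The pipeline mirrors a full twin-imaging analysis: synthetic cohort and 4D
runs with known ground truth, per-run metric extraction with motion QC,
saturated-model assumption and covariate tests, Cholesky model fitting with
AIC selection and constraint tests, exploratory mixed-model associations,
and Benjamini-Hochberg FDR applied within four separate test families:
(1) covariate effects, (2) assumption tests, (3) new-influence and
(de)amplification tests, (4) brain-behavior associations.

All randomness flows from a single master seed through a keyed splitting
scheme, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import brain_behavior_twin, fit_lmm
from .metrics import MetricParams, process_subject
from .synthetic import (
    FmriSimConfig,
    SimulationConfig,
    block_atlas,
    simulate_behavior,
    simulate_fmri_run,
    simulate_twin_cohort,
    truth_from_proportions,
)
from .twin import (
    TwinData,
    decompose_variance,
    fit_cholesky,
    profile_ci,
    select_model,
    test_amplification,
    test_new_influence,
)
from .saturated import fit_saturated, test_assumptions, test_covariate, twin_correlations

__all__ = ["PipelineConfig", "bh_fdr", "run_pipeline", "load_config", "derived_seed"]

log = logging.getLogger("twinlocal")

FLOAT_FMT = "%.8g"


def derived_seed(master: int, *keys) -> int:
    """Stable child seed from the master seed and a key path."""
    h = hashlib.blake2b(repr((int(master),) + keys).encode(), digest_size=4)
    return int.from_bytes(h.digest(), "little") % (2**31 - 1)


def bh_fdr(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up procedure.

    Rejects hypotheses 1..k where k = max{i : p(i) <= q i/m} on the sorted
    p-values; adjusted p-values by the backward cumulative-minimum pass.
    Returns (reject flags, adjusted p) aligned with the input order.
    """
    p = np.asarray(list(pvals), dtype=float)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    below = np.flatnonzero(p[order] <= q * np.arange(1, m + 1) / m)
    reject = np.zeros(m, dtype=bool)
    if below.size:
        reject[order[: below[-1] + 1]] = True
    return reject, adjusted


@dataclass
class PipelineConfig:
    """Flat configuration of the full pipeline."""

    out_dir: str = "twinlocal_out"
    seed: int = 0
    # simulate stage
    n_mz_pairs: int = 16
    n_dz_pairs: int = 16
    grid_shape: tuple = (20, 20, 12)
    n_rois: int = 2
    n_volumes: int = 96
    tr: float = 0.93
    voxel_size: float = 2.0
    coherence_h2: float = 0.5
    coherence_c2: float = 0.2
    coherence_base: float = 0.5
    coherence_sd: float = 0.12
    band_fraction: float = 0.6
    p_missing_wave2: float = 0.2
    # metrics stage
    fd_threshold: float = 0.3
    band_low: float = 0.01
    band_high: float = 0.08
    fwhm: float = 6.0
    scrub_threshold: float = 0.5
    # twin stage
    model_set: tuple = ("ACE", "AE", "CE", "E")
    ci_level: float = 0.95
    with_cis: bool = True
    covariates: bool = True
    # association / FDR
    fdr_q: float = 0.05
    # stage toggles
    run_simulate: bool = True
    run_metrics: bool = True
    run_twin: bool = True
    run_assoc: bool = True
    run_report: bool = True
    metrics_table: str | None = None  # precomputed table when metrics toggled off

    def __post_init__(self):
        if not 0.0 < self.fdr_q < 1.0:
            raise ValueError("fdr_q must lie in (0, 1)")


def load_config(path, overrides: dict | None = None) -> PipelineConfig:
    """Read a flat YAML config file; ``overrides`` (e.g. CLI flags) win."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in (overrides or {}).items() if v is not None})
    known = {f for f in PipelineConfig.__dataclass_fields__}
    bad = set(raw) - known
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    for key in ("grid_shape", "model_set"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _simulate_stage(cfg: PipelineConfig) -> pd.DataFrame:
    """Simulate a cohort whose per-ROI coherence has ACE twin structure, run
    the metric chain on each simulated acquisition, and return the subject x
    wave metrics table."""
    atlas = block_atlas(cfg.grid_shape, cfg.n_rois)
    roi_ids = list(range(1, cfg.n_rois + 1))
    coh_truth = truth_from_proportions(
        h2=cfg.coherence_h2, c2=cfg.coherence_c2, overlap=0.7,
        total_var=cfg.coherence_sd**2,
        mu1=cfg.coherence_base, mu2=cfg.coherence_base,
    )
    cohorts = {}
    for roi in roi_ids:
        sim = SimulationConfig(
            n_mz_pairs=cfg.n_mz_pairs,
            n_dz_pairs=cfg.n_dz_pairs,
            cholesky_truth=coh_truth,
            beta_age=0.0, beta_sex=0.0, beta_fd=0.0,
            p_missing_wave2=0.0,
            p_unpaired=0.0,
            seed=derived_seed(cfg.seed, "coherence", roi),
        )
        cohorts[roi] = simulate_twin_cohort(sim)[0]
    demo = cohorts[roi_ids[0]]
    # one family-level wave-2 missingness pattern shared by every ROI
    miss_rng = np.random.default_rng(derived_seed(cfg.seed, "missing"))
    fams = demo["family_id"].unique()
    missing_w2 = set(fams[miss_rng.random(fams.size) < cfg.p_missing_wave2])

    rows = []
    metric_params = MetricParams(
        band_low=cfg.band_low, band_high=cfg.band_high, fwhm=cfg.fwhm,
        voxel_size=cfg.voxel_size, scrub_threshold=cfg.scrub_threshold,
        fd_threshold=cfg.fd_threshold,
    )
    for (twin_id, wave), grp in demo.groupby(["twin_id", "wave"], sort=True):
        rec = grp.iloc[0]
        if wave == 2 and rec["family_id"] in missing_w2:
            continue
        coh = {}
        for roi in roi_ids:
            sub = cohorts[roi]
            v = sub[(sub.twin_id == twin_id) & (sub.wave == wave)]["value"].iloc[0]
            coh[roi] = float(np.clip(v, 0.05, 0.95))
        fcfg = FmriSimConfig(
            grid_shape=cfg.grid_shape,
            voxel_size=cfg.voxel_size,
            n_volumes=cfg.n_volumes,
            tr=cfg.tr,
            coherence_by_roi=coh,
            band_fraction_by_roi={r: cfg.band_fraction for r in roi_ids},
            seed=derived_seed(cfg.seed, "fmri", twin_id, int(wave)),
        )
        runs, motions = simulate_fmri_run(fcfg, atlas)
        res = process_subject(runs, motions, atlas, metric_params)
        row = {
            "subject": twin_id,
            "family_id": rec["family_id"],
            "birth_order": int(rec["birth_order"]),
            "zygosity": rec["zygosity"],
            "sex": float(rec["sex"]),
            "age_years": float(rec["age_years"]),
            "wave": int(wave),
            "mean_fd_mm": res["mean_fd"],
            "excluded": bool(res["excluded"]),
        }
        for i, roi in enumerate(roi_ids):
            row[f"ReHo_roi{roi}"] = res["ReHo"][i]
            row[f"fALFF_roi{roi}"] = res["fALFF"][i]
        row["coherence_truth"] = coh[roi_ids[0]]
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(["subject", "wave"]).reset_index(drop=True)
    behav = simulate_behavior(
        table.rename(columns={"ReHo_roi1": "value"}),
        seed=derived_seed(cfg.seed, "behavior"),
    )["behavior_score"]
    table["behavior_score"] = behav.to_numpy()
    return table


def _value_frame(table: pd.DataFrame, col: str) -> pd.DataFrame:
    df = table[~table["excluded"]].copy()
    df["value"] = df[col]
    return df[["family_id", "subject", "birth_order", "zygosity", "sex",
               "age_years", "mean_fd_mm", "wave", "value", "behavior_score"]]


def _twin_stage(cfg: PipelineConfig, table: pd.DataFrame, phenos: list[str]):
    twin_rows, sat_rows, corr_rows = [], [], []
    for col in phenos:
        df = _value_frame(table, col)
        data = TwinData.from_long(df)
        seed = derived_seed(cfg.seed, "twin", col)
        sat = fit_saturated(data, covariates=cfg.covariates, seed=seed)
        for _, r in test_assumptions(
            data, covariates=cfg.covariates, full=sat, seed=seed
        ).iterrows():
            sat_rows.append({"phenotype": col, "family": "assumptions", **r})
        for cov in ("age", "sex", "fd"):
            r = test_covariate(data, cov, full=sat, seed=seed)
            r.pop("constrained_fit", None)
            sat_rows.append({"phenotype": col, "family": "covariates", **r})
        tc = twin_correlations(data, covariates=cfg.covariates, fit=sat)
        tc.insert(0, "phenotype", col)
        corr_rows.append(tc)

        fits = [
            fit_cholesky(data, comps, covariates=cfg.covariates,
                         n_starts=3, seed=seed)
            for comps in cfg.model_set
        ]
        best, ambiguous = select_model(fits)
        dec = decompose_variance(best)
        row = {
            "phenotype": col,
            "chosen_model": best.label,
            "minus2ll": best.minus2ll,
            "aic": best.aic,
            "ambiguous_daic_lt2": ambiguous,
            "aic_table": ";".join(
                f"{f.label}={f.aic:.3f}" for f in sorted(fits, key=lambda f: f.aic)
            ),
        }
        for comp in "ACE":
            for w in ("w1", "w2"):
                row[f"raw_{comp}_{w}"] = dec["raw"][comp][w]
                row[f"std_{comp}_{w}"] = dec["std"][comp][w]
            row[f"{comp}_continuing_w2"] = dec["w2_split"][comp]["continuing"]
            row[f"{comp}_new_w2"] = dec["w2_split"][comp]["new"]
        if cfg.with_cis:
            for comp in best.label:
                for w in ("1", "2"):
                    q = f"std_{comp.lower()}{w}"
                    try:
                        lo, hi = profile_ci(best, q, level=cfg.ci_level)
                    except (ValueError, RuntimeError):
                        lo = hi = float("nan")
                    row[f"{q}_lo"], row[f"{q}_hi"] = lo, hi
        for comp in ("A", "C"):
            if comp in best.label:
                new = test_new_influence(best, comp)
                amp = test_amplification(best, comp)
                row[f"new_{comp}_chi2"] = new["chi2"]
                row[f"new_{comp}_p"] = new["p"]
                row[f"amp_{comp}_chi2"] = amp["chi2"]
                row[f"amp_{comp}_p"] = amp["p"]
                row[f"amp_{comp}_direction"] = amp["direction"]
        twin_rows.append(row)
    twin_df = pd.DataFrame(twin_rows)
    sat_df = pd.DataFrame(sat_rows)
    corr_df = pd.concat(corr_rows, ignore_index=True)
    return twin_df, sat_df, corr_df


def _assoc_stage(cfg: PipelineConfig, table: pd.DataFrame, phenos: list[str]):
    rows = []
    for col in phenos:
        df = _value_frame(table, col).rename(
            columns={"subject": "participant_id", "age_years": "age",
                     "mean_fd_mm": "mean_fd", "value": "roi_value"}
        )
        df["wave"] = df["wave"] - 1  # 0 = wave 1, 1 = wave 2
        df = df.dropna(subset=["roi_value"])
        try:
            res = fit_lmm(df)
        except (ValueError, np.linalg.LinAlgError) as exc:
            log.warning("LMM failed for %s: %s", col, exc)
            continue
        rows.append(
            {"phenotype": col, "scale": "behavior_score",
             "estimate": res["estimate"], "se": res["se"],
             "z": res["z"], "p": res["p"]}
        )
    return pd.DataFrame(rows)


def _apply_fdr(cfg, sat_df, twin_df, assoc_df):
    """BH within each declared family, never across families."""
    if len(sat_df):
        for fam in ("covariates", "assumptions"):
            sel = sat_df["family"] == fam
            if sel.any():
                rej, adj = bh_fdr(sat_df.loc[sel, "p"].fillna(1.0), cfg.fdr_q)
                sat_df.loc[sel, "p_fdr"] = adj
                sat_df.loc[sel, "significant_fdr"] = rej
    # family 3: new influences and (de)amplification
    fam3 = []
    for comp in ("A", "C"):
        for kind in ("new", "amp"):
            col = f"{kind}_{comp}_p"
            if col in twin_df.columns:
                for i in twin_df.index[twin_df[col].notna()]:
                    fam3.append((i, col))
    if fam3:
        ps = [twin_df.loc[i, c] for i, c in fam3]
        rej, adj = bh_fdr(ps, cfg.fdr_q)
        for (i, c), r, a in zip(fam3, rej, adj):
            twin_df.loc[i, c + "_fdr"] = a
            twin_df.loc[i, c + "_sig"] = bool(r)
    if len(assoc_df):
        rej, adj = bh_fdr(assoc_df["p"].fillna(1.0), cfg.fdr_q)
        assoc_df["p_fdr"] = adj
        assoc_df["significant_fdr"] = rej
    return sat_df, twin_df, assoc_df


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order and write the report bundle.

    Returns a dict of the result tables.  Output files: metrics_table.tsv,
    twin_results.tsv, saturated_tests.tsv, twin_correlations.tsv,
    associations.tsv, manifest.json, summary.txt, run.log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    results: dict = {}
    try:
        if config.run_simulate or config.run_metrics:
            log.info("simulate + metrics stage")
            table = _simulate_stage(config)
        elif config.metrics_table:
            table = pd.read_csv(config.metrics_table, sep="\t")
        else:
            raise ValueError("no metrics stage and no precomputed metrics_table")
        results["metrics_table"] = table
        phenos = [c for c in table.columns
                  if c.startswith("ReHo_roi") or c.startswith("fALFF_roi")]
        sat_df = twin_df = assoc_df = pd.DataFrame()
        corr_df = pd.DataFrame()
        if config.run_twin:
            log.info("twin-model stage (%d phenotypes)", len(phenos))
            twin_df, sat_df, corr_df = _twin_stage(config, table, phenos)
        if config.run_assoc:
            log.info("association stage")
            assoc_df = _assoc_stage(config, table, phenos)
        sat_df, twin_df, assoc_df = _apply_fdr(config, sat_df, twin_df, assoc_df)
        results.update(
            twin_results=twin_df, saturated_tests=sat_df,
            twin_correlations=corr_df, associations=assoc_df,
        )
        if config.run_report:
            _write_report(config, results, out)
        log.info("pipeline finished in %.1f s", time.time() - t0)
    except Exception:
        log.exception("pipeline stage failed")
        (out / "error.json").write_text(
            json.dumps({"status": "failed", "config": _config_dict(config)})
        )
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return results


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["grid_shape"] = list(d["grid_shape"])
    d["model_set"] = list(d["model_set"])
    return d


def _write_report(config, results, out: Path):
    names = {
        "metrics_table": "metrics_table.tsv",
        "twin_results": "twin_results.tsv",
        "saturated_tests": "saturated_tests.tsv",
        "twin_correlations": "twin_correlations.tsv",
        "associations": "associations.tsv",
    }
    for key, fname in names.items():
        df = results.get(key)
        if df is not None and len(df):
            df.to_csv(out / fname, sep="\t", index=False, float_format=FLOAT_FMT)
    cfg = _config_dict(config)
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest = {
        "twinlocal_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": cfg,
        "config_hash": digest,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    lines = [f"twinlocal {__version__} run (seed {config.seed})"]
    tw = results.get("twin_results")
    if tw is not None and len(tw):
        for _, r in tw.iterrows():
            lines.append(
                f"{r['phenotype']}: model {r['chosen_model']}"
                f"{' (ambiguous)' if r['ambiguous_daic_lt2'] else ''}, "
                f"std A w1={r['std_A_w1']:.3f}, C w1={r['std_C_w1']:.3f}, "
                f"E w1={r['std_E_w1']:.3f}"
            )
    assoc = results.get("associations")
    if assoc is not None and len(assoc):
        n_sig = int(assoc.get("significant_fdr", pd.Series(dtype=bool)).sum())
        lines.append(f"associations: {len(assoc)} tested, {n_sig} FDR-significant")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
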