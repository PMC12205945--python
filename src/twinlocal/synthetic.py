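"""Synthetic twin cohorts and resting-state-like 4D runs with known truth.

Two generators make the whole pipeline testable without any data download:

* :func:`simulate_twin_cohort` draws latent A/C/E factors explicitly per
  family (cross-twin correlation 1 for MZ and 0.5 for DZ on A, 1 on C, 0 on
  E) and maps them through bivariate Cholesky paths to two-occasion
  phenotypes, with covariate effects of age, sex and head motion added on
  top.  Drawing the latent variables rather than sampling the implied
  4-variate normal keeps the ground-truth decomposition auditable per twin.

* :func:`simulate_fmri_run` builds AP/PA pairs of 4D volumes whose voxel
  time series mix a shared per-ROI signal with independent voxel noise,
  both spectrally shaped so the amplitude fraction in the 0.01-0.08 Hz band
  hits a target; neighborhood temporal coherence is set by the shared-signal
  weight.  Motion parameters are smooth random walks.

Default cohort sizes mirror a two-wave adolescent twin study with roughly
56 MZ and 49 DZ complete pairs per wave; recovery harnesses pass larger n.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .twin import CholeskyParams, implied_covariance

__all__ = [
    "SimulationConfig",
    "FmriSimConfig",
    "default_truth",
    "truth_from_proportions",
    "simulate_twin_cohort",
    "simulate_behavior",
    "simulate_fmri_run",
    "block_atlas",
    "write_cohort_tsv",
]


def default_truth() -> CholeskyParams:
    """Moderate-heritability two-wave truth used as the generator default."""
    return truth_from_proportions(h2=0.4, c2=0.2, overlap=0.6)


def truth_from_proportions(
    h2: float,
    c2: float,
    overlap: float = 0.6,
    total_var: float = 1.0,
    mu1: float = 0.0,
    mu2: float = 0.0,
) -> CholeskyParams:
    """Build Cholesky paths from standardized wave-1 proportions.

    Wave 2 reuses the same standardized proportions, with a fraction
    ``overlap`` of each source's wave-2 SD carried by the wave-1 latent
    factor (so cross-wave correlation within each source equals ``overlap``).
    """
    e2 = 1.0 - h2 - c2
    if e2 <= 0:
        raise ValueError("h2 + c2 must be < 1 (E is always present)")
    s = math.sqrt(total_var)
    out = {}
    for comp, frac in (("a", h2), ("c", c2), ("e", e2)):
        sd = math.sqrt(frac) * s
        out[comp + "11"] = sd
        out[comp + "21"] = overlap * sd
        out[comp + "22"] = sd * math.sqrt(max(1.0 - overlap**2, 0.0))
    return CholeskyParams(mu1=mu1, mu2=mu2, **out)


@dataclass
class SimulationConfig:
    """Conditions for one simulated two-wave twin cohort."""

    n_mz_pairs: int = 56
    n_dz_pairs: int = 49
    cholesky_truth: CholeskyParams = field(default_factory=default_truth)
    beta_age: float = 0.01      # phenotype units per year
    beta_sex: float = 0.03      # female (1) minus male (0)
    beta_fd: float = 1.0        # phenotype units per mm of mean FD
    age_mean: float = 11.5      # years at wave 1
    age_sd: float = 1.3
    wave_gap: float = 1.7       # years between waves
    fd_mean: float = 0.19       # mm
    fd_sd: float = 0.06
    p_missing_wave2: float = 0.25
    p_unpaired: float = 0.2
    seed: int = 0

    def validate(self):
        for name in ("p_missing_wave2", "p_unpaired"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_mz_pairs < 0 or self.n_dz_pairs < 0:
            raise ValueError("pair counts must be non-negative")
        t = self.cholesky_truth
        if t.e11 <= 0:
            raise ValueError("truth must have e11 > 0")
        for z in ("MZ", "DZ"):
            w = np.linalg.eigvalsh(implied_covariance(t, z))
            if w.min() < -1e-10:
                raise ValueError(f"truth implies non-PSD {z} covariance")


def _draw_latent(rng, n, r):
    """(n, 2) draws with cross-twin correlation r, unit marginals."""
    shared = rng.standard_normal(n)
    uniq = rng.standard_normal((n, 2))
    a = math.sqrt(r)
    b = math.sqrt(1.0 - r)
    return a * shared[:, None] + b * uniq


def simulate_twin_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a long twin phenotype table plus a ground-truth record.

    Returns a table with one row per individual per wave (columns family_id,
    twin_id, birth_order, zygosity, sex, age_years, mean_fd_mm, wave, value)
    and a truth dict holding the generating parameters and the per-individual
    latent-source contributions (before covariate effects), keyed
    ``contrib[source]`` with shape (n_families, 2 twins, 2 waves).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    t = config.cholesky_truth
    n = config.n_mz_pairs + config.n_dz_pairs
    zyg = np.array(["MZ"] * config.n_mz_pairs + ["DZ"] * config.n_dz_pairs)

    paths = {s: t.path_matrix(s) for s in "ace"}
    contrib = {s: np.zeros((n, 2, 2)) for s in "ACE"}
    y = np.zeros((n, 2, 2))  # family, twin, wave
    for s, r_mz, r_dz in (("A", 1.0, 0.5), ("C", 1.0, 1.0), ("E", 0.0, 0.0)):
        # two latent factors per source (factor 1 -> wave 1 + carry-over,
        # factor 2 -> wave-2-specific), each with the source's cross-twin r
        f1 = np.where(
            (zyg == "MZ")[:, None], _draw_latent(rng, n, r_mz), _draw_latent(rng, n, r_dz)
        )
        f2 = np.where(
            (zyg == "MZ")[:, None], _draw_latent(rng, n, r_mz), _draw_latent(rng, n, r_dz)
        )
        P = paths[s.lower()]
        # wave1 = p11 * f1 ; wave2 = p21 * f1 + p22 * f2
        contrib[s][:, :, 0] = P[0, 0] * f1
        contrib[s][:, :, 1] = P[1, 0] * f1 + P[1, 1] * f2
        y += contrib[s]
    y[:, :, 0] += t.mu1
    y[:, :, 1] += t.mu2

    # covariates: age shared within pair, sex/FD individual
    age_w1 = rng.normal(config.age_mean, config.age_sd, n)
    same_sex = zyg == "MZ"
    sex = rng.integers(0, 2, (n, 2)).astype(float)
    sex[same_sex, 1] = sex[same_sex, 0]
    fd = np.abs(rng.normal(config.fd_mean, config.fd_sd, (n, 2, 2)))
    ages = np.stack([np.tile(age_w1[:, None], (1, 2)),
                     np.tile(age_w1[:, None] + config.wave_gap, (1, 2))], axis=2)
    y = (
        y
        + config.beta_age * ages
        + config.beta_sex * sex[:, :, None]
        + config.beta_fd * fd
    )

    # wave-2 missingness per family; unpaired twins by deleting one co-twin
    miss_w2 = rng.random(n) < config.p_missing_wave2
    unpaired = rng.random(n) < config.p_unpaired
    dropped_twin = rng.integers(0, 2, n)

    rows = []
    for i in range(n):
        for j in range(2):
            for w in range(2):
                v = y[i, j, w]
                if w == 1 and miss_w2[i]:
                    v = np.nan
                if unpaired[i] and j == dropped_twin[i]:
                    v = np.nan
                rows.append(
                    {
                        "family_id": f"fam{i:05d}",
                        "twin_id": f"fam{i:05d}_t{j + 1}",
                        "birth_order": j + 1,
                        "zygosity": zyg[i],
                        "sex": sex[i, j],
                        "age_years": ages[i, j, w],
                        "mean_fd_mm": fd[i, j, w],
                        "wave": w + 1,
                        "value": v,
                    }
                )
    df = pd.DataFrame(rows)
    truth = {
        "params": asdict_params(t),
        "betas": {
            "age": config.beta_age,
            "sex": config.beta_sex,
            "fd": config.beta_fd,
        },
        "zygosity": zyg,
        "contrib": contrib,
        "implied_mz": implied_covariance(t, "MZ"),
        "implied_dz": implied_covariance(t, "DZ"),
    }
    return df, truth


def asdict_params(p: CholeskyParams) -> dict:
    d = asdict(p)
    if d.get("beta") is not None:
        d["beta"] = np.asarray(d["beta"]).tolist()
    return d


def simulate_behavior(
    df: pd.DataFrame,
    seed: int = 0,
    mean: float = 10.0,
    sd: float = 5.0,
    family_icc: float = 0.3,
    brain_slope: float = 0.0,
) -> pd.DataFrame:
    """Attach a behavioral total score (one per individual per wave).

    Scores have a family-level random intercept (intraclass correlation
    ``family_icc``) and optionally load on the phenotype column with
    ``brain_slope`` (in score units per phenotype unit).
    """
    rng = np.random.default_rng(seed)
    fams = df["family_id"].unique()
    fam_eff = dict(
        zip(fams, rng.normal(0.0, sd * math.sqrt(family_icc), len(fams)))
    )
    noise_sd = sd * math.sqrt(1.0 - family_icc)
    out = df.copy()
    base = np.array([fam_eff[f] for f in out["family_id"]])
    out["behavior_score"] = (
        mean
        + base
        + rng.normal(0.0, noise_sd, len(out))
        + brain_slope * np.nan_to_num(out["value"].to_numpy())
    )
    return out


# --------------------------------------------------------------------------
# synthetic fMRI runs
# --------------------------------------------------------------------------

@dataclass
class FmriSimConfig:
    """Conditions for one simulated AP/PA pair of 4D runs."""

    grid_shape: tuple = (20, 20, 12)
    voxel_size: float = 2.0                 # mm
    n_volumes: int = 322
    tr: float = 0.93                        # seconds
    coherence_by_roi: dict = field(default_factory=lambda: {1: 0.5, 2: 0.5})
    band_fraction_by_roi: dict = field(default_factory=lambda: {1: 0.6, 2: 0.6})
    motion_scale: float = 0.02              # mm per step of the random walk
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self):
        if self.n_volumes < 64:
            raise ValueError("n_volumes must be >= 64")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        for d in (self.coherence_by_roi, self.band_fraction_by_roi):
            for k, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"ROI {k}: targets must lie in [0, 1]")


@dataclass
class FmriRun:
    """A 4D intensity array with its acquisition metadata."""

    data: np.ndarray          # (x, y, z, t)
    tr: float
    mask: np.ndarray          # (x, y, z) boolean
    phase_dir: str = "AP"

    def __post_init__(self):
        if self.data.shape[-1] < 2:
            raise ValueError("need at least 2 volumes")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match spatial shape")
        if self.tr <= 0:
            raise ValueError("tr must be positive")


def block_atlas(grid_shape, n_rois: int = 2) -> np.ndarray:
    """Integer label volume splitting the grid into equal slabs along x.

    Label 0 is background (a one-voxel rim); labels 1..n_rois fill the rest.
    """
    labels = np.zeros(grid_shape, dtype=np.int16)
    nx = grid_shape[0]
    inner = slice(1, -1)
    edges = np.linspace(1, nx - 1, n_rois + 1).astype(int)
    for r in range(n_rois):
        labels[edges[r]:edges[r + 1], inner, inner] = r + 1
    return labels


def _shaped_series(rng, n_series, n_t, tr, band_fraction,
                   band=(0.01, 0.08), full_hi=0.25):
    """Series whose expected amplitude-spectrum fraction in ``band`` (relative
    to 0 < f <= ``full_hi``) equals ``band_fraction``; no power above full_hi."""
    freqs = np.fft.rfftfreq(n_t, d=tr)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    in_full = (freqs > 0) & (freqs <= full_hi)
    out_band = in_full & ~in_band
    n_in, n_out = int(in_band.sum()), int(out_band.sum())
    amp = np.zeros_like(freqs)
    f = float(band_fraction)
    if n_in and f > 0:
        amp[in_band] = f * n_out / max((1.0 - f) * n_in, 1e-12) if f < 1 else 1.0
    if n_out and f < 1:
        amp[out_band] = 1.0
    phases = rng.uniform(0, 2 * np.pi, (n_series, freqs.size))
    spec = amp[None, :] * np.exp(1j * phases)
    spec[:, 0] = 0.0
    x = np.fft.irfft(spec, n=n_t, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_fmri_run(
    config: FmriSimConfig, atlas: np.ndarray
) -> tuple[dict, dict]:
    """Simulate an AP/PA pair of runs plus per-run motion parameters.

    Within each ROI, every voxel's series is ``sqrt(rho) * shared +
    sqrt(1 - rho) * noise`` with rho the ROI's coherence target, so the
    expected correlation between two voxels of the ROI equals rho.  Shared
    and noise series carry the same amplitude-spectrum shape, so the band
    fraction is unaffected by the mixing weight.  Background voxels get pure
    noise.  Returns ({'AP': FmriRun, 'PA': FmriRun}, {'AP': motion, 'PA': ...}).
    """
    config.validate()
    atlas = np.asarray(atlas)
    if atlas.shape != tuple(config.grid_shape):
        raise ValueError("atlas grid does not match grid_shape")
    for roi, rho in config.coherence_by_roi.items():
        if rho == 1.0 and config.noise_sd == 0.0:
            raise ValueError(
                f"ROI {roi}: coherence 1 with zero noise is degenerate "
                "(all ranks tie)"
            )
    rng = np.random.default_rng(config.seed)
    mask = atlas > 0
    runs, motions = {}, {}
    for phase in ("AP", "PA"):
        data = np.zeros(tuple(config.grid_shape) + (config.n_volumes,))
        for roi in sorted(config.coherence_by_roi):
            sel = atlas == roi
            nv = int(sel.sum())
            if nv == 0:
                continue
            rho = config.coherence_by_roi[roi]
            frac = config.band_fraction_by_roi.get(roi, 0.5)
            shared = _shaped_series(rng, 1, config.n_volumes, config.tr, frac)[0]
            noise = _shaped_series(rng, nv, config.n_volumes, config.tr, frac)
            w = math.sqrt(rho)
            data[sel] = w * shared[None, :] + math.sqrt(1.0 - rho) * noise
        bg = ~mask
        if bg.any():
            data[bg] = config.noise_sd * rng.standard_normal(
                (int(bg.sum()), config.n_volumes)
            )
        runs[phase] = FmriRun(data=data, tr=config.tr, mask=mask, phase_dir=phase)
        steps = rng.normal(0.0, config.motion_scale, (config.n_volumes, 6))
        steps[:, 3:] /= 50.0  # rotations in radians, comparable FD contribution
        motions[phase] = np.cumsum(steps, axis=0)
        motions[phase] -= motions[phase][0]
    return runs, motions


# --------------------------------------------------------------------------
# text/NIfTI output
# --------------------------------------------------------------------------

def write_cohort_tsv(df: pd.DataFrame, truth: dict, path) -> None:
    """Write the long table as TSV with a JSON ground-truth sidecar."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
    side = {
        "params": truth["params"],
        "betas": truth["betas"],
        "implied_mz": np.asarray(truth["implied_mz"]).tolist(),
        "implied_dz": np.asarray(truth["implied_dz"]).tolist(),
    }
    path.with_suffix(".truth.json").write_text(json.dumps(side, indent=1))


def save_run_nifti(run: FmriRun, path, voxel_size: float = 2.0) -> None:
    import nibabel as nib

    aff = np.diag([voxel_size] * 3 + [1.0])
    img = nib.Nifti1Image(run.data.astype(np.float32), aff)
    img.header.set_zooms((voxel_size,) * 3 + (run.tr,))
    nib.save(img, str(path))


def save_atlas_nifti(atlas: np.ndarray, path, voxel_size: float = 2.0) -> None:
    import nibabel as nib

    aff = np.diag([voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(atlas.astype(np.int16), aff), str(path))


def save_motion_params(motion: np.ndarray, path) -> None:
    np.savetxt(path, motion, fmt="%.8g")
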