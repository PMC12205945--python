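"""Saturated bivariate twin models: free means and covariances per zygosity.

The saturated model places no structure on the data beyond multivariate
normality: each zygosity group gets its own 4-vector of means and 4x4
covariance over (twin1 wave1, twin1 wave2, twin2 wave1, twin2 wave2), with
covariate slopes shared across groups in the mean structure.  It is the
reference point for assumption tests (equality of means/variances across
birth order and zygosity), covariate tests, and twin correlations.

Covariances are parameterized as diag(s) R diag(s) with log-scale standard
deviations and a row-normalized Cholesky factor for the correlation matrix,
so equality constraints on variances reduce to parameter sharing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .twin import (
    COVARIATES,
    ELEM_TWIN,
    ELEM_WAVE,
    TwinData,
    _group_neg2ll,
)

__all__ = [
    "SaturatedFitResult",
    "fit_saturated",
    "test_assumptions",
    "test_covariate",
    "twin_correlations",
]

ZYGOSITIES = ("MZ", "DZ")


def _corr_from_v(v: np.ndarray) -> np.ndarray:
    """Correlation matrix from 6 unconstrained entries via row-normalized
    unit-lower-triangular Cholesky rows."""
    L = np.eye(4)
    k = 0
    for i in range(1, 4):
        row = np.empty(i + 1)
        row[:i] = v[k:k + i]
        row[i] = 1.0
        k += i
        L[i, : i + 1] = row / np.linalg.norm(row)
    return L @ L.T


def _v_from_corr(R: np.ndarray) -> np.ndarray:
    """Inverse of :func:`_corr_from_v` (up to row scaling)."""
    # nearest-PD safeguard for sample correlation matrices
    w, U = np.linalg.eigh((R + R.T) / 2)
    w = np.clip(w, 1e-6, None)
    Rp = U @ np.diag(w) @ U.T
    d = np.sqrt(np.diag(Rp))
    Rp = Rp / np.outer(d, d)
    L = np.linalg.cholesky(Rp)
    out = []
    for i in range(1, 4):
        out.extend(L[i, :i] / L[i, i])
    return np.array(out)


class SaturatedSpec:
    """Slot-based parameterization with optional equality constraints.

    Each mean and each log-SD maps to a named slot; equality across birth
    order or zygosity collapses slots together.  Correlation parameters are
    always free per zygosity.
    """

    def __init__(
        self,
        covariates: bool = False,
        equal_means_birth_order: bool = False,
        equal_means_zygosity: bool = False,
        equal_var_birth_order: bool = False,
        equal_var_zygosity: bool = False,
        drop_covariate: str | None = None,
    ):
        self.covariates = covariates
        self.opts = dict(
            equal_means_birth_order=equal_means_birth_order,
            equal_means_zygosity=equal_means_zygosity,
            equal_var_birth_order=equal_var_birth_order,
            equal_var_zygosity=equal_var_zygosity,
        )
        self.drop_covariate = drop_covariate
        slots: dict = {}

        def slot(key):
            return slots.setdefault(key, len(slots))

        self.mean_map = {}
        self.lsd_map = {}
        self.v_map = {}
        for z in ZYGOSITIES:
            for e in range(4):
                wv, bo = int(ELEM_WAVE[e]), int(ELEM_TWIN[e])
                zm = "*" if equal_means_zygosity else z
                bm = "*" if equal_means_birth_order else bo
                self.mean_map[(z, e)] = slot(("mu", zm, wv, bm))
                zv = "*" if equal_var_zygosity else z
                bv = "*" if equal_var_birth_order else bo
                self.lsd_map[(z, e)] = slot(("lsd", zv, wv, bv))
            for j in range(6):
                self.v_map[(z, j)] = slot(("v", z, j))
        self.beta_map = {}
        if covariates:
            for w in (1, 2):
                for c in COVARIATES:
                    if c == drop_covariate:
                        continue
                    self.beta_map[(c, w)] = slot(("beta", c, w))
        self.slots = slots
        self.n_free = len(slots)
        # index arrays for fast unpacking
        self._mean_idx = {
            z: np.array([self.mean_map[(z, e)] for e in range(4)])
            for z in ZYGOSITIES
        }
        self._lsd_idx = {
            z: np.array([self.lsd_map[(z, e)] for e in range(4)])
            for z in ZYGOSITIES
        }
        self._v_idx = {
            z: np.array([self.v_map[(z, j)] for j in range(6)])
            for z in ZYGOSITIES
        }
        self._beta_idx = [
            (w - 1, COVARIATES.index(c), i) for (c, w), i in self.beta_map.items()
        ]

    def unpack(self, x: np.ndarray):
        means, sigmas = {}, {}
        for z in ZYGOSITIES:
            means[z] = x[self._mean_idx[z]]
            s = np.exp(x[self._lsd_idx[z]])
            R = _corr_from_v(x[self._v_idx[z]])
            sigmas[z] = R * s[:, None] * s[None, :]
        beta = None
        if self.covariates:
            beta = np.zeros((2, 3))
            for w, c, i in self._beta_idx:
                beta[w, c] = x[i]
        return means, sigmas, beta

    def warm_start_from(self, other: "SaturatedSpec", x_other: np.ndarray
                        ) -> np.ndarray:
        """Start values for this (constrained) spec from another spec's
        solution, averaging slots that a constraint merges together."""
        x = np.zeros(self.n_free)
        cnt = np.zeros(self.n_free)
        for m_self, m_other in (
            (self.mean_map, other.mean_map),
            (self.lsd_map, other.lsd_map),
            (self.v_map, other.v_map),
            ({k: v for k, v in self.beta_map.items()}, other.beta_map),
        ):
            for key, i in m_self.items():
                j = m_other.get(key)
                if j is not None:
                    x[i] += x_other[j]
                    cnt[i] += 1
        cnt[cnt == 0] = 1.0
        return x / cnt

    def start(self, data: TwinData, rng=None, jitter: float = 0.0) -> np.ndarray:
        x = np.zeros(self.n_free)
        # pool observed values per (zygosity, element)
        vals = {(z, e): [] for z in ZYGOSITIES for e in range(4)}
        complete = {z: [] for z in ZYGOSITIES}
        for g in data.groups:
            for j, e in enumerate(g.idx):
                vals[(g.zygosity, int(e))].append(g.Y[:, j])
            if len(g.idx) == 4:
                complete[g.zygosity].append(g.Y)
        filled = set()
        for z in ZYGOSITIES:
            for e in range(4):
                v = np.concatenate(vals[(z, e)]) if vals[(z, e)] else np.array([0.0])
                i = self.mean_map[(z, e)]
                if i not in filled:
                    x[i] = float(v.mean())
                    filled.add(i)
                i = self.lsd_map[(z, e)]
                if i not in filled:
                    x[i] = 0.5 * math.log(max(float(v.var()), 1e-8))
                    filled.add(i)
            if complete[z]:
                Y = np.vstack(complete[z])
                if Y.shape[0] >= 5:
                    R = np.corrcoef(Y.T)
                else:
                    R = np.eye(4)
            else:
                R = np.eye(4)
            if not np.all(np.isfinite(R)):
                R = np.eye(4)
            v = _v_from_corr(R)
            for j in range(6):
                x[self.v_map[(z, j)]] = v[j]
        if jitter > 0 and rng is not None:
            x = x + rng.normal(0.0, jitter, x.shape) * np.maximum(np.abs(x), 0.05)
        return x


@dataclass
class SaturatedFitResult:
    minus2ll: float
    n_free: int
    aic: float
    means: dict
    sigmas: dict
    beta: np.ndarray | None
    convergence: bool
    spec: SaturatedSpec = None
    x: np.ndarray | None = None


def _sat_neg2ll(spec: SaturatedSpec, x: np.ndarray, data: TwinData) -> float:
    means, sigmas, beta = spec.unpack(x)
    total = 0.0
    for g in data.groups:
        total += _group_neg2ll(g, sigmas[g.zygosity], means[g.zygosity], beta)
    if not np.isfinite(total):
        return 1.0e12
    return total


def _minimize_sat(fun, x0):
    from scipy import optimize

    return optimize.minimize(
        fun, x0, method="L-BFGS-B",
        options={"maxiter": 800, "maxfun": 40000, "ftol": 1e-11, "gtol": 1e-6},
    )


def fit_saturated(
    data: TwinData,
    covariates: bool = False,
    n_starts: int = 2,
    seed: int = 0,
    x0: np.ndarray | None = None,
    **constraints,
) -> SaturatedFitResult:
    """Fit the saturated bivariate model by FIML.

    Keyword constraints: equal_means_birth_order, equal_means_zygosity,
    equal_var_birth_order, equal_var_zygosity (booleans), drop_covariate
    (one of 'age', 'sex', 'fd').  ``x0`` adds an explicit warm start.
    """
    spec = SaturatedSpec(covariates=covariates, **constraints)
    rng = np.random.default_rng(seed)

    def objective(x):
        return _sat_neg2ll(spec, x, data)

    starts = []
    if x0 is not None:
        starts.append(np.asarray(x0, dtype=float))
    for i in range(n_starts):
        starts.append(spec.start(data, rng=rng, jitter=0.0 if i == 0 else 0.2))
    if not starts:
        raise ValueError("need n_starts >= 1 or an explicit x0")

    best, any_ok = None, False
    for s in starts:
        res = _minimize_sat(objective, s)
        if not np.isfinite(res.fun):
            continue
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if best is None:
        raise RuntimeError("saturated fit failed from all starts")
    means, sigmas, beta = spec.unpack(best.x)
    m2ll = float(best.fun)
    return SaturatedFitResult(
        minus2ll=m2ll,
        n_free=spec.n_free,
        aic=m2ll + 2 * spec.n_free,
        means=means,
        sigmas=sigmas,
        beta=beta,
        convergence=any_ok,
        spec=spec,
        x=best.x.copy(),
    )


def _lrt(full: SaturatedFitResult, constrained: SaturatedFitResult, name: str):
    chi2 = max(0.0, constrained.minus2ll - full.minus2ll)
    df = full.n_free - constrained.n_free
    return {
        "test": name,
        "chi2": chi2,
        "df": df,
        "p": float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan"),
    }


def test_assumptions(
    data: TwinData,
    covariates: bool = False,
    full: SaturatedFitResult | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Likelihood-ratio tests of classical twin-model assumptions.

    Each constrained saturated model (means or variances equated across
    birth order or zygosity) is compared against the full saturated model.
    """
    if full is None:
        full = fit_saturated(data, covariates=covariates, seed=seed)
    rows = []
    for name, kw in (
        ("means_birth_order", {"equal_means_birth_order": True}),
        ("means_zygosity", {"equal_means_zygosity": True}),
        ("variances_birth_order", {"equal_var_birth_order": True}),
        ("variances_zygosity", {"equal_var_zygosity": True}),
    ):
        warm = SaturatedSpec(covariates=covariates, **kw).warm_start_from(
            full.spec, full.x
        )
        con = fit_saturated(data, covariates=covariates, seed=seed, x0=warm,
                            n_starts=0, **kw)
        rows.append(_lrt(full, con, name))
    return pd.DataFrame(rows)


def test_covariate(
    data: TwinData,
    which: str,
    full: SaturatedFitResult | None = None,
    seed: int = 0,
) -> dict:
    """LRT of a zero covariate effect (both waves' slopes dropped at once).

    Reported for information only: covariates are always carried forward to
    the genetic models regardless of significance.
    """
    if which not in COVARIATES:
        raise ValueError(f"unknown covariate {which!r}")
    _check_covariate_varies(data, which)
    if full is None:
        full = fit_saturated(data, covariates=True, seed=seed)
    warm = SaturatedSpec(covariates=True, drop_covariate=which).warm_start_from(
        full.spec, full.x
    )
    con = fit_saturated(data, covariates=True, drop_covariate=which, seed=seed,
                        x0=warm, n_starts=0)
    row = _lrt(full, con, f"covariate_{which}")
    if full.beta is not None:
        j = COVARIATES.index(which)
        raw = data.unscale_beta(full.beta)
        row["beta_w1"] = float(raw[0, j])
        row["beta_w2"] = float(raw[1, j])
    return row


def _check_covariate_varies(data: TwinData, which: str):
    j = COVARIATES.index(which)
    vals = np.concatenate([g.X[:, :, j].ravel() for g in data.groups])
    if np.ptp(vals) == 0:
        raise ValueError(f"covariate {which!r} is constant; effect not testable")


_CORR_CELLS = {
    "rMZ_w1": ("MZ", 0, 2),
    "rMZ_w2": ("MZ", 1, 3),
    "rDZ_w1": ("DZ", 0, 2),
    "rDZ_w2": ("DZ", 1, 3),
    "rMZ_cross": ("MZ", 0, 3),
    "rDZ_cross": ("DZ", 0, 3),
    "r_w1w2_MZ": ("MZ", 0, 1),
    "r_w1w2_DZ": ("DZ", 0, 1),
}


def twin_correlations(
    data: TwinData,
    covariates: bool = False,
    fit: SaturatedFitResult | None = None,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Twin-pair and cross-wave correlations from the saturated MLE covariance.

    When covariates are modelled, the MLE covariance is the covariance of the
    covariate-adjusted phenotypes.  Confidence intervals use the Fisher-z
    approximation with the per-zygosity complete-pair count.
    """
    if fit is None:
        fit = fit_saturated(data, covariates=covariates, seed=seed)
    n_pairs = {z: 0 for z in ZYGOSITIES}
    for g in data.groups:
        if 0 in g.idx and 2 in g.idx:
            n_pairs[g.zygosity] += g.n
    z_crit = stats.norm.ppf(0.5 + level / 2)
    rows = []
    for name, (z, i, j) in _CORR_CELLS.items():
        S = fit.sigmas[z]
        r = float(S[i, j] / math.sqrt(S[i, i] * S[j, j]))
        n = max(n_pairs[z], 4)
        zr = np.arctanh(np.clip(r, -0.999999, 0.999999))
        half = z_crit / math.sqrt(n - 3)
        rows.append(
            {
                "correlation": name,
                "r": r,
                "ci_lo": float(np.tanh(zr - half)),
                "ci_hi": float(np.tanh(zr + half)),
            }
        )
    return pd.DataFrame(rows)
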