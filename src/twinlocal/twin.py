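"""Maximum-likelihood twin models: saturated and Cholesky-decomposed bivariate fits.

The classical twin design contrasts monozygotic (MZ) and dizygotic (DZ)
twin-pair covariances to split phenotypic variance into additive genetic (A),
common/shared environment (C) and unique environment plus measurement error
(E) sources.  Two measurements per person (two longitudinal waves, or two
traits) are handled with a bivariate Cholesky parameterization: a
lower-triangular path matrix per source, e.g. for A

    A = [[a11, 0  ],
         [a21, a22]]

so that the A contribution to the within-person covariance is ``A @ A.T``.
Cross-twin correlations of the latent factors are fixed at 1 (MZ) / 0.5 (DZ)
for A, 1 for C, and 0 for E.  Likelihoods are full-information (FIML): each
family contributes the multivariate-normal density of whichever of its four
possible measurements (2 twins x 2 waves) are observed, so unpaired twins and
single-wave families still inform means and variances.

Covariates (age, sex, mean framewise displacement) enter the mean structure,
never by pre-residualization, and are estimated jointly with the variance
parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CholeskyParams",
    "TwinData",
    "ModelFitResult",
    "implied_covariance",
    "fiml_neg2ll",
    "fit_cholesky",
    "fit_saturated",
    "test_assumptions",
    "test_covariate",
    "twin_correlations",
    "test_new_influence",
    "test_amplification",
    "select_model",
    "decompose_variance",
    "profile_ci",
    "cross_trait_cholesky",
]

LOG2PI = math.log(2.0 * math.pi)

#: order of the four measurements within a family
ELEMENTS = ("t1w1", "t1w2", "t2w1", "t2w2")
#: wave index (0-based) of each element
ELEM_WAVE = np.array([0, 1, 0, 1])
#: birth order (1-based) of each element
ELEM_TWIN = np.array([1, 1, 2, 2])

PATH_NAMES = ("a11", "a21", "a22", "c11", "c21", "c22", "e11", "e21", "e22")
#: diagonal paths are sign-fixed >= 0 to remove reflection non-identifiability
DIAGONAL_PATHS = frozenset({"a11", "a22", "c11", "c22", "e11", "e22"})
COVARIATES = ("age", "sex", "fd")

_SINGULAR_PENALTY = 1.0e12


# --------------------------------------------------------------------------
# parameters and implied covariance
# --------------------------------------------------------------------------

@dataclass
class CholeskyParams:
    """Path coefficients, means and covariate slopes of a bivariate ACE model.

    ``beta`` is a (2, 3) array of slopes for (age, sex, fd) per wave, or
    ``None`` when the mean structure carries no covariates.
    """

    a11: float = 0.0
    a21: float = 0.0
    a22: float = 0.0
    c11: float = 0.0
    c21: float = 0.0
    c22: float = 0.0
    e11: float = 1.0
    e21: float = 0.0
    e22: float = 1.0
    mu1: float = 0.0
    mu2: float = 0.0
    beta: np.ndarray | None = None

    def path_matrix(self, source: str) -> np.ndarray:
        s = source.lower()
        return np.array(
            [
                [getattr(self, s + "11"), 0.0],
                [getattr(self, s + "21"), getattr(self, s + "22")],
            ]
        )

    def mu(self) -> np.ndarray:
        return np.array([self.mu1, self.mu2, self.mu1, self.mu2])


def implied_covariance(p: CholeskyParams, zygosity: str) -> np.ndarray:
    """Model-implied 4x4 covariance over (twin1 w1, twin1 w2, twin2 w1, twin2 w2).

    Within-twin block AA' + CC' + EE'; cross-twin block k AA' + CC' with
    k = 1 (MZ) or 0.5 (DZ).  Positive semidefinite by construction.
    """
    k = 1.0 if zygosity == "MZ" else 0.5
    a11, a21, a22 = p.a11, p.a21, p.a22
    c11, c21, c22 = p.c11, p.c21, p.c22
    e11, e21, e22 = p.e11, p.e21, p.e22
    # AA' cells
    A11 = a11 * a11
    A12 = a11 * a21
    A22 = a21 * a21 + a22 * a22
    C11 = c11 * c11
    C12 = c11 * c21
    C22 = c21 * c21 + c22 * c22
    E11 = e11 * e11
    E12 = e11 * e21
    E22 = e21 * e21 + e22 * e22
    w11 = A11 + C11 + E11
    w12 = A12 + C12 + E12
    w22 = A22 + C22 + E22
    x11 = k * A11 + C11
    x12 = k * A12 + C12
    x22 = k * A22 + C22
    return np.array(
        [
            [w11, w12, x11, x12],
            [w12, w22, x12, x22],
            [x11, x12, w11, w12],
            [x12, x22, w12, w22],
        ]
    )


# --------------------------------------------------------------------------
# data container
# --------------------------------------------------------------------------

@dataclass
class _Group:
    """Families sharing one zygosity and one missingness pattern."""

    zygosity: str
    idx: np.ndarray            # observed element indices, ascending
    Y: np.ndarray              # (n, k) observed phenotypes
    X: np.ndarray              # (n, k, 3) covariates (age, sex, fd) per element
    n: int = 0
    ybar: np.ndarray | None = None
    scatter: np.ndarray | None = None

    def __post_init__(self):
        self.n = self.Y.shape[0]
        self.ybar = self.Y.mean(axis=0)
        R = self.Y - self.ybar
        self.scatter = R.T @ R
        self.ix = np.ix_(self.idx, self.idx)


class TwinData:
    """Per-family twin observations grouped by zygosity and missingness pattern.

    Built from a long table with one row per individual per wave; see
    :meth:`from_long`.  Families with no observed phenotype at all are dropped.
    Covariates are standardized at construction (``covariate_offset`` and
    ``covariate_scale`` keep mean and SD) so the likelihood surface stays
    well conditioned; fitted slopes are on the standardized scale and are
    mapped back with :meth:`unscale_beta` wherever they are reported.
    """

    def __init__(self, groups: list[_Group],
                 covariate_offset: np.ndarray | None = None,
                 covariate_scale: np.ndarray | None = None):
        self.groups = groups
        self.n_families = sum(g.n for g in groups)
        self.n_obs = sum(g.n * len(g.idx) for g in groups)
        self.covariate_offset = (
            np.zeros(3) if covariate_offset is None else covariate_offset
        )
        self.covariate_scale = (
            np.ones(3) if covariate_scale is None else covariate_scale
        )

    @staticmethod
    def _center(groups: list[_Group]) -> tuple[np.ndarray, np.ndarray]:
        X = np.concatenate([g.X.reshape(-1, 3) for g in groups])
        offset = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        for g in groups:
            g.X = (g.X - offset) / scale
        return offset, scale

    def unscale_beta(self, beta: np.ndarray) -> np.ndarray:
        """Slopes per original covariate unit from standardized-scale slopes."""
        return np.asarray(beta) / self.covariate_scale

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        value_col: str = "value",
    ) -> "TwinData":
        """Pivot a long phenotype table into grouped family arrays.

        Required columns: family_id, birth_order (1/2), zygosity (MZ/DZ),
        wave (1/2), and ``value_col``.  Optional covariate columns
        age_years, sex, mean_fd_mm (missing ones are treated as zero).
        """
        df = df.copy()
        for col, default in (("age_years", 0.0), ("sex", 0.0), ("mean_fd_mm", 0.0)):
            if col not in df.columns:
                df[col] = default
        rows: dict = {}
        for rec in df.itertuples(index=False):
            fid = rec.family_id
            bo = int(rec.birth_order)
            wv = int(rec.wave)
            elem = (bo - 1) * 2 + (wv - 1)
            ent = rows.setdefault(
                fid,
                {
                    "zyg": rec.zygosity,
                    "y": np.full(4, np.nan),
                    "x": np.zeros((4, 3)),
                },
            )
            v = getattr(rec, value_col)
            ent["y"][elem] = v
            ent["x"][elem] = (rec.age_years, rec.sex, rec.mean_fd_mm)
        buckets: dict = {}
        for ent in rows.values():
            obs = np.flatnonzero(np.isfinite(ent["y"]))
            if obs.size == 0:
                continue
            key = (ent["zyg"], tuple(obs))
            buckets.setdefault(key, []).append(ent)
        groups = []
        for (zyg, obs), ents in sorted(buckets.items()):
            idx = np.array(obs)
            Y = np.array([e["y"][idx] for e in ents])
            X = np.array([e["x"][idx] for e in ents])
            groups.append(_Group(zyg, idx, Y, X))
        if not groups:
            raise ValueError("no families with observed phenotypes")
        offset, scale = cls._center(groups)
        return cls(groups, covariate_offset=offset, covariate_scale=scale)

    @classmethod
    def from_arrays(
        cls,
        zygosity: np.ndarray,
        y: np.ndarray,
        x: np.ndarray | None = None,
    ) -> "TwinData":
        """Build directly from per-family arrays.

        ``y`` is (n_families, 4) with NaN for missing entries, element order
        (twin1 w1, twin1 w2, twin2 w1, twin2 w2); ``x`` is (n, 4, 3) covariates.
        """
        y = np.asarray(y, dtype=float)
        if x is None:
            x = np.zeros(y.shape + (3,))
        buckets: dict = {}
        for i in range(y.shape[0]):
            obs = np.flatnonzero(np.isfinite(y[i]))
            if obs.size == 0:
                continue
            buckets.setdefault((str(zygosity[i]), tuple(obs)), []).append(i)
        groups = []
        for (zyg, obs), ii in sorted(buckets.items()):
            idx = np.array(obs)
            groups.append(_Group(zyg, idx, y[np.ix_(ii, idx)], x[np.ix_(ii, idx)]))
        if not groups:
            raise ValueError("no families with observed phenotypes")
        return cls(groups)


# --------------------------------------------------------------------------
# FIML likelihood
# --------------------------------------------------------------------------

def _group_neg2ll(g: _Group, sigma4: np.ndarray, mu4: np.ndarray,
                  beta: np.ndarray | None) -> float:
    k = len(g.idx)
    sub = sigma4[g.ix]
    try:
        L = np.linalg.cholesky(sub)
        logdet = 2.0 * float(np.log(L.diagonal()).sum())
        base = g.n * (k * LOG2PI + logdet)
        mu_obs = mu4[g.idx]
        if beta is None:
            d = g.ybar - mu_obs
            P = g.scatter + g.n * np.outer(d, d)
            return base + float(np.linalg.solve(sub, P).trace())
        # means vary per family through covariate slopes
        B = beta[ELEM_WAVE[g.idx]]                      # (k, 3)
        M = mu_obs + np.einsum("nkc,kc->nk", g.X, B)
        R = g.Y - M
        Z = np.linalg.solve(sub, R.T)
        return base + float(np.sum(R.T * Z))
    except np.linalg.LinAlgError:
        return _SINGULAR_PENALTY * (1.0 + abs(float(np.trace(sub))))


def fiml_neg2ll(p: CholeskyParams, data: TwinData) -> float:
    """Full-information -2 log-likelihood of a Cholesky model on twin data.

    Each family contributes the MVN -2 log density of its observed subvector,
    with the implied covariance and mean structure marginalized to the
    observed entries.  A numerically singular marginal covariance yields a
    large penalized value so optimizers retreat into the valid region.
    """
    mu4 = p.mu()
    total = 0.0
    sig = {z: implied_covariance(p, z) for z in ("MZ", "DZ")}
    for g in data.groups:
        total += _group_neg2ll(g, sig[g.zygosity], mu4, p.beta)
    if not np.isfinite(total):
        return _SINGULAR_PENALTY
    return total


# --------------------------------------------------------------------------
# free-parameter bookkeeping
# --------------------------------------------------------------------------

class CholeskySpec:
    """Maps a free-parameter vector to :class:`CholeskyParams`.

    ``components`` selects which sources carry free paths ("ACE", "AE", "CE",
    "E"); paths of excluded sources are fixed at zero.  ``fixed`` pins named
    paths to values (e.g. ``{"a22": 0.0}``) and ``tied`` aliases one path to
    another (e.g. ``{"a21": "a11"}``) for constraint tests.
    """

    def __init__(
        self,
        components: str = "ACE",
        covariates: bool = False,
        fixed: dict | None = None,
        tied: dict | None = None,
    ):
        components = components.upper()
        if "E" not in components or not set(components) <= set("ACE"):
            raise ValueError(f"invalid component set {components!r}")
        self.components = components
        self.covariates = covariates
        self.fixed = dict(fixed or {})
        self.tied = dict(tied or {})
        free = []
        for name in PATH_NAMES:
            if name[0].upper() not in components:
                continue
            if name in self.fixed or name in self.tied:
                continue
            free.append(name)
        free += ["mu1", "mu2"]
        if covariates:
            free += [f"b_{c}{w}" for w in (1, 2) for c in COVARIATES]
        self.free_names = free
        self.n_free = len(free)

    def make_params(self, x: np.ndarray) -> CholeskyParams:
        vals = dict(zip(self.free_names, x))
        kw = {name: 0.0 for name in PATH_NAMES}
        kw.update({k: v for k, v in vals.items() if k in PATH_NAMES})
        kw.update(self.fixed)
        for name, src in self.tied.items():
            kw[name] = kw.get(src, vals.get(src, 0.0))
        kw["mu1"] = vals["mu1"]
        kw["mu2"] = vals["mu2"]
        beta = None
        if self.covariates:
            beta = np.array(
                [[vals[f"b_{c}{w}"] for c in COVARIATES] for w in (1, 2)]
            )
        return CholeskyParams(beta=beta, **kw)

    def bounds(self) -> list:
        return [
            (0.0, None) if name in DIAGONAL_PATHS else (None, None)
            for name in self.free_names
        ]

    # -- moment-based starting values ------------------------------------

    def start(self, data: TwinData, rng: np.random.Generator | None = None,
              jitter: float = 0.0) -> np.ndarray:
        mom = _sample_moments(data)
        v1, v2 = max(mom["v1"], 1e-8), max(mom["v2"], 1e-8)
        h2 = float(np.clip(2.0 * (mom["rmz"] - mom["rdz"]), 0.05, 0.85))
        c2 = float(np.clip(2.0 * mom["rdz"] - mom["rmz"], 0.03, 0.6))
        if "A" not in self.components:
            h2 = 0.0
        if "C" not in self.components:
            c2 = 0.0
        e2 = max(1.0 - h2 - c2, 0.1)
        tot = h2 + c2 + e2
        h2, c2, e2 = h2 / tot, c2 / tot, e2 / tot
        rw = float(np.clip(mom["r12"], -0.8, 0.8))
        vals = {}
        for comp, frac in (("a", h2), ("c", c2), ("e", e2)):
            s1 = math.sqrt(max(frac * v1, 1e-10))
            s2 = math.sqrt(max(frac * v2, 1e-10))
            vals[comp + "11"] = s1
            vals[comp + "21"] = rw * s2
            vals[comp + "22"] = math.sqrt(max(s2 * s2 * (1 - rw * rw), 1e-10))
        vals["mu1"], vals["mu2"] = mom["m1"], mom["m2"]
        x0 = np.array(
            [vals.get(name, 0.0) for name in self.free_names]
        )
        if jitter > 0 and rng is not None:
            scale = np.maximum(np.abs(x0), 0.1 * math.sqrt(v1))
            x0 = x0 + rng.normal(0.0, jitter, x0.shape) * scale
            # respect sign constraints on diagonal paths
            for i, name in enumerate(self.free_names):
                if name in DIAGONAL_PATHS:
                    x0[i] = abs(x0[i])
        return x0


def _sample_moments(data: TwinData) -> dict:
    """Crude moment summaries used only for optimizer starting values."""
    y1, y2 = [], []
    pairs = {"MZ": [], "DZ": []}
    cross = []
    for g in data.groups:
        for j, e in enumerate(g.idx):
            (y1 if ELEM_WAVE[e] == 0 else y2).append(g.Y[:, j])
        if 0 in g.idx and 2 in g.idx:
            j0, j2 = list(g.idx).index(0), list(g.idx).index(2)
            pairs[g.zygosity].append(np.c_[g.Y[:, j0], g.Y[:, j2]])
        if 0 in g.idx and 1 in g.idx:
            j0, j1 = list(g.idx).index(0), list(g.idx).index(1)
            cross.append(np.c_[g.Y[:, j0], g.Y[:, j1]])
    y1 = np.concatenate(y1) if y1 else np.array([0.0])
    y2 = np.concatenate(y2) if y2 else y1

    def _corr(blocks, default):
        if not blocks:
            return default
        m = np.vstack(blocks)
        if m.shape[0] < 3:
            return default
        r = np.corrcoef(m[:, 0], m[:, 1])[0, 1]
        return default if not np.isfinite(r) else r

    return {
        "m1": float(y1.mean()),
        "m2": float(y2.mean()),
        "v1": float(y1.var()),
        "v2": float(y2.var()),
        "rmz": _corr(pairs["MZ"], 0.5),
        "rdz": _corr(pairs["DZ"], 0.3),
        "r12": _corr(cross, 0.4),
    }


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass
class ModelFitResult:
    """Outcome of one maximum-likelihood fit."""

    minus2ll: float
    n_free: int
    aic: float
    params: CholeskyParams
    convergence: bool
    label: str = ""
    x: np.ndarray | None = None
    spec: CholeskySpec | None = None
    data: TwinData | None = None
    profile_cis: dict = field(default_factory=dict)


def _minimize(fun, x0, bounds):
    return optimize.minimize(
        fun, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 1000, "maxfun": 20000, "ftol": 1e-12, "gtol": 1e-7},
    )


def _minimize_fast(fun, x0, bounds):
    # looser tolerance for profile refits, where only the deviance at the
    # constrained optimum matters (to ~1e-3)
    return optimize.minimize(
        fun, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 300, "maxfun": 6000, "ftol": 1e-10, "gtol": 1e-5},
    )


def fit_cholesky(
    data: TwinData,
    components: str = "ACE",
    covariates: bool = False,
    n_starts: int = 5,
    seed: int = 0,
    fixed: dict | None = None,
    tied: dict | None = None,
    x0: np.ndarray | None = None,
) -> ModelFitResult:
    """Fit a Cholesky twin model by FIML with seeded multi-start optimization.

    The first start is moment-based; subsequent starts jitter it.  ``x0``
    adds an explicit warm start (used by constraint tests and profile CIs).
    """
    spec = CholeskySpec(components, covariates, fixed=fixed, tied=tied)
    rng = np.random.default_rng(seed)
    bounds = spec.bounds()

    def objective(x):
        return fiml_neg2ll(spec.make_params(x), data)

    starts = []
    if x0 is not None:
        starts.append(np.asarray(x0, dtype=float))
    starts.append(spec.start(data))
    while len(starts) < n_starts + (1 if x0 is not None else 0):
        starts.append(spec.start(data, rng=rng, jitter=0.3))

    best = None
    any_ok = False
    for s in starts:
        res = _minimize(objective, s, bounds)
        if not np.isfinite(res.fun):
            continue
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if best is None:
        raise RuntimeError("all optimization starts failed")
    params = spec.make_params(best.x)
    m2ll = float(best.fun)
    return ModelFitResult(
        minus2ll=m2ll,
        n_free=spec.n_free,
        aic=m2ll + 2.0 * spec.n_free,
        params=params,
        convergence=any_ok and m2ll < _SINGULAR_PENALTY / 2,
        label=components,
        x=best.x.copy(),
        spec=spec,
        data=data,
    )


# --------------------------------------------------------------------------
# constraint tests on the Cholesky model
# --------------------------------------------------------------------------

def _refit_constrained(fit: ModelFitResult, fixed=None, tied=None) -> ModelFitResult:
    spec = fit.spec
    new_fixed = dict(spec.fixed)
    new_fixed.update(fixed or {})
    new_tied = dict(spec.tied)
    new_tied.update(tied or {})
    cspec = CholeskySpec(spec.components, spec.covariates, new_fixed, new_tied)
    warm = np.array([
        dict(zip(spec.free_names, fit.x)).get(n, 0.0) for n in cspec.free_names
    ])
    return fit_cholesky(
        fit.data, spec.components, spec.covariates,
        n_starts=2, seed=7, fixed=new_fixed, tied=new_tied, x0=warm,
    )


def _lrt_row(name, full, constrained, mixture=False):
    chi2 = max(0.0, constrained.minus2ll - full.minus2ll)
    df = full.n_free - constrained.n_free
    if mixture:
        # 50:50 chi2_0 : chi2_1 mixture for a boundary null
        p = 0.5 * stats.chi2.sf(chi2, 1) if chi2 > 0 else 1.0
    else:
        p = stats.chi2.sf(chi2, df) if df > 0 else float("nan")
    return {"test": name, "chi2": chi2, "df": df, "p": float(p),
            "constrained_fit": constrained}


def test_new_influence(fit: ModelFitResult, component: str = "A",
                       mixture: bool = False) -> dict:
    """LRT for wave-2-specific variance: fix the second diagonal path to zero.

    With the diagonal path (a22 or c22) at zero, the wave-1 latent factor
    alone carries that source's wave-2 variance.  The standard chi-square(1)
    reference is conservative at this boundary null; ``mixture`` switches to
    the 50:50 chi2(0):chi2(1) mixture.
    """
    comp = component.lower()
    if comp not in ("a", "c"):
        raise ValueError("component must be 'A' or 'C'")
    if comp.upper() not in fit.spec.components:
        raise ValueError(f"component {component} not in fitted model")
    con = _refit_constrained(fit, fixed={comp + "22": 0.0})
    return _lrt_row(f"{comp}22=0", fit, con, mixture=mixture)


def test_amplification(fit: ModelFitResult, component: str = "A") -> dict:
    """LRT for a change in strength of the continuing influence (x21 = x11).

    Also reports the direction in the unconstrained fit: 'deamplification'
    when the continuing path weakens at wave 2 (x21 < x11), 'amplification'
    when it strengthens.
    """
    comp = component.lower()
    if comp.upper() not in fit.spec.components:
        raise ValueError(f"component {component} not in fitted model")
    con = _refit_constrained(fit, tied={comp + "21": comp + "11"})
    row = _lrt_row(f"{comp}21={comp}11", fit, con)
    x21 = getattr(fit.params, comp + "21")
    x11 = getattr(fit.params, comp + "11")
    row["direction"] = "deamplification" if x21 < x11 else "amplification"
    return row


def select_model(fits: list[ModelFitResult]) -> tuple[ModelFitResult, bool]:
    """Pick the minimum-AIC converged fit; flag runner-up within 2 AIC units.

    Exact AIC ties are broken toward the model with fewer free parameters.
    """
    ok = [f for f in fits if f.convergence]
    if not ok:
        raise RuntimeError("no converged fits to select from")
    ok = sorted(ok, key=lambda f: (f.aic, f.n_free))
    ambiguous = len(ok) > 1 and (ok[1].aic - ok[0].aic) < 2.0
    return ok[0], ambiguous


# --------------------------------------------------------------------------
# variance decomposition and derived quantities
# --------------------------------------------------------------------------

def decompose_variance(fit: ModelFitResult) -> dict:
    """Raw and standardized variance components per wave, plus the
    per-latent-factor split of wave-2 variance (continuing vs new)."""
    p = fit.params
    raw = {
        "A": (p.a11 ** 2, p.a21 ** 2 + p.a22 ** 2),
        "C": (p.c11 ** 2, p.c21 ** 2 + p.c22 ** 2),
        "E": (p.e11 ** 2, p.e21 ** 2 + p.e22 ** 2),
    }
    v1 = sum(v[0] for v in raw.values())
    v2 = sum(v[1] for v in raw.values())
    out = {
        "raw": {k: {"w1": v[0], "w2": v[1]} for k, v in raw.items()},
        "total": {"w1": v1, "w2": v2},
        "std": {
            k: {"w1": v[0] / v1 if v1 > 0 else np.nan,
                "w2": v[1] / v2 if v2 > 0 else np.nan}
            for k, v in raw.items()
        },
        # wave-2 split: variance through the wave-1 factor (continuing)
        # vs the wave-2-specific factor (new)
        "w2_split": {
            "A": {"continuing": p.a21 ** 2 / v2 if v2 > 0 else np.nan,
                  "new": p.a22 ** 2 / v2 if v2 > 0 else np.nan},
            "C": {"continuing": p.c21 ** 2 / v2 if v2 > 0 else np.nan,
                  "new": p.c22 ** 2 / v2 if v2 > 0 else np.nan},
            "E": {"continuing": p.e21 ** 2 / v2 if v2 > 0 else np.nan,
                  "new": p.e22 ** 2 / v2 if v2 > 0 else np.nan},
        },
    }
    return out


def _source_correlation(x11, x21, x22):
    denom = abs(x11) * math.hypot(x21, x22)
    if denom == 0:
        return float("nan")
    return float(np.clip(x11 * x21 / denom, -1.0, 1.0))


def quantity_value(p: CholeskyParams, quantity: str) -> float:
    """Evaluate a named scalar quantity of the model parameters.

    Supported: any path or mean by name; ``std_{a,c,e}{1,2}`` standardized
    proportions; ``var_{a,c,e}{1,2}`` and ``var_tot{1,2}`` raw variances;
    ``r_a``, ``r_c``, ``r_e`` source correlations across the two variables;
    ``r_ph`` the implied within-twin cross correlation.
    """
    q = quantity.lower()
    if hasattr(p, q) and q in PATH_NAMES + ("mu1", "mu2"):
        return float(getattr(p, q))
    comps = {"a": (p.a11, p.a21, p.a22), "c": (p.c11, p.c21, p.c22),
             "e": (p.e11, p.e21, p.e22)}
    v1 = sum(c[0] ** 2 for c in comps.values())
    v2 = sum(c[1] ** 2 + c[2] ** 2 for c in comps.values())
    if q.startswith("std_") or q.startswith("var_"):
        tag = q.split("_")[1]
        if tag.startswith("tot"):
            return float(v1 if tag[-1] == "1" else v2)
        comp, wave = tag[0], tag[1]
        x = comps[comp]
        raw = x[0] ** 2 if wave == "1" else x[1] ** 2 + x[2] ** 2
        if q.startswith("var_"):
            return float(raw)
        tot = v1 if wave == "1" else v2
        return float(raw / tot) if tot > 0 else float("nan")
    if q in ("r_a", "r_c", "r_e"):
        return _source_correlation(*comps[q[-1]])
    if q == "r_ph":
        sig = implied_covariance(p, "MZ")
        d = math.sqrt(sig[0, 0] * sig[1, 1])
        return float(sig[0, 1] / d) if d > 0 else float("nan")
    raise ValueError(f"unknown quantity {quantity!r}")


# --------------------------------------------------------------------------
# profile-likelihood confidence intervals
# --------------------------------------------------------------------------

def _profile_objective_std(fit: ModelFitResult, quantity: str):
    """Build a reparameterized objective with a standardized proportion pinned.

    For a wave-1 proportion t of source X, the constraint
    x11^2 = t/(1-t) * (sum of the other sources' wave-1 squares) lets x11 be
    derived from the remaining free paths.  At wave 2 the magnitude of
    (x21, x22) is derived the same way, with its direction kept free as an
    angle.  Returns (objective(x, t), reduced names, reducer) or None when
    the quantity is not a standardized proportion of a free source.
    """
    q = quantity.lower()
    if not q.startswith("std_"):
        return None
    comp, wave = q[4], q[5]
    spec = fit.spec
    if comp.upper() not in spec.components or spec.tied or comp + "11" in spec.fixed:
        return None
    others = [c for c in "ace" if c.upper() in spec.components and c != comp]
    if not others:
        return None
    names = list(spec.free_names)
    if wave == "1":
        tgt = comp + "11"
        if tgt not in names:
            return None
        red_names = [n for n in names if n != tgt]

        def build(xr, t):
            vals = dict(zip(red_names, xr))
            s = sum(vals.get(o + "11", 0.0) ** 2 for o in others)
            vals[tgt] = math.sqrt(max(t / max(1.0 - t, 1e-9) * s, 0.0))
            return np.array([vals[n] for n in names])
    else:
        t21, t22 = comp + "21", comp + "22"
        if t21 not in names or t22 not in names:
            return None
        red_names = [n for n in names if n not in (t21, t22)] + ["_phi"]

        def build(xr, t):
            vals = dict(zip(red_names, xr))
            phi = vals.pop("_phi")
            s = sum(
                vals.get(o + "21", 0.0) ** 2 + vals.get(o + "22", 0.0) ** 2
                for o in others
            )
            m = math.sqrt(max(t / max(1.0 - t, 1e-9) * s, 0.0))
            vals[t21] = m * math.cos(phi)
            vals[t22] = abs(m * math.sin(phi))
            return np.array([vals[n] for n in names])

    data = fit.data

    def objective(xr, t):
        return fiml_neg2ll(spec.make_params(build(xr, t)), data)

    def start_from(x_full):
        vals = dict(zip(names, x_full))
        if wave == "1":
            return np.array([vals[n] for n in red_names])
        phi = math.atan2(abs(vals[t22]), vals[t21])
        xr = [vals[n] for n in red_names[:-1]] + [phi]
        return np.array(xr)

    red_bounds = []
    for n in red_names:
        if n == "_phi":
            red_bounds.append((None, None))
        else:
            red_bounds.append((0.0, None) if n in DIAGONAL_PATHS else (None, None))
    return objective, start_from, red_bounds


_QUANT_DOMAIN = {
    "std": (0.0, 1.0),
    "r_": (-1.0, 1.0),
}


def _quantity_domain(quantity: str):
    q = quantity.lower()
    if q.startswith("std_"):
        return 0.0, 1.0
    if q.startswith("r_"):
        return -1.0, 1.0
    if q.startswith("var_") or q in DIAGONAL_PATHS:
        return 0.0, None
    return None, None


def profile_ci(
    fit: ModelFitResult,
    quantity: str,
    level: float = 0.95,
    max_refits: int = 60,
) -> tuple[float, float]:
    """Likelihood-based confidence interval for a scalar quantity.

    Each bound is the value at which the profile deviance (with all other
    free parameters re-optimized) rises by the chi-square(1) quantile of
    ``level`` above the minimum.  Bounds that run into the edge of the
    parameter space (e.g. a proportion at 0 or 1) are reported at that edge.
    Falls back to a Wald interval if the profile search fails.
    """
    qhat = quantity_value(fit.params, quantity)
    crit = stats.chi2.ppf(level, 1)
    target = fit.minus2ll + crit
    lo_dom, hi_dom = _quantity_domain(quantity)
    budget = [max_refits]

    fast = _profile_objective_std(fit, quantity)
    warm = {"x": None}

    if fast is not None:
        objective, start_from, red_bounds = fast
        x_base = start_from(fit.x)
        warm["x"] = x_base
        shift = fit.minus2ll  # optimize O(1) values: the relative-reduction
        # stopping rule is far too coarse on a deviance of ~1e4-1e5

        def profdev(t):
            if budget[0] <= 0:
                raise RuntimeError("profile refit budget exhausted")
            budget[0] -= 1
            # warm-start chaining is fast but can drag a poor local solution
            # along the profile; race it against a start derived from the
            # unconstrained optimum and keep the better one
            best = None
            for x0 in (warm["x"], x_base):
                res = _minimize_fast(
                    lambda xr: objective(xr, t) - shift, x0, red_bounds
                )
                if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                    best = res
                if x0 is x_base and warm["x"] is x_base:
                    break  # identical starts
            if best is None:
                return float("inf")
            warm["x"] = best.x
            return float(best.fun) + shift
    else:
        spec = fit.spec
        data = fit.data
        bounds = spec.bounds()
        warm["x"] = fit.x.copy()

        shift = fit.minus2ll

        def profdev(t):
            if budget[0] <= 0:
                raise RuntimeError("profile refit budget exhausted")
            budget[0] -= 1
            cons = {
                "type": "eq",
                "fun": lambda x: quantity_value(spec.make_params(x), quantity) - t,
            }
            res = optimize.minimize(
                lambda x: fiml_neg2ll(spec.make_params(x), data) - shift,
                warm["x"], method="SLSQP", bounds=bounds, constraints=[cons],
                options={"maxiter": 200, "ftol": 1e-10},
            )
            if np.isfinite(res.fun):
                warm["x"] = res.x
            return float(res.fun) + shift

    # memoize: profdev depends on warm-start state, and a root finder needs
    # one consistent value per t
    cache: dict = {}
    profdev_raw = profdev

    def profdev(t):
        if t not in cache:
            cache[t] = profdev_raw(t)
        return cache[t]

    try:
        bounds_out = []
        scale = max(abs(qhat), 0.1)
        for sign in (-1.0, +1.0):
            edge = lo_dom if sign < 0 else hi_dom

            def clamp(t):
                if edge is None:
                    return t, False
                if (sign < 0 and t <= edge) or (sign > 0 and t >= edge):
                    return edge, True
                return t, False

            # probe once, then jump near the crossing assuming a locally
            # quadratic profile deviance
            d0 = 0.1 * scale
            t_try, at_edge = clamp(qhat + sign * d0)
            f_try = profdev(t_try)
            t_in, t_out = qhat, None
            if f_try >= target:
                t_out = t_try
            elif not at_edge:
                t_in = t_try
                curv = max(f_try - fit.minus2ll, 1e-8) / d0**2
                step = 1.3 * math.sqrt(crit / curv)
                while True:
                    t_try, at_edge = clamp(qhat + sign * step)
                    f_try = profdev(t_try)
                    if f_try >= target:
                        t_out = t_try
                        break
                    if at_edge:
                        break  # deviance never crosses inside the domain
                    t_in = t_try
                    step *= 1.7
            if t_out is None:
                bounds_out.append(edge)
                continue
            lo, hi = (t_out, t_in) if sign < 0 else (t_in, t_out)
            root = optimize.brentq(
                lambda t: profdev(t) - target, lo, hi,
                xtol=5e-4 * scale, maxiter=40,
            )
            bounds_out.append(float(root))
        lo, hi = bounds_out
    except (RuntimeError, ValueError) as exc:
        warnings.warn(
            f"profile CI for {quantity} failed ({exc}); falling back to a "
            "Wald interval", stacklevel=2,
        )
        lo, hi = _wald_ci(fit, quantity, level)
    fit.profile_cis[quantity] = (lo, hi)
    return lo, hi


def _wald_ci(fit: ModelFitResult, quantity: str, level: float):
    """Delta-method interval from a finite-difference Hessian (fallback)."""
    spec, data = fit.spec, fit.data
    x = fit.x
    n = x.size
    h = 1e-4 * np.maximum(np.abs(x), 1.0)

    def f(v):
        return fiml_neg2ll(spec.make_params(v), data)

    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xi, xj = h[i], h[j]
            xpp = x.copy(); xpp[i] += xi; xpp[j] += xj
            xpm = x.copy(); xpm[i] += xi; xpm[j] -= xj
            xmp = x.copy(); xmp[i] -= xi; xmp[j] += xj
            xmm = x.copy(); xmm[i] -= xi; xmm[j] -= xj
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * xi * xj)
    H *= 0.5  # Hessian of -lnL
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    g = np.zeros(n)
    for i in range(n):
        xp = x.copy(); xp[i] += h[i]
        xm = x.copy(); xm[i] -= h[i]
        g[i] = (
            quantity_value(spec.make_params(xp), quantity)
            - quantity_value(spec.make_params(xm), quantity)
        ) / (2 * h[i])
    var = float(g @ cov @ g)
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    qhat = quantity_value(fit.params, quantity)
    lo, hi = qhat - z * se, qhat + z * se
    lo_d, hi_d = _quantity_domain(quantity)
    if lo_d is not None:
        lo = max(lo, lo_d)
    if hi_d is not None:
        hi = min(hi, hi_d)
    return lo, hi


# --------------------------------------------------------------------------
# cross-trait (two traits, one occasion) correlations
# --------------------------------------------------------------------------

@dataclass
class CrossTraitCorrelations:
    r_phenotypic: float
    r_a: float
    r_c: float
    r_e: float
    cis: dict = field(default_factory=dict)


def cross_trait_cholesky(
    data: TwinData,
    covariates: bool = False,
    n_starts: int = 5,
    seed: int = 0,
    with_cis: bool = False,
) -> tuple[CrossTraitCorrelations, ModelFitResult]:
    """Bivariate Cholesky fit of a two-trait twin table; source correlations.

    The two "waves" of the data container hold the two traits.  The genetic
    correlation is r_A = a11 a21 / (|a11| sqrt(a21^2 + a22^2)); C and E
    analogous; the phenotypic correlation comes from the implied within-twin
    cross-trait covariance.
    """
    fit = fit_cholesky(data, "ACE", covariates=covariates,
                       n_starts=n_starts, seed=seed)
    p = fit.params
    out = CrossTraitCorrelations(
        r_phenotypic=quantity_value(p, "r_ph"),
        r_a=quantity_value(p, "r_a"),
        r_c=quantity_value(p, "r_c"),
        r_e=quantity_value(p, "r_e"),
    )
    if with_cis:
        for q in ("r_a", "r_e"):
            out.cis[q] = profile_ci(fit, q)
    return out, fit


# saturated-model operations share the FIML grouping machinery defined above
from .saturated import (  # noqa: E402
    fit_saturated,
    test_assumptions,
    test_covariate,
    twin_correlations,
)
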