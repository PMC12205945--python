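"""Brain-behavior association stage.

Two analyses link ROI-level ReHo/fALFF values to behavioral totals
(anxiety/depression scales or a cognition composite):

* :func:`fit_lmm` — a two-level random-intercept linear mixed model across
  waves: behavior ~ brain + age + sex + mean FD + wave, with random
  intercepts for family (relatedness) and participant nested in family
  (repeated measurement).  Waves are coded 0/1.  The reported p-value for
  the brain predictor is a Wald z test.

* :func:`brain_behavior_twin` — a bivariate Cholesky twin model with the
  (brain metric, behavior score) pair as the two variables, per wave,
  yielding genetic and unique-environment correlations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import norm

from .twin import TwinData, cross_trait_cholesky

__all__ = ["fit_lmm", "brain_behavior_twin", "build_two_trait_table"]

_FIXED = ["roi_value", "age", "sex", "mean_fd", "wave"]


def fit_lmm(
    rows: pd.DataFrame,
    response: str = "behavior_score",
    predictor: str = "roi_value",
    reml: bool = False,
) -> dict:
    """Random-intercept LMM of a behavior score on an ROI metric.

    ``rows`` needs columns participant_id, family_id, wave (0/1), age, sex,
    mean_fd, plus the response and predictor.  A singular nested structure
    (participant variance indistinguishable from residual) triggers a refit
    with the family intercept only, with a warning.
    Returns estimate, SE, Wald z and p for the predictor, plus the fit.
    """
    df = rows.dropna(subset=[response, predictor]).copy()
    if df["wave"].nunique() < 2:
        raise ValueError("need observations from both waves")
    fixed = " + ".join([predictor, "age", "sex", "mean_fd", "wave"])
    formula = f"{response} ~ {fixed}"
    vcf = {"participant": "0 + C(participant_id)"}

    def _fit(with_participant):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                formula,
                df,
                groups=df["family_id"],
                re_formula="1",
                vc_formula=vcf if with_participant else None,
            )
            return model.fit(reml=reml, method="lbfgs")

    res = None
    try:
        res = _fit(True)
    except (np.linalg.LinAlgError, ValueError):
        res = None
    if res is None or not np.all(np.isfinite(res.bse_fe)):
        warnings.warn(
            "singular participant-within-family structure; refitting with "
            "family intercept only",
            stacklevel=2,
        )
        res = _fit(False)
    est = float(res.fe_params[predictor])
    se = float(res.bse_fe[predictor])
    z = est / se if se > 0 else np.nan
    p = float(2.0 * norm.sf(abs(z))) if np.isfinite(z) else float("nan")
    return {"estimate": est, "se": se, "z": z, "p": p, "result": res}


def build_two_trait_table(
    df: pd.DataFrame,
    brain_col: str,
    behavior_col: str,
    wave: int,
) -> TwinData:
    """Recast (brain, behavior) at one wave as a two-variable twin table.

    Variable 1 of the Cholesky model holds the brain metric, variable 2 the
    behavior score; the twin-pair structure is preserved.
    """
    sub = df[df["wave"] == wave]
    fams = {}
    for rec in sub.itertuples(index=False):
        ent = fams.setdefault(
            rec.family_id, {"zyg": rec.zygosity, "y": np.full(4, np.nan)}
        )
        j = int(rec.birth_order) - 1
        ent["y"][j * 2] = getattr(rec, brain_col)
        ent["y"][j * 2 + 1] = getattr(rec, behavior_col)
    zyg = np.array([e["zyg"] for e in fams.values()])
    y = np.array([e["y"] for e in fams.values()])
    return TwinData.from_arrays(zyg, y)


def brain_behavior_twin(
    df: pd.DataFrame,
    brain_col: str = "value",
    behavior_col: str = "behavior_score",
    waves=(1, 2),
    seed: int = 0,
    with_cis: bool = False,
) -> pd.DataFrame:
    """Genetic/unique-environment correlations between a brain metric and a
    behavior score, estimated per wave from bivariate Cholesky twin models."""
    rows = []
    for w in waves:
        data = build_two_trait_table(df, brain_col, behavior_col, w)
        corr, fit = cross_trait_cholesky(
            data, seed=seed + w, with_cis=with_cis
        )
        row = {
            "wave": w,
            "r_phenotypic": corr.r_phenotypic,
            "r_a": corr.r_a,
            "r_c": corr.r_c,
            "r_e": corr.r_e,
            "converged": fit.convergence,
        }
        for q, (lo, hi) in corr.cis.items():
            row[f"{q}_lo"], row[f"{q}_hi"] = lo, hi
        rows.append(row)
    return pd.DataFrame(rows)
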