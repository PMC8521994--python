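"""Daily acoustic summaries and the usage-environment mixed model.

Each logged day is summarized by three acoustic predictors: the
equivalent continuous sound level Leq = 10 log10(mean 10^(SPL/10))
(energetic mean, dominated by the loudest minutes), the within-day SPL
standard deviation (sound-environment diversity), and the daily median
SNR (listening-condition quality).  Daily total usage (hours, from the
remote-log estimator) is regressed on the three predictors with a
linear mixed-effects model: random intercepts for participant, day of
week and device laterality, plus random slopes for the acoustic
predictors (diagonal covariance) within each of those grouping factors.
Crossed random effects are expressed as variance components of a single
all-encompassing group, fitted by maximum likelihood so that likelihood
ratio tests against the intercept-only model are valid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .config import StudyConfig
from .io import LogTable

PREDICTORS = ["spl_leq_db", "spl_sd_db", "snr_median_db"]
Z_COLUMNS = ["leq_z", "splsd_z", "snr_z"]
SLOPE_GROUPS = ("participant", "day_of_week", "side")

_GROUP_FACTOR = {
    "participant": "C(participant_id)",
    "day_of_week": "C(dow)",
    "side": "C(side)",
}


def spl_leq(spl_db: np.ndarray) -> float:
    """Equivalent continuous level of a set of per-minute dB values."""
    x = np.asarray(spl_db, dtype=float)
    return float(10.0 * np.log10(np.mean(np.power(10.0, x / 10.0))))


def daily_acoustics(table: LogTable, cfg: StudyConfig | None = None) -> pd.DataFrame:
    """Leq, SPLSD and median SNR per (participant, date, side).

    Days with fewer than ``cfg.min_minutes_per_day`` logged minutes are
    excluded (their summaries are unstable) and counted in the
    ``n_excluded_short_days`` attribute of the returned frame.
    """
    cfg = cfg or StudyConfig()
    df = table.data
    records = []
    n_short = 0
    if df.empty:
        out = pd.DataFrame(
            columns=["participant_id", "date", "side", "n_minutes", *PREDICTORS]
        )
        out.attrs["n_excluded_short_days"] = 0
        return out
    for (pid, date, side), chunk in df.groupby(
        ["participant_id", df["timestamp"].dt.date, "side"], sort=True
    ):
        chunk = chunk.drop_duplicates(subset="timestamp")
        if len(chunk) < cfg.min_minutes_per_day:
            n_short += 1
            continue
        spl = chunk["spl_db"].to_numpy(dtype=float)
        records.append(
            {
                "participant_id": pid,
                "date": date,
                "side": side,
                "n_minutes": len(chunk),
                "spl_leq_db": spl_leq(spl),
                "spl_sd_db": float(np.std(spl, ddof=1)),
                "snr_median_db": float(chunk["snr_db"].median()),
            }
        )
    out = pd.DataFrame(records)
    out.attrs["n_excluded_short_days"] = n_short
    return out


def participant_zscore(
    daily: pd.DataFrame, columns: list[str] | None = None, min_days: int = 3
) -> pd.DataFrame:
    """Participant-specific z-scores of day-level values.

    Participants with fewer than ``min_days`` days, or zero spread, are
    flagged (column ``zscore_flagged``) and passed through centered but
    unscaled (zero-SD) or untouched (too few days).
    """
    columns = columns or PREDICTORS
    out = daily.copy()
    out["zscore_flagged"] = False
    for pid, idx in daily.groupby("participant_id").groups.items():
        sub = daily.loc[idx, columns]
        if len(idx) < min_days:
            out.loc[idx, "zscore_flagged"] = True
            continue
        mean = sub.mean()
        sd = sub.std(ddof=1)
        if (sd == 0).any():
            out.loc[idx, "zscore_flagged"] = True
            sd = sd.replace(0, 1.0)
        out.loc[idx, columns] = (sub - mean) / sd
    return out


def standardize_pooled(daily: pd.DataFrame) -> pd.DataFrame:
    """Add pooled z-score columns leq_z / splsd_z / snr_z."""
    out = daily.copy()
    for col, z in zip(PREDICTORS, Z_COLUMNS):
        x = out[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        out[z] = (x - x.mean()) / (sd if sd > 0 else 1.0)
    return out


def vif(predictors: pd.DataFrame) -> pd.Series:
    """Variance inflation factors 1 / (1 - R^2_j) per predictor column.

    All modelled predictors are continuous, so the generalized VIF
    reduces to the plain VIF.  Perfect collinearity yields ``inf``.
    """
    if predictors.shape[1] < 2:
        raise ValueError("VIF needs at least two predictor columns")
    X = predictors.to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0):
        raise ValueError("VIF is undefined for constant predictor columns")
    out = {}
    for j, name in enumerate(predictors.columns):
        y = X[:, j]
        others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def _vc_formulas(slope_groups: tuple[str, ...], day_component: bool = True) -> dict[str, str]:
    vc = {
        "participant": "0 + C(participant_id)",
        "day_of_week": "0 + C(dow)",
        "side": "0 + C(side)",
    }
    if day_component:
        vc["participant_day"] = "0 + C(pid_date)"
    for grp in slope_groups:
        factor = _GROUP_FACTOR[grp]
        for z in Z_COLUMNS:
            vc[f"{grp}_slope_{z}"] = f"0 + {factor}:{z}"
    return vc


def _n_params(result) -> int:
    """Free parameters of a fitted MixedLM: fixed + variance components + scale."""
    return int(result.k_fe + result.k_re2 + result.k_vc + 1)


@dataclass
class LmmFit:
    """A fitted mixed model plus the frame it was fitted on."""

    result: object
    data: pd.DataFrame
    vc_names: list[str]
    converged: bool

    @property
    def llf(self) -> float:
        return float(self.result.llf)


def _fit_mixedlm(
    data: pd.DataFrame, fixed: str, vc: dict[str, str], maxiter: int = 1000
) -> LmmFit:
    df = data.copy()
    df["_all"] = 1
    model = MixedLM.from_formula(
        fixed, groups="_all", vc_formula=vc, re_formula="0", data=df
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # Powell is slower than gradient methods here but markedly more
        # reliable on the profiled likelihood with many near-boundary
        # variance components.  Its line searches can wander into
        # numerically singular territory, so fall back if needed.
        result = None
        for method in ("powell", "lbfgs", "nm"):
            try:
                result = model.fit(reml=False, method=method, maxiter=maxiter)
                break
            except np.linalg.LinAlgError:
                continue
        if result is None:
            raise RuntimeError("mixed-model fit failed under all optimizers")
    return LmmFit(
        result=result,
        data=data,
        vc_names=list(model.exog_vc.names),
        converged=bool(result.converged),
    )


@dataclass
class AssociationResult:
    """Fixed effects, LRT, VIFs, variance decomposition and random-effect SDs."""

    beta: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    lrt_stat: float
    lrt_df: int
    lrt_p: float
    vif: pd.Series
    r2_marginal: float
    r2_conditional: float
    random_effect_sd: pd.Series
    residual_sd: float
    dow_intercepts: pd.Series | None
    n_days: int
    converged: bool
    warnings: list = field(default_factory=list)
    fit: LmmFit | None = None
    null_fit: LmmFit | None = None


def prepare_model_frame(
    daily_usage: pd.DataFrame, acoustics: pd.DataFrame
) -> pd.DataFrame:
    """Join usage and acoustic day-level tables and add dow / z columns."""
    joined = daily_usage.merge(
        acoustics, on=["participant_id", "date", "side"], how="inner"
    )
    joined["usage_h"] = joined["t_remote_h"]
    joined["dow"] = pd.to_datetime(joined["date"]).dt.dayofweek
    joined["pid_date"] = joined["participant_id"].astype(str) + "|" + joined["date"].astype(str)
    return standardize_pooled(joined)


def fit_usage_lmm(
    data: pd.DataFrame,
    cfg: StudyConfig | None = None,
    slope_groups: tuple[str, ...] = SLOPE_GROUPS,
    day_component: bool = True,
) -> AssociationResult:
    """Fit the usage ~ acoustics mixed model and assemble all diagnostics.

    ``data`` is a prepared model frame (see :func:`prepare_model_frame`)
    with columns usage_h, leq_z, splsd_z, snr_z, participant_id, dow,
    side.  Because the left and right rows of one wearer-day are near
    duplicates (same wear episode, same environment), a participant-day
    variance component is included by default in both the full and the
    null model; without it, fixed-effect tests on bilateral rows are
    badly anti-conservative.  On a singular or non-converged fit the
    random slopes are dropped progressively (side first, then day of
    week, then participant), with the trail recorded in ``warnings``.
    """
    cfg = cfg or StudyConfig()
    fixed = "usage_h ~ leq_z + splsd_z + snr_z"
    trail: list[str] = []
    groups = tuple(slope_groups)
    order = [g for g in ("side", "day_of_week", "participant") if g in groups]
    fit = None
    while True:
        fit = _fit_mixedlm(data, fixed, _vc_formulas(groups, day_component))
        if fit.converged or not order:
            break
        dropped = order.pop(0)
        groups = tuple(g for g in groups if g != dropped)
        trail.append(f"dropped random slopes for {dropped} (singular/non-converged fit)")
    null_fit = _fit_mixedlm(data, "usage_h ~ 1", _vc_formulas((), day_component))
    chi2, df_lrt, p = lrt_vs_null(fit, null_fit)
    res = fit.result
    fe_names = ["leq_z", "splsd_z", "snr_z"]
    ci = res.conf_int().loc[fe_names]
    ci.columns = ["ci_low", "ci_high"]
    r2m, r2c = variance_explained(fit)
    vcomp = pd.Series(res.vcomp, index=fit.vc_names)
    re_sd = np.sqrt(vcomp.clip(lower=0.0))
    return AssociationResult(
        beta=res.fe_params.loc[fe_names],
        conf_int=ci,
        pvalues=res.pvalues.loc[fe_names],
        lrt_stat=chi2,
        lrt_df=df_lrt,
        lrt_p=p,
        vif=vif(data[Z_COLUMNS]),
        r2_marginal=r2m,
        r2_conditional=r2c,
        random_effect_sd=re_sd,
        residual_sd=float(np.sqrt(res.scale)),
        dow_intercepts=_dow_effects(fit),
        n_days=len(data),
        converged=fit.converged,
        warnings=trail,
        fit=fit,
        null_fit=null_fit,
    )


def lrt_vs_null(full: LmmFit, null: LmmFit) -> tuple[float, int, float]:
    """Likelihood ratio test of the full model against the null.

    Both fits must be maximum-likelihood fits on the same rows.  Returns
    (chi2, df, p) with df the difference in free parameter counts and p
    from the chi-square upper tail.
    """
    if len(full.data) != len(null.data):
        raise ValueError(
            f"row-set mismatch: full model fitted on {len(full.data)} rows, "
            f"null on {len(null.data)}"
        )
    chi2 = max(0.0, 2.0 * (full.llf - null.llf))
    df = _n_params(full.result) - _n_params(null.result)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    if chi2 == 0.0:
        p = 1.0
    return chi2, df, p


def fixed_effects_lrt(
    data: pd.DataFrame,
    cfg: StudyConfig | None = None,
    slope_groups: tuple[str, ...] = SLOPE_GROUPS,
    day_component: bool = True,
) -> tuple[float, int, float]:
    """LRT of the three acoustic fixed effects with the random structure shared.

    Unlike the intercept-only comparison - whose reference distribution
    is conservative because the tested random-slope variances sit on the
    boundary of the parameter space - this comparison differs only in
    the three fixed effects, so the chi-square(3) reference is
    asymptotically exact.  It is the appropriate test for type-I-error
    calibration of the acoustic-effect inference.
    """
    cfg = cfg or StudyConfig()
    vc = _vc_formulas(tuple(slope_groups), day_component)
    full = _fit_mixedlm(data, "usage_h ~ leq_z + splsd_z + snr_z", vc)
    null = _fit_mixedlm(data, "usage_h ~ 1", vc)
    chi2 = max(0.0, 2.0 * (full.llf - null.llf))
    df = int(full.result.k_fe - null.result.k_fe)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def variance_explained(fit: LmmFit) -> tuple[float, float]:
    """Nakagawa marginal and conditional pseudo-R^2 (identity link).

    marginal = var(fixed predictions) / (fixed + random + residual);
    conditional adds the random components to the numerator.  Random
    slope components contribute sigma^2_slope * mean(x^2) for their
    covariate, i.e. the average diagonal of Z Sigma Z'.  The
    participant-day component, when present, is counted as *unexplained*
    (residual-like) variance: the unit of scientific interest is the
    wearer-day, and that component is exactly the day-to-day noise a
    day-level analysis would leave in its residual.
    """
    res = fit.result
    data = fit.data
    design = pd.DataFrame({"Intercept": np.ones(len(data))})
    for name in res.fe_params.index:
        if name != "Intercept":
            design[name] = data[name].to_numpy()
    yhat_fixed = design[res.fe_params.index].to_numpy() @ res.fe_params.to_numpy()
    var_f = float(np.var(yhat_fixed))
    var_r = 0.0
    var_e = float(res.scale)
    for name, v in zip(fit.vc_names, res.vcomp):
        v = max(float(v), 0.0)
        if name == "participant_day":
            var_e += v
        elif "_slope_" in name:
            z = name.rsplit("_slope_", 1)[1]
            var_r += v * float(np.mean(data[z].to_numpy() ** 2))
        else:
            var_r += v
    denom = var_f + var_r + var_e
    return var_f / denom, (var_f + var_r) / denom


def _dow_effects(fit: LmmFit) -> pd.Series | None:
    """Predicted (BLUP) day-of-week intercept shifts, if extractable."""
    try:
        re = fit.result.random_effects
        (values,) = re.values()
        dow = values[[i for i in values.index if i.startswith("day_of_week[C(dow)")]]
        if dow.empty:
            return None
        labels = [i.split("[T.")[-1].rstrip("]").split("[")[-1].rstrip("]") for i in dow.index]
        return pd.Series(dow.to_numpy(), index=labels, name="dow_intercept_h")
    except Exception:
        return None
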