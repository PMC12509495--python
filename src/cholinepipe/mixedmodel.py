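"""Frame-level mixed-effects analysis of ΔF/F on behavior and log speed.

The design regresses z-scored ΔF/F (30 Hz frames, 0.5 s-smoothed) on task
phase, log2 movement speed, the behavior indicators (grooming, rearing,
exploring the stationary / nonstationary object) and their phase interactions,
with random effects for mouse, task repetition nested in mouse, and session.
Movement speed stands in for locomotion (the two are collinear).

The spatial-novelty question is a linear contrast on the two
phase × object-exploration interaction coefficients; its stability over time
is probed by refitting the model in 3 min sliding windows and regressing the
per-window nonstationary-minus-stationary coefficient difference on phase and
window index with OLS.

Backend: statsmodels MixedLM (REML). It supports a single top-level grouping
factor, so the random structure is expressed as mouse-level effects plus
variance components for repetition and session; the requested random-slope
structure falls back (full covariance → diagonal components → intercepts
only) on convergence failure, and the level actually used is recorded.
Because frame-level residuals are strongly autocorrelated, results carry both
naive and effective-sample-size-adjusted standard errors.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from cholinepipe.photometry import moving_average, zscore
from cholinepipe.speedcode import _autocorr_inflation, log2_speed

logger = logging.getLogger(__name__)

FIXED_FORMULA = "dff_z ~ phase * (log2speed + exp_nonstat + exp_stat + rearing + grooming)"
MAIN_TERMS = ("log2speed", "exp_nonstat", "exp_stat", "rearing", "grooming")


@dataclass
class LmmResult:
    fixed: pd.DataFrame  # per term: estimate, se, t, df, p, ci_lo, ci_hi, se_eff, p_eff
    cov: pd.DataFrame  # fixed-effects covariance (naive)
    cov_eff: pd.DataFrame  # autocorrelation-robust (panel HAC) covariance
    df_resid: float
    n_obs: int
    inflation: float  # mean SE inflation factor (se_eff / se)
    random_level: str  # "full" | "diag" | "intercepts"
    converged: bool
    llf: float
    aic: float
    bic: float


@dataclass
class ContrastResult:
    """phase×exp_nonstat − phase×exp_stat, Wald F on the fitted covariance."""

    estimate: float
    se: float
    F: float
    df_num: int
    df_den: float
    p: float
    F_eff: float
    p_eff: float

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("F must be nonnegative")


def assemble_frame_table(records: list[dict]) -> pd.DataFrame:
    """One row per 30 Hz frame across sessions.

    Each record carries ``dff`` (a :class:`~cholinepipe.photometry.DffSeries`
    on the video clock), ``speed`` (cm/s on the same clock), ``etho``
    (:class:`~cholinepipe.behavior.Ethogram`) and ``meta``
    (:class:`~cholinepipe.photometry.SessionMeta`). ΔF/F is smoothed (0.5 s)
    and z-scored here unless its stage tags show that already happened; speed
    is always smoothed before the log2 transform.
    """
    frames = []
    for rec in records:
        dff = rec["dff"]
        speed = np.asarray(rec["speed"], float)
        etho = rec["etho"]
        meta = rec["meta"]
        n = min(dff.values.size, speed.size, etho.n_frames)
        if abs(dff.rate - etho.rate) > 1e-9:
            raise ValueError(
                f"session {meta.session_id}: dff rate {dff.rate} != video rate {etho.rate}"
            )
        values = dff.values[:n]
        if not any(tag.startswith("smoothed") for tag in dff.stage_tags):
            values = moving_average(values, 0.5, dff.rate)
        if "zscored" not in dff.stage_tags:
            values = zscore(values)
        sp = moving_average(speed[:n], 0.5, etho.rate)
        frames.append(
            pd.DataFrame(
                {
                    "dff_z": values,
                    "phase": 1 if meta.phase == "test" else 0,
                    "log2speed": log2_speed(sp),
                    "grooming": etho.flags["grooming"][:n].astype(int),
                    "rearing": etho.flags["rearing"][:n].astype(int),
                    "exp_stat": etho.flags["explore_stat"][:n].astype(int),
                    "exp_nonstat": etho.flags["explore_nonstat"][:n].astype(int),
                    "mouse_id": meta.mouse_id,
                    "session_id": meta.session_id,
                    "oblom_key": f"{meta.mouse_id}:{meta.oblom_id}",
                    "t": dff.t[:n],
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    if table.isna().any().any():
        raise ValueError("frame table contains missing values")
    return table


def build_design_matrix(table: pd.DataFrame, formula: str = FIXED_FORMULA) -> pd.DataFrame:
    """Fixed-effects design matrix (for inspection and oracle tests)."""
    from patsy import dmatrices

    _, X = dmatrices(formula, table, return_type="dataframe")
    return X


def _available_formula(table: pd.DataFrame) -> str:
    """Fixed formula restricted to predictors that vary in this table."""
    terms = [t for t in MAIN_TERMS if table[t].nunique() > 1]
    if not terms:
        return "dff_z ~ phase" if table["phase"].nunique() > 1 else "dff_z ~ 1"
    joined = " + ".join(terms)
    if table["phase"].nunique() > 1:
        return f"dff_z ~ phase * ({joined})"
    return f"dff_z ~ {joined}"


def _vc_formulas(table: pd.DataFrame, level: str) -> dict:
    vc = {}
    if table["oblom_key"].nunique() > 1:
        vc["oblom"] = "0 + C(oblom_key)"
    if table["session_id"].nunique() > 1:
        vc["session"] = "0 + C(session_id)"
    if level == "diag":
        for term in MAIN_TERMS:
            if table[term].nunique() > 1:
                vc[f"slope_{term}"] = f"0 + {term}"
    return vc


def fit_lmm(
    table: pd.DataFrame,
    random_spec: str = "diag",
    formula: str | None = None,
) -> LmmResult:
    """REML fit of the fixed design with the requested random structure.

    ``random_spec`` is the top of the fallback ladder:
    ``full`` (mouse-level intercept + slopes, unstructured covariance) →
    ``diag`` (independent slope variance components) → ``intercepts``.
    The level actually achieved is recorded in the result.
    """
    if table["mouse_id"].nunique() < 2 or table["session_id"].nunique() < 2:
        raise ValueError("fit_lmm needs at least 2 mice and 2 sessions")
    if formula is None:
        formula = _available_formula(table)
    X = build_design_matrix(table, formula)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        u, s, vt = np.linalg.svd(X.to_numpy(), full_matrices=False)
        aliased = [X.columns[i] for i in np.flatnonzero(np.abs(vt[rank:]).max(axis=0) > 1e-8)]
        raise ValueError(f"rank-deficient fixed design; aliased columns: {aliased}")

    ladder = {"full": ["full", "diag", "intercepts"], "diag": ["diag", "intercepts"],
              "intercepts": ["intercepts"]}[random_spec]
    fit = None
    level_used = None
    for level in ladder:
        re_formula = "1"
        if level == "full":
            slope_terms = [t for t in MAIN_TERMS if table[t].nunique() > 1]
            re_formula = "1 + " + " + ".join(slope_terms) if slope_terms else "1"
        vc = _vc_formulas(table, level)
        # per-session z-scoring leaves ~no between-session intercept variance,
        # so the intercepts-only level groups by session directly (fast, and
        # the mouse/ObLoM components would be estimated at ~0 anyway)
        groups = table["session_id"] if level == "intercepts" else table["mouse_id"]
        if level == "intercepts":
            vc = {}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(
                    formula,
                    table,
                    groups=groups,
                    re_formula=re_formula,
                    vc_formula=vc or None,
                )
                candidate = model.fit(reml=True, method="lbfgs", maxiter=200)
            if np.all(np.isfinite(candidate.fe_params)):
                fit = candidate
                level_used = level
                break
        except (np.linalg.LinAlgError, ValueError, KeyError) as exc:
            logger.info("random level %r failed (%s); falling back", level, exc)
    if fit is None:
        raise RuntimeError("mixed model failed to fit at every random-effects level")

    fe = fit.fe_params
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        se = pd.Series(np.asarray(fit.bse_fe), index=fe.index)
        naive_cov = fit.cov_params()
    if not np.all(np.isfinite(se)):
        # REML variance at the boundary can leave the model-based covariance
        # indefinite; fall back to the OLS covariance for the naive column
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ols_se = smf.ols(formula, data=table).fit().bse
        se = se.where(np.isfinite(se), ols_se.reindex(se.index))
        logger.info("naive SEs partially replaced by OLS SEs (boundary covariance)")
    n_obs = len(table)
    df_resid = float(n_obs - len(fe))
    cov_eff = _hac_fixed_cov(table, formula, fe.index)
    se_eff = pd.Series(np.sqrt(np.diag(cov_eff)), index=fe.index)
    tvals = fe / se
    p = 2 * stats.t.sf(np.abs(tvals), df_resid)
    t_eff = fe / se_eff
    p_eff = 2 * stats.t.sf(np.abs(t_eff), df_resid)
    crit = stats.t.ppf(0.975, df_resid)
    fixed = pd.DataFrame(
        {
            "estimate": fe,
            "se": se,
            "t": tvals,
            "df": df_resid,
            "p": p,
            "ci_lo": fe - crit * se,
            "ci_hi": fe + crit * se,
            "se_eff": se_eff,
            "p_eff": p_eff,
        }
    )
    cov = naive_cov.loc[fe.index, fe.index]
    return LmmResult(
        fixed=fixed,
        cov=cov,
        cov_eff=cov_eff,
        df_resid=df_resid,
        n_obs=n_obs,
        inflation=float((se_eff / se).mean()),
        random_level=level_used,
        converged=bool(getattr(fit, "converged", True)),
        llf=float(fit.llf),
        aic=float(fit.aic) if np.isfinite(fit.aic) else math.nan,
        bic=float(fit.bic) if np.isfinite(fit.bic) else math.nan,
    )


def _hac_fixed_cov(table: pd.DataFrame, formula: str, fe_index, hac_seconds: float = 10.0) -> pd.DataFrame:
    """Newey–West (panel, per-session) covariance of the fixed effects.

    Frame-level residuals keep the intrinsic-activity autocorrelation plus the
    0.5 s smoothing kernel, so model-based standard errors at 30 Hz are far
    too small; a within-session HAC estimate with a ~5 s bandwidth gives
    honestly sized tests. Session intercepts enter as fixed dummies here so
    the slow between-session variation does not leak into the HAC terms.
    """
    rate = _infer_rate(table)
    # thin to ~10 Hz: with a correlation time of seconds, the long-run
    # (HAC) variance of the frame-level estimator is unchanged while the
    # bandwidth shrinks threefold in samples
    thin = max(1, int(round(rate / 10.0)))
    sub = table.iloc[::thin]
    maxlags = max(int(hac_seconds * rate / thin), 1)
    # per-session z-scoring removes session intercepts, so the plain fixed
    # design suffices; session dummies would alias the phase main effect
    res = smf.ols(formula, data=sub).fit(
        cov_type="hac-panel",
        cov_kwds={"groups": sub["session_id"], "maxlags": maxlags},
    )
    cov = res.cov_params()
    keep = [name for name in fe_index if name in cov.index]
    missing = [name for name in fe_index if name not in cov.index]
    if missing:
        raise ValueError(f"HAC refit lost fixed-effect columns: {missing}")
    return cov.loc[keep, keep]


def _infer_rate(table: pd.DataFrame) -> float:
    t = table["t"].to_numpy()
    dts = np.diff(t)
    dts = dts[(dts > 0) & (dts < 1.0)]
    return 1.0 / float(np.median(dts)) if dts.size else 30.0


def novelty_contrast(result: LmmResult) -> ContrastResult:
    """Wald F for phase×exp_nonstat − phase×exp_stat (1 numerator df)."""
    names = list(result.fixed.index)
    term_a = _find_term(names, "phase", "exp_nonstat")
    term_b = _find_term(names, "phase", "exp_stat")
    c = np.zeros(len(names))
    c[names.index(term_a)] = 1.0
    c[names.index(term_b)] = -1.0
    est = float(c @ result.fixed["estimate"].to_numpy())
    var = float(c @ result.cov.to_numpy() @ c)
    if not math.isfinite(var) or var <= 0:
        var = float(c @ result.cov_eff.to_numpy() @ c)
    if var <= 0:
        raise ValueError("contrast variance is nonpositive")
    F = est**2 / var
    p = float(stats.f.sf(F, 1, result.df_resid))
    var_eff = float(c @ result.cov_eff.to_numpy() @ c)
    F_eff = est**2 / var_eff
    p_eff = float(stats.f.sf(F_eff, 1, result.df_resid))
    return ContrastResult(
        estimate=est,
        se=math.sqrt(var),
        F=F,
        df_num=1,
        df_den=result.df_resid,
        p=p,
        F_eff=F_eff,
        p_eff=p_eff,
    )


def _find_term(names: list[str], *parts: str) -> str:
    for name in names:
        pieces = set(name.split(":"))
        if pieces == set(parts):
            return name
    raise ValueError(f"interaction term {parts} not in fitted model")


def sliding_lmm(
    table: pd.DataFrame,
    window: float = 180.0,
    step: float = 60.0,
    min_exploration: float = 1.0,
    random_spec: str = "intercepts",
) -> pd.DataFrame:
    """Per-window object-exploration coefficient differences (Fig-4D/E style).

    Refits the frame-level model on each 3 min window of within-session time
    and extracts, per phase, the nonstationary-minus-stationary coefficient
    difference with its SE. A phase's value in a window is skipped (NaN) when
    that phase has less than ``min_exploration`` seconds of exploration of
    either object in the window.
    """
    rate = _infer_rate(table)
    t_max = float(table["t"].max())
    if window > t_max + 1.0 / rate:
        raise ValueError("window exceeds session length")
    rows = []
    start = 0.0
    w_idx = 0
    while start + window <= t_max + 1.0 / rate + 1e-9:
        sub = table[(table["t"] >= start) & (table["t"] < start + window)]
        for phase in sorted(sub["phase"].unique()):
            ph = sub[sub["phase"] == phase]
            sec_stat = ph["exp_stat"].sum() / rate
            sec_nonstat = ph["exp_nonstat"].sum() / rate
            diff = se = math.nan
            if sec_stat >= min_exploration and sec_nonstat >= min_exploration:
                try:
                    res = fit_lmm(sub, random_spec=random_spec)
                    diff, se = _object_difference(res, phase)
                except (ValueError, RuntimeError) as exc:
                    logger.info("window %.0f s phase %d skipped: %s", start, phase, exc)
            rows.append(
                {
                    "window_idx": w_idx,
                    "window_start": start,
                    "phase": int(phase),
                    "diff": diff,
                    "se": se,
                }
            )
        start += step
        w_idx += 1
    return pd.DataFrame(rows)


def _object_difference(result: LmmResult, phase: int) -> tuple[float, float]:
    names = list(result.fixed.index)
    c = np.zeros(len(names))
    c[names.index("exp_nonstat")] = 1.0
    c[names.index("exp_stat")] = -1.0
    if phase == 1:
        c[names.index(_find_term(names, "phase", "exp_nonstat"))] = 1.0
        c[names.index(_find_term(names, "phase", "exp_stat"))] = -1.0
    est = float(c @ result.fixed["estimate"].to_numpy())
    var = float(c @ result.cov.to_numpy() @ c)
    return est, math.sqrt(max(var, 0.0))


def ols_meta(coef_windows: pd.DataFrame):
    """OLS of the per-window coefficient difference on phase × window index."""
    data = coef_windows.dropna(subset=["diff"])
    if data["phase"].nunique() < 2 or data["window_idx"].nunique() < 2:
        raise ValueError("ols_meta needs >= 2 phases and >= 2 windows of coefficients")
    res = smf.ols("diff ~ phase * window_idx", data=data).fit()
    table = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
            "ci_lo": res.conf_int()[0],
            "ci_hi": res.conf_int()[1],
        }
    )
    table.attrs["r2"] = float(res.rsquared)
    table.attrs["f_stat"] = float(res.fvalue)
    table.attrs["n"] = int(res.nobs)
    return table
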