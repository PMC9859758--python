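"""Per-phase rate estimation: segment-wise OLS and joint mixed-effects models.

Each annotated growth or shrinkage segment yields a *partial trajectory* —
the response (microtubule length or punctum intensity) against time from
phase start. Rates can be estimated per partial trajectory by ordinary
least squares, or jointly across strains with a linear mixed-effects model

    y_ij = beta0_s(j) + beta1_s(j) * t_ij + b0_j + b1_j * t_ij + eps_ij

with per-strain fixed intercepts and slopes (cell-means coding, so each
strain reports its own initial value and rate), a random intercept and
slope per partial trajectory with shared 2x2 covariance Psi, and i.i.d.
Gaussian residuals. Parameters are estimated by maximum likelihood;
fixed-effect significance uses two-sided t-tests with residual degrees of
freedom n_obs - n_fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

from tipbody.annotation import PhaseAnnotation
from tipbody.trajectory import GROWTH, SHRINKAGE, Trajectory


class InsufficientDataError(ValueError):
    pass


class DegenerateDesignError(ValueError):
    pass


@dataclass
class PartialTrajectory:
    """Observations of one response during one growth/shrinkage phase."""

    key: str
    strain: str
    phase_kind: str
    response_kind: str  # "length" or "intensity"
    t_rel: np.ndarray  # seconds from phase start
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t_rel = np.asarray(self.t_rel, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.t_rel) != len(self.y):
            raise ValueError("t_rel and y must have equal length")

    @property
    def n_obs(self) -> int:
        return len(self.y)


@dataclass
class OLSFit:
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    t: float
    p: float
    df: int
    sigma2: float


@dataclass
class FixedEffect:
    estimate: float
    se: float
    t: float
    p: float
    ci_lo: float
    ci_hi: float


@dataclass
class MixedModelFit:
    """Joint mixed-effects fit over partial trajectories of all strains."""

    response_kind: str
    phase_kind: str
    strains: list[str]
    intercepts: dict[str, FixedEffect]
    slopes: dict[str, FixedEffect]
    cov_re: np.ndarray  # 2x2 random intercept/slope covariance
    sigma2: float  # residual variance
    llf: float
    n_obs: int
    n_groups: int
    df_resid: int
    fe_params: np.ndarray = field(repr=False)
    fe_cov: np.ndarray = field(repr=False)
    fe_index: dict[tuple[str, str], int] = field(repr=False)
    converged: bool = True
    warnings: list[str] = field(default_factory=list)


def extract_partials(
    traj: Trajectory,
    annotation: PhaseAnnotation,
    response_kind: str = "length",
    min_points: int = 3,
) -> list[PartialTrajectory]:
    """Slice a trajectory into per-segment partial trajectories.

    Only growth and shrinkage segments are kept (indeterminate segments do
    not enter rate models). The annotation's length-based segmentation is
    reused to slice the intensity series; frames with missing response are
    dropped, and partials left with fewer than ``min_points`` observations
    are discarded.
    """
    if response_kind not in ("length", "intensity"):
        raise ValueError("response_kind must be 'length' or 'intensity'")
    series = traj.length if response_kind == "length" else traj.intensity
    out = []
    for i, seg in enumerate(annotation.segments):
        if seg.kind not in (GROWTH, SHRINKAGE):
            continue
        sl = slice(seg.start_frame, seg.end_frame + 1)
        t = traj.time[sl]
        y = np.asarray(series, dtype=float)[sl]
        keep = ~np.isnan(y)
        if keep.sum() < min_points:
            continue
        out.append(
            PartialTrajectory(
                key=f"{traj.key}/seg{i}",
                strain=traj.strain,
                phase_kind=seg.kind,
                response_kind=response_kind,
                t_rel=t[keep] - t[keep][0],
                y=y[keep],
            )
        )
    return out


def fit_phase_ols(partial: PartialTrajectory) -> OLSFit:
    """Ordinary least squares on one partial trajectory.

    Two-sided t-test on the slope with n - 2 degrees of freedom; a perfect
    fit (zero residuals) reports p = 0 for a nonzero slope and p = 1 for a
    zero slope.
    """
    t, y = partial.t_rel, partial.y
    n = len(y)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 observations, got {n}")
    if np.ptp(t) == 0:
        raise DegenerateDesignError("zero time variance in partial trajectory")
    X = np.column_stack([np.ones(n), t])
    beta, rss_arr, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    rss = float(np.sum((y - fitted) ** 2))
    df = n - 2
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(X.T @ X)
    scale = max(float(np.sum((y - y.mean()) ** 2)), 1.0)
    if rss <= 1e-12 * scale:
        # perfect fit: slope counted as zero when its total change over the
        # segment is negligible against the data scale
        slope_zero = abs(beta[1]) * np.ptp(t) <= 1e-9 * (np.max(np.abs(y)) + 1.0)
        se_i, se_s = 0.0, 0.0
        tstat = 0.0 if slope_zero else np.inf
        p = 1.0 if slope_zero else 0.0
    else:
        se_i = float(np.sqrt(sigma2 * xtx_inv[0, 0]))
        se_s = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
        tstat = float(beta[1] / se_s)
        p = float(2 * stats.t.sf(abs(tstat), df))
    return OLSFit(float(beta[0]), float(beta[1]), se_i, se_s, tstat, p, df, sigma2)


def _design(partials: list[PartialTrajectory]) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    rows = []
    for p in partials:
        for t, y in zip(p.t_rel, p.y):
            rows.append((p.key, p.strain, t, y))
    df = pd.DataFrame(rows, columns=["group", "strain", "t", "y"])
    strains = sorted(df["strain"].unique())
    X = np.zeros((len(df), 2 * len(strains)))
    for k, s in enumerate(strains):
        mask = (df["strain"] == s).to_numpy()
        X[mask, 2 * k] = 1.0
        X[mask, 2 * k + 1] = df["t"].to_numpy()[mask]
    return df, strains, X


def fit_lme(
    partials: list[PartialTrajectory],
    response_kind: str | None = None,
    phase_kind: str | None = None,
) -> MixedModelFit:
    """Maximum-likelihood joint mixed-effects fit across strains.

    Fixed effects are per-strain intercepts and slopes (cell-means coding);
    each partial trajectory contributes a correlated random intercept and
    slope drawn from a shared bivariate normal. If the full random-effect
    covariance is singular or the optimiser fails, the fit is retried with
    a diagonal covariance and a warning is recorded.
    """
    if len(partials) < 2:
        raise InsufficientDataError("need >= 2 partial trajectories")
    response_kind = response_kind or partials[0].response_kind
    phase_kind = phase_kind or partials[0].phase_kind
    df, strains, X = _design(partials)
    y_raw = df["y"].to_numpy()
    t_raw = df["t"].to_numpy()

    # standardise t and y internally (variance components on the raw scale
    # can differ by many orders of magnitude, which stalls the optimiser);
    # all estimates are transformed back below
    s_t = float(np.std(t_raw)) or 1.0
    s_y = float(np.std(y_raw)) or 1.0
    y = y_raw / s_y
    Xs = X.copy()
    Xs[:, 1::2] /= s_t  # slope columns carry t; scaled design uses t' = t/s_t
    exog_re = np.column_stack([np.ones(len(df)), t_raw / s_t])

    model = MixedLM(y, Xs, groups=df["group"].to_numpy(), exog_re=exog_re)
    warn_msgs: list[str] = []
    converged = True

    def _try_fit(free=None):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = model.fit(reml=False, method=["lbfgs", "bfgs", "cg"], free=free, maxiter=2000)
        msgs = [str(w.message) for w in caught]
        return res, msgs

    result, msgs = _try_fit()
    warn_msgs.extend(m for m in msgs if "onverge" in m or "ingular" in m or "boundary" in m)
    cov_re = np.asarray(result.cov_re, dtype=float)
    eigmin = float(np.linalg.eigvalsh(cov_re).min())
    if not result.converged or eigmin < -1e-10:
        k_fe = X.shape[1]
        free = MixedLMParams.from_components(
            fe_params=np.ones(k_fe), cov_re=np.eye(2)
        )
        result, msgs = _try_fit(free=free)
        warn_msgs.append("full random-effect covariance singular or fit failed; "
                         "retried with diagonal covariance")
        cov_re = np.asarray(result.cov_re, dtype=float)
        converged = bool(result.converged)

    n_obs = len(y)
    k_fe = X.shape[1]
    df_resid = n_obs - k_fe
    # back-transform from the standardised fit: intercepts scale by s_y,
    # slopes by s_y/s_t, random effects likewise, sigma^2 by s_y^2
    d = np.empty(k_fe)
    d[0::2] = s_y
    d[1::2] = s_y / s_t
    fe = np.asarray(result.fe_params, dtype=float) * d
    fe_cov = np.asarray(result.cov_params(), dtype=float)[:k_fe, :k_fe] * np.outer(d, d)
    dr = np.diag([s_y, s_y / s_t])
    cov_re = dr @ cov_re @ dr
    sigma2 = float(result.scale) * s_y**2
    llf = float(result.llf) - n_obs * np.log(s_y)
    tcrit = stats.t.ppf(0.975, df_resid)

    intercepts, slopes, fe_index = {}, {}, {}
    for k, s in enumerate(strains):
        for j, which in ((2 * k, "intercept"), (2 * k + 1, "slope")):
            est = float(fe[j])
            se = float(np.sqrt(max(fe_cov[j, j], 0.0)))  # guards exact-fit round-off
            tstat = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
            p = float(2 * stats.t.sf(abs(tstat), df_resid)) if np.isfinite(tstat) else 0.0
            eff = FixedEffect(est, se, float(tstat), p, est - tcrit * se, est + tcrit * se)
            fe_index[(s, which)] = j
            (intercepts if which == "intercept" else slopes)[s] = eff

    return MixedModelFit(
        response_kind=response_kind,
        phase_kind=phase_kind,
        strains=strains,
        intercepts=intercepts,
        slopes=slopes,
        cov_re=cov_re,
        sigma2=sigma2,
        llf=llf,
        n_obs=n_obs,
        n_groups=int(df["group"].nunique()),
        df_resid=df_resid,
        fe_params=fe,
        fe_cov=fe_cov,
        fe_index=fe_index,
        converged=converged,
        warnings=warn_msgs,
    )


def compare_fixed_effects(
    fit: MixedModelFit, strain_a: str, strain_b: str, which: str = "slope"
) -> tuple[float, float, float, float]:
    """Wald contrast of one fixed effect between two strains.

    Returns (difference a - b, SE, t, two-sided p) using the fixed-effect
    covariance block and the fit's residual degrees of freedom.
    """
    if which not in ("intercept", "slope"):
        raise ValueError("which must be 'intercept' or 'slope'")
    for s in (strain_a, strain_b):
        if s not in fit.strains:
            raise KeyError(f"unknown strain {s!r}")
    if strain_a == strain_b:
        return 0.0, 0.0, 0.0, 1.0
    c = np.zeros(len(fit.fe_params))
    c[fit.fe_index[(strain_a, which)]] = 1.0
    c[fit.fe_index[(strain_b, which)]] = -1.0
    diff = float(c @ fit.fe_params)
    se = float(np.sqrt(max(c @ fit.fe_cov @ c, 0.0)))
    if se == 0:
        return diff, 0.0, 0.0 if diff == 0 else np.inf, 1.0 if diff == 0 else 0.0
    t = diff / se
    p = float(2 * stats.t.sf(abs(t), fit.df_resid))
    return diff, se, float(t), p


def pooled_ols_loglik(partials: list[PartialTrajectory]) -> float:
    """Gaussian log-likelihood of the pooled per-strain OLS model (Psi = 0).

    Serves as the nesting reference: the mixed model's ML log-likelihood can
    never fall below this value on the same data.
    """
    df, strains, X = _design(partials)
    y = df["y"].to_numpy()
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    sigma2 = float(resid @ resid) / n  # ML variance
    return float(-0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0))
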