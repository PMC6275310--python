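"""Participant-wave table assembly and the longitudinal random-intercept model.

The model relates a participant's perception accuracy to classroom
transitivity with the time-varying predictor split into a between-person and
a within-person part:

    accuracy_it = b0 + b1*time_it + b2*transitivity_t0_i
                  + b3*transitivity_change_it + u_i + e_it

    u_i  ~ N(0, sigma2_intercept)      participant random intercept
    e_it ~ N(0, sigma2_residual)       occasion residual

``transitivity_t0`` is the classroom transitivity at the participant's first
observed wave (between-person differences); ``transitivity_change`` is the
deviation of the current wave's classroom transitivity from that baseline
(within-person change), zero by construction at the first observed wave.
Estimation is restricted maximum likelihood (REML); p-values use a
Satterthwaite degrees-of-freedom approximation computed from the profiled
REML criterion of the one-variance-component model.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import AccuracyRecord, TransitivityRecord

__all__ = [
    "FixedEffect",
    "ModelFit",
    "SingularDesignError",
    "ConvergenceError",
    "assemble_long_table",
    "fit_random_intercept",
    "predicted_accuracy_difference",
    "PREDICTORS",
]

logger = logging.getLogger(__name__)

PREDICTORS = ("intercept", "time", "transitivity_t0", "transitivity_change")

TABLE_COLUMNS = [
    "participant",
    "classroom_id",
    "wave_id",
    "time",
    "accuracy",
    "transitivity",
    "transitivity_t0",
    "transitivity_change",
]


class SingularDesignError(ValueError):
    """The fixed-effect design is rank deficient or the outcome is constant."""


class ConvergenceError(RuntimeError):
    """REML optimisation failed to converge."""


@dataclass(frozen=True)
class FixedEffect:
    name: str
    estimate: float
    se: float
    df: float
    p_value: float


@dataclass(frozen=True)
class ModelFit:
    """Fixed effects, variance components, and fit metadata."""

    fixed_effects: tuple[FixedEffect, ...]
    sigma2_intercept: float
    sigma2_residual: float
    n_participants: int
    n_observations: int
    df_method: str = "satterthwaite"
    converged: bool = True
    log_likelihood: float = field(default=math.nan)

    @classmethod
    def from_coefficients(
        cls,
        estimates: dict[str, float],
        sigma2_intercept: float = 0.0,
        sigma2_residual: float = 0.0,
        n_participants: int = 2,
        n_observations: int = 4,
    ) -> "ModelFit":
        """Build a ModelFit from bare coefficient values (e.g. published ones)
        for effect-translation arithmetic; SEs/dfs/p-values are unset (NaN)."""
        fixed = tuple(
            FixedEffect(name=n, estimate=float(estimates.get(n, 0.0)),
                        se=math.nan, df=math.nan, p_value=math.nan)
            for n in PREDICTORS
        )
        return cls(
            fixed_effects=fixed,
            sigma2_intercept=sigma2_intercept,
            sigma2_residual=sigma2_residual,
            n_participants=n_participants,
            n_observations=n_observations,
            df_method="none",
        )

    def coefficient(self, name: str) -> FixedEffect:
        for fe in self.fixed_effects:
            if fe.name == name:
                return fe
        raise KeyError(
            f"unknown predictor {name!r}; expected one of {[f.name for f in self.fixed_effects]}"
        )

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": [fe.name for fe in self.fixed_effects],
                "estimate": [fe.estimate for fe in self.fixed_effects],
                "se": [fe.se for fe in self.fixed_effects],
                "df": [fe.df for fe in self.fixed_effects],
                "p_value": [fe.p_value for fe in self.fixed_effects],
            }
        )


def assemble_long_table(
    accuracy_records: list[AccuracyRecord],
    transitivity_records: list[TransitivityRecord],
    min_waves: int = 2,
) -> pd.DataFrame:
    """Join accuracy and transitivity records into the participant-wave table.

    Rows join on (classroom_id, wave_id); a participant who changed
    classrooms gets each wave's own classroom transitivity.  Participants
    observed at fewer than ``min_waves`` retained waves are dropped (the
    longitudinal inclusion rule); waves whose classroom transitivity is
    undefined are excluded first and counted in the log.  ``time`` is the
    0-based rank of the wave in the global wave order; ``transitivity_t0``
    is each participant's first retained wave's value.
    """
    if min_waves < 1:
        raise ValueError("min_waves must be >= 1")
    trans = {(t.classroom_id, t.wave_id): t for t in transitivity_records}

    rows = []
    n_undefined = 0
    for rec in accuracy_records:
        key = (rec.classroom_id, rec.wave_id)
        if key not in trans:
            raise KeyError(
                f"no transitivity record for classroom {rec.classroom_id!r} "
                f"wave {rec.wave_id} referenced by perceiver {rec.perceiver!r}"
            )
        t = trans[key]
        if not t.defined:
            n_undefined += 1
            continue
        rows.append(
            {
                "participant": rec.perceiver,
                "classroom_id": rec.classroom_id,
                "wave_id": rec.wave_id,
                "accuracy": rec.accuracy,
                "transitivity": t.transitivity,
            }
        )
    if n_undefined:
        logger.info("excluded %d participant-waves with undefined transitivity", n_undefined)
    if not rows:
        return pd.DataFrame(columns=TABLE_COLUMNS)

    df = pd.DataFrame(rows)
    wave_order = {w: i for i, w in enumerate(sorted(df["wave_id"].unique()))}
    df["time"] = df["wave_id"].map(wave_order)

    df = df.sort_values(["participant", "wave_id"], kind="stable")
    counts = df.groupby("participant")["wave_id"].transform("size")
    n_dropped = df.loc[counts < min_waves, "participant"].nunique()
    if n_dropped:
        logger.info(
            "dropped %d participants observed at fewer than %d waves", n_dropped, min_waves
        )
    df = df[counts >= min_waves].copy()
    if df.empty:
        return pd.DataFrame(columns=TABLE_COLUMNS)

    first = df.groupby("participant")["transitivity"].transform("first")
    df["transitivity_t0"] = first
    df["transitivity_change"] = df["transitivity"] - first
    return df[TABLE_COLUMNS].reset_index(drop=True)


def _design(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    y = table["accuracy"].to_numpy(dtype=float)
    X = np.column_stack(
        [
            np.ones(len(table)),
            table["time"].to_numpy(dtype=float),
            table["transitivity_t0"].to_numpy(dtype=float),
            table["transitivity_change"].to_numpy(dtype=float),
        ]
    )
    groups = table["participant"].to_numpy()
    return y, X, groups


def _check_design(y: np.ndarray, X: np.ndarray) -> None:
    # name the offending predictor before reporting bare rank deficiency
    for j, name in enumerate(PREDICTORS[1:], start=1):
        if np.ptp(X[:, j]) < 1e-12:
            raise SingularDesignError(
                f"predictor {name!r} is constant across all observations; "
                "the fixed-effect design is singular"
            )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError("fixed-effect design matrix is rank deficient (collinear)")
    if np.ptp(y) < 1e-12:
        raise SingularDesignError("outcome (accuracy) has no variance; nothing to model")


def _group_blocks(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    order = np.argsort(groups, kind="stable")
    y, X, groups = y[order], X[order], groups[order]
    _, starts = np.unique(groups, return_index=True)
    bounds = np.append(np.sort(starts), len(groups))
    return [(y[a:b], X[a:b]) for a, b in zip(bounds[:-1], bounds[1:])]


def _reml_neg2loglik(theta: np.ndarray, blocks) -> float:
    """-2 x restricted log-likelihood (up to a constant) at variances theta.

    Uses the closed form of the compound-symmetry covariance
    V_i = s2e*I + s2u*J per participant block.
    """
    s2u, s2e = theta
    if s2e <= 0 or s2u < 0:
        return np.inf
    p = blocks[0][1].shape[1]
    logdet_v = 0.0
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    for yi, xi in blocks:
        ni = len(yi)
        d = s2e + ni * s2u
        logdet_v += (ni - 1) * math.log(s2e) + math.log(d)
        w = s2u / d
        xs, ys = xi.sum(axis=0), yi.sum()
        xtvx += (xi.T @ xi - w * np.outer(xs, xs)) / s2e
        xtvy += (xi.T @ yi - w * xs * ys) / s2e
        ytvy += (yi @ yi - w * ys * ys) / s2e
    sign, logdet_m = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(xtvx, xtvy)
    rss = ytvy - beta @ xtvy  # r' V^-1 r for r = y - X beta(theta)
    return logdet_v + logdet_m + rss


def _xtvix_and_grad(theta: np.ndarray, blocks, k: int):
    """C = (X'V^-1 X)^-1, C_kk and its analytic gradient wrt (s2u, s2e)."""
    s2u, s2e = theta
    p = blocks[0][1].shape[1]
    m = np.zeros((p, p))
    dm_du = np.zeros((p, p))
    dm_de = np.zeros((p, p))
    for yi, xi in blocks:
        ni = len(yi)
        d = s2e + ni * s2u
        w = s2u / d
        vinv_x = (xi - w * np.tile(xi.sum(axis=0), (ni, 1))) / s2e
        m += xi.T @ vinv_x
        # dV/ds2u = J, dV/ds2e = I; dM = -X'V^-1 (dV) V^-1 X
        col = vinv_x.sum(axis=0)
        dm_du -= np.outer(col, col)
        dm_de -= vinv_x.T @ vinv_x
    c = np.linalg.inv(m)
    f = c[k, k]
    ck = c[:, k]
    g_u = -ck @ dm_du @ ck
    g_e = -ck @ dm_de @ ck
    return c, f, np.array([g_u, g_e])


def _satterthwaite_df(theta: np.ndarray, blocks, n_obs: int, p: int) -> np.ndarray:
    """Satterthwaite df per coefficient: 2 f^2 / (g' A g).

    A is the asymptotic covariance of the variance estimates, taken as the
    inverse observed information of the REML criterion (numerical Hessian,
    central differences).  Falls back to the residual df when the intercept
    variance sits on the zero boundary or the information is not positive
    definite.
    """
    resid_df = float(n_obs - p)
    s2u, s2e = theta
    if s2u < 1e-10 * max(s2e, 1e-12):
        return np.full(p, resid_df)

    steps = np.array([max(1e-7, 1e-4 * s2u), max(1e-7, 1e-4 * s2e)])
    steps = np.minimum(steps, theta / 2.0)
    hess = np.empty((2, 2))
    f0 = _reml_neg2loglik(theta, blocks)
    for i in range(2):
        for j in range(i, 2):
            ei = np.zeros(2)
            ej = np.zeros(2)
            ei[i] = steps[i]
            ej[j] = steps[j]
            if i == j:
                fp = _reml_neg2loglik(theta + ei, blocks)
                fm = _reml_neg2loglik(theta - ei, blocks)
                hess[i, i] = (fp - 2 * f0 + fm) / steps[i] ** 2
            else:
                fpp = _reml_neg2loglik(theta + ei + ej, blocks)
                fpm = _reml_neg2loglik(theta + ei - ej, blocks)
                fmp = _reml_neg2loglik(theta - ei + ej, blocks)
                fmm = _reml_neg2loglik(theta - ei - ej, blocks)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    # -2 loglik => information is hess / 2
    try:
        a = np.linalg.inv(hess / 2.0)
    except np.linalg.LinAlgError:
        return np.full(p, resid_df)
    if not np.all(np.isfinite(a)) or np.any(np.diag(a) <= 0):
        return np.full(p, resid_df)

    dfs = np.empty(p)
    for k in range(p):
        _, f, g = _xtvix_and_grad(theta, blocks, k)
        denom = g @ a @ g
        if denom <= 0 or not math.isfinite(denom):
            dfs[k] = resid_df
        else:
            dfs[k] = max(1.0, 2.0 * f * f / denom)
    return dfs


def fit_random_intercept(table: pd.DataFrame) -> ModelFit:
    """Fit the random-intercept model by REML and return the full ModelFit.

    Requires at least 2 participants and non-degenerate predictors; a
    constant predictor (e.g. transitivity_change identically zero) raises
    SingularDesignError naming it, and REML non-convergence raises
    ConvergenceError rather than returning partial estimates.
    """
    import statsmodels.api as sm

    required = {"participant", "time", "accuracy", "transitivity_t0", "transitivity_change"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"long table is missing columns: {sorted(missing)}")
    if table[list(required)].isna().any().any():
        raise ValueError("long table contains missing values in model columns")
    n_participants = table["participant"].nunique()
    if n_participants < 2:
        raise ValueError(f"need >= 2 participants, got {n_participants}")

    y, X, groups = _design(table)
    _check_design(y, X)
    p = X.shape[1]

    model = sm.MixedLM(y, X, groups=groups)
    result = None
    for method in ("bfgs", "powell", "nm"):
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                candidate = model.fit(reml=True, method=method)
        except (np.linalg.LinAlgError, ValueError):
            continue
        if candidate.converged:
            result = candidate
            break
    if result is None:
        raise ConvergenceError("REML estimation of the random-intercept model did not converge")

    beta = np.asarray(result.fe_params, dtype=float)
    se = np.asarray(result.bse_fe, dtype=float)
    sigma2_u = float(np.asarray(result.cov_re).ravel()[0])
    sigma2_e = float(result.scale)

    blocks = _group_blocks(y, X, groups)
    theta = np.array([max(sigma2_u, 0.0), sigma2_e])
    dfs = _satterthwaite_df(theta, blocks, len(y), p)
    t_stats = beta / se
    p_values = 2.0 * stats.t.sf(np.abs(t_stats), dfs)

    fixed = tuple(
        FixedEffect(name=n, estimate=float(b), se=float(s), df=float(d), p_value=float(pv))
        for n, b, s, d, pv in zip(PREDICTORS, beta, se, dfs, p_values)
    )
    return ModelFit(
        fixed_effects=fixed,
        sigma2_intercept=sigma2_u,
        sigma2_residual=sigma2_e,
        n_participants=n_participants,
        n_observations=len(y),
        df_method="satterthwaite",
        converged=True,
        log_likelihood=float(result.llf),
    )


def predicted_accuracy_difference(fit: ModelFit, which: str, delta: float) -> float:
    """Model-implied accuracy difference for a `delta` difference in a predictor.

    E.g. with a between-person transitivity coefficient of 0.67, a 0.10
    classroom difference in baseline transitivity translates into a 0.067
    difference in expected accuracy.
    """
    if which not in {"transitivity_t0", "transitivity_change"}:
        raise KeyError(
            f"unknown predictor {which!r}; use 'transitivity_t0' or 'transitivity_change'"
        )
    return fit.coefficient(which).estimate * delta
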