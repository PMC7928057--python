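"""Temporal-order-judgement analysis: response proportions, logistic
psychometric fits, PSE / JND estimates and group-level inference.

The psychometric model is a two-parameter logistic,

    P(vertical first | lag t) = 1 / (1 + exp(-(t - mu) / s)),

fitted by maximum likelihood to the raw binary responses (default) or by
least squares to the per-lag proportions.  The point of subjective equality
(PSE, the 50% cross-over) equals ``mu``; the just-noticeable difference is
half the lag span between the 25% and 75% points, which for the logistic is
``s * ln 3`` exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

__all__ = [
    "PsychometricFit",
    "GroupStats",
    "response_proportions",
    "logistic_nll",
    "fit_psychometric",
    "jnd_from_curve",
    "group_inference",
    "t_test_from_summary",
    "pooled_curve",
]

LN3 = math.log(3.0)
S_BOUNDS = (1.0, 500.0)  # ms; lower bound guards against separation
MU_BOUNDS = (-1000.0, 1000.0)

REQUIRED_COLUMNS = ("participant_id", "lag_ms", "response")


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted logistic: location ``mu`` and scale ``s`` in ms.

    ``pse = mu`` and ``jnd = s * ln 3`` for the symmetric logistic.
    ``at_bound`` flags fits where the scale hit its bounds (e.g. complete
    separation in the responses).
    """

    mu: float
    s: float
    pse: float
    jnd: float
    n_trials: int
    converged: bool
    neg_log_likelihood: float
    at_bound: bool = False
    mode: str = "mle"


@dataclass(frozen=True)
class GroupStats:
    """One-sample t-test of PSEs against zero plus group summaries."""

    per_participant_pse: tuple[float, ...]
    per_participant_jnd: tuple[float, ...] | None
    mean_pse: float
    se_pse: float
    mean_jnd: float | None
    se_jnd: float | None
    t_stat: float
    df: int
    p_value: float
    tail: str
    degenerate: bool = False


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"response table lacks columns: {missing}")
    if not table["response"].isin([0, 1]).all():
        raise ValueError("responses must be binary 0/1")


def response_proportions(table: pd.DataFrame, participant) -> pd.DataFrame:
    """Per-lag proportion of 'vertical first' responses for one participant.

    Returns a frame with columns ``lag_ms``, ``proportion``, ``n``.
    """
    _check_table(table)
    sub = table[table["participant_id"] == participant]
    if sub.empty:
        known = sorted(table["participant_id"].unique().tolist())
        raise ValueError(f"unknown participant {participant!r}; have {known}")
    grouped = sub.groupby("lag_ms")["response"]
    return pd.DataFrame(
        {
            "lag_ms": grouped.mean().index.to_numpy(dtype=float),
            "proportion": grouped.mean().to_numpy(),
            "n": grouped.count().to_numpy(),
        }
    ).sort_values("lag_ms", ignore_index=True)


def logistic_nll(mu: float, s: float, lags: np.ndarray, responses: np.ndarray) -> float:
    """Negative Bernoulli log-likelihood of the logistic at (mu, s)."""
    p = expit((np.asarray(lags, dtype=float) - mu) / s)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    y = np.asarray(responses, dtype=float)
    return float(-np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def _initial_guess(lags: np.ndarray, props: np.ndarray) -> tuple[float, float]:
    """Deterministic start: mu at the interpolated 50% crossing, s = range/8."""
    order = np.argsort(lags)
    x, q = lags[order], props[order]
    mu0 = float(x[np.argmin(np.abs(q - 0.5))])
    crossing = np.nonzero((q[:-1] - 0.5) * (q[1:] - 0.5) < 0)[0]
    if crossing.size:
        i = int(crossing[0])
        frac = (0.5 - q[i]) / (q[i + 1] - q[i])
        mu0 = float(x[i] + frac * (x[i + 1] - x[i]))
    s0 = float(np.clip(np.ptp(x) / 8.0, *S_BOUNDS))
    return mu0, s0


def fit_psychometric(
    table: pd.DataFrame, participant, mode: str = "mle"
) -> PsychometricFit:
    """Fit the two-parameter logistic to one participant's responses.

    ``mode='mle'`` maximizes the Bernoulli likelihood of the raw responses;
    ``mode='proportions-ls'`` minimizes squared error to the per-lag
    proportions.  Requires responses at >= 4 distinct lags and both
    response categories present.  Complete separation does not abort the
    fit: the scale is bounded below and the result carries ``at_bound``.
    """
    _check_table(table)
    sub = table[table["participant_id"] == participant]
    if sub.empty:
        raise ValueError(f"unknown participant {participant!r}")
    lags = sub["lag_ms"].to_numpy(dtype=float)
    responses = sub["response"].to_numpy(dtype=float)
    if np.unique(lags).size < 4:
        raise ValueError("need responses at >= 4 distinct lags")
    if np.unique(responses).size < 2:
        raise ValueError("need both response categories present")
    props = response_proportions(table, participant)
    x0 = _initial_guess(props["lag_ms"].to_numpy(), props["proportion"].to_numpy())

    if mode == "mle":
        res = optimize.minimize(
            lambda th: logistic_nll(th[0], th[1], lags, responses),
            x0=np.asarray(x0),
            method="L-BFGS-B",
            bounds=[MU_BOUNDS, S_BOUNDS],
            options={"ftol": 1e-10, "gtol": 1e-10, "maxiter": 500},
        )
        mu, s = float(res.x[0]), float(res.x[1])
        converged = bool(res.success)
    elif mode == "proportions-ls":
        xlag = props["lag_ms"].to_numpy(dtype=float)
        q = props["proportion"].to_numpy(dtype=float)
        res = optimize.least_squares(
            lambda th: expit((xlag - th[0]) / th[1]) - q,
            x0=np.asarray(x0),
            bounds=([MU_BOUNDS[0], S_BOUNDS[0]], [MU_BOUNDS[1], S_BOUNDS[1]]),
            xtol=1e-12,
            ftol=1e-12,
        )
        mu, s = float(res.x[0]), float(res.x[1])
        converged = bool(res.success)
    else:
        raise ValueError("mode must be 'mle' or 'proportions-ls'")

    at_bound = bool(
        np.isclose(s, S_BOUNDS[0], atol=1e-6) or np.isclose(s, S_BOUNDS[1], atol=1e-6)
    )
    return PsychometricFit(
        mu=mu,
        s=s,
        pse=mu,
        jnd=s * LN3,
        n_trials=int(len(sub)),
        converged=converged,
        neg_log_likelihood=logistic_nll(mu, s, lags, responses),
        at_bound=at_bound,
        mode=mode,
    )


def jnd_from_curve(fit: PsychometricFit) -> float:
    """JND by numeric inversion of the fitted curve at 25% and 75%.

    Half the lag difference between the 75% and 25% points, found by root
    finding on the fitted logistic.  Agrees with the analytic ``s * ln 3``
    to high relative precision for any converged fit.
    """
    if not fit.converged:
        raise ValueError("cannot invert a non-converged fit")

    def curve(t: float) -> float:
        return float(expit((t - fit.mu) / fit.s))

    span = 60.0 * fit.s
    t25 = optimize.brentq(lambda t: curve(t) - 0.25, fit.mu - span, fit.mu, xtol=1e-12)
    t75 = optimize.brentq(lambda t: curve(t) - 0.75, fit.mu, fit.mu + span, xtol=1e-12)
    return (t75 - t25) / 2.0


def t_test_from_summary(
    mean: float, se: float, n: int, tail: str = "less"
) -> tuple[float, int, float]:
    """One-sample t-test against zero from summary statistics.

    Returns (t, df, p) with ``t = mean / se`` and df = n - 1.  ``tail`` is
    'less', 'greater' or 'two-sided'.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if se <= 0:
        raise ValueError("se must be positive")
    t = mean / se
    df = n - 1
    if tail == "less":
        p = float(stats.t.cdf(t, df))
    elif tail == "greater":
        p = float(stats.t.sf(t, df))
    elif tail == "two-sided":
        p = float(2 * stats.t.sf(abs(t), df))
    else:
        raise ValueError("tail must be 'less', 'greater' or 'two-sided'")
    return float(t), df, p


def group_inference(
    pse_values, tail: str = "less", jnd_values=None
) -> GroupStats:
    """One-sample t-test of per-participant PSEs against zero.

    The tail must be stated explicitly by the caller; it is recorded in the
    result.  JND values, if given, are summarized as mean +- SE.  The
    degenerate all-zero case (sd = 0, mean = 0) returns p = 0.5 with the
    ``degenerate`` flag set.
    """
    pse = np.asarray(pse_values, dtype=float)
    n = pse.size
    if n < 2:
        raise ValueError("need at least 2 participants")
    mean = float(pse.mean())
    sd = float(pse.std(ddof=1))
    se = sd / math.sqrt(n)
    degenerate = False
    if sd == 0:
        degenerate = True
        if mean == 0:
            t, df, p = 0.0, n - 1, 0.5
        else:
            t = math.inf if mean > 0 else -math.inf
            df = n - 1
            p = {"less": 1.0 if mean > 0 else 0.0,
                 "greater": 0.0 if mean > 0 else 1.0,
                 "two-sided": 0.0}[tail]
    else:
        t, df, p = t_test_from_summary(mean, se, n, tail)

    mean_jnd = se_jnd = None
    jnd_tuple = None
    if jnd_values is not None:
        jnd = np.asarray(jnd_values, dtype=float)
        jnd_tuple = tuple(float(v) for v in jnd)
        mean_jnd = float(jnd.mean())
        se_jnd = float(jnd.std(ddof=1) / math.sqrt(jnd.size)) if jnd.size > 1 else None
    return GroupStats(
        per_participant_pse=tuple(float(v) for v in pse),
        per_participant_jnd=jnd_tuple,
        mean_pse=mean,
        se_pse=se,
        mean_jnd=mean_jnd,
        se_jnd=se_jnd,
        t_stat=float(t),
        df=int(df),
        p_value=float(p),
        tail=tail,
        degenerate=degenerate,
    )


def pooled_curve(table: pd.DataFrame) -> tuple[pd.DataFrame, PsychometricFit]:
    """Cross-participant mean proportions per lag, plus a fit to them.

    The standard error is across participants; with a single participant it
    is reported as NaN.  The pooled curve is fitted by least squares to the
    pooled proportions (for plotting/summary use — group inference runs on
    the per-participant fits instead).
    """
    _check_table(table)
    participants = sorted(table["participant_id"].unique().tolist())
    per = []
    for p in participants:
        props = response_proportions(table, p).set_index("lag_ms")["proportion"]
        per.append(props.rename(p))
    wide = pd.concat(per, axis=1)
    pooled = pd.DataFrame(
        {
            "lag_ms": wide.index.to_numpy(dtype=float),
            "proportion": wide.mean(axis=1).to_numpy(),
            "se": wide.std(axis=1, ddof=1).to_numpy() / math.sqrt(len(participants))
            if len(participants) > 1
            else np.full(len(wide), np.nan),
            "n_participants": len(participants),
        }
    ).sort_values("lag_ms", ignore_index=True)

    # fit the pooled proportions with a synthetic single-participant table:
    # weight each lag by its mean proportion via least squares
    x0 = _initial_guess(pooled["lag_ms"].to_numpy(), pooled["proportion"].to_numpy())
    res = optimize.least_squares(
        lambda th: expit((pooled["lag_ms"].to_numpy() - th[0]) / th[1])
        - pooled["proportion"].to_numpy(),
        x0=np.asarray(x0),
        bounds=([MU_BOUNDS[0], S_BOUNDS[0]], [MU_BOUNDS[1], S_BOUNDS[1]]),
        xtol=1e-12,
        ftol=1e-12,
    )
    mu, s = float(res.x[0]), float(res.x[1])
    fit = PsychometricFit(
        mu=mu,
        s=s,
        pse=mu,
        jnd=s * LN3,
        n_trials=int(len(table)),
        converged=bool(res.success),
        neg_log_likelihood=float("nan"),
        at_bound=bool(
            np.isclose(s, S_BOUNDS[0], atol=1e-6) or np.isclose(s, S_BOUNDS[1], atol=1e-6)
        ),
        mode="proportions-ls",
    )
    return pooled, fit
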