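"""State-resolved RT pooling and the statistical comparisons.

Once per-volume brain-state labels and per-trial RTs exist, correct
commission RTs are pooled by the state active at each trial's onset, an
ex-Gaussian is fitted per state per participant, and the parameters are
compared across states with two-tailed paired t-tests and Hedges' g.
Cross-participant structure (parameter-error Spearman correlations, a
Table-style multiple regression of error counts on the three parameters,
and the mind-wandering correlation) lives here too.

Hedges' g uses the pooled-SD standardizer with the small-sample correction
J(df) = 1 - 3/(4 df - 1), df = 2n - 2 — not the paired d_z — so effect sizes
are comparable across studies regardless of the within-pair correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .behavior import RTSeries
from .exgauss import FitReport, InsufficientDataError, fit_with_skew_policy
from .mem import StateSeries

__all__ = [
    "StateRTPools",
    "ComparisonResult",
    "pool_rts",
    "compare_states",
    "paired_stats",
    "hedges_g",
    "correlate_params",
    "regress_errors",
    "mind_wandering_correlation",
]

MIN_POOL_TRIALS = 10


@dataclass
class StateRTPools:
    """Correct-commission RTs pooled by brain state for one participant."""

    pools: dict[int, np.ndarray]
    n_dropped: int = 0            # trials outside the labelled span
    participant: int | None = None

    def n(self, state: int) -> int:
        return self.pools.get(state, np.empty(0)).size


@dataclass
class ComparisonResult:
    """Paired state comparison of the three ex-Gaussian parameters."""

    table: pd.DataFrame           # one row per parameter
    n_included: int
    n_excluded: int
    exclusions: dict[int, str] = field(default_factory=dict)
    per_participant: pd.DataFrame | None = None


def pool_rts(
    rts: RTSeries,
    states: StateSeries,
    tr: float | None = None,
    participant: int | None = None,
) -> StateRTPools:
    """Pool correct-commission RTs by the state at each trial's onset.

    A trial belongs to the volume whose interval [v*tr, (v+1)*tr) contains
    its onset; trials whose onset volume is not labelled (e.g. the shifted
    tail of a run) are dropped and counted, never imputed.
    """
    tr = states.tr if tr is None else tr
    labels = states.labels
    if labels.size == 0:
        raise ValueError("empty state series")
    pools: dict[int, list[float]] = {}
    dropped = 0
    correct = rts.classification == "correct_commission"
    for onset, rt, ok in zip(rts.onsets, rts.rts, correct):
        if not ok:
            continue
        v = int(onset // tr)
        if v >= labels.size:
            dropped += 1
            continue
        pools.setdefault(int(labels[v]), []).append(float(rt))
    return StateRTPools(
        pools={k: np.asarray(v) for k, v in pools.items()},
        n_dropped=dropped,
        participant=participant,
    )


def paired_stats(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Two-tailed paired t-test: (t, df, p) on the differences a - b.

    Identical vectors give t = 0, p = 1 (rather than the 0/0 indeterminate
    form of the usual formula).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need paired vectors with n >= 2")
    d = a - b
    df = d.size - 1
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        t = 0.0 if np.mean(d) == 0 else float("inf") * np.sign(np.mean(d))
    else:
        t = float(np.mean(d) / (sd / np.sqrt(d.size)))
    p = float(2.0 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return t, df, p


def hedges_g(x: np.ndarray, y: np.ndarray) -> float:
    """Pooled-SD Hedges' g with small-sample correction (df = n_x + n_y - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    df = nx + ny - 2
    if df <= 0:
        return float("nan")
    s_pooled = np.sqrt(
        ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / df
    )
    if s_pooled == 0:
        return 0.0 if np.mean(x) == np.mean(y) else float("inf")
    correction = 1.0 - 3.0 / (4.0 * df - 1.0)
    return correction * float((np.mean(x) - np.mean(y)) / s_pooled)


def compare_states(
    pools_by_participant: list[StateRTPools],
    state_a: int,
    state_b: int,
    skew_policy: str = "exclude",
    min_trials: int = MIN_POOL_TRIALS,
) -> ComparisonResult:
    """Fit per-state ex-Gaussians and compare parameters across participants.

    The negative-skew decision is made at the participant level, on the
    combined correct-commission RTs across both states (matching how real
    datasets exclude whole participants whose overall distribution is
    left-tailed): with ``skew_policy='exclude'`` such participants are
    dropped; with ``'flip'`` each state pool is fitted with the mirror
    policy.  Participants failing in either state — too few trials or
    degenerate data — are excluded from all three parameter comparisons
    jointly, keeping the paired design balanced.  Each parameter is then
    tested with a two-tailed paired t-test (df = n_included - 1) and
    summarised with pooled-SD Hedges' g.
    """
    from .exgauss import fit_exgauss, sample_skewness

    rows = []
    exclusions: dict[int, str] = {}
    for idx, pools in enumerate(pools_by_participant):
        pid = pools.participant if pools.participant is not None else idx
        fits: dict[int, FitReport] = {}
        reason = None
        if pools.n(state_a) >= min_trials and pools.n(state_b) >= min_trials:
            combined = np.concatenate([pools.pools[state_a], pools.pools[state_b]])
            if skew_policy == "exclude" and sample_skewness(combined) < 0:
                reason = "negative_skewness"
        for state in (state_a, state_b):
            if reason is not None:
                break
            if pools.n(state) < min_trials:
                reason = f"insufficient_trials_state_{state}"
                break
            try:
                if skew_policy == "flip":
                    rep = fit_with_skew_policy(
                        pools.pools[state], policy="flip", min_trials=min_trials
                    )
                else:
                    rep = fit_exgauss(pools.pools[state], min_trials=min_trials)
            except InsufficientDataError:
                reason = f"degenerate_data_state_{state}"
                break
            fits[state] = rep
        if reason is not None:
            exclusions[pid] = reason
            continue
        rows.append({
            "participant": pid,
            **{f"{p}_a": getattr(fits[state_a].params, p) for p in ("mu", "sigma", "tau")},
            **{f"{p}_b": getattr(fits[state_b].params, p) for p in ("mu", "sigma", "tau")},
        })

    per_part = pd.DataFrame(rows)
    n_inc = len(per_part)
    n_exc = len(exclusions)
    if n_inc < 3:
        raise ValueError(
            f"need at least 3 included participants, got {n_inc} "
            f"({n_exc} excluded)"
        )
    out = []
    for p in ("mu", "sigma", "tau"):
        a = per_part[f"{p}_a"].to_numpy()
        b = per_part[f"{p}_b"].to_numpy()
        t, df, pval = paired_stats(a, b)
        out.append({
            "parameter": p,
            "mean_a": float(np.mean(a)),
            "mean_b": float(np.mean(b)),
            "t": t,
            "df": df,
            "p": pval,
            "hedges_g": hedges_g(a, b),
        })
    return ComparisonResult(
        table=pd.DataFrame(out),
        n_included=n_inc,
        n_excluded=n_exc,
        exclusions=exclusions,
        per_participant=per_part,
    )


def correlate_params(
    params: np.ndarray, outcome: np.ndarray, method: str = "spearman"
) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with two-sided p."""
    if method != "spearman":
        raise ValueError("only Spearman correlations are supported")
    x = np.asarray(params, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector; correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def regress_errors(params: np.ndarray, errors: np.ndarray) -> dict:
    """OLS of error counts on (mu, sigma, tau) with raw and standardized betas.

    Returns per-coefficient estimates, t and p values, plus overall R^2 and
    the F test, in the style of a multiple-regression table predicting each
    error type from the three ex-Gaussian parameters.
    """
    X = np.asarray(params, dtype=float)
    y = np.asarray(errors, dtype=float)
    n, k = X.shape
    if k != 3:
        raise ValueError("params must be n x 3 (mu, sigma, tau)")
    if n <= k + 1:
        raise ValueError("need n > 4 observations")

    def ols(Xd: np.ndarray, yd: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
        A = np.column_stack([np.ones(Xd.shape[0]), Xd])
        rank = np.linalg.matrix_rank(A)
        if rank < A.shape[1]:
            import warnings

            warnings.warn("collinear predictors; using pseudo-inverse")
        beta = np.linalg.pinv(A) @ yd
        resid = yd - A @ beta
        dof = Xd.shape[0] - A.shape[1]
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.pinv(A.T @ A)
        se = np.sqrt(np.diag(cov))
        tvals = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
        ss_tot = float(np.sum((yd - yd.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else float("nan")
        return beta, tvals, r2, s2

    beta, tvals, r2, _ = ols(X, y)
    dof = n - 4
    pvals = 2.0 * sps.t.sf(np.abs(tvals), dof)
    Xz = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    yz = (y - y.mean()) / y.std(ddof=1)
    beta_std, _, _, _ = ols(Xz, yz)
    f_stat = (r2 / 3) / ((1.0 - r2) / dof) if 0 <= r2 < 1 else float("nan")
    f_p = float(sps.f.sf(f_stat, 3, dof)) if np.isfinite(f_stat) else float("nan")
    names = ["intercept", "mu", "sigma", "tau"]
    return {
        "coef": dict(zip(names, beta)),
        "t": dict(zip(names, tvals)),
        "p": dict(zip(names, pvals)),
        "coef_std": dict(zip(names, beta_std)),
        "r2": r2,
        "F": float(f_stat),
        "F_p": f_p,
        "df": (3, dof),
    }


def mind_wandering_correlation(
    sigma: np.ndarray, probe_means: np.ndarray
) -> tuple[float, float]:
    """Spearman correlation between sigma and mean mind-wandering rating.

    Probe ratings run from 0 ("only task") to 100 ("only else"); each
    participant enters with the mean of their probe responses.
    """
    probes = np.asarray(probe_means, dtype=float)
    if np.any((probes < 0) | (probes > 100)):
        raise ValueError("probe scores must lie in [0, 100]")
    return correlate_params(np.asarray(sigma, dtype=float), probes)
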