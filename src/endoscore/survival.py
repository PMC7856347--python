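"""Prognostic stratification of a scored cohort.

The pipeline's last stage: choose a score cut-point by maximally
selected rank statistics (maxstat), split the cohort into high/low
groups, and quantify the contrast with the Kaplan-Meier product-limit
estimator, the log-rank test and a one-covariate Cox proportional
hazards model.

Maxstat follows the rank-statistic formulation: each sample receives a
log-rank score ``a_i = delta_i - H(t_i)`` (event indicator minus the
Nelson-Aalen cumulative hazard at its observed time).  For a candidate
cut-point ``c`` the linear statistic ``S_c = sum_{score_i > c} a_i`` is
standardized by its conditional permutation mean and variance, and the
cut-point maximizing ``|T_c|`` is selected.  Because the selection
itself inflates the naive log-rank p-value, significance is assessed by
a seeded permutation test on ``max_c |T_c|``.

The Cox fit maximizes the partial likelihood (Breslow tie handling) by
Newton iteration; with a single binary covariate the risk-set sums
reduce to group counts, so each iteration is closed-form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datatypes import ScoreTable, SurvivalRecord

__all__ = [
    "KMEstimate",
    "LogRankResult",
    "MaxstatResult",
    "CoxResult",
    "StratificationReport",
    "km_estimate",
    "logrank_test",
    "logrank_scores",
    "maxstat_cutpoint",
    "cox_hr",
    "stratify_and_analyze",
]

logger = logging.getLogger(__name__)


@dataclass
class KMEstimate:
    """Kaplan-Meier product-limit estimate at the distinct event times."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) at each event time
    at_risk: np.ndarray     # n_i just before each event time
    events: np.ndarray      # d_i at each event time

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


@dataclass
class LogRankResult:
    statistic: float  # chi-square, 1 df
    p_value: float


@dataclass
class MaxstatResult:
    cutpoint: float
    statistic: float          # standardized linear rank statistic at the cutpoint
    p_value: float            # permutation tail probability of max |T|
    n_high: int
    n_low: int
    n_permutations: int
    seed: int
    candidate_cutpoints: np.ndarray = field(default_factory=lambda: np.empty(0))
    candidate_statistics: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class CoxResult:
    log_hr: float
    hr: float
    se: float
    p_value: float
    converged: bool


@dataclass
class StratificationReport:
    maxstat: MaxstatResult
    km_high: KMEstimate
    km_low: KMEstimate
    logrank: LogRankResult
    cox: CoxResult
    high_sample_ids: list[str]
    low_sample_ids: list[str]


def _times_events(records: list[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    if not records:
        raise ValueError("no survival records")
    t = np.asarray([r.time for r in records], dtype=float)
    d = np.asarray([r.event for r in records], dtype=np.int64)
    return t, d


def km_estimate(records: list[SurvivalRecord]) -> KMEstimate:
    """Product-limit survival estimate over the distinct event times.

    Censored observations tied with an event time are counted at risk at
    that time (censoring after events, the standard convention).  With no
    events the estimate is identically 1.
    """
    t, d = _times_events(records)
    n = len(t)
    event_times = np.unique(t[d == 1])
    surv, at_risk, events = [], [], []
    s = 1.0
    for ti in event_times:
        ni = int(np.sum(t >= ti))
        di = int(np.sum((t == ti) & (d == 1)))
        s *= 1.0 - di / ni
        at_risk.append(ni)
        events.append(di)
        surv.append(s)
    return KMEstimate(times=event_times, survival=np.asarray(surv),
                      at_risk=np.asarray(at_risk, dtype=np.int64),
                      events=np.asarray(events, dtype=np.int64))


def logrank_test(records: list[SurvivalRecord], group: np.ndarray) -> LogRankResult:
    """Two-sample log-rank test.

    Sums observed-minus-expected events for group 1 over the distinct
    event times, with the hypergeometric variance; the statistic is
    referred to a chi-square distribution with 1 df.
    """
    t, d = _times_events(records)
    group = np.asarray(group, dtype=bool)
    if group.shape != t.shape:
        raise ValueError("group vector length must match records")
    if group.all() or (~group).all():
        raise ValueError("log-rank test needs two non-empty groups")
    if d.sum() == 0:
        raise ValueError("log-rank statistic undefined with zero events")

    o_minus_e = 0.0
    var = 0.0
    for ti in np.unique(t[d == 1]):
        at_risk = t >= ti
        ni = int(at_risk.sum())
        n1 = int((at_risk & group).sum())
        di = int(((t == ti) & (d == 1)).sum())
        d1 = int(((t == ti) & (d == 1) & group).sum())
        o_minus_e += d1 - di * n1 / ni
        if ni > 1:
            var += di * (n1 / ni) * (1 - n1 / ni) * (ni - di) / (ni - 1)
    if var == 0.0:
        return LogRankResult(statistic=0.0, p_value=1.0)
    chi2 = o_minus_e ** 2 / var
    return LogRankResult(statistic=float(chi2), p_value=float(stats.chi2.sf(chi2, df=1)))


def logrank_scores(records: list[SurvivalRecord]) -> np.ndarray:
    """Per-sample log-rank (Savage-type) scores a_i = delta_i - H(t_i).

    H is the Nelson-Aalen cumulative hazard evaluated at each sample's
    observed time, with censored observations tied to an event time
    counted at risk there.
    """
    t, d = _times_events(records)
    event_times = np.unique(t[d == 1])
    increments = np.array([
        np.sum((t == ti) & (d == 1)) / np.sum(t >= ti) for ti in event_times
    ])
    cumhaz = np.concatenate(([0.0], np.cumsum(increments)))
    idx = np.searchsorted(event_times, t, side="right")
    return d - cumhaz[idx]


def maxstat_cutpoint(scores: np.ndarray, records: list[SurvivalRecord],
                     minprop: float = 0.1, maxprop: float = 0.9,
                     n_permutations: int = 1000, seed: int = 0) -> MaxstatResult:
    """Maximally selected rank statistic cut-point with permutation p-value.

    Candidates are the distinct observed score values ``c`` for which the
    fraction of samples with ``score > c`` lies in ``[minprop, maxprop]``.
    The selected cut-point maximizes the absolute standardized log-rank
    statistic of the ``score > c`` split (ties toward the smallest
    candidate); its p-value is the permutation tail probability of the
    maximum over candidates, with add-one smoothing ``(b+1)/(B+1)``.
    """
    scores = np.asarray(scores, dtype=float)
    t, d = _times_events(records)
    n = len(t)
    if scores.shape != (n,):
        raise ValueError("scores length must match records")
    if n < 10:
        raise ValueError(f"maxstat needs n >= 10 samples, got {n}")
    if d.sum() == 0:
        raise ValueError("maxstat undefined with zero events")
    if n_permutations < 100:
        logger.warning("n_permutations=%d < 100: permutation p-value will be coarse",
                       n_permutations)

    a = logrank_scores(records)
    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    a_sorted = a[order]

    # candidate c = s_sorted[i] (last index of each tied run): high group
    # is everything above position i
    last_of_run = np.nonzero(np.r_[s_sorted[:-1] != s_sorted[1:], True])[0]
    m_high = n - (last_of_run + 1)
    frac = m_high / n
    ok = (frac >= minprop) & (frac <= maxprop) & (m_high > 0)
    cand_pos = last_of_run[ok]
    if len(cand_pos) < 2:
        raise ValueError("fewer than 2 admissible cut-point candidates in the "
                         f"[{minprop}, {maxprop}] proportion window")
    cand_values = s_sorted[cand_pos]
    m = n - (cand_pos + 1)

    a_bar = a.mean()
    a_var = np.sum((a - a_bar) ** 2)
    var = m * (n - m) / (n * (n - 1.0)) * a_var
    if np.any(var <= 0):
        raise ValueError("degenerate log-rank scores: zero permutation variance")
    sd = np.sqrt(var)

    def standardized(a_vec: np.ndarray) -> np.ndarray:
        tail = np.cumsum(a_vec[::-1])[::-1]        # sum over positions >= i
        s_high = tail[cand_pos + 1]
        return (s_high - m * a_bar) / sd

    t_obs = standardized(a_sorted)
    best = int(np.argmax(np.abs(t_obs)))  # argmax returns first max: smallest c
    observed_max = float(np.abs(t_obs).max())

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(a_sorted, (n_permutations, 1)), axis=1)
    tails = np.cumsum(perms[:, ::-1], axis=1)[:, ::-1]
    s_high = tails[:, cand_pos + 1]
    t_perm = (s_high - m * a_bar) / sd
    exceed = int(np.sum(np.abs(t_perm).max(axis=1) >= observed_max))
    p = (exceed + 1) / (n_permutations + 1)

    n_high = int(m[best])
    return MaxstatResult(cutpoint=float(cand_values[best]), statistic=float(t_obs[best]),
                         p_value=float(p), n_high=n_high, n_low=n - n_high,
                         n_permutations=n_permutations, seed=seed,
                         candidate_cutpoints=cand_values,
                         candidate_statistics=t_obs)


def cox_hr(records: list[SurvivalRecord], group: np.ndarray,
            tol: float = 1e-8, max_iter: int = 50) -> CoxResult:
    """Cox proportional-hazards fit for one binary covariate.

    Newton iteration on the Breslow partial likelihood.  With complete
    separation of event orderings the likelihood is unbounded; the fit is
    then flagged ``converged=False`` with a signed infinite trend in
    ``log_hr`` rather than raising.
    """
    t, d = _times_events(records)
    group = np.asarray(group, dtype=bool)
    if group.shape != t.shape:
        raise ValueError("group vector length must match records")
    if d[group].sum() == 0 or d[~group].sum() == 0:
        raise ValueError("Cox fit needs at least one event in each group")

    event_times = np.unique(t[d == 1])
    # per distinct event time: events in group 1, total events, at-risk counts
    d1 = np.array([np.sum((t == ti) & (d == 1) & group) for ti in event_times])
    dd = np.array([np.sum((t == ti) & (d == 1)) for ti in event_times])
    r1 = np.array([np.sum((t >= ti) & group) for ti in event_times])
    r0 = np.array([np.sum((t >= ti) & ~group) for ti in event_times])

    def score_info(beta: float) -> tuple[float, float]:
        eb = np.exp(beta)
        denom = r1 * eb + r0
        pi = r1 * eb / denom
        u = float(np.sum(d1 - dd * pi))
        info = float(np.sum(dd * pi * (1 - pi)))
        return u, info

    # |log HR| beyond this is numerically indistinguishable from complete
    # separation: the score function underflows below tol near exp(+-15)
    divergence = 15.0
    beta = 0.0
    converged = False
    for _ in range(max_iter):
        u, info = score_info(beta)
        if abs(u) < tol:
            converged = True
            break
        if info <= 0 or abs(beta) > divergence:
            break
        beta += u / info
    if abs(beta) > divergence:
        # unbounded likelihood: report the trend direction, not a number
        u0, _ = score_info(0.0)
        beta = np.inf if u0 > 0 else -np.inf
        return CoxResult(log_hr=float(beta), hr=float(np.exp(beta)), se=np.inf,
                         p_value=np.nan, converged=False)
    _, info = score_info(beta)
    se = float(1.0 / np.sqrt(info)) if info > 0 else np.inf
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return CoxResult(log_hr=float(beta), hr=float(np.exp(beta)), se=se,
                     p_value=p, converged=converged)


def stratify_and_analyze(score_table: ScoreTable, records: list[SurvivalRecord],
                         minprop: float = 0.1, maxprop: float = 0.9,
                         n_permutations: int = 1000, seed: int = 0) -> StratificationReport:
    """Full prognostic analysis of a scored cohort.

    Inner-joins scores and survival on sample id, selects the maxstat
    cut-point, then compares the resulting high (score > cutpoint) and
    low groups by Kaplan-Meier, log-rank and Cox hazard ratio.
    Deterministic given the seed.
    """
    by_id = {r.sample_id: r for r in records}
    shared = [sid for sid in score_table.sample_ids if sid in by_id]
    dropped = len(score_table.sample_ids) - len(shared) + len(by_id) - len(shared)
    if dropped:
        logger.info("dropping %d samples without both a score and a survival record", dropped)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} samples have both a score and a survival "
                         "record; need >= 10")
    # canonical order: sorted sample id, so results are input-order invariant
    shared = sorted(shared)
    joined = [by_id[sid] for sid in shared]
    scores = score_table.scores.loc[shared].to_numpy(dtype=float)

    ms = maxstat_cutpoint(scores, joined, minprop=minprop, maxprop=maxprop,
                          n_permutations=n_permutations, seed=seed)
    high = scores > ms.cutpoint
    km_high = km_estimate([r for r, h in zip(joined, high) if h])
    km_low = km_estimate([r for r, h in zip(joined, high) if not h])
    lr = logrank_test(joined, high)
    cox = cox_hr(joined, high)
    return StratificationReport(
        maxstat=ms, km_high=km_high, km_low=km_low, logrank=lr, cox=cox,
        high_sample_ids=[s for s, h in zip(shared, high) if h],
        low_sample_ids=[s for s, h in zip(shared, high) if not h],
    )
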