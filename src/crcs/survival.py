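"""Patient-level cumulative scoring and survival risk stratification.

A patient's cumulative score is the mean over their mutations of
2^(k * score_i) - 1 (k = 4 by default), which weights high classifier
scores exponentially; it ranges over [0, 2^k - 1].  Cohorts are filtered to
patients with at least ``min_mutations`` scored mutations and to cancer
types with at least ``min_patients_per_type`` such patients.  Within each
cancer type the cohort is dichotomized at the cutpoint maximising the
log-rank chi-square (among admissible cutpoints), and group survival
separation is tested with the Mantel-Haenszel log-rank test.

Because the cutpoint is chosen to maximise the statistic, the raw log-rank
p at the chosen threshold is anti-conservative.  Both the raw p
(matching the common survfit/survdiff usage) and a permutation-based
selection-adjusted p (maximally selected chi-square null) are reported; the
adjusted p is the calibrated quantity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats as sps

logger = logging.getLogger("crcs")

__all__ = [
    "BLACsConfig",
    "ThresholdConstraints",
    "PatientProfile",
    "StratifiedCohort",
    "blacs_score",
    "cohort_filters",
    "logrank_test",
    "chi2_scan",
    "optimal_threshold",
    "stratify_and_test",
    "km_curve",
]


@dataclass(frozen=True)
class ThresholdConstraints:
    """Admissibility of candidate cutpoints: each side must hold at least
    ``min_fraction`` of patients and at least ``min_group`` patients."""

    min_fraction: float = 0.10
    min_group: int = 5


@dataclass
class BLACsConfig:
    k: float = 4.0
    min_mutations: int = 5
    min_patients_per_type: int = 100
    constraints: ThresholdConstraints = field(default_factory=ThresholdConstraints)
    n_permutations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")


@dataclass
class PatientProfile:
    patient_id: str
    cancer_type: str
    mutation_scores: list[float]
    survival_time: float
    event: int

    def __post_init__(self) -> None:
        if any(not 0.0 <= s <= 1.0 for s in self.mutation_scores):
            raise ValueError("mutation scores must lie in [0, 1]")
        if self.survival_time < 0:
            raise ValueError("survival time must be nonnegative")
        if self.event not in (0, 1):
            raise ValueError("event indicator must be 0 or 1")


@dataclass
class StratifiedCohort:
    cancer_type: str
    patient_ids: list[str]
    scores: np.ndarray
    risk_group: np.ndarray  # "high" / "low"
    threshold: float
    chi2: float
    p_value: float
    adjusted_p_value: Optional[float]
    km_curves: dict[str, pd.DataFrame]


def blacs_score(scores: Sequence[float], k: float = 4.0) -> float:
    """Cumulative patient score: mean over mutations of 2^(k*score) - 1."""
    if len(scores) == 0:
        raise ValueError("patient has no mutation scores")
    s = np.asarray(scores, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must lie in [0, 1]")
    if k <= 0:
        raise ValueError("k must be positive")
    return float(np.mean(2.0 ** (k * s) - 1.0))


def cohort_filters(
    patients: Sequence[PatientProfile], cfg: BLACsConfig = BLACsConfig()
) -> dict[str, list[PatientProfile]]:
    """Drop sparse patients, then sparse cancer types.

    Patients with fewer than ``min_mutations`` scored mutations are removed
    first; cancer types left with fewer than ``min_patients_per_type``
    patients are then dropped entirely.
    """
    enough = [p for p in patients if len(p.mutation_scores) >= cfg.min_mutations]
    by_type: dict[str, list[PatientProfile]] = {}
    for p in enough:
        by_type.setdefault(p.cancer_type, []).append(p)
    kept = {
        ct: ps for ct, ps in by_type.items() if len(ps) >= cfg.min_patients_per_type
    }
    logger.info(
        "cohort_filters: %d/%d patients with >=%d mutations; %d/%d cancer types kept",
        len(enough), len(patients), cfg.min_mutations, len(kept), len(by_type),
    )
    return kept


def _logrank_chi2(times, events, in_a) -> float:
    """Mantel-Haenszel log-rank chi-square for membership vector *in_a*.

    Accumulates observed-minus-expected events for group a over distinct
    event times with the hypergeometric variance; events at a time are
    counted before censorings at the same time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    in_a = np.asarray(in_a, dtype=bool)
    event_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in_a).sum())
        dying = (times == t) & (events == 1)
        d = int(dying.sum())
        d1 = int((dying & in_a).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0.0:
        return 0.0
    return o_minus_e**2 / var


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p) with 1 df."""
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be nonempty")
    if np.any(times_a < 0) or np.any(times_b < 0):
        raise ValueError("times must be nonnegative")
    times = np.concatenate([times_a, times_b])
    events = np.concatenate([events_a, events_b]).astype(int)
    in_a = np.zeros(times.size, dtype=bool)
    in_a[: times_a.size] = True
    chi2 = _logrank_chi2(times, events, in_a)
    p = float(sps.chi2.sf(chi2, df=1))
    return float(chi2), p


def _admissible_cutpoints(scores, constraints: ThresholdConstraints) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    distinct = np.unique(scores)
    if distinct.size < 2:
        return np.array([])
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    min_side = max(int(math.ceil(constraints.min_fraction * n)), constraints.min_group)
    ok = []
    for c in mids:
        high = int((scores >= c).sum())
        if high >= min_side and (n - high) >= min_side:
            ok.append(c)
    return np.asarray(ok)


def chi2_scan(
    scores, times, events, constraints: ThresholdConstraints = ThresholdConstraints()
) -> tuple[np.ndarray, np.ndarray]:
    """Log-rank chi-square at every admissible cutpoint (midpoints of
    consecutive distinct scores).

    Vectorised over cutpoints: with patients ordered by score, every
    cutpoint's high-risk group is a suffix, so the per-event-time risk and
    death counts of all cutpoints are suffix cumulative sums of one
    (event time x patient) risk table.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    cuts = _admissible_cutpoints(scores, constraints)
    if cuts.size == 0:
        return cuts, np.array([])
    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    t_sorted = times[order]
    e_sorted = events[order]
    etimes = np.unique(t_sorted[e_sorted == 1])
    R = t_sorted[None, :] >= etimes[:, None]  # (k, n) at risk
    D = (t_sorted[None, :] == etimes[:, None]) & (e_sorted[None, :] == 1)
    # suffix sums over the score-sorted patient axis -> one column per
    # possible split position j (high group = patients j..n-1)
    n1_suffix = np.cumsum(R[:, ::-1], axis=1)[:, ::-1].astype(float)
    d1_suffix = np.cumsum(D[:, ::-1], axis=1)[:, ::-1].astype(float)
    n_tot = R.sum(axis=1).astype(float)
    d_tot = D.sum(axis=1).astype(float)
    # split position for each cutpoint
    js = np.searchsorted(s_sorted, cuts)
    n1 = n1_suffix[:, js]
    d1 = d1_suffix[:, js]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = n1 / n_tot[:, None]
        o_minus_e = (d1 - d_tot[:, None] * frac).sum(axis=0)
        denom = np.where(n_tot > 1, n_tot - 1, 1.0)
        var_terms = (
            d_tot[:, None]
            * frac
            * (1 - frac)
            * ((n_tot - d_tot) / denom)[:, None]
        )
        var = np.where(n_tot[:, None] > 1, var_terms, 0.0).sum(axis=0)
    chi2s = np.where(var > 0, o_minus_e**2 / np.where(var > 0, var, 1.0), 0.0)
    return cuts, chi2s


def optimal_threshold(
    blacs_scores,
    times,
    events,
    constraints: ThresholdConstraints = ThresholdConstraints(),
) -> float:
    """Cutpoint maximising the log-rank chi-square; ties -> lowest cutpoint."""
    cuts, chi2s = chi2_scan(blacs_scores, times, events, constraints)
    if cuts.size == 0:
        raise ValueError("no admissible cutpoint (scores too concentrated)")
    best = np.max(chi2s)
    return float(cuts[np.nonzero(chi2s >= best - 1e-12)[0][0]])


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier survival estimate as a (time, survival, at_risk) table."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=int))
    surv = kmf.survival_function_
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    return pd.DataFrame(
        {
            "time": surv.index.to_numpy(dtype=float),
            "survival": surv.iloc[:, 0].to_numpy(dtype=float),
            "at_risk": at_risk.to_numpy(dtype=float),
        }
    )


def _max_chi2_permutation_p(
    scores, times, events, observed, constraints, n_permutations, rng
) -> float:
    """Permutation p for the maximally selected chi-square statistic."""
    count = 0
    scores = np.asarray(scores, dtype=float)
    for _ in range(n_permutations):
        perm = rng.permutation(scores.size)
        _, chi2s = chi2_scan(scores[perm], times, events, constraints)
        if chi2s.size and chi2s.max() >= observed - 1e-12:
            count += 1
    return (1 + count) / (n_permutations + 1)


def stratify_and_test(
    patients: Sequence[PatientProfile], cfg: BLACsConfig = BLACsConfig()
) -> dict[str, StratifiedCohort]:
    """Per-cancer-type dichotomization and log-rank testing.

    Assumes :func:`cohort_filters` has already been applied.  Patients with
    cumulative score >= the optimal threshold form the high-risk group.
    """
    by_type: dict[str, list[PatientProfile]] = {}
    for p in patients:
        by_type.setdefault(p.cancer_type, []).append(p)
    rng = np.random.default_rng(cfg.seed)
    out: dict[str, StratifiedCohort] = {}
    for ct in sorted(by_type):
        ps = by_type[ct]
        scores = np.array([blacs_score(p.mutation_scores, cfg.k) for p in ps])
        times = np.array([p.survival_time for p in ps], dtype=float)
        events = np.array([p.event for p in ps], dtype=int)
        threshold = optimal_threshold(scores, times, events, cfg.constraints)
        high = scores >= threshold
        chi2, p = logrank_test(times[high], events[high], times[~high], events[~high])
        adj_p = None
        if cfg.n_permutations > 0:
            adj_p = _max_chi2_permutation_p(
                scores, times, events, chi2, cfg.constraints, cfg.n_permutations, rng
            )
        out[ct] = StratifiedCohort(
            cancer_type=ct,
            patient_ids=[p.patient_id for p in ps],
            scores=scores,
            risk_group=np.where(high, "high", "low"),
            threshold=threshold,
            chi2=chi2,
            p_value=p,
            adjusted_p_value=adj_p,
            km_curves={
                "high": km_curve(times[high], events[high]),
                "low": km_curve(times[~high], events[~high]),
            },
        )
    return out
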