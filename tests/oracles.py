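"""Independent brute-force oracles used to cross-check the package.

Everything here is written from the defining formulas by direct
enumeration over cells, risk sets or observation pairs, deliberately
sharing no code with the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# -- agreement ---------------------------------------------------------------

def kappa_by_definition(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    po = sum(counts[i, i] for i in range(counts.shape[0])) / n
    pe = 0.0
    for i in range(counts.shape[0]):
        pe += (counts[i, :].sum() / n) * (counts[:, i].sum() / n)
    return (po - pe) / (1 - pe)


def cramer_v_by_definition(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    r, c = counts.shape
    chi2 = 0.0
    for i in range(r):
        for j in range(c):
            expected = counts[i, :].sum() * counts[:, j].sum() / n
            chi2 += (counts[i, j] - expected) ** 2 / expected
    return math.sqrt(chi2 / (n * min(r - 1, c - 1)))


# -- Wieneke score -----------------------------------------------------------

def wieneke_score_by_enumeration(case) -> int | None:
    """Re-enumerate the nine criteria independently of the implementation."""
    criteria = []
    criteria.append(None if case.weight_g is None else case.weight_g > 400)
    criteria.append(None if case.size_cm is None else case.size_cm > 10.5)
    criteria.append(case.extra_adrenal_extension)
    criteria.append(case.vena_cava_invasion)
    criteria.append(case.vascular_invasion)
    criteria.append(case.capsular_invasion)
    criteria.append(case.necrosis)
    mc = case.mitoses_per_20hpf
    criteria.append(None if mc is None else mc.count > 15)
    criteria.append(case.atypical_mitoses)
    if any(c is None for c in criteria):
        return None
    return sum(criteria)


# -- survival ----------------------------------------------------------------

def km_by_risk_sets(times, events):
    """Product-limit estimate by explicit risk-set bookkeeping.

    Returns (distinct observed times ascending, survival after each).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    grid = np.unique(times)
    surv = 1.0
    out = []
    for t in grid:
        at_risk = int((times >= t).sum())
        deaths = int(((times == t) & events).sum())
        if at_risk > 0:
            surv *= 1.0 - deaths / at_risk
        out.append(surv)
    return grid, np.array(out)


def logrank_by_risk_sets(times, events, groups):
    """Two-group log-rank chi-square by summation over event times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    assert len(labels) == 2
    observed = expected = variance = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & (groups == labels[0])).sum())
        d = int(((times == t) & events).sum())
        d1 = int(((times == t) & events & (groups == labels[0])).sum())
        observed += d1
        expected += d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if variance == 0:
        return 0.0
    return (observed - expected) ** 2 / variance


def cox_breslow_loglik(beta, times, events, x):
    """Breslow partial log-likelihood for a single covariate, by explicit
    risk-set sums (each tied event counted against the full risk set)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    x = np.asarray(x, dtype=float)
    ll = 0.0
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        ll += beta * x[i] - math.log(np.exp(beta * x[risk]).sum())
    return ll


def cox_grid_mle(times, events, x, lo=-8.0, hi=8.0, steps=160001):
    """1-D grid-search maximizer of the Breslow partial likelihood."""
    grid = np.linspace(lo, hi, steps)
    lls = [cox_breslow_loglik(b, times, events, x) for b in grid]
    return float(grid[int(np.argmax(lls))]), float(max(lls))


# -- AUC ---------------------------------------------------------------------

def auc_by_pair_counting(scores, outcomes) -> float:
    """AUC as the fraction of (positive, negative) pairs the score orders
    correctly, ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=bool)
    pos = scores[outcomes]
    neg = scores[~outcomes]
    wins = 0.0
    for p, q in itertools.product(pos, neg):
        if p > q:
            wins += 1.0
        elif p == q:
            wins += 0.5
    return wins / (len(pos) * len(neg))
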