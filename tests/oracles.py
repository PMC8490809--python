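"""Independent oracles: brute-force counterparts of the package estimators.

Everything here is deliberately naive — plain loops and closed forms that
do not share code with the implementation paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def brute_force_table(frame: pd.DataFrame, drug: str) -> tuple[int, int, int, int]:
    """Double-loop 2x2 count over a prepared report frame."""
    a = b = c = d = 0
    for _, row in frame.iterrows():
        exposed = drug in row["drugs"]
        event = bool(row["event"])
        if exposed and event:
            a += 1
        elif exposed:
            b += 1
        elif event:
            c += 1
        else:
            d += 1
    return a, b, c, d


def generative_ror(
    catalog: list[tuple[str, float]],
    multipliers: dict[str, float],
    base_rate: float,
    drug: str,
    interaction_pair: tuple[str, str] | None = None,
    interaction_multiplier: float = 1.0,
) -> float:
    """Exact ROR for one drug under the multiplicative report model.

    Enumerates every exposure pattern of the *other* drugs to get
    P(event | drug) and P(event | no drug); feasible for small catalogs.
    """
    others = [(g, p) for g, p in catalog if g != drug]
    odds = {}
    for target_exposed in (True, False):
        p_event = 0.0
        for bits in range(2 ** len(others)):
            prob = 1.0
            listed = {drug} if target_exposed else set()
            for j, (g, pg) in enumerate(others):
                if bits >> j & 1:
                    prob *= pg
                    listed.add(g)
                else:
                    prob *= 1.0 - pg
            rate = base_rate
            for g in listed:
                rate *= multipliers.get(g, 1.0)
            if interaction_pair and set(interaction_pair) <= listed:
                rate *= interaction_multiplier
            p_event += prob * min(rate, 0.99)
        odds[target_exposed] = p_event / (1.0 - p_event)
    return odds[True] / odds[False]


def brute_force_ssa_counts(
    first_rx: dict[str, int], first_ev: dict[str, int], window: int
) -> tuple[int, int, int]:
    """(n_pos, n_neg, n_same) by direct pairwise comparison per patient."""
    n_pos = n_neg = n_same = 0
    for pid, m_d in first_rx.items():
        if pid not in first_ev:
            continue
        delta = first_ev[pid] - m_d
        if delta == 0:
            n_same += 1
        elif 1 <= abs(delta) <= window:
            if delta > 0:
                n_pos += 1
            else:
                n_neg += 1
    return n_pos, n_neg, n_same


def efron_partial_loglik(
    beta: float, time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> float:
    """Efron-approximation partial log-likelihood, single binary covariate."""
    ll = 0.0
    risk = np.exp(beta * group.astype(float))
    for t in np.unique(time[event.astype(bool)]):
        at_risk = time >= t
        tied = event.astype(bool) & (time == t)
        d = int(tied.sum())
        sum_risk = risk[at_risk].sum()
        sum_tied = risk[tied].sum()
        ll += beta * group[tied].sum()
        for ell in range(d):
            ll -= math.log(sum_risk - (ell / d) * sum_tied)
    return ll


def grid_search_cox(
    time: np.ndarray, event: np.ndarray, group: np.ndarray, tol: float = 1e-5
) -> float:
    """Maximize the Efron partial likelihood by iterated grid refinement."""
    lo, hi = -5.0, 5.0
    for _ in range(40):
        grid = np.linspace(lo, hi, 41)
        lls = [efron_partial_loglik(b, time, event, group) for b in grid]
        best = grid[int(np.argmax(lls))]
        span = (hi - lo) / 10.0
        lo, hi = best - span, best + span
        if hi - lo < tol:
            break
    return float(best)
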