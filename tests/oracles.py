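"""Independent brute-force oracles used to validate the pipeline.

These deliberately re-derive results from first principles (exhaustive
enumeration, O(n^2) interval checks, assignment search) and share no code
with the implementation they check.
"""

from __future__ import annotations

import itertools

import numpy as np

WINDOW = 60.0  # minutes


def enumerate_boluses(records, gap_tolerance_min):
    """All maximal qualifying merged administrations by exhaustive search.

    ``records``: list of (start_min, end_min, volume_ml), sorted,
    non-overlapping.  Returns a set of (start_min, end_min, volume) for
    every contiguous sub-sequence whose internal gaps are all within the
    tolerance, that meets the bolus definition, and that is not contained
    in a longer qualifying sub-sequence.
    """
    n = len(records)
    qualifying = []
    for i in range(n):
        for j in range(i, n):
            sub = records[i : j + 1]
            gaps_ok = all(
                sub[k + 1][0] - sub[k][1] <= gap_tolerance_min for k in range(len(sub) - 1)
            )
            if not gaps_ok:
                continue
            vol = sum(r[2] for r in sub)
            dur = sub[-1][1] - sub[0][0]
            if dur <= 0 or dur > 30.0:
                continue
            if vol >= 250.0 and vol / dur * 60.0 >= 500.0:
                qualifying.append((i, j, sub[0][0], sub[-1][1], vol))
    maximal = set()
    for i, j, s, e, v in qualifying:
        contained = any(
            (i2 <= i and j <= j2 and (i2, j2) != (i, j))
            for i2, j2, *_ in qualifying
        )
        if not contained:
            maximal.add((round(s, 6), round(e, 6), round(v, 6)))
    return maximal


def isolated_boluses(boluses):
    """Indices of boluses with no other bolus within the +/-60-min window.

    ``boluses``: list of (start_min, end_min).  Pairwise gap check.
    """
    keep = []
    for i, (s_i, e_i) in enumerate(boluses):
        ok = True
        for j, (s_j, e_j) in enumerate(boluses):
            if i == j:
                continue
            gap = max(s_j - e_i, s_i - e_j, 0.0)
            if gap < WINDOW:
                ok = False
                break
        if ok:
            keep.append(i)
    return keep


def control_window_clear(start_min, dur_min, bolus_windows, infusions, max_rate):
    """Brute-force admissibility of one control start.

    ``bolus_windows``: (window_start, window_end) pairs; ``infusions``:
    (start, end, rate) triples.  The control window is
    ``[start-60, start+dur+60)``.
    """
    lo, hi = start_min - WINDOW, start_min + dur_min + WINDOW
    for ws, we in bolus_windows:
        if lo < we and hi > ws:
            return False
    for s, e, rate in infusions:
        if rate > max_rate and lo < e and hi > s:
            return False
    return True


def optimal_assignment(bolus_logits, control_logits, caliper):
    """Minimum-total-distance 1:1 assignment within the caliper.

    Exhaustive over all injective mappings (feasible for n <= 8).  Returns
    the set of (bolus_index, control_index) pairs of the assignment that
    first maximises the number of matches and then minimises total
    distance.
    """
    nb, nc = len(bolus_logits), len(control_logits)
    best = (0, 0.0, frozenset())
    k_max = min(nb, nc)
    for k in range(k_max, 0, -1):
        found = None
        for b_sub in itertools.combinations(range(nb), k):
            for c_perm in itertools.permutations(range(nc), k):
                dists = [
                    abs(bolus_logits[b] - control_logits[c])
                    for b, c in zip(b_sub, c_perm)
                ]
                if any(d > caliper for d in dists):
                    continue
                total = sum(dists)
                pairs = frozenset(zip(b_sub, c_perm))
                if found is None or total < found[0] - 1e-12:
                    found = (total, pairs)
        if found is not None:
            best = (k, found[0], found[1])
            break
    return best[2]


def pearson_chi2(table):
    """Pearson chi-squared by the textbook formula sum (O-E)^2 / E."""
    t = np.asarray(table, dtype=float)
    rows = t.sum(axis=1, keepdims=True)
    cols = t.sum(axis=0, keepdims=True)
    expected = rows * cols / t.sum()
    return float(((t - expected) ** 2 / expected).sum())


def random_infusion_records(rng, n_max=10):
    """Random sorted non-overlapping crystalloid records (minutes, ml)."""
    n = rng.integers(1, n_max + 1)
    t = 0.0
    records = []
    for _ in range(n):
        t += float(rng.choice([0.5, 1.0, 2.0, 2.5, 4.0, 10.0, 40.0]))
        dur = float(rng.choice([2.0, 5.0, 10.0, 15.0, 20.0, 28.0, 35.0]))
        rate = float(rng.choice([20.0, 100.0, 400.0, 600.0, 900.0, 1500.0]))
        records.append((t, t + dur, rate * dur / 60.0))
        t += dur
    return records
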