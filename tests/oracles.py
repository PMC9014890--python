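"""Independent brute-force reference implementations used by the tests.

Each oracle deliberately uses a different algorithmic route than the package
(direct window enumeration instead of run-length scanning, dict-based
accumulation instead of groupby) so that agreement is informative.
"""

from __future__ import annotations

import numpy as np


def wear_mask_oracle(intensities, min_run: int = 3) -> np.ndarray:
    """Wear mask by direct window enumeration over one day's epoch sequence.

    An epoch is nonwear iff some window of ``min_run`` consecutive
    zero-intensity epochs contains it.
    """
    x = np.asarray(intensities)
    n = len(x)
    wear = np.ones(n, dtype=bool)
    for i in range(n):
        for a in range(max(0, i - min_run + 1), min(i, n - min_run) + 1):
            if (x[a : a + min_run] == 0).all():
                wear[i] = False
                break
    return wear


def mvpa_minutes_oracle(
    classes, walk_bout: int = 10, run_bout: int = 1
) -> int:
    """MVPA minutes by enumerating qualifying windows over one day's minutes.

    ``classes``: sequence of 0 (idle), 1 (walk), 2 (run) for consecutive
    minutes. A run minute counts iff it lies in some window of ``run_bout``
    consecutive all-run minutes; a walk minute counts iff it lies in some
    window of ``walk_bout`` consecutive non-idle minutes.
    """
    cls = np.asarray(classes)
    n = len(cls)
    counts = np.zeros(n, dtype=bool)
    for a in range(0, n - run_bout + 1):
        if (cls[a : a + run_bout] == 2).all():
            counts[a : a + run_bout] |= cls[a : a + run_bout] == 2
    for a in range(0, n - walk_bout + 1):
        if (cls[a : a + walk_bout] != 0).all():
            window = np.zeros(n, dtype=bool)
            window[a : a + walk_bout] = True
            counts |= window & (cls == 1)
    return int(counts.sum())


def weighted_weekly_oracle(values, is_weekend) -> float:
    """Direct arithmetic recomputation of the 5/2-weighted weekly value."""
    values = np.asarray(values, dtype=float)
    is_weekend = np.asarray(is_weekend, dtype=bool)
    weekday = values[~is_weekend]
    weekend = values[is_weekend]
    if len(weekday) > 0 and len(weekend) > 0:
        return (weekday.mean() * 5 + weekend.mean() * 2) / 7
    return values.mean()


def chi_square_oracle(table) -> float:
    """Textbook Pearson statistic sum((O-E)^2 / E)."""
    obs = np.asarray(table, dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    return float(((obs - expected) ** 2 / expected).sum())


def epoch_totals_oracle(timestamps, steps, intensities) -> dict:
    """Dict of 15-min cell -> (step sum, max intensity, n minutes), by direct
    accumulation minute by minute."""
    out = {}
    for ts, s, m in zip(timestamps, steps, intensities):
        cell = ts.replace(minute=(ts.minute // 15) * 15, second=0, microsecond=0)
        tot, mx, n = out.get(cell, (0, 0, 0))
        out[cell] = (tot + int(s), max(mx, int(m)), n + 1)
    return out
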