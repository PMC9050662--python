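"""Small numeric helpers shared across modules."""

from __future__ import annotations

import numpy as np


def round_half_away(x):
    """Nearest-integer rounding, halves away from zero.

    ``np.round`` rounds halves to even; copy-number assignment uses the
    conventional half-away rule so CN = round(R/X) is reproducible.
    """
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def weighted_median(values, weights):
    """Weighted median with an even-split tie rule.

    If the cumulative weight hits exactly half the total at a value
    boundary, the mean of the two straddling values is returned.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("weighted_median of empty input")
    if np.any(weights < 0):
        raise ValueError("negative weights")
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    total = cum[-1]
    if total <= 0:
        raise ValueError("all weights zero")
    half = total / 2.0
    idx = int(np.searchsorted(cum, half, side="left"))
    if np.isclose(cum[idx], half) and idx + 1 < v.size:
        return 0.5 * (v[idx] + v[idx + 1])
    return float(v[idx])


def pava_isotonic(y, w=None):
    """Pool-adjacent-violators: weighted least-squares isotonic fit.

    Returns the non-decreasing sequence closest to ``y`` in the
    ``w``-weighted L2 sense. Plain python loop; inputs here are short
    (pseudo-time windows), so this is never a bottleneck.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if w is None:
        w = np.ones(n)
    else:
        w = np.asarray(w, dtype=float)
    # blocks as (value, weight, count) stacks
    vals = []
    wts = []
    cnts = []
    for i in range(n):
        vals.append(y[i])
        wts.append(w[i])
        cnts.append(1)
        while len(vals) > 1 and vals[-2] >= vals[-1]:
            v2, w2, c2 = vals.pop(), wts.pop(), cnts.pop()
            v1, w1, c1 = vals.pop(), wts.pop(), cnts.pop()
            wt = w1 + w2
            vals.append((v1 * w1 + v2 * w2) / wt if wt > 0 else 0.5 * (v1 + v2))
            wts.append(wt)
            cnts.append(c1 + c2)
    out = np.empty(n)
    pos = 0
    for v, c in zip(vals, cnts):
        out[pos:pos + c] = v
        pos += c
    return out


def check_seed(seed):
    """Normalize a user seed into a ``numpy.random.Generator``."""
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("an explicit seed is required for reproducibility")
    return np.random.default_rng(int(seed))
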