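"""Naive loop-based transcriptions of the degree formulas.

Deliberately unvectorized and independent of the production code: plain
Python lists and explicit index loops, used only to cross-check the
implementations on small random panels.
"""

from __future__ import annotations


def _mean_img(values: list[float]) -> list[float]:
    mu = sum(values) / len(values)
    return [v / mu for v in values]


def oracle_deng(
    reference: list[float], comparators: list[list[float]], epsilon: float
) -> list[float]:
    """Deng's degrees via explicit loops over comparators and points."""
    r = _mean_img(reference)
    imgs = [_mean_img(c) for c in comparators]
    deltas = []
    for img in imgs:
        row = []
        for k in range(len(r)):
            row.append(abs(r[k] - img[k]))
        deltas.append(row)
    d_min = min(min(row) for row in deltas)
    d_max = max(max(row) for row in deltas)
    degrees = []
    for row in deltas:
        if d_max == 0:
            gammas = [1.0 for _ in row]
        else:
            gammas = [(d_min + epsilon * d_max) / (d + epsilon * d_max) for d in row]
        degrees.append(sum(gammas) / len(gammas))
    return degrees


def _s_stat(values: list[float]) -> float:
    zeroed = [v - values[0] for v in values]
    total = 0.0
    for k in range(1, len(zeroed) - 1):
        total += zeroed[k]
    return total + 0.5 * zeroed[-1]


def oracle_absolute(x0: list[float], xi: list[float]) -> float:
    s0 = _s_stat(x0)
    si = _s_stat(xi)
    return (1 + abs(s0) + abs(si)) / (1 + abs(s0) + abs(si) + abs(s0 - si))


def oracle_relative(x0: list[float], xi: list[float]) -> float:
    n0 = [v / x0[0] for v in x0]
    ni = [v / xi[0] for v in xi]
    return oracle_absolute(n0, ni)
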