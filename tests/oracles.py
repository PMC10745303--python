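"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by the most literal route available
(explicit sums, full enumeration, quadrature) and stay independent of the
implementation paths they check.
"""
from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.stats import rankdata


def icc_oracle(x: np.ndarray) -> dict:
    """One-/two-way ICC point estimates from an explicit ANOVA decomposition.

    Written with bare loops over the literal sum-of-squares definitions so it
    shares no code path with the package implementation.
    """
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    row_mean = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    col_mean = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_mean)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_mean)
    ss_within = sum((x[i, j] - row_mean[i]) ** 2 for i in range(n) for j in range(k))
    ss_err = sum(
        (x[i, j] - row_mean[i] - col_mean[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    bms = ss_rows / (n - 1)
    wms = ss_within / (n * (k - 1))
    jms = ss_cols / (k - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    return {
        "icc11": (bms - wms) / (bms + (k - 1) * wms),
        "icc2k": (bms - ems) / (bms + (jms - ems) / n),
    }


def wilcoxon_enum_p(differences: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Wilcoxon signed-rank p by enumerating all 2^n signs.

    Zero differences are dropped; tied magnitudes get mid-ranks.  Returns
    (W_plus, p) with p = min(1, 2·min(P(W <= w), P(W >= w))).
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    assert 1 <= n <= 16, "enumeration oracle meant for small n"
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(bool)
    w_all = np.where(signs, ranks, 0.0).sum(axis=1)
    p_low = np.mean(w_all <= w_obs + 1e-12)
    p_high = np.mean(w_all >= w_obs - 1e-12)
    return float(w_obs), float(min(1.0, 2 * min(p_low, p_high)))


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Rank both vectors with mid-ranks, then plain Pearson correlation."""
    rx = rankdata(x)
    ry = rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    return float((rxc * ryc).sum() / np.sqrt((rxc**2).sum() * (ryc**2).sum()))


def drawing_arc_length(
    line_length: float, duration: float, half_amplitude: float, frequency: float
) -> float:
    """Closed-form arc length of the noiseless tremulous line by quadrature.

    The generating curve is x(t) = L·t/T, y(t) = A·sin(2π f t); its arc
    length is the integral of sqrt(x'(t)^2 + y'(t)^2).
    """
    vx = line_length / duration

    def speed(t: float) -> float:
        vy = half_amplitude * 2 * np.pi * frequency * np.cos(2 * np.pi * frequency * t)
        return np.hypot(vx, vy)

    total = 0.0
    # integrate cycle by cycle: the integrand oscillates too fast for one call
    edges = np.linspace(0.0, duration, int(np.ceil(frequency * duration)) * 2 + 1)
    for a, b in zip(edges[:-1], edges[1:]):
        total += quad(speed, a, b, limit=200)[0]
    return total


def per_cycle_geomean_oracle(
    half_amplitudes: np.ndarray,
) -> float:
    """Geometric mean of per-cycle peak-to-peak values from known half-amplitudes."""
    p2p = 2 * np.asarray(half_amplitudes, dtype=float)
    return float(np.exp(np.mean(np.log(p2p))))
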