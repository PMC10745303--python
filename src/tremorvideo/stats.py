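"""Reliability and clinical-association statistics, from first principles.

Implements intraclass correlation coefficients with Shrout–Fleiss
F-distribution confidence intervals, the minimal-detectable-change family
(SDd, MDC95 = 1.96·SDd, MDC%), Spearman rank correlation (mid-ranks),
the Wilcoxon signed-rank test with an exact tie-aware null distribution,
and the Weber–Fechner (log-linear) fit of tremor amplitude on clinical
rating.

Two ICC forms are provided, matching a test–retest design (one-way
random-effects single measure, ICC(1,1)) and a three-rater design (two-way
random-effects average measure, ICC(2,k)).  Negative ICC estimates are
reported as computed and fall in the "very poor" category; they are not
truncated at zero.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MeasurementMatrix",
    "ReliabilityResult",
    "WeberFechnerFit",
    "icc_one_way_single",
    "icc_two_way_average",
    "categorize_icc",
    "mdc95",
    "mdc_percent",
    "spearman_rho",
    "wilcoxon_signed_rank",
    "fit_weber_fechner",
    "holm_adjust",
]

#: ICC reliability categories: lower bound (inclusive) -> label.
ICC_CATEGORIES = (
    (0.90, "excellent"),
    (0.70, "good"),
    (0.50, "moderate"),
    (0.30, "poor"),
    (-np.inf, "very poor"),
)


def categorize_icc(icc: float) -> str:
    """Reliability category for an ICC value (>=0.90 excellent, ... <0.30 very poor)."""
    for lower, label in ICC_CATEGORIES:
        if icc >= lower:
            return label
    return "very poor"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass
class MeasurementMatrix:
    """Subjects × raters-or-occasions matrix of one videographic parameter."""

    values: np.ndarray
    log10_transformed: bool = False
    parameter: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("measurement matrix must be 2-D (subjects × columns)")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 columns")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))
            raise ValueError(f"missing/non-finite cells at (subject, column) {bad.tolist()}")

    @classmethod
    def from_wide(cls, df: pd.DataFrame, **kwargs) -> "MeasurementMatrix":
        return cls(df.to_numpy(dtype=float), **kwargs)

    @classmethod
    def from_tidy(
        cls,
        df: pd.DataFrame,
        subject_col: str = "subject",
        column_col: str = "occasion",
        value_col: str = "value",
        **kwargs,
    ) -> "MeasurementMatrix":
        wide = df.pivot(index=subject_col, columns=column_col, values=value_col)
        if wide.isna().any().any():
            missing = [
                (str(i), str(c))
                for i, c in zip(*np.nonzero(wide.isna().to_numpy()))
            ]
            raise ValueError(f"unbalanced design, missing cells: {missing}")
        return cls(wide.to_numpy(dtype=float), **kwargs)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


@dataclass
class ReliabilityResult:
    """ICC with its 95% CI, plus the minimal-detectable-change quantities.

    ``sdd``/``mdc95``/``mdc_percent`` are populated for two-column
    (test–retest) matrices; ``mdc_percent`` additionally requires the matrix
    to be on the log10 scale (or a rating scale with a known Weber–Fechner
    slope, see :func:`mdc_percent`).
    """

    icc: float
    icc_ci_low: float
    icc_ci_high: float
    icc_type: str
    n_subjects: int
    n_columns: int
    category: str
    sdd: float | None = None
    mdc95: float | None = None
    mdc_percent: float | None = None
    parameter: str = ""

    def summary(self) -> str:
        lines = [
            f"{self.icc_type} reliability{f' — {self.parameter}' if self.parameter else ''}",
            f"  subjects: {self.n_subjects}, columns: {self.n_columns}",
            f"  ICC = {self.icc:.3f} (95% CI {self.icc_ci_low:.3f}–{self.icc_ci_high:.3f})"
            f"  [{self.category}]",
        ]
        if self.sdd is not None:
            lines.append(f"  SDd = {self.sdd:.4g}, MDC95 = {self.mdc95:.4g}")
        if self.mdc_percent is not None:
            lines.append(f"  MDC% = {self.mdc_percent:.0f}%")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# ANOVA mean squares and ICCs
# ---------------------------------------------------------------------------
def _mean_squares(x: np.ndarray) -> dict:
    """Two-way ANOVA mean squares of a subjects × columns matrix."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_within = ((x - row_means[:, None]) ** 2).sum()
    ss_error = ss_total - ss_rows - ss_cols
    return {
        "n": n,
        "k": k,
        "bms": ss_rows / (n - 1),                 # between subjects
        "wms": ss_within / (n * (k - 1)),          # within subjects (one-way)
        "jms": ss_cols / (k - 1),                  # between columns (raters)
        "ems": ss_error / ((n - 1) * (k - 1)),     # residual (two-way)
        "ss_total": ss_total,
    }


def _mdc_fields(m: MeasurementMatrix) -> dict:
    """SDd/MDC quantities for a two-column (test–retest) matrix."""
    if m.n_columns != 2:
        return {}
    diffs = m.values[:, 1] - m.values[:, 0]
    sdd = float(np.std(diffs, ddof=1))
    out = {"sdd": sdd, "mdc95": mdc95_from_sdd(sdd)}
    if m.log10_transformed:
        out["mdc_percent"] = mdc_percent(sdd, scale="log10")
    return out


def icc_one_way_single(m: MeasurementMatrix, confidence: float = 0.95) -> ReliabilityResult:
    """One-way random-effects single-measure ICC — ICC(1,1).

    ``ICC = (BMS - WMS) / (BMS + (k-1)·WMS)`` from the one-way ANOVA mean
    squares; the CI follows the Shrout–Fleiss F-interval construction.
    Suited to test–retest designs where occasions are not crossed factors.
    """
    ms = _mean_squares(m.values)
    n, k = ms["n"], ms["k"]
    if ms["ss_total"] == 0:
        raise ValueError("ICC undefined: the matrix has zero total variance")
    denom = ms["bms"] + (k - 1) * ms["wms"]
    if denom == 0:
        raise ValueError("ICC undefined: degenerate variance structure")
    icc = (ms["bms"] - ms["wms"]) / denom
    alpha = 1 - confidence
    if ms["wms"] == 0:
        lo, hi = 1.0, 1.0
    else:
        f_obs = ms["bms"] / ms["wms"]
        f_lo = f_obs / sps.f.ppf(1 - alpha / 2, n - 1, n * (k - 1))
        f_hi = f_obs * sps.f.ppf(1 - alpha / 2, n * (k - 1), n - 1)
        lo = (f_lo - 1) / (f_lo + k - 1)
        hi = (f_hi - 1) / (f_hi + k - 1)
    return ReliabilityResult(
        icc=float(icc),
        icc_ci_low=float(lo),
        icc_ci_high=float(hi),
        icc_type="ICC(1,1)",
        n_subjects=n,
        n_columns=k,
        category=categorize_icc(icc),
        parameter=m.parameter,
        **_mdc_fields(m),
    )


def icc_two_way_average(m: MeasurementMatrix, confidence: float = 0.95) -> ReliabilityResult:
    """Two-way random-effects average-measure ICC — ICC(2,k).

    ``ICC = (BMS - EMS) / (BMS + (JMS - EMS)/n)``.  The CI is obtained from
    the Shrout–Fleiss interval for the single-measure ICC(2,1) (with a
    Satterthwaite-approximated denominator df) and stepped up to k measures
    by the Spearman–Brown formula.  Suited to inter-rater designs where each
    rater scores every subject.
    """
    ms = _mean_squares(m.values)
    n, k = ms["n"], ms["k"]
    if ms["ss_total"] == 0:
        raise ValueError("ICC undefined: the matrix has zero total variance")
    denom = ms["bms"] + (ms["jms"] - ms["ems"]) / n
    if denom == 0:
        raise ValueError("ICC undefined: degenerate variance structure")
    icc_k = (ms["bms"] - ms["ems"]) / denom
    # single-measure form, needed for the CI construction
    denom1 = ms["bms"] + (k - 1) * ms["ems"] + k * (ms["jms"] - ms["ems"]) / n
    icc_1 = (ms["bms"] - ms["ems"]) / denom1 if denom1 != 0 else 1.0
    alpha = 1 - confidence
    if ms["ems"] == 0 and ms["jms"] == 0:
        lo_k, hi_k = 1.0, 1.0
    elif icc_1 >= 1.0:
        lo_k, hi_k = 1.0, 1.0
    else:
        a = k * icc_1 / (n * (1 - icc_1))
        b = 1 + k * icc_1 * (n - 1) / (n * (1 - icc_1))
        num = (a * ms["jms"] + b * ms["ems"]) ** 2
        den = (a * ms["jms"]) ** 2 / (k - 1) + (b * ms["ems"]) ** 2 / ((n - 1) * (k - 1))
        v = num / den
        f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo_1 = n * (ms["bms"] - f1 * ms["ems"]) / (
            f1 * (k * ms["jms"] + (k * n - k - n) * ms["ems"]) + n * ms["bms"]
        )
        hi_1 = n * (f2 * ms["bms"] - ms["ems"]) / (
            k * ms["jms"] + (k * n - k - n) * ms["ems"] + n * f2 * ms["bms"]
        )
        lo_k = lo_1 * k / (1 + (k - 1) * lo_1)
        hi_k = hi_1 * k / (1 + (k - 1) * hi_1)
    return ReliabilityResult(
        icc=float(icc_k),
        icc_ci_low=float(lo_k),
        icc_ci_high=float(hi_k),
        icc_type=f"ICC(2,{k})",
        n_subjects=n,
        n_columns=k,
        category=categorize_icc(icc_k),
        parameter=m.parameter,
        **_mdc_fields(m),
    )


# ---------------------------------------------------------------------------
# minimal detectable change
# ---------------------------------------------------------------------------
def mdc95_from_sdd(sdd: float) -> float:
    """MDC95 = 1.96 × SDd (SDd: standard deviation of test–retest differences)."""
    if sdd < 0:
        raise ValueError("sdd must be >= 0")
    return 1.96 * sdd


def mdc95(differences) -> float:
    """MDC95 from raw paired test–retest differences (needs >= 2 pairs)."""
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("mdc95 needs at least 2 paired differences")
    return mdc95_from_sdd(float(np.std(d, ddof=1)))


def mdc_percent(sdd: float, scale: str = "log10", slope_b: float | None = None) -> float:
    """Minimal detectable change as a percentage of baseline tremor amplitude.

    For a log10-transformed amplitude measure::

        MDC% = 100 · (1 − 10^(−1.96·SDd))

    i.e. the percent amplitude *reduction* that just exceeds measurement
    noise.  For a clinical rating scale the rating change is first converted
    to log10-amplitude via the Weber–Fechner slope ``b`` (log10-mm per rating
    point)::

        MDC% = 100 · (1 − 10^(−b·1.96·SDd))

    Strictly increasing in SDd and bounded in [0, 100).
    """
    if sdd < 0:
        raise ValueError("sdd must be >= 0")
    if scale == "log10":
        exponent = mdc95_from_sdd(sdd)
    elif scale == "rating":
        if slope_b is None or not slope_b > 0:
            raise ValueError("scale='rating' requires a positive Weber–Fechner slope_b")
        exponent = slope_b * mdc95_from_sdd(sdd)
    else:
        raise ValueError("scale must be 'log10' or 'rating'")
    return 100.0 * (1.0 - 10.0 ** (-exponent))


# ---------------------------------------------------------------------------
# rank statistics
# ---------------------------------------------------------------------------
def spearman_rho(x, y, exact: bool = False) -> tuple[float, float]:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties receive average ranks.  The p-value uses the t-approximation with
    n−2 degrees of freedom; ``exact=True`` enumerates all permutations of one
    argument (only sensible for n ≤ 9) and returns the two-sided permutation
    p-value of |rho|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("spearman_rho needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if exact:
        if n > 9:
            raise ValueError("exact permutation p only supported for n <= 9")
        perms = np.array(list(permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        denom = np.sqrt((rxc**2).sum() * (pc**2).sum(axis=1))
        rhos = pc @ rxc / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return rho, p
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    p = 2 * sps.t.sf(abs(t), n - 2)
    return rho, float(min(p, 1.0))


def _wilcoxon_exact_p(ranks2: np.ndarray, w2: int) -> float:
    """Exact two-sided p for W+ given doubled mid-ranks (tie-aware DP).

    Enumerates the 2^n sign-assignment null via the generating polynomial
    ∏(1 + z^{2r_i}); doubling the mid-ranks keeps exponents integral when
    ties produce .5 ranks.
    """
    total = int(ranks2.sum())
    dp = np.zeros(total + 1)
    dp[0] = 1.0
    for r in ranks2:
        r = int(r)
        dp[r:] += dp[: total + 1 - r]
    dp /= dp.sum()
    cdf = float(dp[: w2 + 1].sum())
    sf = float(dp[w2:].sum())
    return min(1.0, 2 * min(cdf, sf))


def wilcoxon_signed_rank(
    pre, post, exact_threshold: int = 25
) -> tuple[float, float]:
    """Wilcoxon signed-rank test for paired pre/post measurements.

    Differences ``post - pre`` equal to zero are dropped (the classical
    convention); tied absolute differences receive mid-ranks.  For up to
    ``exact_threshold`` non-zero differences the two-sided p-value is exact
    (full enumeration of the sign-flip null, tie-aware); beyond that a normal
    approximation with tie and continuity corrections is used.

    Returns ``(W_plus, p)`` where ``W_plus`` is the positive-rank sum.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size != post.size:
        raise ValueError("pre and post must have equal length")
    d = post - pre
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero; test undefined")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_threshold:
        ranks2 = np.rint(2 * ranks).astype(int)
        w2 = int(round(2 * w_plus))
        return w_plus, _wilcoxon_exact_p(ranks2, w2)
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    sigma = math.sqrt(sigma2)
    # continuity correction toward the mean
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / sigma
    return w_plus, float(min(1.0, 2 * sps.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# Weber–Fechner fit
# ---------------------------------------------------------------------------
@dataclass
class WeberFechnerFit:
    """Least-squares fit of ``log10(amplitude) = a + b·rating``.

    ``slope_b`` converts one rating point into log10-mm of tremor amplitude;
    its reciprocal is the number of rating points per decade of amplitude.
    """

    intercept_a: float
    slope_b: float
    r_squared: float
    slope_se: float
    n: int

    @property
    def slope_ci95(self) -> tuple[float, float]:
        tcrit = sps.t.ppf(0.975, self.n - 2)
        return (self.slope_b - tcrit * self.slope_se, self.slope_b + tcrit * self.slope_se)

    def predict_log10_amplitude(self, rating) -> np.ndarray:
        return self.intercept_a + self.slope_b * np.asarray(rating, dtype=float)

    def predict_amplitude_mm(self, rating) -> np.ndarray:
        return 10.0 ** self.predict_log10_amplitude(rating)

    def summary(self) -> str:
        lo, hi = self.slope_ci95
        return (
            "Weber–Fechner fit: log10(amplitude_mm) = "
            f"{self.intercept_a:.3f} + {self.slope_b:.3f}·rating\n"
            f"  slope 95% CI [{lo:.3f}, {hi:.3f}], R² = {self.r_squared:.3f}, n = {self.n}"
        )

    def plot(self, ratings=None, amplitudes=None, ax=None):
        """Plot amplitude (log scale) against rating with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if ratings is not None and amplitudes is not None:
            ax.semilogy(ratings, amplitudes, "o", alpha=0.6, label="patients")
        grid = np.linspace(0, 4, 50)
        ax.semilogy(grid, self.predict_amplitude_mm(grid), "-", label="fit")
        ax.set_xlabel("clinical rating")
        ax.set_ylabel("tremor amplitude [mm]")
        ax.legend()
        return ax


def fit_weber_fechner(ratings, amplitudes_mm) -> WeberFechnerFit:
    """Fit the log-linear rating↔amplitude relation by least squares.

    Regresses ``log10(amplitude)`` on the integer clinical rating; requires
    positive amplitudes and at least 3 distinct rating values.
    """
    ratings = np.asarray(ratings, dtype=float)
    amps = np.asarray(amplitudes_mm, dtype=float)
    if ratings.size != amps.size:
        raise ValueError("ratings and amplitudes must have equal length")
    if np.any(amps <= 0):
        raise ValueError("amplitudes must be positive for the log transform")
    if np.unique(ratings).size < 3:
        raise ValueError("fit requires at least 3 distinct rating values")
    res = sps.linregress(ratings, np.log10(amps))
    return WeberFechnerFit(
        intercept_a=float(res.intercept),
        slope_b=float(res.slope),
        r_squared=float(res.rvalue**2),
        slope_se=float(res.stderr),
        n=int(ratings.size),
    )


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment (optional; raw p-values are reported by default)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
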