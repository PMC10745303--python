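"""End-to-end study orchestration: from per-patient metrics and ratings to a
structured report.

The report mirrors the layout of a treatment study: a reliability section
(ICC + CI + SDd/MDC95/MDC% per parameter), a correlation section (Spearman
rho of each log10 parameter against each clinical score), a pre/post section
(medians with min–max for scores, means with SD for videographic parameters,
Wilcoxon signed-rank p) and a change-correlation section (rho of the log10
treatment ratio against the rating change R2 − R1).

Every cell of the report is traceable: each section records the operation
calls that produced it in the report's run log.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .stats import (
    MeasurementMatrix,
    icc_one_way_single,
    icc_two_way_average,
    spearman_rho,
    wilcoxon_signed_rank,
)

__all__ = [
    "StudyReport",
    "run_reliability_study",
    "run_correlation_study",
    "run_prepost_study",
    "build_report",
    "significance_stars",
]


def significance_stars(p: float, levels=(0.05, 0.01)) -> str:
    """Two-level star convention: p < levels[0] -> '*', p < levels[1] -> '**'."""
    if np.isnan(p):
        return ""
    if p < levels[1]:
        return "**"
    if p < levels[0]:
        return "*"
    return ""


@dataclass
class StudyReport:
    """Container for the four study sections plus an operation-level run log."""

    reliability: pd.DataFrame | None = None
    correlation: pd.DataFrame | None = None
    prepost: pd.DataFrame | None = None
    change_correlation: pd.DataFrame | None = None
    run_log: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {"format": "tremorvideo-report v1", "sections": {}, "run_log": self.run_log}
        for name in ("reliability", "correlation", "prepost", "change_correlation"):
            df = getattr(self, name)
            if df is not None:
                payload["sections"][name] = json.loads(df.to_json(orient="records"))
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def write_csv_tables(self, directory) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        for name in ("reliability", "correlation", "prepost", "change_correlation"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(os.path.join(directory, f"{name}.csv"), index=False)

    def summary(self) -> str:
        parts = []
        for name in ("reliability", "correlation", "prepost", "change_correlation"):
            df = getattr(self, name)
            if df is not None:
                parts.append(f"== {name} ==")
                parts.append(df.to_string(index=False))
        return "\n".join(parts)


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------
def run_reliability_study(
    matrices: dict[str, np.ndarray | pd.DataFrame],
    design: str = "test_retest",
    log10_parameters: tuple[str, ...] = (),
    config: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, list]:
    """Per-parameter reliability table.

    Parameters
    ----------
    matrices : dict
        Maps parameter name -> subjects × occasions (or raters) matrix.
        All matrices must be complete (balanced design).
    design : {"test_retest", "inter_rater"}
        ``test_retest`` uses one-way single-measure ICC(1,1) plus
        SDd/MDC95; ``inter_rater`` uses two-way average-measure ICC(2,k).
    log10_parameters : tuple of str
        Parameters whose matrix is on the log10 scale; those get an MDC%
        (test–retest only).

    Returns the table and the run log entries that produced it.
    """
    if design not in ("test_retest", "inter_rater"):
        raise ValueError("design must be 'test_retest' or 'inter_rater'")
    rows = []
    log = []
    for name, values in matrices.items():
        if isinstance(values, pd.DataFrame):
            values = values.to_numpy(dtype=float)
        m = MeasurementMatrix(
            values, log10_transformed=name in log10_parameters, parameter=name
        )
        if design == "test_retest":
            res = icc_one_way_single(m)
            op = "icc_one_way_single"
        else:
            res = icc_two_way_average(m)
            op = "icc_two_way_average"
        rows.append(
            {
                "parameter": name,
                "icc_type": res.icc_type,
                "icc": res.icc,
                "icc_ci_low": res.icc_ci_low,
                "icc_ci_high": res.icc_ci_high,
                "category": res.category,
                "sdd": res.sdd,
                "mdc95": res.mdc95,
                "mdc_percent": res.mdc_percent,
                "n_subjects": res.n_subjects,
                "n_columns": res.n_columns,
            }
        )
        log.append(
            {
                "operation": op,
                "parameter": name,
                "shape": list(m.values.shape),
                "log10": bool(m.log10_transformed),
            }
        )
    return pd.DataFrame(rows), log


# ---------------------------------------------------------------------------
# correlation (severity vs videographic parameters)
# ---------------------------------------------------------------------------
def run_correlation_study(
    cohort: pd.DataFrame,
    parameter_cols: tuple[str, ...] = ("amplitude_pre_mm",),
    score_cols: tuple[str, ...] = ("rating_pre",),
    log10: bool = True,
    config: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, list]:
    """Spearman rho of each (log10) parameter against each clinical score.

    Constant columns yield an 'undefined' row with NaN rho rather than an
    exception; each defined pair carries the two-level significance stars.
    Requires at least 3 complete rows per pair.
    """
    config = config or AnalysisConfig()
    rows = []
    log = []
    for param in parameter_cols:
        for score in score_cols:
            sub = cohort[[param, score]].dropna()
            if len(sub) < 3:
                raise ValueError(f"pair ({param}, {score}) has fewer than 3 complete rows")
            x = sub[param].to_numpy(dtype=float)
            if log10:
                if np.any(x <= 0):
                    raise ValueError(f"{param} must be positive for the log10 transform")
                x = np.log10(x)
            y = sub[score].to_numpy(dtype=float)
            try:
                rho, p = spearman_rho(x, y)
            except ValueError:
                rho, p = float("nan"), float("nan")
            rows.append(
                {
                    "parameter": f"log10({param})" if log10 else param,
                    "score": score,
                    "rho": rho,
                    "p": p,
                    "stars": significance_stars(p, config.significance_levels),
                    "n": len(sub),
                    "defined": not np.isnan(rho),
                }
            )
            log.append(
                {"operation": "spearman_rho", "parameter": param, "score": score, "n": len(sub)}
            )
    return pd.DataFrame(rows), log


# ---------------------------------------------------------------------------
# pre/post treatment
# ---------------------------------------------------------------------------
def run_prepost_study(
    cohort: pd.DataFrame,
    parameter_pairs: dict[str, tuple[str, str]] | None = None,
    score_pairs: dict[str, tuple[str, str]] | None = None,
    config: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Pre/post comparison plus change correlations.

    ``parameter_pairs`` maps a videographic parameter name to its
    (pre_column, post_column); ``score_pairs`` likewise for clinical scores.
    The summary table reports both median (min–max) and mean (SD) for every
    variable — scores are conventionally summarised by the former,
    videographic parameters by the latter — with the Wilcoxon signed-rank p.
    The change table correlates ``log10(T2/T1)`` of each parameter with
    ``R2 − R1`` of each score.
    """
    config = config or AnalysisConfig()
    parameter_pairs = parameter_pairs or {
        "amplitude": ("amplitude_pre_mm", "amplitude_post_mm")
    }
    score_pairs = score_pairs or {"rating": ("rating_pre", "rating_post")}
    log = []

    def _summary_row(name, pre, post, kind):
        stat, p = wilcoxon_signed_rank(pre, post)
        log.append({"operation": "wilcoxon_signed_rank", "variable": name, "n": len(pre)})
        return {
            "variable": name,
            "kind": kind,
            "pre_median": float(np.median(pre)),
            "pre_min": float(np.min(pre)),
            "pre_max": float(np.max(pre)),
            "pre_mean": float(np.mean(pre)),
            "pre_sd": float(np.std(pre, ddof=1)),
            "post_median": float(np.median(post)),
            "post_min": float(np.min(post)),
            "post_max": float(np.max(post)),
            "post_mean": float(np.mean(post)),
            "post_sd": float(np.std(post, ddof=1)),
            "wilcoxon_w": stat,
            "p": p,
            "stars": significance_stars(p, config.significance_levels),
        }

    summary_rows = []
    for name, (pre_col, post_col) in score_pairs.items():
        sub = cohort[[pre_col, post_col]].dropna()
        if len(sub) < len(cohort):
            missing = cohort.index.difference(sub.index).tolist()
            raise ValueError(f"unpaired rows for {name}: {missing}")
        summary_rows.append(
            _summary_row(name, sub[pre_col].to_numpy(), sub[post_col].to_numpy(), "score")
        )
    for name, (pre_col, post_col) in parameter_pairs.items():
        sub = cohort[[pre_col, post_col]].dropna()
        if len(sub) < len(cohort):
            missing = cohort.index.difference(sub.index).tolist()
            raise ValueError(f"unpaired rows for {name}: {missing}")
        summary_rows.append(
            _summary_row(name, sub[pre_col].to_numpy(), sub[post_col].to_numpy(), "parameter")
        )

    change_rows = []
    for pname, (ppre, ppost) in parameter_pairs.items():
        t1 = cohort[ppre].to_numpy(dtype=float)
        t2 = cohort[ppost].to_numpy(dtype=float)
        if np.any(t1 <= 0) or np.any(t2 <= 0):
            raise ValueError(f"{pname}: log10 change requires positive pre/post values")
        log_ratio = np.log10(t2 / t1)
        for sname, (spre, spost) in score_pairs.items():
            delta = cohort[spost].to_numpy(dtype=float) - cohort[spre].to_numpy(dtype=float)
            try:
                rho, p = spearman_rho(log_ratio, delta)
            except ValueError:
                rho, p = float("nan"), float("nan")
            change_rows.append(
                {
                    "parameter": f"logT2/T1({pname})",
                    "score_change": f"{sname} (R2-R1)",
                    "rho": rho,
                    "p": p,
                    "stars": significance_stars(p, config.significance_levels),
                    "n": len(cohort),
                }
            )
            log.append(
                {
                    "operation": "spearman_rho",
                    "parameter": f"logT2/T1({pname})",
                    "score": f"{sname} delta",
                    "n": len(cohort),
                }
            )
    return pd.DataFrame(summary_rows), pd.DataFrame(change_rows), log


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------
def build_report(
    cohort: pd.DataFrame,
    reliability_matrices: dict[str, np.ndarray] | None = None,
    reliability_design: str = "test_retest",
    log10_parameters: tuple[str, ...] = (),
    parameter_cols: tuple[str, ...] = ("amplitude_pre_mm",),
    score_cols: tuple[str, ...] = ("rating_pre",),
    parameter_pairs: dict[str, tuple[str, str]] | None = None,
    score_pairs: dict[str, tuple[str, str]] | None = None,
    config: AnalysisConfig | None = None,
) -> StudyReport:
    """Assemble the full study report from a cohort table (and optionally
    reliability matrices).  Deterministic: identical inputs produce
    byte-identical JSON."""
    config = config or AnalysisConfig()
    report = StudyReport()
    if reliability_matrices:
        report.reliability, log = run_reliability_study(
            reliability_matrices, reliability_design, log10_parameters, config
        )
        report.run_log.extend(log)
    report.correlation, log = run_correlation_study(
        cohort, parameter_cols, score_cols, config=config
    )
    report.run_log.extend(log)
    report.prepost, report.change_correlation, log = run_prepost_study(
        cohort, parameter_pairs, score_pairs, config
    )
    report.run_log.extend(log)
    return report
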