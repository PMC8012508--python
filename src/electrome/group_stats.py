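"""Inferential statistics for before/after and between-treatment contrasts.

Paired contrasts (the same plants before and after a stimulus) use a
paired t-test when the paired differences pass a Shapiro–Wilk normality
check at α = 0.05, otherwise the Wilcoxon signed-rank test.  Independent
contrasts (different treatments) use Student's t when both groups pass
the check, otherwise the Mann–Whitney U test.  All tests are two-sided
and reported per parameter without multiple-testing correction (a Holm
adjustment is available but off by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .complexity import apen, pdf_tail_fit
from .descriptive import acf, correlation_time, dispersion
from .io import Recording
from .spectral import fit_psd_exponent, psd

__all__ = [
    "ComparisonResult",
    "paired_compare",
    "independent_compare",
    "recording_parameters",
    "parameter_table",
    "holm_adjust",
    "significance_stars",
]


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one normality-gated two-group comparison."""

    parameter: str
    test: str  # paired_t | wilcoxon_signed_rank | students_t | mann_whitney_u | degenerate
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    normality_p: tuple[float, ...]
    alpha: float = 0.05
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_value <= self.alpha


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 0.0  # constant data: clearly non-normal, route to the rank test
    return float(sstats.shapiro(x).pvalue)


def paired_compare(
    before: Sequence[float],
    after: Sequence[float],
    alpha: float = 0.05,
    parameter: str = "",
) -> ComparisonResult:
    """Paired before/after comparison with a normality-gated test choice.

    Shapiro–Wilk on the paired differences decides between the paired
    t-test and the Wilcoxon signed-rank test.  All-zero differences are
    reported as a degenerate no-effect result (p = 1).
    """
    a = np.asarray(before, dtype=np.float64)
    b = np.asarray(after, dtype=np.float64)
    if a.size != b.size:
        raise ValueError("paired comparison needs equal-length groups")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    d = b - a
    if np.all(d == 0):
        return ComparisonResult(
            parameter=parameter, test="degenerate", statistic=0.0, p_value=1.0,
            n_a=a.size, n_b=b.size, normality_p=(float("nan"),), alpha=alpha,
            degenerate=True,
        )
    norm_p = _shapiro_p(d)
    if norm_p >= 0.05:
        res = sstats.ttest_rel(b, a)
        test = "paired_t"
    else:
        res = sstats.wilcoxon(b, a)
        test = "wilcoxon_signed_rank"
    return ComparisonResult(
        parameter=parameter, test=test, statistic=float(res.statistic),
        p_value=float(res.pvalue), n_a=a.size, n_b=b.size,
        normality_p=(norm_p,), alpha=alpha,
    )


def independent_compare(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alpha: float = 0.05,
    parameter: str = "",
) -> ComparisonResult:
    """Two-sample comparison: Student's t or Mann–Whitney U, normality-gated."""
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return ComparisonResult(
            parameter=parameter, test="degenerate", statistic=0.0, p_value=1.0,
            n_a=a.size, n_b=b.size, normality_p=(float("nan"), float("nan")),
            alpha=alpha, degenerate=True,
        )
    pa, pb = _shapiro_p(a), _shapiro_p(b)
    if pa >= 0.05 and pb >= 0.05:
        res = sstats.ttest_ind(a, b, equal_var=True)
        test = "students_t"
    else:
        res = sstats.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann_whitney_u"
    return ComparisonResult(
        parameter=parameter, test=test, statistic=float(res.statistic),
        p_value=float(res.pvalue), n_a=a.size, n_b=b.size,
        normality_p=(pa, pb), alpha=alpha,
    )


PARAMETERS = ("asymmetry", "kurtosis", "mean_uV", "L", "apen", "psd_slope", "pdf_slope")


def recording_parameters(
    rec: Recording,
    max_lag: int | None = None,
    apen_max_n: int = 20000,
) -> dict[str, float]:
    """The seven per-recording signal parameters used in group contrasts.

    asymmetry (skewness), raw kurtosis, mean voltage (µV), integral
    correlation time L (samples), ApEn at scale 1 (m = 2, r = 0.2·SD,
    on a centred sub-window of at most ``apen_max_n`` samples), the PSD
    log-log slope (−β), and the PDF tail slope (−μ).  Slopes are reported
    signed, matching the convention of printing the regression slope.
    """
    d = dispersion(rec)
    if max_lag is None:
        max_lag = min(rec.n // 4, 2000)
    L = correlation_time(acf(rec, max_lag=max_lag)).samples
    x = rec.samples
    if x.size > apen_max_n:
        start = (x.size - apen_max_n) // 2
        x = x[start : start + apen_max_n]
    entropy = apen(x, m=2, r=0.2 * float(np.std(x)))
    beta = fit_psd_exponent(psd(rec)).exponent
    try:
        mu = pdf_tail_fit(rec).exponent
    except ValueError:
        mu = float("nan")
    return {
        "asymmetry": d.skewness,
        "kurtosis": d.kurtosis,
        "mean_uV": d.mean,
        "L": L,
        "apen": entropy,
        "psd_slope": -beta,
        "pdf_slope": -mu,
    }


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=np.float64)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def parameter_table(
    dataset: Mapping[str, Sequence[Recording]],
    alpha: float = 0.05,
    holm: bool = False,
    precomputed: Mapping[str, Sequence[Mapping[str, float]]] | None = None,
) -> pd.DataFrame:
    """Parameter summary and p-values across the four condition cells.

    ``dataset`` maps class names (``CB-before``, ``CB-after``,
    ``CW-before``, ``CW-after``) to recordings.  For each of the seven
    parameters the table carries the per-cell mean ± SD, the paired
    before-vs-after p-value within each treatment, and the independent
    between-treatment p-values (before vs before, after vs after), with
    significance stars at ``alpha`` levels.  ``precomputed`` may supply
    per-recording parameter dicts to skip recomputation.
    """
    cells = ("CB-before", "CB-after", "CW-before", "CW-after")
    for cell in cells:
        if cell not in dataset:
            raise ValueError(f"dataset is missing cell '{cell}'")
        if len(dataset[cell]) < 2:
            raise ValueError(f"cell '{cell}' needs at least 2 recordings")
    values: dict[str, pd.DataFrame] = {}
    for cell in cells:
        if precomputed is not None and cell in precomputed:
            rows = list(precomputed[cell])
        else:
            rows = [recording_parameters(rec) for rec in dataset[cell]]
        values[cell] = pd.DataFrame(rows)

    records = []
    for param in PARAMETERS:
        row: dict[str, object] = {"parameter": param}
        for cell in cells:
            v = values[cell][param].to_numpy()
            v = v[np.isfinite(v)]
            row[f"{cell} mean"] = float(np.mean(v)) if v.size else float("nan")
            row[f"{cell} sd"] = float(np.std(v, ddof=1)) if v.size > 1 else float("nan")
        for treat, before_cell, after_cell in (
            ("bean", "CB-before", "CB-after"),
            ("wheat", "CW-before", "CW-after"),
        ):
            vb = values[before_cell][param].to_numpy()
            va = values[after_cell][param].to_numpy()
            finite = np.isfinite(vb) & np.isfinite(va)
            if finite.sum() >= 3:
                cmp = paired_compare(vb[finite], va[finite], alpha=alpha,
                                     parameter=param)
                row[f"p {treat} before-after"] = cmp.p_value
                row[f"test {treat}"] = cmp.test
            else:
                row[f"p {treat} before-after"] = float("nan")
                row[f"test {treat}"] = "insufficient"
        for phase, cell_a, cell_b in (
            ("before", "CB-before", "CW-before"),
            ("after", "CB-after", "CW-after"),
        ):
            va = values[cell_a][param].to_numpy()
            vb = values[cell_b][param].to_numpy()
            va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
            if va.size >= 3 and vb.size >= 3:
                cmp = independent_compare(va, vb, alpha=alpha, parameter=param)
                row[f"p bean-wheat {phase}"] = cmp.p_value
            else:
                row[f"p bean-wheat {phase}"] = float("nan")
        records.append(row)
    table = pd.DataFrame(records).set_index("parameter")
    p_cols = [c for c in table.columns if c.startswith("p ")]
    if holm:
        for col in p_cols:
            table[col] = holm_adjust(table[col].to_numpy())
    for col in p_cols:
        table[col.replace("p ", "stars ")] = [
            significance_stars(p) for p in table[col]
        ]
    return table
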