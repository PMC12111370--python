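"""Stage-2 pairwise comparison of deconvolution outputs.

Two samples are compared component by component with two-sample t-tests
computed from summary statistics (mean, SD, n across portions), for both the
integral intensity and the relative percentage content, with Bonferroni
control of the family-wise error over the comparison family.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .deconv import DeconvolutionResult, relative_content

MEASURES = ("area", "relative_pct")


class SummaryStat(NamedTuple):
    """Summary of one component measure across portions."""

    mean: float
    sd: float
    n: int


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float
    ci_low: float
    ci_high: float
    mean_diff: float


def tsum_test(
    a: SummaryStat,
    b: SummaryStat,
    var_equal: bool = False,
    conf_level: float = 0.95,
) -> TTestResult:
    """Two-sided two-sample t-test from summary statistics.

    Welch by default (`var_equal=False`, Welch-Satterthwaite df); pooled
    variance with df = n_a + n_b - 2 otherwise.  Returns the t statistic,
    degrees of freedom, two-sided p and the confidence interval of the mean
    difference a - b.  Two degenerate summaries with zero SDs and equal
    means are reported as no difference (t = 0, p = 1).
    """
    for s in (a, b):
        if s.n < 2:
            raise ValueError("each summary needs n >= 2")
        if s.sd < 0:
            raise ValueError("sd must be non-negative")
    diff = a.mean - b.mean
    if a.sd == 0 and b.sd == 0:
        if diff == 0:
            return TTestResult(0.0, float(a.n + b.n - 2), 1.0, 0.0, 0.0, 0.0)
        t = np.inf if diff > 0 else -np.inf
        return TTestResult(float(t), float(a.n + b.n - 2), 0.0, diff, diff, diff)
    if var_equal:
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
        se = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    t = diff / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    half = float(stats.t.ppf(0.5 + conf_level / 2.0, df)) * se
    return TTestResult(float(t), float(df), p, diff - half, diff + half, diff)


def summarize_portions(
    results: Sequence[DeconvolutionResult],
    measure: str,
) -> dict[str, SummaryStat]:
    """Across-portion summary of one measure for each component."""
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}")
    if len(results) < 2:
        raise ValueError("need at least 2 portions to summarize")
    indices = [c.index for c in results[0].components]
    rows = []
    for res in results:
        if [c.index for c in res.components] != indices:
            raise ValueError("portion results use different component libraries")
        rows.append(res.areas if measure == "area" else relative_content(res))
    arr = np.asarray(rows)
    return {
        idx: SummaryStat(float(m), float(s), arr.shape[0])
        for idx, m, s in zip(indices, arr.mean(axis=0), arr.std(axis=0, ddof=1))
    }


def _family_size(family: str, n_components: int, n_measures: int, n_pairs: int) -> int:
    if family == "run":
        return n_pairs * n_components * n_measures
    if family == "per_comparison":
        return n_components * n_measures
    if family == "per_measure":
        return n_components
    raise ValueError(f"unknown family policy {family!r}")


def compare_samples(
    res_a: Sequence[DeconvolutionResult],
    res_b: Sequence[DeconvolutionResult],
    alpha: float = 0.05,
    family: str = "run",
    n_pairs: int = 1,
    measures: Iterable[str] = MEASURES,
    var_equal: bool = False,
) -> pd.DataFrame:
    """Component-wise comparison of two samples from per-portion results.

    For every component and measure the across-portion summaries feed a
    summary-statistic t-test; p-values are Bonferroni-adjusted with the
    family size set by `family`: ``"run"`` multiplies by the number of
    pairwise comparisons in the run (`n_pairs`) times components times
    measures (the conservative default when samples are reused across
    pairs), ``"per_comparison"`` by components times measures, and
    ``"per_measure"`` by components only.

    Returns a long-format frame (component, measure, means, diff, t, df,
    p_raw, p_adj, significant) with the family size and alpha in `attrs`.
    """
    measures = tuple(measures)
    if not measures or any(m not in MEASURES for m in measures):
        raise ValueError(f"measures must be a non-empty subset of {MEASURES}")
    sum_a = {m: summarize_portions(res_a, m) for m in measures}
    sum_b = {m: summarize_portions(res_b, m) for m in measures}
    if list(sum_a[measures[0]]) != list(sum_b[measures[0]]):
        raise ValueError("samples were deconvolved with different component libraries")
    indices = list(sum_a[measures[0]])
    m_family = _family_size(family, len(indices), len(measures), n_pairs)
    rows = []
    for measure in measures:
        for idx in indices:
            a, b = sum_a[measure][idx], sum_b[measure][idx]
            r = tsum_test(a, b, var_equal=var_equal)
            p_adj = min(1.0, m_family * r.p)
            rows.append(
                {
                    "component": idx,
                    "measure": measure,
                    "mean_a": a.mean,
                    "mean_b": b.mean,
                    "diff": r.mean_diff,
                    "t": r.t,
                    "df": r.df,
                    "p_raw": r.p,
                    "p_adj": p_adj,
                    "significant": bool(p_adj < alpha),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["family_size"] = m_family
    out.attrs["alpha"] = alpha
    out.attrs["family"] = family
    return out


def significant_only(comparison: pd.DataFrame) -> pd.DataFrame:
    """Compact report of the significant differences only."""
    return comparison.loc[comparison["significant"]].reset_index(drop=True)
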