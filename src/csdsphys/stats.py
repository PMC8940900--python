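"""Normality-gated correlation and group-comparison stage.

Distribution checks use a plain Kolmogorov-Smirnov test of the
standardized sample against the standard normal (note this understates
non-normality when parameters are estimated — the Lilliefors effect —
but plain KS is the convention followed here; the threshold is
configurable).  Parametric routes (Pearson, one-way ANOVA, t-tests) are
taken only when every sample passes the gate, and for group tests also
Levene's homoscedasticity check; otherwise the rank-based analogues
(Spearman, Kruskal-Wallis, Mann-Whitney) are used.  All p-values are
two-sided; post hoc pairwise p-values are Bonferroni-corrected.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["normality_gate", "correlate", "compare_groups",
           "CorrelationResult", "GroupComparisonResult"]

logger = logging.getLogger(__name__)

ALPHA_GATE = 0.05


@dataclass
class CorrelationResult:
    method: str          # pearson | spearman
    r: float
    p: float
    n: int
    x_label: str = "x"
    y_label: str = "y"

    def ci95(self) -> tuple[float, float]:
        """Fisher-z 95% confidence interval for the coefficient."""
        if self.n < 4 or abs(self.r) >= 1.0:
            return (float("nan"), float("nan"))
        z = np.arctanh(self.r)
        half = 1.959963984540054 / np.sqrt(self.n - 3)
        return (float(np.tanh(z - half)), float(np.tanh(z + half)))


@dataclass
class GroupComparisonResult:
    omnibus: str         # anova | kruskal_wallis
    statistic: float
    p: float
    posthoc: pd.DataFrame  # columns: group1, group2, test, statistic, p_raw, p_corrected
    correction: str = "bonferroni"


def normality_gate(sample, alpha: float = ALPHA_GATE) -> str:
    """Route a sample: 'parametric' iff KS-vs-normal p >= alpha.

    Samples with fewer than five values or zero variance are routed
    nonparametric with a warning.
    """
    x = np.asarray(sample, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 5:
        logger.warning("n=%d < 5: routing nonparametric", len(x))
        return "nonparametric"
    sd = x.std(ddof=1)
    if sd == 0:
        logger.warning("constant sample: routing nonparametric (degenerate)")
        return "nonparametric"
    z = (x - x.mean()) / sd
    p = sps.kstest(z, "norm").pvalue
    return "parametric" if p >= alpha else "nonparametric"


def correlate(x, y, x_label: str = "x", y_label: str = "y",
              method: str | None = None) -> CorrelationResult:
    """Pearson when both variables pass the normality gate, else Spearman."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D samples")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least three pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    if method is None:
        parametric = normality_gate(x) == "parametric" and normality_gate(y) == "parametric"
        method = "pearson" if parametric else "spearman"
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(method, float(r), float(p), len(x), x_label, y_label)


def compare_groups(samples: dict[str, np.ndarray],
                   alpha_gate: float = ALPHA_GATE) -> GroupComparisonResult:
    """Omnibus test across groups plus Bonferroni-corrected pairwise tests.

    One-way ANOVA (with pairwise Welch-free two-sided t-tests) when every
    group passes the KS gate and Levene's test accepts equal variances,
    else Kruskal-Wallis with pairwise Mann-Whitney tests.
    """
    names = list(samples)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = []
    for name in names:
        a = np.asarray(samples[name], dtype=float)
        a = a[np.isfinite(a)]
        if len(a) < 2:
            raise ValueError(f"group {name!r} has fewer than two values")
        arrays.append(a)

    gates = [normality_gate(a, alpha_gate) for a in arrays]
    homosced = sps.levene(*arrays).pvalue >= alpha_gate if all(
        len(a) >= 3 and a.std(ddof=1) > 0 for a in arrays) else False
    parametric = all(g == "parametric" for g in gates) and homosced

    if parametric:
        stat, p = sps.f_oneway(*arrays)
        omnibus = "anova"
    else:
        stat, p = sps.kruskal(*arrays)
        omnibus = "kruskal_wallis"

    rows = []
    for (i, gi), (j, gj) in itertools.combinations(enumerate(names), 2):
        if parametric:
            s, pr = sps.ttest_ind(arrays[i], arrays[j])
            test = "t"
        else:
            s, pr = sps.mannwhitneyu(arrays[i], arrays[j], alternative="two-sided")
            test = "mannwhitney"
        rows.append({"group1": gi, "group2": gj, "test": test,
                     "statistic": float(s), "p_raw": float(pr)})
    posthoc = pd.DataFrame(rows)
    posthoc["p_corrected"] = multipletests(posthoc["p_raw"], method="bonferroni")[1]
    return GroupComparisonResult(omnibus, float(stat), float(p), posthoc)
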