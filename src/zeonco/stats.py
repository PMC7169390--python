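"""Cohort statistics: robust outlier removal, normality screening, test
selection and significance annotation.

The workflow mirrors standard practice in larval xenograft screens:
ROUT-style FDR-controlled outlier removal (Q, percent) on each group, a
D'Agostino–Pearson omnibus normality screen, then a parametric path
(t-test; one-way ANOVA with Tukey or Šidák post hoc for >2 groups) when
every group looks Normal and a rank-based path (Wilcoxon signed-rank /
Mann–Whitney U / Kruskal–Wallis) otherwise. Significance is annotated with
the usual star ladder (strict thresholds 0.05 / 0.01 / 0.001 / 0.0001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def annotate_stars(p: float) -> str:
    """Map a p-value to ns/*/**/***/**** with strict (<) thresholds."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value must be in [0, 1], got {p}")
    for cut, stars in STAR_THRESHOLDS:
        if p < cut:
            return stars
    return "ns"


def rout_outliers(
    values: Sequence[float], q: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Univariate ROUT-style outlier flagging at FDR ``q`` percent.

    Adaptation of robust-regression-plus-FDR outlier removal to a constant
    (location-only) fit: the robust location is the median; the robust
    scale (RSDR) is the 68.27th percentile of absolute residuals times the
    small-sample correction n/(n−1). Each residual is converted to a
    t-statistic with n−1 degrees of freedom and the resulting two-sided
    p-values are tested outside-in with a Benjamini–Hochberg step-up at
    rate q/100; flagged values are removed.

    Returns
    -------
    (kept, flags)
        ``kept`` is the array of retained values; ``flags`` is a boolean
        array aligned with the input (True = outlier).
    """
    x = np.asarray(list(values), dtype=float)
    n = x.size
    flags = np.zeros(n, dtype=bool)
    if n < 3:
        warnings.warn("ROUT needs n >= 3; no outlier removal performed")
        return x, flags
    if not (0.0 < q < 100.0):
        raise ValueError(f"Q must be in (0, 100) percent, got {q}")
    resid = x - np.median(x)
    abs_resid = np.abs(resid)
    rsdr = float(np.percentile(abs_resid, 68.27)) * n / (n - 1)
    if rsdr == 0.0:
        # >68% of values sit exactly at the median: any deviation is extreme
        flags = abs_resid > 0
        return x[~flags], flags
    t = abs_resid / rsdr
    p = 2.0 * sps.t.sf(t, df=n - 1)
    order = np.argsort(p, kind="stable")
    thresholds = (q / 100.0) * (np.arange(1, n + 1) / n)
    below = p[order] <= thresholds
    if below.any():
        k = int(np.max(np.nonzero(below)[0])) + 1
        flags[order[:k]] = True
    return x[~flags], flags


def normality_test(values: Sequence[float]) -> float:
    """D'Agostino–Pearson omnibus normality p-value.

    The omnibus statistic K² combines the transformed-moment Z scores of
    sample skewness and kurtosis and is referred to a chi-square with 2
    degrees of freedom. The moment corrections are undefined below n = 8;
    such samples return NaN (callers route them to the rank-based path).
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 8:
        warnings.warn(
            f"normality test needs n >= 8 (got {x.size}); routing to the "
            "non-parametric path"
        )
        return float("nan")
    return float(sps.normaltest(x).pvalue)


@dataclass
class CohortComparison:
    """Outcome of the full decision tree on labeled groups."""

    group_names: tuple[str, ...]
    groups: dict[str, np.ndarray]
    removed_outliers: dict[str, np.ndarray]
    normality_p: dict[str, float]
    test_name: str
    p_value: float
    stars: str
    posthoc: Optional[dict[tuple[str, str], float]] = None

    def to_dict(self) -> dict:
        return {
            "groups": {k: list(map(float, v)) for k, v in self.groups.items()},
            "n_before": {
                k: int(len(self.groups[k]) + len(self.removed_outliers[k]))
                for k in self.group_names
            },
            "n_after": {k: int(len(self.groups[k])) for k in self.group_names},
            "removed_outliers": {
                k: list(map(float, v)) for k, v in self.removed_outliers.items()
            },
            "normality_p": {k: float(v) for k, v in self.normality_p.items()},
            "test_name": self.test_name,
            "p_value": float(self.p_value),
            "stars": self.stars,
            "posthoc": (
                {f"{a} vs {b}": float(p) for (a, b), p in self.posthoc.items()}
                if self.posthoc
                else None
            ),
        }


def _sidak_pairwise(
    names: Sequence[str], data: Sequence[np.ndarray]
) -> dict[tuple[str, str], float]:
    """Pairwise t-tests with Šidák multiplicity correction."""
    pairs = [
        (i, j) for i in range(len(names)) for j in range(i + 1, len(names))
    ]
    m = len(pairs)
    out = {}
    for i, j in pairs:
        p_raw = float(sps.ttest_ind(data[i], data[j]).pvalue)
        out[(names[i], names[j])] = float(1.0 - (1.0 - p_raw) ** m)
    return out


def select_and_run(
    groups: dict[str, Sequence[float]],
    paired: bool = False,
    alpha: float = 0.05,
    q: float = 1.0,
    posthoc: str = "tukey",
    apply_rout: bool = True,
) -> CohortComparison:
    """Run the full decision tree on labeled groups.

    Outliers are removed per group (ROUT at rate ``q``), each group is
    screened for normality, and the test is chosen accordingly: for two
    groups Student's t (paired or unpaired) when both pass, otherwise
    Wilcoxon signed-rank (paired) or Mann–Whitney U (unpaired); for more
    than two groups one-way ANOVA with a Tukey or Šidák post hoc when all
    pass, otherwise Kruskal–Wallis. Groups with n < 8 after removal cannot
    be normality-screened and take the rank-based path.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if posthoc not in ("tukey", "sidak"):
        raise ValueError(f"posthoc must be 'tukey' or 'sidak', got {posthoc!r}")
    names = tuple(groups.keys())
    kept: dict[str, np.ndarray] = {}
    removed: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size < 3:
            raise ValueError(f"group {name!r} has n < 3")
        if apply_rout:
            k, flags = rout_outliers(arr, q=q)
        else:
            k, flags = arr, np.zeros(arr.size, dtype=bool)
        if k.size < 3:
            raise ValueError(f"group {name!r} has n < 3 after outlier removal")
        kept[name] = k
        removed[name] = arr[flags]
    norm_p = {name: normality_test(kept[name]) for name in names}
    all_normal = all(np.isfinite(p) and p >= alpha for p in norm_p.values())
    data = [kept[n] for n in names]
    posthoc_table: Optional[dict[tuple[str, str], float]] = None

    if len(names) == 2:
        if paired and data[0].size != data[1].size:
            raise ValueError("paired comparison requires equal group sizes")
        if all_normal:
            test_name = "t"
            res = sps.ttest_rel(*data) if paired else sps.ttest_ind(*data)
        elif paired:
            test_name = "Wilcoxon"
            res = sps.wilcoxon(*data)
        else:
            test_name = "Mann-Whitney"
            res = sps.mannwhitneyu(*data, alternative="two-sided")
        p_value = float(res.pvalue)
    else:
        if all_normal:
            res = sps.f_oneway(*data)
            p_value = float(res.pvalue)
            if posthoc == "tukey":
                test_name = "ANOVA+Tukey"
                hsd = sps.tukey_hsd(*data)
                posthoc_table = {
                    (names[i], names[j]): float(hsd.pvalue[i, j])
                    for i in range(len(names))
                    for j in range(i + 1, len(names))
                }
            else:
                test_name = "ANOVA+Sidak"
                posthoc_table = _sidak_pairwise(names, data)
        else:
            test_name = "Kruskal-Wallis"
            p_value = float(sps.kruskal(*data).pvalue)

    return CohortComparison(
        group_names=names,
        groups=kept,
        removed_outliers=removed,
        normality_p=norm_p,
        test_name=test_name,
        p_value=p_value,
        stars=annotate_stars(p_value),
        posthoc=posthoc_table,
    )
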