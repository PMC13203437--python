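"""Statistical harness for cross-arm comparisons.

Test selection is prospective and auditable: for two-group comparisons of
continuous outcomes, Shapiro-Wilk normality (alpha = 0.05) on each sample
selects Welch's two-sided t-test (neither rejected) or the two-sided
Mann-Whitney U (either rejected).  Multi-group comparisons use the
Kruskal-Wallis omnibus test followed, when significant, by Dunn's post hoc
test with Bonferroni correction.  Binomial proportions carry Wilson 95%
score intervals, which keep good coverage at small event counts.
All p-values are two-sided; alpha = 0.05 throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "ProportionCI",
    "wilson_interval",
    "compare_two_arms",
    "compare_multi_arms",
    "dunn_posthoc",
]

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    """One hypothesis-test outcome plus its selection trace."""

    test: str            # shapiro | welch_t | mann_whitney | kruskal_wallis | dunn_bonferroni
    statistic: float
    p_value: float
    groups: tuple[str, ...]
    alpha: float = ALPHA
    selection_trace: tuple[str, ...] = field(default_factory=tuple)
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class ProportionCI:
    """Binomial point estimate with a Wilson score interval."""

    successes: int
    trials: int
    point: float
    lower: float
    upper: float
    confidence: float = 0.95


def wilson_interval(successes: int, trials: int, confidence: float = 0.95) -> ProportionCI:
    """Wilson score interval for a binomial proportion.

    Uses the two-sided normal quantile for the stated confidence.  The
    interval for (k, n) is the reflection about 1/2 of the interval for
    (n - k, n), and the lower bound at k = 0 is exactly 0.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    z = sps.norm.ppf(0.5 + confidence / 2.0)
    n = float(trials)
    p = successes / n
    z2 = z * z
    denom = 1.0 + z2 / n
    centre = p + z2 / (2.0 * n)
    half = z * np.sqrt(p * (1.0 - p) / n + z2 / (4.0 * n * n))
    # boundary cases are exact by construction (centre == half there)
    lower = 0.0 if successes == 0 else max(0.0, (centre - half) / denom)
    upper = 1.0 if successes == trials else min(1.0, (centre + half) / denom)
    return ProportionCI(
        successes=int(successes),
        trials=int(trials),
        point=p,
        lower=lower,
        upper=upper,
        confidence=confidence,
    )


def compare_two_arms(
    a, b, names: tuple[str, str] = ("a", "b"), alpha: float = ALPHA
) -> TestResult:
    """Two-group comparison with prospective Shapiro-Wilk test selection."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    trace: list[str] = []
    flags: list[str] = []
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate zero-variance pair: report no-difference convention
        same = float(a[0] == b[0])
        return TestResult(
            test="welch_t",
            statistic=0.0 if same else float("inf"),
            p_value=1.0 if same else 0.0,
            groups=names,
            alpha=alpha,
            selection_trace=("zero variance in both groups",),
            flags=("degenerate",),
        )
    normal = []
    for name, x in zip(names, (a, b)):
        if np.ptp(x) == 0:
            trace.append(f"shapiro[{name}]: zero variance, treated as non-normal")
            normal.append(False)
            flags.append("degenerate")
            continue
        w, p = sps.shapiro(x)
        trace.append(f"shapiro[{name}]: W={w:.4f} p={p:.4g}")
        normal.append(p >= alpha)
    if all(normal):
        stat, p = sps.ttest_ind(a, b, equal_var=False)
        trace.append("normality not rejected in either group -> Welch t")
        test = "welch_t"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        trace.append("normality rejected -> Mann-Whitney U")
        test = "mann_whitney"
    return TestResult(
        test=test,
        statistic=float(stat),
        p_value=float(p),
        groups=names,
        alpha=alpha,
        selection_trace=tuple(trace),
        flags=tuple(flags),
    )


def dunn_posthoc(
    groups: dict[str, np.ndarray], alpha: float = ALPHA
) -> list[TestResult]:
    """Dunn's rank-based pairwise z-tests with Bonferroni correction.

    Pooled ranks with mid-rank ties; the tie-corrected variance term
    follows the textbook definition.  Adjusted p-values are the raw
    two-sided normal p-values multiplied by the number of comparisons,
    capped at 1.
    """
    names = list(groups)
    data = [np.asarray(groups[k], dtype=float) for k in names]
    pooled = np.concatenate(data)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction: sum(t^3 - t) over tie groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_factor = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    mean_ranks = {}
    start = 0
    for k, x in zip(names, data):
        mean_ranks[k] = ranks[start : start + x.size].mean()
        start += x.size
    m = len(names) * (len(names) - 1) // 2
    out = []
    for a, b in itertools.combinations(names, 2):
        na, nb = groups[a].size if hasattr(groups[a], "size") else len(groups[a]), len(
            np.asarray(groups[b])
        )
        se = np.sqrt(var_factor * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        out.append(
            TestResult(
                test="dunn_bonferroni",
                statistic=float(z),
                p_value=float(min(1.0, p_raw * m)),
                groups=(a, b),
                alpha=alpha,
                selection_trace=(f"raw p={p_raw:.4g}, Bonferroni x{m}",),
            )
        )
    return out


def compare_multi_arms(groups: dict[str, np.ndarray], alpha: float = ALPHA) -> list[TestResult]:
    """Kruskal-Wallis omnibus; Dunn-Bonferroni pairwise when significant."""
    if len(groups) < 3:
        raise ValueError("multi-arm comparison needs at least 3 groups")
    data = [np.asarray(v, dtype=float) for v in groups.values()]
    if all(np.ptp(np.concatenate(data)) == 0 for _ in (0,)):
        omnibus = TestResult(
            test="kruskal_wallis",
            statistic=0.0,
            p_value=1.0,
            groups=tuple(groups),
            alpha=alpha,
            selection_trace=("all observations identical",),
            flags=("degenerate",),
        )
        return [omnibus]
    stat, p = sps.kruskal(*data)
    omnibus = TestResult(
        test="kruskal_wallis",
        statistic=float(stat),
        p_value=float(p),
        groups=tuple(groups),
        alpha=alpha,
        selection_trace=("omnibus non-parametric ANOVA",),
    )
    results = [omnibus]
    if omnibus.significant:
        results.extend(dunn_posthoc(groups, alpha=alpha))
    return results
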