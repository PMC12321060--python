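"""Paired-comparison statistics: normality gating, tests, effect sizes.

The analysis contrasts the same subjects before and after fatigue
induction, so every comparison is paired. The branch between the paired
t-test and the Wilcoxon signed-rank test is a pure function of a
normality gate on the paired differences (Shapiro–Wilk, or the
Kolmogorov–Smirnov/Lilliefors variant used for the spectral family);
there is no silent fallback.

Effect sizes: Cohen's d = M_diff / S_diff for the parametric branch,
r = Z / sqrt(N) for the signed-rank branch, and the conversion
r = d / sqrt(d**2 + 4) between the two scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "PairedSample",
    "NormalityResult",
    "TestResult",
    "normality_gate",
    "paired_test",
    "d_to_r",
    "r_to_d",
    "bonferroni",
    "spearman",
]


@dataclass
class PairedSample:
    """Pre/post values for the same subjects, in subject order."""

    pre: np.ndarray
    post: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=float)
        self.post = np.asarray(self.post, dtype=float)
        if self.pre.shape != self.post.shape or self.pre.ndim != 1:
            raise ValueError("pre and post must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(self.pre)) and np.all(np.isfinite(self.post))):
            raise ValueError(f"sample {self.label!r} has missing/non-finite pairs")

    @property
    def n(self) -> int:
        return self.pre.size

    @property
    def differences(self) -> np.ndarray:
        return self.post - self.pre


@dataclass
class NormalityResult:
    """Outcome of the normality gate on paired differences.

    ``evaluated`` is False when the sample is too small to test (n <= 3),
    mirroring the convention of omitting the test rather than failing;
    an unevaluated gate routes to the nonparametric branch.
    """

    p: float
    is_normal: bool | None
    evaluated: bool
    method: str


def normality_gate(
    differences: np.ndarray, method: str = "shapiro", alpha: float = 0.05
) -> NormalityResult:
    """Test paired differences for normality.

    ``method="shapiro"`` uses Shapiro–Wilk; ``method="ks"`` uses the
    Lilliefors-corrected Kolmogorov–Smirnov test (normal with estimated
    mean and variance). Samples with n <= 3 are not evaluated.
    """
    diffs = np.asarray(differences, dtype=float).ravel()
    if diffs.size <= 3:
        return NormalityResult(p=math.nan, is_normal=None, evaluated=False,
                               method=method)
    if method == "shapiro":
        p = float(sstats.shapiro(diffs).pvalue)
    elif method == "ks":
        _, p = lilliefors(diffs, dist="norm")
        p = float(p)
    else:
        raise ValueError(f"unknown normality method {method!r}")
    return NormalityResult(p=p, is_normal=bool(p > alpha), evaluated=True,
                           method=method)


@dataclass
class TestResult:
    """One paired comparison with its effect sizes and threshold."""

    test: str                 # "paired_t" | "wilcoxon"
    p: float
    statistic: float          # t, or Z for the signed-rank branch
    d: float | None           # Cohen's d (parametric branch only)
    r: float                  # effect size on the r scale
    significant_at: float     # adjusted threshold used
    normality_p: float
    mean_pre: float
    mean_post: float
    sd_pre: float
    sd_post: float
    mean_diff: float
    label: str = ""

    @property
    def significant(self) -> bool:
        return self.p < self.significant_at


def d_to_r(d: float) -> float:
    """Convert Cohen's d to the r effect-size scale: r = d / sqrt(d² + 4)."""
    d = float(d)
    if not math.isfinite(d):
        raise ValueError("d must be finite")
    return d / math.sqrt(d * d + 4.0)


def r_to_d(r: float) -> float:
    """Inverse conversion: d = 2 r / sqrt(1 − r²), for |r| < 1."""
    r = float(r)
    if not -1 < r < 1:
        raise ValueError("r must lie strictly inside (-1, 1)")
    return 2.0 * r / math.sqrt(1.0 - r * r)


def bonferroni(alpha: float, m: int) -> float:
    """Family-wise adjusted threshold α′ = α / m."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if int(m) != m or m < 1:
        raise ValueError("m must be a positive integer")
    return alpha / int(m)


def _wilcoxon_z(diffs: np.ndarray) -> float:
    """Signed Z statistic of the signed-rank test (normal approximation,
    continuity-corrected, midranks, zero-differences dropped)."""
    d = diffs[diffs != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = sstats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    # tie correction on the rank variance
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / 48.0
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    if sigma == 0:
        raise ValueError("degenerate sample: zero rank variance")
    correction = 0.5 * np.sign(w_plus - mu)
    return float((w_plus - mu - correction) / sigma)


def paired_test(
    sample: PairedSample,
    gate: NormalityResult | None = None,
    significant_at: float = 0.05,
    wilcoxon_r: str = "z_over_sqrt_n",
) -> TestResult:
    """Paired t-test or Wilcoxon signed-rank, chosen by the normality gate.

    Parameters
    ----------
    sample
        The paired observations.
    gate
        Normality result for ``sample.differences``. When None, a
        Shapiro–Wilk gate is computed here. An unevaluated gate (n <= 3)
        routes to the nonparametric branch.
    significant_at
        The (possibly Bonferroni-adjusted) threshold recorded in the result.
    wilcoxon_r
        ``"z_over_sqrt_n"`` (conventional r = Z/√N, default) or
        ``"z_over_n"`` (the literal printed form, kept for audit).

    Notes
    -----
    The Wilcoxon p-value uses the exact distribution for n < 20 (no ties,
    no zeros) and the continuity-corrected normal approximation otherwise;
    the Z statistic reported for the effect size always comes from the
    normal approximation so that r is well-defined in both regimes.
    """
    if sample.n < 2:
        raise ValueError("need at least 2 pairs")
    diffs = sample.differences
    if np.all(diffs == 0):
        raise ValueError(f"degenerate sample {sample.label!r}: all differences zero")
    if gate is None:
        gate = normality_gate(diffs, method="shapiro")
    if wilcoxon_r not in ("z_over_sqrt_n", "z_over_n"):
        raise ValueError(f"unknown wilcoxon_r convention {wilcoxon_r!r}")

    common = dict(
        significant_at=significant_at,
        normality_p=gate.p,
        mean_pre=float(sample.pre.mean()),
        mean_post=float(sample.post.mean()),
        sd_pre=float(sample.pre.std(ddof=1)) if sample.n > 1 else math.nan,
        sd_post=float(sample.post.std(ddof=1)) if sample.n > 1 else math.nan,
        mean_diff=float(diffs.mean()),
        label=sample.label,
    )

    if gate.evaluated and gate.is_normal:
        res = sstats.ttest_rel(sample.post, sample.pre)
        s_diff = diffs.std(ddof=1)
        if s_diff == 0:
            raise ValueError(
                f"degenerate sample {sample.label!r}: zero-variance differences"
            )
        d = float(diffs.mean() / s_diff)
        return TestResult(test="paired_t", p=float(res.pvalue),
                          statistic=float(res.statistic), d=d, r=d_to_r(d),
                          **common)

    z = _wilcoxon_z(diffs)
    nonzero = diffs[diffs != 0]
    use_exact = nonzero.size < 20 and np.unique(np.abs(nonzero)).size == nonzero.size
    method = "exact" if use_exact else "approx"
    p = float(sstats.wilcoxon(nonzero, method=method).pvalue)
    n_for_r = sample.n if wilcoxon_r == "z_over_n" else math.sqrt(sample.n)
    return TestResult(test="wilcoxon", p=p, statistic=z, d=None,
                      r=float(z / n_for_r), **common)


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation and its p-value.

    Raises
    ------
    ValueError
        On length mismatch, n < 3, or a constant input (the rank
        correlation is undefined).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("inputs have different lengths")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    rho, p = sstats.spearmanr(x, y)
    return float(rho), float(p)
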