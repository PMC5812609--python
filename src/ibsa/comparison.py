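"""Method-comparison statistics for surface measurements.

Percent relative error against a known truth, Bland-Altman agreement
analysis on paired measurements (bias, SD, limits of agreement), bootstrap
confidence intervals, and F/t comparison of inter-method variances and
biases.

The Bland-Altman proportional difference of a pair (a, b) uses the pair
mean as denominator — the standard choice for ratio-scale data:

    d = 100 · (a − b) / ((a + b) / 2)     [percent]

bias = mean(d); SD = sample standard deviation (n−1); limits of agreement
LoA = bias ± 1.96·SD.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidTruthError,
    InvalidValuesError,
)


def percent_relative_error(surf: float, surf_truth: float) -> float:
    """Signed percent error: 100·(Surf − SurfTruth)/SurfTruth."""
    if surf_truth <= 0:
        raise InvalidTruthError("invalid truth: reference surface must be > 0")
    return 100.0 * (surf - surf_truth) / surf_truth


def accuracy_summary(errors) -> dict:
    """Order statistics of a set of percent errors: median, min, max, mean."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise InsufficientDataError("no data")
    return {
        "median": float(np.median(errors)),
        "min": float(errors.min()),
        "max": float(errors.max()),
        "mean": float(errors.mean()),
        "n": int(errors.size),
    }


@dataclass
class PairedSeries:
    """Paired measurements of the same quantity by two methods."""

    values_a: np.ndarray
    values_b: np.ndarray
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if self.values_a.shape != self.values_b.shape or self.values_a.ndim != 1:
            raise InsufficientDataError("paired series must be equal-length 1-D")
        if self.ids is None:
            self.ids = [str(i) for i in range(len(self.values_a))]

    def __len__(self) -> int:
        return len(self.values_a)


@dataclass
class BlandAltmanResult:
    bias_pct: float
    sd_pct: float
    loa_low_pct: float
    loa_high_pct: float
    n: int
    mode: str = "proportional"
    ci_bias: tuple[float, float] | None = None
    ci_sd: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _differences(pairs: PairedSeries, mode: str) -> np.ndarray:
    a, b = pairs.values_a, pairs.values_b
    if mode == "proportional":
        if np.any(a <= 0) or np.any(b <= 0):
            raise InvalidValuesError(
                "invalid values: proportional differences need positive data"
            )
        return 100.0 * (a - b) / ((a + b) / 2.0)
    if mode == "absolute":
        return a - b
    raise ValueError(f"unknown mode {mode!r}")


def bland_altman(pairs: PairedSeries, mode: str = "proportional") -> BlandAltmanResult:
    """Bland-Altman agreement: bias, sample SD (n−1), LoA = bias ± 1.96·SD."""
    if len(pairs) < 2:
        raise InsufficientDataError("insufficient pairs: need at least 2")
    d = _differences(pairs, mode)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias_pct=bias,
        sd_pct=sd,
        loa_low_pct=bias - 1.96 * sd,
        loa_high_pct=bias + 1.96 * sd,
        n=len(pairs),
        mode=mode,
    )


def bootstrap_ci(pairs: PairedSeries, statistic: str = "bias",
                 n_boot: int = 2000, seed: int = 0,
                 mode: str = "proportional") -> tuple[float, float]:
    """Percentile 95% bootstrap CI for the Bland-Altman bias or SD.

    Whole pairs are resampled with replacement; deterministic given seed.
    """
    if len(pairs) < 2:
        raise InsufficientDataError("insufficient pairs: need at least 2")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    d = _differences(pairs, mode)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(d), size=(n_boot, len(d)))
    resamples = d[idx]
    if statistic == "bias":
        stats_ = resamples.mean(axis=1)
    elif statistic == "sd":
        stats_ = resamples.std(axis=1, ddof=1)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    lo, hi = np.percentile(stats_, [2.5, 97.5])
    return float(lo), float(hi)


def compare_methods(diffs_a, diffs_b) -> dict:
    """Compare two difference series: F-test on variances, Welch t-test on means.

    The larger variance goes in the F numerator; both tests are two-sided.
    """
    a = np.asarray(diffs_a, dtype=float)
    b = np.asarray(diffs_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("need at least 2 values per series")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise DegenerateDataError("degenerate: zero variance in both series")
    if va >= vb:
        f, dfn, dfd = (va / vb if vb > 0 else np.inf), len(a) - 1, len(b) - 1
    else:
        f, dfn, dfd = (vb / va if va > 0 else np.inf), len(b) - 1, len(a) - 1
    f_pvalue = float(min(1.0, 2.0 * stats.f.sf(f, dfn, dfd)))
    t_stat, t_pvalue = stats.ttest_ind(a, b, equal_var=False)
    return {
        "f_statistic": float(f),
        "f_pvalue": f_pvalue,
        "t_statistic": float(t_stat),
        "t_pvalue": float(t_pvalue),
    }


def bland_altman_plot(pairs: PairedSeries, result: BlandAltmanResult,
                      path: str) -> None:
    """Save a Bland-Altman plot (mean vs difference, bias and LoA lines)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = _differences(pairs, result.mode)
    means = (pairs.values_a + pairs.values_b) / 2.0
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, d, s=18, alpha=0.8)
    ax.axhline(result.bias_pct, color="k", label=f"bias {result.bias_pct:.2f}")
    for loa in (result.loa_low_pct, result.loa_high_pct):
        ax.axhline(loa, color="r", ls="--")
    unit = "%" if result.mode == "proportional" else ""
    ax.set_xlabel("pair mean")
    ax.set_ylabel(f"difference {unit}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
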