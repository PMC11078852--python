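"""Test–retest agreement statistics and the sample-size calculation.

Implements the evaluation toolkit for paired measurement studies: single-
measure absolute-agreement intraclass correlation from the two-way ANOVA
mean squares, Bland–Altman limits of agreement (unit and percentage modes)
with a Shapiro–Wilk normality check, error summaries (RMSD, median absolute
difference, mean absolute percentage), and the Fisher-z correlation-based
sample-size formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import StatsError


@dataclass
class PairedMeasurements:
    """Two measurement sessions (or method vs reference) of the same items."""

    x: np.ndarray
    y: np.ndarray
    units: str = "mm"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).reshape(-1)
        self.y = np.asarray(self.y, dtype=float).reshape(-1)
        if len(self.x) != len(self.y):
            raise StatsError(f"length mismatch: {len(self.x)} vs {len(self.y)}")
        if len(self.x) < 3:
            raise StatsError(f"need >= 3 pairs, got {len(self.x)}")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise StatsError("non-finite measurements")

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    mean_diff_ci: tuple[float, float]
    percent_mode: bool
    normality_p: float
    degenerate: bool = False  # all differences identical: limits collapse


@dataclass
class ICCResult:
    icc: float
    ci: tuple[float, float]
    model: str
    p_value: float
    degenerate: bool = False


def bland_altman(
    data: PairedMeasurements,
    percent: bool = False,
    alpha: float = 0.05,
    loa_factor: float = 1.96,
) -> BlandAltmanResult:
    """Bland–Altman agreement analysis.

    Differences are x - y, or 100*(x - y)/mean(x, y) in percent mode.
    Limits of agreement are d ± ``loa_factor``·s (1.96 for the exact 95%
    normal quantile; pass 2.0 for the rounded convention).  The mean
    difference gets a t-based CI; ``normality_p`` is a Shapiro–Wilk p-value
    on the differences — advisory, the analysis always computes.
    """
    if percent:
        means = 0.5 * (data.x + data.y)
        zero = np.nonzero(means == 0)[0]
        if zero.size:
            raise StatsError(f"zero pairwise mean at indices {zero.tolist()} in percent mode")
        diffs = 100.0 * (data.x - data.y) / means
    else:
        diffs = data.x - data.y
    n = len(diffs)
    d = float(np.mean(diffs))
    s = float(np.std(diffs, ddof=1))
    degenerate = s == 0.0
    if degenerate:
        lo = hi = d
        ci = (d, d)
        normality_p = float("nan")
    else:
        lo, hi = d - loa_factor * s, d + loa_factor * s
        half = sps.t.ppf(1.0 - alpha / 2.0, n - 1) * s / math.sqrt(n)
        ci = (d - half, d + half)
        normality_p = float(sps.shapiro(diffs).pvalue)
    return BlandAltmanResult(
        mean_diff=d,
        sd_diff=s,
        loa_lower=lo,
        loa_upper=hi,
        mean_diff_ci=ci,
        percent_mode=percent,
        normality_p=normality_p,
        degenerate=degenerate,
    )


def _two_way_mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    """(MS_rows, MS_cols, MS_error) of a complete two-way layout."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ms_r = k * np.sum((row_means - grand) ** 2) / (n - 1)
    ms_c = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = data - row_means[:, None] - col_means[None, :] + grand
    ms_e = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(ms_r), float(ms_c), float(ms_e)


def icc_absolute(data: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """Single-measure absolute-agreement ICC from a two-way model.

    ``data`` is n_subjects x k_sessions with no missing cells.  The point
    estimate is (MS_R - MS_E) / (MS_R + (k-1)MS_E + (k/n)(MS_C - MS_E));
    the CI uses the standard F-based bounds and the p-value tests ICC = 0
    via F = MS_R / MS_E on (n-1, (n-1)(k-1)) df.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise StatsError(f"data must be 2D (subjects x raters), got shape {data.shape}")
    n, k = data.shape
    if n < 3 or k < 2:
        raise StatsError(f"need >= 3 subjects and >= 2 sessions, got {n} x {k}")
    if not np.all(np.isfinite(data)):
        raise StatsError("missing or non-finite cells")
    ms_r, ms_c, ms_e = _two_way_mean_squares(data)
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    model = "two-way mixed, absolute agreement, single measure"
    if denom == 0:
        return ICCResult(icc=float("nan"), ci=(float("nan"), float("nan")),
                         model=model, p_value=float("nan"), degenerate=True)
    icc = (ms_r - ms_e) / denom

    if ms_e == 0:
        # perfect agreement: no residual variance, CI collapses
        return ICCResult(icc=float(icc), ci=(float(icc), float(icc)),
                         model=model, p_value=0.0, degenerate=False)
    # F-based confidence bounds (two-way absolute agreement, single measure)
    fj = ms_c / ms_e
    vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = vn / vd
    f_u = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (ms_r - f_u * ms_e) / (f_u * (k * ms_c + (k * n - k - n) * ms_e) + n * ms_r)
    upper = n * (f_l * ms_r - ms_e) / (k * ms_c + (k * n - k - n) * ms_e + n * f_l * ms_r)
    f_obs = ms_r / ms_e
    p = float(sps.f.sf(f_obs, n - 1, (n - 1) * (k - 1)))
    return ICCResult(icc=float(icc), ci=(float(lower), float(upper)), model=model, p_value=p)


def error_summaries(data: PairedMeasurements) -> dict[str, float]:
    """RMSD, median/IQR of absolute differences, mean ± SD absolute %.

    Percentages are relative to ``y`` (the reference); any zero reference
    value is an error.
    """
    if np.any(data.y == 0):
        raise StatsError("zero reference value; percentage terms undefined")
    d = data.x - data.y
    abs_d = np.abs(d)
    q1, q3 = np.percentile(abs_d, [25.0, 75.0])
    abs_pct = 100.0 * abs_d / np.abs(data.y)
    return {
        "rmsd": float(np.sqrt(np.mean(d**2))),
        "median_abs_diff": float(np.median(abs_d)),
        "iqr_abs_diff": float(q3 - q1),
        "mean_abs_pct": float(np.mean(abs_pct)),
        "sd_abs_pct": float(np.std(abs_pct, ddof=1)) if len(d) > 1 else 0.0,
    }


def sample_size_correlation(
    r: float, alpha: float = 0.05, power: float = 0.8, inflation: float = 0.10
) -> int:
    """Sample size for detecting correlation ``r`` against H0: rho = 0.

    Fisher z: C' = arctanh(|r|); n = ((z_{1-alpha/2} + z_power)/C')^2 + 3,
    inflated by ``inflation`` and rounded up once at the end.  The default
    settings (r = 0.7, alpha = 0.05, power = 0.8, +10%) give 15.
    """
    if not (0.0 < abs(r) < 1.0):
        raise StatsError(f"need 0 < |r| < 1, got {r}")
    if not (0.0 < alpha < 1.0 and 0.0 < power < 1.0):
        raise StatsError(f"alpha and power must lie in (0, 1), got {alpha}, {power}")
    if inflation < 0:
        raise StatsError(f"inflation must be >= 0, got {inflation}")
    c_prime = math.atanh(abs(r))
    z_alpha = sps.norm.ppf(1.0 - alpha / 2.0)
    z_power = sps.norm.ppf(power)
    n_raw = ((z_alpha + z_power) / c_prime) ** 2 + 3.0
    return int(math.ceil(n_raw * (1.0 + inflation)))
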