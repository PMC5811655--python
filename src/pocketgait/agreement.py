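"""Method-comparison and test-retest reliability statistics.

Validating a new gait-measurement device against a gold standard uses
three complementary analyses:

* **Passing-Bablok regression** — a nonparametric orthogonal regression
  built from the shifted median of all pairwise slopes, appropriate when
  both methods carry measurement error. Slope 1 / intercept 0 indicate
  agreement without proportional or constant bias.
* **Bland-Altman analysis** — per-pair differences plotted against
  per-pair means; the mean difference is the bias, bias +/- 1.96 SD the
  95% limits of agreement.
* **One-way intraclass correlations** ICC(1,1) and ICC(1,k)
  (Shrout-Fleiss case 1) — test-retest reliability of single trials and
  of k-trial averages; values above .80 are read as excellent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError

logger = logging.getLogger(__name__)


@dataclass
class PairedMeasurements:
    """Matched reference (x) and test (y) values, e.g. mat vs app stride times."""

    x: np.ndarray
    y: np.ndarray
    unit: str = "s"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise DegenerateInputError("x and y must be 1-D arrays of equal length")
        if np.isnan(self.x).any() or np.isnan(self.y).any():
            raise DegenerateInputError("missing values in paired measurements")

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class PassingBablokResult:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    n: int
    n_undefined_skipped: int = 0


@dataclass
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd: float
    n: int
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)


class ICCType(str, Enum):
    ICC_1_1 = "ICC(1,1)"
    ICC_1_K = "ICC(1,k)"


@dataclass
class ICCResult:
    icc: float
    type: ICCType
    n: int
    k: int
    ci_low: float
    ci_high: float
    p: float
    msb: float
    msw: float
    f: float


@dataclass
class AgreementResult:
    """Full validity battery for one paired dataset."""

    passing_bablok: PassingBablokResult
    bland_altman: BlandAltmanResult
    r_squared: float
    n: int

    def to_dict(self) -> dict:
        pb, ba = self.passing_bablok, self.bland_altman
        return {
            "n": self.n,
            "pb_slope": pb.slope,
            "pb_slope_ci": list(pb.slope_ci),
            "pb_intercept": pb.intercept,
            "pb_intercept_ci": list(pb.intercept_ci),
            "ba_bias": ba.bias,
            "ba_loa_low": ba.loa_low,
            "ba_loa_high": ba.loa_high,
            "r_squared": self.r_squared,
        }


def passing_bablok(data: PairedMeasurements, alpha: float = 0.05) -> PassingBablokResult:
    """Passing-Bablok regression of y on x.

    All pairwise slopes ``S_ij = (y_j - y_i) / (x_j - x_i)`` for ``i < j``
    are formed; slopes of exactly -1 are discarded and pairs with tied x
    are skipped (counted). The slope estimate is the median of the sorted
    slopes shifted by ``K``, the number of slopes below -1 — this offset
    makes the estimator invariant to swapping the roles of x and y. The
    intercept is ``median(y_i - slope * x_i)``. Confidence bounds use the
    classical rank-based normal approximation with
    ``C = z_{1-alpha/2} * sqrt(n (n-1) (2n+5) / 18)``.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 pairs.
    DegenerateInputError
        All x identical, or no valid pairwise slopes.
    """
    n = len(data)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {n}")
    x, y = data.x, data.y
    if np.all(x == x[0]):
        raise DegenerateInputError("all x values identical")

    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    defined = dx != 0
    n_skipped = int(np.sum(~defined))
    if n_skipped:
        logger.info("passing_bablok: skipped %d pair(s) with tied x", n_skipped)
    slopes = dy[defined] / dx[defined]
    slopes = slopes[slopes != -1.0]
    if len(slopes) == 0:
        raise DegenerateInputError("no valid pairwise slopes")
    slopes = np.sort(slopes)
    n_slopes = len(slopes)
    k_offset = int(np.sum(slopes < -1.0))

    # Shifted median (1-indexed ranks offset by K, then converted to 0-based).
    if n_slopes % 2 == 1:
        slope = slopes[np.clip((n_slopes + 1) // 2 + k_offset - 1, 0, n_slopes - 1)]
    else:
        lo = np.clip(n_slopes // 2 + k_offset - 1, 0, n_slopes - 1)
        hi = np.clip(n_slopes // 2 + k_offset, 0, n_slopes - 1)
        slope = 0.5 * (slopes[lo] + slopes[hi])

    z = stats.norm.ppf(1 - alpha / 2)
    c = z * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(round((n_slopes - c) / 2.0))
    m2 = n_slopes - m1 + 1
    lo_idx = np.clip(m1 + k_offset - 1, 0, n_slopes - 1)
    hi_idx = np.clip(m2 + k_offset - 1, 0, n_slopes - 1)
    slope_ci = (float(slopes[lo_idx]), float(slopes[hi_idx]))

    intercept = float(np.median(y - slope * x))
    # Higher slope pulls the intercept down, so the bounds swap roles.
    a_from_hi = float(np.median(y - slope_ci[1] * x))
    a_from_lo = float(np.median(y - slope_ci[0] * x))
    intercept_ci = (min(a_from_hi, a_from_lo), max(a_from_hi, a_from_lo))

    return PassingBablokResult(
        slope=float(slope), intercept=intercept,
        slope_ci=slope_ci, intercept_ci=intercept_ci,
        n=n, n_undefined_skipped=n_skipped,
    )


def bland_altman(data: PairedMeasurements) -> BlandAltmanResult:
    """Bland-Altman bias and 95% limits of agreement for y - x.

    Raises
    ------
    InsufficientDataError
        Fewer than 2 pairs.
    """
    if len(data) < 2:
        raise InsufficientDataError("need >= 2 pairs for Bland-Altman")
    d = data.y - data.x
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd=sd,
        n=len(data),
        means=(data.x + data.y) / 2.0,
        diffs=d,
    )


def bland_altman_plot(result: BlandAltmanResult, ax=None, unit: str = "s"):
    """Scatter of per-pair difference vs mean with bias and LoA lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(result.means, result.diffs, s=12, alpha=0.7)
    ax.axhline(result.bias, color="k", lw=1, label=f"bias = {result.bias:.4g} {unit}")
    for y, label in ((result.loa_low, "LoA"), (result.loa_high, None)):
        ax.axhline(y, color="k", lw=1, ls="--", label=label)
    ax.set_xlabel(f"mean of methods ({unit})")
    ax.set_ylabel(f"difference, test - reference ({unit})")
    ax.legend(loc="best", frameon=False)
    return ax


def icc_oneway(table: np.ndarray, icc_type: ICCType = ICCType.ICC_1_1,
               alpha: float = 0.05) -> ICCResult:
    """One-way random-effects intraclass correlation (Shrout-Fleiss case 1).

    ``table`` has one row per subject and one column per repeated
    measurement. From the one-way ANOVA decomposition with between-subject
    mean square MSB (df ``n-1``) and within-subject mean square MSW (df
    ``n(k-1)``):

    * ``ICC(1,1) = (MSB - MSW) / (MSB + (k-1) MSW)`` — reliability of a
      single measurement;
    * ``ICC(1,k) = (MSB - MSW) / MSB`` — reliability of the k-measurement
      average.

    The 95% CI and p-value come from the F distribution of ``MSB/MSW``.
    Negative estimates are reported as computed, not truncated.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 subjects or 2 columns.
    DegenerateInputError
        Incomplete table, or all values identical (MSB = MSW = 0).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise DegenerateInputError("table must be 2-D (subjects x measurements)")
    n, k = table.shape
    if n < 3 or k < 2:
        raise InsufficientDataError(f"need >= 3 subjects and >= 2 columns, got {n}x{k}")
    if np.isnan(table).any():
        raise DegenerateInputError("incomplete table: missing cells")

    grand = table.mean()
    row_means = table.mean(axis=1)
    msb = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msw = np.sum((table - row_means[:, None]) ** 2) / (n * (k - 1))
    if msb == 0 and msw == 0:
        raise DegenerateInputError("all values identical; ICC undefined")

    df1, df2 = n - 1, n * (k - 1)
    if msw == 0:
        # Perfect within-subject agreement: reliability is exactly 1.
        return ICCResult(icc=1.0, type=icc_type, n=n, k=k, ci_low=1.0, ci_high=1.0,
                         p=0.0, msb=float(msb), msw=0.0, f=np.inf)

    f_obs = msb / msw
    p = float(stats.f.sf(f_obs, df1, df2))
    f_lo = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    f_hi = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    if icc_type is ICCType.ICC_1_1:
        icc = (msb - msw) / (msb + (k - 1) * msw)
        ci = ((f_lo - 1) / (f_lo + k - 1), (f_hi - 1) / (f_hi + k - 1))
    else:
        icc = (msb - msw) / msb
        ci = (1 - 1 / f_lo, 1 - 1 / f_hi)
    return ICCResult(icc=float(icc), type=icc_type, n=n, k=k,
                     ci_low=float(ci[0]), ci_high=float(ci[1]), p=p,
                     msb=float(msb), msw=float(msw), f=float(f_obs))


def correlation_r2(data: PairedMeasurements) -> float:
    """Squared Pearson correlation between the two methods.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 pairs.
    DegenerateInputError
        Zero variance in x or y.
    """
    if len(data) < 3:
        raise InsufficientDataError("need >= 3 pairs for correlation")
    if np.std(data.x) == 0 or np.std(data.y) == 0:
        raise DegenerateInputError("zero variance; correlation undefined")
    r = stats.pearsonr(data.x, data.y).statistic
    return float(r ** 2)


def match_events(times_test: np.ndarray, times_ref: np.ndarray,
                 window_s: float = 0.25) -> list[tuple[int, int]]:
    """One-to-one nearest-neighbour matching of two event-time streams.

    Candidate pairs within ``window_s`` are accepted greedily in order of
    increasing |time difference|, each event used at most once. Returns
    ``(test_index, ref_index)`` pairs sorted by reference time.
    """
    times_test = np.asarray(times_test, dtype=float)
    times_ref = np.asarray(times_ref, dtype=float)
    cand = [(abs(tt - tr), i, j)
            for i, tt in enumerate(times_test)
            for j, tr in enumerate(times_ref)
            if abs(tt - tr) <= window_s]
    cand.sort()
    used_t: set[int] = set()
    used_r: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in cand:
        if i in used_t or j in used_r:
            continue
        used_t.add(i)
        used_r.add(j)
        pairs.append((i, j))
    pairs.sort(key=lambda p: p[1])
    return pairs


def paired_stride_times(hs_test: np.ndarray, hs_ref: np.ndarray,
                        window_s: float = 0.25) -> PairedMeasurements:
    """Build paired stride times from two heel-strike streams.

    Heel strikes are matched one-to-one within ``window_s``; a stride pair
    is kept when two consecutive reference heel strikes are matched to two
    consecutive test heel strikes.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 matched stride pairs.
    """
    hs_test = np.sort(np.asarray(hs_test, dtype=float))
    hs_ref = np.sort(np.asarray(hs_ref, dtype=float))
    pairs = match_events(hs_test, hs_ref, window_s)
    x, y = [], []
    for (i0, j0), (i1, j1) in zip(pairs, pairs[1:]):
        if j1 == j0 + 1 and i1 == i0 + 1:
            x.append(hs_ref[j1] - hs_ref[j0])
            y.append(hs_test[i1] - hs_test[i0])
    if len(x) < 3:
        raise InsufficientDataError(
            f"only {len(x)} matched stride pair(s); need at least 3")
    return PairedMeasurements(x=np.array(x), y=np.array(y))


def agreement_battery(data: PairedMeasurements) -> AgreementResult:
    """Passing-Bablok + Bland-Altman + r^2 on one paired dataset."""
    return AgreementResult(
        passing_bablok=passing_bablok(data),
        bland_altman=bland_altman(data),
        r_squared=correlation_r2(data),
        n=len(data),
    )
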