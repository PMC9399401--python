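"""Reliability and validity statistics for paired measurement systems.

Implements the agreement battery used to compare two measurements of the
same subjects (test vs retest within a system, or markerless vs
marker-based across systems), per angle:

* single-measure intraclass correlations in the McGraw-Wong notation —
  ICC(C,1), two-way consistency, and ICC(A,1), two-way absolute agreement —
  with 95% confidence intervals from the corresponding F distributions and
  a p-value for ICC = 0;
* SEM = pooled SD * sqrt(1 - ICC(A,1)) and the smallest detectable change
  SDC = 1.96 * sqrt(2) * SEM;
* Bland-Altman bias, 95% limits of agreement, and the proportional-bias
  slope (least-squares regression of differences on means);
* assumption-gated difference tests: Shapiro-Wilk normality and Levene
  (median-centred) homogeneity gates select a t-test when both pass and a
  Wilcoxon test otherwise, with Bonferroni adjustment across comparisons;
* the qualitative ICC bands: almost perfect 0.81-1.0, substantial
  0.61-0.80, moderate 0.41-0.60, fair 0.21-0.40, slight 0.00-0.20.

The ICC estimates and intervals are computed directly from the two-way
ANOVA mean squares (MS_rows, MS_cols, MS_error) rather than delegated to a
stats package, so every number in a report is auditable from the formulas
above.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import DataError, DegenerateError

__all__ = [
    "IccResult", "BlandAltmanResult", "DifferenceTestResult",
    "AngleAgreement", "AgreementReport", "icc", "sem_sdc", "bland_altman",
    "difference_test", "band", "compare_tables",
]

SDC_FACTOR = 1.96 * math.sqrt(2.0)

_BANDS = (
    (0.81, "almost perfect"),
    (0.61, "substantial"),
    (0.41, "moderate"),
    (0.21, "fair"),
    (0.00, "slight"),
)


def _as_pairs(data: np.ndarray) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DataError(f"expected an n x 2 table, got shape {arr.shape}")
    if arr.shape[0] < 3:
        raise DataError("need at least 3 subjects")
    if not np.all(np.isfinite(arr)):
        raise DataError("missing cells in a fitted pair")
    return arr


def _mean_squares(arr: np.ndarray) -> tuple[float, float, float, int, int]:
    """Two-way ANOVA mean squares: (MS_rows, MS_cols, MS_error, n, k)."""
    n, k = arr.shape
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((arr - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


@dataclass(frozen=True)
class IccResult:
    form: str               # "C1" or "A1"
    estimate: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n_subjects: int

    @property
    def band(self) -> str:
        return band(self.estimate)


def icc(data: np.ndarray, form: str = "A1", alpha: float = 0.05) -> IccResult:
    """Single-measure ICC with 95% CI for a balanced subjects x 2 table.

    ``form="C1"`` is two-way mixed consistency; ``form="A1"`` is two-way
    absolute agreement.  Both use the mean-square formulas, with confidence
    limits from the F distribution (the A,1 interval uses the
    Satterthwaite degrees of freedom).  Zero between-subject variance makes
    the ICC undefined and raises :class:`DegenerateError`.
    """
    arr = _as_pairs(data)
    msr, msc, mse, n, k = _mean_squares(arr)
    if msr <= 0:
        raise DegenerateError("zero between-subject variance: ICC undefined")

    if mse == 0 and (form == "C1" or msc == 0):
        # perfect (or perfectly consistent) agreement
        est = 1.0
        return IccResult(form, est, 1.0, 1.0, 0.0, n)

    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_obs = msr / mse if mse > 0 else math.inf
    p = float(stats.f.sf(f_obs, df1, df2)) if math.isfinite(f_obs) else 0.0

    if form == "C1":
        est = (msr - mse) / (msr + (k - 1) * mse)
        fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lower = (fl - 1) / (fl + k - 1)
        upper = (fu - 1) / (fu + k - 1)
    elif form == "A1":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        est = (msr - mse) / denom
        # Satterthwaite df for the A,1 interval
        a = (k * est) / (n * (1 - est)) if est < 1 else math.inf
        b = 1 + (k * est * (n - 1)) / (n * (1 - est)) if est < 1 else math.inf
        if math.isinf(a):
            lower = upper = 1.0
        else:
            num_v = (a * msc + b * mse) ** 2
            den_v = ((a * msc) ** 2 / (k - 1)
                     + (b * mse) ** 2 / ((n - 1) * (k - 1)))
            v = num_v / den_v if den_v > 0 else df2
            f2u = stats.f.ppf(1 - alpha / 2, df1, v)
            f2l = stats.f.ppf(1 - alpha / 2, v, df1)
            lower = (n * (msr - f2u * mse)
                     / (f2u * (k * msc + (k * n - k - n) * mse) + n * msr))
            upper = (n * (f2l * msr - mse)
                     / (k * msc + (k * n - k - n) * mse + n * f2l * msr))
    else:
        raise DataError(f"unknown ICC form {form!r}; use 'C1' or 'A1'")

    lower = float(np.clip(lower, -1.0, 1.0))
    upper = float(np.clip(upper, -1.0, 1.0))
    est = float(np.clip(est, -1.0, 1.0))
    return IccResult(form, est, min(lower, est), max(upper, est), p, n)


def sem_sdc(data: np.ndarray, icc_a1: float | None = None
            ) -> tuple[float, float]:
    """Standard error of measurement and smallest detectable change.

    SEM = pooled SD of both ratings * sqrt(1 - ICC(A,1));
    SDC = 1.96 * sqrt(2) * SEM.  The ICC is computed from ``data`` unless
    supplied.
    """
    arr = _as_pairs(data)
    if icc_a1 is None:
        icc_a1 = icc(arr, "A1").estimate
    pooled_sd = float(arr.std(ddof=1))
    sem = pooled_sd * math.sqrt(max(0.0, 1.0 - icc_a1))
    return sem, SDC_FACTOR * sem


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    slope: float            # proportional bias: diff ~ mean
    intercept: float
    n: int

    def table(self, a: np.ndarray, b: np.ndarray) -> pd.DataFrame:
        """Plot-ready per-pair table (mean, diff) plus the reference lines."""
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        mean = (a + b) / 2.0
        return pd.DataFrame({
            "mean": mean,
            "diff": a - b,
            "bias": self.bias,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "trend": self.intercept + self.slope * mean,
        })


def bland_altman(a: np.ndarray, b: np.ndarray) -> BlandAltmanResult:
    """Bland-Altman agreement between two paired measurements.

    Bias = mean(a - b); 95% limits of agreement = bias +/- 1.96 * SD of the
    differences (sample SD); the slope is the least-squares regression of
    differences on pair means and captures proportional bias.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("bland_altman: a and b must be equal-length 1-D")
    if len(a) < 3:
        raise DataError("bland_altman: need n >= 3 pairs")
    diff = a - b
    mean = (a + b) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.ptp(mean) > 0:
        slope, intercept = np.polyfit(mean, diff, 1)
    else:
        slope, intercept = 0.0, bias
    return BlandAltmanResult(bias=bias, sd_diff=sd,
                             loa_lower=bias - 1.96 * sd,
                             loa_upper=bias + 1.96 * sd,
                             slope=float(slope), intercept=float(intercept),
                             n=len(a))


@dataclass(frozen=True)
class DifferenceTestResult:
    test_name: str
    statistic: float
    p_value: float
    p_adjusted: float
    normality_p: tuple[float, float]
    homogeneity_p: float
    gates_passed: bool


def difference_test(a: np.ndarray, b: np.ndarray, *, paired: bool = True,
                    alpha: float = 0.05, comparisons: int = 1
                    ) -> DifferenceTestResult:
    """Assumption-gated two-sided difference test with Bonferroni correction.

    Shapiro-Wilk is run on each sample and Levene (median-centred) across
    the two; when every gate passes at ``alpha`` a t-test (paired or
    independent) is used, otherwise the Wilcoxon signed-rank
    (paired) / rank-sum (independent) test.  The adjusted p-value is
    min(1, p * comparisons).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise DataError("difference_test: need >= 3 observations per group")
    if paired and a.shape != b.shape:
        raise DataError("difference_test: paired groups must align")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if not paired or np.allclose(a, b):
            # no variance anywhere: report the trivial no-difference result
            name = "paired t-test" if paired else "independent t-test"
            return DifferenceTestResult(name, 0.0, 1.0, 1.0, (1.0, 1.0),
                                        1.0, True)
        raise DegenerateError("degenerate variance in both groups")

    sw_a = float(stats.shapiro(a).pvalue) if np.ptp(a) > 0 else 0.0
    sw_b = float(stats.shapiro(b).pvalue) if np.ptp(b) > 0 else 0.0
    lev = float(stats.levene(a, b, center="median").pvalue)
    gates = sw_a > alpha and sw_b > alpha and lev > alpha

    if gates:
        if paired:
            diff = a - b
            if np.ptp(diff) == 0:
                stat, p = 0.0, 1.0
            else:
                res = stats.ttest_rel(a, b)
                stat, p = float(res.statistic), float(res.pvalue)
            name = "paired t-test"
        else:
            res = stats.ttest_ind(a, b)
            stat, p = float(res.statistic), float(res.pvalue)
            name = "independent t-test"
    else:
        if paired:
            diff = a - b
            if np.ptp(diff) == 0 and np.all(diff == 0):
                stat, p, name = 0.0, 1.0, "wilcoxon signed-rank"
            else:
                res = stats.wilcoxon(a, b)
                stat, p = float(res.statistic), float(res.pvalue)
                name = "wilcoxon signed-rank"
        else:
            res = stats.ranksums(a, b)
            stat, p = float(res.statistic), float(res.pvalue)
            name = "wilcoxon rank-sum"

    return DifferenceTestResult(
        test_name=name, statistic=stat, p_value=p,
        p_adjusted=min(1.0, p * comparisons),
        normality_p=(sw_a, sw_b), homogeneity_p=lev, gates_passed=gates)


def band(icc_value: float) -> str:
    """Qualitative ICC band; lower edges inclusive; negatives flagged."""
    if icc_value < 0:
        return "below slight"
    if icc_value > 1:
        raise DataError(f"ICC {icc_value} > 1")
    for cut, label in _BANDS:
        if icc_value >= cut:
            return label
    return "slight"


# ---------------------------------------------------------------------------
# Reports

@dataclass
class AngleAgreement:
    """Agreement summary for one angle."""

    angle: str
    icc_type: str
    icc: float
    icc_ci_lower: float
    icc_ci_upper: float
    icc_p: float
    icc_band: str
    bias: float | None = None
    bias_ci_lower: float | None = None
    bias_ci_upper: float | None = None
    bias_p: float | None = None
    bias_p_adjusted: float | None = None
    bias_test: str | None = None
    sem: float | None = None
    sdc: float | None = None
    loa_lower: float | None = None
    loa_upper: float | None = None
    ba_slope: float | None = None


@dataclass
class AgreementReport:
    """Per-angle agreement battery for one comparison of two measurements."""

    mode: str                         # "test_retest" or "cross_system"
    angles: list[AngleAgreement] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"mode": self.mode, "angles": [asdict(a) for a in self.angles]}

    @classmethod
    def from_dict(cls, doc: dict) -> "AgreementReport":
        return cls(mode=doc["mode"],
                   angles=[AngleAgreement(**a) for a in doc["angles"]])

    def to_frame(self) -> pd.DataFrame:
        cols = [f.name for f in
                AngleAgreement.__dataclass_fields__.values()]  # type: ignore
        rows = [asdict(a) for a in self.angles]
        df = pd.DataFrame(rows, columns=list(cols))
        if self.mode == "test_retest":
            df = df.drop(columns=["sem", "sdc", "loa_lower", "loa_upper",
                                  "ba_slope", "bias", "bias_ci_lower",
                                  "bias_ci_upper", "bias_p",
                                  "bias_p_adjusted", "bias_test"])
        return df


def compare_tables(table_a: pd.DataFrame, table_b: pd.DataFrame,
                   mode: str = "cross_system", *, paired: bool = True,
                   alpha: float = 0.05) -> AgreementReport:
    """Run the agreement battery on two aligned participant x angle tables.

    ``test_retest`` mode reports ICC(C,1) per angle; ``cross_system`` mode
    reports bias (with CI and gated difference test), ICC(A,1), SEM, SDC and
    Bland-Altman numbers.  The Bonferroni correction spans the shared
    angles.  Tables must share participants (index) and angles (columns).
    """
    if mode not in ("test_retest", "cross_system"):
        raise DataError(f"unknown mode {mode!r}")
    shared = [c for c in table_a.columns if c in table_b.columns]
    if not shared:
        raise DataError("no shared angle columns")
    if not table_a.index.equals(table_b.index):
        raise DataError("misaligned participants between tables")
    form = "C1" if mode == "test_retest" else "A1"
    comparisons = len(shared)
    report = AgreementReport(mode=mode)
    for name in shared:
        a = table_a[name].to_numpy(float)
        b = table_b[name].to_numpy(float)
        keep = np.isfinite(a) & np.isfinite(b)
        a, b = a[keep], b[keep]
        if len(a) < 3:
            # angle undefined for most participants (e.g. a degenerate
            # constant signal): skip rather than fabricate a number
            continue
        pairs = np.column_stack([a, b])
        try:
            res = icc(pairs, form, alpha=alpha)
        except DegenerateError as exc:
            warnings.warn(f"angle {name}: {exc}; skipped", stacklevel=2)
            continue
        entry = AngleAgreement(
            angle=name, icc_type=res.form, icc=res.estimate,
            icc_ci_lower=res.ci_lower, icc_ci_upper=res.ci_upper,
            icc_p=res.p_value, icc_band=res.band)
        if mode == "cross_system":
            sem, sdc = sem_sdc(pairs, icc_a1=res.estimate)
            ba = bland_altman(a, b)
            test = difference_test(a, b, paired=paired, alpha=alpha,
                                   comparisons=comparisons)
            diff = a - b
            se = diff.std(ddof=1) / math.sqrt(len(diff))
            tcrit = stats.t.ppf(1 - alpha / 2, len(diff) - 1)
            entry.bias = ba.bias
            entry.bias_ci_lower = ba.bias - tcrit * se
            entry.bias_ci_upper = ba.bias + tcrit * se
            entry.bias_p = test.p_value
            entry.bias_p_adjusted = test.p_adjusted
            entry.bias_test = test.test_name
            entry.sem = sem
            entry.sdc = sdc
            entry.loa_lower = ba.loa_lower
            entry.loa_upper = ba.loa_upper
            entry.ba_slope = ba.slope
        report.angles.append(entry)
    return report
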