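"""Method-agreement and rater-reliability statistics for ROM measurements.

Implements the validation toolkit used to compare an automated goniometry
method against a clinical benchmark and to quantify inter-rater spread:

* mean difference (absolute by default, signed available),
* Pearson correlation and simple-regression R²,
* intraclass correlation from the two-way random-effects ANOVA model
  (absolute agreement or consistency, single or average measurement;
  the default ICC(2,1) = two-way random / single / agreement),
* per-subject coefficient of variation averaged across subjects,
* a paired two-sided Student t test,
* a normal-approximation sample-size formula for a paired design.

Interpretation bands follow the clinical cutoffs commonly used for ICC
(<0.20 unacceptable, 0.20–0.40 questionable, 0.40–0.60 good, 0.60–0.80
very good, ≥0.80 excellent) and CV (<10% low, 10–20% moderate, ≥20% high
variability); the published cutoff lists leave the boundaries between
bands unassigned, so each band is the half-open interval closed at its
lower printed cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, UndefinedStatisticError

__all__ = [
    "RaterMatrix",
    "AgreementReport",
    "ReliabilityReport",
    "mean_difference",
    "pearson",
    "icc_two_way_random",
    "interpret_icc",
    "mean_cv",
    "interpret_cv",
    "regression_r2",
    "paired_t_test",
    "power_sample_size",
    "consensus",
    "compare_methods",
    "rater_reliability",
]


@dataclass
class RaterMatrix:
    """A complete subjects × raters (or methods) table of measurements in degrees."""

    values: np.ndarray
    subject_ids: list[str] = field(default_factory=list)
    rater_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InputError(f"expected a 2D table, got shape {self.values.shape}")
        if np.isnan(self.values).any():
            raise InputError("incomplete matrix: missing cells are not supported")
        n, k = self.values.shape
        if not self.subject_ids:
            self.subject_ids = [f"S{i + 1}" for i in range(n)]
        if not self.rater_ids:
            self.rater_ids = [f"R{j + 1}" for j in range(k)]
        if len(self.subject_ids) != n or len(self.rater_ids) != k:
            raise InputError("id lists must match the table dimensions")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def k_raters(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RaterMatrix":
        return cls(df.to_numpy(dtype=float), [str(i) for i in df.index],
                   [str(c) for c in df.columns])

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "RaterMatrix":
        """Read a matrix CSV: first column subject ids, header row rater ids."""
        try:
            df = pd.read_csv(path, index_col=0)
        except (ValueError, pd.errors.ParserError) as exc:
            raise InputError(f"cannot parse rater matrix {path}: {exc}") from exc
        if df.isna().any().any():
            raise InputError(f"rater matrix {path} has missing cells")
        try:
            return cls.from_dataframe(df.astype(float))
        except ValueError as exc:
            raise InputError(f"non-numeric cell in rater matrix {path}: {exc}") from exc


def _as_vectors(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise InputError(f"length mismatch: {x.size} vs {y.size}")
    return x, y


def mean_difference(x: Sequence[float], y: Sequence[float], mode: str = "absolute") -> float:
    """Mean difference between two measurement methods, in degrees.

    ``absolute`` (default) is mean |x_i − y_i|; ``signed`` is mean (x_i − y_i).
    """
    x, y = _as_vectors(x, y)
    if x.size < 1:
        raise InputError("mean_difference needs at least one pair")
    if mode == "absolute":
        return float(np.mean(np.abs(x - y)))
    if mode == "signed":
        return float(np.mean(x - y))
    raise InputError(f"mode must be 'absolute' or 'signed', got {mode!r}")


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient in [−1, 1]."""
    x, y = _as_vectors(x, y)
    if x.size < 3:
        raise InputError(f"pearson needs at least 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation is undefined for a constant input")
    r = stats.pearsonr(x, y).statistic
    return float(np.clip(r, -1.0, 1.0))


def _anova_mean_squares(values: np.ndarray) -> tuple[float, float, float]:
    """Two-way (subjects × raters, one observation per cell) mean squares.

    Returns (MSR, MSC, MSE): between-subjects, between-raters, residual.
    """
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((values - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_two_way_random(
    m: RaterMatrix, form: str = "agreement", unit: str = "single"
) -> float:
    """Intraclass correlation under the two-way random-effects model.

    Subjects and raters are both treated as random samples.  The default
    ``form="agreement", unit="single"`` is ICC(2,1) — absolute agreement
    of single measurements; ``consistency`` ignores systematic rater
    offsets, and ``unit="average"`` rates the mean of the k raters.

    All four variants come from the two-way ANOVA mean squares
    (MSR between subjects, MSC between raters, MSE residual), e.g.

        ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n).
    """
    if m.n_subjects < 2 or m.k_raters < 2:
        raise InputError(
            f"ICC needs >= 2 subjects and >= 2 raters, got {m.n_subjects}×{m.k_raters}"
        )
    if form not in ("agreement", "consistency"):
        raise InputError(f"form must be 'agreement' or 'consistency', got {form!r}")
    if unit not in ("single", "average"):
        raise InputError(f"unit must be 'single' or 'average', got {unit!r}")
    n, k = m.n_subjects, m.k_raters
    msr, msc, mse = _anova_mean_squares(m.values)
    if form == "agreement":
        if unit == "single":
            denom = msr + (k - 1) * mse + k * (msc - mse) / n
        else:
            denom = msr + (msc - mse) / n
    else:
        denom = msr + (k - 1) * mse if unit == "single" else msr
    if denom == 0.0:
        # All cells identical: no variance anywhere; perfect agreement.
        return 1.0
    # Every variant is mathematically <= 1; trim the roundoff ulp.
    return float(min((msr - mse) / denom, 1.0))


_ICC_BANDS = [
    (0.20, "unacceptable"),
    (0.40, "questionable"),
    (0.60, "good"),
    (0.80, "very good"),
    (math.inf, "excellent"),
]


def interpret_icc(icc: float) -> str:
    """Clinical interpretation band for an ICC value (total over (−∞, 1])."""
    if icc > 1.0:
        raise InputError(f"ICC cannot exceed 1, got {icc}")
    for upper, label in _ICC_BANDS:
        if icc < upper:
            return label
    raise AssertionError("unreachable")


def mean_cv(m: RaterMatrix) -> float:
    """Average per-subject coefficient of variation across raters, in percent.

    CV_i = 100 · sd(row i) / mean(row i) with the sample (n−1) standard
    deviation; the result is the mean of CV_i over subjects.
    """
    means = m.values.mean(axis=1)
    if np.any(means == 0):
        raise UndefinedStatisticError("CV is undefined for a subject with zero mean")
    sds = m.values.std(axis=1, ddof=1)
    return float(np.mean(100.0 * sds / means))


def interpret_cv(cv_percent: float) -> str:
    """Variability band for a mean CV: <10% low, 10–20% moderate, ≥20% high."""
    if cv_percent < 0:
        raise InputError(f"CV cannot be negative, got {cv_percent}")
    if cv_percent < 10.0:
        return "low variability"
    if cv_percent < 20.0:
        return "moderate variability"
    return "high variability"


def regression_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """R² of the ordinary least-squares fit of y on x, in [0, 1]."""
    x, y = _as_vectors(x, y)
    if x.size < 3:
        raise InputError(f"regression needs at least 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise InputError("regression is undefined for constant x")
    if np.ptp(y) == 0:
        return 0.0  # SST = 0: the flat fit leaves nothing to explain
    r = stats.linregress(x, y).rvalue
    return float(np.clip(r * r, 0.0, 1.0))


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired Student t test on the differences x − y.

    Returns (t statistic, p value).  Raises for zero-variance differences,
    where the test is degenerate.
    """
    x, y = _as_vectors(x, y)
    if x.size < 2:
        raise InputError(f"paired t test needs at least 2 pairs, got {x.size}")
    d = x - y
    if np.ptp(d) == 0:
        raise UndefinedStatisticError(
            "paired t test is degenerate: the differences have zero variance"
        )
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def power_sample_size(
    delta: float, sd: float, alpha: float = 0.05, power: float = 0.85,
    method: str = "normal",
) -> int:
    """Sample size for a paired design detecting a mean difference ``delta``.

    With the default normal approximation,

        n = ceil( ((z_{1−α/2} + z_power) · sd / delta)² ).

    ``method="t"`` solves the noncentral-t power equation instead, which
    is slightly conservative (typically 1–2 subjects more).
    """
    if delta <= 0 or sd <= 0:
        raise InputError("delta and sd must be > 0")
    if not (0.0 < alpha < 1.0):
        raise InputError(f"alpha must lie in (0, 1), got {alpha}")
    if not (0.5 <= power < 1.0):
        raise InputError(f"power must lie in [0.5, 1), got {power}")
    if method == "normal":
        z_a = stats.norm.ppf(1.0 - alpha / 2.0)
        z_b = stats.norm.ppf(power)
        return int(math.ceil(((z_a + z_b) * sd / delta) ** 2))
    if method == "t":
        effect = delta / sd
        n = 2
        while n < 10_000:
            df = n - 1
            crit = stats.t.ppf(1.0 - alpha / 2.0, df)
            achieved = 1.0 - stats.nct.cdf(crit, df, effect * math.sqrt(n)) \
                + stats.nct.cdf(-crit, df, effect * math.sqrt(n))
            if achieved >= power:
                return n
            n += 1
        raise InputError("sample size search did not converge")
    raise InputError(f"method must be 'normal' or 't', got {method!r}")


def consensus(m: RaterMatrix) -> np.ndarray:
    """Per-subject mean across raters (the consensus measurement)."""
    return m.values.mean(axis=1)


@dataclass(frozen=True)
class AgreementReport:
    """Agreement between two measurement methods on the same subjects."""

    mean_difference: float
    mean_difference_signed: float
    pearson_r: float
    icc: float
    icc_label: str
    r_squared: float
    t_statistic: Optional[float]
    p_value: Optional[float]

    def to_dict(self) -> dict:
        return {
            "mean_difference_deg": self.mean_difference,
            "mean_difference_signed_deg": self.mean_difference_signed,
            "pearson_r": self.pearson_r,
            "icc": self.icc,
            "icc_label": self.icc_label,
            "r_squared": self.r_squared,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
        }

    def summary(self) -> str:
        t = "n/a (zero-variance differences)" if self.t_statistic is None \
            else f"t={self.t_statistic:.4f}, p={self.p_value:.4f}"
        return (
            f"mean difference: {self.mean_difference:.3f} deg "
            f"(signed {self.mean_difference_signed:+.3f})\n"
            f"Pearson r:       {self.pearson_r:.3f}\n"
            f"ICC(2,1):        {self.icc:.3f} ({self.icc_label})\n"
            f"regression R^2:  {self.r_squared:.4f}\n"
            f"paired t test:   {t}"
        )


@dataclass(frozen=True)
class ReliabilityReport:
    """Inter-rater reliability of one method across a panel of raters."""

    intraclass_cc: float
    icc_label: str
    mean_cv_percent: float
    cv_label: str

    def to_dict(self) -> dict:
        return {
            "intraclass_cc": self.intraclass_cc,
            "icc_label": self.icc_label,
            "mean_cv_percent": self.mean_cv_percent,
            "cv_label": self.cv_label,
        }

    def summary(self) -> str:
        return (
            f"intraclass CC: {self.intraclass_cc:.3f} ({self.icc_label})\n"
            f"mean CV:       {self.mean_cv_percent:.3f}% ({self.cv_label})"
        )


def compare_methods(
    x: Sequence[float],
    y: Sequence[float],
    icc_form: str = "agreement",
) -> AgreementReport:
    """Full agreement analysis between two methods' per-subject measurements.

    The between-method correlation coefficient is the two-way random ICC
    applied to the subjects × 2 (method) matrix.  The t test fields are
    None when the differences have zero variance (e.g. x == y).
    """
    x, y = _as_vectors(x, y)
    m = RaterMatrix(np.column_stack([x, y]), rater_ids=["method_x", "method_y"])
    icc = icc_two_way_random(m, form=icc_form, unit="single")
    try:
        t_stat, p = paired_t_test(x, y)
    except UndefinedStatisticError:
        t_stat, p = None, None
    return AgreementReport(
        mean_difference=mean_difference(x, y, "absolute"),
        mean_difference_signed=mean_difference(x, y, "signed"),
        pearson_r=pearson(x, y),
        icc=icc,
        icc_label=interpret_icc(icc),
        r_squared=regression_r2(x, y),
        t_statistic=t_stat,
        p_value=p,
    )


def rater_reliability(m: RaterMatrix, icc_form: str = "agreement") -> ReliabilityReport:
    """Inter-rater reliability: two-way random ICC plus the mean CV."""
    icc = icc_two_way_random(m, form=icc_form, unit="single")
    cv = mean_cv(m)
    return ReliabilityReport(
        intraclass_cc=icc,
        icc_label=interpret_icc(icc),
        mean_cv_percent=cv,
        cv_label=interpret_cv(cv),
    )
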