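"""Agreement and reliability statistics: RMSE, bias, RoM, ICC(3,1), box summaries.

Per-frame agreement between a test system and the optical reference is scored
with

    RMSE = sqrt( (1/n) * sum_i (test_i - ref_i)^2 )
    bias =       (1/n) * sum_i (test_i - ref_i)

over the analysis window, so RMSE reflects unstable frame-to-frame error and
bias reflects systematic offsets over time.  Trial-to-trial consistency of the
range of motion is scored with the intraclass correlation ICC(3,1) — two-way
mixed-effects, single measurement, consistency form — on a subjects x trials
matrix, with the 95% confidence interval from the standard F-distribution
bounds (Shrout-Fleiss construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import f as f_dist

from .errors import EmptySeriesError, IncompleteMatrixError, StreamMismatchError
from .kinematics import JointAngleSeries


@dataclass(frozen=True)
class PairedWindow:
    """Frame-matched test/reference angle windows for one channel."""

    test: np.ndarray
    reference: np.ndarray
    joint: str = ""
    dof: str = ""
    task: str = ""
    system: str = ""

    def __post_init__(self):
        object.__setattr__(self, "test", np.asarray(self.test, dtype=float).ravel())
        object.__setattr__(
            self, "reference", np.asarray(self.reference, dtype=float).ravel()
        )
        if self.test.shape != self.reference.shape:
            raise StreamMismatchError(
                f"paired window length mismatch: {self.test.shape} vs "
                f"{self.reference.shape}"
            )
        if self.n == 0:
            raise EmptySeriesError("paired window is empty")

    @property
    def n(self) -> int:
        return self.test.size

    @classmethod
    def from_series(
        cls, test: JointAngleSeries, reference: JointAngleSeries, task: str = ""
    ) -> "PairedWindow":
        """Pair two aligned series on their joint valid mask."""
        if len(test) != len(reference):
            raise StreamMismatchError(
                f"series length mismatch: {len(test)} vs {len(reference)}"
            )
        m = test.quality_mask & reference.quality_mask
        if not m.any():
            raise EmptySeriesError("no jointly valid samples")
        return cls(
            test=test.values[m],
            reference=reference.values[m],
            joint=test.joint,
            dof=test.dof,
            task=task,
            system=test.system,
        )


def rmse(w: PairedWindow) -> float:
    """Root-mean-square per-frame difference, degrees."""
    d = w.test - w.reference
    return float(np.sqrt(np.mean(d * d)))


def bias(w: PairedWindow) -> float:
    """Signed mean per-frame difference (test - reference), degrees."""
    return float(np.mean(w.test - w.reference))


def range_of_motion(series: JointAngleSeries) -> float:
    """Max minus min over the valid samples of the window, degrees."""
    v = series.valid_values()
    if v.size == 0:
        raise EmptySeriesError("range of motion needs at least one valid sample")
    return float(v.max() - v.min())


# ---------------------------------------------------------------------------
# ICC(3,1)
# ---------------------------------------------------------------------------

#: Category thresholds: < 0.4 weak; [0.4, 0.75) moderate; >= 0.75 strong.
ICC_WEAK_BELOW = 0.4
ICC_STRONG_FROM = 0.75


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    category: str
    degenerate: bool = False  # zero error mean square (ICC pinned at 1)


def classify_icc(value: float) -> str:
    """Strength category for an ICC estimate."""
    if not np.isfinite(value):
        raise ValueError("ICC value must be finite")
    if value < ICC_WEAK_BELOW:
        return "weak"
    if value < ICC_STRONG_FROM:
        return "moderate"
    return "strong"


def icc_3_1(matrix, alpha: float = 0.05) -> ICCResult:
    """ICC(3,1) with 95% CI from a complete subjects x trials RoM matrix.

    With BMS the between-subjects mean square and EMS the residual mean square
    of the two-way (subjects x trials, no interaction) decomposition:

        ICC(3,1) = (BMS - EMS) / (BMS + (k - 1) * EMS)

    The CI follows the F-bound construction: F = BMS/EMS with (n-1, (n-1)(k-1))
    degrees of freedom.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise IncompleteMatrixError("expected a 2-D subjects x trials matrix")
    n, k = m.shape
    if n < 2 or k < 2:
        raise IncompleteMatrixError("need >= 2 subjects and >= 2 trials")
    if not np.all(np.isfinite(m)):
        raise IncompleteMatrixError("matrix contains missing/non-finite cells")

    grand = m.mean()
    ss_rows = k * float(((m.mean(axis=1) - grand) ** 2).sum())
    ss_cols = n * float(((m.mean(axis=0) - grand) ** 2).sum())
    ss_total = float(((m - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols

    bms = ss_rows / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))

    if ems <= 0 or np.isclose(ems, 0.0, atol=1e-14 * max(1.0, abs(bms))):
        return ICCResult(
            icc=1.0, ci_low=1.0, ci_high=1.0, category="strong", degenerate=True
        )

    icc = (bms - ems) / (bms + (k - 1) * ems)
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_obs = bms / ems
    fl = f_obs / f_dist.ppf(1 - alpha / 2, df1, df2)
    fu = f_obs * f_dist.ppf(1 - alpha / 2, df2, df1)
    ci_low = (fl - 1) / (fl + k - 1)
    ci_high = (fu - 1) / (fu + k - 1)
    return ICCResult(
        icc=float(icc),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        category=classify_icc(float(icc)),
    )


# ---------------------------------------------------------------------------
# distribution summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoxplotSummary:
    """Tukey box-and-whisker summary of a value distribution (degrees)."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...] = field(default_factory=tuple)
    n: int = 0


def boxplot_summary(values) -> BoxplotSummary:
    """Median, quartiles (linear interpolation), 1.5*IQR whiskers, outliers."""
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise EmptySeriesError("boxplot summary of an empty value set")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = tuple(sorted(float(x) for x in v[(v < lo_fence) | (v > hi_fence)]))
    return BoxplotSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
        n=int(v.size),
    )
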