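"""Paired statistical comparison of electrode reconstruction methods.

The unit of analysis is one electrode (one hemisphere of one patient) whose
four contact coordinates have been averaged into a single point per method.
Comparisons follow a normality-gated ladder:

* per-axis two-method comparison: Lilliefors-corrected Kolmogorov–Smirnov
  normality check on the paired differences, then paired t-test if normal,
  Wilcoxon signed-rank otherwise;
* three-condition comparison (e.g. two reconstruction methods plus an
  intraoperative reference distance): repeated-measures ANOVA with Tukey
  HSD on the within-subject error term when all pairwise difference sets
  are normal, otherwise Friedman with Dunn's pairwise z-tests and a
  Bonferroni adjustment over the three pairs.

Pooling across hemispheres ("all" scope) uses per-axis magnitudes, because
the two sides carry opposite signs under the reporting convention; "left"
and "right" scopes use the display-convention signed values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .acpc import AXES, Hemisphere, Point3, display_point, pool_magnitude

__all__ = [
    "ComparisonResult",
    "DistanceValidationRecord",
    "NormalityResult",
    "PairedCoordinateTable",
    "consistency_rate",
    "distance_validation",
    "ks_normality",
    "mean_discrepancy",
    "paired_axis_test",
    "subregion_rate",
    "three_method_posthoc",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05
_ZERO_VAR_TOL = 1e-12


@dataclass(frozen=True)
class NormalityResult:
    normal: bool
    statistic: float
    p_value: float


def ks_normality(sample: Sequence[float]) -> NormalityResult:
    """Lilliefors-corrected KS test for normality with estimated parameters.

    The plain one-sample KS test is anti-conservative when the normal
    parameters are estimated from the same sample, so the Lilliefors
    correction is used.  ``normal`` is ``p >= 0.05``.
    """
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("normality assessment requires at least 4 observations")
    if float(np.std(x, ddof=1)) < _ZERO_VAR_TOL:
        raise ValueError("sample has zero standard deviation")
    stat, p = lilliefors(x, dist="norm")
    return NormalityResult(normal=bool(p >= ALPHA), statistic=float(stat), p_value=float(p))


def mean_discrepancy(mean_a: float, mean_b: float, ndigits: int = 2) -> float:
    """Reported between-method discrepancy: ``mean_b - mean_a`` rounded.

    Summary tables print discrepancies to 2 decimals; internal computation
    stays at full precision and rounds only here.
    """
    return round(float(mean_b) - float(mean_a), ndigits)


@dataclass(frozen=True)
class ComparisonResult:
    """One pairwise comparison on one axis/scope."""

    axis: str
    scope: str
    method_a: str
    method_b: str
    mean_a: float
    mean_b: float
    mean_discrepancy: float  # mean_b - mean_a on the values actually compared
    test_name: str
    statistic: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class DistanceValidationRecord:
    """Tip-to-planned-target distances for one electrode under each method,
    plus the intraoperative microelectrode-recording (MER) depth reference."""

    patient_id: str
    side: Hemisphere
    euclid_method_a: float
    euclid_method_b: float
    mer_distance: float

    def __post_init__(self) -> None:
        for name in ("euclid_method_a", "euclid_method_b", "mer_distance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


class PairedCoordinateTable:
    """Per-electrode averaged contact coordinates under two or more methods.

    Wraps a DataFrame with columns ``patient_id, side, method, x, y, z``
    (AC-PC mm, signed canonical convention), exactly one row per
    (patient, side, method).
    """

    COLUMNS = ("patient_id", "side", "method", "x", "y", "z")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["side"] = df["side"].map(
            lambda s: s if isinstance(s, Hemisphere) else Hemisphere(str(s))
        )
        if df.duplicated(subset=["patient_id", "side", "method"]).any():
            raise ValueError("duplicate (patient_id, side, method) rows")
        if not np.isfinite(df[["x", "y", "z"]].to_numpy(float)).all():
            raise ValueError("non-finite coordinates")
        self.df = df

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, Hemisphere, str, Point3]],
    ) -> "PairedCoordinateTable":
        rows = [
            {
                "patient_id": pid,
                "side": side,
                "method": method,
                "x": p.x,
                "y": p.y,
                "z": p.z,
            }
            for pid, side, method, p in records
        ]
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    @property
    def methods(self) -> list[str]:
        return sorted(self.df["method"].unique())

    def axis_values(self, axis: str, scope: str) -> pd.DataFrame:
        """Per-electrode values of one axis, methods as columns.

        scope "all": magnitude pooling across both sides; scope "left" /
        "right": display-convention signed values of that side only.  Only
        electrodes present under every method are kept (listwise).
        """
        if axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}")
        if scope not in ("all", "left", "right"):
            raise ValueError("scope must be 'all', 'left' or 'right'")
        df = self.df
        if scope in ("left", "right"):
            df = df[df["side"] == Hemisphere(scope)]

        def value(row) -> float:
            p = Point3(row["x"], row["y"], row["z"])
            if scope == "all":
                return pool_magnitude([(p, row["side"])], axis)[0]
            return getattr(display_point(p, row["side"]), axis)

        df = df.assign(value=df.apply(value, axis=1))
        wide = df.pivot_table(
            index=["patient_id", "side"], columns="method", values="value",
            aggfunc="first",
        )
        n_before = len(wide)
        wide = wide.dropna()
        dropped = n_before - len(wide)
        if dropped:
            logger.warning(
                "dropped %d electrode(s) with incomplete method coverage", dropped
            )
        return wide


def _paired_two_sample(
    a: np.ndarray, b: np.ndarray, test: str
) -> tuple[str, float, float]:
    """Normality-gated paired test on ``b - a``; returns (name, stat, p)."""
    diff = b - a
    n = len(diff)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    sd = float(np.std(diff, ddof=1))
    if sd < _ZERO_VAR_TOL:
        # constant differences: no sampling variability to test against
        return ("paired_t", 0.0 if abs(diff.mean()) < _ZERO_VAR_TOL else np.inf,
                1.0 if abs(diff.mean()) < _ZERO_VAR_TOL else 0.0)
    if test == "auto":
        if n >= 4:
            test = "t" if ks_normality(diff).normal else "wilcoxon"
        else:
            test = "t"  # too few pairs to assess normality
    if test == "t":
        res = stats.ttest_rel(b, a)
        return "paired_t", float(res.statistic), float(res.pvalue)
    if test == "wilcoxon":
        res = stats.wilcoxon(b, a)
        return "wilcoxon_signed_rank", float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def paired_axis_test(
    table: PairedCoordinateTable,
    axis: str,
    scope: str,
    method_a: str,
    method_b: str,
    test: Literal["auto", "t", "wilcoxon"] = "auto",
) -> ComparisonResult:
    """Compare one coordinate axis between two methods on matched electrodes.

    Differences are ``method_b - method_a``.  With ``test="auto"`` the
    paired t-test is used when the differences pass the normality check and
    the Wilcoxon signed-rank test otherwise.
    """
    wide = table.axis_values(axis, scope)
    for m in (method_a, method_b):
        if m not in wide.columns:
            raise ValueError(f"method {m!r} not present in table")
    a = wide[method_a].to_numpy(float)
    b = wide[method_b].to_numpy(float)
    if len(a) < 2:
        raise ValueError("fewer than 2 matched pairs")
    name, statistic, p = _paired_two_sample(a, b, test)
    return ComparisonResult(
        axis=axis,
        scope=scope,
        method_a=method_a,
        method_b=method_b,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        mean_discrepancy=float(b.mean() - a.mean()),
        test_name=name,
        statistic=statistic,
        p_value=p,
        n=len(a),
    )


def _diffs_all_normal(X: np.ndarray) -> bool:
    """Gate for the parametric branch: all pairwise difference sets normal.

    Zero-variance difference sets carry no evidence against normality and
    pass the gate; with fewer than 4 subjects the check cannot run and the
    parametric branch is used.
    """
    n, k = X.shape
    if n < 4:
        return True
    for i in range(k):
        for j in range(i + 1, k):
            d = X[:, j] - X[:, i]
            if float(np.std(d, ddof=1)) < _ZERO_VAR_TOL:
                continue
            if not ks_normality(d).normal:
                return False
    return True


def _tukey_pairs(X: np.ndarray, labels: Sequence[str]) -> list[tuple]:
    """Repeated-measures ANOVA + Tukey HSD on the within-subject error term."""
    n, k = X.shape
    grand = X.mean()
    subj = X.mean(axis=1, keepdims=True)
    cond = X.mean(axis=0, keepdims=True)
    resid = X - subj - cond + grand
    df_err = (n - 1) * (k - 1)
    mse = float((resid**2).sum() / df_err)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            delta = float(X[:, j].mean() - X[:, i].mean())
            if mse < 1e-15:
                q = 0.0 if abs(delta) < 1e-12 else np.inf
                p = 1.0 if abs(delta) < 1e-12 else 0.0
            else:
                q = abs(delta) / np.sqrt(mse / n)
                p = float(stats.studentized_range.sf(q, k, df_err))
            out.append((labels[i], labels[j], delta, "tukey_hsd", q, p))
    return out


def _dunn_pairs(X: np.ndarray, labels: Sequence[str]) -> list[tuple]:
    """Friedman test followed by Dunn's pairwise z-tests (Bonferroni x3)."""
    n, k = X.shape
    fried_stat, fried_p = stats.friedmanchisquare(*(X[:, i] for i in range(k)))
    logger.info("Friedman chi2=%.4f p=%.4g (n=%d, k=%d)", fried_stat, fried_p, n, k)
    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    n_pairs = k * (k - 1) // 2
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            delta = float(X[:, j].mean() - X[:, i].mean())
            z = float((mean_ranks[j] - mean_ranks[i]) / se)
            p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))) * n_pairs)
            out.append((labels[i], labels[j], delta, "dunn", z, p))
    return out


def _posthoc_from_wide(
    wide: pd.DataFrame,
    axis: str,
    scope: str,
    force: Literal["auto", "tukey", "dunn"] = "auto",
) -> list[ComparisonResult]:
    if wide.shape[1] != 3:
        raise ValueError("post-hoc ladder requires exactly 3 conditions")
    if len(wide) < 3:
        raise ValueError("fewer than 3 complete subjects")
    labels = list(wide.columns)
    X = wide.to_numpy(float)
    if force == "auto":
        branch = "tukey" if _diffs_all_normal(X) else "dunn"
    else:
        branch = force
    pairs = _tukey_pairs(X, labels) if branch == "tukey" else _dunn_pairs(X, labels)
    results = []
    for la, lb, delta, name, statistic, p in pairs:
        results.append(
            ComparisonResult(
                axis=axis,
                scope=scope,
                method_a=la,
                method_b=lb,
                mean_a=float(wide[la].mean()),
                mean_b=float(wide[lb].mean()),
                mean_discrepancy=delta,
                test_name=name,
                statistic=float(statistic),
                p_value=float(p),
                n=len(wide),
            )
        )
    return results


def three_method_posthoc(
    table: PairedCoordinateTable,
    axis: str,
    scope: str = "all",
    force: Literal["auto", "tukey", "dunn"] = "auto",
) -> list[ComparisonResult]:
    """All three pairwise comparisons among exactly three methods.

    Incomplete method triplets are dropped listwise (with a logged count).
    The parametric (Tukey) branch is taken when every pairwise difference
    set passes the normality check, the rank-based (Dunn) branch otherwise;
    ``force`` overrides the gate.
    """
    if len(table.methods) != 3:
        raise ValueError("three_method_posthoc requires exactly 3 methods")
    wide = table.axis_values(axis, scope)
    return _posthoc_from_wide(wide, axis=axis, scope=scope, force=force)


def distance_validation(
    records: Sequence[DistanceValidationRecord],
    force: Literal["auto", "tukey", "dunn"] = "auto",
) -> list[ComparisonResult]:
    """Compare both methods' tip-to-target distances against the MER depth.

    The three distances per electrode are treated as three paired
    conditions and run through the same post-hoc ladder as the coordinate
    comparisons.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 complete records")
    wide = pd.DataFrame(
        {
            "euclid_a": [r.euclid_method_a for r in records],
            "euclid_b": [r.euclid_method_b for r in records],
            "mer": [r.mer_distance for r in records],
        },
        index=pd.MultiIndex.from_tuples(
            [(r.patient_id, r.side.value) for r in records],
            names=["patient_id", "side"],
        ),
    )
    return _posthoc_from_wide(wide, axis="distance", scope="all", force=force)


def consistency_rate(
    categories_a: Sequence[str], categories_b: Sequence[str]
) -> tuple[float, float]:
    """Fraction and percentage of index-matched equal categorical calls.

    Returns ``(fraction, percent)`` with the percentage rounded to one
    decimal, the convention used for reported agreement rates.
    """
    if len(categories_a) != len(categories_b):
        raise ValueError("category lists have different lengths")
    if len(categories_a) == 0:
        raise ValueError("empty category lists")
    matches = sum(a == b for a, b in zip(categories_a, categories_b))
    frac = matches / len(categories_a)
    return frac, round(100.0 * frac, 1)


def subregion_rate(labels: Sequence[str]) -> float:
    """Percentage of contacts labelled ``dorsolateral`` (1-decimal rounding)."""
    if len(labels) == 0:
        raise ValueError("empty label list")
    return round(100.0 * sum(l == "dorsolateral" for l in labels) / len(labels), 1)
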