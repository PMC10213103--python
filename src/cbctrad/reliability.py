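"""ICC-based repeatability/reproducibility screening and cohort comparison.

The reliability statistic is the two-way mixed-effects intraclass correlation
with absolute agreement (McGraw & Wong): single measures

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

and average measures

    ICC(A,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n),

where MSR/MSC/MSE are the rows (subjects), columns (raters) and residual mean
squares of the two-way ANOVA on an n × k measurement matrix.  95% confidence
bounds use the F-distribution method: a Satterthwaite-approximate F for the
single form, and the Spearman–Brown transform of the single-form bounds for
the average form.

A feature is *reliable* when ICC > 0.8 and *highly robust* when additionally
the lower 95% bound exceeds 0.7 (strict inequalities).  Features that are
constant over the whole measurement matrix have no defined ICC; they are
flagged degenerate and excluded from reliable/robust sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

LABELS = ("not_reliable", "reliable", "robust")


# --------------------------------------------------------------------------
# ICC
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasurementMatrix:
    """n subjects × k raters of one quantity; no missing cells."""

    values: np.ndarray
    subject_ids: tuple | None = None
    rater_labels: tuple | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("measurement matrix must be 2-D (subjects × raters)")
        n, k = v.shape
        if n < 2 or k < 2:
            raise ValueError(f"need n >= 2 subjects and k >= 2 raters, got {n} × {k}")
        if not np.all(np.isfinite(v)):
            raise ValueError("measurement matrix contains non-finite cells")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    form: str          # "single" | "average"
    msr: float
    msc: float
    mse: float
    n: int
    k: int
    agreement: str = "absolute"
    degenerate: bool = False


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    n, k = x.shape
    gm = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(np.sum((row_means - gm) ** 2))
    ssc = n * float(np.sum((col_means - gm) ** 2))
    sst = float(np.sum((x - gm) ** 2))
    sse = max(0.0, sst - ssr - ssc)
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def icc_absolute(
    data: MeasurementMatrix | np.ndarray,
    form: str = "single",
    alpha: float = 0.05,
) -> ICCResult:
    """Two-way mixed-effects absolute-agreement ICC with 95% CI."""
    if form not in ("single", "average"):
        raise ValueError("form must be 'single' or 'average'")
    if not isinstance(data, MeasurementMatrix):
        data = MeasurementMatrix(np.asarray(data))
    x = data.values
    n, k = x.shape
    msr, msc, mse = _anova_mean_squares(x)

    scale = float(np.max(np.abs(x))) or 1.0
    if np.ptp(x) <= 1e-12 * scale:
        # every cell identical: perfect (but uninformative) agreement
        return ICCResult(1.0, 1.0, 1.0, form, msr, msc, mse, n, k, degenerate=True)

    denom_single = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc_single = (msr - mse) / denom_single if denom_single != 0 else 0.0

    if mse == 0.0 and msc <= 1e-300:
        lo_s, hi_s = 1.0, 1.0
        icc_single = 1.0
    else:
        r = min(icc_single, 1.0 - 1e-12)
        with np.errstate(all="ignore"):
            a = (k * r) / (n * (1.0 - r))
            b = 1.0 + (k * r * (n - 1.0)) / (n * (1.0 - r))
            num_v = (a * msc + b * mse) ** 2
            den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = num_v / den_v if den_v > 0 else (n - 1) * (k - 1)
            f1 = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
            f2 = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
            lo_s = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi_s = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
        # strongly negative ICCs can drive the Satterthwaite df towards zero
        # and the F quantile to overflow; fall back to the trivial bound
        lo_s = float(np.clip(lo_s, -1.0, 1.0)) if np.isfinite(lo_s) else -1.0
        hi_s = float(np.clip(hi_s, -1.0, 1.0)) if np.isfinite(hi_s) else 1.0

    if form == "single":
        icc, lo, hi = icc_single, lo_s, hi_s
    else:
        denom_avg = msr + (msc - mse) / n
        icc = (msr - mse) / denom_avg if denom_avg != 0 else 0.0
        # Spearman–Brown transform of the single-form bounds
        def sb(r1: float) -> float:
            d = 1.0 + (k - 1.0) * r1
            return k * r1 / d if d != 0 else 1.0
        lo, hi = sb(lo_s), sb(hi_s)
        if mse == 0.0 and msc <= 1e-300:
            icc, lo, hi = 1.0, 1.0, 1.0

    icc = float(min(icc, 1.0))
    lo = float(min(lo, icc))
    hi = float(max(hi, icc))
    return ICCResult(icc, lo, hi, form, msr, msc, mse, n, k)


def classify_reliability(result: ICCResult) -> str:
    """Reliability label: robust ⟺ ICC > 0.8 and lower 95% bound > 0.7."""
    if result.icc > 0.8 and result.ci_low > 0.7:
        return "robust"
    if result.icc > 0.8:
        return "reliable"
    return "not_reliable"


# --------------------------------------------------------------------------
# screening
# --------------------------------------------------------------------------

@dataclass
class ReliabilityRecord:
    feature: str
    condition: object
    result: ICCResult
    label: str
    degenerate: bool


@dataclass
class ReliabilityReport:
    """Per-feature ICC records and the derived reliable/robust feature sets."""

    records: list[ReliabilityRecord]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_name": [r.feature for r in self.records],
                "condition": [r.condition for r in self.records],
                "icc": [r.result.icc for r in self.records],
                "ci_low": [r.result.ci_low for r in self.records],
                "ci_high": [r.result.ci_high for r in self.records],
                "label": [r.label for r in self.records],
                "degenerate": [r.degenerate for r in self.records],
            }
        )

    @property
    def conditions(self) -> list:
        seen = []
        for r in self.records:
            if r.condition not in seen:
                seen.append(r.condition)
        return seen

    def _sets(self, labels: tuple[str, ...], condition) -> set[str]:
        return {
            r.feature
            for r in self.records
            if r.condition == condition and r.label in labels and not r.degenerate
        }

    def robust_set(self, condition) -> set[str]:
        return self._sets(("robust",), condition)

    def reliable_set(self, condition) -> set[str]:
        """Features with ICC > 0.8 (robust included)."""
        return self._sets(("reliable", "robust"), condition)

    def degenerate_set(self, condition) -> set[str]:
        return {r.feature for r in self.records if r.condition == condition and r.degenerate}

    def robust_intersection(self, conditions: list | None = None) -> set[str]:
        conds = conditions if conditions is not None else self.conditions
        sets = [self.robust_set(c) for c in conds]
        if not sets:
            return set()
        out = sets[0]
        for s in sets[1:]:
            out = out & s
        return out

    def summary(self) -> pd.DataFrame:
        rows = []
        for c in self.conditions:
            rows.append(
                {
                    "condition": c,
                    "n_reliable": len(self.reliable_set(c)),
                    "n_robust": len(self.robust_set(c)),
                    "n_degenerate": len(self.degenerate_set(c)),
                }
            )
        return pd.DataFrame(rows)


LONG_COLUMNS = ["roi_id", "condition", "replicate", "feature_name", "value"]


def _check_long(df: pd.DataFrame, need_replicate: bool = True) -> None:
    cols = set(LONG_COLUMNS if need_replicate else [c for c in LONG_COLUMNS if c != "replicate"])
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"long-format table missing columns: {sorted(missing)}")


def screen_features(table: pd.DataFrame) -> ReliabilityReport:
    """Scan–rescan repeatability screening.

    ``table`` is long-format with columns roi_id (subject), condition,
    replicate (scan/rescan), feature_name, value.  Per condition and feature
    an ICC(A,1) is computed across the replicate raters with ROIs as
    subjects.
    """
    _check_long(table)
    records: list[ReliabilityRecord] = []
    for cond, cdf in table.groupby("condition", sort=False):
        names = list(dict.fromkeys(cdf["feature_name"]))
        by_feature = {f: g for f, g in cdf.groupby("feature_name", sort=False)}
        for f in names:
            wide = by_feature[f].pivot(index="roi_id", columns="replicate", values="value")
            if wide.isna().any().any():
                raise ValueError(f"feature {f!r} in condition {cond!r} has missing cells")
            res = icc_absolute(wide.to_numpy(), form="single")
            label = classify_reliability(res)
            records.append(ReliabilityRecord(f, cond, res, label, res.degenerate))
    # feature-name sets must match across conditions
    by_cond = {}
    for r in records:
        by_cond.setdefault(r.condition, set()).add(r.feature)
    sets = list(by_cond.values())
    if any(s != sets[0] for s in sets[1:]):
        raise ValueError("feature name sets differ across conditions")
    return ReliabilityReport(records)


def reproducibility_screen(table: pd.DataFrame) -> ReliabilityReport:
    """Across-condition reproducibility screening on condition-averaged values.

    ``table`` is long-format with columns roi_id, condition, feature_name,
    value where each value is the mean of scan and rescan for that condition.
    Raters are the conditions; the ICC form is average measures over the k
    conditions.  The report carries a single pseudo-condition ``"all"``.
    """
    _check_long(table, need_replicate=False)
    conds = list(dict.fromkeys(table["condition"]))
    if len(conds) < 2:
        raise ValueError("reproducibility screening needs >= 2 conditions")
    records: list[ReliabilityRecord] = []
    for f, g in table.groupby("feature_name", sort=False):
        wide = g.pivot(index="roi_id", columns="condition", values="value")
        if wide.isna().any().any():
            raise ValueError(f"feature {f!r} has missing condition cells")
        res = icc_absolute(wide.to_numpy(), form="average")
        label = classify_reliability(res)
        records.append(ReliabilityRecord(f, "all", res, label, res.degenerate))
    return ReliabilityReport(records)


# --------------------------------------------------------------------------
# volume correlation
# --------------------------------------------------------------------------

def volume_correlation(
    feature_table: pd.DataFrame,
    volumes: np.ndarray,
    threshold: float = 0.8,
    absolute: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of each feature with segmentation volume.

    ``feature_table`` has one row per segmentation volume (aligned with
    ``volumes``, typically MeshVolume) and one column per feature.  A feature
    is flagged when r > threshold — the signed rule as printed in the source
    convention; ``absolute=True`` switches to |r| > threshold.  Constant
    features have undefined r and are recorded degenerate, never flagged.
    """
    volumes = np.asarray(volumes, dtype=np.float64)
    if len(volumes) < 3:
        raise ValueError("need >= 3 volumes for correlation analysis")
    if len(feature_table) != len(volumes):
        raise ValueError("feature_table rows must align with volumes")
    rows = []
    for col in feature_table.columns:
        y = feature_table[col].to_numpy(dtype=np.float64)
        degenerate = bool(np.ptp(y) <= 1e-12 * (np.max(np.abs(y)) or 1.0))
        if degenerate:
            r = np.nan
            flagged = False
        else:
            r = float(stats.pearsonr(volumes, y).statistic)
            flagged = (abs(r) if absolute else r) > threshold
        rows.append({"feature_name": col, "pearson_r": r, "flagged": flagged, "degenerate": degenerate})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# cohort comparison
# --------------------------------------------------------------------------

def compare_cohorts(
    table: pd.DataFrame,
    features: list[str] | None = None,
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Paired two-tailed t-test per feature between two cohort arms.

    ``table`` has columns cohort, subject, plus one column per feature;
    subjects are index-paired across the two arms (equal n).  Returns per
    feature the t statistic, p value and significance at ``alpha``
    (optionally Benjamini–Hochberg adjusted).
    """
    arms = list(dict.fromkeys(table["cohort"]))
    if len(arms) != 2:
        raise ValueError(f"expected exactly 2 cohorts, got {arms}")
    a = table[table["cohort"] == arms[0]].sort_values("subject")
    b = table[table["cohort"] == arms[1]].sort_values("subject")
    if len(a) != len(b):
        raise ValueError(f"unequal arm sizes ({len(a)} vs {len(b)}): pairing impossible")
    if features is None:
        features = [c for c in table.columns if c not in ("cohort", "subject")]
    rows = []
    for f in features:
        xa = a[f].to_numpy(dtype=np.float64)
        xb = b[f].to_numpy(dtype=np.float64)
        d = xa - xb
        if np.ptp(d) <= 1e-12 * (np.max(np.abs(d)) or 1.0) and np.allclose(d, 0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(xa, xb)
        rows.append({"feature_name": f, "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    if bh_correction and len(out):
        order = np.argsort(out["p"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        prev = 1.0
        for rank, idx in list(enumerate(order, start=1))[::-1]:
            prev = min(prev, out["p"].iloc[idx] * m / rank)
            adj[idx] = prev
        out["p_adjusted"] = adj
        out["significant"] = out["p_adjusted"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out
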