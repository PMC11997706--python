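"""Diagnostic performance and secondary statistical analyses.

Confusion-matrix metrics with Wilson score intervals, ROC/AUC with DeLong
intervals, two-sample t-tests on paired-feature distributions, covariate
association screens (Pearson/slope test for age, one-way ANOVA for
categorical covariates, chi-squared for cohort-composition tables), and
between-time-point correlation of donor profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .containers import SignalMatrix
from .model import _as_binary
from .pairing import PairedFeatureDef, compute_paired_features


@dataclass
class ConfusionCounts:
    """2x2 diagnostic confusion table (positive class = malignant)."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @classmethod
    def from_calls(cls, calls, labels) -> "ConfusionCounts":
        y = _as_binary(labels).astype(bool)
        c = np.asarray(calls, dtype=bool)
        return cls(
            tp=int((c & y).sum()),
            fn=int((~c & y).sum()),
            tn=int((~c & ~y).sum()),
            fp=int((c & ~y).sum()),
        )


@dataclass
class IntervalEstimate:
    """Point estimate with a confidence interval on the same scale."""

    point: float
    lower: float
    upper: float
    confidence: float = 0.95
    method: str = "wilson"

    def __post_init__(self) -> None:
        if not self.lower <= self.point <= self.upper:
            raise ValueError("interval must contain the point estimate")


def percent(x: float, decimals: int = 1) -> float:
    """Half-up percent rounding for report display (91.17647 -> 91.2)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(x * 100).quantize(q, rounding=ROUND_HALF_UP))


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Sensitivity, specificity, NPV, PPV, accuracy as fractions.

    A metric whose denominator is zero is reported as None (undefined),
    never silently as 0.
    """
    total = counts.tp + counts.fn + counts.tn + counts.fp
    return {
        "sensitivity": _ratio(counts.tp, counts.tp + counts.fn),
        "specificity": _ratio(counts.tn, counts.tn + counts.fp),
        "npv": _ratio(counts.tn, counts.tn + counts.fn),
        "ppv": _ratio(counts.tp, counts.tp + counts.fp),
        "accuracy": _ratio(counts.tp + counts.tn, total),
    }


def wilson_ci(successes: int, n: int, confidence: float = 0.95) -> IntervalEstimate:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    alpha = 1.0 - confidence
    lower, upper = proportion_confint(successes, n, alpha=alpha, method="wilson")
    return IntervalEstimate(
        point=successes / n,
        lower=float(np.clip(lower, 0.0, 1.0)),
        upper=float(np.clip(upper, 0.0, 1.0)),
        confidence=confidence,
        method="wilson",
    )


def roc_curve_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC curve and the Mann-Whitney AUC (ties counted one half).

    The curve is built from every distinct score threshold under the rule
    "score >= threshold is positive"; the AUC equals both the trapezoidal
    area under that curve and the probability that a random positive
    outscores a random negative, with ties contributing 1/2.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes")

    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    tpr = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    for k, t in enumerate(thresholds):
        pred = s >= t
        tpr[k] = (pred & y).sum() / n_pos
        fpr[k] = (pred & ~y).sum() / n_neg
    curve = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})

    # Mann-Whitney via midranks
    ranks = stats.rankdata(s)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return curve, float(auc)


def _placement_values(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels).astype(bool)
    pos, neg = s[y], s[~y]
    m, n = len(pos), len(neg)
    # V10_i = fraction of negatives strictly below pos_i, ties count 1/2
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    auc = v10.mean()
    return v10, v01, float(auc)


def delong_auc_ci(scores, labels, confidence: float = 0.95) -> IntervalEstimate:
    """DeLong nonparametric confidence interval for the AUC.

    Variance is estimated from the empirical variances of the placement
    values; the normal-approximation interval is clipped to [0, 1]. Perfect
    separation gives a degenerate zero-width interval at 1, reported rather
    than raised. The point estimate equals the Mann-Whitney AUC exactly.
    """
    y = _as_binary(labels).astype(bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("DeLong interval needs at least 2 subjects per class")
    v10, v01, _ = _placement_values(scores, labels)
    # same midrank formula as roc_curve_auc, so the points agree exactly
    s = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(s)
    n_pos, n_neg = len(v10), len(v01)
    auc = float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))
    s10 = v10.var(ddof=1)
    s01 = v01.var(ddof=1)
    var = s10 / len(v10) + s01 / len(v01)
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    half = z * np.sqrt(var)
    return IntervalEstimate(
        point=auc,
        lower=float(np.clip(auc - half, 0.0, 1.0)),
        upper=float(np.clip(auc + half, 0.0, 1.0)),
        confidence=confidence,
        method="delong",
    )


def two_sample_ttest(values_a, values_b, equal_var: bool = False) -> dict[str, float]:
    """Two-tailed two-sample t-test; Welch by default, pooled on request."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue)}


def chi_squared_table(table) -> dict[str, float]:
    """Pearson chi-squared on a contingency table, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    res = stats.chi2_contingency(obs, correction=False)
    return {"chi2": float(res.statistic), "df": float(res.dof), "p": float(res.pvalue)}


def covariate_associations(
    indices, covariates: pd.DataFrame, min_group_size: int = 2
) -> dict[str, dict]:
    """Association screen of the classifier index against clinical covariates.

    Numeric covariates (e.g. age) are tested by Pearson correlation with the
    two-tailed t-test on the regression slope; categorical covariates by
    one-way ANOVA after dropping groups smaller than ``min_group_size``. An
    all-constant covariate is flagged as undefined instead of erroring.
    """
    idx = pd.Series(np.asarray(indices, dtype=float), index=covariates.index)
    out: dict[str, dict] = {}
    for col in covariates.columns:
        v = covariates[col]
        if pd.api.types.is_numeric_dtype(v):
            x = v.to_numpy(dtype=float)
            if np.ptp(x[~np.isnan(x)]) == 0.0:
                out[col] = {"kind": "pearson", "defined": False}
                continue
            keep = ~np.isnan(x)
            fit = stats.linregress(x[keep], idx.to_numpy()[keep])
            out[col] = {
                "kind": "pearson",
                "defined": True,
                "r": float(fit.rvalue),
                "slope": float(fit.slope),
                "p_slope": float(fit.pvalue),
                "n": int(keep.sum()),
            }
        else:
            sizes = v.value_counts()
            kept_levels = sizes[sizes >= min_group_size].index
            groups = [idx[v == lev].to_numpy() for lev in kept_levels]
            pooled = np.concatenate(groups) if groups else np.empty(0)
            if len(groups) < 2 or pooled.size == 0 or np.ptp(pooled) == 0.0:
                out[col] = {"kind": "anova", "defined": False,
                            "n_groups": int(len(groups))}
                continue
            res = stats.f_oneway(*groups)
            out[col] = {
                "kind": "anova",
                "defined": bool(np.isfinite(res.statistic)),
                "F": float(res.statistic),
                "p": float(res.pvalue),
                "n_groups": int(len(groups)),
                "dropped_levels": [str(x) for x in sizes[sizes < min_group_size].index],
            }
    return out


def timepoint_correlation(
    matrix: SignalMatrix,
    metadata: pd.DataFrame,
    feature_defs: list[PairedFeatureDef],
) -> dict[str, dict[str, pd.DataFrame]]:
    """Per-donor Pearson correlation between time-point profiles.

    For every donor, correlates each pair of time points twice: over the raw
    log2 signals of the model's member miRNAs, and over the paired log2-ratio
    features. Both matrices are symmetric with unit diagonal. Requires at
    least two time points per donor and at least two features per profile.
    """
    if len(feature_defs) < 2:
        raise ValueError("need at least 2 paired features for correlation")
    member_mirnas: list[str] = []
    for d in feature_defs:
        for m in (d.mirna_i, d.mirna_j):
            if m not in member_mirnas:
                member_mirnas.append(m)
    paired = compute_paired_features(matrix.subset_mirnas(member_mirnas), feature_defs)
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for donor, grp in metadata.groupby("donor", sort=True):
        ids = grp.sort_values("timepoint").index.tolist()
        if len(ids) < 2:
            raise ValueError(f"donor {donor!r} has fewer than 2 time points")
        tp_names = [f"t{t}" for t in grp.sort_values("timepoint")["timepoint"]]
        sig = matrix.values.loc[ids, member_mirnas].T
        sig.columns = tp_names
        feat = paired.loc[ids].T
        feat.columns = tp_names
        out[str(donor)] = {
            "signals": sig.corr(method="pearson"),
            "paired": feat.corr(method="pearson"),
        }
    return out


def diagnostic_report(
    counts: ConfusionCounts, scores=None, labels=None, confidence: float = 0.95
) -> dict:
    """Bundle of headline metrics with Wilson (and optional DeLong) intervals.

    Fractions are reported full-precision alongside a display-rounded percent
    (half-up, one decimal), matching clinical-report convention.
    """
    metrics = confusion_metrics(counts)
    report: dict = {"counts": vars(counts).copy(), "metrics": {}}
    ci_inputs = {
        "sensitivity": (counts.tp, counts.tp + counts.fn),
        "specificity": (counts.tn, counts.tn + counts.fp),
        "npv": (counts.tn, counts.tn + counts.fn),
        "ppv": (counts.tp, counts.tp + counts.fp),
    }
    for name, value in metrics.items():
        entry: dict = {"fraction": value,
                       "percent": percent(value) if value is not None else None}
        if name in ci_inputs and value is not None:
            k, n = ci_inputs[name]
            ci = wilson_ci(k, n, confidence)
            entry["ci_lower_percent"] = percent(ci.lower)
            entry["ci_upper_percent"] = percent(ci.upper)
        report["metrics"][name] = entry
    if scores is not None and labels is not None:
        _, auc = roc_curve_auc(scores, labels)
        ci = delong_auc_ci(scores, labels, confidence)
        report["auc"] = {"point": auc, "ci_lower": ci.lower, "ci_upper": ci.upper,
                         "method": "delong"}
    return report
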