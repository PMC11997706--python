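"""Specimen- and miRNA-level quality control.

Implements the exclusion cascade applied before model development —
metadata-based exclusion (hemolysis, lack of pathology consensus,
non-eligible pathology category), the minimum detected-signal-count filter,
and the universal-detection screen on the training set — plus the
dilution-series linearity screen that qualifies miRNAs for pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .containers import SignalMatrix

#: pathology categories eligible for classifier development
ELIGIBLE_CATEGORIES = frozenset({"Benign", "Breast cancer"})
#: categories excluded from development (pre-cancerous / ambiguous lesions)
EXCLUDED_CATEGORIES = frozenset({"Other (in situ)", "Suspicious/atypical"})
KNOWN_CATEGORIES = ELIGIBLE_CATEGORIES | EXCLUDED_CATEGORIES


@dataclass
class ExclusionReport:
    """Outcome of one exclusion stage, mirroring a study-flowchart box."""

    stage: str
    subjects_in: int
    excluded: dict[str, str] = field(default_factory=dict)  # subject -> reason
    retained_ids: list[str] = field(default_factory=list)

    @property
    def subjects_excluded(self) -> int:
        return len(self.excluded)

    @property
    def subjects_out(self) -> int:
        return len(self.retained_ids)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "subjects_in": self.subjects_in,
            "subjects_excluded": self.subjects_excluded,
            "subjects_out": self.subjects_out,
            "reasons": dict(self.excluded),
        }


@dataclass
class LinearityResult:
    """Per-miRNA dilution-series regression summary.

    ``slope`` is log2 signal per log2 relative concentration (1.0 means the
    signal is directly proportional to input RNA); ``r_squared`` the ordinary
    coefficient of determination of the fit.
    """

    mirna_id: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    passed: bool

    def to_dict(self) -> dict:
        return {
            "mirna_id": self.mirna_id,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "passed": self.passed,
        }


def exclude_by_metadata(metadata: pd.DataFrame) -> ExclusionReport:
    """Exclude subjects unfit for algorithm development.

    A subject is removed when the specimen is hemolyzed, the pathology review
    reached no consensus, or the adjudicated category is a pre-cancerous or
    ambiguous lesion ("Other (in situ)" or "Suspicious/atypical"). Remaining
    subjects all carry category "Benign" or "Breast cancer". An unknown
    category label raises, naming the offending subject.
    """
    excluded: dict[str, str] = {}
    retained: list[str] = []
    for subject_id, row in metadata.iterrows():
        category = row["category"]
        if category not in KNOWN_CATEGORIES:
            raise ValueError(
                f"subject {subject_id!r} has unknown pathology category "
                f"{category!r}; expected one of {sorted(KNOWN_CATEGORIES)}"
            )
        if bool(row.get("hemolysis", False)):
            excluded[str(subject_id)] = "hemolysis"
        elif not bool(row.get("consensus", True)):
            excluded[str(subject_id)] = "no pathology consensus"
        elif category in EXCLUDED_CATEGORIES:
            excluded[str(subject_id)] = "category"
        else:
            retained.append(str(subject_id))
    return ExclusionReport(
        stage="metadata exclusion",
        subjects_in=len(metadata),
        excluded=excluded,
        retained_ids=retained,
    )


def filter_low_signal(matrix: SignalMatrix, min_detected: int = 250) -> ExclusionReport:
    """Exclude specimens with fewer than ``min_detected`` detected miRNAs.

    The boundary is inclusive on the keep side: a specimen with exactly
    ``min_detected`` signals is retained ("fewer than" excludes).
    """
    if matrix.n_mirna == 0:
        raise ValueError("signal matrix has no miRNA columns")
    counts = matrix.detected_counts()
    excluded = {
        str(sid): f"only {int(c)} detected miRNAs (< {min_detected})"
        for sid, c in counts.items()
        if c < min_detected
    }
    retained = [str(s) for s in counts.index if str(s) not in excluded]
    return ExclusionReport(
        stage="low signal count",
        subjects_in=matrix.n_subjects,
        excluded=excluded,
        retained_ids=retained,
    )


def filter_universal_detection(
    matrix: SignalMatrix, training_subject_ids
) -> list[str]:
    """miRNAs detected in 100% of the training specimens.

    Only the training set determines eligibility; detection status in held-out
    specimens is deliberately ignored so the screen cannot leak test-set
    information.
    """
    ids = list(training_subject_ids)
    if len(ids) == 0:
        raise ValueError("training set is empty")
    missing = set(ids) - set(matrix.subject_ids)
    if missing:
        raise ValueError(f"training ids not in matrix: {sorted(missing)}")
    det = matrix.detected.loc[ids]
    universal = det.all(axis=0)
    return [m for m in matrix.mirna_ids if universal[m]]


def assess_linearity(
    series: pd.DataFrame, r2_threshold: float = 0.975
) -> list[LinearityResult]:
    """Per-miRNA OLS of log2 signal on log2 relative concentration.

    All replicate points enter the regression individually (no replicate
    averaging). A miRNA passes when R^2 >= ``r2_threshold`` (inclusive).
    Raises when a miRNA has fewer than two distinct concentration levels,
    since the slope is then undefined.
    """
    results = []
    for mirna, grp in series.groupby("mirna_id", sort=True):
        x = grp["log2_concentration"].to_numpy(dtype=float)
        y = grp["log2_signal"].to_numpy(dtype=float)
        if len(pd.unique(x)) < 2:
            raise ValueError(
                f"miRNA {mirna!r} has fewer than 2 distinct concentrations; "
                "slope undefined"
            )
        fit = stats.linregress(x, y)
        # rvalue is the Pearson r of (x, y); its square is the OLS R^2
        r2 = float(fit.rvalue**2)
        results.append(
            LinearityResult(
                mirna_id=str(mirna),
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                r_squared=r2,
                n_points=len(x),
                passed=r2 >= r2_threshold,
            )
        )
    return results
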