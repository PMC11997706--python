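"""Slope-matched miRNA pair enumeration and log2-ratio features.

The classifier's explanatory variable is the within-subject difference of
log2 signals of two miRNAs whose dilution-series slopes agree within a
tolerance. Because the feature is a within-subject difference, any global
additive shift of a subject's log2 profile — RNA input amount, labeling or
hybridization efficiency — cancels exactly, which is what makes the approach
reference-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import SignalMatrix
from .qc import LinearityResult


@dataclass(frozen=True)
class PairedFeatureDef:
    """An ordered miRNA pair; the feature is log2(i) - log2(j).

    Enumeration canonicalizes orientation (``mirna_i < mirna_j``
    lexicographically); a fitted coefficient's sign absorbs direction.
    """

    mirna_i: str
    mirna_j: str
    slope_i: float = float("nan")
    slope_j: float = float("nan")

    def __post_init__(self) -> None:
        if self.mirna_i == self.mirna_j:
            raise ValueError("pair members must be distinct")

    @property
    def name(self) -> str:
        return f"{self.mirna_i}|{self.mirna_j}"

    def swapped(self) -> "PairedFeatureDef":
        return PairedFeatureDef(self.mirna_j, self.mirna_i,
                                self.slope_j, self.slope_i)


def enumerate_pairs(
    linearity: list[LinearityResult],
    eligible: list[str],
    slope_tolerance: float = 0.05,
) -> list[PairedFeatureDef]:
    """All unordered pairs of eligible miRNAs with matching dilution slopes.

    A pair qualifies when ``|slope_i - slope_j| <= slope_tolerance``
    (inclusive). Pairs come back canonically ordered (lexicographic within
    pair and across the list), with no duplicates. Every eligible miRNA must
    have a linearity result.
    """
    if slope_tolerance < 0:
        raise ValueError("slope_tolerance must be >= 0")
    slope_of = {r.mirna_id: r.slope for r in linearity}
    missing = [m for m in eligible if m not in slope_of]
    if missing:
        raise ValueError(f"no linearity result for miRNAs: {missing}")
    out = []
    # tiny absolute slack keeps the inclusive boundary robust to float error
    tol = slope_tolerance + 1e-12
    for a, b in combinations(sorted(set(eligible)), 2):
        if abs(slope_of[a] - slope_of[b]) <= tol:
            out.append(PairedFeatureDef(a, b, slope_of[a], slope_of[b]))
    return out


def compute_paired_features(
    matrix: SignalMatrix,
    defs: list[PairedFeatureDef],
    on_missing: str = "error",
) -> pd.DataFrame:
    """Subjects x pairs matrix of paired-miRNA values.

    Cell value is ``log2 signal(mirna_i) - log2 signal(mirna_j)``, i.e. the
    log2 fold change between the two miRNAs within that subject. Both members
    must be detected in every scored subject; a missing signal raises with
    the subject and pair identified (``on_missing="error"``, the default) or
    silently drops the affected subjects (``on_missing="drop"``, for scoring
    held-out specimens that escaped the universal-detection screen).
    """
    if on_missing not in ("error", "drop"):
        raise ValueError("on_missing must be 'error' or 'drop'")
    col_of = {m: k for k, m in enumerate(matrix.values.columns)}
    for d in defs:
        for m in (d.mirna_i, d.mirna_j):
            if m not in col_of:
                raise ValueError(f"miRNA {m!r} absent from signal matrix")
    ii = np.array([col_of[d.mirna_i] for d in defs], dtype=int)
    jj = np.array([col_of[d.mirna_j] for d in defs], dtype=int)
    V = matrix.values.to_numpy(dtype=float)
    D = matrix.detected.to_numpy(dtype=bool)
    det = D[:, ii] & D[:, jj]
    keep = det.all(axis=1)
    if not keep.all():
        if on_missing == "error":
            s, p = np.argwhere(~det)[0]
            raise ValueError(
                f"subject {matrix.subject_ids[s]!r} lacks a detected signal "
                f"for pair {defs[p].name}"
            )
    return pd.DataFrame(
        (V[:, ii] - V[:, jj])[keep],
        index=matrix.values.index[keep],
        columns=[d.name for d in defs],
    )


def class_fold_change(
    features: pd.DataFrame, labels: pd.Series, positive: str = "malignant"
) -> pd.Series:
    """Per-pair fold change 2**(mean difference of the paired feature).

    Reported as a descriptive quantity alongside each pair; never used for
    model fitting.
    """
    pos = features.loc[labels == positive]
    neg = features.loc[labels != positive]
    return np.power(2.0, pos.mean(axis=0) - neg.mean(axis=0))
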