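"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class SignalMatrix:
    """Subjects x miRNAs matrix of log2 signal intensities with detection flags.

    Parameters
    ----------
    values
        Log2 signal intensities, indexed by subject id, columns are miRNA ids.
        Undetected cells hold NaN.
    detected
        Boolean mask aligned with ``values``; True where the scanner called a
        signal. A cell may carry a numeric value yet be flagged undetected —
        downstream filters consult the flag, not the value.
    """

    values: pd.DataFrame
    detected: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.detected is None:
            self.detected = self.values.notna()
        if not self.values.index.equals(self.detected.index) or not (
            self.values.columns.equals(self.detected.columns)
        ):
            raise ValueError("values and detected must share index and columns")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_mirna(self) -> int:
        return self.values.shape[1]

    def detected_counts(self) -> pd.Series:
        """Number of detected miRNAs per subject."""
        return self.detected.sum(axis=1)

    def subset_subjects(self, subject_ids) -> "SignalMatrix":
        ids = list(subject_ids)
        return SignalMatrix(self.values.loc[ids], self.detected.loc[ids])

    def subset_mirnas(self, mirna_ids) -> "SignalMatrix":
        ids = list(mirna_ids)
        return SignalMatrix(self.values[ids], self.detected[ids])

    def to_raw(self) -> pd.DataFrame:
        """Raw-scale intensities (2**log2 value); NaN stays NaN."""
        return np.power(2.0, self.values)

    def to_tsv(self, path: str | Path) -> None:
        """Write log2 values as TSV; undetected cells become empty fields."""
        out = self.values.where(self.detected)
        out.to_csv(path, sep="\t", index_label="subject_id", na_rep="")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignalMatrix":
        values = pd.read_csv(path, sep=None, engine="python", index_col=0)
        values.index = values.index.astype(str)
        return cls(values=values, detected=values.notna())
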