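"""Synthetic cohorts, dilution series, and donor time-series.

The generator reproduces the statistical structure the downstream analysis
assumes: log2 signal intensities that are approximately normal per miRNA, a
global per-subject additive offset in log2 space (modelling RNA input amount
and labeling efficiency, which the paired features must cancel), planted
case/control effects of opposite sign on designated miRNA pairs, detection
dropout including specimens forced below the detection-count QC threshold,
hemolyzed specimens, multi-site cohort structure, serial two-fold dilution
series in replicate, and repeated draws from healthy donors.

Randomness is hierarchical: one top-level seed spawns independent streams for
miRNA-level baselines and for each subject, so enlarging a cohort leaves
previously generated subjects bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import SignalMatrix

# covariate distributions loosely patterned on a BI-RADS 4/5 referral cohort
_BIRADS_CATEGORIES = ("4", "5", "Other")
_BIRADS_PROBS = (0.42, 0.50, 0.08)
_COMPOSITION_CATEGORIES = ("A", "B", "C", "D", "Unknown")
_COMPOSITION_PROBS = (0.04, 0.28, 0.55, 0.04, 0.09)
_RACE_CATEGORIES = (
    "Caucasian, non-Hispanic",
    "Caucasian, Hispanic",
    "Asian",
    "African American",
    "Black Hispanic",
    "Other",
)
_RACE_PROBS = (0.79, 0.09, 0.04, 0.02, 0.02, 0.04)


@dataclass
class CohortSpec:
    """Parameters of a two-class synthetic serum miRNA cohort.

    All signal parameters are in log2 intensity units. ``planted_pairs`` is a
    list of ``(mirna_up, mirna_down, effect)`` triples: malignant subjects get
    ``+effect`` added to ``mirna_up`` and ``-effect`` to ``mirna_down``, so the
    paired log2-ratio feature separates the classes by ``2 * effect``.
    miRNAs may be referenced by integer column index or by id string.
    """

    n_benign: int = 140
    n_malignant: int = 34
    n_mirna: int = 300
    n_sites: int = 9
    planted_pairs: list[tuple] = field(default_factory=list)
    baseline_mean: float = 10.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.3
    subject_offset_sd: float = 0.5
    # calibrated so ~70% of miRNAs survive universal detection over ~174
    # training specimens, mirroring the study's screen
    detection_dropout_rate: float = 0.002
    detection_threshold: int = 250
    n_low_signal: int = 0
    n_hemolyzed: int = 0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_benign", "n_malignant", "n_mirna", "n_sites",
                     "n_low_signal", "n_hemolyzed", "detection_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not 0.0 <= self.detection_dropout_rate <= 1.0:
            raise ValueError("detection_dropout_rate must be in [0, 1]")
        n_total = self.n_benign + self.n_malignant
        if self.n_low_signal + self.n_hemolyzed > n_total:
            raise ValueError("designated low-signal + hemolyzed exceed cohort size")
        if self.n_low_signal > 0 and self.detection_threshold > self.n_mirna:
            raise ValueError(
                "cannot force low-signal specimens when detection_threshold "
                "exceeds n_mirna (every specimen would fail)"
            )
        for pair in self.planted_pairs:
            if len(pair) != 3:
                raise ValueError("planted pair must be (mirna_up, mirna_down, effect)")
            if pair[0] == pair[1]:
                raise ValueError("planted pair members must be distinct")


@dataclass
class DilutionSpec:
    """Serial-dilution design for the microarray linearity screen.

    ``true_slopes`` maps miRNA id to the slope of log2 signal against log2
    relative concentration (1.0 means perfectly proportional signal).
    ``n_dilutions`` counts concentration levels including the undiluted one.
    """

    true_slopes: Mapping[str, float] = field(
        default_factory=lambda: {"miR-0001": 1.0}
    )
    n_dilutions: int = 4
    dilution_factor: float = 2.0
    n_replicates: int = 3
    intercept: float = 10.0
    replicate_noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_dilutions < 2:
            raise ValueError("n_dilutions must be >= 2")
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must be > 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.replicate_noise_sd < 0:
            raise ValueError("replicate_noise_sd must be >= 0")
        if not self.true_slopes:
            raise ValueError("true_slopes must name at least one miRNA")


def _mirna_ids(n: int) -> list[str]:
    return [f"miR-{i + 1:04d}" for i in range(n)]


def _resolve_mirna(ref, mirna_ids: list[str]) -> str:
    if isinstance(ref, (int, np.integer)):
        if not 0 <= ref < len(mirna_ids):
            raise ValueError(f"planted pair references miRNA index {ref}, "
                             f"but the cohort has {len(mirna_ids)} miRNAs")
        return mirna_ids[ref]
    if ref not in mirna_ids:
        raise ValueError(f"planted pair references unknown miRNA {ref!r}")
    return str(ref)


def generate_cohort(spec: CohortSpec) -> tuple[SignalMatrix, pd.DataFrame]:
    """Generate a two-class cohort of log2 miRNA profiles plus metadata.

    Returns
    -------
    matrix : SignalMatrix
        Benign subjects first, then malignant. Undetected cells are NaN.
    metadata : DataFrame
        One row per subject: label, pathology category, site, hemolysis and
        consensus flags, age, BI-RADS category, breast composition,
        race/ethnicity.
    """
    spec.validate()
    n_total = spec.n_benign + spec.n_malignant
    mirnas = _mirna_ids(spec.n_mirna)
    planted = [
        (_resolve_mirna(up, mirnas), _resolve_mirna(dn, mirnas), float(eff))
        for up, dn, eff in spec.planted_pairs
    ]

    root = np.random.SeedSequence(spec.seed)
    # stream 0: miRNA baselines and cohort-level designations;
    # streams 1..n: one per subject
    cohort_ss, *subject_ss = root.spawn(n_total + 1)
    cohort_rng = np.random.default_rng(cohort_ss)
    baseline = cohort_rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_mirna)

    subject_ids = [f"S{i + 1:04d}" for i in range(n_total)]
    labels = ["benign"] * spec.n_benign + ["malignant"] * spec.n_malignant
    designated = cohort_rng.choice(
        n_total, size=spec.n_low_signal + spec.n_hemolyzed, replace=False
    )
    low_signal_idx = set(designated[: spec.n_low_signal].tolist())
    hemolyzed_idx = set(designated[spec.n_low_signal:].tolist())

    values = np.empty((n_total, spec.n_mirna))
    detected = np.ones((n_total, spec.n_mirna), dtype=bool)
    meta_rows = []
    col_of = {m: k for k, m in enumerate(mirnas)}

    for i, ss in enumerate(subject_ss):
        rng = np.random.default_rng(ss)
        offset = rng.normal(0.0, spec.subject_offset_sd) if spec.subject_offset_sd > 0 else 0.0
        row = baseline + offset + rng.normal(0.0, spec.noise_sd, spec.n_mirna)
        if labels[i] == "malignant":
            for up, dn, eff in planted:
                row[col_of[up]] += eff
                row[col_of[dn]] -= eff

        if i in low_signal_idx:
            # force fewer detected miRNAs than the QC threshold
            lo = max(1, spec.detection_threshold // 2)
            n_det = int(rng.integers(lo, spec.detection_threshold))
            keep = rng.choice(spec.n_mirna, size=n_det, replace=False)
            det = np.zeros(spec.n_mirna, dtype=bool)
            det[keep] = True
        else:
            det = rng.random(spec.n_mirna) >= spec.detection_dropout_rate
            if spec.n_mirna >= spec.detection_threshold:
                deficit = spec.detection_threshold - int(det.sum())
                if deficit > 0:  # keep non-designated specimens above threshold
                    missing = np.flatnonzero(~det)
                    det[rng.choice(missing, size=deficit, replace=False)] = True
        values[i] = np.where(det, row, np.nan)
        detected[i] = det

        meta_rows.append({
            "subject_id": subject_ids[i],
            "label": labels[i],
            "category": "Breast cancer" if labels[i] == "malignant" else "Benign",
            "site": f"site_{(i % spec.n_sites) + 1:02d}",
            "hemolysis": i in hemolyzed_idx,
            "consensus": True,
            "age": int(np.clip(round(rng.normal(55.0, 10.0)), 30, 85)),
            "birads": str(rng.choice(_BIRADS_CATEGORIES, p=_BIRADS_PROBS)),
            "breast_composition": str(
                rng.choice(_COMPOSITION_CATEGORIES, p=_COMPOSITION_PROBS)
            ),
            "race_ethnicity": str(rng.choice(_RACE_CATEGORIES, p=_RACE_PROBS)),
        })

    matrix = SignalMatrix(
        values=pd.DataFrame(values, index=subject_ids, columns=mirnas),
        detected=pd.DataFrame(detected, index=subject_ids, columns=mirnas),
    )
    metadata = pd.DataFrame(meta_rows).set_index("subject_id")
    return matrix, metadata


def generate_dilution_series(spec: DilutionSpec) -> pd.DataFrame:
    """Simulate a serial-dilution microarray run in replicate.

    Returns a long-format frame with one row per (miRNA, dilution step,
    replicate): ``log2_concentration`` is relative to the undiluted sample
    (step 0 -> 0.0, each further step subtracts log2(dilution_factor)), and
    ``log2_signal`` is ``intercept + true_slope * log2_concentration`` plus
    independent replicate noise.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    step_conc = -np.log2(spec.dilution_factor) * np.arange(spec.n_dilutions)
    rows = []
    for mirna in spec.true_slopes:
        slope = float(spec.true_slopes[mirna])
        for d, conc in enumerate(step_conc):
            expected = spec.intercept + slope * conc
            noise = rng.normal(0.0, spec.replicate_noise_sd, spec.n_replicates) \
                if spec.replicate_noise_sd > 0 else np.zeros(spec.n_replicates)
            for r in range(spec.n_replicates):
                rows.append({
                    "mirna_id": mirna,
                    "dilution_step": d,
                    "replicate": r + 1,
                    "log2_concentration": conc,
                    "log2_signal": expected + noise[r],
                })
    return pd.DataFrame(rows)


def generate_donor_series(
    n_donors: int = 5,
    n_timepoints: int = 6,
    within_donor_sd: float = 0.1,
    seed: int = 0,
    mirna_ids: Sequence[str] | None = None,
    baseline_mean: float = 10.0,
    baseline_sd: float = 1.5,
) -> tuple[SignalMatrix, pd.DataFrame]:
    """Repeated blood draws from healthy donors.

    Each donor has a fixed base profile (per-miRNA log2 level drawn once);
    each time point observes that profile plus independent N(0, within_donor_sd)
    perturbations, emulating biweekly serum collections from the same person.

    Returns the profile matrix (rows ``D<k>_t<j>``) and a metadata frame with
    ``donor`` and ``timepoint`` columns.
    """
    if n_donors < 1:
        raise ValueError("n_donors must be >= 1")
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    if within_donor_sd < 0:
        raise ValueError("within_donor_sd must be >= 0")
    mirnas = list(mirna_ids) if mirna_ids is not None else _mirna_ids(10)

    root = np.random.SeedSequence(seed)
    donor_streams = root.spawn(n_donors)
    rows, ids, meta = [], [], []
    for d, ss in enumerate(donor_streams):
        rng = np.random.default_rng(ss)
        base = rng.normal(baseline_mean, baseline_sd, len(mirnas))
        for t in range(n_timepoints):
            pert = rng.normal(0.0, within_donor_sd, len(mirnas)) \
                if within_donor_sd > 0 else np.zeros(len(mirnas))
            rows.append(base + pert)
            ids.append(f"D{d + 1}_t{t + 1}")
            meta.append({"subject_id": ids[-1], "donor": f"D{d + 1}",
                         "timepoint": t + 1})
    matrix = SignalMatrix(
        values=pd.DataFrame(np.asarray(rows), index=ids, columns=mirnas)
    )
    return matrix, pd.DataFrame(meta).set_index("subject_id")
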