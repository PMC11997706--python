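"""End-to-end orchestration: simulate -> QC -> pairs -> train -> evaluate.

The pipeline mirrors the classifier-development flow: metadata exclusion,
the detected-signal-count filter, a site-level train/test split, the
universal-detection screen on the training set, the dilution-series
linearity screen, slope-matched pair enumeration, AIC best-subset logistic
training with the sensitivity-constrained cutoff, and evaluation on both
partitions. All randomness derives from one top-level seed; per-stage
sub-seeds are spawned deterministically so stages reproduce independently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from . import model as mdl
from . import pairing, qc, synth
from .containers import SignalMatrix

logger = logging.getLogger("mirpair")


@dataclass
class PipelineConfig:
    """Thresholds, model settings, split settings, and cohort parameters."""

    # synthetic cohort (used when no input paths are given)
    cohort: dict = field(default_factory=dict)
    dilution_noise_sd: float = 0.05
    nonlinear_fraction: float = 0.1
    nonlinear_noise_sd: float = 1.0
    slope_mean: float = 1.0
    slope_sd: float = 0.12
    # optional input files (override simulation)
    matrix_path: str | None = None
    metadata_path: str | None = None
    dilution_path: str | None = None
    # QC thresholds
    min_detected: int = 250
    r2_threshold: float = 0.975
    slope_tolerance: float = 0.05
    # model settings
    max_pairs: int = 5
    strategy: str = "auto"
    min_sensitivity: float = 0.90
    # split settings
    test_sites: list[str] | None = None
    test_fraction: float = 0.34
    # run settings
    seed: int = 0
    out_dir: str = "mirpair_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.min_detected < 0:
            raise ValueError("min_detected must be >= 0")
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must be in [0, 1]")
        if self.slope_tolerance < 0:
            raise ValueError("slope_tolerance must be >= 0")
        if self.max_pairs < 1:
            raise ValueError("max_pairs must be >= 1")
        if not 0.0 < self.min_sensitivity <= 1.0:
            raise ValueError("min_sensitivity must be in (0, 1]")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")


def _sub_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2**31 derived from one seed."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s & 0x7FFFFFFF) for s in state]


def split_by_site(
    metadata: pd.DataFrame,
    test_sites: list[str] | None = None,
    seed: int | None = None,
    test_fraction: float = 0.34,
) -> tuple[list[str], list[str]]:
    """Partition subjects into training and test sets at the site level.

    Every site's subjects land wholly in one partition, so the test set
    measures transportability across institutions rather than within-site
    noise. Either pass the test sites explicitly, or let a seeded shuffle
    assign sites: the shuffled prefix whose subject share is closest to
    ``test_fraction`` becomes the test set.
    """
    if "site" not in metadata.columns:
        raise ValueError("metadata lacks a 'site' column")
    sites = metadata["site"].astype(str)
    site_names = sorted(sites.unique())
    if test_sites is not None:
        missing = sorted(set(map(str, test_sites)) - set(site_names))
        if missing:
            raise ValueError(f"requested test sites absent from data: {missing}")
        test_set = set(map(str, test_sites))
    else:
        if len(site_names) < 2:
            raise ValueError("need at least 2 sites for a seeded site-level split")
        rng = np.random.default_rng(seed)
        order = list(rng.permutation(site_names))
        counts = sites.value_counts()
        total = len(metadata)
        best_k, best_gap = 1, float("inf")
        for k in range(1, len(order)):  # leave at least one training site
            frac = sum(counts[s] for s in order[:k]) / total
            gap = abs(frac - test_fraction)
            if gap < best_gap:
                best_k, best_gap = k, gap
        test_set = set(order[:best_k])
    test_ids = [str(i) for i in metadata.index[sites.isin(test_set)]]
    train_ids = [str(i) for i in metadata.index[~sites.isin(test_set)]]
    if not train_ids:
        raise ValueError("site split leaves the training set empty")
    if not test_ids:
        raise ValueError("site split leaves the test set empty")
    return train_ids, test_ids


def _simulate_inputs(config: PipelineConfig, seeds: list[int]):
    spec = synth.CohortSpec(**{**config.cohort, "seed": seeds[0]})
    matrix, metadata = synth.generate_cohort(spec)
    # dilution series: true slopes vary across miRNAs; a fraction of probes
    # get grossly noisy replicates and should fail the linearity screen
    rng = np.random.default_rng(seeds[1])
    slopes = {
        m: float(rng.normal(config.slope_mean, config.slope_sd))
        for m in matrix.mirna_ids
    }
    noisy = set(
        rng.choice(
            matrix.mirna_ids,
            size=int(round(config.nonlinear_fraction * matrix.n_mirna)),
            replace=False,
        ).tolist()
    )
    clean = {m: s for m, s in slopes.items() if m not in noisy}
    frames = []
    if clean:
        frames.append(synth.generate_dilution_series(synth.DilutionSpec(
            true_slopes=clean,
            replicate_noise_sd=config.dilution_noise_sd,
            seed=seeds[2],
        )))
    if noisy:
        frames.append(synth.generate_dilution_series(synth.DilutionSpec(
            true_slopes={m: slopes[m] for m in noisy},
            replicate_noise_sd=config.nonlinear_noise_sd,
            seed=seeds[3],
        )))
    dilution = pd.concat(frames, ignore_index=True)
    return matrix, metadata, dilution


def _load_inputs(config: PipelineConfig):
    matrix = SignalMatrix.from_tsv(config.matrix_path)
    metadata = pd.read_csv(config.metadata_path, sep=None, engine="python",
                           index_col=0)
    metadata.index = metadata.index.astype(str)
    dilution = pd.read_csv(config.dilution_path, sep=None, engine="python")
    return matrix, metadata, dilution


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, persist artifacts under ``config.out_dir``.

    Returns the manifest dictionary. Identical config and seed reproduce
    byte-identical JSON/TSV artifacts; wall-clock timestamps appear only in
    the log file.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _sub_seeds(config.seed, 6)
    manifest: dict = {"stages": [], "seed": config.seed,
                      "thresholds": {
                          "min_detected": config.min_detected,
                          "r2_threshold": config.r2_threshold,
                          "slope_tolerance": config.slope_tolerance,
                          "max_pairs": config.max_pairs,
                          "min_sensitivity": config.min_sensitivity,
                      }}

    def stage(name: str, **info) -> None:
        logger.info("stage %s: %s", name, info)
        manifest["stages"].append({"name": name, **info})

    # ---- inputs -------------------------------------------------------
    if config.matrix_path:
        matrix, metadata, dilution = _load_inputs(config)
        stage("inputs", source="files", subjects=matrix.n_subjects)
    else:
        matrix, metadata, dilution = _simulate_inputs(config, seeds)
        matrix.to_tsv(out / "signals.tsv")
        metadata.to_csv(out / "metadata.tsv", sep="\t")
        dilution.to_csv(out / "dilution.tsv", sep="\t", index=False)
        stage("simulate", subjects=matrix.n_subjects, mirnas=matrix.n_mirna)

    # ---- QC: metadata exclusion then signal-count filter --------------
    meta_report = qc.exclude_by_metadata(metadata)
    kept = matrix.subset_subjects(meta_report.retained_ids)
    signal_report = qc.filter_low_signal(kept, config.min_detected)
    cohort = kept.subset_subjects(signal_report.retained_ids)
    cohort_meta = metadata.loc[signal_report.retained_ids]
    (out / "qc_report.json").write_text(json.dumps(
        {"stages": [meta_report.to_dict(), signal_report.to_dict()]}, indent=2
    ) + "\n")
    stage("qc", metadata_excluded=meta_report.subjects_excluded,
          low_signal_excluded=signal_report.subjects_excluded,
          retained=cohort.n_subjects)

    # ---- site-level split --------------------------------------------
    train_ids, test_ids = split_by_site(
        cohort_meta, test_sites=config.test_sites, seed=seeds[4],
        test_fraction=config.test_fraction,
    )
    stage("split", n_train=len(train_ids), n_test=len(test_ids))

    # ---- miRNA eligibility: linearity screen + universal detection ----
    linearity = qc.assess_linearity(dilution, config.r2_threshold)
    (out / "linearity.json").write_text(json.dumps(
        [r.to_dict() for r in linearity], indent=2) + "\n")
    linear_ok = {r.mirna_id for r in linearity if r.passed}
    universal = qc.filter_universal_detection(cohort, train_ids)
    eligible = sorted(linear_ok & set(universal))
    stage("mirna_eligibility", linear=len(linear_ok),
          universal=len(universal), eligible=len(eligible))
    if len(eligible) < 2:
        raise RuntimeError("mirna_eligibility: fewer than 2 eligible miRNAs")

    # ---- pair enumeration and features -------------------------------
    defs = pairing.enumerate_pairs(linearity, eligible, config.slope_tolerance)
    if not defs:
        raise RuntimeError("pairing: no slope-matched pairs under tolerance")
    (out / "pairs.json").write_text(json.dumps(
        [[d.mirna_i, d.mirna_j] for d in defs], indent=2) + "\n")
    # universal detection guarantees every training subject has all members
    train_features = pairing.compute_paired_features(
        cohort.subset_subjects(train_ids).subset_mirnas(eligible), defs)
    stage("pairing", candidate_pairs=len(defs))

    # ---- training -----------------------------------------------------
    labels = cohort_meta["label"]
    y_train = labels.loc[train_ids]
    if y_train.nunique() < 2:
        raise RuntimeError("train: training partition has a single class")
    model = mdl.best_subset_select(
        train_features, y_train,
        max_pairs=config.max_pairs, strategy=config.strategy,
        min_sensitivity=config.min_sensitivity, pair_defs=defs,
    )
    model.to_json(out / "model.json")
    stage("train", selected_pairs=len(model.pairs), aic=model.meta["aic"])

    # ---- evaluation ---------------------------------------------------
    evaluation = {}
    for part, ids in (("training", train_ids), ("test", test_ids)):
        # held-out subjects missing a model miRNA cannot be scored; drop them
        part_feat = pairing.compute_paired_features(
            cohort.subset_subjects(ids).subset_mirnas(model.mirnas),
            model.pairs, on_missing="drop")
        scored_ids = part_feat.index.tolist()
        if len(scored_ids) < len(ids):
            logger.info("evaluate %s: %d subjects unscorable (missing model "
                        "miRNA)", part, len(ids) - len(scored_ids))
        scores = mdl.compute_index(model, part_feat)
        calls = scores >= model.cutoff
        counts = ev.ConfusionCounts.from_calls(calls, labels.loc[scored_ids])
        evaluation[part] = ev.diagnostic_report(
            counts, scores=scores, labels=labels.loc[scored_ids])
        evaluation[part]["n_unscorable"] = len(ids) - len(scored_ids)
        pd.DataFrame({"index": scores, "call": calls}).to_csv(
            out / f"scores_{part}.tsv", sep="\t", index_label="subject_id")
    (out / "evaluation.json").write_text(
        json.dumps(evaluation, indent=2) + "\n")
    stage("evaluate", **{
        f"{p}_{m}": evaluation[p]["metrics"][m]["percent"]
        for p in ("training", "test")
        for m in ("sensitivity", "specificity", "npv")
    })

    manifest["config"] = asdict(config)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
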