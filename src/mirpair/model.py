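"""Best-subset logistic regression on paired-miRNA features.

Fits logistic regressions by iteratively reweighted least squares, searches
for the AIC-minimizing subset of at most ``max_pairs`` paired features
(exhaustively for small candidate pools, by forward selection with
single-swap refinement for large ones), selects the classification cutoff as
the probability threshold maximizing specificity subject to a training
sensitivity floor, and ships the published five-pair serum classifier as a
fixed model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .pairing import PairedFeatureDef

MAX_PAIRS_DEFAULT = 5
#: candidate-pool size up to which subset search is exhaustive under "auto"
EXHAUSTIVE_LIMIT = 15


@dataclass
class LogisticFit:
    """Result of a single maximum-likelihood logistic fit."""

    coefficients: np.ndarray  # per-feature, excludes intercept
    intercept: float
    log_likelihood: float
    converged: bool
    n_iter: int
    constant_columns: list[int] = field(default_factory=list)
    message: str = ""


@dataclass
class LogisticPairModel:
    """A fitted (or published) paired-miRNA logistic classifier.

    The classifier index for a subject with paired values v is
    ``1 / (1 + exp(-(intercept + sum(beta_m * v_m))))``; an index at or above
    ``cutoff`` calls the subject positive (malignant), below it calls
    "neither cancer nor a pre-cancerous diagnosis".
    """

    pairs: list[PairedFeatureDef]
    coefficients: list[float]
    intercept: float
    cutoff: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.pairs):
            raise ValueError("one coefficient per pair required")
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError("cutoff must lie strictly inside (0, 1)")

    @property
    def feature_names(self) -> list[str]:
        return [p.name for p in self.pairs]

    @property
    def mirnas(self) -> list[str]:
        seen: list[str] = []
        for p in self.pairs:
            for m in (p.mirna_i, p.mirna_j):
                if m not in seen:
                    seen.append(m)
        return seen

    def to_dict(self) -> dict:
        return {
            "pairs": [[p.mirna_i, p.mirna_j] for p in self.pairs],
            "coefficients": list(map(float, self.coefficients)),
            "intercept": float(self.intercept),
            "cutoff": float(self.cutoff),
            "meta": self.meta,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticPairModel":
        pairs = [PairedFeatureDef(i, j) for i, j in d["pairs"]]
        return cls(pairs=pairs, coefficients=list(d["coefficients"]),
                   intercept=float(d["intercept"]), cutoff=float(d["cutoff"]),
                   meta=d.get("meta", {}))

    @classmethod
    def from_json(cls, path: str | Path) -> "LogisticPairModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _as_binary(labels, positive: str = "malignant") -> np.ndarray:
    """Coerce labels to a 0/1 vector; strings match ``positive``."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        return (arr == positive).astype(float)
    return arr.astype(float)


def _log_likelihood(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_logistic(
    features, labels, max_iter: int = 100, tol: float = 1e-8
) -> LogisticFit:
    """Maximum-likelihood logistic regression via IRLS (Newton-Raphson).

    Convergence is declared when the largest absolute coefficient update
    falls below ``tol``. Non-convergence — typically complete separation,
    where the likelihood is monotone in a diverging coefficient — is reported
    through ``converged``/``message`` rather than raised, because subset
    search must tolerate degenerate candidate subsets. Constant feature
    columns are flagged and handled through a pseudo-inverse solve.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = _as_binary(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree on n")
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise ValueError("labels contain a single class; logistic fit undefined")

    constant = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) == 0.0]
    A = np.hstack([np.ones((X.shape[0], 1)), X])
    beta = np.zeros(A.shape[1])
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(A @ beta, -30.0, 30.0)
        p = expit(eta)
        w = p * (1 - p)
        # Newton step on the score; pinv tolerates rank deficiency
        H = A.T @ (A * w[:, None])
        g = A.T @ (y - p)
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            delta = np.linalg.pinv(H) @ g
        if not np.all(np.isfinite(delta)):
            message = "singular update; likelihood may be monotone"
            break
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    if not converged and not message:
        message = ("did not converge in "
                   f"{max_iter} iterations; monotone likelihood "
                   "(complete separation) is the usual cause")
    eta = np.clip(A @ beta, -30.0, 30.0)
    ll = _log_likelihood(y, expit(eta))
    return LogisticFit(
        coefficients=beta[1:].copy(),
        intercept=float(beta[0]),
        log_likelihood=ll,
        converged=converged,
        n_iter=it,
        constant_columns=constant,
        message=message,
    )


def aic(fit: LogisticFit) -> float:
    """Akaike information criterion, 2k - 2 logL, k counting the intercept."""
    k = len(fit.coefficients) + 1
    return 2.0 * k - 2.0 * fit.log_likelihood


def _defs_from_columns(columns, defs: list[PairedFeatureDef] | None):
    if defs is not None:
        by_name = {d.name: d for d in defs}
        return [by_name[c] if c in by_name else _parse_pair_name(c) for c in columns]
    return [_parse_pair_name(c) for c in columns]


def _parse_pair_name(name: str) -> PairedFeatureDef:
    if "|" in name:
        i, j = name.split("|", 1)
        return PairedFeatureDef(i, j)
    return PairedFeatureDef(name, f"{name}~ref")


def best_subset_select(
    features: pd.DataFrame,
    labels,
    max_pairs: int = MAX_PAIRS_DEFAULT,
    strategy: str = "auto",
    min_sensitivity: float = 0.90,
    pair_defs: list[PairedFeatureDef] | None = None,
) -> LogisticPairModel:
    """Select the AIC-minimizing subset of at most ``max_pairs`` pairs.

    ``strategy``:

    - ``"exhaustive"`` — enumerate every subset of size 0..max_pairs
      (the empty subset is the intercept-only model).
    - ``"heuristic"`` — forward selection to ``max_pairs``, keeping the best
      subset seen, followed by single-swap and single-drop local refinement
      until the AIC stops improving. Stands in for an active-set search on
      candidate pools where enumeration is infeasible.
    - ``"auto"`` — exhaustive when the pool has at most 15 candidates,
      heuristic otherwise.

    Ties break toward the smaller subset, then lexicographic pair order. The
    returned model's cutoff is chosen on the training scores under the
    ``min_sensitivity`` floor.
    """
    if max_pairs < 1:
        raise ValueError("max_pairs must be >= 1")
    if features.shape[1] < 1:
        raise ValueError("no candidate pairs provided")
    y = _as_binary(labels)
    candidates = list(features.columns)
    X = features.to_numpy(dtype=float)
    col_idx = {c: i for i, c in enumerate(candidates)}

    cache: dict[tuple, tuple[float, LogisticFit]] = {}

    def evaluate(subset: tuple) -> tuple[float, LogisticFit]:
        if subset not in cache:
            idx = [col_idx[c] for c in subset]
            Xs = X[:, idx] if idx else np.empty((X.shape[0], 0))
            fit = fit_logistic(Xs, y)
            cache[subset] = (aic(fit), fit)
        return cache[subset]

    def better(a: tuple, b: tuple) -> bool:
        """True when subset a beats subset b under AIC with tie-breaks."""
        aic_a, aic_b = evaluate(a)[0], evaluate(b)[0]
        if abs(aic_a - aic_b) > 1e-9:
            return aic_a < aic_b
        if len(a) != len(b):
            return len(a) < len(b)
        return tuple(sorted(a)) < tuple(sorted(b))

    if strategy == "auto":
        strategy = "exhaustive" if len(candidates) <= EXHAUSTIVE_LIMIT else "heuristic"
    if strategy not in ("exhaustive", "heuristic"):
        raise ValueError(f"unknown strategy {strategy!r}")

    best: tuple = ()
    evaluate(best)
    if strategy == "exhaustive":
        for k in range(1, min(max_pairs, len(candidates)) + 1):
            for subset in combinations(candidates, k):
                if better(subset, best):
                    best = subset
    else:
        current: tuple = ()
        while len(current) < min(max_pairs, len(candidates)):
            step_best = None
            for c in candidates:
                if c in current:
                    continue
                trial = tuple(sorted(current + (c,)))
                if step_best is None or better(trial, step_best):
                    step_best = trial
            current = step_best
            if better(current, best):
                best = current
        improved = True
        while improved:
            improved = False
            for drop in best:
                reduced = tuple(sorted(set(best) - {drop}))
                if better(reduced, best):
                    best = reduced
                    improved = True
                for add in candidates:
                    if add in best:
                        continue
                    trial = tuple(sorted(set(reduced) | {add}))
                    if better(trial, best):
                        best = trial
                        improved = True

    best = tuple(sorted(best))
    best_aic, fit = evaluate(best)
    defs = _defs_from_columns(best, pair_defs)
    if best:
        scores = compute_index_matrix(
            fit.intercept, fit.coefficients, features[list(best)].to_numpy()
        )
    else:
        scores = np.full(len(y), expit(fit.intercept))
    cutoff = select_cutoff(scores, y, min_sensitivity=min_sensitivity)
    if cutoff <= 0.0:
        # the everyone-positive candidate sits below the probability scale;
        # any value under the minimum score is equivalent, so stay in (0, 1)
        cutoff = float(np.min(scores)) / 2.0
    return LogisticPairModel(
        pairs=defs,
        coefficients=[float(b) for b in fit.coefficients],
        intercept=fit.intercept,
        cutoff=float(cutoff),
        meta={
            "n": int(len(y)),
            "n_positive": int(y.sum()),
            "aic": float(best_aic),
            "log_likelihood": float(fit.log_likelihood),
            "converged": bool(fit.converged),
            "strategy": strategy,
            "n_candidates": len(candidates),
            "min_sensitivity": float(min_sensitivity),
        },
    )


def compute_index_matrix(intercept: float, coefficients, values: np.ndarray) -> np.ndarray:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    x = intercept + values @ np.asarray(coefficients, dtype=float)
    return expit(x)


def compute_index(model: LogisticPairModel, paired_values) -> float | np.ndarray:
    """Classifier index 1/(1 + exp(-x)) for one subject or a batch.

    ``paired_values`` is either a vector aligned with ``model.pairs``, a 2-D
    array (subjects x pairs), or a DataFrame whose columns include the
    model's pair names.
    """
    if isinstance(paired_values, pd.DataFrame):
        missing = [n for n in model.feature_names if n not in paired_values.columns]
        if missing:
            raise ValueError(f"feature matrix lacks pair columns: {missing}")
        values = paired_values[model.feature_names].to_numpy(dtype=float)
        return pd.Series(
            compute_index_matrix(model.intercept, model.coefficients, values),
            index=paired_values.index,
            name="index",
        )
    arr = np.asarray(paired_values, dtype=float)
    if arr.ndim == 1:
        if arr.shape[0] != len(model.pairs):
            raise ValueError(
                f"expected {len(model.pairs)} paired values, got {arr.shape[0]}"
            )
        return float(compute_index_matrix(model.intercept, model.coefficients, arr)[0])
    if arr.shape[1] != len(model.pairs):
        raise ValueError(
            f"expected {len(model.pairs)} paired-value columns, got {arr.shape[1]}"
        )
    return compute_index_matrix(model.intercept, model.coefficients, arr)


def select_cutoff(scores, labels, min_sensitivity: float = 0.90) -> float:
    """Probability cutoff: highest specificity at sensitivity >= the floor.

    Candidate cutoffs are the midpoints between consecutive distinct sorted
    scores plus one value below the minimum (which classifies everyone
    positive, so sensitivity 1 is always attainable and the constraint is
    always satisfiable). Classification rule: score >= cutoff is positive.
    Ties in specificity resolve to the largest cutoff.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    n_pos = y.sum()
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes are required to choose a cutoff")
    distinct = np.unique(s)
    candidates = np.concatenate(
        [[distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0]
    )
    best_cut = None
    best_spec = -1.0
    for c in candidates:
        pred = s >= c
        sens = (pred & (y == 1)).sum() / n_pos
        if sens < min_sensitivity:
            continue
        spec = (~pred & (y == 0)).sum() / n_neg
        if spec > best_spec or (spec == best_spec and c > best_cut):
            best_spec = spec
            best_cut = c
    return float(best_cut)


def classify(model: LogisticPairModel, features) -> np.ndarray | pd.Series:
    """Positive (malignant) call iff the classifier index >= model.cutoff."""
    idx = compute_index(model, features)
    if isinstance(idx, pd.Series):
        return idx >= model.cutoff
    return np.asarray(idx) >= model.cutoff


_PUBLISHED = Path(__file__).parent / "data" / "published_model.json"


def published_model() -> LogisticPairModel:
    """The published five-pair serum breast-lesion classifier.

    Pairs (miR-12120, miR-6075), (miR-1233-5p, miR-4651), (miR-4656, miR-575),
    (miR-4725-3p, miR-7110-5p), (miR-4787-5p, miR-6125) with coefficients
    4.16, -3.82, 1.63, 1.93, -6.30, intercept 5.19 and index cutoff 0.0892.
    Coefficients are fixed; the training serum data are not redistributable,
    so this model is applied, never refit.
    """
    return LogisticPairModel.from_json(_PUBLISHED)
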