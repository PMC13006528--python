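"""Evaluation protocol on labelled in-frame insertion variants.

Treats tag-site prediction as the inverse of insertion-pathogenicity
prediction: a logistic regression on the per-position features (entropy,
RSA, secondary-structure score, disordered-binding complement, the weighted
sum S_i, the minimum score E_i, and a one-hot encoding of the
secondary-structure code) is fit on a stratified 80:20 split and scored by
precision, recall and F1 with the pathogenic class as positive.

The real curated variant sets (clinical databases filtered to insertions of
tag length) are supported only as an input schema; a class-conditional
simulator stands in for them so the protocol runs end-to-end offline. The
simulator draws the four primary features from Beta distributions whose
means differ between classes — benign insertions sit at exposed, coil-like,
variable, non-binding positions, pathogenic ones the reverse — and derives
S_i and E_i through the scoring module, never independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .scoring import DEFAULT_WEIGHTS, min_score, weighted_score
from .structure import ss_feature

log = logging.getLogger(__name__)

#: Fixed numeric column order of the design matrix.
NUMERIC_COLUMNS = ("entropy", "rsa", "ss_score", "dbr", "s_weighted", "e_min")

#: Published summary F1 scores of external indel-pathogenicity predictors,
#: kept for report context only; nothing in this package recomputes them.
REFERENCE_F1 = {"this_method": 0.739, "sift_indel": 0.694, "mutpred2_indel": 0.831}


@dataclass
class InsertionVariant:
    protein_id: str
    position: int
    label: str  # 'pathogenic' | 'benign'
    entropy: float
    rsa: float
    ss_score: float
    dbr: float
    s_weighted: float
    e_min: float
    ss_code: str

    def __post_init__(self) -> None:
        if self.label not in ("pathogenic", "benign"):
            raise ValueError(f"label must be pathogenic|benign, got {self.label!r}")
        for name in ("entropy", "rsa", "ss_score", "dbr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"feature {name}={v} outside [0, 1]")


@dataclass
class MetricsRecord:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    split_seed: int
    n_train: int
    n_test: int
    converged: bool = True


@dataclass
class SimulationParams:
    """Class-conditional generative settings for the variant simulator.

    ``benign_mean``/``pathogenic_mean`` set the Beta-distribution mean of
    the continuous features (entropy, RSA, 1-BR) per class;
    ``concentration`` is the Beta a+b total (larger = tighter).
    ``*_coil_prob`` sets how often each class falls in coil (the remaining
    mass is spread over helix/strand/turn codes).
    """

    n_pathogenic: int = 401
    n_benign: int = 433
    benign_mean: float = 0.62
    pathogenic_mean: float = 0.38
    concentration: float = 8.0
    benign_coil_prob: float = 0.75
    pathogenic_coil_prob: float = 0.30
    #: class-conditional distribution over non-coil codes (H, E, G, T, S);
    #: benign non-coil residues lean to turns/bends, pathogenic to helix/strand.
    benign_noncoil_p: tuple[float, ...] = (0.15, 0.10, 0.05, 0.40, 0.30)
    pathogenic_noncoil_p: tuple[float, ...] = (0.50, 0.30, 0.10, 0.06, 0.04)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pathogenic <= 0 or self.n_benign <= 0:
            raise ValueError("class counts must be positive")
        for name in ("benign_mean", "pathogenic_mean",
                     "benign_coil_prob", "pathogenic_coil_prob"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0 if "mean" in name else not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} invalid")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")

    @classmethod
    def null(cls, seed: int = 0, n_per_class: int = 200) -> "SimulationParams":
        """Zero class separation: both classes share one distribution."""
        uniform = (0.2, 0.2, 0.2, 0.2, 0.2)
        return cls(n_pathogenic=n_per_class, n_benign=n_per_class,
                   benign_mean=0.5, pathogenic_mean=0.5,
                   benign_coil_prob=0.5, pathogenic_coil_prob=0.5,
                   benign_noncoil_p=uniform, pathogenic_noncoil_p=uniform,
                   seed=seed)

    @classmethod
    def separable(cls, seed: int = 0, n_per_class: int = 200) -> "SimulationParams":
        """Extreme separation: classes are linearly separable on E_i alone."""
        return cls(n_pathogenic=n_per_class, n_benign=n_per_class,
                   benign_mean=0.92, pathogenic_mean=0.08,
                   concentration=60.0,
                   benign_coil_prob=1.0, pathogenic_coil_prob=0.0, seed=seed)


# ---------------------------------------------------------------------------


def encode_design_matrix(
    variants: Sequence[InsertionVariant],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Encode variants as (X, y, column_names); pathogenic = 1.

    Numeric columns come first in :data:`NUMERIC_COLUMNS` order, followed by
    one-hot indicator columns for each observed secondary-structure code
    with the first (alphabetically) dropped as the reference level.
    """
    if len(variants) < 2:
        raise ValueError(">=2 variants required")
    labels = {v.label for v in variants}
    if len(labels) < 2:
        raise ValueError("both classes must be present to fit a classifier")
    frame = pd.DataFrame(
        {
            **{c: [getattr(v, c) for v in variants] for c in NUMERIC_COLUMNS},
            "ss_code": [v.ss_code for v in variants],
        }
    )
    codes = sorted(frame["ss_code"].unique())
    onehot_cols: list[str] = []
    if len(codes) > 1:
        for code in codes[1:]:  # first code is the reference level
            col = f"ss_{code}"
            frame[col] = (frame["ss_code"] == code).astype(float)
            onehot_cols.append(col)
    else:
        log.warning("all variants share secondary-structure code %r; "
                    "no one-hot columns emitted", codes[0])
    columns = list(NUMERIC_COLUMNS) + onehot_cols
    X = frame[columns].to_numpy(dtype=float)
    y = np.array([1 if v.label == "pathogenic" else 0 for v in variants])
    return X, y, columns


def split_train_test(
    variants: Sequence[InsertionVariant],
    fraction: float = 0.8,
    seed: int = 0,
) -> tuple[list[InsertionVariant], list[InsertionVariant]]:
    """Stratified train/test split: floor(fraction * n) per class to train."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1) (empty train or test set)")
    by_class: dict[str, list[int]] = {}
    for i, v in enumerate(variants):
        by_class.setdefault(v.label, []).append(i)
    if len(by_class) < 2:
        raise ValueError("both classes must be present")
    for label, idx in by_class.items():
        if len(idx) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 members")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in sorted(by_class):
        idx = np.array(by_class[label])
        perm = rng.permutation(len(idx))
        n_train = int(np.floor(fraction * len(idx)))
        if n_train == 0 or n_train == len(idx):
            raise ValueError(f"class {label!r}: split leaves an empty set")
        train_idx.extend(idx[perm[:n_train]])
        test_idx.extend(idx[perm[n_train:]])
    return ([variants[i] for i in sorted(train_idx)],
            [variants[i] for i in sorted(test_idx)])


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> tuple[float, float, float]:
    """Precision TP/(TP+FP), recall TP/(TP+FN), F1 = harmonic mean.

    Undefined ratios (zero denominators) are reported as 0, as is F1 when
    precision + recall = 0.
    """
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) > 0 else 0.0)
    return precision, recall, f1


def fit_eval_logistic(
    train: Sequence[InsertionVariant],
    test: Sequence[InsertionVariant],
    threshold: float = 0.5,
    regularized: bool = False,
    split_seed: int = 0,
    max_iter: int = 2000,
) -> MetricsRecord:
    """Fit a logistic model on the training variants and score the test set.

    The fit is unregularised by default (``regularized=True`` switches to
    scikit-learn's default L2 penalty). On linearly separable data the
    unregularised maximum-likelihood estimate does not exist and the solver
    stops at its iteration cap; this is recorded as ``converged=False``
    rather than raised, because the thresholded predictions are still
    well-defined (and perfect) in exactly that regime.
    """
    if not test:
        raise ValueError("test set is empty")
    X_all, y_all, _ = encode_design_matrix(list(train) + list(test))
    n_train = len(train)
    X_train, y_train = X_all[:n_train], y_all[:n_train]
    X_test, y_test = X_all[n_train:], y_all[n_train:]
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set contains a single class")
    model = LogisticRegression(
        C=1.0 if regularized else np.inf,
        solver="lbfgs",
        max_iter=max_iter,
    )
    import warnings as _warnings

    converged = True
    with _warnings.catch_warnings():
        _warnings.simplefilter("always", ConvergenceWarning)
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            model.fit(X_train, y_train)
            converged = not any(
                issubclass(w.category, ConvergenceWarning) for w in caught
            )
    if not converged:
        log.warning("logistic solver hit its iteration cap (n_iter=%s); "
                    "data may be separable", model.n_iter_)
    prob = model.predict_proba(X_test)[:, 1]
    pred = (prob >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y_test == 1)))
    fp = int(np.sum((pred == 1) & (y_test == 0)))
    fn = int(np.sum((pred == 0) & (y_test == 1)))
    tn = int(np.sum((pred == 0) & (y_test == 0)))
    precision, recall, f1 = confusion_metrics(tp, fp, fn, tn)
    return MetricsRecord(tp=tp, fp=fp, fn=fn, tn=tn, precision=precision,
                         recall=recall, f1=f1, split_seed=split_seed,
                         n_train=len(train), n_test=len(test),
                         converged=converged)


# ---------------------------------------------------------------------------
# Simulator

_SS_NONCOIL = np.array(["H", "E", "G", "T", "S"])


def _beta_params(mean: float, concentration: float) -> tuple[float, float]:
    return mean * concentration, (1.0 - mean) * concentration


def simulate_benchmark(params: SimulationParams) -> list[InsertionVariant]:
    """Draw a labelled variant set under the class-conditional model.

    Benign variants are shifted toward high entropy/RSA/1-BR and coil;
    pathogenic the reverse. ``s_weighted`` and ``e_min`` are computed from
    the sampled features with the scoring functions, so the derived columns
    are exactly as the scorer would produce them. Deterministic per seed.
    """
    rng = np.random.default_rng(params.seed)
    variants: list[InsertionVariant] = []
    for label, n, mean, coil_p, noncoil_p in (
        ("pathogenic", params.n_pathogenic, params.pathogenic_mean,
         params.pathogenic_coil_prob, np.asarray(params.pathogenic_noncoil_p)),
        ("benign", params.n_benign, params.benign_mean,
         params.benign_coil_prob, np.asarray(params.benign_noncoil_p)),
    ):
        a, b = _beta_params(mean, params.concentration)
        entropy = rng.beta(a, b, size=n)
        rsa = rng.beta(a, b, size=n)
        dbr = rng.beta(a, b, size=n)
        is_coil = rng.random(n) < coil_p
        noncoil = rng.choice(_SS_NONCOIL, size=n, p=noncoil_p / noncoil_p.sum())
        for i in range(n):
            code = "C" if is_coil[i] else str(noncoil[i])
            ssv = float(ss_feature(code))
            vec = (float(entropy[i]), ssv, float(rsa[i]), float(dbr[i]))
            variants.append(
                InsertionVariant(
                    protein_id=f"sim_{label[:4]}_{i}",
                    position=i + 1,
                    label=label,
                    entropy=vec[0],
                    rsa=vec[2],
                    ss_score=ssv,
                    dbr=vec[3],
                    s_weighted=weighted_score(vec, DEFAULT_WEIGHTS),
                    e_min=min_score(vec),
                    ss_code=code,
                )
            )
    return variants


def run_benchmark(
    params: SimulationParams,
    split_seed: Optional[int] = None,
    regularized: bool = False,
) -> MetricsRecord:
    """Simulate, split 80:20, fit, and score — one full protocol pass."""
    variants = simulate_benchmark(params)
    seed = params.seed if split_seed is None else split_seed
    train, test = split_train_test(variants, fraction=0.8, seed=seed)
    return fit_eval_logistic(train, test, split_seed=seed,
                             regularized=regularized)


def repeat_eval(
    variants: Sequence[InsertionVariant],
    n_repeats: int,
    base_seed: int = 0,
    regularized: bool = False,
) -> tuple[float, float, list[MetricsRecord]]:
    """Repeat the split/fit/score protocol; report mean and sample s.d. of F1."""
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    seeds = [int(s) for s in
             np.random.SeedSequence(base_seed).generate_state(n_repeats) % (2**31)]
    records = []
    for s in seeds:
        train, test = split_train_test(variants, fraction=0.8, seed=s)
        records.append(fit_eval_logistic(train, test, split_seed=s,
                                         regularized=regularized))
    f1s = np.array([r.f1 for r in records])
    return float(f1s.mean()), float(f1s.std(ddof=1)), records


# ---------------------------------------------------------------------------
# Real-data schema (acquisition out of scope; schema supported for users
# who hold a curated variant table)

VARIANT_TSV_COLUMNS = (
    "protein_id", "uniprot_accession", "position", "inserted_length", "label",
)


def read_variant_tsv(path) -> pd.DataFrame:
    """Read a curated labelled-variant table (features must be added by the
    caller by running the scorer on each protein)."""
    frame = pd.read_csv(path, sep="\t")
    missing = set(VARIANT_TSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    bad = set(frame["label"].unique()) - {"pathogenic", "benign"}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    return frame
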