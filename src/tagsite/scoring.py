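"""Per-residue score assembly, windowed smoothing, and site ranking.

Four normalised feature tracks (conservation entropy, secondary structure,
relative solvent accessibility, disordered-binding complement) are combined
per residue in two ways: E_i, the minimum over the features — a single
unfavourable feature vetoes the site — and S_i, a weighted sum with the
entropy weight raised to 1.5 by default. Candidate insertion sites are
ranked by the sliding-window average of E_i.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

#: Fixed feature order used everywhere a feature matrix appears.
FEATURE_ORDER = ("entropy", "secondary_structure", "rsa", "dbr")

#: Default feature weights for the weighted-sum score S_i.
DEFAULT_WEIGHTS = {
    "entropy": 1.5,
    "secondary_structure": 1.0,
    "rsa": 1.0,
    "dbr": 1.0,
}


@dataclass
class FeatureTrack:
    """Per-residue values of one named feature, normalised to [0, 1]."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError(f"track {self.name!r}: values must be 1-D")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ScoringConfig:
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    window: int = 7
    top_k: int = 5
    report_precision: int = 2
    #: 'clipped': centred window truncated at the termini (4-6 residues at
    #: the three terminal positions). 'terminal4': the three positions at
    #: each end all average the four terminal residues.
    terminal_mode: str = "clipped"

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        if not any(w > 0 for w in self.weights.values()):
            raise ValueError("at least one weight must be positive")
        if self.terminal_mode not in ("clipped", "terminal4"):
            raise ValueError(f"unknown terminal_mode {self.terminal_mode!r}")


@dataclass
class ResidueScore:
    position: int  # 1-based
    aa: str
    features: dict[str, float]
    e_min: float
    s_weighted: float
    e_windowed: float


@dataclass
class TagSiteReport:
    """Ranked candidate insertion positions with per-residue provenance."""

    query_id: str
    config: ScoringConfig
    residues: list[ResidueScore]
    #: (position, e_windowed, e_min), sorted by e_windowed descending,
    #: ties by ascending position.
    candidates: list[tuple[int, float, float]]
    #: scores at positions 1 and L, for N/C-terminal comparison.
    terminals: list[tuple[int, float, float]]
    tie_warning: bool = False

    def to_json(self) -> str:
        payload = {
            "query_id": self.query_id,
            "window": self.config.window,
            "top_k": self.config.top_k,
            "weights": dict(sorted(self.config.weights.items())),
            "candidates": [
                {"position": p,
                 "windowed_min_score": round(w, 6),
                 "min_score": round(e, 6)}
                for p, w, e in self.candidates
            ],
            "terminals": [
                {"position": p,
                 "windowed_min_score": round(w, 6),
                 "min_score": round(e, 6)}
                for p, w, e in self.terminals
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------


def assemble_features(
    entropy: FeatureTrack,
    ss: FeatureTrack,
    rsa: FeatureTrack,
    dbr: FeatureTrack,
) -> np.ndarray:
    """Stack the four tracks into an (L, 4) matrix in :data:`FEATURE_ORDER`.

    Raises if track lengths differ or any value falls outside [0, 1]
    (normalisation is the responsibility of the upstream feature modules).
    """
    tracks = {"entropy": entropy, "secondary_structure": ss,
              "rsa": rsa, "dbr": dbr}
    lengths = {name: len(t) for name, t in tracks.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"track length mismatch: {lengths}")
    for name, track in tracks.items():
        vals = track.values
        if np.any(~np.isfinite(vals)) or vals.min() < 0 or vals.max() > 1:
            bad = int(np.argmax((vals < 0) | (vals > 1) | ~np.isfinite(vals)))
            raise ValueError(
                f"track {name!r} has value {vals[bad]} outside [0, 1] "
                f"at position {bad + 1}"
            )
    return np.column_stack([tracks[name].values for name in FEATURE_ORDER])


def min_score(feature_vector: Sequence[float]) -> float:
    """E_i: the minimum over the feature values — one bad feature vetoes."""
    vec = np.asarray(feature_vector, dtype=float)
    if vec.size == 0:
        raise ValueError("empty feature vector")
    return float(vec.min())


def weighted_score(
    feature_vector: Sequence[float],
    weights: Mapping[str, float] = DEFAULT_WEIGHTS,
    feature_order: Sequence[str] = FEATURE_ORDER,
) -> float:
    """S_i: the weighted sum of the features, sum_f w_f * value_f."""
    missing = [f for f in feature_order if f not in weights]
    if missing:
        raise ValueError(f"missing weight for features: {missing}")
    vec = np.asarray(feature_vector, dtype=float)
    if vec.size != len(feature_order):
        raise ValueError(
            f"feature vector length {vec.size} != {len(feature_order)}"
        )
    w = np.array([weights[f] for f in feature_order])
    return float(vec @ w)


def window_average(
    track: np.ndarray,
    window: int = 7,
    terminal_mode: str = "clipped",
) -> np.ndarray:
    """Sliding-window mean of a per-residue track.

    'clipped' (default): the centred window is truncated at the sequence
    ends, so with window 7 the first three positions average 4, 5 and 6
    residues and interior positions average 7. 'terminal4': as above, but
    the three positions at each end all take the mean of the four terminal
    residues.
    """
    track = np.asarray(track, dtype=float)
    if track.ndim != 1 or track.size < 1:
        raise ValueError("track must be a non-empty 1-D array")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    # full convolution then an explicit centre slice: np.convolve(..., "same")
    # returns the wrong length when the track is shorter than the window
    half = window // 2
    kernel = np.ones(window)
    sums = np.convolve(track, kernel, mode="full")[half : half + track.size]
    counts = np.convolve(np.ones_like(track), kernel,
                         mode="full")[half : half + track.size]
    out = sums / counts
    if terminal_mode == "terminal4":
        ncap = min(3, track.size)
        k = min(4, track.size)
        out[:ncap] = track[:k].mean()
        out[-ncap:] = track[-k:].mean()
    elif terminal_mode != "clipped":
        raise ValueError(f"unknown terminal_mode {terminal_mode!r}")
    return out


def score_residues(
    matrix: np.ndarray,
    sequence: str,
    config: Optional[ScoringConfig] = None,
) -> list[ResidueScore]:
    """Compute E_i, S_i and the windowed E for every residue."""
    config = config or ScoringConfig()
    if matrix.shape[0] != len(sequence):
        raise ValueError(
            f"feature matrix has {matrix.shape[0]} rows but sequence "
            f"has {len(sequence)} residues"
        )
    e = matrix.min(axis=1)
    w = np.array([config.weights[f] for f in FEATURE_ORDER])
    s = matrix @ w
    ew = window_average(e, config.window, config.terminal_mode)
    return [
        ResidueScore(
            position=i + 1,
            aa=sequence[i],
            features={f: float(matrix[i, j]) for j, f in enumerate(FEATURE_ORDER)},
            e_min=float(e[i]),
            s_weighted=float(s[i]),
            e_windowed=float(ew[i]),
        )
        for i in range(matrix.shape[0])
    ]


def rank_sites(
    scores: Sequence[ResidueScore],
    top_k: Optional[int] = None,
    config: Optional[ScoringConfig] = None,
    query_id: str = "query",
) -> TagSiteReport:
    """Rank positions by windowed E descending (ties by ascending position).

    Returns the top ``top_k`` candidates plus any positions tied with the
    k-th; the two terminal positions are always reported separately so the
    internal sites can be compared with conventional end-tagging.
    """
    config = config or ScoringConfig()
    if top_k is None:
        top_k = config.top_k
    if not scores:
        raise ValueError("no residue scores to rank")
    order = sorted(scores, key=lambda r: (-r.e_windowed, r.position))
    cut = min(top_k, len(order))
    kth = order[cut - 1].e_windowed
    selected = [r for r in order[:cut]]
    selected += [r for r in order[cut:] if r.e_windowed == kth]
    tie_warning = len(selected) > top_k
    last = scores[-1].position
    terminals = [
        (r.position, r.e_windowed, r.e_min)
        for r in scores if r.position in (1, last)
    ]
    return TagSiteReport(
        query_id=query_id,
        config=config,
        residues=list(scores),
        candidates=[(r.position, r.e_windowed, r.e_min) for r in selected],
        terminals=terminals,
        tie_warning=tie_warning,
    )
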