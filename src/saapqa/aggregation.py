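"""Sequence-level aggregation-propensity profiling and hot-spot detection.

Reimplements the Aggrescan procedure from its published constants: each
residue gets an intrinsic aggregation propensity (a3v); a length-dependent
sliding window averages it (a4v, assigned to the central residue, windows
shrinking at the termini); a hot spot is a maximal run of at least five
consecutive residues whose window average exceeds the hot-spot threshold
and that contains no proline.  Residues inside hot spots are the
aggregation-prone set whose solvent exposure the SAAP score measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import config
from .core import SequenceRecord


class PropensityLookupError(KeyError):
    """Raised when a letter outside the 20-residue scale is looked up."""


def propensity_table() -> dict[str, float]:
    """The 20-entry intrinsic aggregation-propensity scale (a3v)."""
    return dict(config.AGGRESCAN_A3V)


def propensity(letter: str) -> float:
    try:
        return config.AGGRESCAN_A3V[letter]
    except KeyError:
        raise PropensityLookupError(
            f"no aggregation propensity for {letter!r}; scale covers the 20 standard residues"
        ) from None


#: Neutral propensity assigned to 'X' residues: the mean of the scale.
_SCALE_MEAN = float(np.mean(list(config.AGGRESCAN_A3V.values())))


def window_size_for_length(length: int,
                           bands: tuple[tuple[float, int], ...] = config.AGGRESCAN_WINDOW_BANDS,
                           ) -> int:
    """Length-banded sliding-window size (5/7/9/11 by default)."""
    for max_len, window in bands:
        if length <= max_len:
            return window
    raise AssertionError("window bands must cover all lengths")


@dataclass
class AggregationProfile:
    """Per-residue aggregation propensities, window averages and hot spots."""

    sequence_id: str
    sequence: str
    window: int
    per_residue_propensity: np.ndarray
    window_average: np.ndarray
    hot_spots: list[tuple[int, int]] = field(default_factory=list)   # inclusive, 0-based
    is_aggregation_prone: np.ndarray | None = None

    @property
    def aggre_prone_total(self) -> int:
        """Total number of aggregation-prone residues (the SAAP denominator)."""
        if self.is_aggregation_prone is None:
            return 0
        return int(np.sum(self.is_aggregation_prone))

    def __len__(self) -> int:
        return len(self.sequence)


def window_profile(seq: SequenceRecord,
                   cfg: config.RunConfig = config.DEFAULT_CONFIG) -> AggregationProfile:
    """Compute per-residue propensities and the window-averaged profile.

    The window is centred on each residue and shrinks at the termini to the
    available residues (no padding).
    """
    n = len(seq.sequence)
    window = window_size_for_length(n, cfg.window_bands)
    if n < min(w for _, w in cfg.window_bands):
        raise ValueError(
            f"sequence {seq.id!r} of length {n} is shorter than the smallest window")
    per_res = np.array([
        _SCALE_MEAN if aa == "X" else propensity(aa) for aa in seq.sequence
    ])
    half = (window - 1) // 2
    avg = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        avg[i] = per_res[lo:hi].mean()
    return AggregationProfile(
        sequence_id=seq.id, sequence=seq.sequence, window=window,
        per_residue_propensity=per_res, window_average=avg,
    )


def detect_hot_spots(profile: AggregationProfile,
                     cfg: config.RunConfig = config.DEFAULT_CONFIG) -> AggregationProfile:
    """Segment the profile into hot spots and flag their residues.

    A residue is eligible when its window average strictly exceeds the
    threshold and it is neither proline (aggregation breaker) nor an
    unknown 'X'; maximal eligible runs of at least ``hot_spot_min_run``
    residues become hot spots.
    """
    n = len(profile)
    eligible = (profile.window_average > cfg.hot_spot_threshold)
    for i, aa in enumerate(profile.sequence):
        if aa in ("P", "X"):
            eligible[i] = False
    flags = np.zeros(n, dtype=bool)
    spots: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if eligible[i]:
            j = i
            while j + 1 < n and eligible[j + 1]:
                j += 1
            if j - i + 1 >= cfg.hot_spot_min_run:
                spots.append((i, j))
                flags[i:j + 1] = True
            i = j + 1
        else:
            i += 1
    profile.hot_spots = spots
    profile.is_aggregation_prone = flags
    return profile


def profile_sequence(seq: SequenceRecord,
                     cfg: config.RunConfig = config.DEFAULT_CONFIG) -> AggregationProfile:
    """Full profiling: window averages plus hot-spot segmentation."""
    return detect_hot_spots(window_profile(seq, cfg), cfg)


def profile_table(profile: AggregationProfile) -> "list[dict]":
    """Per-residue rows for CSV export (index, aa, a3v, a4v, hot spot id, flag)."""
    spot_of = {}
    for sid, (lo, hi) in enumerate(profile.hot_spots):
        for k in range(lo, hi + 1):
            spot_of[k] = sid
    flags = profile.is_aggregation_prone
    return [
        {
            "index": i,
            "aa": profile.sequence[i],
            "propensity": float(profile.per_residue_propensity[i]),
            "window_average": float(profile.window_average[i]),
            "hot_spot_id": spot_of.get(i, -1),
            "is_aggregation_prone": bool(flags[i]) if flags is not None else False,
        }
        for i in range(len(profile))
    ]
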