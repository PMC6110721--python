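"""The SAAP score: solvent accessibility of aggregation-prone patches.

Joins sequence-level aggregation flags with structure-level side-chain
accessibility.  Per residue, SAAP_i = 1 iff the residue is inside a
sequence-predicted aggregation hot spot AND its side chain is more than 50%
solvent accessible in the model; the protein score SAAP_p is the percentage
of aggregation-prone residues that are accessible:

    SAAP_p = 100 * sum_i SAAP_i / AggreProne_T

Aggregation flags always come from the full target sequence; flagged
positions unresolved in the model contribute 0 to the numerator but still
count in the denominator.  Native-like folds bury their aggregation patches
and score low; unfolded or poorly modelled structures score high.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import config
from .aggregation import AggregationProfile, profile_sequence
from .core import SequenceRecord, read_structure, structure_sequence
from .surface import AccessibilityProfile, compute_sasa

logger = logging.getLogger(__name__)


class UndefinedSaapError(ValueError):
    """Raised when the sequence has no aggregation patches (denominator 0)."""


@dataclass
class SaapResult:
    structure_id: str
    saap_p: float | None             # percent, None when undefined
    saap_i: np.ndarray               # boolean per sequence position
    n_accessible_agg: int            # numerator
    aggre_prone_total: int           # denominator

    @property
    def defined(self) -> bool:
        return self.saap_p is not None


def saap_score(agg: AggregationProfile, acc: AccessibilityProfile,
               mapping: Mapping[int, tuple[int, str]] | None = None,
               cutoff_percent: float = config.EXPOSURE_CUTOFF_PERCENT,
               strict: bool = False) -> SaapResult:
    """Score one model against the target's aggregation profile.

    ``mapping`` pairs 0-based sequence positions with structure residue keys
    (seq_number, insertion_code); by default position i maps to residue
    number i+1 (target numbering).  Exposure uses strict inequality:
    exactly 50% counts as buried.

    With ``strict=True`` an aggregation-free sequence raises
    :class:`UndefinedSaapError`; otherwise the result is returned with
    ``saap_p = None``.
    """
    flags = agg.is_aggregation_prone
    if flags is None:
        raise ValueError("aggregation profile lacks hot-spot flags; run detect_hot_spots")
    n = len(agg)
    if mapping is None:
        mapping = {i: (i + 1, "") for i in range(n)}
    rel = acc.rel_by_key()
    saap_i = np.zeros(n, dtype=bool)
    for i in range(n):
        if not flags[i]:
            continue
        key = mapping.get(i)
        if key is None or key not in rel:
            continue        # unresolved in the model: counts in denominator only
        r = rel[key]
        if np.isfinite(r) and r > cutoff_percent:
            saap_i[i] = True
    total = agg.aggre_prone_total
    numerator = int(saap_i.sum())
    if total == 0:
        if strict:
            raise UndefinedSaapError(
                f"{acc.structure_id}: no aggregation patches in sequence {agg.sequence_id!r}")
        return SaapResult(acc.structure_id, None, saap_i, 0, 0)
    return SaapResult(acc.structure_id, 100.0 * numerator / total, saap_i,
                      numerator, total)


def identity_mapping_from_numbers(seq_len: int, offset: int = 0) -> dict[int, tuple[int, str]]:
    """Map sequence position i to residue number i + 1 + offset."""
    return {i: (i + 1 + offset, "") for i in range(seq_len)}


def score_structure(path: str | Path, target_seq: SequenceRecord | None = None,
                    cfg: config.RunConfig = config.DEFAULT_CONFIG) -> SaapResult:
    """Full single-structure pipeline: parse, profile, SASA, SAAP."""
    s = read_structure(path)
    seq = target_seq if target_seq is not None else structure_sequence(s)
    agg = profile_sequence(seq, cfg)
    acc = compute_sasa(s, probe=cfg.probe_radius, n_points=cfg.sasa_points)
    return saap_score(agg, acc, cutoff_percent=cfg.exposure_cutoff)


def batch_saap(paths: Sequence[str | Path], target_seq: SequenceRecord | None = None,
               cfg: config.RunConfig = config.DEFAULT_CONFIG) -> pd.DataFrame:
    """Score a pool of models; per-file failures are logged and skipped.

    Returns one row per successfully scored structure with columns
    model_id, saap_p, n_accessible_agg, aggre_prone_total, defined.
    Undefined rows (no aggregation patches) carry NaN saap_p and
    ``defined = False`` so summaries can exclude them.
    """
    rows = []
    for path in paths:
        try:
            res = score_structure(path, target_seq=target_seq, cfg=cfg)
        except Exception as exc:                     # noqa: BLE001 - per-file isolation
            logger.warning("skipping %s: %s", path, exc)
            continue
        rows.append({
            "model_id": res.structure_id,
            "saap_p": res.saap_p if res.defined else np.nan,
            "n_accessible_agg": res.n_accessible_agg,
            "aggre_prone_total": res.aggre_prone_total,
            "defined": res.defined,
        })
    return pd.DataFrame(rows, columns=["model_id", "saap_p", "n_accessible_agg",
                                       "aggre_prone_total", "defined"])
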