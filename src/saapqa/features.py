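"""Secondary-structure assignment and the six quality-assessment descriptors.

Secondary structure is assigned with a reduced DSSP-style method: amide
hydrogens are reconstructed from the backbone, backbone H-bonds are scored
with the Kabsch-Sander electrostatic energy (bond if E < -0.5 kcal/mol),
helices come from consecutive 3-/4-/5-turns and strands from parallel or
antiparallel bridge patterns, then the 8 states collapse to H/E/C.  If a
``stride`` or other external assigner is preferred it can be swapped in
behind :func:`assign_secondary_structure`; the three-state fractions used
downstream are robust to the assigner choice.

The descriptor vector feeding the regression model is, in fixed order:
SAAP_p, helix fraction, sheet fraction, loop fraction, loop content
(residue count) and SAAP_p / loop content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import config
from .aggregation import AggregationProfile
from .core import Structure
from .saap import saap_score
from .surface import compute_sasa

#: Kabsch-Sander H-bond energy threshold (kcal/mol).
HBOND_ENERGY_CUTOFF = -0.5

#: Fixed feature order: the input contract of the regression model.
FEATURE_NAMES = ("saap_p", "helix_fraction", "sheet_fraction",
                 "loop_fraction", "loop_content", "saap_loop_ratio")


class BackboneError(ValueError):
    """Raised when too few residues have complete backbones."""


@dataclass
class SecondaryStructure:
    """Three-state (H/E/C) assignment, one state per resolved residue."""

    states: str

    def fraction(self, state: str) -> float:
        if not self.states:
            return 0.0
        return self.states.count(state) / len(self.states)

    def count(self, state: str) -> int:
        return self.states.count(state)

    def __len__(self) -> int:
        return len(self.states)


def _backbone_frames(s: Structure) -> tuple[np.ndarray, np.ndarray]:
    """(n,4,3) N/CA/C/O coordinates and a completeness mask."""
    n = len(s.residues)
    coords = np.full((n, 4, 3), np.nan)
    ok = np.zeros(n, dtype=bool)
    for i, r in enumerate(s.residues):
        parts = [r.atom_coord(a) for a in ("N", "CA", "C", "O")]
        if all(p is not None for p in parts):
            coords[i] = np.stack(parts)  # type: ignore[arg-type]
            ok[i] = True
    return coords, ok


def hbond_energy_matrix(s: Structure) -> np.ndarray:
    """Kabsch-Sander energies E[donor, acceptor] in kcal/mol (inf if undefined).

    The amide H of residue i is placed 1.0 Å from N, anti to the preceding
    carbonyl.  Chain-break-adjacent and proline donors get no H.
    """
    bb, ok = _backbone_frames(s)
    n = len(s.residues)
    energy = np.full((n, n), np.inf)
    h_pos = np.full((n, 3), np.nan)
    for i in range(1, n):
        if not (ok[i] and ok[i - 1]):
            continue
        if s.residues[i].name == "PRO":
            continue
        # consecutive in author numbering and peptide-bonded (C-N < 2.5 Å)
        c_prev, o_prev = bb[i - 1, 2], bb[i - 1, 3]
        n_i = bb[i, 0]
        if np.linalg.norm(n_i - c_prev) > 2.5:
            continue
        d = c_prev - o_prev
        h_pos[i] = n_i + d / np.linalg.norm(d)
    q1q2f = 0.084 * 332.0
    for i in range(n):            # donor NH
        if not np.isfinite(h_pos[i]).all():
            continue
        for j in range(n):        # acceptor C=O
            if abs(i - j) < 2 or not ok[j]:
                continue
            c_j, o_j = bb[j, 2], bb[j, 3]
            n_i, h_i = bb[i, 0], h_pos[i]
            r_on = np.linalg.norm(o_j - n_i)
            r_ch = np.linalg.norm(c_j - h_i)
            r_oh = np.linalg.norm(o_j - h_i)
            r_cn = np.linalg.norm(c_j - n_i)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                energy[i, j] = -9.9
                continue
            energy[i, j] = q1q2f * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
    return energy


def assign_secondary_structure(s: Structure,
                               min_backbone_fraction: float = 0.9) -> SecondaryStructure:
    """Three-state secondary structure from backbone H-bond patterns.

    Residues with incomplete backbones are assigned C.  Raises
    :class:`BackboneError` if fewer than ``min_backbone_fraction`` of the
    residues have complete N/CA/C/O backbones.
    """
    n = len(s.residues)
    _, ok = _backbone_frames(s)
    if ok.sum() < min_backbone_fraction * n:
        raise BackboneError(
            f"{s.id}: only {int(ok.sum())}/{n} residues have full backbones")
    energy = hbond_energy_matrix(s)
    hbond = energy < HBOND_ENERGY_CUTOFF   # hbond[donor, acceptor]

    def turn(k: int) -> np.ndarray:
        """turn_k[i]: H-bond from NH(i+k) to CO(i)."""
        t = np.zeros(n, dtype=bool)
        for i in range(n - k):
            t[i] = hbond[i + k, i]
        return t

    states = np.full(n, "C", dtype="<U1")
    # Helices: two consecutive n-turns start a helix of n residues.
    for k in (4, 3, 5):
        tk = turn(k)
        for i in range(1, n - k):
            if tk[i - 1] and tk[i]:
                states[i:i + k] = "H"
    # Bridges (parallel / antiparallel), residues marked E unless helical.
    bridge = np.zeros(n, dtype=bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hbond[j, i - 1] and hbond[i + 1, j]) or (hbond[i, j - 1] and hbond[j + 1, i])
            anti = (hbond[i, j] and hbond[j, i]) or (hbond[j + 1, i - 1] and hbond[i + 1, j - 1])
            if para or anti:
                bridge[i] = True
                bridge[j] = True
    states[bridge & (states != "H")] = "E"
    return SecondaryStructure(states="".join(states))


@dataclass
class DescriptorVector:
    """The six SAAP-QA features in fixed order (see FEATURE_NAMES)."""

    saap_p: float
    helix_fraction: float
    sheet_fraction: float
    loop_fraction: float
    loop_content: int
    saap_loop_ratio: float
    valid: bool = True

    def as_array(self) -> np.ndarray:
        return np.array([self.saap_p, self.helix_fraction, self.sheet_fraction,
                         self.loop_fraction, float(self.loop_content),
                         self.saap_loop_ratio])

    def as_dict(self) -> dict[str, float]:
        d = dict(zip(FEATURE_NAMES, self.as_array()))
        d["valid"] = self.valid
        return d


def compute_descriptors(s: Structure, agg: AggregationProfile,
                        cfg: config.RunConfig = config.DEFAULT_CONFIG,
                        sse: SecondaryStructure | None = None) -> DescriptorVector:
    """Assemble the six-descriptor vector for one model.

    Fractions are over the model's resolved residues.  When the sequence
    has no aggregation patches SAAP_p is undefined and the vector is
    flagged invalid (excluded from training).  A precomputed secondary
    structure may be passed to avoid recomputation.
    """
    if sse is None:
        sse = assign_secondary_structure(s)
    acc = compute_sasa(s, probe=cfg.probe_radius, n_points=cfg.sasa_points)
    res = saap_score(agg, acc, cutoff_percent=cfg.exposure_cutoff)
    loop_content = sse.count("C")
    if not res.defined:
        return DescriptorVector(np.nan, sse.fraction("H"), sse.fraction("E"),
                                sse.fraction("C"), loop_content, np.nan, valid=False)
    saap_p = float(res.saap_p)
    # All-helix/sheet models: define the ratio against a loop content of 1.
    ratio = saap_p / max(loop_content, 1)
    return DescriptorVector(saap_p, sse.fraction("H"), sse.fraction("E"),
                            sse.fraction("C"), loop_content, ratio, valid=True)
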