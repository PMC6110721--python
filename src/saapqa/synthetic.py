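"""Synthetic reference structures and perturbation-graded decoy pools.

Emulates CASP-style template-based-modelling decoy sets without any
downloads.  A reference "native" is a five-helix bundle built from ideal
geometry: a fully hydrophobic central helix (the sequence-level aggregation
hot spot) surrounded by four amphipathic helices whose core-facing residues
are mildly hydrophobic and whose solvent faces are polar/charged, connected
by proline-containing loops.  By construction the aggregation patch is
buried, so the reference scores a low SAAP_p — the behaviour observed for
native folds.  Decoys are generated per noise tier by randomising the
backbone torsions of a contiguous segment (re-embedding the chain from
internal coordinates) plus residue-correlated Cartesian noise; unfolding
exposes the aggregation patch, so decoy quality (true GDT, computed against
the reference) and SAAP_p move in opposite directions across tiers.

Decoys are idealized, not energy-minimized: the descriptors used downstream
depend only on Cα geometry, backbone H-bonding and side-chain exposure.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import config, _geometry
from .aggregation import profile_sequence
from .core import ONE_TO_THREE, Residue, SequenceRecord, Structure, write_fasta, write_structure
from .features import compute_descriptors
from .gdt import compute_gdt
from .saap import saap_score
from .surface import compute_sasa

HYDROPHOBIC_CORE = "IVLF"           # high aggregation propensity
INWARD_MILD = "AVL"                 # outer-helix residues facing the core
OUTWARD_POLAR = "KESTNQDR"          # solvent faces and termini
LOOP_RESIDUES = "GSND"              # plus one proline per loop


class ReferenceGenerationError(RuntimeError):
    """Raised when no sufficiently buried reference emerges after retries."""


@dataclass
class DecoyPoolSpec:
    """Study conditions for one synthetic benchmark pool."""

    n_targets: int = 20
    models_per_target: int = 50
    chain_length: int = 120
    noise_tiers: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0)      # σ in Å
    unfold_fraction_per_tier: tuple[float, ...] = (0.0, 0.08, 0.2, 0.4, 0.65)
    seed: int = 0

    def __post_init__(self) -> None:
        sig = list(self.noise_tiers)
        if any(s <= 0 for s in sig) or any(b <= a for a, b in zip(sig, sig[1:])):
            raise ValueError("noise tiers must be positive and strictly increasing")
        if len(self.unfold_fraction_per_tier) != len(self.noise_tiers):
            raise ValueError("one unfold fraction per noise tier required")
        if not all(0 <= f <= 1 for f in self.unfold_fraction_per_tier):
            raise ValueError("unfold fractions must be in [0, 1]")

    def to_json(self) -> str:
        return json.dumps({
            "n_targets": self.n_targets,
            "models_per_target": self.models_per_target,
            "chain_length": self.chain_length,
            "noise_tiers": list(self.noise_tiers),
            "unfold_fraction_per_tier": list(self.unfold_fraction_per_tier),
            "seed": self.seed,
        }, indent=2)


@dataclass
class ModelPool:
    """One target's decoy set with true GDT labels."""

    target_id: str
    reference: Structure
    sequence: SequenceRecord
    models: list[tuple[str, Structure]]
    labels: dict[str, float]
    tiers: dict[str, int] = field(default_factory=dict)     # model_id -> tier index

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir) / self.target_id
        out.mkdir(parents=True, exist_ok=True)
        write_structure(self.reference, out / "reference.pdb")
        write_fasta([self.sequence], out / "target.fasta")
        for model_id, s in self.models:
            write_structure(s, out / f"{model_id}.pdb")
        pd.DataFrame(
            [{"model_id": mid, "true_gdt": self.labels[mid], "tier": self.tiers.get(mid, -1)}
             for mid, _ in self.models]
        ).to_csv(out / "labels.csv", index=False)


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

def _ideal_helix_backbone(n_res: int) -> np.ndarray:
    return _geometry.build_backbone([_geometry.HELIX_PHI_PSI] * n_res)


def _principal_axis(ca: np.ndarray) -> np.ndarray:
    centered = ca - ca.mean(axis=0)
    _u, _s, vt = np.linalg.svd(centered)
    axis = vt[0]
    # orient along increasing residue index
    if np.dot(ca[-1] - ca[0], axis) < 0:
        axis = -axis
    return axis


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector a to unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180° flip about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        v = np.cross(a, perp)
        v /= np.linalg.norm(v)
        return 2 * np.outer(v, v) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1 / (1 + c))


def _place_helix(n_res: int, center_xy: tuple[float, float], direction_up: bool) -> np.ndarray:
    """Ideal helix backbone aligned to ±z through (x, y), z-centred at 0."""
    bb = _ideal_helix_backbone(n_res)
    ca = bb[1::3]
    axis = _principal_axis(ca)
    target = np.array([0.0, 0.0, 1.0 if direction_up else -1.0])
    rot = _rotation_between(axis, target)
    bb = bb @ rot.T
    ca = bb[1::3]
    centroid = ca.mean(axis=0)
    bb = bb - centroid + np.array([center_xy[0], center_xy[1], 0.0])
    return bb


def _loop_backbone(start: np.ndarray, end: np.ndarray, n_res: int,
                   bow: np.ndarray) -> np.ndarray:
    """Crude loop backbone: CA along a bowed path, N/C interpolated.

    Geometry is only approximately peptide-like; loops are assigned coil by
    the H-bond assigner, which is the intended behaviour.
    """
    out = np.zeros((3 * n_res, 3))
    step = (end - start) / (n_res + 1)
    step_n = step / max(np.linalg.norm(step), 1e-9)
    # a perpendicular kink keeps N/CA/C non-collinear so torsions stay defined
    perp = np.cross(step_n, np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(step_n, np.array([1.0, 0.0, 0.0]))
    perp /= np.linalg.norm(perp)
    for i in range(n_res):
        t = (i + 1) / (n_res + 1)
        ca = (1 - t) * start + t * end + math.sin(math.pi * t) * bow
        out[3 * i] = ca - 1.40 * step_n + 0.45 * perp    # N
        out[3 * i + 1] = ca                              # CA
        out[3 * i + 2] = ca + 1.45 * step_n + 0.45 * perp  # C
    return out


def _build_bundle_backbone(length: int) -> tuple[np.ndarray, list[str]]:
    """Backbone of the five-helix bundle and a per-residue role string.

    Roles: 'c' central-helix, 'o' outer-helix, 'l' loop.  The central helix
    is third in chain order so unfolding windows can hit it from either side.
    """
    n_loops = 4
    loop_len = 5
    helix_len = (length - n_loops * loop_len) // 5
    extra = length - n_loops * loop_len - 5 * helix_len
    helix_lens = [helix_len] * 5
    helix_lens[2] += extra                       # remainder to the central helix
    a = 9.8 / math.sqrt(2)                       # outer helix axes 9.8 Å from centre
    positions = [(-a, -a), (-a, a), (0.0, 0.0), (a, a), (a, -a)]
    segments: list[np.ndarray] = []
    roles: list[str] = []
    prev_end: np.ndarray | None = None
    for h, (pos, n_res) in enumerate(zip(positions, helix_lens)):
        up = h % 2 == 0
        bb = _place_helix(n_res, pos, direction_up=up)
        if prev_end is not None:
            start = prev_end
            end = bb[1]                          # first CA of the next helix
            outward = np.array([*(np.array(pos) * 0.35), 0.0])
            bow = outward + np.array([0.0, 0.0, 3.0 if start[2] > 0 else -3.0])
            segments.append(_loop_backbone(start, end, loop_len, bow))
            roles.extend("l" * loop_len)
        segments.append(bb)
        roles.extend(("c" if h == 2 else "o") * n_res)
        prev_end = bb[-2]                        # last CA of this helix
    return np.vstack(segments), roles


def _design_sequence(backbone: np.ndarray, roles: list[str],
                     rng: np.random.Generator) -> str:
    """Sequence design: hydrophobic buried core, polar solvent faces."""
    n = len(roles)
    ca = backbone[1::3]
    letters: list[str] = []
    loop_positions = [i for i, r in enumerate(roles) if r == "l"]
    # one proline per loop, placed centrally
    loop_groups: list[list[int]] = []
    for i in loop_positions:
        if loop_groups and i == loop_groups[-1][-1] + 1:
            loop_groups[-1].append(i)
        else:
            loop_groups.append([i])
    proline_at = {g[len(g) // 2] for g in loop_groups}
    for i, role in enumerate(roles):
        if role == "c":
            letters.append(HYDROPHOBIC_CORE[int(rng.integers(len(HYDROPHOBIC_CORE)))])
        elif role == "l":
            if i in proline_at:
                letters.append("P")
            else:
                letters.append(LOOP_RESIDUES[int(rng.integers(len(LOOP_RESIDUES)))])
        else:
            # outer helix: inward-facing residues mildly hydrophobic
            nn, cca, cc = backbone[3 * i], backbone[3 * i + 1], backbone[3 * i + 2]
            cb = _geometry.place_atom(cc, nn, cca, 1.53, 110.4, -122.0)
            outward = cb - cca
            toward_core = np.array([-cca[0], -cca[1], 0.0])
            norm = np.linalg.norm(toward_core)
            inward = norm > 1e-6 and float(
                np.dot(outward, toward_core / norm)) > 0.5 * np.linalg.norm(outward)
            if inward:
                letters.append(INWARD_MILD[int(rng.integers(len(INWARD_MILD)))])
            else:
                letters.append(OUTWARD_POLAR[int(rng.integers(len(OUTWARD_POLAR)))])
    return "".join(letters)


def _structure_from_backbone(backbone: np.ndarray, sequence: str,
                             structure_id: str) -> Structure:
    """Full heavy-atom structure: backbone + carbonyl O + template side chains."""
    oxy = _geometry.carbonyl_oxygens(backbone)
    residues = []
    for i, aa in enumerate(sequence):
        res_name = ONE_TO_THREE[aa]
        n, ca, c = backbone[3 * i], backbone[3 * i + 1], backbone[3 * i + 2]
        atoms = [
            ("N", "N", *map(float, n)),
            ("CA", "C", *map(float, ca)),
            ("C", "C", *map(float, c)),
            ("O", "O", *map(float, oxy[i])),
        ]
        for name, pos in _geometry.build_side_chain(res_name, n, ca, c):
            atoms.append((name, _geometry.element_of(name), *map(float, pos)))
        residues.append(Residue(name=res_name, seq_number=i + 1, atoms=atoms))
    return Structure(id=structure_id, chain_id="A", residues=residues)


def build_reference(length: int, seed: int, target_id: str = "SYN",
                    max_attempts: int = 5,
                    cfg: config.RunConfig = config.DEFAULT_CONFIG,
                    ) -> tuple[Structure, SequenceRecord]:
    """Deterministic reference native with a buried aggregation patch.

    The generated structure must score SAAP_p < 30 (the regime native
    structures occupy); sequence design is retried up to ``max_attempts``
    times before failing with diagnostics.
    """
    if not 60 <= length <= 500:
        raise ValueError(f"length {length} outside the supported 60-500 range")
    backbone, roles = _build_bundle_backbone(length)
    attempts: list[float] = []
    for attempt in range(max_attempts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        sequence = _design_sequence(backbone, roles, rng)
        seq = SequenceRecord(id=target_id, sequence=sequence)
        s = _structure_from_backbone(backbone, sequence, target_id)
        agg = profile_sequence(seq, cfg)
        if agg.aggre_prone_total == 0:
            attempts.append(float("nan"))
            continue
        acc = compute_sasa(s, probe=cfg.probe_radius, n_points=cfg.sasa_points)
        res = saap_score(agg, acc, cutoff_percent=cfg.exposure_cutoff)
        attempts.append(float(res.saap_p))
        if res.saap_p is not None and res.saap_p < 30.0:
            return s, seq
    raise ReferenceGenerationError(
        f"no reference with SAAP_p < 30 in {max_attempts} attempts "
        f"(observed: {attempts}); length={length} seed={seed}")


# ---------------------------------------------------------------------------
# Decoy generation
# ---------------------------------------------------------------------------

#: Coil torsion region sampled during unfolding (degrees): broadly extended
#: polyproline-II/β basin, which maximises exposure of the unfolded segment.
_COIL_PHI = (-160.0, -60.0)
_COIL_PSI = (60.0, 175.0)


def _backbone_of(s: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Flat (3n,3) N/CA/C array and per-residue O torsion internal coords."""
    n = len(s.residues)
    bb = np.zeros((3 * n, 3))
    o_int = np.zeros((n, 3))
    for i, r in enumerate(s.residues):
        for k, name in enumerate(("N", "CA", "C")):
            coord = r.atom_coord(name)
            if coord is None:
                raise ValueError(f"{s.id}: residue {r.seq_number} lacks backbone atom {name}")
            bb[3 * i + k] = coord
        o = r.atom_coord("O")
        if o is None:
            o_int[i] = (_geometry.BOND_C_O, _geometry.ANGLE_CA_C_O, 180.0)
        else:
            o_int[i] = (
                float(np.linalg.norm(o - bb[3 * i + 2])),
                _geometry.bond_angle(bb[3 * i + 1], bb[3 * i + 2], o),
                _geometry.dihedral(bb[3 * i], bb[3 * i + 1], bb[3 * i + 2], o),
            )
    return bb, o_int


def _perturbed_structure(reference: Structure, sequence: str, model_id: str,
                         sigma: float, unfold_fraction: float,
                         rng: np.random.Generator) -> Structure:
    bb, o_int = _backbone_of(reference)
    n = len(sequence)
    if unfold_fraction > 0:
        bonds, angles, torsions = _geometry.extract_internal(bb)
        w = max(1, int(round(unfold_fraction * n)))
        start = int(rng.integers(1, max(2, n - w)))       # keep residue 0 anchored
        for i in range(start, min(start + w, n)):
            phi = float(rng.uniform(*_COIL_PHI))
            psi = float(rng.uniform(*_COIL_PSI))
            pi, si = _geometry.phi_atom_index(i), _geometry.psi_atom_index(i)
            if pi >= 3:
                torsions[pi] = phi
            if si < 3 * n:
                torsions[si] = psi
        bb = _geometry.rebuild_backbone(bb[:3], bonds, angles, torsions)
    # Residue-correlated Cartesian noise: iid per-residue offsets smoothed
    # along the chain (window 5) preserve local geometry while degrading
    # the global fold, then rescaled to marginal std sigma per coordinate.
    raw = rng.normal(size=(n + 4, 3))
    kernel = np.ones(5) / 5.0
    smooth = np.stack([np.convolve(raw[:, k], kernel, mode="valid") for k in range(3)], axis=1)
    smooth *= sigma / math.sqrt(np.mean(kernel ** 2) * 5)
    offsets = smooth[:n]
    # Rebuild O and side chains in the (possibly re-embedded) frames.
    structure = _structure_from_backbone_with_o(bb, o_int, sequence, model_id)
    for i, r in enumerate(structure.residues):
        r.atoms = [(name, el, x + offsets[i, 0], y + offsets[i, 1], z + offsets[i, 2])
                   for name, el, x, y, z in r.atoms]
    return structure


def _structure_from_backbone_with_o(bb: np.ndarray, o_int: np.ndarray,
                                    sequence: str, structure_id: str) -> Structure:
    residues = []
    for i, aa in enumerate(sequence):
        res_name = ONE_TO_THREE[aa]
        n, ca, c = bb[3 * i], bb[3 * i + 1], bb[3 * i + 2]
        o = _geometry.place_atom(n, ca, c, *o_int[i])
        atoms = [
            ("N", "N", *map(float, n)),
            ("CA", "C", *map(float, ca)),
            ("C", "C", *map(float, c)),
            ("O", "O", *map(float, o)),
        ]
        for name, pos in _geometry.build_side_chain(res_name, n, ca, c):
            atoms.append((name, _geometry.element_of(name), *map(float, pos)))
        residues.append(Residue(name=res_name, seq_number=i + 1, atoms=atoms))
    return Structure(id=structure_id, chain_id="A", residues=residues)


def make_decoys(reference: Structure, sequence: SequenceRecord,
                spec: DecoyPoolSpec, target_id: str | None = None,
                gdt_seed_stride: int = 3) -> ModelPool:
    """Decoy pool spanning a quality gradient, with computed true GDT labels.

    Models are distributed evenly over the noise tiers; each tier applies
    its torsion-randomised unfolding window plus correlated Cartesian
    noise.  All randomness derives from ``spec.seed``.
    """
    target_id = target_id or reference.id
    n_tiers = len(spec.noise_tiers)
    per_tier = [spec.models_per_target // n_tiers] * n_tiers
    for i in range(spec.models_per_target - sum(per_tier)):
        per_tier[i % n_tiers] += 1
    models: list[tuple[str, Structure]] = []
    labels: dict[str, float] = {}
    tiers: dict[str, int] = {}
    counter = 0
    for tier, (sigma, unfold) in enumerate(zip(spec.noise_tiers,
                                               spec.unfold_fraction_per_tier)):
        for j in range(per_tier[tier]):
            rng = np.random.default_rng(np.random.SeedSequence([spec.seed, tier, j]))
            model_id = f"{target_id}_t{tier}_m{counter:03d}"
            counter += 1
            s = _perturbed_structure(reference, sequence.sequence, model_id,
                                     sigma, unfold, rng)
            gdt = compute_gdt(s, reference, seed_stride=gdt_seed_stride)
            models.append((model_id, s))
            labels[model_id] = gdt.gdt_ts
            tiers[model_id] = tier
    return ModelPool(target_id=target_id, reference=reference, sequence=sequence,
                     models=models, labels=labels, tiers=tiers)


# ---------------------------------------------------------------------------
# Benchmark assembly
# ---------------------------------------------------------------------------

def build_benchmark(spec: DecoyPoolSpec,
                    cfg: config.RunConfig = config.DEFAULT_CONFIG) -> list[ModelPool]:
    """Generate ``spec.n_targets`` independent pools (deterministic by seed)."""
    pools = []
    lengths = _target_lengths(spec)
    for t in range(spec.n_targets):
        target_id = f"SYN{t:03d}"
        target_seed = int(np.random.SeedSequence([spec.seed, t]).generate_state(1)[0]
                          % (2 ** 31))
        ref, seq = build_reference(lengths[t], target_seed, target_id=target_id, cfg=cfg)
        pool_spec = DecoyPoolSpec(
            n_targets=1, models_per_target=spec.models_per_target,
            chain_length=lengths[t], noise_tiers=spec.noise_tiers,
            unfold_fraction_per_tier=spec.unfold_fraction_per_tier,
            seed=target_seed,
        )
        pools.append(make_decoys(ref, seq, pool_spec, target_id=target_id))
    return pools


def _target_lengths(spec: DecoyPoolSpec) -> list[int]:
    """Deterministic mild length variation across targets (±12 residues)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 987]))
    jitter = rng.integers(-12, 13, size=spec.n_targets)
    return [int(max(60, spec.chain_length + j)) for j in jitter]


def benchmark_features(pools: list[ModelPool],
                       cfg: config.RunConfig = config.DEFAULT_CONFIG) -> pd.DataFrame:
    """Descriptor table for every model in every pool, with true GDT labels."""
    rows = []
    for pool in pools:
        agg = profile_sequence(pool.sequence, cfg)
        for model_id, s in pool.models:
            vec = compute_descriptors(s, agg, cfg)
            row = {"target_id": pool.target_id, "model_id": model_id,
                   "true_gdt": pool.labels[model_id], "tier": pool.tiers.get(model_id, -1)}
            row.update(vec.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)
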