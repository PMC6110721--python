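"""Central configuration for the SAAP-QA pipeline.

Every constant that affects a score lives here so that a run can be audited
and reproduced from its emitted metadata alone.  Defaults follow the
published Aggrescan constants (intrinsic a3v scale, length-banded window
sizes, hot-spot threshold), naccess conventions for solvent accessibility
(1.4 Å water probe, Chothia-style van der Waals radii, extended Ala-X-Ala
reference state) and the SAAP-QA model contract (50% side-chain exposure
cutoff, 700-tree random forest with 2 candidate features per split, GDT
quality cutoff 50, target-level 70/30 split).
"""

from __future__ import annotations

import dataclasses
import json
from typing import Any

# ---------------------------------------------------------------------------
# Aggregation profiling (Aggrescan intrinsic aggregation-propensity scale)
# ---------------------------------------------------------------------------

#: Intrinsic per-residue aggregation propensities (a3v) from the Aggrescan
#: amyloidogenesis scale, derived from in vivo experimental data.
#: Hydrophobic/aromatic residues score high, charged residues and proline low.
AGGRESCAN_A3V: dict[str, float] = {
    "A": -0.036,
    "C": 0.604,
    "D": -1.836,
    "E": -1.412,
    "F": 1.754,
    "G": -0.535,
    "H": -1.033,
    "I": 1.822,
    "K": -0.931,
    "L": 1.380,
    "M": 0.910,
    "N": -0.713,
    "P": -1.733,
    "Q": -1.231,
    "R": -1.240,
    "S": -0.294,
    "T": -0.159,
    "V": 1.594,
    "W": 1.037,
    "Y": 1.159,
}

#: Length-banded sliding-window sizes: (max_length_inclusive, window).
#: The window grows with protein length; the average over the window (a4v)
#: is assigned to the central residue.
AGGRESCAN_WINDOW_BANDS: tuple[tuple[float, int], ...] = (
    (75, 5),
    (175, 7),
    (300, 9),
    (float("inf"), 11),
)

#: Hot-spot threshold on the window-averaged propensity (a4v).
HOT_SPOT_THRESHOLD: float = -0.02

#: Minimum number of consecutive above-threshold residues forming a hot spot.
HOT_SPOT_MIN_RUN: int = 5

# ---------------------------------------------------------------------------
# Solvent accessible surface area
# ---------------------------------------------------------------------------

#: Water-probe radius in Å (the naccess default).
PROBE_RADIUS: float = 1.4

#: Number of sampling points per atom for Shrake-Rupley SASA.
SASA_POINTS: int = 960

#: Name of the van der Waals radius set (Chothia 1976 values, as used by
#: naccess): carbonyl/aromatic C 1.76, tetrahedral C 1.87, N 1.65, O 1.40,
#: S 1.85.
RADII_SET_NAME: str = "chothia-naccess"

#: Relative side-chain accessibility (%) above which a residue counts as
#: surface exposed.  Strict inequality: exactly 50% is buried.
EXPOSURE_CUTOFF_PERCENT: float = 50.0

# ---------------------------------------------------------------------------
# Quality-assessment model
# ---------------------------------------------------------------------------

#: Number of trees in the random-forest regressor.
RF_N_TREES: int = 700

#: Candidate features examined at every split.
RF_FEATURES_PER_SPLIT: int = 2

#: Fraction of targets assigned to the training split.
TRAIN_FRACTION: float = 0.7

#: GDT above which a model counts as high quality (ROC label).
GDT_QUALITY_CUTOFF: float = 50.0

#: GDT_TS distance cutoffs in Å.
GDT_CUTOFFS: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)

# Target admission rules.
CASP_MIN_DOMAIN_LENGTH: int = 100          # shorter domains lack a hydrophobic core
CASP_MIN_AGG_FRACTION: float = 0.20        # smaller aggregation patches are uninformative
CAMEO_MIN_LENGTH: int = 50
CAMEO_MAX_LENGTH: int = 500


@dataclasses.dataclass
class RunConfig:
    """Bag of tunables for one pipeline run; defaults are the shipped constants."""

    hot_spot_threshold: float = HOT_SPOT_THRESHOLD
    hot_spot_min_run: int = HOT_SPOT_MIN_RUN
    window_bands: tuple[tuple[float, int], ...] = AGGRESCAN_WINDOW_BANDS
    probe_radius: float = PROBE_RADIUS
    sasa_points: int = SASA_POINTS
    radii_set: str = RADII_SET_NAME
    exposure_cutoff: float = EXPOSURE_CUTOFF_PERCENT
    rf_n_trees: int = RF_N_TREES
    rf_features_per_split: int = RF_FEATURES_PER_SPLIT
    train_fraction: float = TRAIN_FRACTION
    gdt_quality_cutoff: float = GDT_QUALITY_CUTOFF
    seed: int | None = None

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["window_bands"] = [list(b) for b in self.window_bands]
        return d

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(self.to_dict(), **kwargs)


DEFAULT_CONFIG = RunConfig()
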