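"""Target-ROI atlas handling: the 264-node partition into resting-state networks.

The connectivity analyses correlate four hippocampal seed time series (left
and right head and body of the hippocampus) against a fixed set of target
ROIs, canonically the 264 10-mm spheres of the Power atlas, each assigned to
one of 13 resting-state networks.  This module loads and validates that
partition from a plain TSV table; no image-space work is done here — the
pipeline starts from extracted time series, so the atlas is consumed purely
as a table of labels and coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: The 13 resting-state networks of the canonical 264-ROI partition.
NETWORKS: tuple[str, ...] = (
    "SOM",      # somatomotor
    "AUD",      # auditory
    "VIS",      # visual
    "DMN",      # default mode
    "MRN",      # memory retrieval
    "DAN",      # dorsal attention
    "VAN",      # ventral attention
    "SN",       # salience
    "COTCN",    # cingulo-opercular task control
    "FPTCN",    # frontoparietal task control
    "SUB",      # subcortical
    "CER",      # cerebellar
    "uncertain",
)

#: The four hippocampal seeds, in fixed canonical order.
SEEDS: tuple[str, ...] = ("left_head", "left_body", "right_head", "right_body")

#: Canonical network sizes of the 264-ROI partition (sum = 264).
_CANONICAL_SIZES: dict[str, int] = {
    "SOM": 35, "COTCN": 14, "AUD": 13, "DMN": 58, "MRN": 5, "VIS": 31,
    "FPTCN": 25, "SN": 18, "SUB": 13, "VAN": 9, "DAN": 11, "CER": 4,
    "uncertain": 28,
}

_ATLAS_COLUMNS = ["roi_id", "x", "y", "z", "network"]


class AtlasValidationError(ValueError):
    """Raised when an atlas table violates the partition contract."""


@dataclass(frozen=True)
class TargetAtlas:
    """A validated target-ROI table.

    Row order is canonical: it fixes the column order of every connectivity
    matrix built against this atlas.

    Parameters
    ----------
    table :
        DataFrame with columns ``roi_id, x, y, z, network``.
    sphere_diameter_mm :
        Informational ROI sphere diameter (the canonical atlas uses 10 mm).
    """

    table: pd.DataFrame
    sphere_diameter_mm: float = 10.0

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _ATLAS_COLUMNS if c not in t.columns]
        if missing:
            raise AtlasValidationError(f"atlas table missing columns: {missing}")
        if len(t) == 0:
            raise AtlasValidationError("atlas table is empty")
        dup = t["roi_id"][t["roi_id"].duplicated()]
        if len(dup):
            raise AtlasValidationError(
                f"duplicate roi_id values: {sorted(set(dup.tolist()))}"
            )
        bad = sorted(set(t["network"]) - set(NETWORKS))
        if bad:
            raise AtlasValidationError(
                f"unknown network labels {bad}; expected one of {list(NETWORKS)}"
            )
        if self.sphere_diameter_mm <= 0:
            raise AtlasValidationError("sphere_diameter_mm must be positive")

    @property
    def n_targets(self) -> int:
        return len(self.table)

    @property
    def roi_ids(self) -> np.ndarray:
        """Target ROI ids in canonical (row) order."""
        return self.table["roi_id"].to_numpy()

    @property
    def network_labels(self) -> np.ndarray:
        """Per-target network label, aligned with :attr:`roi_ids`."""
        return self.table["network"].to_numpy()

    def network_sizes(self) -> dict[str, int]:
        """ROI count per network over all 13 possible labels (absent -> 0)."""
        counts = self.table["network"].value_counts()
        return {net: int(counts.get(net, 0)) for net in NETWORKS}

    def to_tsv(self, path: str | Path) -> None:
        self.table[_ATLAS_COLUMNS].to_csv(path, sep="\t", index=False)


def load_atlas(path: str | Path, sphere_diameter_mm: float = 10.0) -> TargetAtlas:
    """Load and validate a target atlas from a tab-separated table.

    The file must have columns ``roi_id, x, y, z, network`` with MNI
    coordinates in mm.  Row order is preserved and becomes the canonical
    target order for all downstream matrices.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep="\t")
    return TargetAtlas(table=table, sphere_diameter_mm=sphere_diameter_mm)


def network_sizes(atlas: TargetAtlas) -> dict[str, int]:
    """Mapping network label -> ROI count (all 13 labels; absent -> 0)."""
    return atlas.network_sizes()


def synthetic_power264_atlas(seed: int = 0) -> TargetAtlas:
    """A synthetic stand-in for the canonical 264-ROI atlas.

    The real atlas table (MNI sphere centres and network assignments) is
    distributed by its authors and is not bundled here.  This generator
    produces a synthetic table with the canonical 13-network partition sizes
    (summing to 264) and placeholder coordinates drawn uniformly inside a
    brain-sized bounding box.  Coordinates are informational only — no
    downstream statistic in this package reads them.
    """
    rng = np.random.default_rng(seed)
    labels = np.concatenate(
        [np.repeat(net, size) for net, size in _CANONICAL_SIZES.items()]
    )
    n = labels.size
    xyz = np.column_stack([
        rng.uniform(-70, 70, n),    # x: left-right extent, mm
        rng.uniform(-105, 70, n),   # y: posterior-anterior
        rng.uniform(-45, 75, n),    # z: inferior-superior
    ]).round(1)
    table = pd.DataFrame({
        "roi_id": np.arange(1, n + 1),
        "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
        "network": labels,
    })
    return TargetAtlas(table=table)
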