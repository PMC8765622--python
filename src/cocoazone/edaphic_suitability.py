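"""Soil-by-infrastructure suitability rules.

A cell's soil is suitable for the crop when all of the following hold:
it belongs to one of the four selected reference soil groups (Acrisols,
Fluvisols, Nitosols, Ferralsols), its stoniness is low, its fertility
satisfies the infrastructure rule — eutrophic (high-fertility) soils
qualify in every territory, dystrophic (low-fertility) soils only inside
the well-connected network territory — and it is not protected
(indigenous lands and conservation units merged into one boolean layer).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .geo_core import AlignmentError, GridSpec, Layer, total_area_km2

__all__ = [
    "REFERENCE_GROUPS",
    "SUITABLE_GROUPS",
    "TROPHIC_LEVELS",
    "STONINESS_LEVELS",
    "TERRITORIES",
    "SoilMap",
    "soil_suitability_mask",
    "soil_summary",
]

REFERENCE_GROUPS = {0: "Acrisol", 1: "Fluvisol", 2: "Nitosol", 3: "Ferralsol", 4: "Other"}
SUITABLE_GROUPS = ("Acrisol", "Fluvisol", "Nitosol", "Ferralsol")
TROPHIC_LEVELS = {0: "eutrophic", 1: "dystrophic"}
STONINESS_LEVELS = {0: "low", 1: "high"}
TERRITORIES = {0: "network", 1: "zone", 2: "border"}


@dataclass
class SoilMap:
    """Categorical soil attributes, one aligned layer per attribute."""

    reference_group: Layer
    trophic: Layer
    stoniness: Layer

    def __post_init__(self) -> None:
        grid = self.reference_group.grid
        for attr in ("trophic", "stoniness"):
            if getattr(self, attr).grid != grid:
                raise AlignmentError(f"soil attribute {attr!r} is misaligned")
        for attr in ("reference_group", "trophic", "stoniness"):
            if getattr(self, attr).categories is None:
                raise ValueError(f"soil attribute {attr!r} must be categorical")

    @property
    def grid(self) -> GridSpec:
        return self.reference_group.grid

    def _codes_for(self, layer: Layer, labels) -> np.ndarray:
        lookup = {v: k for k, v in layer.categories.items()}
        return np.array([lookup[label] for label in labels])


def _label_mask(layer: Layer, labels) -> np.ndarray:
    lookup = {v: k for k, v in layer.categories.items()}
    missing = [l for l in labels if l not in lookup]
    if missing:
        raise ValueError(f"layer {layer.name!r} lacks categories {missing}")
    codes = [lookup[l] for l in labels]
    return np.isin(layer.values, codes)


def soil_suitability_mask(
    soil: SoilMap, territory: Layer, protected: Layer
) -> Layer:
    """Boolean suitable-soil mask from the fertility-by-infrastructure rule.

    suitable ⇔ reference group ∈ {Acrisol, Fluvisol, Nitosol, Ferralsol}
              ∧ stoniness = low
              ∧ (eutrophic ∨ (dystrophic ∧ territory = network))
              ∧ ¬protected
    Nodata in any input propagates to the mask.
    """
    grid = soil.grid
    if territory.grid != grid or protected.grid != grid:
        raise AlignmentError("territory/protected layers are misaligned with soil")
    if territory.categories is None:
        raise ValueError("territory layer must be categorical")

    good_group = _label_mask(soil.reference_group, SUITABLE_GROUPS)
    low_stone = _label_mask(soil.stoniness, ["low"])
    eutrophic = _label_mask(soil.trophic, ["eutrophic"])
    dystrophic = _label_mask(soil.trophic, ["dystrophic"])
    network = _label_mask(territory, ["network"])
    protected_cells = np.asarray(protected.values, dtype=bool)

    suitable = (
        good_group
        & low_stone
        & (eutrophic | (dystrophic & network))
        & ~protected_cells
    )
    nodata = (
        soil.reference_group.nodata_mask
        | soil.trophic.nodata_mask
        | soil.stoniness.nodata_mask
        | territory.nodata_mask
        | protected.nodata_mask
    )
    suitable &= ~nodata
    return Layer(grid=grid, name="suitable_soil", values=suitable, nodata_mask=nodata)


def soil_summary(mask: Layer) -> dict:
    """Suitable km² and share of the grid, serializable as JSON."""
    grid = mask.grid
    suitable_km2 = total_area_km2(mask, grid)
    total_km2 = grid.n_cells * grid.cell_area_km2
    return {
        "suitable_km2": suitable_km2,
        "grid_km2": total_km2,
        "suitable_percent": 100.0 * suitable_km2 / total_km2,
    }


def write_summary(mask: Layer, path) -> None:
    with open(path, "w") as fh:
        json.dump(soil_summary(mask), fh, indent=2)
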