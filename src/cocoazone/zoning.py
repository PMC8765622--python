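"""Suitability classes, crop-prevalence classes and adaptation zoning.

Continuous suitability is cut into three classes — very low (<20%), low
to medium (20–50%), medium to high (>50%) — and combined with the
municipality-level prevalence of the crop (dominant / present / absent,
from production rankings) in a decision table that assigns each cell of
the suitable-soil mask to one of five climate-adaptation zones:
intensification, expansion, diversification, conversion, or not
recommended. The published table does not cover every (current, future,
prevalence) combination; a conservative completion rule resolves the
remainder and logs its footprint so it is auditable.
"""

from __future__ import annotations

import logging
from enum import Enum

import numpy as np
import pandas as pd

from .geo_core import AlignmentError, Layer
from .sdm_ensemble import SuitabilityMap

__all__ = [
    "SuitabilityClass",
    "PrevalenceClass",
    "Zone",
    "ZONE_CODES",
    "SUITABILITY_CUTS",
    "classify_suitability",
    "classify_prevalence",
    "assign_zone",
    "current_zoning",
    "build_zone_map",
    "ZoneMap",
]

logger = logging.getLogger(__name__)

SUITABILITY_CUTS = (0.20, 0.50)


class SuitabilityClass(Enum):
    """Suitability bands: boundary values 0.20 and 0.50 both fall in LM."""

    VL = "very_low"        # < 20%
    LM = "low_to_medium"   # 20–50% inclusive
    MH = "medium_to_high"  # > 50%


class PrevalenceClass(Enum):
    DOMINANT = "dominant"  # 1st or 2nd in the municipal production ranking
    PRESENT = "present"    # produced, but ranked 3rd or lower
    ABSENT = "absent"      # no production


class Zone(Enum):
    INTENSIFICATION = "intensification"
    EXPANSION = "expansion"
    DIVERSIFICATION = "diversification"
    CONVERSION = "conversion"
    NOT_RECOMMENDED = "not_recommended"


ZONE_CODES = {
    Zone.INTENSIFICATION: 1,
    Zone.EXPANSION: 2,
    Zone.DIVERSIFICATION: 3,
    Zone.CONVERSION: 4,
    Zone.NOT_RECOMMENDED: 5,
}
ZONE_LABELS = {code: zone.value for zone, code in ZONE_CODES.items()}

_CLASS_CODES = {SuitabilityClass.VL: 0, SuitabilityClass.LM: 1, SuitabilityClass.MH: 2}


def classify_suitability(suitability: SuitabilityMap | Layer) -> Layer:
    """Cut a [0,1] suitability surface into the three classes.

    0.20 and 0.50 are classed LM (the published bands read "<20%",
    "20 to 50%", ">50%").
    """
    layer = suitability.layer if isinstance(suitability, SuitabilityMap) else suitability
    values = np.asarray(layer.values, dtype=float)
    valid = ~layer.nodata_mask
    if np.any((values[valid] < 0) | (values[valid] > 1)):
        raise ValueError("suitability values must lie in [0, 1]")
    lo, hi = SUITABILITY_CUTS
    codes = np.full(layer.grid.shape, _CLASS_CODES[SuitabilityClass.VL], dtype=np.int32)
    codes[values >= lo] = _CLASS_CODES[SuitabilityClass.LM]
    codes[values > hi] = _CLASS_CODES[SuitabilityClass.MH]
    return Layer(
        grid=layer.grid,
        name="suitability_class",
        values=codes,
        nodata_mask=layer.nodata_mask.copy(),
        categories={v: k.value for k, v in _CLASS_CODES.items()},
    )


def classify_prevalence(production: pd.DataFrame) -> dict[int, PrevalenceClass]:
    """Per-municipality prevalence from crop production rankings.

    Crops are ranked by production value descending within each
    municipality, ties sharing the better (minimum) rank. The crop is
    dominant if ranked 1st or 2nd with positive value, present if ranked
    3rd or lower with positive value, absent if its value is zero or it
    has no row.
    """
    required = {"municipality_id", "crop_name", "production_value"}
    missing = required - set(production.columns)
    if missing:
        raise ValueError(f"production table lacks columns {sorted(missing)}")
    if (production["production_value"] < 0).any():
        raise ValueError("production values must be nonnegative")
    dup = production.duplicated(["municipality_id", "crop_name"])
    if dup.any():
        raise ValueError("at most one row per (municipality, crop)")

    out: dict[int, PrevalenceClass] = {}
    for muni, sub in production.groupby("municipality_id"):
        ranks = sub["production_value"].rank(method="min", ascending=False)
        cocoa = sub[sub["crop_name"] == "cocoa"]
        if cocoa.empty or float(cocoa["production_value"].iloc[0]) == 0.0:
            out[int(muni)] = PrevalenceClass.ABSENT
        elif float(ranks[cocoa.index[0]]) <= 2:
            out[int(muni)] = PrevalenceClass.DOMINANT
        else:
            out[int(muni)] = PrevalenceClass.PRESENT
    return out


def assign_zone(
    current: SuitabilityClass,
    future: SuitabilityClass,
    prevalence: PrevalenceClass,
    completion_log: list | None = None,
) -> Zone:
    """Decision table mapping (current, future, prevalence) to a zone.

    Rules are checked in order; combinations the published table omits
    fall through to a conservative completion rule (recorded in
    ``completion_log`` when provided): a cell improving from very-low
    current suitability is not recommended unless the future is
    medium-to-high on an established base, and a low-to-medium future
    with no current production is not recommended.
    """
    MH, LM, VL = SuitabilityClass.MH, SuitabilityClass.LM, SuitabilityClass.VL
    DOM, PRES, ABS = (
        PrevalenceClass.DOMINANT,
        PrevalenceClass.PRESENT,
        PrevalenceClass.ABSENT,
    )
    if future == MH and current == MH and prevalence == DOM:
        return Zone.INTENSIFICATION
    if future == MH and current == MH and prevalence in (PRES, ABS):
        return Zone.EXPANSION
    if future == LM and current in (LM, MH) and prevalence in (DOM, PRES):
        return Zone.DIVERSIFICATION
    if future == VL and current in (LM, MH) and prevalence in (DOM, PRES):
        return Zone.CONVERSION
    if future == VL and prevalence == ABS:
        return Zone.NOT_RECOMMENDED
    # completion rule: combinations the published table does not cover
    # (improvement from a very-low current base, low-to-medium futures
    # with no current production, and very-low futures on a very-low base)
    if future == MH:
        zone = Zone.EXPANSION if current != VL else Zone.NOT_RECOMMENDED
    else:  # future in {LM, VL}, unmatched above
        zone = Zone.NOT_RECOMMENDED
    if completion_log is not None:
        completion_log.append((current, future, prevalence, zone))
    return zone


def current_zoning(
    current: SuitabilityClass, prevalence: PrevalenceClass
) -> Zone:
    """Single-column zoning used for the current-scenario map.

    MH + dominant → intensification; MH otherwise → expansion;
    LM + {dominant, present} → diversification; VL + {dominant,
    present} → conversion; {LM, VL} + absent → not recommended.
    """
    MH, LM, VL = SuitabilityClass.MH, SuitabilityClass.LM, SuitabilityClass.VL
    DOM, PRES, ABS = (
        PrevalenceClass.DOMINANT,
        PrevalenceClass.PRESENT,
        PrevalenceClass.ABSENT,
    )
    if current == MH:
        return Zone.INTENSIFICATION if prevalence == DOM else Zone.EXPANSION
    if prevalence == ABS:
        return Zone.NOT_RECOMMENDED
    return Zone.DIVERSIFICATION if current == LM else Zone.CONVERSION


class ZoneMap:
    """Per-cell zone codes over the suitable-soil mask (off-mask = nodata)."""

    def __init__(self, layer: Layer, scenario_label: str,
                 completion_log: list | None = None):
        self.layer = layer
        self.scenario_label = scenario_label
        self.completion_log = completion_log or []

    @property
    def grid(self):
        return self.layer.grid


_CODE_TO_CLASS = {v: k for k, v in _CLASS_CODES.items()}


def build_zone_map(
    suit_current: SuitabilityMap | Layer,
    suit_future: SuitabilityMap | Layer | None,
    prevalence_by_municipality: dict[int, PrevalenceClass],
    municipalities: Layer,
    soil_mask: Layer,
    scenario_label: str,
) -> ZoneMap:
    """Apply the decision table cell-wise over the suitable-soil mask.

    For ``scenario_label == "current"`` (or a None future map) the
    single-column current table is used. Municipalities without a
    prevalence entry are treated as absent and logged.
    """
    cur_classes = classify_suitability(suit_current)
    fut_classes = None
    if suit_future is not None and scenario_label != "current":
        fut_classes = classify_suitability(suit_future)
        if fut_classes.grid != cur_classes.grid:
            raise AlignmentError("current and future suitability grids differ")
    grid = cur_classes.grid
    if municipalities.grid != grid or soil_mask.grid != grid:
        raise AlignmentError("municipality or soil-mask layer misaligned")

    on_mask = (
        np.asarray(soil_mask.values, dtype=bool)
        & ~soil_mask.nodata_mask
        & ~cur_classes.nodata_mask
        & ~municipalities.nodata_mask
    )
    if fut_classes is not None:
        on_mask &= ~fut_classes.nodata_mask

    codes = np.zeros(grid.shape, dtype=np.int32)
    completion_log: list = []
    missing_prevalence: set[int] = set()
    rows, cols = np.nonzero(on_mask)
    for r, c in zip(rows, cols):
        muni = int(municipalities.values[r, c])
        prev = prevalence_by_municipality.get(muni)
        if prev is None:
            missing_prevalence.add(muni)
            prev = PrevalenceClass.ABSENT
        cur = _CODE_TO_CLASS[int(cur_classes.values[r, c])]
        if fut_classes is None:
            zone = current_zoning(cur, prev)
        else:
            fut = _CODE_TO_CLASS[int(fut_classes.values[r, c])]
            zone = assign_zone(cur, fut, prev, completion_log=completion_log)
        codes[r, c] = ZONE_CODES[zone]
    if missing_prevalence:
        logger.warning(
            "municipalities without prevalence treated as absent: %s",
            sorted(missing_prevalence),
        )
    layer = Layer(
        grid=grid,
        name=f"zones_{scenario_label}",
        values=codes,
        nodata_mask=~on_mask,
        categories=dict(ZONE_LABELS),
    )
    return ZoneMap(layer, scenario_label, completion_log)
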