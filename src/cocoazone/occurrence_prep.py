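"""Occurrence-record cleaning and collinearity-based predictor selection.

Cleaning removes records with malformed or out-of-range coordinates and
collapses exact coordinate duplicates, keeping a provenance log of how
many records each rule removed. Predictor selection greedily eliminates
bioclimatic layers until no kept pair has |Pearson r| above the
threshold (0.7 by default), the standard remedy for collinearity in
correlative distribution models.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .geo_core import EnvStack

__all__ = [
    "OccurrenceRecord",
    "OccurrenceSet",
    "PredictorSelection",
    "clean_occurrences",
    "correlation_filter",
    "canonical_bioclim_order",
]


@dataclass(frozen=True)
class OccurrenceRecord:
    longitude: float
    latitude: float
    source_label: str = ""


@dataclass
class OccurrenceSet:
    """Cleaned occurrence points plus a log of removals per cleaning rule."""

    records: list[OccurrenceRecord]
    provenance_log: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def coordinates(self) -> np.ndarray:
        """(n, 2) array of (longitude, latitude)."""
        if not self.records:
            return np.empty((0, 2))
        return np.array([(r.longitude, r.latitude) for r in self.records])


def _coerce_float(value) -> float | None:
    try:
        out = float(value)
    except (TypeError, ValueError):
        return None
    if not np.isfinite(out):
        return None
    return out


def clean_occurrences(
    raw_records,
    lon_bounds: tuple[float, float] = (-180.0, 180.0),
    lat_bounds: tuple[float, float] = (-90.0, 90.0),
) -> OccurrenceSet:
    """Drop invalid-coordinate records, then collapse exact duplicates.

    Parameters
    ----------
    raw_records:
        Iterable of ``(longitude, latitude)`` or
        ``(longitude, latitude, source_label)`` tuples (or objects with
        those attributes). Coordinates may be strings or malformed.
    lon_bounds, lat_bounds:
        Valid coordinate ranges. Defaults are geographic degrees; pass
        the grid extent for projected synthetic worlds.

    Invalid records are removed first; exact coordinate duplicates are
    then collapsed to their first occurrence in input order. Two records
    that differ only in source label still count as duplicates. The
    provenance log reports ``{"invalid": ..., "duplicate": ...}``.
    """
    raw = list(raw_records)
    if not raw:
        warnings.warn("clean_occurrences received an empty record list", stacklevel=2)
        return OccurrenceSet(records=[], provenance_log={"invalid": 0, "duplicate": 0})

    n_invalid = 0
    valid: list[OccurrenceRecord] = []
    for rec in raw:
        if isinstance(rec, OccurrenceRecord):
            lon_raw, lat_raw, src = rec.longitude, rec.latitude, rec.source_label
        elif hasattr(rec, "longitude"):
            lon_raw, lat_raw = rec.longitude, rec.latitude
            src = getattr(rec, "source_label", "")
        else:
            parts = tuple(rec)
            lon_raw, lat_raw = parts[0], parts[1]
            src = str(parts[2]) if len(parts) > 2 else ""
        lon = _coerce_float(lon_raw)
        lat = _coerce_float(lat_raw)
        if (
            lon is None
            or lat is None
            or not (lon_bounds[0] <= lon <= lon_bounds[1])
            or not (lat_bounds[0] <= lat <= lat_bounds[1])
        ):
            n_invalid += 1
            continue
        valid.append(OccurrenceRecord(lon, lat, str(src)))

    seen: set[tuple[float, float]] = set()
    survivors: list[OccurrenceRecord] = []
    n_dup = 0
    for rec in valid:
        key = (rec.longitude, rec.latitude)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        survivors.append(rec)

    return OccurrenceSet(
        records=survivors,
        provenance_log={"invalid": n_invalid, "duplicate": n_dup},
    )


@dataclass
class PredictorSelection:
    """Outcome of the collinearity filter.

    ``kept`` and ``dropped`` partition the input layer names; each drop
    carries the reason and the largest |r| that triggered it.
    """

    kept: list[str]
    dropped: list[tuple[str, str, float]]
    threshold: float = 0.7

    @property
    def dropped_names(self) -> list[str]:
        return [name for name, _, _ in self.dropped]

    def to_dict(self) -> dict:
        return {
            "kept": self.kept,
            "dropped": [
                {"name": n, "reason": r, "max_abs_r": m} for n, r, m in self.dropped
            ],
            "threshold": self.threshold,
        }


_BIO_RE = re.compile(r"^bio(\d+)$")


def canonical_bioclim_order(names) -> list[str]:
    """Sort names bio1..bio19 numerically, then any others alphabetically."""

    def key(name: str):
        m = _BIO_RE.match(name)
        if m:
            return (0, int(m.group(1)), name)
        return (1, 0, name)

    return sorted(names, key=key)


def correlation_filter(stack: EnvStack, threshold: float = 0.7) -> PredictorSelection:
    """Greedy elimination of collinear layers.

    Pearson correlations are computed over all shared non-nodata cells.
    While some kept pair has |r| > threshold, the pair with the largest
    |r| is found and the member with the larger mean |r| against all
    currently kept layers is dropped (ties drop the later name in
    canonical bioclim order). Zero-variance layers are excluded up front
    with reason ``"constant"``. Every kept pair ends with |r| <= threshold.
    """
    names = canonical_bioclim_order(stack.layer_names)
    if len(names) < 2:
        raise ValueError("correlation_filter needs at least two layers")
    valid = ~stack.shared_mask
    if valid.sum() < 3:
        raise ValueError("too few shared non-nodata cells to estimate correlations")

    dropped: list[tuple[str, str, float]] = []
    data = {}
    for name in names:
        vec = stack.layers[name].values[valid].astype(float)
        if np.ptp(vec) == 0 or np.std(vec) == 0:
            dropped.append((name, "constant", 0.0))
        else:
            data[name] = vec

    kept = [n for n in names if n in data]
    if kept:
        mat = np.column_stack([data[n] for n in kept])
        corr = np.corrcoef(mat, rowvar=False)
        corr = np.atleast_2d(corr)
        abs_r = np.abs(corr)
        np.fill_diagonal(abs_r, 0.0)

        index = {n: i for i, n in enumerate(kept)}
        active = list(kept)
        while len(active) > 1:
            idx = np.array([index[n] for n in active])
            sub = abs_r[np.ix_(idx, idx)]
            i, j = np.unravel_index(np.argmax(sub), sub.shape)
            max_r = sub[i, j]
            if max_r <= threshold:
                break
            # mean |r| of each pair member against the other active layers
            mean_i = sub[i].sum() / (len(active) - 1)
            mean_j = sub[j].sum() / (len(active) - 1)
            if mean_i > mean_j:
                loser = active[i]
            elif mean_j > mean_i:
                loser = active[j]
            else:  # tie: drop the later name in canonical order
                loser = active[max(i, j)]
            dropped.append((loser, "collinear", float(max_r)))
            active.remove(loser)
        kept = active

    return PredictorSelection(kept=kept, dropped=dropped, threshold=threshold)
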