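"""Zone area accounting, derived change statistics, and the ANOVA.

The zone table mirrors the published presentation: per scenario and
zone, an area in km² and a percent of the suitable-soil total, both
rounded half-up to two decimals. Change statistics are reported in
percentage points on that printed scale: combined
intensification+expansion and diversification+conversion shares are
computed from the raw areas and then rounded, while the drop/increase
statistics are differences of the already-rounded per-zone percents —
the only convention under which the published derived numbers are
reproduced exactly from the published table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .geo_core import GridSpec, total_area_km2
from .zoning import ZONE_CODES, Zone, ZoneMap

__all__ = [
    "round_half_up",
    "ZoneTable",
    "ChangeStats",
    "AnovaResult",
    "tabulate_zones",
    "derived_change_stats",
    "suitability_anova",
]

ZONE_ORDER = [z.value for z in Zone]


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (banker's rounding cannot reproduce the
    published percents)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ZoneTable:
    """Per-(scenario, zone) areas and percents, plus per-scenario totals."""

    df: pd.DataFrame  # columns: scenario, zone, area_km2, percent
    totals: dict[str, float]
    scenarios: list[str]

    @classmethod
    def from_areas(
        cls,
        areas: dict[str, dict[str, float]],
        totals: dict[str, float] | None = None,
    ) -> "ZoneTable":
        """Build a table from per-zone areas (e.g. a published table).

        ``areas[scenario][zone] = km²``; missing zones count as 0. The
        per-scenario total defaults to the sum of the zone areas.
        """
        scenarios = list(areas)
        totals = dict(totals) if totals else {}
        rows = []
        for scenario in scenarios:
            zone_areas = {z: float(areas[scenario].get(z, 0.0)) for z in ZONE_ORDER}
            total = totals.get(scenario, sum(zone_areas.values()))
            totals[scenario] = total
            if total <= 0:
                raise ValueError(f"scenario {scenario!r} has nonpositive total area")
            for zone in ZONE_ORDER:
                area = zone_areas[zone]
                if area < 0:
                    raise ValueError("zone areas must be nonnegative")
                rows.append(
                    {
                        "scenario": scenario,
                        "zone": zone,
                        "area_km2": round_half_up(area, 2),
                        "percent": round_half_up(100.0 * area / total, 2),
                    }
                )
        return cls(df=pd.DataFrame(rows), totals=totals, scenarios=scenarios)

    def area(self, scenario: str, zone: str | Zone) -> float:
        zone = zone.value if isinstance(zone, Zone) else zone
        sel = self.df[(self.df.scenario == scenario) & (self.df.zone == zone)]
        return float(sel["area_km2"].iloc[0])

    def percent(self, scenario: str, zone: str | Zone) -> float:
        zone = zone.value if isinstance(zone, Zone) else zone
        sel = self.df[(self.df.scenario == scenario) & (self.df.zone == zone)]
        return float(sel["percent"].iloc[0])

    def total(self, scenario: str) -> float:
        return self.totals[scenario]


def tabulate_zones(zone_maps: dict[str, ZoneMap], grid: GridSpec) -> ZoneTable:
    """Area and percent per (scenario, zone) over the common soil mask.

    All five zones are reported even when empty. Scenarios must share
    one mask (the suitable-soil footprint), so every scenario has the
    same total.
    """
    if not zone_maps:
        raise ValueError("tabulate_zones needs at least one zone map")
    labels = list(zone_maps)
    ref_mask = zone_maps[labels[0]].layer.nodata_mask
    for label in labels[1:]:
        zm = zone_maps[label]
        if zm.layer.grid != grid:
            raise ValueError(f"zone map {label!r} grid differs")
        if not np.array_equal(zm.layer.nodata_mask, ref_mask):
            raise ValueError(f"zone map {label!r} covers a different mask")
    areas: dict[str, dict[str, float]] = {}
    for label in labels:
        zm = zone_maps[label]
        valid = ~zm.layer.nodata_mask
        areas[label] = {}
        for zone, code in ZONE_CODES.items():
            cells = (zm.layer.values == code) & valid
            areas[label][zone.value] = total_area_km2(cells, grid)
    totals = {label: total_area_km2(~zone_maps[label].layer.nodata_mask, grid)
              for label in labels}
    return ZoneTable.from_areas(areas, totals)


@dataclass
class ChangeStats:
    """Derived percentage-point statistics, on the printed 2-decimal scale."""

    combined_int_exp_share: dict[str, float] = field(default_factory=dict)
    combined_div_conv_share: dict[str, float] = field(default_factory=dict)
    int_exp_drop_pp: dict[str, float] = field(default_factory=dict)
    not_recommended_change_pp: dict[str, float] = field(default_factory=dict)
    future_zone_gap_pp: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "combined_int_exp_share": self.combined_int_exp_share,
            "combined_div_conv_share": self.combined_div_conv_share,
            "int_exp_drop_pp": self.int_exp_drop_pp,
            "not_recommended_change_pp": self.not_recommended_change_pp,
            "future_zone_gap_pp": self.future_zone_gap_pp,
        }


def derived_change_stats(table: ZoneTable, current_label: str = "current") -> ChangeStats:
    """Change statistics quoted alongside the zone table.

    Combined shares (intensification+expansion, diversification+
    conversion) are computed from the raw areas against the scenario
    total, then rounded half-up. Percentage-point changes (the
    "reduction"/"increase" statistics and between-future gaps) are
    differences of the table's rounded percents, rounded again — the
    published convention.
    """
    if current_label not in table.scenarios:
        raise ValueError(f"table lacks the {current_label!r} scenario")
    futures = [s for s in table.scenarios if s != current_label]
    stats = ChangeStats()

    for scenario in table.scenarios:
        total = table.total(scenario)
        int_exp_area = (
            table.area(scenario, Zone.INTENSIFICATION)
            + table.area(scenario, Zone.EXPANSION)
        )
        div_conv_area = (
            table.area(scenario, Zone.DIVERSIFICATION)
            + table.area(scenario, Zone.CONVERSION)
        )
        stats.combined_int_exp_share[scenario] = round_half_up(
            100.0 * int_exp_area / total, 2
        )
        stats.combined_div_conv_share[scenario] = round_half_up(
            100.0 * div_conv_area / total, 2
        )

    def pct_sum(scenario: str, zones: list[Zone]) -> float:
        return sum(table.percent(scenario, z) for z in zones)

    cur_int_exp = pct_sum(current_label, [Zone.INTENSIFICATION, Zone.EXPANSION])
    cur_nr = table.percent(current_label, Zone.NOT_RECOMMENDED)
    for future in futures:
        fut_int_exp = pct_sum(future, [Zone.INTENSIFICATION, Zone.EXPANSION])
        stats.int_exp_drop_pp[future] = round_half_up(cur_int_exp - fut_int_exp, 2)
        stats.not_recommended_change_pp[future] = round_half_up(
            table.percent(future, Zone.NOT_RECOMMENDED) - cur_nr, 2
        )

    for zone in Zone:
        gaps = {}
        for i, f1 in enumerate(futures):
            for f2 in futures[i + 1:]:
                gaps[f"{f1}-{f2}"] = round_half_up(
                    table.percent(f1, zone) - table.percent(f2, zone), 2
                )
        if gaps:
            stats.future_zone_gap_pp[zone.value] = gaps
    return stats


@dataclass
class AnovaResult:
    """Two-way (or degenerate one-way) fixed-effects main-effects ANOVA."""

    factors: list[str]
    ss: dict[str, float]
    df: dict[str, int]
    f_stats: dict[str, float]
    p_values: dict[str, float]
    ss_residual: float
    df_residual: int
    ss_total: float

    def to_dict(self) -> dict:
        return {
            "factors": self.factors,
            "ss": self.ss,
            "df": self.df,
            "F": self.f_stats,
            "p": self.p_values,
            "ss_residual": self.ss_residual,
            "df_residual": self.df_residual,
            "ss_total": self.ss_total,
        }


def suitability_anova(
    samples: pd.DataFrame,
    value_col: str = "value",
    factor_cols: tuple[str, str] = ("territory", "scenario"),
) -> AnovaResult:
    """Main-effects ANOVA of suitability over territories and scenarios.

    Computed from explicit sums of squares: per factor,
    SS = Σ_level n_level (mean_level − grand_mean)²; the residual is
    SS_total minus the factor SS (the classical decomposition, exact in
    the balanced case). A factor with a single level is dropped, so the
    analysis degenerates to a one-way ANOVA. F statistics use the
    residual mean square; p-values come from the F distribution.
    """
    y = np.asarray(samples[value_col], dtype=float)
    if len(y) < 3:
        raise ValueError("too few observations")
    factors = []
    for col in factor_cols:
        levels = samples[col].unique()
        if any(samples[samples[col] == lv].empty for lv in levels):
            raise ValueError(f"empty level in factor {col!r}")
        if len(levels) >= 2:
            factors.append(col)
    if not factors:
        raise ValueError("need at least one factor with two or more levels")

    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss: dict[str, float] = {}
    dof: dict[str, int] = {}
    for col in factors:
        groups = samples.groupby(col)[value_col]
        means = groups.mean().to_numpy()
        counts = groups.size().to_numpy()
        ss[col] = float((counts * (means - grand) ** 2).sum())
        dof[col] = len(means) - 1

    ss_resid = ss_total - sum(ss.values())
    df_resid = len(y) - 1 - sum(dof.values())
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    ss_resid = max(ss_resid, 0.0)
    ms_resid = ss_resid / df_resid

    f_stats: dict[str, float] = {}
    p_values: dict[str, float] = {}
    for col in factors:
        if ms_resid == 0.0:
            f_val = 0.0 if ss[col] == 0.0 else float("inf")
        else:
            f_val = (ss[col] / dof[col]) / ms_resid
        f_stats[col] = float(f_val)
        if np.isinf(f_val):
            p_values[col] = 0.0
        else:
            p_values[col] = float(f_dist.sf(f_val, dof[col], df_resid))
    return AnovaResult(
        factors=factors,
        ss=ss,
        df=dof,
        f_stats=f_stats,
        p_values=p_values,
        ss_residual=ss_resid,
        df_residual=df_resid,
        ss_total=ss_total,
    )
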