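"""End-to-end orchestration: world → ensemble → zoning → reporting.

`run_pipeline` executes the full analysis on a synthetic world and
returns every intermediate product, which is what the command-line
subcommands, the tests and the acceptance script all build on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .edaphic_suitability import soil_suitability_mask
from .geo_core import Layer
from .occurrence_prep import PredictorSelection, correlation_filter
from .reporting import (
    AnovaResult,
    ChangeStats,
    ZoneTable,
    derived_change_stats,
    suitability_anova,
    tabulate_zones,
)
from .sdm_ensemble import (
    EnsembleModel,
    PresenceAbsenceSet,
    SplitPlan,
    SuitabilityMap,
    ensemble_project,
    fit_ensemble,
    fit_envelope,
    gcm_consensus,
    sample_pseudo_absences,
)
from .synthetic_data import SyntheticWorld, WorldConfig, make_world
from .zoning import ZoneMap, build_zone_map, classify_prevalence

__all__ = ["PipelineResult", "run_pipeline", "anova_samples", "recovery_spearman"]


@dataclass
class PipelineResult:
    world: SyntheticWorld
    selection: PredictorSelection
    pa_set: PresenceAbsenceSet
    ensemble: EnsembleModel
    split_plans: list[SplitPlan]
    suitability: dict[str, SuitabilityMap]
    soil_mask: Layer
    zone_maps: dict[str, ZoneMap]
    zone_table: ZoneTable
    change_stats: ChangeStats
    anova: AnovaResult | None = None
    extras: dict = field(default_factory=dict)


def anova_samples(
    suitability: dict[str, SuitabilityMap],
    territory: Layer,
    soil_mask: Layer,
    n_cells: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample per-cell ensemble suitability on the suitable-soil mask,
    tagged with territory and scenario, for the two-way ANOVA."""
    valid = np.asarray(soil_mask.values, dtype=bool) & ~soil_mask.nodata_mask
    rows, cols = np.nonzero(valid)
    if len(rows) == 0:
        raise ValueError("soil mask is empty; nothing to sample")
    rng = np.random.default_rng(seed)
    if n_cells < len(rows):
        take = rng.choice(len(rows), size=n_cells, replace=False)
        rows, cols = rows[take], cols[take]
    terr_labels = np.array(
        [territory.categories[int(v)] for v in territory.values[rows, cols]]
    )
    frames = []
    for scenario, smap in suitability.items():
        frames.append(
            pd.DataFrame(
                {
                    "value": smap.layer.values[rows, cols].astype(float),
                    "territory": terr_labels,
                    "scenario": scenario,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def recovery_spearman(
    result_map: SuitabilityMap, truth: Layer, exclude_cells: np.ndarray | None = None
) -> float:
    """Spearman rank correlation between predicted and true suitability
    on cells not used for training."""
    valid = ~result_map.layer.nodata_mask & ~truth.nodata_mask
    if exclude_cells is not None and len(exclude_cells):
        valid = valid.copy()
        valid[exclude_cells[:, 0], exclude_cells[:, 1]] = False
    pred = result_map.layer.values[valid]
    true = truth.values[valid]
    rho, _ = spearmanr(pred, true)
    return float(rho)


def run_pipeline(
    config: WorldConfig | None = None,
    seed: int = 0,
    n_pseudo_absences: int = 300,
    sre_q: float = 0.025,
    train_fraction: float = 0.75,
    tss_gate: float = 0.7,
    learners: list[str] | None = None,
    n_replicates: int = 1,
    anova_n_cells: int = 1000,
    run_anova: bool = True,
) -> PipelineResult:
    """Run the whole analysis on a generated world.

    Stages: generate world; collinearity-filter the current stack; fit
    the presence envelope and draw pseudo-absences; fit and gate the
    learner ensemble; project suitability for the current climate and
    for each scenario's GCM-consensus stack; derive the suitable-soil
    mask; zone every scenario; tabulate areas and change statistics; and
    (optionally) run the territory-by-scenario ANOVA.
    """
    if config is None:
        config = WorldConfig(seed=seed)
    world = make_world(config, seed=seed)

    selection = correlation_filter(world.current)
    current_sel = world.current.subset(selection.kept)

    envelope = fit_envelope(world.occurrences, current_sel, q=sre_q)
    pa_set = sample_pseudo_absences(
        envelope, current_sel, world.occurrences, n=n_pseudo_absences, seed=seed
    )
    ensemble, plans = fit_ensemble(
        pa_set,
        train_fraction=train_fraction,
        tss_gate=tss_gate,
        learners=learners,
        seed=seed,
        n_replicates=n_replicates,
    )

    suitability = {"current": ensemble_project(ensemble, current_sel, "current")}
    for scenario, gcm_stacks in world.future.items():
        consensus = gcm_consensus(gcm_stacks, source_label=scenario)
        suitability[scenario] = ensemble_project(
            ensemble, consensus.subset(selection.kept), scenario
        )

    soil_mask = soil_suitability_mask(
        world.soil, world.territory, world.protected_mask
    )
    prevalence = classify_prevalence(world.production)

    zone_maps = {
        "current": build_zone_map(
            suitability["current"], None, prevalence, world.municipalities,
            soil_mask, "current",
        )
    }
    for scenario in world.future:
        zone_maps[scenario] = build_zone_map(
            suitability["current"], suitability[scenario], prevalence,
            world.municipalities, soil_mask, scenario,
        )

    zone_table = tabulate_zones(zone_maps, world.grid)
    change_stats = derived_change_stats(zone_table)

    anova = None
    if run_anova:
        samples = anova_samples(
            suitability, world.territory, soil_mask,
            n_cells=anova_n_cells, seed=seed,
        )
        anova = suitability_anova(samples)

    return PipelineResult(
        world=world,
        selection=selection,
        pa_set=pa_set,
        ensemble=ensemble,
        split_plans=plans,
        suitability=suitability,
        soil_mask=soil_mask,
        zone_maps=zone_maps,
        zone_table=zone_table,
        change_stats=change_stats,
        anova=anova,
        extras={"envelope": envelope, "prevalence": prevalence},
    )
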