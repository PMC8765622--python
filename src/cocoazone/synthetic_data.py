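"""Self-contained synthetic world with known ground truth.

The generator emulates the data a climate-suitability zoning study
consumes: 19 spatially smooth, partly collinear bioclimatic layers;
future climates for two emissions scenarios built by shifting the
current layers by reported per-variable deltas and adding cross-GCM
disagreement noise; a known true suitability surface (a logistic
function of six of the layers) from which occurrence points are
sampled; categorical soil attributes; a three-territory planning
partition; a municipality mosaic with per-crop production values; and
a protected-area mask covering roughly a tenth of the landscape.

Smoothness comes from low-pass-filtered white noise (Gaussian kernel of
width one tenth of the grid), giving the spatial autocorrelation that
makes climate envelopes and Voronoi mosaics plausible. The six layers
that drive the truth are built from mutually orthogonalized,
heavy-tailed latent fields, so their pairwise Pearson correlations are
small, while the remaining thirteen layers are noisy mixtures dominated
by one latent each and are therefore strongly collinear with it — the
collinearity filter has real work to do. Everything is bit-reproducible
given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .edaphic_suitability import (
    REFERENCE_GROUPS,
    STONINESS_LEVELS,
    TERRITORIES,
    TROPHIC_LEVELS,
    SoilMap,
)
from .geo_core import EnvStack, GridSpec, Layer
from .occurrence_prep import OccurrenceRecord, OccurrenceSet

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "BIOCLIM_STATS",
    "DEFAULT_TRUE_COEFFICIENTS",
    "DEFAULT_SCENARIO_DELTAS",
    "make_bioclim",
    "make_future",
    "make_truth_and_occurrences",
    "make_context_layers",
    "make_world",
]


# Plausible (mean, sd) per bioclim code on a wet-tropics landscape;
# temperatures °C, precipitation mm, bio3 %, bio15 CV.
BIOCLIM_STATS: dict[str, tuple[float, float]] = {
    "bio1": (25.5, 1.2), "bio2": (10.0, 1.0), "bio3": (80.0, 5.0),
    "bio4": (80.0, 20.0), "bio5": (32.0, 1.5), "bio6": (20.0, 1.5),
    "bio7": (12.0, 2.0), "bio8": (26.0, 1.5), "bio9": (24.0, 1.5),
    "bio10": (27.0, 1.5), "bio11": (24.5, 1.5), "bio12": (2200.0, 400.0),
    "bio13": (320.0, 60.0), "bio14": (60.0, 20.0), "bio15": (70.0, 10.0),
    "bio16": (850.0, 150.0), "bio17": (220.0, 70.0), "bio18": (600.0, 120.0),
    "bio19": (420.0, 100.0),
}

# The six predictors driving the true suitability surface. Warmer dry
# seasons, wider diurnal range and stronger precipitation seasonality
# depress suitability; dry-month rainfall raises it. Magnitudes are
# large relative to the unit-sd layers, giving the crop a well-defined
# climate niche (suitability close to 0 or 1 over most of the map, a
# narrow transition band); the negative intercept makes clearly
# suitable habitat occupy roughly a third of the landscape.
DEFAULT_TRUE_COEFFICIENTS: dict[str, float] = {
    "bio2": -3.2,
    "bio3": 2.0,
    "bio8": -2.4,
    "bio9": -4.0,
    "bio14": 4.8,
    "bio15": -3.2,
}
DEFAULT_INTERCEPT = -4.0

# Reported mid-century shifts of the selected variables under the two
# emissions scenarios (°C for bio2/bio8/bio9, mm/month for bio14,
# CV units for bio15).
DEFAULT_SCENARIO_DELTAS: dict[str, dict[str, float]] = {
    "RCP4.5": {"bio2": 0.25, "bio8": 1.45, "bio9": 2.0, "bio14": -9.0, "bio15": 4.0},
    "RCP8.5": {"bio2": 0.31, "bio8": 2.94, "bio9": 2.67, "bio14": -19.6, "bio15": 7.7},
}

# Cross-GCM spread per shifted variable (same units as the deltas).
DEFAULT_GCM_NOISE_SD: dict[str, float] = {
    "bio2": 0.08, "bio8": 0.3, "bio9": 0.3, "bio14": 2.0, "bio15": 1.0,
}


@dataclass
class WorldConfig:
    """Knobs of the synthetic world; defaults define the study conditions."""

    n_rows: int = 120
    n_cols: int = 120
    cell_area_km2: float = 25.0
    n_bioclim: int = 19
    latent_dim: int = 6
    occurrence_n: int = 300
    true_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_COEFFICIENTS)
    )
    intercept: float = DEFAULT_INTERCEPT
    scenario_deltas: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SCENARIO_DELTAS.items()}
    )
    n_gcms: int = 5
    gcm_noise_sd: dict[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_GCM_NOISE_SD)
    )
    n_municipalities: int = 30
    protected_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim > self.n_bioclim:
            raise ValueError("latent_dim cannot exceed n_bioclim")
        if self.n_gcms < 1:
            raise ValueError("n_gcms must be at least 1")
        for name, value in (
            ("n_rows", self.n_rows),
            ("n_cols", self.n_cols),
            ("n_bioclim", self.n_bioclim),
            ("latent_dim", self.latent_dim),
            ("occurrence_n", self.occurrence_n),
            ("n_municipalities", self.n_municipalities),
        ):
            if value < 1:
                raise ValueError(f"{name} must be positive")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            origin_x=0.0,
            origin_y=float(self.n_rows),
            cell_size=1.0,
            cell_area_km2=self.cell_area_km2,
        )


@dataclass
class SyntheticWorld:
    """One generated world: climates, truth, occurrences and context."""

    config: WorldConfig
    grid: GridSpec
    current: EnvStack
    future: dict[str, list[EnvStack]]
    true_suitability: Layer
    occurrences: OccurrenceSet
    soil: SoilMap
    territory: Layer
    municipalities: Layer
    production: pd.DataFrame
    protected_mask: Layer


# Latent fields are assigned to these codes first (the variables the
# reference analysis ends up selecting); all other codes are mixtures.
_LATENT_CODES = ("bio2", "bio3", "bio8", "bio9", "bio14", "bio15")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Standardized low-pass-filtered white noise (kernel = grid/10)."""
    sigma = max(shape) / 10.0
    field_ = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    field_ -= field_.mean()
    sd = field_.std()
    if sd > 0:
        field_ /= sd
    return field_


def _latent_fields(
    rng: np.random.Generator, shape, k: int, tail_alpha: float = 0.7
) -> np.ndarray:
    """k weakly correlated smooth fields with heavy-tailed marginals.

    Smooth fields are centered and QR-orthogonalized (linear mixing of
    smooth fields stays smooth), then each is passed through
    ``z + tail_alpha * z**3`` and re-standardized. The cubic term
    fattens the marginal tails — real landscapes hold much land that is
    climatically far outside any one crop's niche, which unit-Gaussian
    fields understate — at the cost of small (empirically |r| < 0.35)
    residual correlations between latents, far below the 0.7 filter.
    Returns an array of shape (k, n_rows, n_cols), each field unit-sd.
    """
    cols = np.column_stack([_smooth_field(rng, shape).ravel() for _ in range(k)])
    q, _ = np.linalg.qr(cols)
    q -= q.mean(axis=0, keepdims=True)  # numerically re-center
    q /= q.std(axis=0, keepdims=True)
    out = []
    for col in q.T:
        t = col + tail_alpha * col**3
        t -= t.mean()
        t /= t.std()
        out.append(t.reshape(shape))
    return np.array(out)


def make_bioclim(config: WorldConfig, seed: int | None = None) -> EnvStack:
    """Generate the current-climate stack of ``n_bioclim`` layers.

    The first ``latent_dim`` codes (bio2, bio3, bio8, bio9, bio14, bio15
    at defaults) are pure latent fields — at most weakly correlated.
    Every other code is a mixture dominated by one latent (weight 0.95)
    plus a second latent (0.2) and white noise (0.15, then smoothed), so
    it is collinear (|r| ≈ 0.95) with its dominant latent.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    shape = (config.n_rows, config.n_cols)
    latents = _latent_fields(rng, shape, config.latent_dim)

    latent_codes = list(_LATENT_CODES[: config.latent_dim])
    all_codes = [f"bio{i}" for i in range(1, config.n_bioclim + 1)]
    # keep only latent codes that actually exist at this n_bioclim
    latent_codes = [c for c in latent_codes if c in all_codes]
    while len(latent_codes) < config.latent_dim:
        extras = [c for c in all_codes if c not in latent_codes]
        latent_codes.append(extras[0])

    grid = config.grid
    layers: dict[str, Layer] = {}
    mixture_codes = [c for c in all_codes if c not in latent_codes]
    for i, code in enumerate(all_codes):
        mean, sd = BIOCLIM_STATS.get(code, (0.0, 1.0))
        if code in latent_codes:
            z = latents[latent_codes.index(code)]
        else:
            j = mixture_codes.index(code)
            dom = j % config.latent_dim
            other = (dom + 1 + j // config.latent_dim) % config.latent_dim
            noise = _smooth_field(rng, shape)
            raw = 0.95 * latents[dom] + 0.2 * latents[other] + 0.15 * noise
            z = (raw - raw.mean()) / raw.std()
        layers[code] = Layer(grid=grid, name=code, values=mean + sd * z)
    return EnvStack(grid=grid, layers=layers, source_label="current")


def make_future(
    current: EnvStack,
    deltas: dict[str, float],
    n_gcms: int = 5,
    noise_sd: dict[str, float] | float = 0.0,
    seed: int = 0,
    scenario_label: str = "future",
) -> list[EnvStack]:
    """Per-GCM future stacks: current + per-variable delta + GCM noise.

    ``noise_sd`` is the standard deviation of the zero-mean cross-GCM
    disagreement, in the variable's own units; a scalar applies to every
    layer, a dict only to the named layers. The cross-GCM mean of each
    shifted layer converges to current + delta as the noise vanishes.
    """
    unknown = [k for k in deltas if k not in current]
    if unknown:
        raise KeyError(f"delta keys not in stack: {unknown}")
    if isinstance(noise_sd, dict):
        unknown = [k for k in noise_sd if k not in current]
        if unknown:
            raise KeyError(f"noise keys not in stack: {unknown}")
        sd_of = dict(noise_sd)
    else:
        sd_of = {name: float(noise_sd) for name in current.layer_names}

    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    grid = current.grid
    stacks = []
    for g in range(n_gcms):
        layers = {}
        for name in current.layer_names:
            base = current.layers[name]
            values = base.values + deltas.get(name, 0.0)
            sd = sd_of.get(name, 0.0)
            if sd > 0:
                values = values + rng.normal(0.0, sd, size=grid.shape)
            layers[name] = Layer(
                grid=grid, name=name, values=values,
                nodata_mask=base.nodata_mask.copy(),
            )
        stacks.append(
            EnvStack(grid=grid, layers=layers,
                     source_label=f"{scenario_label}/GCM{g + 1}")
        )
    return stacks


def make_truth_and_occurrences(
    stack: EnvStack, config: WorldConfig, seed: int | None = None
) -> tuple[Layer, OccurrenceSet]:
    """True suitability surface and occurrences sampled from it.

    Truth = logistic(intercept + Σ βk · zk) over the configured layers,
    each standardized to zero mean / unit sd on the stack's valid cells.
    ``occurrence_n`` distinct cells are drawn without replacement with
    probability proportional to true suitability; records are placed at
    cell centers.
    """
    seed = config.seed if seed is None else seed
    missing = [k for k in config.true_coefficients if k not in stack]
    if missing:
        raise KeyError(f"true_coefficients reference missing layers: {missing}")
    grid = stack.grid
    mask = stack.shared_mask
    logit = np.full(grid.shape, config.intercept, dtype=float)
    for name, beta in config.true_coefficients.items():
        vals = stack.layers[name].values
        valid_vals = vals[~mask]
        z = (vals - valid_vals.mean()) / valid_vals.std()
        logit += beta * z
    suit = expit(logit)
    truth = Layer(
        grid=grid, name="true_suitability", values=suit, nodata_mask=mask.copy()
    )

    rows, cols = np.nonzero(~mask)
    if config.occurrence_n > len(rows):
        raise ValueError("occurrence_n exceeds the number of available cells")
    weights = suit[rows, cols]
    probs = weights / weights.sum()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    take = rng.choice(len(rows), size=config.occurrence_n, replace=False, p=probs)
    take = np.sort(take)
    records = []
    for i in take:
        x = grid.origin_x + (cols[i] + 0.5) * grid.cell_size
        y = grid.origin_y - (rows[i] + 0.5) * grid.cell_size
        records.append(OccurrenceRecord(longitude=x, latitude=y, source_label="synthetic"))
    occ = OccurrenceSet(records=records, provenance_log={"invalid": 0, "duplicate": 0})
    return truth, occ


def _voronoi_labels(
    rng: np.random.Generator, grid: GridSpec, seeds: np.ndarray
) -> np.ndarray:
    """Nearest-seed (Euclidean, cell units) label per cell."""
    rr, cc = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij")
    d2 = (
        (rr[None, :, :] - seeds[:, 0, None, None]) ** 2
        + (cc[None, :, :] - seeds[:, 1, None, None]) ** 2
    )
    return np.argmin(d2, axis=0)


_CROPS = ("cocoa", "acai", "banana", "black_pepper")


def make_context_layers(
    grid: GridSpec,
    seed: int = 0,
    n_municipalities: int = 30,
    protected_fraction: float = 0.10,
) -> tuple[SoilMap, Layer, Layer, pd.DataFrame, Layer]:
    """Soil, territory, municipality, production and protection layers.

    Soil attributes come from independent smooth fields cut at fixed
    quantiles (reference groups 25/10/15/25/25%, eutrophic 40%, low
    stoniness 70%). The territory is a contiguous 3-seed Voronoi
    partition; municipalities a Voronoi mosaic of ``n_municipalities``
    seed cells. Production values are engineered so every prevalence
    class (dominant / present / absent) occurs, including at least one
    municipality with zero cocoa. The protected mask is the top
    ``protected_fraction`` of one more smooth field (contiguous blobs).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    shape = grid.shape

    def categorize(fractions: list[float]) -> np.ndarray:
        f = _smooth_field(rng, shape)
        qs = np.quantile(f, np.cumsum(fractions)[:-1])
        return np.searchsorted(qs, f, side="right")

    group_codes = categorize([0.25, 0.10, 0.15, 0.25, 0.25])
    trophic_codes = categorize([0.40, 0.60])
    stony_codes = categorize([0.70, 0.30])
    soil = SoilMap(
        reference_group=Layer(
            grid=grid, name="reference_group", values=group_codes.astype(np.int32),
            categories=dict(REFERENCE_GROUPS),
        ),
        trophic=Layer(
            grid=grid, name="trophic", values=trophic_codes.astype(np.int32),
            categories=dict(TROPHIC_LEVELS),
        ),
        stoniness=Layer(
            grid=grid, name="stoniness", values=stony_codes.astype(np.int32),
            categories=dict(STONINESS_LEVELS),
        ),
    )

    # one territory seed per column third keeps all three present and contiguous
    third = grid.n_cols // 3
    terr_seeds = np.array(
        [
            (rng.integers(0, grid.n_rows), rng.integers(i * third, (i + 1) * third))
            for i in range(3)
        ]
    )
    territory = Layer(
        grid=grid, name="territory",
        values=_voronoi_labels(rng, grid, terr_seeds).astype(np.int32),
        categories=dict(TERRITORIES),
    )

    flat = rng.choice(grid.n_cells, size=n_municipalities, replace=False)
    muni_seeds = np.column_stack(np.unravel_index(flat, shape))
    muni = Layer(
        grid=grid, name="municipality",
        values=_voronoi_labels(rng, grid, muni_seeds).astype(np.int32),
        categories={i: f"M{i:03d}" for i in range(n_municipalities)},
    )

    # engineer prevalence classes: cycle dominant / present / absent
    rows = []
    order = rng.permutation(n_municipalities)
    for rank_pos, m in enumerate(order):
        others = rng.uniform(20.0, 120.0, size=len(_CROPS) - 1)
        kind = rank_pos % 3
        if kind == 0:  # dominant: cocoa tops the ranking
            cocoa = float(others.max() + rng.uniform(5.0, 30.0))
        elif kind == 1:  # present: cocoa positive but below 3rd place
            cocoa = float(max(others.min() * 0.5, 0.5))
        else:  # absent: no cocoa production
            cocoa = 0.0
        rows.append({"municipality_id": int(m), "crop_name": "cocoa",
                     "production_value": cocoa})
        for crop, val in zip(_CROPS[1:], others):
            rows.append({"municipality_id": int(m), "crop_name": crop,
                         "production_value": float(val)})
    production = pd.DataFrame(rows).sort_values(
        ["municipality_id", "crop_name"], kind="stable"
    ).reset_index(drop=True)

    pf = _smooth_field(rng, shape)
    cut = np.quantile(pf, 1.0 - protected_fraction)
    protected = Layer(grid=grid, name="protected", values=pf > cut)
    return soil, territory, muni, production, protected


def make_world(config: WorldConfig | None = None, seed: int | None = None) -> SyntheticWorld:
    """Generate a complete world from one config and one seed."""
    config = config if config is not None else WorldConfig()
    seed = config.seed if seed is None else seed
    current = make_bioclim(config, seed=seed)
    future = {
        scenario: make_future(
            current,
            deltas,
            n_gcms=config.n_gcms,
            noise_sd=config.gcm_noise_sd,
            seed=seed + hash_scenario(scenario),
            scenario_label=scenario,
        )
        for scenario, deltas in config.scenario_deltas.items()
    }
    truth, occurrences = make_truth_and_occurrences(current, config, seed=seed)
    soil, territory, muni, production, protected = make_context_layers(
        config.grid,
        seed=seed,
        n_municipalities=config.n_municipalities,
        protected_fraction=config.protected_fraction,
    )
    return SyntheticWorld(
        config=config,
        grid=config.grid,
        current=current,
        future=future,
        true_suitability=truth,
        occurrences=occurrences,
        soil=soil,
        territory=territory,
        municipalities=muni,
        production=production,
        protected_mask=protected,
    )


def hash_scenario(scenario: str) -> int:
    """Small deterministic per-scenario seed offset (stable across runs)."""
    return sum(ord(ch) for ch in scenario) % 1000
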