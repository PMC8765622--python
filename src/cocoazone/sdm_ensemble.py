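"""Ensemble species-distribution modelling with TSS-gated averaging.

Workflow: fit a surface range envelope (SRE) on presence climates, draw
pseudo-absences from cells *outside* that envelope, split the labelled
set 75/25, fit several learners from a registry, evaluate each with the
True Skill Statistic (TSS, maximized over score thresholds) and AUC, and
project the unweighted mean of the learners whose TSS exceeds the gate
(0.7 by default) onto an environmental stack. Future projections use a
per-scenario consensus stack (cell-wise mean across GCMs) computed
before projection.

TSS and AUC are computed exactly: the TSS threshold search enumerates
all midpoints between distinct sorted scores, and AUC is the
tie-corrected rank statistic (probability that a random presence
outscores a random pseudo-absence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .geo_core import AlignmentError, EnvStack, Layer

__all__ = [
    "Envelope",
    "PresenceAbsenceSet",
    "SplitPlan",
    "ModelEvaluation",
    "SuitabilityMap",
    "EnsembleModel",
    "LEARNER_REGISTRY",
    "fit_envelope",
    "sample_pseudo_absences",
    "split",
    "fit_learner",
    "evaluate",
    "fit_ensemble",
    "ensemble_project",
    "variable_importance",
    "gcm_consensus",
]


# --------------------------------------------------------------------------
# Surface range envelope and pseudo-absence design
# --------------------------------------------------------------------------


@dataclass
class Envelope:
    """Rectangular climate envelope of the presence points.

    Per variable, bounds are the [q, 1-q] empirical quantiles of the
    presence-cell values; q=0 gives the full presence range.
    """

    bounds: dict[str, tuple[float, float]]
    q: float = 0.025

    @property
    def variables(self) -> list[str]:
        return list(self.bounds)

    def contains(self, X: np.ndarray, names: list[str] | None = None) -> np.ndarray:
        """Boolean inside-envelope flag per row of a cell-by-variable matrix."""
        names = names if names is not None else self.variables
        X = np.atleast_2d(np.asarray(X, dtype=float))
        inside = np.ones(X.shape[0], dtype=bool)
        for j, name in enumerate(names):
            if name not in self.bounds:
                continue
            lo, hi = self.bounds[name]
            inside &= (X[:, j] >= lo) & (X[:, j] <= hi)
        return inside


def _presence_cells(presences, grid) -> np.ndarray:
    """Normalize presence input to an (n, 2) array of (row, col) cells."""
    if hasattr(presences, "coordinates"):  # OccurrenceSet in map coordinates
        cells = []
        for lon, lat in presences.coordinates():
            cell = grid.cell_of_point(lon, lat)
            if cell is not None:
                cells.append(cell)
        return np.array(cells, dtype=int).reshape(-1, 2)
    return np.asarray(presences, dtype=int).reshape(-1, 2)


def fit_envelope(presences, stack: EnvStack, q: float = 0.025) -> Envelope:
    """Fit the surface range envelope on presence cells.

    ``presences`` is an (n, 2) array of (row, col) cells or an
    OccurrenceSet whose points are mapped onto the stack grid.
    Presences falling on nodata cells are skipped with a warning.
    """
    if not 0 <= q < 0.5:
        raise ValueError("q must be in [0, 0.5)")
    cells = _presence_cells(presences, stack.grid)
    mask = stack.shared_mask
    on_data = ~mask[cells[:, 0], cells[:, 1]]
    if not np.all(on_data):
        warnings.warn(
            f"{int((~on_data).sum())} presence point(s) on nodata cells skipped",
            stacklevel=2,
        )
        cells = cells[on_data]
    if len(cells) < 2:
        raise ValueError("fit_envelope needs at least two presences on data cells")
    bounds = {}
    for name in stack.layer_names:
        vals = stack.layers[name].values[cells[:, 0], cells[:, 1]].astype(float)
        lo = float(np.quantile(vals, q))
        hi = float(np.quantile(vals, 1.0 - q))
        bounds[name] = (lo, hi)
    return Envelope(bounds=bounds, q=q)


@dataclass
class PresenceAbsenceSet:
    """Labelled design matrix of presences and pseudo-absences.

    ``cells`` holds (row, col) per row of ``X``; ``y`` is 1 for presence
    and 0 for pseudo-absence. ``shortfall`` flags that fewer eligible
    cells existed than pseudo-absences requested.
    """

    cells: np.ndarray
    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    seed: int
    shortfall: bool = False

    @property
    def n_presence(self) -> int:
        return int(self.y.sum())

    @property
    def n_pseudo(self) -> int:
        return int((self.y == 0).sum())

    def __len__(self) -> int:
        return len(self.y)


def sample_pseudo_absences(
    envelope: Envelope,
    stack: EnvStack,
    presences,
    n: int = 300,
    seed: int = 0,
) -> PresenceAbsenceSet:
    """Draw pseudo-absences uniformly from cells outside the envelope.

    Eligible cells are non-nodata, outside the envelope on at least one
    variable, and not presence cells. If fewer than ``n`` are eligible,
    all of them are returned and the shortfall flag is set; zero
    eligible cells is a hard error (shrink q).
    """
    names = envelope.variables
    for name in names:
        if name not in stack:
            raise KeyError(f"envelope variable {name!r} missing from stack")
    grid = stack.grid
    pres_cells = _presence_cells(presences, grid)
    mask = stack.shared_mask
    on_data = ~mask[pres_cells[:, 0], pres_cells[:, 1]]
    pres_cells = pres_cells[on_data]
    if len(pres_cells) == 0:
        raise ValueError("no presences on data cells")

    valid = ~mask
    rows, cols = np.nonzero(valid)
    X_all = np.column_stack(
        [stack.layers[name].values[rows, cols].astype(float) for name in names]
    )
    inside = envelope.contains(X_all, names)
    is_presence = np.zeros(len(rows), dtype=bool)
    pres_set = set(map(tuple, pres_cells))
    for i, (r, c) in enumerate(zip(rows, cols)):
        if (r, c) in pres_set:
            is_presence[i] = True
    eligible = ~inside & ~is_presence
    n_eligible = int(eligible.sum())
    if n_eligible == 0:
        raise ValueError(
            "no cells outside the presence envelope are available for "
            "pseudo-absences; refit the envelope with a smaller q"
        )
    shortfall = n_eligible < n
    if shortfall:
        warnings.warn(
            f"only {n_eligible} eligible cells for {n} requested pseudo-absences",
            stacklevel=2,
        )
        take = np.nonzero(eligible)[0]
    else:
        rng = np.random.default_rng(seed)
        take = rng.choice(np.nonzero(eligible)[0], size=n, replace=False)
        take = np.sort(take)

    pa_cells = np.column_stack([rows[take], cols[take]])
    X_pa = X_all[take]
    X_pres = np.column_stack(
        [
            stack.layers[name].values[pres_cells[:, 0], pres_cells[:, 1]].astype(float)
            for name in names
        ]
    )
    cells = np.vstack([pres_cells, pa_cells])
    X = np.vstack([X_pres, X_pa])
    y = np.concatenate(
        [np.ones(len(pres_cells), dtype=int), np.zeros(len(pa_cells), dtype=int)]
    )
    return PresenceAbsenceSet(
        cells=cells, X=X, y=y, feature_names=list(names), seed=seed,
        shortfall=shortfall,
    )


# --------------------------------------------------------------------------
# Train/test split
# --------------------------------------------------------------------------


@dataclass
class SplitPlan:
    """Stratified train/test row indices for a PresenceAbsenceSet."""

    train_rows: np.ndarray
    test_rows: np.ndarray
    train_fraction: float
    seed: int


def split(
    pa_set: PresenceAbsenceSet, train_fraction: float = 0.75, seed: int = 0
) -> SplitPlan:
    """Stratified-by-label random split honouring the fraction per label.

    The per-label train count is ``round(fraction * n_label)``, clipped
    so both halves keep at least one row of each label.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    y = pa_set.y
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for label in (1, 0):
        rows = np.nonzero(y == label)[0]
        if len(rows) < 2:
            raise ValueError(f"label {label} has fewer than 2 rows; cannot split")
        n_train = int(round(train_fraction * len(rows)))
        n_train = min(max(n_train, 1), len(rows) - 1)
        perm = rng.permutation(rows)
        train_idx.append(np.sort(perm[:n_train]))
        test_idx.append(np.sort(perm[n_train:]))
    return SplitPlan(
        train_rows=np.sort(np.concatenate(train_idx)),
        test_rows=np.sort(np.concatenate(test_idx)),
        train_fraction=train_fraction,
        seed=seed,
    )


# --------------------------------------------------------------------------
# Learner registry
# --------------------------------------------------------------------------


class SREModel:
    """Envelope-membership learner: score 1 inside the training-presence
    envelope, 0 outside."""

    def __init__(self, q: float = 0.025):
        self.q = q
        self.lower: np.ndarray | None = None
        self.upper: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int = 0) -> "SREModel":
        X = np.asarray(X, dtype=float)
        pres = X[np.asarray(y) == 1]
        if len(pres) < 1:
            raise ValueError("SRE needs at least one presence row")
        self.lower = np.quantile(pres, self.q, axis=0)
        self.upper = np.quantile(pres, 1.0 - self.q, axis=0)
        return self

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        inside = np.all((X >= self.lower) & (X <= self.upper), axis=1)
        return inside.astype(float)


class _SklearnProbModel:
    """Adapter exposing score() = P(presence) from an sklearn classifier."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X, y, seed: int = 0):
        self.estimator.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
        return self

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        proba = self.estimator.predict_proba(X)
        presence_col = list(self.estimator.classes_).index(1)
        return proba[:, presence_col]


def _make_linear(seed: int):
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    return _SklearnProbModel(
        make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000))
    )


def _make_flexible(seed: int):
    from sklearn.ensemble import GradientBoostingClassifier

    return _SklearnProbModel(
        GradientBoostingClassifier(
            n_estimators=150, max_depth=3, learning_rate=0.1, random_state=seed
        )
    )


def _make_smooth(seed: int):
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import SplineTransformer, StandardScaler

    return _SklearnProbModel(
        make_pipeline(
            StandardScaler(),
            SplineTransformer(n_knots=5, degree=3),
            LogisticRegression(max_iter=1000, C=1.0),
        )
    )


def _make_sre(seed: int):
    return SREModel(q=0.025)


LEARNER_REGISTRY = {
    "sre": _make_sre,
    "linear": _make_linear,
    "flexible": _make_flexible,
    "smooth": _make_smooth,
}


def fit_learner(name: str, X_train: np.ndarray, y_train: np.ndarray, seed: int = 0):
    """Fit one registered learner; the returned model exposes
    ``score(X) -> [0, 1]`` and is deterministic given the seed."""
    if name not in LEARNER_REGISTRY:
        raise KeyError(
            f"unknown learner {name!r}; registered: {sorted(LEARNER_REGISTRY)}"
        )
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data contains a single class")
    model = LEARNER_REGISTRY[name](seed)
    return model.fit(X_train, y_train, seed=seed)


# --------------------------------------------------------------------------
# Evaluation: TSS and AUC
# --------------------------------------------------------------------------


@dataclass
class ModelEvaluation:
    """Held-out skill of one learner.

    ``tss`` is the maximum of sensitivity + specificity - 1 over all
    score thresholds (searched at midpoints of distinct sorted scores);
    ``auc`` is the tie-corrected rank probability that a presence
    outscores a pseudo-absence. Membership in the ensemble requires
    tss > the gate (0.7 in the reference workflow).
    """

    learner_name: str
    tss: float
    tss_threshold: float
    auc: float
    tss_gate: float = 0.7

    @property
    def included_in_ensemble(self) -> bool:
        return self.tss > self.tss_gate


def _tss_at_threshold(scores: np.ndarray, y: np.ndarray, t: float) -> float:
    pred = scores >= t
    pres = y == 1
    sens = np.count_nonzero(pred & pres) / np.count_nonzero(pres)
    spec = np.count_nonzero(~pred & ~pres) / np.count_nonzero(~pres)
    return sens + spec - 1.0


def max_tss(scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(TSS, threshold) maximizing sensitivity + specificity - 1.

    Candidate cuts are the midpoints of consecutive distinct sorted
    scores; a set with a single distinct score has TSS 0 at that score.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    uniq = np.unique(scores)
    if len(uniq) == 1:
        return 0.0, float(uniq[0])
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    tss_values = np.array([_tss_at_threshold(scores, y, t) for t in cuts])
    best = int(np.argmax(tss_values))
    return float(tss_values[best]), float(cuts[best])


def rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected AUC: P(score_presence > score_absence) + ½P(tie)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    n1 = int(np.count_nonzero(y == 1))
    n0 = int(np.count_nonzero(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both labels")
    ranks = rankdata(scores)
    r1 = ranks[y == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def evaluate(
    model, X_test: np.ndarray, y_test: np.ndarray, name: str = "", tss_gate: float = 0.7
) -> ModelEvaluation:
    """Score a fitted model on held-out rows and compute TSS and AUC."""
    y_test = np.asarray(y_test)
    if len(np.unique(y_test)) < 2:
        raise ValueError("test set contains a single class")
    scores = np.asarray(model.score(X_test), dtype=float)
    tss, threshold = max_tss(scores, y_test)
    auc = rank_auc(scores, y_test)
    return ModelEvaluation(
        learner_name=name or type(model).__name__,
        tss=tss,
        tss_threshold=threshold,
        auc=auc,
        tss_gate=tss_gate,
    )


# --------------------------------------------------------------------------
# Ensemble
# --------------------------------------------------------------------------


@dataclass
class EnsembleModel:
    """TSS-gated unweighted ensemble of fitted learners."""

    members: list[tuple[str, object]]
    evaluations: list[ModelEvaluation]
    feature_names: list[str]
    tss_gate: float = 0.7

    @property
    def passing_members(self) -> list[tuple[str, object]]:
        passing = {
            ev.learner_name for ev in self.evaluations if ev.included_in_ensemble
        }
        return [(name, m) for name, m in self.members if name in passing]

    @property
    def member_learners(self) -> list[str]:
        return [name for name, _ in self.passing_members]

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        """Unweighted mean score of the gate-passing members."""
        passing = self.passing_members
        if not passing:
            summary = ", ".join(
                f"{ev.learner_name}: TSS={ev.tss:.3f}" for ev in self.evaluations
            )
            raise ValueError(f"no learner passes the TSS gate ({summary})")
        scores = np.mean([m.score(X) for _, m in passing], axis=0)
        return np.asarray(scores, dtype=float)


def fit_ensemble(
    pa_set: PresenceAbsenceSet,
    train_fraction: float = 0.75,
    tss_gate: float = 0.7,
    learners: list[str] | None = None,
    seed: int = 0,
    n_replicates: int = 1,
) -> tuple[EnsembleModel, list[SplitPlan]]:
    """Split, fit every requested learner and evaluate on held-out rows.

    With ``n_replicates > 1`` the split/fit/evaluate cycle is repeated on
    independent seeded splits; a learner's reported TSS/AUC is then the
    mean over replicates, the gate applies to that mean, and every
    replicate model of a passing learner joins the ensemble.
    """
    learners = learners if learners is not None else sorted(LEARNER_REGISTRY)
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    plans = [
        split(pa_set, train_fraction=train_fraction, seed=seed * 1000 + rep)
        for rep in range(n_replicates)
    ]
    members: list[tuple[str, object]] = []
    evaluations = []
    for name in learners:
        per_rep = []
        for rep, plan in enumerate(plans):
            X_tr, y_tr = pa_set.X[plan.train_rows], pa_set.y[plan.train_rows]
            X_te, y_te = pa_set.X[plan.test_rows], pa_set.y[plan.test_rows]
            model = fit_learner(name, X_tr, y_tr, seed=seed * 1000 + rep)
            members.append((name, model))
            per_rep.append(evaluate(model, X_te, y_te, name=name, tss_gate=tss_gate))
        evaluations.append(
            ModelEvaluation(
                learner_name=name,
                tss=float(np.mean([ev.tss for ev in per_rep])),
                tss_threshold=float(np.mean([ev.tss_threshold for ev in per_rep])),
                auc=float(np.mean([ev.auc for ev in per_rep])),
                tss_gate=tss_gate,
            )
        )
    return (
        EnsembleModel(
            members=members,
            evaluations=evaluations,
            feature_names=list(pa_set.feature_names),
            tss_gate=tss_gate,
        ),
        plans,
    )


@dataclass
class SuitabilityMap:
    """Continuous per-cell suitability in [0, 1] for one scenario."""

    layer: Layer
    scenario_label: str
    member_learners: list[str] = field(default_factory=list)
    importance: dict[str, float] | None = None

    @property
    def grid(self):
        return self.layer.grid


def ensemble_project(
    ensemble: EnsembleModel, stack: EnvStack, scenario_label: str | None = None
) -> SuitabilityMap:
    """Project the gated ensemble mean onto every non-nodata cell."""
    names = ensemble.feature_names
    for name in names:
        if name not in stack:
            raise KeyError(f"ensemble feature {name!r} missing from stack")
    mask = stack.shared_mask
    rows, cols = np.nonzero(~mask)
    X = np.column_stack(
        [stack.layers[n].values[rows, cols].astype(float) for n in names]
    )
    scores = ensemble.score_matrix(X)
    values = np.zeros(stack.grid.shape, dtype=float)
    values[rows, cols] = scores
    layer = Layer(
        grid=stack.grid, name="suitability", values=values, nodata_mask=mask.copy()
    )
    return SuitabilityMap(
        layer=layer,
        scenario_label=scenario_label or stack.source_label,
        member_learners=ensemble.member_learners,
    )


def variable_importance(
    ensemble: EnsembleModel,
    stack: EnvStack,
    n_permutations: int = 5,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation importance: 1 - Pearson r between ensemble scores on
    the intact stack and on a stack with one variable shuffled, averaged
    over permutations; returned sorted descending."""
    names = ensemble.feature_names
    mask = stack.shared_mask
    rows, cols = np.nonzero(~mask)
    X = np.column_stack(
        [stack.layers[n].values[rows, cols].astype(float) for n in names]
    )
    base = ensemble.score_matrix(X)
    rng = np.random.default_rng(seed)
    importance = {}
    base_sd = base.std()
    for j, name in enumerate(names):
        drops = []
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            perm_scores = ensemble.score_matrix(Xp)
            if base_sd == 0 or perm_scores.std() == 0:
                r = 1.0 if np.allclose(perm_scores, base) else 0.0
            else:
                r = float(np.corrcoef(base, perm_scores)[0, 1])
            drops.append(1.0 - r)
        importance[name] = float(np.mean(drops))
    return dict(sorted(importance.items(), key=lambda kv: -kv[1]))


# --------------------------------------------------------------------------
# GCM consensus
# --------------------------------------------------------------------------


def gcm_consensus(stacks: list[EnvStack], source_label: str | None = None) -> EnvStack:
    """Cell-wise arithmetic mean of each layer across GCM stacks.

    All stacks must share grid and layer names; a cell is nodata in the
    consensus wherever any member is nodata.
    """
    if not stacks:
        raise ValueError("gcm_consensus requires at least one stack")
    grid = stacks[0].grid
    names = set(stacks[0].layer_names)
    for s in stacks[1:]:
        if s.grid != grid:
            raise AlignmentError("GCM stacks are not grid-aligned")
        if set(s.layer_names) != names:
            raise ValueError("GCM stacks carry different layer sets")
    union = np.zeros(grid.shape, dtype=bool)
    for s in stacks:
        union |= s.shared_mask
    layers = {}
    for name in stacks[0].layer_names:
        mean = np.mean([s.layers[name].values for s in stacks], axis=0)
        layers[name] = Layer(
            grid=grid, name=name, values=mean, nodata_mask=union.copy()
        )
    label = source_label or f"consensus({stacks[0].source_label})"
    return EnvStack(grid=grid, layers=layers, source_label=label)
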