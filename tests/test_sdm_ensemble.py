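import numpy as np
import pytest

from cocoazone.geo_core import EnvStack, GridSpec, Layer
from cocoazone.sdm_ensemble import (
    EnsembleModel,
    Envelope,
    ModelEvaluation,
    PresenceAbsenceSet,
    ensemble_project,
    evaluate,
    fit_envelope,
    fit_learner,
    gcm_consensus,
    max_tss,
    rank_auc,
    sample_pseudo_absences,
    split,
    variable_importance,
)

from oracles import brute_force_tss, pair_counting_auc


def line_stack(**vectors):
    n = len(next(iter(vectors.values())))
    grid = GridSpec(n_rows=1, n_cols=n, origin_y=1.0)
    return EnvStack(
        grid=grid,
        layers={
            k: Layer(grid=grid, name=k, values=np.asarray(v, float).reshape(1, n))
            for k, v in vectors.items()
        },
    )


class TestEnvelope:
    def test_q0_bounds_are_min_max(self):
        stack = line_stack(bio1=[1.0, 2.0, 3.0, 9.0])
        env = fit_envelope(np.array([[0, 0], [0, 1], [0, 2]]), stack, q=0.0)
        assert env.bounds["bio1"] == (1.0, 3.0)
        assert env.contains(np.array([[1.0], [3.0]]), ["bio1"]).all()

    def test_q_half_would_be_degenerate_at_median(self):
        stack = line_stack(bio1=[1.0, 2.0, 3.0, 9.0])
        env = fit_envelope(np.array([[0, 0], [0, 1], [0, 2]]), stack, q=0.4999999)
        lo, hi = env.bounds["bio1"]
        assert lo == pytest.approx(2.0, abs=1e-5)
        assert hi == pytest.approx(2.0, abs=1e-5)

    def test_default_trim_leaves_about_5pct_outside(self):
        rng = np.random.default_rng(0)
        n = 400
        vals = rng.standard_normal(n)
        grid = GridSpec(n_rows=1, n_cols=n, origin_y=1.0)
        stack = EnvStack(grid=grid, layers={
            "bio1": Layer(grid=grid, name="bio1", values=vals.reshape(1, n))})
        cells = np.column_stack([np.zeros(200, int), np.arange(200)])
        env = fit_envelope(cells, stack, q=0.025)
        inside = env.contains(vals[:200].reshape(-1, 1), ["bio1"])
        frac_out = 1 - inside.mean()
        assert 0.01 <= frac_out <= 0.10  # ~5%, binomial slack

    def test_presence_on_nodata_skipped_with_warning(self):
        grid = GridSpec(n_rows=1, n_cols=4, origin_y=1.0)
        mask = np.array([[False, False, False, True]])
        stack = EnvStack(grid=grid, layers={
            "bio1": Layer(grid=grid, name="bio1",
                          values=np.array([[1.0, 2.0, 3.0, 9.0]]), nodata_mask=mask)})
        with pytest.warns(UserWarning, match="nodata"):
            env = fit_envelope(np.array([[0, 0], [0, 1], [0, 3]]), stack, q=0.0)
        assert env.bounds["bio1"] == (1.0, 2.0)

    def test_rejects_bad_quantile(self):
        stack = line_stack(bio1=[1.0, 2.0])
        with pytest.raises(ValueError):
            fit_envelope(np.array([[0, 0], [0, 1]]), stack, q=0.5)


class TestPseudoAbsences:
    def test_toy_world_returns_exactly_the_outside_cells(self):
        stack = line_stack(bio1=[1.0, 2.0, 5.0, 9.0])
        env = Envelope(bounds={"bio1": (1.0, 2.0)}, q=0.0)
        pa = sample_pseudo_absences(env, stack, np.array([[0, 0], [0, 1]]),
                                    n=2, seed=0)
        assert pa.n_presence == 2 and pa.n_pseudo == 2
        assert not pa.shortfall
        pa_cells = {tuple(c) for c in pa.cells[pa.y == 0]}
        assert pa_cells == {(0, 2), (0, 3)}

    def test_zero_eligible_cells_is_a_hard_error(self):
        stack = line_stack(bio1=[1.0, 2.0, 3.0])
        env = Envelope(bounds={"bio1": (1.0, 3.0)}, q=0.0)  # whole range
        with pytest.raises(ValueError, match="smaller q"):
            sample_pseudo_absences(env, stack, np.array([[0, 0], [0, 1]]), n=2, seed=0)

    def test_shortfall_flag_when_pool_too_small(self):
        stack = line_stack(bio1=[1.0, 2.0, 5.0, 9.0])
        env = Envelope(bounds={"bio1": (1.0, 2.0)}, q=0.0)
        with pytest.warns(UserWarning, match="eligible"):
            pa = sample_pseudo_absences(env, stack, np.array([[0, 0], [0, 1]]),
                                        n=5, seed=0)
        assert pa.shortfall
        assert pa.n_pseudo == 2

    def test_fixed_seed_reproduces_sample(self, default_world):
        from cocoazone.occurrence_prep import correlation_filter

        sel = correlation_filter(default_world.current)
        sub = default_world.current.subset(sel.kept)
        env = fit_envelope(default_world.occurrences, sub, q=0.025)
        pa1 = sample_pseudo_absences(env, sub, default_world.occurrences, n=300, seed=5)
        pa2 = sample_pseudo_absences(env, sub, default_world.occurrences, n=300, seed=5)
        np.testing.assert_array_equal(pa1.cells, pa2.cells)
        # every sampled pseudo-absence is outside the envelope
        assert not env.contains(pa1.X[pa1.y == 0], pa1.feature_names).any()


def make_pa(n_pres, n_abs, n_feat=2, seed=0):
    rng = np.random.default_rng(seed)
    n = n_pres + n_abs
    return PresenceAbsenceSet(
        cells=np.column_stack([np.zeros(n, int), np.arange(n)]),
        X=rng.standard_normal((n, n_feat)),
        y=np.concatenate([np.ones(n_pres, int), np.zeros(n_abs, int)]),
        feature_names=[f"v{i}" for i in range(n_feat)],
        seed=seed,
    )


class TestSplit:
    def test_stratified_75_25_arithmetic(self):
        pa = make_pa(100, 300)
        plan = split(pa, train_fraction=0.75, seed=1)
        y = pa.y
        assert (y[plan.train_rows] == 1).sum() == 75
        assert (y[plan.train_rows] == 0).sum() == 225
        assert (y[plan.test_rows] == 1).sum() == 25
        assert (y[plan.test_rows] == 0).sum() == 75
        assert not set(plan.train_rows) & set(plan.test_rows)
        assert len(plan.train_rows) + len(plan.test_rows) == 400

    def test_degenerate_fractions_rejected(self):
        pa = make_pa(10, 10)
        with pytest.raises(ValueError):
            split(pa, train_fraction=1.0)
        with pytest.raises(ValueError):
            split(pa, train_fraction=0.0)

    def test_same_seed_same_plan(self):
        pa = make_pa(20, 30)
        p1, p2 = split(pa, seed=9), split(pa, seed=9)
        np.testing.assert_array_equal(p1.train_rows, p2.train_rows)


class TestLearners:
    def test_sre_scores_are_binary(self):
        pa = make_pa(50, 50, seed=2)
        model = fit_learner("sre", pa.X, pa.y, seed=0)
        assert set(np.unique(model.score(pa.X))) <= {0.0, 1.0}

    def test_linear_on_separable_data_reaches_tss_one(self):
        rng = np.random.default_rng(4)
        X = np.concatenate([rng.uniform(1, 2, 100), rng.uniform(-2, -1, 100)])
        X = X.reshape(-1, 1)
        y = np.array([1] * 100 + [0] * 100)
        model = fit_learner("linear", X[::2], y[::2], seed=0)
        ev = evaluate(model, X[1::2], y[1::2])
        assert ev.tss == 1.0
        assert ev.auc == 1.0

    def test_unknown_learner_name_rejected(self):
        pa = make_pa(5, 5)
        with pytest.raises(KeyError, match="xgbfoo"):
            fit_learner("xgbfoo", pa.X, pa.y)

    def test_single_class_training_rejected(self):
        pa = make_pa(5, 5)
        with pytest.raises(ValueError, match="single class"):
            fit_learner("linear", pa.X, np.ones(10, int))

    @pytest.mark.parametrize("name", ["linear", "flexible", "smooth", "sre"])
    def test_scores_live_in_unit_interval(self, name):
        pa = make_pa(40, 40, seed=6)
        model = fit_learner(name, pa.X, pa.y, seed=3)
        s = model.score(pa.X)
        assert np.all((s >= 0) & (s <= 1))


class TestEvaluate:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        y = np.array([1, 1, 0, 0])
        tss, _ = max_tss(scores, y)
        assert tss == 1.0
        assert rank_auc(scores, y) == 1.0

    def test_constant_scores_have_no_skill(self):
        scores = np.full(6, 0.4)
        y = np.array([1, 1, 1, 0, 0, 0])
        tss, t = max_tss(scores, y)
        assert tss == 0.0 and t == 0.4
        assert rank_auc(scores, y) == 0.5

    def test_worked_four_score_example(self):
        # P: 0.9, 0.6; A: 0.7, 0.2 — midpoints 0.4, 0.65, 0.8
        scores = np.array([0.9, 0.6, 0.7, 0.2])
        y = np.array([1, 1, 0, 0])
        assert rank_auc(scores, y) == pytest.approx(0.75)
        tss, threshold = max_tss(scores, y)
        assert tss == pytest.approx(0.5)
        assert threshold in (0.4, 0.8)  # both cuts attain 0.5
        oracle_tss, _ = brute_force_tss(scores, y)
        assert tss == pytest.approx(oracle_tss)

    def test_tss_and_auc_match_brute_force_on_random_sets(self):
        rng = np.random.default_rng(12)
        for _ in range(60):
            n1, n0 = rng.integers(2, 12, size=2)
            scores = rng.choice(np.linspace(0, 1, 7), size=n1 + n0)
            y = np.array([1] * n1 + [0] * n0)
            tss, _ = max_tss(scores, y)
            bf_tss, _ = brute_force_tss(scores, y)
            assert tss == pytest.approx(bf_tss)
            assert rank_auc(scores, y) == pytest.approx(pair_counting_auc(scores, y))

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(13)
        scores = rng.uniform(0.01, 1, 40)
        y = rng.integers(0, 2, 40)
        y[0], y[1] = 1, 0
        a1 = rank_auc(scores, y)
        assert rank_auc(np.log(scores), y) == pytest.approx(a1)
        assert rank_auc(scores**3, y) == pytest.approx(a1)

    def test_one_class_test_set_rejected(self):
        pa = make_pa(10, 10)
        model = fit_learner("linear", pa.X, pa.y)
        with pytest.raises(ValueError):
            evaluate(model, pa.X[:5], np.ones(5, int))


class _StubModel:
    def __init__(self, value):
        self.value = value

    def score(self, X):
        return np.full(np.atleast_2d(X).shape[0], self.value)


def stub_ensemble(tss_by_name, score_by_name, gate=0.7):
    members = [(n, _StubModel(s)) for n, s in score_by_name.items()]
    evals = [
        ModelEvaluation(learner_name=n, tss=t, tss_threshold=0.5, auc=0.9,
                        tss_gate=gate)
        for n, t in tss_by_name.items()
    ]
    return EnsembleModel(members=members, evaluations=evals,
                         feature_names=["v0"], tss_gate=gate)


class TestEnsemble:
    def test_gate_excludes_weak_member_before_averaging(self):
        ens = stub_ensemble({"a": 0.8, "b": 0.6}, {"a": 0.9, "b": 0.1})
        assert ens.score_matrix(np.zeros((1, 1)))[0] == pytest.approx(0.9)
        assert ens.member_learners == ["a"]

    def test_single_passing_member_is_identity(self):
        ens = stub_ensemble({"a": 0.75}, {"a": 0.42})
        assert ens.score_matrix(np.zeros((3, 1))) == pytest.approx([0.42] * 3)

    def test_three_members_average(self):
        ens = stub_ensemble({"a": 0.8, "b": 0.9, "c": 0.71},
                            {"a": 0.2, "b": 0.5, "c": 0.8})
        assert ens.score_matrix(np.zeros((1, 1)))[0] == pytest.approx(0.5)

    def test_no_passing_member_fails_loudly_with_tss_list(self):
        ens = stub_ensemble({"a": 0.5, "b": 0.6}, {"a": 0.2, "b": 0.5})
        with pytest.raises(ValueError, match="a: TSS=0.500"):
            ens.score_matrix(np.zeros((1, 1)))

    def test_ensemble_bounded_by_member_scores(self):
        pa = make_pa(60, 60, seed=8)
        from cocoazone.sdm_ensemble import fit_ensemble

        ens, _ = fit_ensemble(pa, seed=8, tss_gate=-1.1)  # everyone passes
        scores = ens.score_matrix(pa.X)
        member_scores = np.array([m.score(pa.X) for _, m in ens.members])
        assert np.all(scores >= member_scores.min(axis=0) - 1e-12)
        assert np.all(scores <= member_scores.max(axis=0) + 1e-12)

    def test_projection_respects_nodata(self):
        grid = GridSpec(n_rows=2, n_cols=2, origin_y=2.0)
        mask = np.array([[False, True], [False, False]])
        stack = EnvStack(grid=grid, layers={
            "v0": Layer(grid=grid, name="v0",
                        values=np.ones((2, 2)), nodata_mask=mask)})
        ens = stub_ensemble({"a": 0.9}, {"a": 0.3})
        smap = ensemble_project(ens, stack, "current")
        assert smap.layer.nodata_mask[0, 1]
        assert smap.layer.values[0, 0] == pytest.approx(0.3)


class TestVariableImportance:
    def test_unused_variable_has_near_zero_importance(self):
        rng = np.random.default_rng(21)
        n = 1500
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        y = (x1 > 0).astype(int)
        X = np.column_stack([x1, x2])
        model = fit_learner("linear", X, y, seed=0)
        ens = EnsembleModel(
            members=[("linear", model)],
            evaluations=[ModelEvaluation("linear", 0.95, 0.5, 0.99)],
            feature_names=["x1", "x2"],
        )
        grid = GridSpec(n_rows=30, n_cols=50, origin_y=30.0)
        stack = EnvStack(grid=grid, layers={
            "x1": Layer(grid=grid, name="x1", values=x1.reshape(30, 50)),
            "x2": Layer(grid=grid, name="x2", values=x2.reshape(30, 50)),
        })
        imp = variable_importance(ens, stack, n_permutations=3, seed=4)
        assert imp["x2"] < 0.05
        assert imp["x1"] > 0.5
        assert list(imp) == sorted(imp, key=imp.get, reverse=True)
        imp2 = variable_importance(ens, stack, n_permutations=3, seed=4)
        assert imp == imp2  # same seed, same importances


class TestGcmConsensus:
    def constant_stack(self, value, mask=None, label="s"):
        grid = GridSpec(n_rows=2, n_cols=2, origin_y=2.0)
        return EnvStack(grid=grid, layers={
            "bio14": Layer(grid=grid, name="bio14",
                           values=np.full((2, 2), float(value)),
                           nodata_mask=mask)}, source_label=label)

    def test_mean_of_constant_stacks(self):
        stacks = [self.constant_stack(v) for v in (1, 2, 3, 4, 5)]
        cons = gcm_consensus(stacks)
        np.testing.assert_allclose(cons["bio14"].values, 3.0)

    def test_single_stack_is_identity(self):
        s = self.constant_stack(7)
        cons = gcm_consensus([s])
        np.testing.assert_array_equal(cons["bio14"].values, s["bio14"].values)

    def test_idempotent_on_identical_stacks(self):
        s = self.constant_stack(7)
        cons = gcm_consensus([s, s, s])
        np.testing.assert_array_equal(cons["bio14"].values, s["bio14"].values)

    def test_nodata_propagates_from_any_member(self):
        mask = np.array([[True, False], [False, False]])
        cons = gcm_consensus([self.constant_stack(1),
                              self.constant_stack(2, mask=mask)])
        assert cons["bio14"].nodata_mask[0, 0]
        assert cons["bio14"].nodata_mask.sum() == 1

    def test_mismatched_layer_sets_rejected(self):
        grid = GridSpec(n_rows=2, n_cols=2, origin_y=2.0)
        other = EnvStack(grid=grid, layers={
            "bio15": Layer(grid=grid, name="bio15", values=np.ones((2, 2)))})
        with pytest.raises(ValueError, match="layer sets"):
            gcm_consensus([self.constant_stack(1), other])

    def test_commutes_with_layer_selection(self, small_world):
        stacks = small_world.future["RCP4.5"]
        names = ["bio2", "bio14"]
        a = gcm_consensus(stacks).subset(names)
        b = gcm_consensus([s.subset(names) for s in stacks])
        for n in names:
            np.testing.assert_allclose(a[n].values, b[n].values)


class TestParameterRecoveryPerLearner:
    @pytest.mark.timeout(300)
    def test_linear_and_flexible_skill_on_default_worlds(self):
        """The additive-logistic and boosted-tree learners each exceed
        TSS 0.7 (replicate-mean over five splits) on three default
        synthetic worlds — the niche signal is strong enough for
        qualitatively different model families to recover it."""
        from cocoazone.occurrence_prep import correlation_filter
        from cocoazone.sdm_ensemble import fit_ensemble
        from cocoazone.synthetic_data import WorldConfig, make_world

        for seed in (1, 2, 3):
            world = make_world(WorldConfig(seed=seed))
            sel = correlation_filter(world.current)
            stack = world.current.subset(sel.kept)
            env = fit_envelope(world.occurrences, stack, q=0.025)
            pa = sample_pseudo_absences(env, stack, world.occurrences,
                                        n=300, seed=seed)
            ens, _ = fit_ensemble(pa, learners=["linear", "flexible"],
                                  seed=seed, n_replicates=5)
            for ev in ens.evaluations:
                assert ev.tss > 0.7, f"seed {seed}: {ev.learner_name} {ev.tss:.3f}"
                assert ev.auc > 0.8
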