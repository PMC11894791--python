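from itertools import product

import numpy as np
import pytest
from scipy.stats import f as f_dist
from scipy.stats import kstest

from erpmem.cluster import (
    F_SENTINEL,
    Cluster,
    EffectSpec,
    FMap,
    cluster_mean_amplitude,
    cluster_test,
    form_clusters,
    perm_null,
    pointwise_f,
)
from erpmem.epochs import EpochSet
from erpmem.erpsim import EffectPatch, ErpGenConfig, gen_condition_averages
from conftest import line_layout


def make_epochs(values, conditions, sample_rate=250.0, t0=0.0):
    values = np.asarray(values, dtype=float)
    n_subj, n_cond, n_sen, n_t = values.shape
    dt = 1000.0 / sample_rate
    return EpochSet(
        values=values,
        time_ms=t0 + dt * np.arange(n_t),
        sensor_ids=list(range(1, n_sen + 1)),
        conditions=list(conditions),
        subjects=[f"s{i}" for i in range(n_subj)],
        sample_rate=sample_rate,
        baseline_ms=(t0, t0 + dt),
    )


def make_fmap(f, df=(1, 10), sample_rate=250.0):
    f = np.asarray(f, dtype=float)
    return FMap(
        f=f,
        df=df,
        p=f_dist.sf(f, *df),
        sensor_ids=list(range(1, f.shape[0] + 1)),
        time_ms=4.0 * np.arange(f.shape[1]),
        sample_rate=sample_rate,
    )


# -- independent oracles -------------------------------------------------


def brute_force_clusters(f, f_crit, edges, min_run):
    """Enumeration oracle: per-sensor runs, then BFS over point adjacency."""
    ns, nt = f.shape
    surviving = set()
    for s in range(ns):
        run = []
        for t in range(nt + 1):
            if t < nt and f[s, t] > f_crit:
                run.append(t)
            else:
                if len(run) >= min_run:
                    surviving.update((s, tt) for tt in run)
                run = []
    sym = set()
    for i, j in edges:
        sym.add((i, j))
        sym.add((j, i))
    clusters = []
    todo = set(surviving)
    while todo:
        start = todo.pop()
        comp = {start}
        frontier = [start]
        while frontier:
            s, t = frontier.pop()
            candidates = [(s, t - 1), (s, t + 1)]
            candidates += [(s2, t) for s2 in range(ns) if (s, s2) in sym]
            for nb in candidates:
                if nb in todo:
                    todo.remove(nb)
                    comp.add(nb)
                    frontier.append(nb)
        clusters.append(comp)
    return {
        frozenset(comp): sum(f[s, t] for s, t in comp) for comp in clusters
    }


def brute_force_interaction_f(values):
    """Direct-formula one-sample t^2 on the 2x2 double difference."""
    c = (values[:, 0] - values[:, 1]) - (values[:, 2] - values[:, 3])
    n = len(c)
    t = c.mean() / (c.std(ddof=1) / np.sqrt(n))
    return t**2


class TestPointwiseF:
    def test_hand_written_2x2_matches_direct_formula(self, rng):
        values = rng.normal(size=(3, 4, 1, 1))
        ep = make_epochs(values, ["a1", "a2", "b1", "b2"])
        eff = EffectSpec("ix", "interaction_within", cells=(("a1", "a2"), ("b1", "b2")))
        fmap = pointwise_f(ep, eff)
        assert fmap.df == (1, 2)
        assert fmap.f[0, 0] == pytest.approx(brute_force_interaction_f(values[:, :, 0, 0]))

    def test_paired_matches_scipy(self, rng):
        from scipy.stats import ttest_rel

        values = rng.normal(size=(8, 2, 2, 3))
        ep = make_epochs(values, ["a", "b"])
        fmap = pointwise_f(ep, EffectSpec("d", "paired", cells=("a", "b")))
        t, p = ttest_rel(values[:, 0], values[:, 1], axis=0)
        assert np.allclose(fmap.f, t**2)
        assert np.allclose(fmap.p, p)

    def test_mixed_matches_pooled_two_sample(self, rng):
        from scipy.stats import ttest_ind

        values = rng.normal(size=(10, 2, 1, 4))
        groups = {f"s{i}": ("g1" if i < 5 else "g2") for i in range(10)}
        ep = make_epochs(values, ["a", "b"])
        fmap = pointwise_f(
            ep, EffectSpec("gx", "interaction_mixed", cells=("a", "b"), groups=groups)
        )
        diff = values[:, 0] - values[:, 1]
        t, p = ttest_ind(diff[5:], diff[:5], axis=0, equal_var=True)
        assert fmap.df == (1, 8)
        assert np.allclose(fmap.f, t**2)

    def test_zero_variance_contrast_capped_and_flagged(self):
        values = np.zeros((4, 4, 1, 2))
        values[:, 0] = 1.0  # identical nonzero contrast for every subject
        ep = make_epochs(values, ["a1", "a2", "b1", "b2"])
        fmap = pointwise_f(
            ep, EffectSpec("ix", "interaction_within", cells=(("a1", "a2"), ("b1", "b2")))
        )
        assert np.all(fmap.f == F_SENTINEL)
        assert fmap.degenerate.all()
        assert np.all(fmap.p < 1e-10)

    def test_null_pointwise_pvalues_uniform(self, rng):
        # independent points under a true null: KS test against uniform
        values = rng.normal(size=(40, 2, 1, 2000))
        ep = make_epochs(values, ["a", "b"])
        fmap = pointwise_f(ep, EffectSpec("d", "paired", cells=("a", "b")))
        assert kstest(fmap.p.ravel(), "uniform").pvalue > 0.01


class TestFormClusters:
    def test_all_subthreshold_gives_no_clusters(self):
        lay = line_layout(3)
        fmap = make_fmap(np.zeros((3, 12)))
        assert form_clusters(fmap, lay) == []

    def test_exact_five_sample_run_mass_and_duration(self):
        lay = line_layout(1)
        f = np.zeros((1, 12))
        f[0, 3:8] = [3.0, 4.0, 5.0, 4.0, 3.0]
        fmap = make_fmap(f, df=(1, 10))
        # forming threshold below 3 so the whole run is supra-threshold
        alpha = 0.15  # F_crit(0.15; 1, 10) ~ 2.5
        assert f_dist.isf(alpha, 1, 10) < 3.0
        clusters = form_clusters(fmap, lay, forming_alpha=alpha, min_run=5)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.mass == pytest.approx(19.0)
        assert c.window_ms[1] - c.window_ms[0] == pytest.approx(20.0)  # 5 samples at 250 Hz

    def test_four_sample_run_discarded(self):
        lay = line_layout(1)
        f = np.zeros((1, 12))
        f[0, 3:7] = 10.0
        fmap = make_fmap(f)
        assert form_clusters(fmap, lay, forming_alpha=0.05, min_run=5) == []

    def test_nonadjacent_sensors_form_separate_clusters(self):
        lay = line_layout(4)
        f = np.zeros((4, 12))
        f[0, 2:9] = 30.0
        f[3, 2:9] = 20.0  # sensors 1 and 4 are not neighbors on the chain
        clusters = form_clusters(make_fmap(f), lay)
        assert len(clusters) == 2
        assert clusters[0].sensor_ids == [1]
        assert clusters[1].sensor_ids == [4]

    def test_adjacent_sensors_merge(self):
        lay = line_layout(4)
        f = np.zeros((4, 12))
        f[1, 2:9] = 30.0
        f[2, 2:9] = 20.0
        clusters = form_clusters(make_fmap(f), lay)
        assert len(clusters) == 1
        assert clusters[0].sensor_ids == [2, 3]

    def test_invalid_parameters_rejected(self):
        fmap = make_fmap(np.zeros((2, 8)))
        lay = line_layout(2)
        with pytest.raises(ValueError):
            form_clusters(fmap, lay, min_run=0)
        with pytest.raises(ValueError):
            form_clusters(fmap, lay, forming_alpha=1.5)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_enumeration_on_small_grids(self, trial):
        # randomized grids up to 4 sensors x 12 samples vs the oracle
        rng = np.random.default_rng(100 + trial)
        ns = int(rng.integers(1, 5))
        nt = 12
        f = rng.exponential(2.0, size=(ns, nt))
        edges = {
            (i, j)
            for i in range(ns)
            for j in range(i + 1, ns)
            if rng.uniform() < 0.5
        }
        from erpmem.layout import SensorLayout

        lay = SensorLayout(
            ids=list(range(1, ns + 1)),
            positions=np.column_stack([np.arange(ns), np.zeros(ns), np.zeros(ns)]),
            edges=edges,
        )
        min_run = int(rng.integers(1, 6))
        alpha = 0.3
        fmap = make_fmap(f, df=(1, 9))
        f_crit = f_dist.isf(alpha, 1, 9)
        expected = brute_force_clusters(f, f_crit, edges, min_run)
        got = form_clusters(fmap, lay, forming_alpha=alpha, min_run=min_run)
        got_map = {
            frozenset(
                (si, ti) for si, ti in zip(*np.nonzero(c.mask))
            ): c.mass
            for c in got
        }
        assert set(got_map) == set(expected)
        for key, mass in expected.items():
            assert got_map[key] == pytest.approx(mass)


class TestPermNull:
    def test_zero_contrast_zero_noise_null_is_all_zero(self):
        lay = line_layout(2)
        values = np.zeros((5, 4, 2, 16))
        values[:, :, :, :] = np.arange(16)  # identical in every condition
        ep = make_epochs(values, ["a1", "a2", "b1", "b2"])
        eff = EffectSpec("ix", "interaction_within", cells=(("a1", "a2"), ("b1", "b2")))
        null = perm_null(ep, eff, lay, n_perm=100, seed=0)
        assert np.all(null.max_mass == 0.0)
        assert null.critical_mass == 0.0

    def test_same_seed_reproduces_null_sample(self, rng):
        lay = line_layout(3)
        ep = make_epochs(rng.normal(size=(6, 2, 3, 20)), ["a", "b"])
        eff = EffectSpec("d", "paired", cells=("a", "b"))
        a = perm_null(ep, eff, lay, n_perm=150, seed=5)
        b = perm_null(ep, eff, lay, n_perm=150, seed=5)
        assert np.array_equal(a.max_mass, b.max_mass)

    def test_exhaustive_sign_flips_match_enumeration_oracle(self, rng):
        # 4 subjects, 1 sensor, 8 samples: all 2^4 sign patterns
        lay = line_layout(1)
        data = rng.normal(size=(4, 2, 1, 8)) + 0.8
        ep = make_epochs(data, ["a", "b"])
        eff = EffectSpec("d", "paired", cells=("a", "b"))
        alpha, min_run = 0.2, 3
        null = perm_null(
            ep, eff, lay, seed=0, forming_alpha=alpha, min_run=min_run, exhaustive=True
        )
        assert null.n_perm == 16

        contrast = data[:, 0, 0] - data[:, 1, 0]  # (4, 8)
        f_crit = f_dist.isf(alpha, 1, 3)
        expected = []
        for signs in product([-1.0, 1.0], repeat=4):
            flipped = np.asarray(signs)[:, None] * contrast
            m = flipped.mean(axis=0)
            sd = flipped.std(axis=0, ddof=1)
            f = (m / (sd / 2.0)) ** 2  # sqrt(4) = 2
            masses = brute_force_clusters(f[None, :], f_crit, set(), min_run)
            expected.append(max(masses.values()) if masses else 0.0)
        assert np.allclose(np.sort(null.max_mass), np.sort(expected))

    def test_too_few_permutations_rejected(self, rng):
        lay = line_layout(1)
        ep = make_epochs(rng.normal(size=(4, 2, 1, 8)), ["a", "b"])
        with pytest.raises(ValueError, match="n_perm"):
            perm_null(ep, EffectSpec("d", "paired", cells=("a", "b")), lay, n_perm=10)


class TestClusterTest:
    def test_pvalues_bounded_by_plus_one_correction(self, rng):
        lay = line_layout(3)
        values = rng.normal(size=(8, 2, 3, 30))
        values[:, 0, 1, 10:25] += 4.0  # strong effect
        ep = make_epochs(values, ["a", "b"])
        res = cluster_test(ep, EffectSpec("d", "paired", cells=("a", "b")), lay,
                           n_perm=199, seed=1)
        assert res.clusters
        for c in res.clusters:
            assert 0.0 < c.p <= 1.0
            assert c.p >= 1.0 / (1 + 199)

    def test_mass_invariant_to_constant_shift_of_all_conditions(self, rng):
        lay = line_layout(3)
        values = rng.normal(size=(8, 4, 3, 30))
        ep1 = make_epochs(values, ["a1", "a2", "b1", "b2"])
        ep2 = make_epochs(values + 11.3, ["a1", "a2", "b1", "b2"])
        eff = EffectSpec("ix", "interaction_within", cells=(("a1", "a2"), ("b1", "b2")))
        f1 = pointwise_f(ep1, eff)
        f2 = pointwise_f(ep2, eff)
        assert np.allclose(f1.f, f2.f)

    def test_determinism_of_full_test(self, rng):
        lay = line_layout(3)
        ep = make_epochs(rng.normal(size=(6, 2, 3, 25)), ["a", "b"])
        eff = EffectSpec("d", "paired", cells=("a", "b"))
        a = cluster_test(ep, eff, lay, n_perm=120, seed=3)
        b = cluster_test(ep, eff, lay, n_perm=120, seed=3)
        assert a.to_dict() == b.to_dict()
        assert np.array_equal(a.null_max_mass, b.null_max_mass)

    def test_recovers_injected_patch_with_high_overlap(self, small_layout):
        # amplitude 10x the noise SD: exactly one significant cluster whose
        # footprint overlaps the injected patch at Jaccard >= 0.5
        patch = EffectPatch(
            window_ms=(100.0, 200.0), center=10, radius=2, amplitudes={"a1": 1.0}
        )
        cfg = ErpGenConfig(
            n_sensors=32, window_ms=(0.0, 256.0), baseline_ms=(0.0, 8.0),
            noise_sd=0.1, smoothing_steps=2, ar_coef=0.3, effects=[patch],
        )
        ep, truth = gen_condition_averages(
            cfg, [f"s{i}" for i in range(12)], ["a1", "a2", "b1", "b2"],
            small_layout, seed=21,
        )
        eff = EffectSpec("ix", "interaction_within", cells=(("a1", "a2"), ("b1", "b2")))
        res = cluster_test(ep, eff, small_layout, n_perm=200, seed=2)
        sig = res.significant_clusters()
        assert len(sig) == 1
        truth_mask = np.zeros_like(sig[0].mask)
        sidx = [small_layout.index(s) for s in truth[0]["sensors"]]
        tmask = ep.time_mask(truth[0]["window_ms"])
        truth_mask[np.ix_(sidx, np.where(tmask)[0])] = True
        inter = (sig[0].mask & truth_mask).sum()
        union = (sig[0].mask | truth_mask).sum()
        assert inter / union >= 0.5


class TestClusterMeanAmplitude:
    def test_constant_epochs_give_constant_mean(self):
        ep = make_epochs(np.full((3, 2, 4, 20), 2.5), ["a", "b"])
        cl = Cluster(
            sensor_ids=[1, 3], window_ms=(8.0, 40.0), sample_span=(2, 10),
            mass=1.0, n_points=16,
        )
        means = cluster_mean_amplitude(ep, cl)
        assert np.allclose(means["mean_uv"], 2.5)

    def test_matches_masked_mean_oracle(self, rng):
        values = rng.normal(size=(4, 2, 5, 20))
        ep = make_epochs(values, ["a", "b"])
        cl = Cluster(
            sensor_ids=[2, 4, 5], window_ms=(12.0, 48.0), sample_span=(3, 12),
            mass=1.0, n_points=27,
        )
        means = cluster_mean_amplitude(ep, cl)
        expected = values[np.ix_(range(4), range(2), [1, 3, 4], range(3, 12))].mean(axis=(2, 3))
        got = means.pivot(index="subject", columns="condition", values="mean_uv")
        assert np.allclose(got.to_numpy(), expected)

    def test_disjoint_cluster_rejected(self, rng):
        ep = make_epochs(rng.normal(size=(2, 2, 3, 10)), ["a", "b"])
        cl = Cluster(
            sensor_ids=[99], window_ms=(0.0, 8.0), sample_span=(0, 2),
            mass=1.0, n_points=2,
        )
        with pytest.raises(ValueError):
            cluster_mean_amplitude(ep, cl)
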