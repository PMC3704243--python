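import numpy as np
import pytest

from invpopgen.coalescent import (
    CoalescentConfig,
    Genealogy,
    accept_genealogy,
    accepted_genealogies,
    drop_mutations,
    nested_subsample,
    neutrality_envelope,
    place_inversions,
    simulate_genealogy,
)
from invpopgen.diversity import harmonic


def _labels_with_frequencies(freqs, rng=None):
    """A label vector realising the given class frequencies, shuffled."""
    lab = np.repeat(np.arange(len(freqs)), freqs)
    if rng is not None:
        rng.shuffle(lab)
    return lab


class TestSimulateGenealogy:
    def test_times_increase_rootward(self, rng):
        g = simulate_genealogy(40, 0.0, rng)
        internal = g.node_time[40:]
        assert (np.diff(internal) > 0).all()
        assert (g.node_time[:40] == 0).all()
        # exactly n-1 internal nodes, every non-root node has a parent
        assert (g.parent[:-1] >= 40).all()
        assert g.parent[-1] == -1

    def test_pair_tmrca_is_standard_exponential(self, rng):
        t = [simulate_genealogy(2, 0.0, rng).tmrca for _ in range(4000)]
        assert np.mean(t) == pytest.approx(1.0, abs=3 * np.std(t) / np.sqrt(4000))

    def test_tmrca_matches_closed_form(self, rng):
        # E[TMRCA] = 2(1 - 1/n)
        t = [simulate_genealogy(50, 0.0, rng).tmrca for _ in range(3000)]
        se = np.std(t) / np.sqrt(len(t))
        assert np.mean(t) == pytest.approx(2 * (1 - 1 / 50), abs=3 * se)

    def test_growth_shrinks_tmrca(self):
        # paired comparison: identical random draws, different time rescaling
        t0 = [simulate_genealogy(50, 0.0, np.random.default_rng(s)).tmrca for s in range(500)]
        t7 = [simulate_genealogy(50, 7.0, np.random.default_rng(s)).tmrca for s in range(500)]
        diff = np.array(t0) - np.array(t7)
        assert (diff > 0).all()  # rescaling is monotone, so every pair orders


class TestPlaceInversions:
    def test_no_events_single_class(self, rng):
        g = simulate_genealogy(10, 0.0, rng)
        labels = place_inversions(g, 0, rng)
        assert set(labels) == {0}

    def test_single_event_on_terminal_branch(self):
        # hand-built 3-tip caterpillar: tips 0,1 join at node 3, then node 4
        g = Genealogy(
            n_tips=3,
            parent=np.array([3, 3, 4, 4, -1]),
            node_time=np.array([0.0, 0.0, 0.0, 1.0, 2.0]),
        )
        from invpopgen import _kernels

        labels_all = np.zeros(5, dtype=np.int64)
        _kernels.label_tips(
            g.parent, 3, np.array([2]), np.array([0.5]), labels_all
        )
        assert sorted(np.bincount(labels_all[:3])) == [1, 2]

    def test_labels_match_root_path_walk(self, rng):
        # oracle: for each tip, walk to the root collecting events on the way
        for _ in range(20):
            g = simulate_genealogy(30, 0.0, rng)
            place_inversions(g, 5, rng)
            branch, ev_time = g.events
            for tip in range(30):
                best_t, best_lab = np.inf, 0
                node = tip
                while node != -1:
                    for e, b in enumerate(branch):
                        if b == node and ev_time[e] < best_t:
                            best_t, best_lab = ev_time[e], e + 1
                    node = g.parent[node]
                assert g.class_labels[tip] == best_lab

    def test_shadowed_events_reduce_class_count(self, rng):
        # many events on a tiny tree must still yield labels in range
        g = simulate_genealogy(5, 0.0, rng)
        labels = place_inversions(g, 10, rng)
        assert len(np.unique(labels)) <= 6


class TestAcceptance:
    def test_wrong_class_count(self):
        lab = _labels_with_frequencies([100, 200, 300, 400, 500])
        assert not accept_genealogy(lab, (16, 19, 20, 18, 4, 30))

    def test_componentwise_comparison(self):
        lab = _labels_with_frequencies([16, 20, 25, 30, 40, 4869])
        assert accept_genealogy(lab, (16, 19, 20, 18, 4, 30))

    def test_first_component_violation(self):
        lab = _labels_with_frequencies([10, 20, 25, 30, 40, 4875])
        assert not accept_genealogy(lab, (16, 19, 20, 18, 4, 30))


class TestDropMutations:
    def test_mean_segregating_sites(self, rng):
        # E[S] = theta * a_n at n = 2
        s = [drop_mutations(simulate_genealogy(2, 0.0, rng), 1.0, rng).shape[1]
             for _ in range(4000)]
        se = np.std(s) / np.sqrt(len(s))
        assert np.mean(s) == pytest.approx(1.0, abs=3 * se)

    def test_columns_are_clades(self, rng):
        # oracle: every segregating column's carrier set must equal the
        # descendant tip set of some branch, recomputed independently
        g = simulate_genealogy(12, 0.0, rng)
        hap = drop_mutations(g, 10.0, rng)
        desc = {}
        for node in range(g.n_nodes - 1):
            tips = set()
            stack = [node]
            while stack:
                v = stack.pop()
                if v < 12:
                    tips.add(v)
                else:
                    stack.extend(np.nonzero(g.parent == v)[0])
            desc[node] = frozenset(tips)
        clades = set(desc.values())
        for col in range(hap.shape[1]):
            carriers = frozenset(np.nonzero(hap[:, col])[0])
            assert carriers in clades

    def test_rejects_nonpositive_theta(self, rng):
        with pytest.raises(ValueError):
            drop_mutations(simulate_genealogy(4, 0.0, rng), 0.0, rng)


class TestNestedSubsample:
    def _accepted(self, counts, rng, n_tips=400):
        while True:
            g = simulate_genealogy(n_tips, 0.0, rng)
            place_inversions(g, len(counts) - 1, rng)
            if accept_genealogy(g.class_labels, counts):
                return g

    def test_minimal_counts_one_per_class(self, rng):
        g = self._accepted((1, 1, 1, 1, 1, 1), rng, n_tips=200)
        hap = drop_mutations(g, 5.0, rng)
        sub, labels, idx = nested_subsample(
            hap, g.class_labels, (1, 1, 1, 1, 1, 1), rng, g.class_birth_time
        )
        assert sub.shape[0] == 6
        assert len(set(labels)) == 6

    def test_size_conservation(self, rng):
        counts = (16, 19, 20, 18, 4)
        g = self._accepted(counts, rng)
        hap = drop_mutations(g, 5.0, rng)
        sub, labels, idx = nested_subsample(
            hap, g.class_labels, counts, rng, g.class_birth_time,
            ("CH", "AR", "PP", "ST", "TL"),
        )
        assert sub.shape[0] == 77
        assert [labels.count(a) for a in ("CH", "AR", "PP", "ST", "TL")] == list(counts)

    def test_deterministic_under_seed(self, rng):
        counts = (5, 8, 10)
        g = self._accepted(counts, rng, n_tips=100)
        hap = drop_mutations(g, 5.0, rng)
        out1 = nested_subsample(hap, g.class_labels, counts,
                                np.random.default_rng(3), g.class_birth_time)
        out2 = nested_subsample(hap, g.class_labels, counts,
                                np.random.default_rng(3), g.class_birth_time)
        assert np.array_equal(out1[2], out2[2])
        assert np.array_equal(out1[0], out2[0])

    def test_pairwise_total_conserves_across_partition(self, rng):
        # total pairwise differences = within-class + between-class parts
        counts = (6, 9, 12)
        g = self._accepted(counts, rng, n_tips=150)
        hap = drop_mutations(g, 8.0, rng)
        sub, labels, _ = nested_subsample(
            hap, g.class_labels, counts, rng, g.class_birth_time
        )
        labels = np.array(labels)
        total = 0
        within = 0
        between = 0
        n = sub.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                d = int((sub[i] != sub[j]).sum())
                total += d
                if labels[i] == labels[j]:
                    within += d
                else:
                    between += d
        assert total == within + between


class TestEnvelope:
    @pytest.fixture()
    def config(self):
        return CoalescentConfig(
            arrangement_names=("CH", "AR", "PP"),
            observed_counts_by_age={"locA": (5, 8, 10), "locB": (5, 8, 10)},
            theta_per_locus={"locA": 0.01, "locB": 0.02},
            sites_per_locus={"locA": 500.0, "locB": 800.0},
            n_tips=300,
            n_accepted=60,
            seed=5,
        )

    def test_percentiles_monotone_and_flags(self, config):
        res = neutrality_envelope(config)
        t = res.table
        assert (t.p025 <= t.p500).all() and (t.p500 <= t.p975).all()
        med = t[(t.locus == "locA") & (t.arrangement == "all")
                & (t.statistic == "pi")].iloc[0]
        observed = {
            ("locA", "all", "pi"): float(med.p500),
            ("locB", "all", "pi"): 10.0,
            ("locA", "CH", "theta_w"): -1.0,
        }
        res2 = neutrality_envelope(config, observed)
        assert res2.flag("locA", "all", "pi") == "inside"
        assert res2.flag("locB", "all", "pi") == "above"
        assert res2.flag("locA", "CH", "theta_w") == "below"

    def test_deterministic_under_seed(self, config):
        t1 = neutrality_envelope(config).table
        t2 = neutrality_envelope(config).table
        assert t1.equals(t2)

    def test_emitted_genealogies_satisfy_predicate(self, config):
        # re-check the acceptance predicate with an independent comparison
        rng = np.random.default_rng(0)
        stream = accepted_genealogies(config, (5, 8, 10), rng)
        for _ in range(25):
            gen, _ = next(stream)
            freqs = np.sort(np.bincount(gen.class_labels))
            freqs = freqs[freqs > 0]
            assert len(freqs) == 3
            assert (freqs >= np.array([5, 8, 10])).all()

    def test_acceptance_floor_aborts(self):
        config = CoalescentConfig(
            arrangement_names=("A", "B", "C"),
            observed_counts_by_age={"x": (45, 45, 5)},  # needs 2 classes >= 45/100
            theta_per_locus={"x": 0.01},
            sites_per_locus={"x": 100.0},
            n_tips=100,
            n_accepted=50,
            seed=1,
            acceptance_floor=0.5,  # unattainably high rate
            acceptance_floor_window=500,
        )
        with pytest.raises(RuntimeError, match="acceptance rate"):
            neutrality_envelope(config)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="n_tips"):
            CoalescentConfig(
                arrangement_names=("A", "B"),
                observed_counts_by_age={"x": (80, 80)},
                theta_per_locus={"x": 0.01},
                sites_per_locus={"x": 100.0},
                n_tips=100,
            )


def test_subsample_estimators_recover_theta(rng):
    # constant size, no inversion filtering: E[S] = theta*a_n, E[pi] = theta
    n, theta, reps = 20, 4.0, 1500
    S_vals, pi_vals = [], []
    for _ in range(reps):
        g = simulate_genealogy(n, 0.0, rng)
        hap = drop_mutations(g, theta, rng)
        S_vals.append(hap.shape[1])
        c = hap.sum(axis=0)
        pi_vals.append((c * (n - c)).sum() / (n * (n - 1) / 2))
    se_S = np.std(S_vals) / np.sqrt(reps)
    se_pi = np.std(pi_vals) / np.sqrt(reps)
    assert np.mean(S_vals) == pytest.approx(theta * harmonic(n), abs=3 * se_S)
    assert np.mean(pi_vals) == pytest.approx(theta, abs=3 * se_pi)
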