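import numpy as np
import pytest

from taskspike.latency import (
    bic,
    bootstrap_flow,
    gmm_select,
    order_label,
    peak_latency,
    xmeans_check,
)
from taskspike.peth import Peth


def _peth(rates, lo=-0.5, hi=0.5):
    rates = np.asarray(rates, float)
    edges = np.linspace(lo, hi, rates.size + 1)
    return Peth(edges, rates, 10)


class TestPeakLatency:
    def test_gaussian_bump_at_60ms(self):
        c = np.linspace(-0.5, 0.5, 1001)[:-1] + 0.0005
        rates = np.exp(-0.5 * ((c - 0.060) / 0.0125) ** 2)
        ms, flat = peak_latency(_peth(rates), (-0.5, 0.5))
        assert not flat
        assert ms == pytest.approx(60.0, abs=1.0)

    def test_tie_broken_to_earliest(self):
        c = np.linspace(-0.5, 0.5, 51)[:-1]
        rates = np.zeros(50)
        i1 = np.argmin(np.abs(c + 0.1))
        i2 = np.argmin(np.abs(c - 0.1))
        rates[i1] = rates[i2] = 5.0
        ms, _ = peak_latency(_peth(rates), (-0.5, 0.5))
        assert ms < 0

    def test_flat_flagged(self):
        ms, flat = peak_latency(_peth(np.full(50, 3.0)), (-0.5, 0.5))
        assert flat and np.isnan(ms)


class TestBic:
    def test_closed_forms(self):
        assert bic(0.0, 0, 10) == 0.0
        # -2 ln L = 20 and k ln n = 2 ln(e^2) = 4
        assert bic(-10.0, 2, np.e ** 2) == pytest.approx(24.0)

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            bic(0.0, 1, 0)

    def test_matches_recomputation_from_fit(self, rng):
        x = rng.normal(0, 1, 100)
        sel = gmm_select(x, k_range=[1], repeats=5, seed=0)
        mu, sd, w = sel.means[0], sel.sds[0], sel.weights[0]
        ll = np.sum(np.log(w / np.sqrt(2 * np.pi * sd**2)
                           * np.exp(-((x - mu) ** 2) / (2 * sd**2))))
        assert sel.mean_bic[1] == pytest.approx(bic(ll, 2, 100), rel=1e-6)


class TestGmmSelect:
    def test_one_component_selected(self):
        hits = sum(
            gmm_select(np.random.default_rng(s).normal(0, 20, 200),
                       repeats=100, seed=s).chosen_k == 1
            for s in range(5)
        )
        assert hits == 5

    def test_two_components_selected_at_5sd(self):
        hits = 0
        for s in range(5):
            r = np.random.default_rng(s)
            x = np.concatenate([r.normal(-100, 20, 100), r.normal(100, 20, 100)])
            sel = gmm_select(x, repeats=100, seed=s)
            hits += sel.chosen_k == 2
            if sel.chosen_k == 2:
                assert sorted(np.abs(sel.means).round(-1)) == [100, 100]
        assert hits == 5

    def test_best_likelihood_nondecreasing_in_k(self):
        r = np.random.default_rng(3)
        x = np.concatenate([r.normal(-100, 20, 100), r.normal(100, 20, 100)])
        sel = gmm_select(x, repeats=200, seed=3)
        lls = [sel.best_loglik[k] for k in sel.k_range]
        assert all(b >= a - 0.5 for a, b in zip(lls, lls[1:]))

    def test_matches_sklearn_likelihood(self):
        from sklearn.mixture import GaussianMixture

        r = np.random.default_rng(4)
        x = np.concatenate([r.normal(-100, 20, 100), r.normal(100, 20, 100)])
        sel = gmm_select(x, k_range=[2], repeats=100, seed=4)
        gm = GaussianMixture(2, n_init=10, random_state=0).fit(x.reshape(-1, 1))
        sk_ll = gm.score(x.reshape(-1, 1)) * x.size
        assert sel.best_loglik[2] == pytest.approx(sk_ll, abs=1.0)

    def test_deterministic_under_seed(self):
        x = np.random.default_rng(5).normal(0, 10, 120)
        a = gmm_select(x, repeats=50, seed=9)
        b = gmm_select(x, repeats=50, seed=9)
        assert a.chosen_k == b.chosen_k
        assert a.mean_bic == b.mean_bic
        assert np.array_equal(a.means, b.means)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            gmm_select(np.arange(5.0), repeats=10, seed=0)


class TestXmeans:
    def test_single_tight_cluster(self):
        x = np.random.default_rng(0).normal(50, 5, 150)
        assert xmeans_check(x, seed=0) == 1

    def test_two_separated_clusters(self):
        r = np.random.default_rng(1)
        x = np.concatenate([r.normal(-100, 20, 100), r.normal(100, 20, 100)])
        assert xmeans_check(x, seed=1) == 2

    def test_k_max_respected(self):
        r = np.random.default_rng(2)
        x = np.concatenate([r.normal(m, 2, 50) for m in (0, 50, 100, 150, 200, 250)])
        assert xmeans_check(x, k_max=5, seed=2) <= 5


class TestOrderLabel:
    @pytest.mark.parametrize("cs,cd,expected", [
        (10.0, -10.0, "s->c->d"),   # the LECs -> CA1 -> LECd quadrant
        (-10.0, -20.0, "c->s->d"),
        (0.0, 0.0, "c->s->d"),      # boundary rule: ties toward c, s, d
        (-10.0, 10.0, "d->c->s"),
        (20.0, 10.0, "s->d->c"),  # s leads c by 20 ms, d by 10 ms
    ])
    def test_examples(self, cs, cd, expected):
        assert order_label(cs, cd) == expected

    def test_partition_property(self, rng):
        labels = {order_label(a, b)
                  for a, b in rng.normal(0, 50, (500, 2))}
        assert labels <= {"c->s->d", "c->d->s", "s->c->d", "s->d->c",
                          "d->c->s", "d->s->c"}
        assert len(labels) == 6
        # label consistent with the sign comparisons
        for a, b in rng.normal(0, 50, (50, 2)):
            lab = order_label(a, b)
            if a > 0:
                assert lab.index("s") < lab.index("c")
            if b > 0:
                assert lab.index("d") < lab.index("c")
            if b - a > 0:
                assert lab.index("d") < lab.index("s")


class TestBootstrapFlow:
    def test_degenerate_configuration_single_order(self):
        fr = bootstrap_flow({"CA1": [0.0], "LECs": [-100.0], "LECd": [100.0]},
                            B=500, seed=0, repeats_2d=3)
        assert (fr.order_labels == "s->c->d").all()
        assert fr.quadrant_fraction == 1.0

    def test_identical_distributions_centered(self):
        lat = list(np.random.default_rng(0).normal(0, 30, 40))
        fr = bootstrap_flow({"CA1": lat, "LECs": lat, "LECd": lat},
                            B=1000, seed=1, repeats_2d=3)
        se = 30 * np.sqrt(2) / np.sqrt(1000)
        assert abs(fr.lag_cs.mean()) < 4 * se
        assert abs(fr.lag_cd.mean()) < 4 * se

    def test_planted_mixture_recovers_clusters(self):
        r = np.random.default_rng(2)
        ca1 = np.concatenate([r.normal(-225, 15, 25), r.normal(60, 15, 25)])
        fr = bootstrap_flow({"CA1": ca1, "LECs": r.normal(-225, 15, 30),
                             "LECd": r.normal(170, 15, 30)},
                            B=600, seed=2, repeats_2d=5)
        assert fr.chosen_k >= 2

    def test_deterministic_under_seed(self):
        regions = {"CA1": [0.0, 10.0], "LECs": [-50.0, -40.0], "LECd": [80.0, 90.0]}
        a = bootstrap_flow(regions, B=200, seed=5, repeats_2d=3)
        b = bootstrap_flow(regions, B=200, seed=5, repeats_2d=3)
        assert np.array_equal(a.lag_cs, b.lag_cs)
        assert np.array_equal(a.cluster_assignments, b.cluster_assignments)
        assert a.chosen_k == b.chosen_k

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="LECd"):
            bootstrap_flow({"CA1": [1.0], "LECs": [2.0], "LECd": []}, B=10, seed=0)
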