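import warnings

import numpy as np
import pytest
from scipy import integrate, optimize
from scipy.special import gammaln

from cstdyn.dmm import (
    ALPHA_PRIOR_RATE,
    assign_cst,
    fit_dmm,
    laplace_evidence,
    relabel_by_frequency,
    select_k,
)
from cstdyn.types import CountsTable


def dm_loglik(x, alpha):
    """Straight-line Dirichlet-Multinomial log-likelihood (oracle)."""
    x = np.asarray(x, float)
    alpha = np.asarray(alpha, float)
    n = x.sum(axis=1)
    a = alpha.sum()
    return float(np.sum(
        gammaln(n + 1) - gammaln(x + 1).sum(axis=1)
        + gammaln(a) - gammaln(n + a)
        + (gammaln(x + alpha) - gammaln(alpha)).sum(axis=1)))


class TestFitDMM:
    def test_k1_matches_direct_optimizer(self, two_group_counts):
        table, _ = two_group_counts
        fit = fit_dmm(table, 1, seed=0)
        # independent oracle: direct optimization of the single-component
        # DM likelihood over log-alpha
        res = optimize.minimize(
            lambda la: -dm_loglik(table.counts, np.exp(la)),
            np.log(fit.alpha[0] + 0.5), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-6)
        assert fit.pi.tolist() == [1.0]

    def test_two_separated_groups_recovered(self, two_group_counts):
        table, labels = two_group_counts
        fit = fit_dmm(table, 2, seed=1)
        asg = assign_cst(fit, table)
        assert asg.posterior.max(axis=1).min() > 0.99
        first = asg.map_label[labels == 1]
        second = asg.map_label[labels == 2]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]

    def test_em_loglik_monotone(self, two_group_counts):
        table, _ = two_group_counts
        fit = fit_dmm(table, 2, seed=3)
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs >= -1e-8 * np.abs(fit.loglik_trace[:-1]))

    def test_k_exceeding_samples_rejected(self, overdispersed_toy):
        with pytest.raises(ValueError):
            fit_dmm(overdispersed_toy, 5, seed=0)


class TestLaplaceEvidence:
    def test_matches_quadrature_on_2otu_toy(self, overdispersed_toy):
        fit = fit_dmm(overdispersed_toy, 1, seed=0)
        nle = laplace_evidence(fit, overdispersed_toy)

        nu = ALPHA_PRIOR_RATE
        counts = overdispersed_toy.counts

        def integrand(a1, a2):
            return np.exp(dm_loglik(counts, np.array([a1, a2]))
                          + 2 * np.log(nu) - nu * (a1 + a2))

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            val, _ = integrate.dblquad(integrand, 1e-9, 500, 1e-9, 500)
        oracle = -np.log(val)
        assert abs(nle - oracle) / abs(oracle) < 0.05

    def test_evidence_penalizes_extra_components(self):
        wins = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            base = np.array([5.0, 3, 2, 4, 6, 2, 1, 3, 2, 2]) * 2
            x = np.array([rng.multinomial(300, rng.dirichlet(base))
                          for _ in range(60)])
            table = CountsTable([f"s{i}" for i in range(60)],
                                [f"o{j}" for j in range(10)], x)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                e1 = laplace_evidence(fit_dmm(table, 1, seed=rep), table)
                e2 = laplace_evidence(fit_dmm(table, 2, seed=rep), table)
            wins += e2 >= e1
        assert wins >= 9

    def test_invariant_to_otu_permutation(self, overdispersed_toy):
        fit = fit_dmm(overdispersed_toy, 1, seed=0)
        e = laplace_evidence(fit, overdispersed_toy)
        perm = CountsTable(overdispersed_toy.sample_ids, ["b", "a"],
                           overdispersed_toy.counts[:, ::-1].copy())
        pfit = fit_dmm(perm, 1, seed=0)
        assert laplace_evidence(pfit, perm) == pytest.approx(e, rel=1e-4)


class TestSelectK:
    def test_kmax_one_trivial(self, two_group_counts):
        table, _ = two_group_counts
        sel = select_k(table, k_max=1, reps=3, seed=0)
        assert sel.chosen_k == 1

    def test_recovers_k2_on_separated_groups(self, two_group_counts):
        table, _ = two_group_counts
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = select_k(table, k_max=3, reps=5, seed=0)
        assert sel.chosen_k == 2
        assert sel.scores.shape == (5, 3)
        assert np.all(np.isfinite(sel.mean[:3]))


class TestAssignment:
    def test_posterior_rows_sum_to_one(self, two_group_counts):
        table, _ = two_group_counts
        fit = fit_dmm(table, 2, seed=1)
        asg = assign_cst(fit, table)
        assert np.allclose(asg.posterior.sum(axis=1), 1.0, atol=1e-10)

    def test_tie_goes_to_lowest_index(self):
        from cstdyn.dmm import DMMFit

        # symmetric two-component model; the sample [5, 5] is equidistant
        alpha = np.array([[20.0, 5.0], [5.0, 20.0]])
        fit = DMMFit(k=2, alpha=alpha, pi=np.array([0.5, 0.5]), loglik=0.0,
                     loglik_trace=np.zeros(1), n_iter=1, converged=True,
                     otu_ids=["a", "b"])
        table = CountsTable(["s", "t", "u"], ["a", "b"],
                            np.array([[5, 5], [9, 1], [1, 9]]))
        asg = assign_cst(fit, table)
        assert np.allclose(asg.posterior[0], [0.5, 0.5], atol=1e-12)
        # both components equally frequent -> canonical keeps fit order,
        # and the tied sample goes to component 1
        assert asg.map_label[0] == 1

    def test_sample_order_invariance(self, two_group_counts):
        table, _ = two_group_counts
        fit = fit_dmm(table, 2, seed=1)
        asg = assign_cst(fit, table)
        rev = table.select_samples(table.sample_ids[::-1])
        asg_rev = assign_cst(fit, rev)
        lookup = dict(zip(asg_rev.sample_ids, asg_rev.map_label))
        assert [lookup[s] for s in table.sample_ids] == list(asg.map_label)


class TestRelabel:
    @pytest.mark.parametrize("labels,expected", [
        ([2, 2, 2, 1], [1, 1, 1, 2]),
        ([1, 1, 2], [1, 1, 2]),          # already ordered: identity
        ([1, 2, 1, 2], [1, 2, 1, 2]),    # tie: original order preserved
    ])
    def test_frequency_relabeling(self, labels, expected):
        canonical, _ = relabel_by_frequency(labels)
        assert canonical.tolist() == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            relabel_by_frequency([])
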