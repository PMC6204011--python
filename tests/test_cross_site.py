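import warnings

import numpy as np
import pandas as pd
import pytest

from cstdyn.cross_site import (
    AssociationRecord,
    cooccurrence_chisq,
    cst_probability_correlation,
    fdr_and_rollup,
    fit_taxon_models,
    pair_visits,
    shared_otu_residual_corr,
    taxon_abundances,
)
from cstdyn.dmm import CSTAssignment
from cstdyn.types import CountsTable, VisitSample


def _visit(sample, subject, site, wol, ill=False):
    return VisitSample(sample, subject, site, wol=wol, pma=30.0 + wol,
                       illness_flag=ill)


class TestPairVisits:
    def test_pairs_by_subject_and_visit(self):
        samples = [_visit("g1", "P0", "gut", 3.0), _visit("n1", "P0", "nasal", 3.0),
                   _visit("g2", "P1", "gut", 3.0)]
        pairs = pair_visits(samples, "gut", "nasal")
        assert len(pairs) == 1
        assert (pairs[0].sample_a, pairs[0].sample_b) == ("g1", "n1")

    def test_toy_cohort_counts(self):
        # 3 subjects x 4 visits, one nasal sample missing -> 11 pairs
        samples = []
        for s in range(3):
            for w in range(4):
                samples.append(_visit(f"g{s}{w}", f"P{s}", "gut", float(w)))
                if not (s == 1 and w == 2):
                    samples.append(_visit(f"n{s}{w}", f"P{s}", "nasal", float(w)))
        assert len(pair_visits(samples, "gut", "nasal")) == 11

    def test_illness_flagged_excluded(self):
        samples = [_visit("g1", "P0", "gut", 3.0, ill=True),
                   _visit("n1", "P0", "nasal", 3.0)]
        assert pair_visits(samples, "gut", "nasal") == []


class TestCooccurrenceChisq:
    @staticmethod
    def _pairs(n):
        return [pair_visits([_visit(f"g{i}", f"P{i}", "gut", 0.0),
                             _visit(f"n{i}", f"P{i}", "nasal", 0.0)],
                            "gut", "nasal")[0] for i in range(n)]

    def test_diagonal_table_closed_form(self):
        pairs = self._pairs(100)
        la = np.repeat([1, 2], 50)
        chi2, p = cooccurrence_chisq(pairs, la, la)
        assert chi2 == pytest.approx(100.0)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        pairs = self._pairs(200)
        la, lb = rng.integers(1, 4, 200), rng.integers(1, 3, 200)
        chi2_ab, _ = cooccurrence_chisq(pairs, la, lb)
        chi2_ba, _ = cooccurrence_chisq(pairs, lb, la)
        assert chi2_ab == pytest.approx(chi2_ba)

    def test_degenerate_table_rejected(self):
        pairs = self._pairs(10)
        with pytest.raises(ValueError):
            cooccurrence_chisq(pairs, np.ones(10, int), np.ones(10, int))


class TestProbabilityCorrelation:
    @staticmethod
    def _assignment(post):
        n, k = post.shape
        return CSTAssignment([f"g{i}" for i in range(n)], post,
                             post.argmax(axis=1) + 1, np.arange(1, k + 1))

    def test_self_correlation_diagonal(self):
        rng = np.random.default_rng(0)
        post = rng.dirichlet([1, 1, 1], size=50)
        asg_a = self._assignment(post)
        asg_b = CSTAssignment([f"n{i}" for i in range(50)], post.copy(),
                              post.argmax(axis=1) + 1, np.arange(1, 4))
        pairs = TestCooccurrenceChisq._pairs(50)
        corr = cst_probability_correlation(pairs, asg_a, asg_b)
        assert np.allclose(np.diag(corr), 1.0)

    def test_zero_variance_column_missing(self):
        post = np.column_stack([np.full(20, 0.5), np.full(20, 0.5)])
        asg_a = self._assignment(post)
        rng = np.random.default_rng(1)
        post_b = rng.dirichlet([1, 1], size=20)
        asg_b = CSTAssignment([f"n{i}" for i in range(20)], post_b,
                              post_b.argmax(axis=1) + 1, np.arange(1, 3))
        pairs = TestCooccurrenceChisq._pairs(20)
        corr = cst_probability_correlation(pairs, asg_a, asg_b)
        assert np.isnan(corr).all()


def _null_design(seed, n=200, n_subj=25, shift=0.0):
    rng = np.random.default_rng(seed)
    subj = rng.integers(0, n_subj, n)
    wol = rng.uniform(0, 60, n)
    gab = rng.uniform(23, 42, n_subj)[subj]
    cov = pd.DataFrame({
        "delivery_mode": np.array(["c-section", "vaginal"])[
            rng.integers(0, 2, n_subj)][subj],
        "birth_season": np.array(["winter", "spring", "summer", "fall"])[
            rng.integers(0, 4, n_subj)][subj],
        "ga_birth": gab, "wol": wol})
    remote = {"nasal": rng.integers(1, 4, n), "throat": rng.integers(1, 4, n)}
    y = 0.3 + rng.normal(0, 0.1, n_subj)[subj] + rng.normal(0, 0.15, n)
    y = y + shift * (remote["nasal"] == 2)
    return y, remote, cov, [f"S{s}" for s in subj]


class TestTaxonModels:
    def test_sum_to_zero_coding(self):
        y, remote, cov, subj = _null_design(0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = fit_taxon_models(y, remote, cov, subj, transform=False,
                                   compute_delta=False, wol_df=6)
        for rsite in remote:
            # deviation estimates reconstruct to zero sum across levels
            signs = {"increase": 1, "decrease": -1}
            assert set(rec.wald_p[rsite]) == {1, 2, 3}
        # every direction is a valid label
        assert all(d in {"increase", "decrease"}
                   for site_d in rec.direction.values() for d in site_d.values())

    def test_no_cst_terms_gives_zero_delta(self):
        y, _, cov, subj = _null_design(1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = fit_taxon_models(y, {}, cov, subj, transform=False, wol_df=6)
        assert rec.delta_pseudo_r2 == 0.0

    def test_effect_detected_with_direction(self):
        y, remote, cov, subj = _null_design(2, shift=0.25)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = fit_taxon_models(y, remote, cov, subj, transform=False,
                                   wol_df=6)
        assert rec.wald_p["nasal"][2] < 0.05
        assert rec.direction["nasal"][2] == "increase"
        assert rec.delta_pseudo_r2 > 0

    def test_transformed_outcome_in_range(self):
        y, remote, cov, subj = _null_design(3)
        rel = np.clip(y, 0, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = fit_taxon_models(rel, remote, cov, subj, wol_df=6,
                                   compute_delta=False)
        assert np.isfinite(rec.f_p)


class TestTaxonRollup:
    @staticmethod
    def _record(taxon, p, site="gut"):
        return AssociationRecord(site=site, taxon=taxon, rank="x",
                                 wald_p={}, direction={}, f_stat=1.0, f_p=p)

    def test_bh_step_up_arithmetic(self):
        records = [self._record((f"t{i}",), p)
                   for i, p in enumerate([0.01, 0.02, 0.03, 0.04])]
        out = fdr_and_rollup(records, "gut")
        assert len(out) == 4
        assert all(r.q == pytest.approx(0.04) for r in out)

    def test_most_specific_taxon_reported(self):
        family = self._record(("Bacteria", "F1"), 0.001)
        genus = self._record(("Bacteria", "F1", "G1"), 0.002)
        other = self._record(("Bacteria", "F2"), 0.003)
        out = fdr_and_rollup([family, genus, other], "gut")
        taxa = {r.taxon for r in out}
        assert taxa == {("Bacteria", "F1", "G1"), ("Bacteria", "F2")}

    def test_no_significant_empty(self):
        records = [self._record(("a",), 0.9), self._record(("b",), 0.8)]
        assert fdr_and_rollup(records, "gut") == []

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(0)
        records = [self._record((f"t{i}",), p)
                   for i, p in enumerate(rng.random(30))]
        fdr_and_rollup(records, "gut")
        df = pd.DataFrame({"p": [r.f_p for r in records],
                           "q": [r.q for r in records]}).sort_values("p")
        assert df.q.is_monotonic_increasing


class TestTaxonAbundances:
    def test_lineage_rollup_sums(self):
        table = CountsTable(
            ["s0", "s1"], ["o1", "o2", "o3"],
            np.array([[10, 20, 70], [50, 25, 25]]),
            taxonomy={"o1": ("B", "F1", "G1"), "o2": ("B", "F1", "G2"),
                      "o3": ("B", "F2")})
        ab = taxon_abundances(table)
        assert np.allclose(ab[("B",)], 1.0)
        assert np.allclose(ab[("B", "F1")], [0.3, 0.75])
        assert np.allclose(ab[("B", "F1", "G2")], [0.2, 0.25])


class TestSharedOtuResiduals:
    @staticmethod
    def _tables(rho, seed, n=300, n_otus=8):
        rng = np.random.default_rng(seed)
        pma = np.tile(np.linspace(25, 80, n // 25), 25)
        subj = [f"P{i % 25}" for i in range(n)]
        shared = [f"shared{j}" for j in range(n_otus)]

        def counts(latent):
            base = rng.lognormal(3, 0.3, size=(n, n_otus))
            base *= np.exp(0.5 * np.sin(pma / 9))[:, None]   # time trend
            base[:, : n_otus] *= np.exp(latent)
            other = rng.lognormal(4, 0.2, size=(n, 2))
            mat = np.column_stack([base, other]).astype(int) + 1
            return mat

        z = rng.normal(size=(n, n_otus))
        za = rho * z + np.sqrt(1 - rho ** 2) * rng.normal(size=(n, n_otus))
        zb = rho * z + np.sqrt(1 - rho ** 2) * rng.normal(size=(n, n_otus))
        ta = CountsTable([f"a{i}" for i in range(n)], shared + ["xa", "ya"],
                         counts(za))
        tb = CountsTable([f"b{i}" for i in range(n)], shared + ["xb", "yb"],
                         counts(zb))
        pairs = [pair_visits([_visit(f"a{i}", subj[i], "gut", float(i)),
                              _visit(f"b{i}", subj[i], "nasal", float(i))],
                             "gut", "nasal")[0] for i in range(n)]
        return pairs, ta, tb, pma, subj

    def test_independent_residuals_near_zero(self):
        pairs, ta, tb, pma, subj = self._tables(rho=0.0, seed=0)
        out = shared_otu_residual_corr(pairs, ta, tb, pma, subj)
        assert abs(out.correlation.mean()) < 0.05

    def test_shared_factor_detected(self):
        pairs, ta, tb, pma, subj = self._tables(rho=0.85, seed=1)
        out = shared_otu_residual_corr(pairs, ta, tb, pma, subj)
        assert out.correlation.mean() > 0.3

    def test_unshared_otus_excluded(self):
        pairs, ta, tb, pma, subj = self._tables(rho=0.0, seed=2)
        out = shared_otu_residual_corr(pairs, ta, tb, pma, subj)
        assert set(out.otu) <= {f"shared{j}" for j in range(8)}
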