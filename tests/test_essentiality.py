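"""Insertion index, sectioned mixture fit and likelihood-ratio classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq, minimize

import tradistat.essentiality as ess
from tradistat import (
    GeneFeature,
    InsertionSite,
    MixtureFit,
    classify,
    fit_mixture,
    insertion_index_table,
    library_summary,
    log_likelihood_score,
)


def exp_pdf(x, rate):
    """Textbook exponential density, independent of the implementation path."""
    return rate * math.exp(-rate * x)


def gamma_pdf(x, shape, scale):
    """Textbook gamma density via lgamma; independent of scipy.stats."""
    return math.exp(
        (shape - 1) * math.log(x) - x / scale - math.lgamma(shape) - shape * math.log(scale)
    )


FIT = MixtureFit(exp_rate=500.0, gamma_shape=3.0, gamma_scale=0.03)


class TestInsertionIndex:
    def test_index_arithmetic(self):
        gene = GeneFeature("chr1", 1001, 2000, "g1")
        sites = [InsertionSite("chr1", p) for p in (1100, 1500, 1900)]
        (rec,) = insertion_index_table([gene], sites)
        assert rec.unique_insertions == 3
        assert rec.insertion_index == 3 / 1000 == 0.003

    def test_gene_without_sites_scores_zero(self):
        gene = GeneFeature("chr1", 10, 100, "g1")
        (rec,) = insertion_index_table([gene], [InsertionSite("chr2", 50)])
        assert rec.unique_insertions == 0 and rec.insertion_index == 0.0

    def test_counts_match_interval_membership_oracle(self, rng):
        genes = []
        pos = 1
        for i in range(60):
            length = int(rng.integers(50, 800))
            start = pos + int(rng.integers(0, 100))
            genes.append(GeneFeature("chr1", start, start + length - 1, f"g{i}"))
            pos = start + int(rng.integers(0, length))  # allow overlaps
        genes.sort(key=lambda g: g.start)
        positions = np.unique(rng.integers(1, pos + 1000, size=3000))
        sites = [InsertionSite("chr1", int(p)) for p in positions]
        table = {r.feature_id: r.unique_insertions
                 for r in insertion_index_table(genes, sites)}
        for g in genes:  # O(genes x sites) scan
            assert table[g.feature_id] == sum(g.start <= p <= g.end for p in positions)

    def test_overlapping_genes_both_count_shared_sites(self):
        genes = [GeneFeature("chr1", 1, 100, "a"), GeneFeature("chr1", 50, 150, "b")]
        sites = [InsertionSite("chr1", 75)]
        recs = {r.feature_id: r.unique_insertions for r in insertion_index_table(genes, sites)}
        assert recs == {"a": 1, "b": 1}


class TestLibrarySummary:
    def test_bp_per_insertion_headline(self):
        sites = [InsertionSite("chr1", int(p)) for p in np.linspace(1, 1100, 100)]
        summary = library_summary([], sites, {"chr1": 1100})
        assert summary.loc["chr1", "bp_per_insertion"] == 11

    def test_genic_intergenic_conservation_and_oracle(self, rng):
        genes = [GeneFeature("chr1", int(s), int(s) + 99, f"g{i}")
                 for i, s in enumerate(range(1, 5000, 250))]
        positions = np.unique(rng.integers(1, 6000, size=800))
        sites = [InsertionSite("chr1", int(p)) for p in positions]
        summary = library_summary(genes, sites, {"chr1": 6000})
        row = summary.loc["chr1"]
        assert row["genic_sites"] + row["intergenic_sites"] == row["unique_sites"] == len(positions)
        oracle_genic = sum(any(g.start <= p <= g.end for g in genes) for p in positions)
        assert row["genic_sites"] == oracle_genic


class TestFitMixture:
    def test_exponential_closed_form(self):
        indices = [0.001, 0.003] + list(np.linspace(0.03, 0.2, 30))
        fit = fit_mixture(indices, min_section=2)
        assert fit.exp_rate == 2 / 0.004 == 500.0
        assert fit.n_exp_fit == 2

    def test_zeros_included_in_exponential_mle(self):
        indices = [0.0, 0.0, 0.002] + list(np.linspace(0.03, 0.2, 30))
        fit = fit_mixture(indices, min_section=2)
        assert fit.exp_rate == 3 / 0.002

    def test_all_zero_section_gives_point_mass_limit(self):
        indices = [0.0] * 20 + list(np.linspace(0.03, 0.2, 30))
        fit = fit_mixture(indices)
        assert math.isinf(fit.exp_rate)

    def test_gamma_recovery_matches_independent_mle_oracle(self, rng):
        shape0, scale0 = 3.0, 0.03
        draws = rng.gamma(shape0, scale0, size=40_000)
        sec2 = draws[(draws >= 0.022) & (draws <= 0.25)][:10_000]
        indices = np.concatenate([np.full(50, 0.001), sec2])
        fit = fit_mixture(indices)

        def negloglik(params):  # hand-written, optimized independently of gamma.fit
            k, theta = params
            if k <= 0 or theta <= 0:
                return np.inf
            return -np.sum((k - 1) * np.log(sec2) - sec2 / theta
                           - math.lgamma(k) - k * math.log(theta))

        oracle = minimize(negloglik, x0=[1.0, float(sec2.mean())], method="Nelder-Mead").x
        assert fit.gamma_shape == pytest.approx(oracle[0], rel=0.10)
        assert fit.gamma_scale == pytest.approx(oracle[1], rel=0.10)

    def test_empty_section_instructs_cutoff_adjustment(self):
        with pytest.raises(ValueError, match="cutoff"):
            fit_mixture(np.linspace(0.05, 0.2, 50))  # nothing below 0.013

    def test_parameter_recovery_on_leaky_library(self, leaky_library):
        cfg, annotation, _, sites, truth = leaky_library
        table = insertion_index_table(annotation, sites)
        fit = fit_mixture(table)
        non = [r.insertion_index for r in table if truth[r.feature_id] == "non_essential"]
        assert fit.gamma_mean == pytest.approx(np.mean(non), rel=0.10)
        # exponential rate reflects the leak density: mean leak index ~ 1/rate
        assert 1 / fit.exp_rate == pytest.approx(cfg.essential_leak_density, rel=0.5)


class TestScore:
    def test_zero_score_at_density_crossing(self):
        xstar = brentq(lambda x: exp_pdf(x, FIT.exp_rate) - gamma_pdf(x, 3.0, 0.03), 1e-6, 0.2)
        assert log_likelihood_score(xstar, FIT) == pytest.approx(0.0, abs=1e-9)

    def test_threshold_point_scores_log2_12(self):
        x12 = brentq(
            lambda x: exp_pdf(x, FIT.exp_rate) - 12 * gamma_pdf(x, 3.0, 0.03), 1e-6, 0.2
        )
        assert log_likelihood_score(x12, FIT) == pytest.approx(math.log2(12), abs=1e-9)

    def test_matches_textbook_pdf_oracle(self, rng):
        for _ in range(200):
            fit = MixtureFit(
                exp_rate=float(rng.uniform(50, 2000)),
                gamma_shape=float(rng.uniform(1.2, 20)),
                gamma_scale=float(rng.uniform(0.005, 0.1)),
            )
            x = float(rng.uniform(1e-4, 0.5))
            # textbook log-densities, written out to avoid underflow
            log_exp = math.log(fit.exp_rate) - fit.exp_rate * x
            log_gamma = ((fit.gamma_shape - 1) * math.log(x) - x / fit.gamma_scale
                         - math.lgamma(fit.gamma_shape)
                         - fit.gamma_shape * math.log(fit.gamma_scale))
            expected = (log_exp - log_gamma) / math.log(2)
            assert log_likelihood_score(x, fit) == pytest.approx(expected, rel=1e-9)

    def test_zero_index_scores_positive_infinity_sentinel(self):
        assert log_likelihood_score(0.0, FIT) == math.inf

    def test_monotone_nonincreasing_where_ratio_monotone(self):
        # with exp_rate > 1/scale the log-ratio is strictly decreasing
        xs = np.linspace(1e-5, 0.5, 400)
        scores = [log_likelihood_score(float(x), FIT) for x in xs]
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert log_likelihood_score(0.0, FIT) >= scores[0]


def make_records(indices):
    return [
        ess.InsertionIndexRecord(f"g{i}", "chr1", 1000, round(x * 1000), x)
        for i, x in enumerate(indices)
    ]


class TestClassify:
    def test_label_signs(self):
        xstar = brentq(lambda x: exp_pdf(x, FIT.exp_rate) - gamma_pdf(x, 3.0, 0.03), 1e-6, 0.2)
        records = make_records([0.0, 0.4, xstar])
        labels = [c.label for c in classify(records, FIT)]
        assert labels == ["essential", "non_essential", "unclear"]

    def test_boundary_score_exactly_log2_12_is_unclear(self, monkeypatch):
        monkeypatch.setattr(ess, "log_likelihood_score", lambda x, fit: math.log2(12))
        (call,) = ess.classify(make_records([0.01]), FIT, k_threshold=12)
        assert call.label == "unclear"
        monkeypatch.setattr(ess, "log_likelihood_score", lambda x, fit: -math.log2(12))
        (call,) = ess.classify(make_records([0.01]), FIT, k_threshold=12)
        assert call.label == "unclear"

    @given(indices=st.lists(st.floats(min_value=0, max_value=1.0, allow_nan=False),
                            max_size=100))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_partition_always_sums_to_gene_count(self, indices):
        calls = classify(make_records(indices), FIT)
        counts = {}
        for c in calls:
            counts[c.label] = counts.get(c.label, 0) + 1
        assert sum(counts.values()) == len(indices)
        assert set(counts) <= {"essential", "non_essential", "unclear"}

    def test_scale_consistency(self, rng):
        indices = np.abs(rng.normal(0.05, 0.05, size=300))
        c = 3.7
        scaled_fit = MixtureFit(
            exp_rate=FIT.exp_rate / c,
            gamma_shape=FIT.gamma_shape,
            gamma_scale=FIT.gamma_scale * c,
            cutoff_low=FIT.cutoff_low * c,
            cutoff_mid=FIT.cutoff_mid * c,
            cutoff_high=FIT.cutoff_high * c,
        )
        base = [x.label for x in classify(make_records(indices), FIT)]
        scaled = [x.label for x in classify(make_records(indices * c), scaled_fit)]
        assert base == scaled

    def test_recovery_on_default_library(self, default_library):
        _, annotation, _, sites, truth = default_library
        table = insertion_index_table(annotation, sites)
        calls = classify(table, fit_mixture(table))
        ok = sum(
            (c.label == truth[c.feature_id])
            or (truth[c.feature_id] == "domain_essential")  # rescued later by the window scan
            for c in calls
        )
        assert ok / len(calls) >= 0.99

    def test_cutoff_perturbation_changes_few_labels(self, default_library):
        _, annotation, _, sites, _ = default_library
        table = insertion_index_table(annotation, sites)
        base = [c.label for c in classify(table, fit_mixture(table))]
        for factor in (0.8, 1.2):
            cutoffs = tuple(c * factor for c in ess.DEFAULT_CUTOFFS)
            labels = [c.label for c in classify(table, fit_mixture(table, cutoffs=cutoffs))]
            changed = sum(a != b for a, b in zip(base, labels))
            assert changed / len(base) < 0.02
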