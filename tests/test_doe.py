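"""Factorial design generation, response computation, effect estimation."""

import itertools
import math

import numpy as np
import pytest

from flowrig import (
    DesignError,
    Factor,
    compute_responses,
    estimate_effects,
    full_factorial,
    rank_factors,
    significant_terms,
)
from flowrig.doe import _terms

FACTORS3 = [Factor("T", 40.0, 100.0), Factor("H", "20bar", "full"),
            Factor("Q", 0.1, 0.2)]


def synth_responses(design, coeffs, intercept=10.0, noise=0.0, seed=None):
    """Attach y = intercept + sum(coeffs[term] * contrast) (+ noise) to a design."""
    rng = np.random.default_rng(seed)
    names = [f.name for f in design.factors]
    for run in design.runs:
        y = intercept
        for label, idx in _terms(names):
            c = coeffs.get(label, 0.0)
            y += c * math.prod(run.coded[i] for i in idx)
        if noise:
            y += float(rng.normal(0.0, noise))
        design.attach_response(run.run_id, {"y": y})
    return design


class TestFullFactorial:
    def test_three_factors_duplicated_gives_sixteen_runs(self):
        design = full_factorial(FACTORS3, replicates=2, seed=0)
        assert design.n_runs == 16
        counts = {}
        for run in design.runs:
            counts[run.coded] = counts.get(run.coded, 0) + 1
        assert len(counts) == 8 and set(counts.values()) == {2}

    def test_minimal_design(self):
        assert full_factorial([Factor("A", 0, 1)], replicates=1).n_runs == 2

    def test_sixteen_runs_split_over_nine_port_valve(self):
        design = full_factorial(FACTORS3, replicates=2, seed=0, ports=9)
        assert design.n_batches == 2
        sizes = {}
        for run in design.runs:
            sizes[run.batch] = sizes.get(run.batch, 0) + 1
        assert sizes == {0: 9, 1: 7}
        assert all(1 <= run.port <= 9 for run in design.runs)

    def test_execution_order_is_seeded_permutation(self):
        a = full_factorial(FACTORS3, replicates=2, seed=5)
        b = full_factorial(FACTORS3, replicates=2, seed=5)
        c = full_factorial(FACTORS3, replicates=2, seed=6)
        assert [r.order for r in a.runs] == [r.order for r in b.runs]
        assert [r.order for r in a.runs] != [r.order for r in c.runs]
        assert sorted(r.order for r in a.runs) == list(range(16))

    def test_physical_settings_follow_coded_levels(self):
        design = full_factorial(FACTORS3, replicates=1, seed=0)
        for run in design.runs:
            assert run.settings["H"] == ("full" if run.coded[1] > 0 else "20bar")

    def test_degenerate_factor_rejected(self):
        with pytest.raises(DesignError):
            Factor("T", 100.0, 100.0)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_contrast_columns_mutually_orthogonal(self, k):
        factors = [Factor(chr(65 + i), 0, 1) for i in range(k)]
        design = full_factorial(factors, replicates=1, seed=0)
        X = np.array([r.coded for r in design.runs], dtype=float)
        names = [f.name for f in factors]
        cols = [X[:, idx].prod(axis=1) for _, idx in _terms(names)]
        for a, b in itertools.combinations(range(len(cols)), 2):
            assert float(cols[a] @ cols[b]) == 0.0


class TestResponses:
    def test_pure_product(self):
        r = compute_responses(1.0, 0.0, 0.0, 0.0)
        assert (r.conversion, r.yield_1, r.impurity_4, r.impurity_x) == (1, 1, 0, 0)

    def test_no_reaction(self):
        r = compute_responses(0.0, 1.0, 0.0, 0.0)
        assert r.conversion == 0.0 and r.yield_1 == 0.0

    def test_mixed_sample_arithmetic(self):
        r = compute_responses(2.0, 1.0, 1.0, 0.0)
        assert r.conversion == pytest.approx(0.75)
        assert r.yield_1 == pytest.approx(0.5)
        assert r.impurity_4 == pytest.approx(1.0 / 3.0)

    def test_all_zero_row_rejected(self):
        with pytest.raises(DesignError):
            compute_responses(0.0, 0.0, 0.0, 0.0)

    def test_undefined_impurity_reference_rejected(self):
        with pytest.raises(DesignError):
            compute_responses(0.0, 0.0, 1.0, 0.0)


class TestEffects:
    def test_pure_main_effect_is_twice_the_coefficient(self):
        design = full_factorial(FACTORS3, replicates=2, seed=1)
        synth_responses(design, {"H": 3.0})
        effects = {e.term: e.estimate for e in estimate_effects(design, "y")}
        assert effects["H"] == pytest.approx(6.0)
        for term, est in effects.items():
            if term != "H":
                assert est == pytest.approx(0.0, abs=1e-12)

    def test_constant_responses_give_zero_effects(self):
        design = full_factorial(FACTORS3, replicates=2, seed=1)
        synth_responses(design, {})
        assert all(e.estimate == pytest.approx(0.0)
                   for e in estimate_effects(design, "y"))

    def test_matches_doubled_least_squares_coefficients(self):
        """Oracle: effects equal 2x the coefficients of the orthogonal fit."""
        design = full_factorial(FACTORS3, replicates=2, seed=2)
        synth_responses(design, {"T": 1.5, "H": -2.0, "T:Q": 0.7}, noise=0.3, seed=9)
        y = np.array([design.responses[r.run_id]["y"] for r in design.runs])
        X = np.array([r.coded for r in design.runs], dtype=float)
        names = [f.name for f in design.factors]
        cols = [np.ones(len(y))] + [X[:, idx].prod(axis=1) for _, idx in _terms(names)]
        beta, *_ = np.linalg.lstsq(np.column_stack(cols), y, rcond=None)
        effects = estimate_effects(design, "y")
        for e, b in zip(effects, beta[1:]):
            assert e.estimate == pytest.approx(2.0 * b)

    def test_run_order_randomisation_does_not_change_estimates(self):
        est = []
        for seed in (3, 4):
            design = full_factorial(FACTORS3, replicates=2, seed=seed)
            synth_responses(design, {"T": 1.0, "H": 2.0, "Q": -0.5})
            est.append({e.term: e.estimate for e in estimate_effects(design, "y")})
        assert est[0] == pytest.approx(est[1])

    def test_missing_response_errors_with_run_list(self):
        design = full_factorial(FACTORS3, replicates=2, seed=0)
        with pytest.raises(DesignError):
            estimate_effects(design, "y")

    def test_noisy_estimates_fall_within_three_se(self):
        """Across 200 seeded repetitions, ~all estimates lie within 3 SE."""
        coeffs = {"T": 1.0, "H": 2.0, "Q": -0.5}
        sigma = 0.4
        total = within = 0
        for rep in range(200):
            design = full_factorial(FACTORS3, replicates=2, seed=rep)
            synth_responses(design, coeffs, noise=sigma, seed=rep)
            for e in estimate_effects(design, "y"):
                truth = 2.0 * coeffs.get(e.term, 0.0)
                total += 1
                if abs(e.estimate - truth) <= 3.0 * e.std_error:
                    within += 1
        assert within / total >= 0.95

    def test_significance_flags_strong_terms_only(self):
        design = full_factorial(FACTORS3, replicates=2, seed=0)
        synth_responses(design, {"H": 2.0}, noise=0.1, seed=0)
        sig = significant_terms(estimate_effects(design, "y"))
        assert "H" in sig


class TestRanking:
    def _estimates(self, values):
        design = full_factorial(FACTORS3, replicates=2, seed=0)
        synth_responses(design, values)
        return estimate_effects(design, "y")

    def test_dominant_term_first_then_alphabetical_ties(self):
        order = rank_factors(self._estimates({"H": 3.0, "T": 0.5, "Q": -0.5}))
        assert order[0] == "H"
        assert order.index("Q") < order.index("T")  # |t| tie, alphabetical

    def test_all_zero_effects_rank_alphabetically(self):
        order = rank_factors(self._estimates({}))
        assert order == sorted(order)

    def test_single_term_design(self):
        design = full_factorial([Factor("A", 0, 1)], replicates=2, seed=0)
        synth_responses(design, {"A": 1.0})
        assert rank_factors(estimate_effects(design, "y")) == ["A"]
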