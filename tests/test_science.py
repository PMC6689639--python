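"""Science stage: investigation outcomes and the communication filters."""

import numpy as np
import pytest
from scipy import stats

from labevo import Lab, LabPopulation, Params
from labevo.oracle import outcome_table
from labevo.science import (
    draw_hypothesis,
    investigate,
    publication_probability,
    run_science_step,
)


def make_pop(n=100, alpha=0.05, funds=10):
    return LabPopulation.from_labs(
        [Lab(id=i, alpha=alpha, funds=funds, age=0) for i in range(n)]
    )


class TestPublicationProbability:
    @pytest.mark.parametrize(
        "truth, positive, p, r, expected",
        [
            (True, True, 0.3, 0.5, 1.0),    # positive results always publishable
            (False, True, 0.0, 0.4, 0.6),   # false positive faces review only
            (False, False, 0.7, 0.9, 0.7),  # correct negative never blocked
            (True, False, 0.4, 0.25, 0.3),  # false negative: both filters, 0.4*0.75
            (False, False, 0.0, 0.0, 0.0),  # negative unpublishable at p=0
            (True, False, 1.0, 1.0, 0.0),   # perfect review blocks the error
        ],
    )
    def test_closed_form(self, truth, positive, p, r, expected):
        assert publication_probability(truth, positive, p, r) == pytest.approx(
            expected
        )

    def test_monte_carlo_cell_frequencies(self, rng):
        """Chi-square fit of published/blocked counts per outcome cell."""
        n = 100_000
        alpha, b, W, p, r = 0.3, 0.2, 0.8, 0.4, 0.5
        pop = make_pop(n=n, alpha=alpha, funds=1)
        params = Params(n=n, b=b, W=W, p=p, r=r, d=1)
        _, events = run_science_step(pop, params, rng, record_investigations=True)
        table = outcome_table(alpha, b, W, p, r).cells
        observed, expected = [], []
        for (t, pos), cell in table.items():
            pub = sum(
                1 for e in events
                if e.hypothesis_true == t and e.result_positive == pos
                and e.published
            )
            blocked = sum(
                1 for e in events
                if e.hypothesis_true == t and e.result_positive == pos
                and not e.published
            )
            observed += [pub, blocked]
            expected += [
                n * cell.occurrence * cell.publication,
                n * cell.occurrence * (1 - cell.publication),
            ]
        obs = np.array(observed, float)
        exp = np.array(expected, float)
        keep = exp > 0
        chi = stats.chisquare(obs[keep], exp[keep] * obs[keep].sum() / exp[keep].sum())
        assert chi.pvalue > 1e-4


class TestDraws:
    def test_degenerate_probabilities(self, rng):
        assert all(not draw_hypothesis(0.0, rng) for _ in range(100))
        assert all(draw_hypothesis(1.0, rng) for _ in range(100))
        assert all(not investigate(False, 0.0, 0.8, rng) for _ in range(100))
        assert all(investigate(False, 1.0, 0.8, rng) for _ in range(100))

    def test_base_rate_frequency(self, rng):
        n = 100_000
        b = 0.1
        hits = sum(draw_hypothesis(b, rng) for _ in range(n))
        se = np.sqrt(b * (1 - b) / n)
        assert abs(hits / n - b) < 3 * se

    def test_power_frequency(self, rng):
        n = 100_000
        W = 0.8
        hits = sum(investigate(True, 0.05, W, rng) for _ in range(n))
        se = np.sqrt(W * (1 - W) / n)
        assert abs(hits / n - W) < 3 * se


class TestScienceStep:
    def test_unfunded_labs_untouched(self, rng, default_params):
        pop = make_pop(funds=0)
        before = pop.copy()
        stats_, events = run_science_step(
            pop, default_params, rng, record_investigations=True
        )
        assert stats_.investigations == 0 and events == []
        assert np.array_equal(pop.funds, before.funds)
        assert np.array_equal(pop.publications, before.publications)

    def test_everything_published_when_unbiased(self, rng):
        pop = make_pop(n=100, funds=5)
        params = Params(p=1.0, r=0.0)
        stats_, _ = run_science_step(pop, params, rng)
        assert stats_.investigations == 100
        assert stats_.publications == 100
        assert np.all(pop.funds == 4)

    def test_fund_conservation(self, rng):
        pop = make_pop(n=50, funds=3)
        pop.funds[::2] = 0
        params = Params(n=50, d=10)
        total_before = pop.funds.sum()
        stats_, _ = run_science_step(pop, params, rng)
        assert pop.funds.sum() == total_before - stats_.investigations
        assert stats_.investigations == 25

    def test_perfect_review_blocks_every_error(self, rng):
        params = Params(r=1.0, p=0.5, alpha0=0.5)
        pop = make_pop(n=200, alpha=0.5, funds=1)
        for _ in range(20):
            pop.funds[:] = 1
            _, events = run_science_step(
                pop, params, rng, record_investigations=True
            )
            assert not any(e.published and e.erroneous for e in events)

    def test_no_negative_results_published_at_p_zero(self, rng):
        params = Params(p=0.0, r=0.0, alpha0=0.5)
        pop = make_pop(n=200, alpha=0.5, funds=1)
        _, events = run_science_step(pop, params, rng, record_investigations=True)
        assert not any(e.published and not e.result_positive for e in events)

    def test_stats_consistent_with_event_list(self, rng):
        pop = make_pop(n=100, alpha=0.3, funds=2)
        params = Params(p=0.4, r=0.3)
        stats_, events = run_science_step(
            pop, params, rng, record_investigations=True
        )
        assert stats_.investigations == len(events) == 100
        assert stats_.publications == sum(e.published for e in events)
        assert stats_.erroneous_publications == sum(
            e.published and e.erroneous for e in events
        )
        assert stats_.true_hypotheses == sum(e.hypothesis_true for e in events)
        for e in events:
            assert e.erroneous == (e.hypothesis_true != e.result_positive)
        assert (
            stats_.erroneous_publications
            <= stats_.publications
            <= stats_.investigations
            <= len(pop)
        )
        # published tallies landed on the right labs
        assert pop.publications.sum() == stats_.publications
        assert pop.erroneous_publications.sum() == stats_.erroneous_publications
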