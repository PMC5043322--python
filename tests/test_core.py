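"""Closed-form functions and Science-stage mechanics."""

import numpy as np
import pytest

from labsim import (
    Lab,
    Literature,
    PublicationRecord,
    SimulationParameters,
    apply_payoffs,
    communicate,
    expected_fdr_novel,
    false_positive_rate,
    prob_positive_novel,
    productivity_rate,
    run_experiment,
    select_hypothesis,
)


class TestClosedForms:
    @pytest.mark.parametrize(
        "effort,eta,expected",
        [(75, 0.2, 0.625), (1, 0.2, 1.0), (100, 0.2, 0.6), (15, 0.2, 0.765)],
    )
    def test_productivity_anchors(self, effort, eta, expected):
        assert productivity_rate(effort, eta) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize(
        "power,effort,expected",
        [(0.8, 75, 0.05), (0.8, 15, 0.2), (1.0, 50, 1.0), (0.0, 50, 0.0)],
    )
    def test_false_positive_anchors(self, power, effort, expected):
        assert false_positive_rate(power, effort) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "b,expected", [(1.0, 0.8), (0.0, 0.05), (0.1, 0.125)]
    )
    def test_prob_positive_novel(self, b, expected):
        assert prob_positive_novel(b, 0.8, 75) == pytest.approx(expected)

    @pytest.mark.parametrize("b,expected", [(1.0, 0.0), (0.0, 1.0), (0.1, 0.36)])
    def test_expected_fdr(self, b, expected):
        assert expected_fdr_novel(b, 0.8, 75) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "func,args",
        [
            (productivity_rate, (0.5, 0.2)),       # effort below 1
            (productivity_rate, (100.0, 0.6)),     # h would go negative
            (false_positive_rate, (1.2, 50.0)),
            (false_positive_rate, (0.8, 0.5)),
            (prob_positive_novel, (1.5, 0.8, 75.0)),
        ],
    )
    def test_domain_errors(self, func, args):
        with pytest.raises(ValueError):
            func(*args)

    def test_fdr_undefined_at_zero_positive_probability(self):
        with pytest.raises(ValueError):
            expected_fdr_novel(0.0, 0.0, 50.0)

    def test_alpha_monotone_in_power_and_effort(self):
        powers = np.arange(0.1, 0.95, 0.1)
        efforts = np.array([1.0, 15.0, 75.0, 100.0])
        for e in efforts:
            a = false_positive_rate(powers, e)
            assert np.all(np.diff(a) > 0), f"alpha not increasing in W at e={e}"
        for w in powers:
            a = false_positive_rate(w, efforts)
            assert np.all(np.diff(a) < 0), f"alpha not decreasing in e at W={w}"

    def test_prob_positive_strictly_increasing_in_power(self):
        powers = np.arange(0.1, 0.95, 0.1)
        for e in (1.0, 15.0, 75.0, 100.0):
            p = prob_positive_novel(0.1, powers, e)
            assert np.all(np.diff(p) > 0)

    def test_productivity_decreasing_in_effort(self):
        efforts = np.linspace(1, 100, 25)
        h = productivity_rate(efforts, 0.2)
        assert h[0] == pytest.approx(1.0)
        assert h[-1] == pytest.approx(0.6)
        assert np.all(np.diff(h) < 0)


class TestLiterature:
    def test_replicable_index_tracks_positive_records(self, rng):
        lit = Literature(capacity=100)
        h1 = lit.new_hypothesis(True, 0, 0)
        h2 = lit.new_hypothesis(False, 1, 0)
        lit.add_record(PublicationRecord(h1.hyp_id, 0, 0, "positive", "novel", True))
        lit.add_record(
            PublicationRecord(h2.hyp_id, 1, 1, "negative", "replication", False)
        )
        assert lit.replicable_index == {h1.hyp_id}
        assert lit.sample_replicable(rng).hyp_id == h1.hyp_id

    def test_truncation_drops_earliest_and_updates_index(self):
        lit = Literature(capacity=5)
        hyps = [lit.new_hypothesis(True, 0, t) for t in range(8)]
        for t, h in enumerate(hyps):
            lit.add_record(PublicationRecord(h.hyp_id, 0, t, "positive", "novel", True))
        lit.truncate()
        assert len(lit) == 5
        kept = [rec.hyp_id for rec in lit.iter_records()]
        assert kept == [h.hyp_id for h in hyps[3:]]
        # hypotheses whose only positive record was truncated are gone
        assert lit.replicable_index == set(kept)

    def test_truncation_noop_under_capacity(self):
        lit = Literature(capacity=5)
        h = lit.new_hypothesis(True, 0, 0)
        lit.add_record(PublicationRecord(h.hyp_id, 0, 0, "positive", "novel", True))
        assert lit.truncate() == 0
        assert len(lit) == 1

    def test_negative_novel_record_rejected(self):
        with pytest.raises(ValueError):
            PublicationRecord(0, 0, 0, "negative", "novel", True)


class TestHypothesisSelection:
    def test_zero_replication_rate_always_novel(self, params, small_literature, rng):
        lab = Lab(0, 0.8, 75.0, replication_rate=0.0)
        kinds = {
            select_hypothesis(lab, small_literature, params, rng)[1]
            for _ in range(50)
        }
        assert kinds == {"novel"}

    def test_full_replication_rate_always_replicates(self, params, small_literature, rng):
        lab = Lab(0, 0.8, 75.0, replication_rate=1.0)
        kinds = {
            select_hypothesis(lab, small_literature, params, rng)[1]
            for _ in range(50)
        }
        assert kinds == {"replication"}

    def test_empty_literature_falls_back_to_novel(self, params, rng):
        lab = Lab(0, 0.8, 75.0, replication_rate=1.0)
        hyp, kind = select_hypothesis(lab, Literature(), params, rng)
        assert kind == "novel"

    def test_replication_fraction_matches_rate(self, params, small_literature, rng):
        lab = Lab(0, 0.8, 75.0, replication_rate=0.2)
        n = 100_000
        n_rep = sum(
            select_hypothesis(lab, small_literature, params, rng)[1] == "replication"
            for _ in range(n)
        )
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(n_rep / n - 0.2) < 3 * se

    def test_novel_hypotheses_are_fresh(self, params, rng):
        lab = Lab(0, 0.8, 75.0, replication_rate=0.0)
        lit = Literature()
        ids = [select_hypothesis(lab, lit, params, rng)[0].hyp_id for _ in range(100)]
        assert len(set(ids)) == 100


class TestExperiment:
    def test_certain_outcomes(self, rng):
        lit = Literature()
        true_hyp = lit.new_hypothesis(True, 0, 0)
        assert run_experiment(Lab(0, 1.0, 75.0, 0.0), true_hyp, rng) == "positive"
        assert run_experiment(Lab(0, 0.0, 75.0, 0.0), true_hyp, rng) == "negative"

    def test_false_positive_frequency_matches_alpha(self, rng):
        lab = Lab(0, 0.8, 75.0, 0.0)
        lit = Literature()
        false_hyp = lit.new_hypothesis(False, 1, 0)
        n = 100_000
        k = sum(run_experiment(lab, false_hyp, rng) == "positive" for _ in range(n))
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(k / n - 0.05) < 3 * se


class TestCommunication:
    def test_novel_asymmetry(self, params, rng):
        assert communicate("positive", "novel", params, rng) is True
        assert communicate("negative", "novel", params, rng) is False

    def test_replication_channels(self, rng):
        p = SimulationParameters(c_r_pos=1.0, c_r_neg=1.0)
        assert communicate("negative", "replication", p, rng) is True
        p0 = SimulationParameters(c_r_pos=0.0, c_r_neg=0.0)
        assert communicate("positive", "replication", p0, rng) is False


class TestPayoffs:
    def _population(self):
        return [Lab(i, 0.8, 75.0, 0.0) for i in range(3)]

    def test_novel_publication_pays_author_only(self, params):
        pop = self._population()
        lit = Literature()
        h = lit.new_hypothesis(True, 0, 0)
        rec = PublicationRecord(h.hyp_id, 0, 0, "positive", "novel", True)
        deltas = apply_payoffs(rec, pop, lit, params)
        assert deltas == {0: 1.0}
        assert pop[0].payoff == 1.0 and pop[1].payoff == 0.0

    def test_failed_replication_penalizes_living_originator(self, params):
        pop = self._population()
        lit = Literature()
        h = lit.new_hypothesis(False, originator=1, step=0)
        rec = PublicationRecord(h.hyp_id, 0, 5, "negative", "replication", False)
        deltas = apply_payoffs(rec, pop, lit, params)
        assert deltas == {0: 0.5, 1: -100.0}

    def test_replication_of_dead_originator_pays_author_only(self, params):
        pop = self._population()
        lit = Literature()
        h = lit.new_hypothesis(True, originator=99, step=0)  # lab 99 not in population
        rec = PublicationRecord(h.hyp_id, 0, 5, "positive", "replication", True)
        assert apply_payoffs(rec, pop, lit, params) == {0: 0.5}

    def test_self_replication_earns_no_originator_bonus(self, params):
        pop = self._population()
        lit = Literature()
        h = lit.new_hypothesis(True, originator=0, step=0)
        rec = PublicationRecord(h.hyp_id, 0, 5, "positive", "replication", True)
        assert apply_payoffs(rec, pop, lit, params) == {0: 0.5}

    def test_payoff_conservation_over_a_run(self, params, rng):
        """Sum of lab pay-offs equals the sum of all logged deltas."""
        from labsim import initialize, science_stage

        p = params.replace(r0=0.3, n_steps=0)
        pop, lit = initialize(p)
        total = 0.0
        for t in range(40):
            stage = science_stage(pop, lit, p, rng, t)
            total += sum(sum(d.values()) for d in stage.payoff_deltas)
        assert sum(lab.payoff for lab in pop) == pytest.approx(total)
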