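import numpy as np
import pytest

from capsidyn.analysis import (AnalysisParams, EmptyContactSubsetError, QTrace,
                               TranslocationEvent, count_events_by_position,
                               detect_translocation, ensemble_statistics,
                               q_fraction, q_probability_distribution, q_trace,
                               tail_contact_subset)
from capsidyn.contacts import ContactMap
from capsidyn.trajectory import Trajectory


def _subset(r_native, chain_i="A", chain_j="B"):
    n = len(r_native)
    r = np.asarray(r_native, dtype=float)
    return ContactMap(atom_i=np.arange(n, dtype=np.int64),
                      atom_j=np.arange(n, dtype=np.int64) + n,
                      r_native=r, sigma=0.95 * r,
                      chain_i=np.full(n, chain_i), chain_j=np.full(n, chain_j),
                      intermolecular=np.full(n, chain_i != chain_j))


def _positions_at(subset, factors):
    """Positions placing each pair at factor * r_native along x."""
    n = len(subset)
    pos = np.zeros((2 * n, 3))
    for idx, (r, f) in enumerate(zip(subset.r_native, factors)):
        pos[idx] = [idx * 10.0, 0, 0]
        pos[idx + n] = [idx * 10.0 + f * r, 0, 0]
    return pos


class TestQFraction:
    def test_reference_frame_gives_exactly_one(self):
        sub = _subset([0.4, 0.5, 0.6])
        pos = _positions_at(sub, [1.0, 1.0, 1.0])
        assert q_fraction(pos, sub) == 1.0

    def test_doubled_distances_give_zero(self):
        sub = _subset([0.4, 0.5, 0.6])
        pos = _positions_at(sub, [2.0, 2.0, 2.0])
        assert q_fraction(pos, sub) == 0.0

    def test_mixed_distances_count_formed_pairs(self):
        sub = _subset([0.5] * 4)
        pos = _positions_at(sub, [1.2, 1.4, 1.6, 1.8])
        assert q_fraction(pos, sub) == pytest.approx(0.5)

    def test_empty_subset_rejected(self):
        sub = _subset([0.5]).subset(np.zeros(1, dtype=bool))
        with pytest.raises(EmptyContactSubsetError):
            q_fraction(np.zeros((2, 3)), sub)


class TestDetectTranslocation:
    def _trace(self, values):
        return QTrace("A", "A", np.arange(len(values), dtype=float) + 1.0,
                      np.asarray(values, dtype=float))

    def test_never_reaching_threshold_returns_none(self):
        assert detect_translocation(self._trace([0.1, 0.5, 0.75]), 0.8) is None

    def test_first_crossing_wins(self):
        ev = detect_translocation(self._trace([0.1, 0.5, 0.85, 0.7, 0.9]), 0.8)
        assert ev.first_passage_time == 3.0

    def test_threshold_comparison_is_inclusive(self):
        ev = detect_translocation(self._trace([0.1, 0.8, 0.1]), 0.8)
        assert ev is not None
        assert ev.first_passage_time == 2.0

    def test_dwell_requirement_skips_transients(self):
        tr = self._trace([0.1, 0.85, 0.1, 0.9, 0.9, 0.9])
        ev = detect_translocation(tr, 0.8, dwell_frames=3)
        assert ev.first_passage_time == 4.0

    def test_first_passage_invariant_to_stride_refinement(self):
        # on a monotone trace, dropping intermediate frames never changes
        # which crossing is first
        times = np.linspace(1, 10, 91)
        values = np.clip((times - 1) / 9, 0, 1)
        full = detect_translocation(QTrace("A", "A", times, values), 0.8)
        for stride in (2, 3, 5, 9):
            sub = detect_translocation(
                QTrace("A", "A", times[::stride], values[::stride]), 0.8)
            assert sub.first_passage_time >= full.first_passage_time
            # the coarse first passage brackets the fine one within a stride
            assert sub.first_passage_time - full.first_passage_time <= \
                (times[1] - times[0]) * stride


class TestCounts:
    def test_empty_event_list(self):
        counts = count_events_by_position([], list("ABC"), 3, 5)
        assert counts == {"A": 0, "B": 0, "C": 0}

    def test_hand_built_five_event_fixture(self):
        events = [
            TranslocationEvent("a1", "A", 0, 1.0),
            TranslocationEvent("a2", "A", 0, 2.0),
            TranslocationEvent("a1", "A", 1, 3.0),
            TranslocationEvent("b1", "B", 0, 4.0),
            TranslocationEvent("c1", "C", 2, 5.0),
        ]
        counts = count_events_by_position(events, list("ABC"), 3, 5)
        assert counts == {"A": 3, "B": 1, "C": 1}

    def test_duplicate_event_for_run_and_chain_rejected(self):
        events = [TranslocationEvent("a1", "A", 0, 1.0),
                  TranslocationEvent("a1", "A", 0, 2.0)]
        with pytest.raises(ValueError, match="duplicate"):
            count_events_by_position(events, ["A"], 3, 5)

    def test_denominator_bound(self):
        # 20 runs x 60 chains per position caps each position at 1200
        events = [TranslocationEvent(f"c{i}", "A", r, 1.0)
                  for r in range(20) for i in range(60)]
        counts = count_events_by_position(events, ["A"], 60, 20)
        assert counts["A"] == 1200
        with pytest.raises(ValueError, match="exceed"):
            count_events_by_position(events, ["A"], 60, 19)


class TestEnsembleStatistics:
    def test_identical_runs_have_zero_sd(self):
        curves = np.tile(np.arange(5.0), (4, 1))
        mean, sd = ensemble_statistics(curves)
        np.testing.assert_array_equal(sd, 0.0)
        np.testing.assert_array_equal(mean, np.arange(5.0))

    def test_two_runs_sample_sd_convention(self):
        mean, sd = ensemble_statistics(np.array([[2.0], [4.0]]))
        assert mean[0] == pytest.approx(3.0)
        assert sd[0] == pytest.approx(np.sqrt(2.0))   # n-1 denominator

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            ensemble_statistics(np.array([[1.0, 2.0]]))

    def test_mean_of_non_decreasing_curves_is_non_decreasing(self):
        rng = np.random.default_rng(0)
        curves = np.cumsum(rng.integers(0, 2, (6, 40)), axis=1).astype(float)
        mean, _ = ensemble_statistics(curves)
        assert np.all(np.diff(mean) >= 0)


class TestQDistribution:
    def test_point_mass_occupies_single_bin(self):
        dists = q_probability_distribution({"A": np.full(1000, 0.5)})
        d = dists["A"]
        assert np.count_nonzero(d.probabilities) == 1
        assert d.probabilities.max() == pytest.approx(1.0)

    def test_normalization(self):
        rng = np.random.default_rng(1)
        d = q_probability_distribution({"A": rng.uniform(0, 1, 5000)})["A"]
        assert abs(d.probabilities.sum() - 1.0) <= 1e-12

    def test_uniform_samples_within_binomial_error(self):
        rng = np.random.default_rng(2)
        n = 100_000
        bins = 50
        d = q_probability_distribution(
            {"A": rng.uniform(0, 1, n)},
            AnalysisParams(histogram_bins=bins))["A"]
        p = 1 / bins
        se = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(d.probabilities - p) < 3 * se + 1e-12)

    def test_trimodal_mixture_yields_exactly_one_intermediate_peak(self):
        rng = np.random.default_rng(3)
        n = 30_000
        samples = np.concatenate([
            rng.normal(0.1, 0.03, n), rng.normal(0.5, 0.03, n),
            rng.normal(0.9, 0.03, n)]).clip(0, 1)
        d = q_probability_distribution({"A": samples})["A"]
        assert len(d.intermediate_peaks) == 1
        assert d.intermediate_peaks[0]["q"] == pytest.approx(0.5, abs=0.05)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            q_probability_distribution({"A": np.empty(0)})


class TestTailContactSubset:
    def test_toy_tails_have_intermolecular_contacts(self, toy_pair, toy_topology):
        params = AnalysisParams()
        for ann in toy_pair.annotations:
            sub = tail_contact_subset(toy_topology.contacts,
                                      toy_pair.expanded_reference,
                                      ann.chain_id, params)
            assert len(sub) >= 1
            assert np.all(sub.intermolecular)

    def test_all_contacts_scope_is_superset(self, toy_pair, toy_topology):
        inter = AnalysisParams(contact_scope="intermolecular_only")
        allc = AnalysisParams(contact_scope="all_tail_contacts")
        for ann in toy_pair.annotations[:5]:
            s_int = tail_contact_subset(toy_topology.contacts,
                                        toy_pair.expanded_reference,
                                        ann.chain_id, inter)
            s_all = tail_contact_subset(toy_topology.contacts,
                                        toy_pair.expanded_reference,
                                        ann.chain_id, allc)
            assert s_int.pair_set() <= s_all.pair_set()

    def test_tail_range_outside_chain_span_rejected(self, toy_pair, toy_topology):
        params = AnalysisParams(tail_range=(900, 950))
        with pytest.raises(ValueError, match="outside"):
            tail_contact_subset(toy_topology.contacts,
                                toy_pair.expanded_reference,
                                toy_pair.annotations[0].chain_id, params)

    def test_q_trace_on_constant_reference_trajectory(self, toy_pair, toy_topology):
        exp = toy_pair.expanded_reference
        traj = Trajectory(positions=np.stack([exp.positions] * 3),
                          times=np.arange(3.0) + 1)
        ann = toy_pair.annotations[0]
        sub = tail_contact_subset(toy_topology.contacts, exp, ann.chain_id)
        trace = q_trace(traj, sub, ann.chain_id, ann.position_label)
        np.testing.assert_array_equal(trace.q_values, 1.0)
        assert len(trace.times) == traj.n_frames
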