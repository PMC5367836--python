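"""Synthetic FACS generation and gating: presets, noise models, round trips."""

import numpy as np
import pandas as pd
import pytest

from edupulse import (
    DotPlotSummary,
    FitConfig,
    GateConfig,
    GroupDesign,
    derived_kinetics,
    expected_endpoint_state,
    expected_triplet,
    fit_sample,
    gate_events,
    generate_events,
    sample_triplet,
    signature_presets,
)
from edupulse.facs import EmptyLiveError


def preset(organ, strain, age, population):
    for d in signature_presets():
        if (d.organ, d.strain, d.age_months, d.population) == (organ, strain, age, population):
            return d
    raise KeyError


class TestSignaturePresets:
    @pytest.mark.parametrize(
        "organ,strain,age,population,p_day,tol",
        [
            ("thymus", "B6", 2, "total", 32.0, 1.0),
            ("thymus", "FVB", 18, "total", 9.0, 1.0),
            ("spleen", "B6", 2, "total", 3.0, 1.0),
            ("spleen", "B6", 18, "total", 13.0, 1.0),
            ("thymus", "B6", 2, "CD8", 45.0, 1.0),
        ],
    )
    def test_preset_rates_hit_reported_ballparks(self, organ, strain, age, population, p_day, tol):
        d = preset(organ, strain, age, population)
        assert derived_kinetics(d.true_a_G, d.true_a_M).p_per_day == pytest.approx(
            p_day, abs=tol
        )

    def test_presets_span_the_kinetic_range(self):
        rates = [derived_kinetics(d.true_a_G, d.true_a_M).p_per_day for d in signature_presets()]
        assert min(rates) < 1.5 and max(rates) >= 44.0

    def test_all_presets_inside_default_search_box(self):
        cfg = FitConfig()
        for d in signature_presets():
            assert cfg.grid_min <= d.true_a_G <= cfg.grid_max
            assert cfg.grid_min <= d.true_a_M <= cfg.grid_max


class TestExpectedTriplet:
    def test_fast_cycling_labels_most_cells(self, protocol):
        d = GroupDesign("B6", 2, "thymus", "x", true_a_G=1 / 6.5, true_a_M=1 / 6.5)
        t = expected_triplet(d, protocol)
        assert t.pct_labelled > 50.0

    def test_slow_entry_labels_few_cells(self, protocol):
        d = GroupDesign("B6", 2, "thymus", "x", true_a_G=1e-4, true_a_M=0.25)
        assert expected_triplet(d, protocol).pct_labelled < 1.0

    def test_triplet_sums_to_100(self, protocol):
        d = GroupDesign("B6", 2, "thymus", "x", true_a_G=0.02, true_a_M=0.1)
        assert expected_triplet(d, protocol).total == pytest.approx(100.0, abs=1e-6)


class TestSampleTriplet:
    def test_reproducible_under_fixed_seed(self):
        e = DotPlotSummary(80.0, 5.0, 15.0)
        a = sample_triplet(e, 10_000, seed=42)
        b = sample_triplet(e, 10_000, seed=42)
        assert a == b

    def test_large_counts_converge_to_expectation(self):
        e = DotPlotSummary(80.0, 5.0, 15.0)
        s = sample_triplet(e, 10_000_000, seed=1)
        assert s.as_array() == pytest.approx(e.as_array(), abs=0.1)

    def test_percentages_sum_to_100(self):
        s = sample_triplet(DotPlotSummary(80.0, 5.0, 15.0), 997, seed=3)
        assert s.total == pytest.approx(100.0, abs=1e-9)

    def test_counting_error_scales_inverse_sqrt(self):
        """Component error vs expectation shrinks ~ n^(-1/2)."""
        e = DotPlotSummary(70.0, 10.0, 20.0)
        errs = []
        for n in (1_000, 100_000):
            reps = [
                np.abs(sample_triplet(e, n, seed=s).as_array() - e.as_array()).max()
                for s in range(30)
            ]
            errs.append(np.mean(reps))
        assert errs[1] < errs[0] / 5  # expect ~x10 reduction, allow slack


@pytest.fixture(scope="module")
def design():
    return GroupDesign(
        "B6", 2, "thymus", "total",
        true_a_G=0.0223, true_a_M=0.5, n_events=20_000,
    )


class TestGenerateEvents:

    def test_zero_dead_fractions_keep_all_events_live(self, protocol):
        d = GroupDesign(
            "B6", 2, "thymus", "x", true_a_G=0.02, true_a_M=0.2,
            n_events=5_000, dead_frac_apoptotic=0.0, dead_frac_engulfed=0.0,
        )
        events = generate_events(d, expected_endpoint_state(d, protocol), seed=0)
        g = GateConfig()
        assert ((events["dna_content"] >= g.dna_g1_lo)
                & (events["dna_content"] <= g.dna_g2m_hi)).all()

    def test_class_counts_match_proportions_exactly(self, design, protocol):
        state = expected_endpoint_state(design, protocol)
        events = generate_events(design, state, seed=0)
        live = events[~events["true_class"].isin(["apoptotic", "engulfed"])]
        props = np.array(state.as_tuple()) / state.total
        for cls, p in zip(("G", "S", "M", "Gp", "Sp", "Mp"), props):
            assert abs((live["true_class"] == cls).sum() - p * design.n_events) <= 1

    def test_dead_events_appended_at_design_fractions(self, design, protocol):
        events = generate_events(design, expected_endpoint_state(design, protocol), seed=0)
        n_apop = (events["true_class"] == "apoptotic").sum()
        n_eng = (events["true_class"] == "engulfed").sum()
        assert n_apop == round(design.dead_frac_apoptotic * design.n_events)
        assert n_eng == round(design.dead_frac_engulfed * design.n_events)

    def test_gating_round_trip_recovers_triplet(self, design, protocol):
        state = expected_endpoint_state(design, protocol)
        expected = np.array([state.G, state.M, state.labelled])
        events = generate_events(design, state, seed=1)
        gr = gate_events(events)
        assert gr.summary.as_array() == pytest.approx(expected, abs=1.0)

    def test_gated_triplet_converges_with_event_count(self, protocol):
        base = dict(strain="B6", age_months=2, organ="thymus", population="x",
                    true_a_G=0.02, true_a_M=0.2)
        state = expected_endpoint_state(GroupDesign(**base, n_events=10), protocol)
        expected = np.array([state.G, state.M, state.labelled])
        errs = []
        for n in (2_000, 200_000):
            d = GroupDesign(**base, n_events=n)
            err = [
                np.abs(gate_events(generate_events(d, state, seed=s)).summary.as_array()
                       - expected).max()
                for s in range(5)
            ]
            errs.append(np.mean(err))
        assert errs[1] < errs[0]


class TestGateEvents:
    @staticmethod
    def events_from(rows):
        return pd.DataFrame(
            [dict(event_id=i, dna_content=d, edu_intensity=e, true_class=c)
             for i, (d, e, c) in enumerate(rows)]
        )

    def test_classification_rules(self):
        g = GateConfig()
        ev = self.events_from([
            (1.0, 10.0, "G"),        # diploid DNA, dim EdU -> G unlabelled
            (2.0, 10.0, "M"),        # tetraploid DNA, dim EdU -> G2/M unlabelled
            (1.5, 500.0, "Sp"),      # bright EdU -> labelled regardless of DNA
            (1.0, 500.0, "Gp"),      # bright EdU at 2N -> labelled
            (0.5, 10.0, "apoptotic"),   # sub-G0/G1
            (4.5, 10.0, "engulfed"),    # >4N
            (3.0, 10.0, "aggregate"),   # (2.2, 4]: discarded
        ])
        gr = gate_events(ev, g)
        assert gr.n_live == 4
        assert gr.summary.pct_G == pytest.approx(25.0)
        assert gr.summary.pct_M == pytest.approx(25.0)
        assert gr.summary.pct_labelled == pytest.approx(50.0)
        assert gr.n_apoptotic == 1 and gr.n_engulfed == 1 and gr.n_discarded == 1
        assert gr.edu_dead_ratio == pytest.approx(2 / 2)

    def test_no_dead_cells_flags_undefined_ratio(self):
        ev = self.events_from([(1.0, 500.0, "Gp")] * 60)
        gr = gate_events(ev)
        assert not gr.ratio_defined
        assert np.isnan(gr.edu_dead_ratio)

    def test_all_dead_raises(self):
        ev = self.events_from([(0.5, 10.0, "apoptotic"), (4.5, 10.0, "engulfed")])
        with pytest.raises(EmptyLiveError):
            gate_events(ev)

    def test_empty_table_raises(self):
        with pytest.raises(EmptyLiveError):
            gate_events(self.events_from([]))

    def test_gate_boundaries_must_increase(self):
        with pytest.raises(ValueError):
            GateConfig(dna_g1_lo=0.5, dna_apoptotic_max=0.7)


def test_end_to_end_recovery_for_every_preset(protocol):
    """generate -> gate -> fit recovers each preset's proliferation rate,
    within 10% relative or within Monte-Carlo scatter of 4 mice."""
    for gi, design in enumerate(signature_presets()):
        state = expected_endpoint_state(design, protocol)
        truth = derived_kinetics(design.true_a_G, design.true_a_M).p_per_day
        estimates = []
        for mi in range(design.n_mice):
            rng = np.random.default_rng([0, gi, mi])
            gr = gate_events(generate_events(design, state, rng))
            estimates.append(fit_sample(gr.summary, protocol).kinetics.p_per_day)
        mean = np.mean(estimates)
        scatter = 3 * np.std(estimates, ddof=1) / np.sqrt(design.n_mice)
        assert abs(mean - truth) <= max(0.10 * truth, scatter), design.key
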