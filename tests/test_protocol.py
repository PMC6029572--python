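"""Protocol expansion, frequency-plan invariants and serialisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfeit.errors import PlanError, ProtocolError
from mfeit.protocol import (COLUMN_ORDERS, ElectrodeLayout, FrequencyPlan,
                            InjectionProtocol, MeasurementList, PlanEntry,
                            build_measurement_list, load_frequency_plan)


def _layout(n):
    return ElectrodeLayout.default(n)


def _ring_pairs(n_inj, n_el, offset=2):
    return InjectionProtocol(tuple(
        (1 + i % n_el, 1 + (i + offset) % n_el) for i in range(n_inj)))


class TestMeasurementListCounts:
    @pytest.mark.parametrize("n_inj, n_el, exclude, expected", [
        (31, 32, True, 930),
        (31, 32, False, 992),
        (1, 3, True, 1),
        (2, 5, True, 6),
    ])
    def test_row_counts(self, n_inj, n_el, exclude, expected):
        protocol = _ring_pairs(n_inj, n_el)
        ml = build_measurement_list(protocol, _layout(n_el), exclude)
        assert ml.n_protocol == expected

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(n_el=st.integers(3, 12), n_inj=st.integers(1, 8),
           seed=st.integers(0, 100))
    def test_count_matches_brute_force(self, n_el, n_inj, seed):
        rng = np.random.default_rng(seed)
        pairs = []
        for _ in range(n_inj):
            src, snk = rng.choice(np.arange(1, n_el + 1), size=2, replace=False)
            pairs.append((int(src), int(snk)))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # duplicate pairs are allowed
            protocol = InjectionProtocol(tuple(pairs))
            ml = build_measurement_list(protocol, _layout(n_el), True)
        brute = [(s, k, e) for s, k in pairs
                 for e in range(1, n_el + 1) if e not in (s, k)]
        assert ml.n_protocol == len(brute) == n_inj * (n_el - 2)
        assert [tuple(r[:3]) for r in ml.rows] == brute

    def test_row_order_injection_major(self):
        ml = build_measurement_list(
            InjectionProtocol(((1, 3), (2, 4))), _layout(5), True)
        assert ml.rows[:, 2].tolist() == [2, 4, 5, 1, 3, 5]

    def test_vminus_is_common_everywhere(self):
        ml = build_measurement_list(_ring_pairs(4, 8), _layout(8), True)
        assert np.all(ml.rows[:, 3] == 9)

    def test_out_of_range_electrode_raises(self):
        with pytest.raises(ProtocolError):
            build_measurement_list(
                InjectionProtocol(((1, 9),)), _layout(8), True)

    def test_duplicate_pair_warns_but_is_retained(self):
        with pytest.warns(UserWarning, match="duplicate"):
            protocol = InjectionProtocol(((1, 3), (3, 1)))
        assert protocol.n_injections == 2

    def test_source_equals_sink_rejected(self):
        with pytest.raises(ProtocolError):
            InjectionProtocol(((2, 2),))


class TestColumnOrder:
    def test_worked_example_row(self):
        """Canonical (CS+ 5, CS- 32, V+ 1, V- 33) serialises to [1, 5, 32, 33]
        in the worked-example order and [5, 32, 1, 33] in header order."""
        ml = MeasurementList(np.array([[5, 32, 1, 33]]), 33)
        assert ml.to_array("example").tolist() == [[1, 5, 32, 33]]
        assert ml.to_array("header").tolist() == [[5, 32, 1, 33]]

    @pytest.mark.parametrize("order", sorted(COLUMN_ORDERS))
    def test_file_round_trip(self, order, tmp_path):
        ml = build_measurement_list(_ring_pairs(3, 6), _layout(6), True)
        path = tmp_path / "protocol.txt"
        ml.to_file(path, order)
        back = MeasurementList.from_file(path, 7, order)
        assert np.array_equal(back.rows, ml.rows)


class TestFrequencyPlan:
    def test_table1_shape_and_first_row(self):
        plan = load_frequency_plan("table1")
        assert plan.n_frequencies == 17
        first = plan.entries[0]
        assert (first.carrier_hz, first.amplitude_ua, first.periods,
                first.injection_time_ms) == (5.0, 45.0, 32, 6400)

    def test_td_variant(self):
        plan = load_frequency_plan("table1_td")
        assert plan.carriers.tolist() == [200.0, 1200.0, 2000.0]

    def test_injection_time_rule(self):
        entry = PlanEntry(100.0, 50.0, 32, 320)
        entry.validate()  # 32 periods / 100 Hz = 320 ms

    def test_inconsistent_injection_time_names_row(self):
        with pytest.raises(PlanError, match="100"):
            FrequencyPlan((PlanEntry(100.0, 50.0, 32, 300),))

    def test_carriers_must_increase(self):
        with pytest.raises(PlanError, match="increasing"):
            FrequencyPlan((PlanEntry(100.0, 50.0, 32, 320),
                           PlanEntry(100.0, 50.0, 32, 320)))

    def test_amplitudes_must_not_decrease(self):
        with pytest.raises(PlanError, match="non-decreasing"):
            FrequencyPlan((PlanEntry(100.0, 90.0, 32, 320),
                           PlanEntry(200.0, 45.0, 64, 320)))

    def test_config_round_trip(self, tmp_path):
        plan = FrequencyPlan.table1()
        path = tmp_path / "plan.cfg"
        plan.to_config(path)
        assert load_frequency_plan(path) == plan

    def test_full_spectrum_active_time(self):
        # one frame of all carriers over 31 injections, three frames: ~20 min
        plan = FrequencyPlan.table1()
        total = 3 * plan.frame_duration_s(31)
        assert total == pytest.approx(1218, abs=5)


class TestElectrodeLayout:
    def test_tsv_round_trip(self, tmp_path):
        layout = ElectrodeLayout.default()
        path = tmp_path / "electrodes.tsv"
        layout.to_tsv(path)
        back = ElectrodeLayout.from_tsv(path)
        assert back.labels == layout.labels
        assert np.allclose(back.coords, layout.coords)
        assert back.common_electrode == 33

    def test_label_count_must_match(self):
        with pytest.raises(ProtocolError):
            ElectrodeLayout(3, ("a", "b"), np.zeros((3, 3)))

    def test_common_outside_measurement_set(self):
        with pytest.raises(ProtocolError):
            ElectrodeLayout(3, ("a", "b", "c"), np.zeros((3, 3)),
                            common_electrode=2)
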