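"""Phantom solver and waveform synthesis: exactness, reciprocity, determinism."""

import numpy as np
import pytest

from mfeit import (NoiseModel, PhantomModel, normalize_current, solve_phantom,
                   synthesize_recording, synthesize_z_recording,
                   transfer_impedance)
from mfeit.errors import ModelError, SynthesisError
from mfeit.protocol import ElectrodeLayout, FrequencyPlan, InjectionProtocol, PlanEntry


class TestSolvePhantom:
    def test_ohms_law_single_resistor(self):
        # 1 kOhm between two electrode nodes, negligible contact impedance:
        # 100 uA drops 100 mV across the resistor
        g = np.array([[0.0, 1e-3], [1e-3, 0.0]])
        model = PhantomModel(g, (0, 1), np.zeros(2))
        v = solve_phantom(model, (1, 2), 100.0)
        assert v[0] - v[1] == pytest.approx(100.0, rel=1e-6)
        assert v[1] == 0.0  # common electrode is the reference

    def test_matches_independent_nodal_oracle(self):
        # 4-node mesh with 3 electrodes, solved here by assembling the full
        # Kirchhoff system from the branch list, independently of the package
        branches = [(0, 1, 2e-3), (1, 2, 1e-3), (2, 3, 5e-3), (0, 3, 1e-3),
                    (1, 3, 3e-3)]
        g = np.zeros((4, 4))
        for i, j, c in branches:
            g[i, j] = g[j, i] = c
        contact = np.array([1000.0, 1500.0, 800.0])
        electrode_nodes = (0, 2, 3)
        model = PhantomModel(g, electrode_nodes, contact)
        got = solve_phantom(model, (1, 2), 50.0)

        # oracle: unknowns = 4 mesh potentials + 3 electrode potentials
        n = 7
        lap = np.zeros((n, n))
        all_branches = branches + [
            (4 + e, node, 1.0 / contact[e])
            for e, node in enumerate(electrode_nodes)]
        for i, j, c in all_branches:
            lap[i, i] += c
            lap[j, j] += c
            lap[i, j] -= c
            lap[j, i] -= c
        rhs = np.zeros(n)
        rhs[4] = 50e-6
        rhs[5] = -50e-6
        keep = np.arange(n) != 6  # ground the common electrode node
        x = np.zeros(n)
        x[keep] = np.linalg.solve(lap[np.ix_(keep, keep)], rhs[keep])
        assert got == pytest.approx(x[4:] * 1e3, rel=1e-9)

    def test_reciprocity_on_random_meshes(self):
        rng = np.random.default_rng(11)
        for seed in range(10):
            model = PhantomModel.random_mesh(8, seed=seed)
            e = rng.choice(np.arange(1, 9), size=4, replace=False)
            z_ab = transfer_impedance(model, (e[0], e[1]), (e[2], e[3]))
            z_ba = transfer_impedance(model, (e[2], e[3]), (e[0], e[1]))
            assert abs(z_ab - z_ba) / abs(z_ab) < 1e-9

    def test_current_linearity(self):
        model = PhantomModel.random_mesh(8, seed=3)
        v1 = solve_phantom(model, (1, 4), 100.0)
        v2 = solve_phantom(model, (1, 4), 200.0)
        assert np.allclose(v2, 2 * v1, rtol=1e-12)

    def test_disconnected_mesh_rejected(self):
        g = np.zeros((4, 4))
        g[0, 1] = g[1, 0] = 1e-3  # nodes 2, 3 isolated
        with pytest.raises(ModelError, match="disconnected"):
            PhantomModel(g, (0, 1, 2), np.zeros(3))

    def test_same_electrode_injection_rejected(self):
        model = PhantomModel.random_mesh(8, seed=0)
        with pytest.raises(ModelError):
            solve_phantom(model, (2, 2), 100.0)


class TestSynthesizeRecording:
    def test_segment_and_trigger_layout(self, small_noiseless):
        ns = small_noiseless
        assert len(ns.rec.triggers) == 2 * 5 * 3  # frames x injections x carriers
        assert len(ns.gt.segment_map) == 30
        # frame-major, injection-next, carrier-minor ordering
        first = ns.gt.segment_map.entries[:4]
        assert [(e.frame, e.injection, e.frequency_slot) for e in first] == [
            (1, 1, 1), (1, 1, 2), (1, 1, 3), (1, 2, 1)]

    def test_segment_sample_counts_floor(self):
        plan = FrequencyPlan.table1()
        # 6.4 s at 16384 Hz floors to 104857 samples; 320 ms to 5242
        assert plan.entries[0].segment_samples(16384.0) == 104857
        assert plan.entries[4].segment_samples(16384.0) == 5242

    def test_seeded_determinism(self, plan_short, protocol5, layout8, phantom8):
        noise = NoiseModel(seed=42)
        rec1, _ = synthesize_recording(plan_short, protocol5, layout8,
                                       phantom8, noise, n_frames=1)
        rec2, _ = synthesize_recording(plan_short, protocol5, layout8,
                                       phantom8, NoiseModel(seed=42), n_frames=1)
        rec3, _ = synthesize_recording(plan_short, protocol5, layout8,
                                       phantom8, NoiseModel(seed=43), n_frames=1)
        assert np.array_equal(rec1.samples, rec2.samples)
        assert not np.array_equal(rec1.samples, rec3.samples)

    def test_ground_truth_frequency_invariant_after_normalisation(self, small_noiseless):
        # purely resistive phantom: current-normalised true voltages are the
        # same at every carrier
        norm = normalize_current(small_noiseless.gt.true_voltages,
                                 small_noiseless.plan)
        assert np.allclose(norm, norm[:, :1], rtol=1e-12)

    def test_doubling_currents_doubles_amplitudes(self, protocol5, layout8, phantom8):
        base = FrequencyPlan((PlanEntry(200.0, 90.0, 64, 320),))
        doubled = FrequencyPlan((PlanEntry(200.0, 180.0, 64, 320),))
        rec1, _ = synthesize_recording(base, protocol5, layout8, phantom8,
                                       NoiseModel.silent(), n_frames=1,
                                       pre_s=0.0, post_s=0.0)
        rec2, _ = synthesize_recording(doubled, protocol5, layout8, phantom8,
                                       NoiseModel.silent(), n_frames=1,
                                       pre_s=0.0, post_s=0.0)
        assert np.allclose(rec2.samples, 2 * rec1.samples, atol=1e-12)

    def test_fs_below_eight_times_carrier_rejected(self, protocol5, layout8, phantom8):
        plan = FrequencyPlan((PlanEntry(2000.0, 280.0, 128, 64),))
        with pytest.raises(SynthesisError, match="8 x max carrier"):
            synthesize_recording(plan, protocol5, layout8, phantom8, fs=8192.0)

    def test_sub_segment_below_two_periods_rejected(self, protocol5, layout8, phantom8):
        plan = FrequencyPlan((PlanEntry(200.0, 90.0, 1, 5),))
        with pytest.raises(SynthesisError, match="2 carrier periods"):
            synthesize_recording(plan, protocol5, layout8, phantom8)

    def test_layout_phantom_mismatch_rejected(self, plan_short, protocol5, phantom8):
        layout16 = ElectrodeLayout.default(16)
        prot = InjectionProtocol(((1, 9),))
        with pytest.raises(SynthesisError, match="electrodes"):
            synthesize_recording(plan_short, prot, layout16, phantom8)


class TestZRecording:
    def test_one_injection_per_electrode(self, layout8, phantom8):
        rec, plan, protocol = synthesize_z_recording(layout8, phantom8,
                                                     fs=16384.0)
        assert protocol.n_injections == 8
        assert sorted(p[0] for p in protocol.pairs) == list(range(1, 9))
        assert len(rec.triggers) == 8
        assert plan.entries[0].carrier_hz == 1000.0
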