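"""Ground-truthed synthetic MFEIT recordings.

A lumped resistor network stands in for the head: mesh nodes joined by
conductances, with each electrode attached to a mesh node through its contact
impedance.  Nodal analysis of this network gives exact boundary voltages for
any injection pair, so every downstream stage (segmentation, demodulation,
normalisation, cleaning, QC) can be tested against a known truth without any
deposited recordings.  The network is purely resistive: transfer impedances
are frequency-invariant and obey reciprocity exactly, the two properties the
real hardware is validated against.

Waveform synthesis then emits the protocol-shaped recording: for every
(frame, injection, carrier) sub-segment, a sinusoid at the phantom-predicted
amplitude and the plan's current amplitude, with a trigger at each sub-segment
start, plus configurable noise terms (white noise, per-channel DC offsets,
mains interference, switching transients).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

from .errors import ModelError, SynthesisError
from .protocol import (ElectrodeLayout, FrequencyPlan, InjectionProtocol,
                       MeasurementList, PlanEntry, build_measurement_list)
from .rawseg import RawRecording, SegmentEntry, SegmentIndex

MAINS_HZ = 50.0


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------

@dataclass
class PhantomModel:
    """Lumped resistor-network phantom.

    Parameters
    ----------
    conductances:
        Symmetric ``n_nodes x n_nodes`` matrix of branch conductances (S);
        zero diagonal, ``conductances[i, j]`` is the conductance of the
        branch between mesh nodes ``i`` and ``j``.
    electrode_nodes:
        Mesh node index (0-based) for each electrode, ordered by 1-based
        electrode index ``1 .. n_electrodes + 1``; the last entry is the
        common (reference) electrode.
    contact_impedances:
        Series electrode-skin resistance per electrode (Ohm), same order.
    """

    conductances: np.ndarray
    electrode_nodes: tuple[int, ...]
    contact_impedances: np.ndarray

    def __post_init__(self):
        self.conductances = np.asarray(self.conductances, dtype=float)
        self.contact_impedances = np.asarray(self.contact_impedances, dtype=float)
        g = self.conductances
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ModelError("conductance matrix must be square")
        if not np.allclose(g, g.T):
            raise ModelError("conductance matrix must be symmetric")
        if np.any(g < 0) or np.any(np.diag(g) != 0):
            raise ModelError("branch conductances must be >= 0 with zero diagonal")
        if len(self.electrode_nodes) != len(self.contact_impedances):
            raise ModelError("one contact impedance per electrode required")
        if np.any(self.contact_impedances < 0):
            raise ModelError("contact impedances must be >= 0")
        if max(self.electrode_nodes) >= g.shape[0]:
            raise ModelError("electrode node index out of mesh range")
        self._check_connected()

    @property
    def n_electrodes(self) -> int:
        """Number of measurement electrodes (the common electrode excluded)."""
        return len(self.electrode_nodes) - 1

    @property
    def n_nodes(self) -> int:
        return self.conductances.shape[0]

    def _check_connected(self) -> None:
        n, ne = self.n_nodes, len(self.electrode_nodes)
        adj = np.zeros((n + ne, n + ne))
        adj[:n, :n] = self.conductances
        for i, node in enumerate(self.electrode_nodes):
            adj[n + i, node] = adj[node, n + i] = 1.0  # contact branch
        ncomp, _ = connected_components(adj > 0, directed=False)
        if ncomp != 1:
            raise ModelError("phantom network is disconnected "
                             "(isolated electrode or mesh island)")

    def system_matrix(self) -> np.ndarray:
        """Full Kirchhoff conductance (Laplacian) matrix, mesh then electrode nodes."""
        n, ne = self.n_nodes, len(self.electrode_nodes)
        lap = np.zeros((n + ne, n + ne))
        lap[:n, :n] = np.diag(self.conductances.sum(axis=1)) - self.conductances
        for i, node in enumerate(self.electrode_nodes):
            gc = 1.0 / max(self.contact_impedances[i], 1e-6)
            lap[n + i, n + i] += gc
            lap[node, node] += gc
            lap[n + i, node] -= gc
            lap[node, n + i] -= gc
        return lap

    @classmethod
    def random_mesh(cls, n_electrodes: int = 32, n_internal: int = 8,
                    seed: int = 0,
                    conductance_range: tuple[float, float] = (5e-3, 5e-2),
                    contact_range: tuple[float, float] = (500.0, 3000.0),
                    ) -> "PhantomModel":
        """Random connected phantom with realistic scalp-scale magnitudes.

        Boundary nodes (one per electrode, common included) form a ring with
        random chords to internal nodes; branch conductances are log-uniform
        over ``conductance_range`` (default 20-200 Ohm branches, which yields
        boundary voltages of roughly 1-50 mV at the 45-280 uA plan currents),
        and contact impedances uniform over ``contact_range`` (around the
        1-3 kOhm acceptance band used when applying electrodes).
        """
        rng = np.random.default_rng(seed)
        nb = n_electrodes + 1
        n = nb + n_internal
        g = np.zeros((n, n))

        def draw():
            lo, hi = conductance_range
            return np.exp(rng.uniform(np.log(lo), np.log(hi)))

        for i in range(nb):  # boundary ring
            j = (i + 1) % nb
            g[i, j] = g[j, i] = draw()
        for i in range(nb):  # spokes to internal nodes
            j = nb + int(rng.integers(n_internal)) if n_internal else (i + 2) % nb
            g[i, j] = g[j, i] = draw()
        for i in range(n_internal):  # internal clique keeps the core connected
            for j in range(i + 1, n_internal):
                g[nb + i, nb + j] = g[nb + j, nb + i] = draw()
        contact = rng.uniform(*contact_range, size=nb)
        return cls(g, tuple(range(nb)), contact)


def solve_phantom(model: PhantomModel, injection: tuple[int, int],
                  current_ua: float) -> np.ndarray:
    """Nodal-analysis boundary voltages for one injection.

    Current ``current_ua`` enters at the source electrode and leaves at the
    sink, each through its contact impedance.  Returns the voltage (mV) on
    every electrode — index ``e - 1`` for 1-based electrode ``e``, the last
    entry being the common electrode — referenced to the common electrode
    (which is therefore exactly 0).
    """
    src, snk = injection
    if src == snk:
        raise ModelError("injection electrodes must be distinct")
    ne = len(model.electrode_nodes)
    for e in (src, snk):
        if not 1 <= e <= ne:
            raise ModelError(f"electrode {e} out of range [1, {ne}]")
    n = model.n_nodes
    lap = model.system_matrix()
    rhs = np.zeros(n + ne)
    rhs[n + src - 1] = current_ua * 1e-6
    rhs[n + snk - 1] = -current_ua * 1e-6
    ground = n + ne - 1  # common electrode node
    keep = np.arange(n + ne) != ground
    try:
        x = np.linalg.solve(lap[np.ix_(keep, keep)], rhs[keep])
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by validate
        raise ModelError("singular phantom network") from exc
    pot = np.zeros(n + ne)
    pot[keep] = x
    return pot[n:] * 1e3  # V -> mV


def transfer_impedance(model: PhantomModel, injection: tuple[int, int],
                       measurement: tuple[int, int]) -> float:
    """Four-terminal transfer impedance in Ohm (reciprocity test quantity)."""
    v = solve_phantom(model, injection, 1.0)  # mV per uA == kOhm
    mp, mn = measurement
    return float((v[mp - 1] - v[mn - 1]) * 1e3)


# ---------------------------------------------------------------------------
# Noise and ground truth
# ---------------------------------------------------------------------------

@dataclass
class NoiseModel:
    """Additive artefact model for synthetic recordings.

    All amplitudes are non-negative; ``seed`` reproducibly determines every
    random draw.  Defaults emulate a well-applied EEG-amplifier setup: a few
    uV of broadband noise, per-channel DC electrode offsets well below the
    50 mV acceptance cap, a few uV of mains pickup and a small decaying
    transient at every electrode-pair switch.
    """

    white_noise_sd_uv: float = 5.0
    dc_offset_range_mv: float = 20.0
    mains_amplitude_uv: float = 5.0
    switch_transient_mv: float = 1.0
    switch_transient_tau_ms: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for name in ("white_noise_sd_uv", "dc_offset_range_mv",
                     "mains_amplitude_uv", "switch_transient_mv",
                     "switch_transient_tau_ms"):
            if getattr(self, name) < 0:
                raise SynthesisError(f"{name} must be >= 0")

    @classmethod
    def silent(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0)


@dataclass
class GroundTruth:
    """Noiseless truth recorded alongside a synthetic recording.

    ``true_voltages`` are the signed real demodulated voltages (mV) per
    (measurement row, carrier) at the plan's injected currents, before any
    amplifier-gain or current normalisation (``convention`` documents this).
    """

    true_voltages: np.ndarray
    segment_map: SegmentIndex
    measurement_list: MeasurementList
    transfer_mv_per_ua: np.ndarray
    convention: str = ("signed real voltage in mV at the plan current, "
                       "referenced to the common electrode, no amplifier gain")


# ---------------------------------------------------------------------------
# Waveform synthesis
# ---------------------------------------------------------------------------

def synthesize_recording(plan: FrequencyPlan, protocol: InjectionProtocol,
                         layout: ElectrodeLayout, model: PhantomModel,
                         noise: NoiseModel | None = None, n_frames: int = 3,
                         fs: float = 16384.0, *, carrier_phase: float = 0.0,
                         dead_time_ms: float = 0.0, pre_s: float = 1.0,
                         post_s: float = 1.0, gain=None,
                         dtype=np.float64) -> tuple[RawRecording, GroundTruth]:
    """Emit a trigger-annotated multichannel recording plus its ground truth.

    One sub-segment of ``periods / carrier`` seconds is synthesised per
    (frame, injection, carrier), in frame-major, injection-next,
    carrier-minor order, with one trigger at every sub-segment start and an
    optional dead time between sub-segments.  ``gain`` may be a
    :class:`~mfeit.postproc.GainModel` emulating the amplifier's frequency
    response (the processing chain's gain correction then undoes it).

    Channel ``e - 1`` of the output carries electrode ``e`` (1-based),
    already referenced to the common electrode, as in the deposited
    recordings.
    """
    if noise is None:
        noise = NoiseModel.silent()
    protocol.validate(layout)
    if layout.n_electrodes != model.n_electrodes:
        raise SynthesisError(
            f"layout has {layout.n_electrodes} electrodes but the phantom "
            f"exposes {model.n_electrodes}")
    fmax = plan.carriers.max()
    if fs < 8 * fmax:
        raise SynthesisError(f"fs = {fs} Hz below 8 x max carrier ({8 * fmax} Hz)")
    for e in plan.entries:
        if e.periods < 2:
            raise SynthesisError(
                f"{e.carrier_hz} Hz sub-segment of {e.periods} periods is "
                "shorter than 2 carrier periods")

    rng = np.random.default_rng(noise.seed)
    n_el = layout.n_electrodes
    nf, ninj = plan.n_frequencies, protocol.n_injections
    seg_samples = [e.segment_samples(fs) for e in plan.entries]
    dead = int(round(dead_time_ms * 1e-3 * fs))
    pre, post = int(round(pre_s * fs)), int(round(post_s * fs))
    total = pre + n_frames * ninj * (sum(seg_samples) + nf * dead) + post

    # per-injection transfer (mV per uA) on every electrode, common last
    transfer = np.stack([solve_phantom(model, pair, 1.0)
                         for pair in protocol.pairs])  # (ninj, n_el + 1)
    gains = np.array([1.0 if gain is None else gain.gain(e.carrier_hz)
                      for e in plan.entries])

    x = np.zeros((n_el, total), dtype=dtype)
    triggers: list[int] = []
    entries: list[SegmentEntry] = []
    cursor = pre
    for frame in range(1, n_frames + 1):
        for inj in range(1, ninj + 1):
            for slot, entry in enumerate(plan.entries, start=1):
                nseg = seg_samples[slot - 1]
                t = np.arange(nseg) / fs
                amp = (transfer[inj - 1, :n_el] * entry.amplitude_ua
                       * gains[slot - 1])  # mV, signed
                x[:, cursor:cursor + nseg] += amp[:, None] * np.cos(
                    2 * np.pi * entry.carrier_hz * t + carrier_phase)
                if noise.switch_transient_mv > 0:
                    tau = noise.switch_transient_tau_ms * 1e-3
                    x[:, cursor:cursor + nseg] += (
                        noise.switch_transient_mv * np.exp(-t / tau))
                triggers.append(cursor)
                entries.append(SegmentEntry(frame, inj, slot, cursor, cursor + nseg))
                cursor += nseg + dead

    if noise.dc_offset_range_mv > 0:
        x += rng.uniform(-noise.dc_offset_range_mv, noise.dc_offset_range_mv,
                         size=(n_el, 1))
    if noise.mains_amplitude_uv > 0:
        tg = np.arange(total) / fs
        x += (noise.mains_amplitude_uv * 1e-3
              * np.sin(2 * np.pi * MAINS_HZ * tg + rng.uniform(0, 2 * np.pi)))
    if noise.white_noise_sd_uv > 0:
        x += rng.normal(0.0, noise.white_noise_sd_uv * 1e-3, size=x.shape)

    rec = RawRecording(x, fs, np.array(triggers), meta={
        "kind": "synthetic", "n_frames": n_frames,
        "n_injections": ninj, "n_frequencies": nf,
    })
    index = SegmentIndex(entries, n_frames, ninj, nf)
    mlist = build_measurement_list(protocol, layout, exclude_injection=True)
    # signed real voltage per (row, carrier) at the plan current, gain-free
    v_el = transfer[:, :n_el]  # mV per uA
    rows_inj = np.repeat(np.arange(ninj), n_el - 2)
    rows_el = mlist.rows[:, 2] - 1
    true_v = v_el[rows_inj, rows_el][:, None] * plan.amplitudes_ua[None, :]
    gt = GroundTruth(true_v, index, mlist, transfer)
    return rec, gt


def synthesize_z_recording(layout: ElectrodeLayout, model: PhantomModel,
                           current_ua: float = 140.0, carrier: float = 1000.0,
                           periods: int = 64, fs: float = 16384.0,
                           noise: NoiseModel | None = None,
                           ) -> tuple[RawRecording, FrequencyPlan, InjectionProtocol]:
    """Contact-impedance check recording: one injection through every electrode.

    Emulates the pre/post-recording contact check: a single-carrier (default
    1 kHz) injection cycles through each electrode in turn, paired with its
    ring neighbour, so the voltage on the injecting electrode is dominated by
    its own contact impedance.
    """
    n = layout.n_electrodes
    pairs = tuple((e, e % n + 1) for e in range(1, n + 1))
    protocol = InjectionProtocol(pairs)
    plan = FrequencyPlan((PlanEntry(
        carrier, current_ua, periods, round(1000.0 * periods / carrier)),))
    rec, _ = synthesize_recording(plan, protocol, layout, model, noise,
                                  n_frames=1, fs=fs)
    rec.meta["kind"] = "synthetic-z-check"
    return rec, plan, protocol
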