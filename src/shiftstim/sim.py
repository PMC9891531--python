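"""Clock-driven LIF network simulation with delayed transmission and STDP.

Dynamics
--------
Membrane potentials follow, in threshold-normalized units,

    dv_i/dlambda = -v_i + I_syn + I_ext + I_stim,      lambda = t / tau_m,

integrated by forward Euler at ``dt`` (default 0.1 ms).  A neuron crossing
``v_th = 1`` emits a spike and resets to ``v_r = 0``.  Each neuron carries
an outgoing synaptic trace that decays with ``tau_s`` and jumps by one at
each spike; the synaptic current onto neuron *i* is the weighted sum of
presynaptic traces, with inhibitory presynaptic cells contributing
negatively.  Intra-module transmission is instantaneous; inter-module
currents use the trace delayed by the total conduction delay
``tau = tau_d + tau_a``.  Stimulation pulses kick ``v`` by ``K``
instantaneously.  Background drive is an aggregate Poisson process per
neuron feeding an external trace.

Plasticity
----------
Inter-module excitatory-to-excitatory synapses are updated online by the
pair-based STDP rule

    dg = A_(+/-) * sgn(Dl) * exp(-|Dl| / tau_(+/-)),

where ``Dl`` is the lag between the *arrival* of pre- and postsynaptic
activity at the synapse: a presynaptic somatic spike at ``t`` reaches the
synapse at ``t + tau_a``, a postsynaptic spike back-propagates and arrives
at ``t + tau_d``, so ``Dl = (t_post - t_pre) + xi`` with
``xi = tau_d - tau_a``.  Pairing is nearest-spike (each arrival pairs with
the partner's most recent arrival) and updates fire at both pre- and
post-arrival events.  Updates are additive with hard clipping to
``[g_min, g_max]``.  Evaluating the rule at synapse-local arrival times —
rather than pairing somatic spikes and shifting by ``xi`` afterwards —
matters when ``|xi|`` is large enough to reorder events at the synapse;
only the arrival-time scheme reproduces the period-averaged theory of
:mod:`shiftstim.theory`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from shiftstim.network import Connectivity, DriveSpec, NeuronParams
from shiftstim.theory import STDPParams, DelaySpec

__all__ = [
    "SimConfig",
    "SpikeRecord",
    "SimResult",
    "LIFSimulator",
    "pair_update",
    "run",
    "run_forced_pair",
]


@dataclass(frozen=True)
class SimConfig:
    """Integration settings.

    ``dt`` must resolve the fastest time constant (at most
    ``min(tau_s, tau_m) / 10``) and all delays must be integer multiples
    of it, so delay lines are exact ring buffers.
    """

    dt: float = 0.1
    t_total: float = 1000.0
    seed: int = 0
    record_weights_every: float = 50.0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.t_total > 0:
            raise ValueError("t_total must be positive")
        if not self.record_weights_every > 0:
            raise ValueError("record_weights_every must be positive")

    def n_steps(self) -> int:
        return int(round(self.t_total / self.dt))


@dataclass
class SpikeRecord:
    """Timestamped spikes with neuron identity annotations."""

    times: np.ndarray
    neuron_ids: np.ndarray
    module_ids: np.ndarray
    ei_flags: np.ndarray

    def select(self, module=None, excitatory=None, window=None) -> "SpikeRecord":
        m = np.ones(self.times.size, dtype=bool)
        if module is not None:
            m &= self.module_ids == module
        if excitatory is not None:
            m &= self.ei_flags == excitatory
        if window is not None:
            m &= (self.times >= window[0]) & (self.times < window[1])
        return SpikeRecord(
            self.times[m], self.neuron_ids[m], self.module_ids[m], self.ei_flags[m]
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_ms": self.times,
                "module": self.module_ids,
                "neuron_id": self.neuron_ids,
                "ei_flag": np.where(self.ei_flags, "E", "I"),
            }
        )


@dataclass
class SimResult:
    """Simulation output: spikes, weight trajectories, mean couplings.

    ``plastic_values`` holds, per snapshot, the weights of every plastic
    synapse (ordered by ``plastic_rows``/``plastic_cols``).  The
    per-direction mean coupling series ``g21_series``/``g12_series`` are
    per-edge means (average plastic synaptic strength), the scale on
    which weight bounds and the stability threshold live.
    """

    spikes: SpikeRecord
    snapshot_times: np.ndarray
    plastic_values: np.ndarray
    plastic_rows: np.ndarray
    plastic_cols: np.ndarray
    g21_series: np.ndarray
    g12_series: np.ndarray
    final_weights: np.ndarray
    config: SimConfig
    connectivity: Connectivity = field(repr=False, default=None)

    def firing_rate_series(self, module: int, bin_ms: float = 100.0,
                           excitatory=None):
        """(bin centers, population mean rate in Hz) for one module."""
        rec = self.spikes.select(module=module, excitatory=excitatory)
        conn = self.connectivity
        idx = conn.module_slice(module)
        if excitatory is not None:
            idx = idx[conn.ei_identity[idx] == excitatory]
        n = max(idx.size, 1)
        edges = np.arange(0.0, self.config.t_total + bin_ms, bin_ms)
        counts, _ = np.histogram(rec.times, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        return centers, counts / n / (bin_ms / 1000.0)

    def coupling_trajectory(self, direction: str, normalization: str = "per_edge"):
        """(snapshot times, mean coupling) for one direction ('21' or '12')."""
        if direction == "21":
            series = self.g21_series
        elif direction == "12":
            series = self.g12_series
        else:
            raise ValueError("direction must be '21' or '12'")
        if normalization == "per_edge":
            return self.snapshot_times, series
        if normalization == "per_neuron":
            conn = self.connectivity
            n_mod = int(np.count_nonzero(conn.module_id == 0))
            sub = conn.plastic_submask(direction)
            n_edges = int(sub.sum())
            return self.snapshot_times, series * n_edges / n_mod
        raise ValueError("normalization must be 'per_edge' or 'per_neuron'")


def pair_update(delta_local: float, stdp: STDPParams) -> float:
    """Single pair-based STDP update for a synapse-local lag (ms).

    ``delta_local`` is the post-minus-pre lag measured at the synapse
    (somatic lag plus effective delay xi).  Positive lags potentiate with
    (A_plus, tau_plus); negative lags depress with (A_minus, tau_minus);
    an exactly coincident pair leaves the weight unchanged.
    """
    if delta_local > 0:
        return stdp.A_plus * float(np.exp(-delta_local / stdp.tau_plus))
    if delta_local < 0:
        return -stdp.A_minus * float(np.exp(delta_local / stdp.tau_minus))
    return 0.0


def _delay_steps(delay_ms: float, dt: float) -> int:
    steps = delay_ms / dt
    if abs(steps - round(steps)) > 1e-9:
        raise ValueError(f"delay {delay_ms} ms is not a multiple of dt = {dt} ms")
    return int(round(steps))


class LIFSimulator:
    """Stateful clock-driven integrator; one :meth:`step` advances dt.

    Parameters
    ----------
    connectivity : Connectivity
    drive : DriveSpec or None
        Aggregate Poisson background; None disables external input.
    stim_events : sequence of (times_ms, neuron_mask)
        Each entry delivers instantaneous kicks of size ``stim_K`` to the
        masked neurons at the listed times.
    config : SimConfig
    neuron : NeuronParams
    stdp : STDPParams or None
        None freezes all weights.
    stim_K : float
        Kick amplitude per stimulation pulse.
    """

    def __init__(
        self,
        connectivity: Connectivity,
        drive: DriveSpec | None,
        stim_events,
        config: SimConfig,
        neuron: NeuronParams | None = None,
        stdp: STDPParams | None = None,
        stim_K: float = 1.3,
        forced_spikes=None,
    ):
        self.conn = connectivity
        self.config = config
        self.neuron = neuron or NeuronParams()
        self.stdp = stdp
        self.stim_K = stim_K
        n = connectivity.n_total
        dt = config.dt
        if dt > min(self.neuron.tau_s, self.neuron.tau_m) / 10 + 1e-12:
            raise ValueError("dt must be at most min(tau_s, tau_m)/10")

        spec = connectivity.spec
        delays = spec.delays_inter if spec is not None else DelaySpec(0.5, 10.5)
        self.inter_scale = spec.effective_inter_scale() if spec is not None else 1.0
        self.d_total = _delay_steps(delays.total, dt)
        self.d_axonal = _delay_steps(delays.tau_a, dt)
        self.d_dendritic = _delay_steps(delays.tau_d, dt)

        # static intra-module weights, signed by presynaptic identity
        intra = np.zeros((n, n))
        for m in (0, 1):
            idx = connectivity.module_id == m
            blk = np.ix_(idx, idx)
            intra[blk] = np.where(
                connectivity.adjacency[blk], connectivity.weights[blk], 0.0
            )
        sign = np.where(connectivity.ei_identity, 1.0, -1.0)
        self.W_static = intra * sign[None, :]
        # plastic (inter-module) weights, all excitatory
        self.W_plastic = np.where(connectivity.plastic_mask, connectivity.weights, 0.0)
        self.pmask = connectivity.plastic_mask
        self.has_plastic_in = self.pmask.any(axis=1)
        self.has_plastic_out = self.pmask.any(axis=0)

        self.rng = np.random.default_rng(config.seed)
        if drive is not None:
            rate_hz = np.array(
                [drive.aggregate_rate_hz(bool(e)) for e in connectivity.ei_identity]
            )
            self.lam = rate_hz * dt / 1000.0
            self.w_ext = np.array(
                [drive.amplitude(bool(e)) for e in connectivity.ei_identity]
            )
        else:
            self.lam = None
            self.w_ext = 0.0

        # stimulation kick schedule: step index -> boolean mask
        self._stim: dict[int, np.ndarray] = {}
        for times, mask in stim_events:
            for t in np.atleast_1d(times):
                k = int(round(t / dt))
                if 0 <= k < config.n_steps():
                    cur = self._stim.get(k)
                    self._stim[k] = mask.copy() if cur is None else (cur | mask)

        # optional externally imposed spike trains (forced firing)
        self._forced: dict[int, np.ndarray] = {}
        if forced_spikes is not None:
            for times, mask in forced_spikes:
                for t in np.atleast_1d(times):
                    k = int(round(t / dt))
                    if 0 <= k < config.n_steps():
                        cur = self._forced.get(k)
                        self._forced[k] = mask.copy() if cur is None else (cur | mask)

        # state
        self.refrac_until = np.full(n, -np.inf)
        self.v = np.zeros(n)
        self.s = np.zeros(n)  # instantaneous outgoing trace (intra current)
        self.s_del = np.zeros(n)  # trace delayed by the inter-module delay
        self.s_ext = np.zeros(n)
        self.decay = float(np.exp(-dt / self.neuron.tau_s))
        buf_len = max(self.d_total, self.d_axonal, self.d_dendritic) + 1
        self._buf = np.zeros((buf_len, n), dtype=bool)
        self.last_pre_arrival = np.full(n, -np.inf)
        self.last_post_arrival = np.full(n, -np.inf)
        self.istep = 0
        self.spike_times: list[float] = []
        self.spike_ids: list[np.ndarray] = []

    # -- helpers ---------------------------------------------------------

    def _buffered(self, lag_steps: int) -> np.ndarray:
        """Spike flags from ``lag_steps`` steps ago (False before warm-up)."""
        if lag_steps > self.istep:
            return np.zeros(self.conn.n_total, dtype=bool)
        return self._buf[(self.istep - lag_steps) % self._buf.shape[0]]

    def _apply_stdp(self, t: float) -> None:
        """Process pre/post arrivals due this step and update plastic weights."""
        pre_now = self._buffered(self.d_axonal) & self.has_plastic_out
        post_now = self._buffered(self.d_dendritic) & self.has_plastic_in
        if not (pre_now.any() or post_now.any()):
            return
        self.last_pre_arrival[pre_now] = t
        self.last_post_arrival[post_now] = t
        stdp = self.stdp
        gmin, gmax = self.conn.g_min, self.conn.g_max
        if post_now.any():
            # each post arrival pairs with every presynaptic partner's
            # most recent arrival -> potentiation (x == 0 contributes 0)
            x = t - self.last_pre_arrival
            pot = np.where(
                np.isfinite(x) & (x > 0), stdp.A_plus * np.exp(-x / stdp.tau_plus), 0.0
            )
            rows = np.flatnonzero(post_now)
            sub = self.W_plastic[rows, :] + pot[None, :] * self.pmask[rows, :]
            self.W_plastic[rows, :] = np.where(
                self.pmask[rows, :], np.clip(sub, gmin, gmax), 0.0
            )
        if pre_now.any():
            # each pre arrival pairs with the postsynaptic cell's most
            # recent arrival -> depression
            y = t - self.last_post_arrival
            dep = np.where(
                np.isfinite(y) & (y > 0),
                stdp.A_minus * np.exp(-y / stdp.tau_minus),
                0.0,
            )
            cols = np.flatnonzero(pre_now)
            sub = self.W_plastic[:, cols] - dep[:, None] * self.pmask[:, cols]
            self.W_plastic[:, cols] = np.where(
                self.pmask[:, cols], np.clip(sub, gmin, gmax), 0.0
            )

    # -- main loop -------------------------------------------------------

    def step(self) -> np.ndarray:
        """Advance one time step; returns the boolean spike vector."""
        cfg = self.config
        t = self.istep * cfg.dt

        # synaptic + external currents from traces at the step start
        current = (
            self.W_static @ self.s
            + self.inter_scale * (self.W_plastic @ self.s_del)
            + self.s_ext
        )
        self.v += (cfg.dt / self.neuron.tau_m) * (-self.v + current)

        kick = self._stim.get(self.istep)
        if kick is not None:
            self.v[kick] += self.stim_K

        # absolute refractory period: clamp at reset, ignore kicks
        refractory = t < self.refrac_until
        if refractory.any():
            self.v[refractory] = self.neuron.v_r

        spiked = self.v >= self.neuron.v_th
        forced = self._forced.get(self.istep)
        if forced is not None:
            spiked = spiked | forced
        if spiked.any():
            ids = np.flatnonzero(spiked)
            self.spike_times.append(t)
            self.spike_ids.append(ids)
            self.v[spiked] = self.neuron.v_r
            self.refrac_until[spiked] = t + self.neuron.tau_ref
        self._buf[self.istep % self._buf.shape[0]] = spiked

        # traces: decay, then add this step's events
        self.s *= self.decay
        self.s_del *= self.decay
        if spiked.any():
            self.s[spiked] += 1.0
        arriving = self._buffered(self.d_total) if self.d_total > 0 else spiked
        if arriving.any():
            self.s_del[arriving] += 1.0
        if self.lam is not None:
            counts = self.rng.poisson(self.lam)
            self.s_ext = self.s_ext * self.decay + self.w_ext * counts
        if self.stdp is not None:
            self._apply_stdp(t)

        self.istep += 1
        if self.istep % 2000 == 0 and not np.isfinite(self.v).all():
            raise FloatingPointError(
                f"membrane potential diverged at t = {t:.1f} ms"
            )
        return spiked

    def run(self) -> SimResult:
        cfg = self.config
        rows, cols = np.nonzero(self.pmask)
        sub21 = self.conn.plastic_submask("21")[rows, cols] if rows.size else None
        sub12 = self.conn.plastic_submask("12")[rows, cols] if rows.size else None

        rec_every = max(int(round(cfg.record_weights_every / cfg.dt)), 1)
        snap_t, snaps, g21, g12 = [], [], [], []

        def snapshot(t):
            vals = self.W_plastic[rows, cols] if rows.size else np.empty(0)
            snap_t.append(t)
            snaps.append(vals.copy())
            if rows.size:
                g21.append(float(vals[sub21].mean()) if sub21.any() else np.nan)
                g12.append(float(vals[sub12].mean()) if sub12.any() else np.nan)
            else:
                g21.append(np.nan)
                g12.append(np.nan)

        snapshot(0.0)
        n_steps = cfg.n_steps()
        for k in range(n_steps):
            self.step()
            if (k + 1) % rec_every == 0:
                snapshot((k + 1) * cfg.dt)

        if self.spike_times:
            times = np.concatenate(
                [np.full(ids.size, tt) for tt, ids in zip(self.spike_times, self.spike_ids)]
            )
            ids = np.concatenate(self.spike_ids)
        else:
            times = np.empty(0)
            ids = np.empty(0, dtype=int)
        record = SpikeRecord(
            times=times,
            neuron_ids=ids,
            module_ids=self.conn.module_id[ids] if ids.size else np.empty(0, dtype=int),
            ei_flags=self.conn.ei_identity[ids] if ids.size else np.empty(0, dtype=bool),
        )
        final = self.conn.weights.copy()
        final[self.pmask] = self.W_plastic[self.pmask]
        return SimResult(
            spikes=record,
            snapshot_times=np.asarray(snap_t),
            plastic_values=np.asarray(snaps),
            plastic_rows=rows,
            plastic_cols=cols,
            g21_series=np.asarray(g21),
            g12_series=np.asarray(g12),
            final_weights=final,
            config=cfg,
            connectivity=self.conn,
        )


def run(
    connectivity: Connectivity,
    drive: DriveSpec | None,
    stim_events,
    config: SimConfig,
    neuron: NeuronParams | None = None,
    stdp: STDPParams | None = STDPParams(),
    stim_K: float = 1.3,
    forced_spikes=None,
) -> SimResult:
    """Simulate the network and return spikes, weights and couplings.

    ``stim_events`` is a sequence of ``(pulse_times_ms, neuron_mask)``
    pairs (see :func:`shiftstim.stimulation.pulse_times` and
    :func:`shiftstim.stimulation.target_mask`).  Passing ``stdp=None``
    freezes all weights.  Deterministic under ``config.seed``.
    """
    simulator = LIFSimulator(
        connectivity,
        drive,
        stim_events,
        config,
        neuron=neuron,
        stdp=stdp,
        stim_K=stim_K,
        forced_spikes=forced_spikes,
    )
    return simulator.run()


def run_forced_pair(
    delta_t: float,
    T: float,
    stdp: STDPParams,
    delays: DelaySpec,
    n_periods: int = 50,
    warmup_periods: int = 2,
) -> tuple[float, float]:
    """Per-period weight drift of a reciprocal pair under forced periodic firing.

    Both neurons fire perfectly periodically with period ``T``; neuron 2
    lags neuron 1 by ``delta_t``.  The online pair-based rule is applied
    event-by-event at synapse-local arrival times (unclipped), and the
    mean change per period after a warm-up is returned for both synapses
    ``(dg_21, dg_12)``.  On periodic trains this reproduces the
    period-averaged theory of :func:`shiftstim.theory.net_change`.
    """
    if n_periods < warmup_periods + 4:
        raise ValueError("n_periods too small for the requested warm-up")
    t1 = np.arange(n_periods) * T
    t2 = t1 + delta_t

    def synapse_drift(pre_somatic, post_somatic):
        pre_arr = pre_somatic + delays.tau_a
        post_arr = post_somatic + delays.tau_d
        events = sorted(
            [(t, "pre") for t in pre_arr] + [(t, "post") for t in post_arr]
        )
        last = {"pre": -np.inf, "post": -np.inf}
        total = 0.0
        # average over a window spanning an exact whole number of periods,
        # so each synapse sees equally many pre and post arrival events
        n_count = n_periods - warmup_periods - 2
        t_open = warmup_periods * T
        t_close = t_open + n_count * T
        for t, kind in events:
            last[kind] = t
            if kind == "post":
                d = t - last["pre"]
            else:
                d = last["post"] - t
            if np.isfinite(d) and t_open <= t < t_close:
                total += pair_update(d, stdp)
        return total / n_count

    dg_21 = synapse_drift(t1, t2)  # synapse 1 -> 2
    dg_12 = synapse_drift(t2, t1)  # synapse 2 -> 1
    return dg_21, dg_12
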