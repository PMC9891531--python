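"""Time-shifted two-channel stimulation schedules.

Two pulse-train signals are delivered to the two neurons / modules.  Each
signal is either a *burst* pattern — ``k_pulses`` pulses spaced
``T_pulse`` ms apart (the ON-epoch), followed by a silent OFF-epoch of
``T_off`` ms — or a *continuous* pattern, obtained by collapsing the
OFF-epoch to the inter-pulse interval (``T_off = T_pulse``).  Signal 2 is
a copy of signal 1 shifted by ``delta_t`` ms; the shift is the control
parameter that decides whether the inter-population synapses are
depressed or potentiated through STDP.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["StimProtocol", "pulse_times", "schedule_frame", "target_mask"]


@dataclass(frozen=True)
class StimProtocol:
    """Parameters of the two-signal stimulation protocol.

    Parameters
    ----------
    K : float
        Stimulation intensity: the instantaneous kick added to the
        dimensionless membrane potential at each pulse.  The default 1.3
        is suprathreshold (threshold is 1), so a pulse fires a resting
        neuron within one integration step.
    T_pulse : float
        Inter-pulse interval within a burst (ms); the intra-burst
        frequency is ``nu = 1000 / T_pulse`` Hz.
    k_pulses : int
        Pulses per burst.
    T_off : float
        OFF-epoch between bursts (ms).  ``T_off == T_pulse`` yields the
        continuous pattern.
    T_stim : float
        Total stimulation duration per signal (ms).
    t_start : float
        Onset of the first pulse of signal 1 (ms).
    delta_t : float
        Time shift of signal 2 relative to signal 1 (ms); 0 is the
        unshifted control.
    pattern : {"burst", "continuous"}
    target : {"all", "excitatory_only", "inhibitory_only"}
        Which cell class within each module receives the pulses.
    """

    K: float = 1.3
    T_pulse: float = 30.0
    k_pulses: int = 5
    T_off: float = 360.0
    T_stim: float = 5000.0
    t_start: float = 10000.0
    delta_t: float = 5.0
    pattern: str = "burst"
    target: str = "all"

    def __post_init__(self) -> None:
        if not self.T_pulse > 0:
            raise ValueError("T_pulse must be positive")
        if self.k_pulses < 1:
            raise ValueError("k_pulses must be >= 1")
        if self.pattern not in ("burst", "continuous"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.target not in ("all", "excitatory_only", "inhibitory_only"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.pattern == "continuous" and self.T_off != self.T_pulse:
            raise ValueError("continuous pattern requires T_off == T_pulse")
        if not 0 <= self.delta_t < self.T_pulse:
            raise ValueError(
                "delta_t must lie in [0, T_pulse); 0 is the unshifted control"
            )

    @property
    def nu_hz(self) -> float:
        """Intra-burst stimulation frequency (Hz), derived from T_pulse."""
        return 1000.0 / self.T_pulse

    @property
    def T_on(self) -> float:
        """ON-epoch spanned by one burst: (k_pulses - 1) * T_pulse (ms)."""
        return (self.k_pulses - 1) * self.T_pulse

    @classmethod
    def continuous(cls, **kwargs) -> "StimProtocol":
        """Continuous-pattern variant (OFF-epoch collapsed to T_pulse)."""
        kwargs.setdefault("T_pulse", 30.0)
        kwargs["pattern"] = "continuous"
        kwargs["T_off"] = kwargs["T_pulse"]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


def pulse_times(protocol: StimProtocol, signal_index: int) -> np.ndarray:
    """Ordered pulse-onset times (ms) of one stimulation signal.

    The recurrence adds ``T_pulse`` after each pulse, except after the
    ``k``-th pulse of a burst where the gap is ``T_off`` instead.  Signal
    1 starts at ``t_start``, signal 2 at ``t_start + delta_t``; each
    signal stops at its own onset + ``T_stim`` (pulses strictly after the
    window end are dropped).
    """
    if signal_index not in (1, 2):
        raise ValueError("signal_index must be 1 or 2")
    t0 = protocol.t_start + (protocol.delta_t if signal_index == 2 else 0.0)
    t_end = t0 + protocol.T_stim
    times = []
    t = t0
    i = 1  # index of the pulse within the current burst
    while t <= t_end:
        times.append(t)
        if i == protocol.k_pulses:
            t += protocol.T_off
            i = 1
        else:
            t += protocol.T_pulse
            i += 1
    return np.asarray(times)


def schedule_frame(protocol: StimProtocol):
    """Both signals' pulse times as a two-column table (signal, pulse_time_ms)."""
    import pandas as pd

    frames = []
    for sig in (1, 2):
        t = pulse_times(protocol, sig)
        frames.append(pd.DataFrame({"signal": sig, "pulse_time_ms": t}))
    return pd.concat(frames, ignore_index=True)


def target_mask(protocol: StimProtocol, connectivity) -> np.ndarray:
    """Boolean per-neuron stimulation mask, shape (2, n_total).

    Row 0 masks the neurons of module 1 (driven by signal 1), row 1 those
    of module 2 (signal 2), restricted to the cell class requested by
    ``protocol.target``.
    """
    ei = connectivity.ei_identity  # True = excitatory
    module = connectivity.module_id
    if protocol.target == "all":
        class_mask = np.ones_like(ei, dtype=bool)
    elif protocol.target == "excitatory_only":
        class_mask = ei.copy()
    else:  # inhibitory_only
        class_mask = ~ei
    return np.stack([(module == m) & class_mask for m in (0, 1)])
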