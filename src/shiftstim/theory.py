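"""Period-averaged STDP theory for a reciprocally coupled neuron pair.

When two neurons fire periodically with period ``T`` (ms) and a fixed lag,
each synapse between them experiences one potentiation and one depression
event per period under a pair-based STDP rule with nearest-spike pairing.
The two contributions compete, and the sign of their sum decides whether
the synapse grows or decays.  Transmission delays shift the lag perceived
at the synapse: with dendritic (back-propagation) delay ``tau_d`` and
axonal delay ``tau_a``, the effective delay ``xi = tau_d - tau_a`` is
added to the somatic lag before the STDP window is evaluated.

For a synapse whose presynaptic somatic spike leads the postsynaptic one
by ``dt_lag`` (ms), let ``y = (dt_lag + xi) mod T`` be the synapse-local
lag reduced into one period.  The net change per period is::

    dg = A_plus * exp(-y / tau_plus) - A_minus * exp(-(T - y) / tau_minus)

i.e. potentiation acts at lag ``y`` and depression at the complementary
lag ``T - y``.  Classifying the sign of ``dg`` for both directions of a
reciprocal pair partitions the (time shift, period) plane into regimes in
which both synapses decay (*decoupled*), both grow (*bidirectional*), or
one grows at the expense of the other (*unidirectional*).

This module is purely analytic: it assumes perfectly periodic spike
trains and never inspects network dynamics.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STDPParams",
    "DelaySpec",
    "RegionLabel",
    "PhaseMap",
    "net_change",
    "classify_pair",
    "phase_map",
    "stdp_ratio_map",
    "depression_dominates",
]


@dataclass(frozen=True)
class STDPParams:
    """Amplitudes and time constants of the pair-based STDP window.

    Parameters
    ----------
    A_plus : float
        Maximum potentiation amplitude (dimensionless weight change per
        pairing event).
    A_minus : float
        Maximum depression amplitude.
    tau_plus : float
        Potentiation time constant (ms).
    tau_minus : float
        Depression time constant (ms).

    Defaults follow generic cortical STDP profiles: potentiation stronger
    but narrower than depression (``A_plus > A_minus``,
    ``tau_plus < tau_minus``).
    """

    A_plus: float = 0.008
    A_minus: float = 0.005
    tau_plus: float = 10.0
    tau_minus: float = 20.0

    def __post_init__(self) -> None:
        for name in ("A_plus", "A_minus", "tau_plus", "tau_minus"):
            if not getattr(self, name) > 0:
                raise ValueError(f"STDPParams.{name} must be strictly positive")


@dataclass(frozen=True)
class DelaySpec:
    """Dendritic and axonal transmission delays of a synapse (ms).

    The total conduction delay ``tau = tau_d + tau_a`` sets when a
    presynaptic spike reaches the postsynaptic membrane; the effective
    delay ``xi = tau_d - tau_a`` is the timing offset perceived by the
    plasticity mechanism at the synapse.  Long-range projections have
    ``tau_a > tau_d``, hence ``xi < 0``.
    """

    tau_d: float = 0.5
    tau_a: float = 10.5

    def __post_init__(self) -> None:
        if self.tau_d < 0 or self.tau_a < 0:
            raise ValueError("delays must be non-negative")

    @property
    def total(self) -> float:
        """Total transmission delay tau_d + tau_a (ms)."""
        return self.tau_d + self.tau_a

    @property
    def xi(self) -> float:
        """Effective delay xi = tau_d - tau_a (ms); negative for long-range links."""
        return self.tau_d - self.tau_a


class RegionLabel(enum.Enum):
    """Emergent connectivity regime of a reciprocal pair."""

    DECOUPLED = "decoupled"
    UNIDIRECTIONAL = "unidirectional"
    BIDIRECTIONAL = "bidirectional"
    NOT_APPLICABLE = "n/a"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def net_change(dt_lag: float, T: float, stdp: STDPParams, xi: float = 0.0) -> float:
    """Net synaptic change per period for one direction of a periodic pair.

    Parameters
    ----------
    dt_lag : float
        Pre-to-post somatic spike lag (ms), i.e. t_post - t_pre for the
        nearest pair.
    T : float
        Firing period (ms); must be positive.
    stdp : STDPParams
        STDP window parameters.
    xi : float
        Signed effective delay tau_d - tau_a (ms).  Figures in the field
        are often parameterised by |xi|; pass ``-abs(xi)`` for long-range
        links where the axonal delay dominates.

    Returns
    -------
    float
        Signed weight change accumulated over one period (dimensionless).

    Raises
    ------
    ValueError
        If ``T <= 0`` or ``|dt_lag + xi| > T`` (the caller must reduce
        lags into one period first).
    """
    if not T > 0:
        raise ValueError("period T must be strictly positive")
    z = dt_lag + xi
    if abs(z) > T:
        raise ValueError(
            f"synapse-local lag dt_lag + xi = {z} lies outside one period "
            f"(|{z}| > T = {T}); reduce modulo T first"
        )
    y = z % T  # reduce into [0, T): the potentiation lag at the synapse
    pot = stdp.A_plus * np.exp(-y / stdp.tau_plus)
    dep = stdp.A_minus * np.exp(-(T - y) / stdp.tau_minus)
    return float(pot - dep)


def _label_from_signs(dg_fwd: float, dg_rev: float) -> RegionLabel:
    """Map the sign pair of the two directional changes onto a regime label.

    Exact zeros (a measure-zero boundary) defer to the non-zero direction
    if one exists, else fall back to unidirectional, keeping the
    classification deterministic.
    """
    s1, s2 = np.sign(dg_fwd), np.sign(dg_rev)
    if s1 == 0 and s2 == 0:
        return RegionLabel.UNIDIRECTIONAL
    if s1 == 0:
        s1 = s2
    elif s2 == 0:
        s2 = s1
    if s1 < 0 and s2 < 0:
        return RegionLabel.DECOUPLED
    if s1 > 0 and s2 > 0:
        return RegionLabel.BIDIRECTIONAL
    return RegionLabel.UNIDIRECTIONAL


def classify_pair(
    delta_t: float, T: float, stdp: STDPParams, xi: float = 0.0
) -> RegionLabel:
    """Classify the emergent connectivity of a reciprocal pair.

    The pair is stimulated periodically with period ``T``; neuron 1 fires
    first and neuron 2 follows after the time shift ``delta_t``.  The
    1→2 synapse then sees the lag ``delta_t``, the reverse synapse the
    lag ``T - delta_t``; both are shifted by the effective delay ``xi``
    before the STDP window is applied.

    Returns :attr:`RegionLabel.NOT_APPLICABLE` when ``delta_t`` falls
    outside the open interval (0, T), where the protocol is undefined.
    """
    if not T > 0:
        raise ValueError("period T must be strictly positive")
    if not 0 < delta_t < T:
        return RegionLabel.NOT_APPLICABLE
    dg_21 = net_change(delta_t, T, stdp, xi)  # 1 -> 2 synapse
    dg_12 = net_change(T - delta_t, T, stdp, xi)  # 2 -> 1 synapse
    return _label_from_signs(dg_21, dg_12)


@dataclass
class PhaseMap:
    """Dense classification of the (time shift, period) plane.

    Attributes
    ----------
    dt_axis, T_axis : ndarray
        Grid axes (ms), strictly increasing.
    labels : ndarray of RegionLabel, shape (len(T_axis), len(dt_axis))
        Regime per cell; cells violating 0 < Δt < T carry
        :attr:`RegionLabel.NOT_APPLICABLE`.
    dg_21, dg_12 : ndarray
        Signed net change per period for each direction (NaN where not
        applicable).
    xi : float
        Effective delay used.
    stdp : STDPParams
    """

    dt_axis: np.ndarray
    T_axis: np.ndarray
    labels: np.ndarray
    dg_21: np.ndarray
    dg_12: np.ndarray
    xi: float
    stdp: STDPParams = field(default_factory=STDPParams)

    def to_frame(self):
        """Long-format table (delta_t_ms, T_ms, dg_21, dg_12, label)."""
        import pandas as pd

        dt_grid, T_grid = np.meshgrid(self.dt_axis, self.T_axis)
        return pd.DataFrame(
            {
                "delta_t_ms": dt_grid.ravel(),
                "T_ms": T_grid.ravel(),
                "dg_21": self.dg_21.ravel(),
                "dg_12": self.dg_12.ravel(),
                "label": [lab.value for lab in self.labels.ravel()],
            }
        )


def phase_map(
    dt_axis,
    T_axis,
    stdp: STDPParams | None = None,
    xi: float = 0.0,
) -> PhaseMap:
    """Classify every cell of a (time shift, period) grid.

    Axes must be strictly increasing and positive-bounded (``T_axis`` must
    be strictly positive; ``dt_axis`` may include 0, which is marked not
    applicable).  Default grid resolution used by the CLI is 1 ms in both
    axes, matching the granularity at which the regimes are usually drawn.
    """
    stdp = stdp or STDPParams()
    dt_axis = np.asarray(dt_axis, dtype=float)
    T_axis = np.asarray(T_axis, dtype=float)
    if dt_axis.size == 0 or T_axis.size == 0:
        raise ValueError("axes must be non-empty")
    if np.any(np.diff(dt_axis) <= 0) or np.any(np.diff(T_axis) <= 0):
        raise ValueError("axes must be strictly increasing")
    if np.any(T_axis <= 0) or np.any(dt_axis < 0):
        raise ValueError("T axis must be positive and dt axis non-negative")

    shape = (T_axis.size, dt_axis.size)
    labels = np.empty(shape, dtype=object)
    dg_21 = np.full(shape, np.nan)
    dg_12 = np.full(shape, np.nan)
    for r, T in enumerate(T_axis):
        for c, dt in enumerate(dt_axis):
            if not 0 < dt < T or abs(dt + xi) > T or abs(T - dt + xi) > T:
                labels[r, c] = RegionLabel.NOT_APPLICABLE
                continue
            g21 = net_change(dt, T, stdp, xi)
            g12 = net_change(T - dt, T, stdp, xi)
            dg_21[r, c], dg_12[r, c] = g21, g12
            labels[r, c] = _label_from_signs(g21, g12)
    return PhaseMap(dt_axis, T_axis, labels, dg_21, dg_12, xi, stdp)


def stdp_ratio_map(
    A_ratio_axis,
    tau_ratio_axis,
    delta_t: float,
    T: float,
    xi: float = 0.0,
    A_minus: float = 0.005,
    tau_minus: float = 20.0,
):
    """Classify a grid of STDP parameter ratios at a fixed stimulation point.

    Holds the depression parameters fixed and scans the potentiation
    amplitude and time constant through the ratios ``A_plus/A_minus`` and
    ``tau_plus/tau_minus``.  Used to judge which STDP profiles let a given
    (``delta_t``, ``T``) stimulation point decouple a reciprocal pair:
    with the default depression parameters the low/low corner of the grid
    is decoupled and the high/high corner bidirectional.

    Returns
    -------
    (labels, dg_21, dg_12) : tuple of ndarrays
        Shaped (len(tau_ratio_axis), len(A_ratio_axis)).
    """
    A_ratio_axis = np.asarray(A_ratio_axis, dtype=float)
    tau_ratio_axis = np.asarray(tau_ratio_axis, dtype=float)
    if np.any(A_ratio_axis <= 0) or np.any(tau_ratio_axis <= 0):
        raise ValueError("ratio grids must be strictly positive")

    shape = (tau_ratio_axis.size, A_ratio_axis.size)
    labels = np.empty(shape, dtype=object)
    dg_21 = np.full(shape, np.nan)
    dg_12 = np.full(shape, np.nan)
    for r, tr in enumerate(tau_ratio_axis):
        for c, ar in enumerate(A_ratio_axis):
            stdp = STDPParams(
                A_plus=ar * A_minus,
                A_minus=A_minus,
                tau_plus=tr * tau_minus,
                tau_minus=tau_minus,
            )
            if not 0 < delta_t < T:
                labels[r, c] = RegionLabel.NOT_APPLICABLE
                continue
            g21 = net_change(delta_t, T, stdp, xi)
            g12 = net_change(T - delta_t, T, stdp, xi)
            dg_21[r, c], dg_12[r, c] = g21, g12
            labels[r, c] = _label_from_signs(g21, g12)
    return labels, dg_21, dg_12


def depression_dominates(stdp: STDPParams) -> bool:
    """Whether the STDP window is depression-dominated in the integral sense.

    ``A_plus * tau_plus < A_minus * tau_minus`` means uncorrelated
    (jittered, low-rate) firing drifts synapses downward on average — the
    condition for a decoupled state to be self-sustaining once reached.
    """
    return stdp.A_plus * stdp.tau_plus < stdp.A_minus * stdp.tau_minus
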