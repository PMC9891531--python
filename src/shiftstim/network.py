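"""Construction of the two-module network and its background drive.

Each module is a sparse, locally balanced random network of excitatory
(80%) and inhibitory (20%) leaky integrate-and-fire neurons.  Intra-module
synapses are static and instantaneous; inhibitory synapses are on average
4-fold stronger than excitatory ones, keeping each isolated module in an
inhibition-stabilized, asynchronous-irregular regime.  The two modules
interact exclusively through delayed excitatory-to-excitatory projections,
drawn independently in both directions; these long-range synapses are the
plastic substrate modified by STDP.

Weights are stored as positive magnitudes; the simulator applies the
negative sign to currents from inhibitory presynaptic cells.  All
randomness is driven by the spec's seed, so identical specs give bitwise
identical networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from shiftstim.theory import DelaySpec

__all__ = [
    "NeuronParams",
    "ModuleSpec",
    "NetworkSpec",
    "Connectivity",
    "DriveSpec",
    "build_network",
    "build_motif",
    "sample_weight_distributions",
    "make_drive",
    "calibrate_drive",
]

#: Default per-arrival external synaptic amplitudes, fixed by
#: :func:`calibrate_drive` so that an isolated module with the default
#: parameters fires irregularly at a low rate in the inhibition-stabilized
#: regime while staying close to the oscillatory instability.  Inhibitory
#: cells receive fewer input trains (6500 vs 8000) and therefore need a
#: larger per-arrival amplitude for the inhibitory feedback to engage
#: before runaway excitation; with the calibrated pair the excitatory
#: population sits at ~8 Hz with CV of inter-spike intervals ~0.9.
W_EXT_DEFAULT = 0.0225
W_EXT_IN_DEFAULT = 0.0315


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire parameters in threshold-normalized units.

    ``tau_ref`` is an absolute refractory period during which the
    membrane is clamped at reset and stimulation kicks are ignored.
    Without it the strongly coupled two-module system has no rate bound
    at all (firing at the integration-step ceiling), so a small
    biologically standard value is part of the neuron model.
    """

    tau_m: float = 10.0  # membrane time constant (ms)
    v_th: float = 1.0  # dimensionless spiking threshold
    v_r: float = 0.0  # dimensionless reset / resting potential
    tau_s: float = 5.0  # synaptic trace time constant (ms)
    tau_ref: float = 2.0  # absolute refractory period (ms)

    def __post_init__(self) -> None:
        if not self.tau_m > 0 or not self.tau_s > 0:
            raise ValueError("time constants must be positive")
        if not self.v_th > self.v_r:
            raise ValueError("v_th must exceed v_r")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be non-negative")


@dataclass(frozen=True)
class ModuleSpec:
    """One module: size, composition and intra-module coupling statistics."""

    N: int = 200
    frac_ex: float = 0.8
    p_intra: float = 0.15
    w_ex_mean: float = 0.2
    w_ex_sd: float = 0.05
    w_in_mean: float = 0.8
    w_in_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        n_ex = self.N * self.frac_ex
        if abs(n_ex - round(n_ex)) > 1e-9:
            raise ValueError("N * frac_ex must be an integer")
        if not 0 <= self.p_intra <= 1:
            raise ValueError("p_intra must lie in [0, 1]")

    @property
    def n_ex(self) -> int:
        return int(round(self.N * self.frac_ex))

    @property
    def n_in(self) -> int:
        return self.N - self.n_ex


@dataclass(frozen=True)
class NetworkSpec:
    """Full two-module architecture.

    ``w_inter_mean`` defaults to 0.8 ("pathologically strong" initial
    long-range coupling).  A variant initialised at the weak mean 0.2 is
    available as ``NetworkSpec.weak_inter()``.
    """

    module_1: ModuleSpec = field(default_factory=ModuleSpec)
    module_2: ModuleSpec = field(default_factory=ModuleSpec)
    p_inter: float = 0.15
    w_inter_mean: float = 0.8
    w_inter_sd: float = 0.05
    #: Dimensionless current scale of the long-range (inter-module)
    #: synapses: the synaptic current of a plastic synapse is
    #: ``inter_current_scale * g * s``.  The plastic weights g live on the
    #: [g_min, g_max] scale on which STDP amplitudes and coupling
    #: thresholds are defined; this calibrated constant scales the weights
    #: into currents so that the coupled system reproduces the intended
    #: dynamics (quiet irregular modules when decoupled, elevated
    #: synchronized firing when strongly coupled).  ``None`` (default)
    #: uses the calibrated per-in-degree scale 0.6 / (p_inter * N_ex),
    #: which keeps the summed long-range current per neuron invariant
    #: when the network is scaled down (0.025 for the reference module
    #: size of 200).
    inter_current_scale: float | None = None
    delays_intra: DelaySpec = field(default_factory=lambda: DelaySpec(0.0, 0.0))
    delays_inter: DelaySpec = field(default_factory=lambda: DelaySpec(0.5, 10.5))
    g_min: float = 0.05
    g_max: float = 1.00
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_inter <= 1:
            raise ValueError("p_inter must lie in [0, 1]")
        if not self.g_min < self.g_max:
            raise ValueError("g_min must be below g_max")
        if not self.g_min <= self.w_inter_mean <= self.g_max:
            raise ValueError("w_inter_mean must lie within [g_min, g_max]")
        for mod in (self.module_1, self.module_2):
            for mean in (mod.w_ex_mean, mod.w_in_mean):
                if not self.g_min <= mean <= self.g_max:
                    raise ValueError("weight means must lie within [g_min, g_max]")

    def effective_inter_scale(self) -> float:
        """Current scale actually applied to plastic synapses."""
        if self.inter_current_scale is not None:
            return self.inter_current_scale
        k_in = self.p_inter * self.module_1.n_ex
        if k_in <= 0:
            return 1.0
        return 0.6 / k_in

    @classmethod
    def weak_inter(cls, **kwargs) -> "NetworkSpec":
        """Preset with the weak initial inter-module mean (0.2)."""
        kwargs.setdefault("w_inter_mean", 0.2)
        return cls(**kwargs)

    @classmethod
    def zero_delay(cls, **kwargs) -> "NetworkSpec":
        """Preset with all transmission delays removed (xi = 0, tau = 0)."""
        kwargs.setdefault("delays_inter", DelaySpec(0.0, 0.0))
        return cls(**kwargs)

    @classmethod
    def reduced(cls, N: int = 50, **kwargs) -> "NetworkSpec":
        """Proportionally shrunk network for fast tests (same fractions/ratios)."""
        kwargs.setdefault("module_1", ModuleSpec(N=N))
        kwargs.setdefault("module_2", ModuleSpec(N=N))
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "NetworkSpec":
        data = dict(data)
        for key in ("module_1", "module_2"):
            if isinstance(data.get(key), dict):
                data[key] = ModuleSpec(**data[key])
        for key in ("delays_intra", "delays_inter"):
            if isinstance(data.get(key), dict):
                data[key] = DelaySpec(**data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "NetworkSpec":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class Connectivity:
    """Realised network: adjacency, weights, identities and the plastic mask.

    Matrix convention: entry ``[i, j]`` refers to the synapse from
    presynaptic neuron ``j`` onto postsynaptic neuron ``i``.  Weights are
    positive magnitudes; ``ei_identity`` (True = excitatory) carries the
    sign information.  ``plastic_mask`` marks exactly the inter-module
    excitatory-to-excitatory synapses; intra-module synapses are static.
    """

    adjacency: np.ndarray
    weights: np.ndarray
    plastic_mask: np.ndarray
    ei_identity: np.ndarray
    module_id: np.ndarray
    g_min: float
    g_max: float
    spec: NetworkSpec | None = None

    @property
    def n_total(self) -> int:
        return self.adjacency.shape[0]

    def module_slice(self, m: int) -> np.ndarray:
        return np.flatnonzero(self.module_id == m)

    def plastic_submask(self, direction: str) -> np.ndarray:
        """Plastic-synapse mask for one direction: '21' = module 1 -> module 2.

        Direction "nm" selects synapses from presynaptic module m onto
        postsynaptic module n (1-based module labels).
        """
        if direction not in ("21", "12"):
            raise ValueError("direction must be '21' or '12'")
        post_m = 1 if direction == "21" else 0
        pre_m = 0 if direction == "21" else 1
        mask = np.zeros_like(self.plastic_mask)
        rows = self.module_id == post_m
        cols = self.module_id == pre_m
        mask[np.ix_(rows, cols)] = self.plastic_mask[np.ix_(rows, cols)]
        return mask

    def to_edge_list(self):
        """Edge list as a DataFrame (pre_id, post_id, weight, plastic_flag)."""
        import pandas as pd

        post, pre = np.nonzero(self.adjacency)
        return pd.DataFrame(
            {
                "pre_id": pre,
                "post_id": post,
                "weight": self.weights[post, pre],
                "plastic_flag": self.plastic_mask[post, pre].astype(int),
            }
        )

    def save_npz(self, path) -> None:
        """Dense matrices in a compressed numpy archive.

        Stores adjacency, weights, plastic_mask, ei_identity, module_id
        and the weight bounds under those key names.
        """
        np.savez_compressed(
            path,
            adjacency=self.adjacency,
            weights=self.weights,
            plastic_mask=self.plastic_mask,
            ei_identity=self.ei_identity,
            module_id=self.module_id,
            g_bounds=np.array([self.g_min, self.g_max]),
        )

    @classmethod
    def load_npz(cls, path) -> "Connectivity":
        with np.load(path) as data:
            return cls(
                adjacency=data["adjacency"],
                weights=data["weights"],
                plastic_mask=data["plastic_mask"],
                ei_identity=data["ei_identity"],
                module_id=data["module_id"],
                g_min=float(data["g_bounds"][0]),
                g_max=float(data["g_bounds"][1]),
            )


@dataclass(frozen=True)
class DriveSpec:
    """Aggregate Poisson background drive.

    Each excitatory neuron receives ``n_inputs_ex`` independent Poisson
    trains (``n_inputs_in`` for inhibitory cells) at ``rate_per_input``
    spikes/s each; superposition of independent Poisson processes is
    Poisson, so the simulator draws a single aggregate train per neuron at
    ``n_inputs * rate_per_input`` Hz.  Every arrival adds ``w_ext`` to the
    neuron's external synaptic trace.
    """

    n_inputs_ex: int = 8000
    n_inputs_in: int = 6500
    rate_per_input: float = 1.0
    w_ext: float = W_EXT_DEFAULT
    w_ext_in: float | None = W_EXT_IN_DEFAULT

    def __post_init__(self) -> None:
        if self.n_inputs_ex < 0 or self.n_inputs_in < 0 or self.rate_per_input < 0:
            raise ValueError("rates must be non-negative")
        if not self.w_ext > 0:
            raise ValueError("w_ext must be positive")
        if self.w_ext_in is not None and not self.w_ext_in > 0:
            raise ValueError("w_ext_in must be positive when given")

    def amplitude(self, excitatory: bool) -> float:
        """Per-arrival amplitude for one cell class."""
        if excitatory or self.w_ext_in is None:
            return self.w_ext
        return self.w_ext_in

    def aggregate_rate_hz(self, excitatory: bool) -> float:
        n = self.n_inputs_ex if excitatory else self.n_inputs_in
        return n * self.rate_per_input


def _draw_block(rng, shape, p, mean, sd, g_min, g_max, allow_self=False):
    """Bernoulli adjacency block with clipped-Gaussian weights."""
    adj = rng.random(shape) < p
    if not allow_self and shape[0] == shape[1]:
        np.fill_diagonal(adj, False)
    w = np.clip(rng.normal(mean, sd, size=shape), g_min, g_max)
    return adj, np.where(adj, w, 0.0)


def build_network(spec: NetworkSpec) -> Connectivity:
    """Realise a two-module network from its specification.

    Adjacency is independent Bernoulli per ordered pair (Erdős–Rényi, no
    self-connections); weights are Gaussian draws clipped into
    ``[g_min, g_max]``.  Inter-module links are drawn only between
    excitatory cells, independently in both directions, and form the
    plastic mask.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    mods = (spec.module_1, spec.module_2)
    n_tot = mods[0].N + mods[1].N

    ei = np.zeros(n_tot, dtype=bool)
    module_id = np.zeros(n_tot, dtype=np.int64)
    offsets = (0, mods[0].N)
    for m, mod in enumerate(mods):
        sl = slice(offsets[m], offsets[m] + mod.N)
        module_id[sl] = m
        # excitatory neurons first within each module
        ei[offsets[m] : offsets[m] + mod.n_ex] = True

    adjacency = np.zeros((n_tot, n_tot), dtype=bool)
    weights = np.zeros((n_tot, n_tot), dtype=float)
    plastic = np.zeros((n_tot, n_tot), dtype=bool)

    # intra-module blocks: excitatory and inhibitory columns drawn separately
    for m, mod in enumerate(mods):
        sl = slice(offsets[m], offsets[m] + mod.N)
        cols_ex = np.flatnonzero(ei[sl]) + offsets[m]
        cols_in = np.flatnonzero(~ei[sl]) + offsets[m]
        a_ex, w_ex = _draw_block(
            rng, (mod.N, cols_ex.size), mod.p_intra, mod.w_ex_mean, mod.w_ex_sd,
            spec.g_min, spec.g_max,
        )
        a_in, w_in = _draw_block(
            rng, (mod.N, cols_in.size), mod.p_intra, mod.w_in_mean, mod.w_in_sd,
            spec.g_min, spec.g_max,
        )
        rows = np.arange(offsets[m], offsets[m] + mod.N)
        adjacency[np.ix_(rows, cols_ex)] = a_ex
        weights[np.ix_(rows, cols_ex)] = w_ex
        adjacency[np.ix_(rows, cols_in)] = a_in
        weights[np.ix_(rows, cols_in)] = w_in
        # self-connections were only possible inside these square-ish
        # blocks when row == col; remove explicitly
    np.fill_diagonal(adjacency, False)
    np.fill_diagonal(weights, 0.0)

    # inter-module E->E blocks, both directions independently
    for post_m, pre_m in ((1, 0), (0, 1)):
        rows = np.flatnonzero((module_id == post_m) & ei)
        cols = np.flatnonzero((module_id == pre_m) & ei)
        a, w = _draw_block(
            rng, (rows.size, cols.size), spec.p_inter, spec.w_inter_mean,
            spec.w_inter_sd, spec.g_min, spec.g_max,
        )
        adjacency[np.ix_(rows, cols)] = a
        weights[np.ix_(rows, cols)] = w
        plastic[np.ix_(rows, cols)] = a

    return Connectivity(
        adjacency=adjacency,
        weights=weights,
        plastic_mask=plastic,
        ei_identity=ei,
        module_id=module_id,
        g_min=spec.g_min,
        g_max=spec.g_max,
        spec=spec,
    )


def build_motif(
    g_21: float = 0.5,
    g_12: float = 0.5,
    delays: DelaySpec | None = None,
    g_min: float = 0.05,
    g_max: float = 1.00,
) -> Connectivity:
    """Two excitatory neurons coupled by reciprocal plastic synapses.

    Neuron 0 plays the role of module 1, neuron 1 of module 2; both
    synapses carry the inter-module delays and are plastic.
    """
    delays = delays or DelaySpec(0.5, 10.5)
    adjacency = np.array([[False, True], [True, False]])
    weights = np.array([[0.0, g_12], [g_21, 0.0]])
    spec = NetworkSpec(
        module_1=ModuleSpec(N=1, frac_ex=1.0, p_intra=0.0),
        module_2=ModuleSpec(N=1, frac_ex=1.0, p_intra=0.0),
        p_inter=1.0,
        w_inter_mean=min(max(g_21, g_min), g_max),
        delays_inter=delays,
        g_min=g_min,
        g_max=g_max,
        # a single reciprocal pair is not a population projection; its
        # synapses enter the current at full strength
        inter_current_scale=1.0,
    )
    return Connectivity(
        adjacency=adjacency,
        weights=weights,
        plastic_mask=adjacency.copy(),
        ei_identity=np.array([True, True]),
        module_id=np.array([0, 1]),
        g_min=g_min,
        g_max=g_max,
        spec=spec,
    )


def sample_weight_distributions(conn: Connectivity) -> dict:
    """Summary statistics of the drawn weight distributions.

    Returns per-class mean/sd/count for intra-module excitatory,
    intra-module inhibitory and inter-module (plastic) synapses, plus the
    inhibitory/excitatory mean ratio.
    """
    ei = conn.ei_identity
    intra = np.zeros_like(conn.adjacency)
    for m in (0, 1):
        idx = conn.module_id == m
        intra[np.ix_(idx, idx)] = conn.adjacency[np.ix_(idx, idx)]

    out = {}
    for name, mask in (
        ("intra_ex", intra & ei[None, :]),
        ("intra_in", intra & ~ei[None, :]),
        ("inter", conn.plastic_mask),
    ):
        w = conn.weights[mask]
        out[name] = {
            "mean": float(w.mean()) if w.size else np.nan,
            "sd": float(w.std(ddof=1)) if w.size > 1 else np.nan,
            "count": int(w.size),
        }
    if out["intra_ex"]["count"] and out["intra_in"]["count"]:
        out["in_ex_ratio"] = out["intra_in"]["mean"] / out["intra_ex"]["mean"]
    return out


def make_drive(
    drive: DriveSpec, ei_identity: np.ndarray, duration: float, seed: int
) -> list[np.ndarray]:
    """Aggregate Poisson arrival times per neuron over ``duration`` ms.

    Mainly a reference/diagnostic generator: the simulator draws the same
    process step-by-step for efficiency.  Each neuron's aggregate rate is
    ``n_inputs * rate_per_input`` (8000 Hz for excitatory cells with the
    defaults, 6500 Hz for inhibitory ones).
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    trains = []
    for exc in ei_identity:
        rate_ms = drive.aggregate_rate_hz(bool(exc)) / 1000.0
        n = rng.poisson(rate_ms * duration)
        trains.append(np.sort(rng.uniform(0.0, duration, size=n)))
    return trains


def calibrate_drive(
    module: ModuleSpec | None = None,
    drive: DriveSpec | None = None,
    w_ext_grid=None,
    target_rate_hz: tuple[float, float] = (2.0, 10.0),
    duration: float = 2000.0,
    seed: int = 0,
) -> dict:
    """Scan the external synaptic amplitude for the isolated-module regime.

    Simulates one isolated module for each candidate ``w_ext`` and
    records the excitatory population rate and mean single-neuron CV of
    inter-spike intervals.  Returns the scan table and the smallest
    ``w_ext`` whose excitatory rate falls inside ``target_rate_hz`` —
    low-rate irregular firing, the inhibition-stabilized operating point
    from which strong long-range excitation can still drive the coupled
    system into collective oscillation.
    """
    from shiftstim import sim as _sim
    from shiftstim import metrics as _metrics

    module = module or ModuleSpec()
    drive = drive or DriveSpec()
    if w_ext_grid is None:
        w_ext_grid = np.arange(0.018, 0.031, 0.001)

    rows = []
    chosen = None
    for w_ext in w_ext_grid:
        spec = NetworkSpec(
            module_1=module,
            module_2=ModuleSpec(N=module.N, frac_ex=module.frac_ex, p_intra=0.0),
            p_inter=0.0,
            seed=seed,
        )
        conn = build_network(spec)
        d = DriveSpec(
            n_inputs_ex=drive.n_inputs_ex,
            n_inputs_in=drive.n_inputs_in,
            rate_per_input=drive.rate_per_input,
            w_ext=float(w_ext),
        )
        cfg = _sim.SimConfig(t_total=duration, seed=seed, record_weights_every=duration)
        res = _sim.run(conn, d, [], cfg)
        m1 = conn.module_slice(0)
        ex1 = m1[conn.ei_identity[m1]]
        sel = np.isin(res.spikes.neuron_ids, ex1)
        # discard a settling transient
        t0 = min(500.0, duration / 4)
        n_spk = np.count_nonzero(sel & (res.spikes.times >= t0))
        rate = 1000.0 * n_spk / (ex1.size * (duration - t0))
        cvs = [
            _metrics.cv_isi(res.spikes, int(i), window=(t0, duration))
            for i in ex1
        ]
        cvs = [c for c in cvs if np.isfinite(c)]
        rows.append(
            {
                "w_ext": float(w_ext),
                "rate_ex_hz": rate,
                "cv_mean": float(np.mean(cvs)) if cvs else np.nan,
            }
        )
        if chosen is None and target_rate_hz[0] <= rate <= target_rate_hz[1]:
            chosen = float(w_ext)
    return {"scan": rows, "w_ext": chosen}
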