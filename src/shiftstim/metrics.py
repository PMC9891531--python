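"""Coupling, synchrony and irregularity measures for spike/weight records.

All analysis quantities used to characterise the network state before and
after stimulation: inter-population mean coupling, population activity,
pairwise spike-count correlations, coefficient of variation of
inter-spike intervals, population Fano factor, spectral peak of the
population activity, inter-module phase lags, and the thresholded binary
topology of the plastic weight matrix.  Default analysis windows are
10 s, the duration over which before/after comparisons are evaluated.

Bin widths (population activity 1 ms, correlations 50 ms, Fano factor
5 ms) are package defaults, exposed on every function; reported metrics
should always be quoted together with the bin used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

__all__ = [
    "MetricsReport",
    "TopologySummary",
    "mean_coupling",
    "population_activity",
    "pairwise_correlations",
    "cv_isi",
    "pff",
    "peak_frequency",
    "phase_lags",
    "threshold_topology",
    "report",
]

#: Default before/after analysis window length (ms).
DEFAULT_WINDOW_MS = 10_000.0


def mean_coupling(
    weights: np.ndarray,
    plastic_mask: np.ndarray,
    n_module: int | None = None,
    normalization: str = "per_edge",
) -> float:
    """Mean inter-population coupling over one direction's plastic synapses.

    Parameters
    ----------
    weights, plastic_mask : ndarray
        Weight matrix and the boolean mask of the direction's plastic
        synapses (e.g. ``Connectivity.plastic_submask("21")``).
    n_module : int, optional
        Neurons per module; required for ``normalization="per_neuron"``.
    normalization : {"per_edge", "per_neuron"}
        ``per_edge`` returns the average plastic synaptic strength — the
        scale on which the weight bounds and the stability threshold are
        defined.  ``per_neuron`` divides the summed strength by the
        module size instead, so the value scales with connection density.
    """
    if not plastic_mask.any():
        raise ValueError("empty plastic mask")
    w = weights[plastic_mask]
    if normalization == "per_edge":
        return float(w.mean())
    if normalization == "per_neuron":
        if n_module is None:
            raise ValueError("n_module required for per_neuron normalization")
        return float(w.sum() / n_module)
    raise ValueError("normalization must be 'per_edge' or 'per_neuron'")


def population_activity(
    spikes, n_neurons: int, bin_ms: float = 1.0, window=None
):
    """Fraction of the population firing per time bin.

    Returns ``(bin_centers_ms, activity)`` where activity is the spike
    count per bin divided by ``n_neurons``.
    """
    if not bin_ms > 0:
        raise ValueError("bin width must be positive")
    times = spikes.times if hasattr(spikes, "times") else np.asarray(spikes)
    if window is None:
        t0 = 0.0
        t1 = float(times.max()) + bin_ms if times.size else bin_ms
    else:
        t0, t1 = window
    edges = np.arange(t0, t1 + bin_ms * 0.5, bin_ms)
    if edges.size < 2:
        raise ValueError("degenerate window")
    counts, _ = np.histogram(times, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / n_neurons


def _binned_counts(spikes, neuron_ids, bin_ms, window):
    t0, t1 = window
    edges = np.arange(t0, t1 + bin_ms * 0.5, bin_ms)
    mat = np.empty((len(neuron_ids), edges.size - 1))
    for k, nid in enumerate(neuron_ids):
        t = spikes.times[spikes.neuron_ids == nid]
        mat[k], _ = np.histogram(t, bins=edges)
    return mat


def pairwise_correlations(
    spikes,
    neuron_ids,
    bin_ms: float = 50.0,
    window=None,
    max_pairs: int | None = 20_000,
    seed: int = 0,
) -> np.ndarray:
    """Pearson correlations of binned spike counts over sampled pairs.

    Neurons with zero count variance in the window are excluded.  All
    pairs are used when their number does not exceed ``max_pairs``;
    otherwise a seeded random subsample is drawn.
    """
    if window is None:
        window = (0.0, float(spikes.times.max()) + bin_ms if spikes.times.size else bin_ms)
    if window[1] - window[0] <= bin_ms:
        raise ValueError("window too short for the requested bin width")
    neuron_ids = np.asarray(neuron_ids)
    counts = _binned_counts(spikes, neuron_ids, bin_ms, window)
    keep = counts.std(axis=1) > 0
    counts = counts[keep]
    n = counts.shape[0]
    if n < 2:
        return np.empty(0)
    corr = np.corrcoef(counts)
    iu, ju = np.triu_indices(n, k=1)
    vals = corr[iu, ju]
    if max_pairs is not None and vals.size > max_pairs:
        rng = np.random.default_rng(seed)
        vals = rng.choice(vals, size=max_pairs, replace=False)
    return vals


def cv_isi(spikes, neuron_id: int, window=None) -> float:
    """Coefficient of variation of one neuron's inter-spike intervals.

    Returns NaN (undefined marker) when fewer than three spikes fall in
    the window; such neurons are excluded from histograms.
    """
    t = spikes.times[spikes.neuron_ids == neuron_id]
    if window is not None:
        t = t[(t >= window[0]) & (t < window[1])]
    if t.size < 3:
        return float("nan")
    isi = np.diff(np.sort(t))
    mu = isi.mean()
    if mu == 0:
        return float("nan")
    return float(isi.std(ddof=0) / mu)


def pff(activity: np.ndarray) -> float:
    """Population Fano factor: variance / mean of the population activity.

    Near zero for asynchronous firing (constant activity), growing with
    the amplitude of collective oscillations; raises on zero-mean
    activity where the ratio is undefined.
    """
    activity = np.asarray(activity, dtype=float)
    mu = activity.mean()
    if mu == 0:
        raise ValueError("zero-mean activity: population Fano factor undefined")
    return float(activity.var() / mu)


def peak_frequency(
    activity: np.ndarray,
    bin_ms: float = 1.0,
    band_hz: tuple[float, float] = (1.0, 100.0),
) -> float:
    """Dominant frequency (Hz) of the mean-subtracted population activity.

    Searches the magnitude spectrum inside ``band_hz``.  Returns NaN when
    the spectrum carries no power in the band (flat/empty activity); for
    broadband (noise-like) activity the argmax is reported but is not a
    stable statistic.
    """
    activity = np.asarray(activity, dtype=float)
    n = activity.size
    if n * bin_ms < 1000.0:
        raise ValueError("window shorter than 1 s: sub-Hz resolution unavailable")
    spec = np.abs(np.fft.rfft(activity - activity.mean()))
    freqs = np.fft.rfftfreq(n, d=bin_ms / 1000.0)
    band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    # guard against pure float residue of a constant series
    floor = 1e-9 * max(1.0, float(np.abs(activity).max())) * n
    if not band.any() or spec[band].max() <= floor:
        return float("nan")
    return float(freqs[band][np.argmax(spec[band])])


def phase_lags(
    activity_1: np.ndarray,
    activity_2: np.ndarray,
    bin_ms: float = 1.0,
    smooth_ms: float = 5.0,
) -> np.ndarray:
    """Per-cycle phase lags between the collective discharges of two modules.

    Peaks of the (moving-average smoothed) population activities are
    detected; each peak of module 2 is mapped to the phase of module 1's
    concurrent cycle, giving one lag in [0, 2*pi) per cycle.  Raises when
    either series has fewer than two detectable peaks.
    """
    def peaks(a):
        a = np.asarray(a, dtype=float)
        k = max(int(round(smooth_ms / bin_ms)), 1)
        if k > 1:
            a = np.convolve(a, np.ones(k) / k, mode="same")
        height = a.mean() + 0.5 * a.std()
        idx, _ = _signal.find_peaks(a, height=height, distance=max(k, 2))
        return idx * bin_ms

    p1, p2 = peaks(activity_1), peaks(activity_2)
    if p1.size < 2 or p2.size < 2:
        raise ValueError("no detectable oscillation peaks in window")
    period = float(np.median(np.diff(p1)))
    lags = []
    for t2 in p2:
        k = np.searchsorted(p1, t2, side="right") - 1
        if 0 <= k < p1.size:
            lags.append(((t2 - p1[k]) / period) * 2 * np.pi % (2 * np.pi))
    return np.asarray(lags)


@dataclass
class TopologySummary:
    """Binary topology of a weight matrix above a strength threshold."""

    threshold: float
    binary: np.ndarray
    in_degree: np.ndarray
    out_degree: np.ndarray


def threshold_topology(weights: np.ndarray, h: float = 0.3,
                       mask: np.ndarray | None = None) -> TopologySummary:
    """Binarise ``weights`` at threshold ``h`` and summarise degrees.

    A link is kept when its weight is at least ``h``; with ``mask`` the
    binarisation is restricted to the masked synapses (e.g. the plastic
    inter-module block).
    """
    binary = weights >= h
    if mask is not None:
        binary = binary & mask
    return TopologySummary(
        threshold=h,
        binary=binary,
        in_degree=binary.sum(axis=1),
        out_degree=binary.sum(axis=0),
    )


@dataclass
class MetricsReport:
    """Bundle of the standard per-window analysis quantities."""

    window: tuple[float, float]
    G_ave: dict = field(default_factory=dict)
    pff: dict = field(default_factory=dict)
    corr_mean: dict = field(default_factory=dict)
    cv_mean: dict = field(default_factory=dict)
    peak_freq: dict = field(default_factory=dict)
    bins: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "window_ms": list(self.window),
            "G_ave": self.G_ave,
            "pff": self.pff,
            "corr_mean": self.corr_mean,
            "cv_mean": self.cv_mean,
            "peak_freq_hz": self.peak_freq,
            "bins_ms": self.bins,
        }


def report(
    result,
    window,
    activity_bin_ms: float = 1.0,
    corr_bin_ms: float = 50.0,
    pff_bin_ms: float = 5.0,
    max_corr_neurons: int = 200,
    seed: int = 0,
) -> MetricsReport:
    """Standard analysis of a :class:`~shiftstim.sim.SimResult` window.

    Computes, per module: population Fano factor, mean pairwise
    correlation, mean CV of inter-spike intervals and the spectral peak;
    plus the time-averaged mean coupling per direction over the window.
    """
    conn = result.connectivity
    rep = MetricsReport(
        window=tuple(window),
        bins={"activity": activity_bin_ms, "corr": corr_bin_ms, "pff": pff_bin_ms},
    )
    in_win = (result.snapshot_times >= window[0]) & (result.snapshot_times <= window[1])
    for direction, series in (("21", result.g21_series), ("12", result.g12_series)):
        vals = series[in_win]
        rep.G_ave[direction] = float(np.nanmean(vals)) if vals.size else float("nan")
    for m in (0, 1):
        idx = conn.module_slice(m)
        rec = result.spikes.select(module=m, window=window)
        _, act_pff = population_activity(rec, idx.size, pff_bin_ms, window)
        try:
            rep.pff[str(m + 1)] = pff(act_pff)
        except ValueError:
            rep.pff[str(m + 1)] = float("nan")
        _, act = population_activity(rec, idx.size, activity_bin_ms, window)
        try:
            rep.peak_freq[str(m + 1)] = peak_frequency(act, activity_bin_ms)
        except ValueError:
            rep.peak_freq[str(m + 1)] = float("nan")
        sample = idx if idx.size <= max_corr_neurons else np.random.default_rng(
            seed
        ).choice(idx, size=max_corr_neurons, replace=False)
        try:
            corr = pairwise_correlations(
                result.spikes, sample, corr_bin_ms, window, seed=seed
            )
            rep.corr_mean[str(m + 1)] = float(corr.mean()) if corr.size else float("nan")
        except ValueError:
            rep.corr_mean[str(m + 1)] = float("nan")
        cvs = [cv_isi(result.spikes, int(i), window) for i in idx]
        cvs = [c for c in cvs if np.isfinite(c)]
        rep.cv_mean[str(m + 1)] = float(np.mean(cvs)) if cvs else float("nan")
    return rep
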