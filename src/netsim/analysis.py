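"""Post-simulation statistics and figures.

Numerical results are always computed and returned separately from any
figure; plotting helpers render to files and never need to be parsed
back.  All statistics are pure functions of the simulation output and
the instantiated network.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

__all__ = [
    "spike_stats", "golomb_synchrony", "isi_cv", "rate_psd",
    "spectrogram", "connectivity_matrix",
    "plot_raster", "plot_rate_stats", "plot_psd", "plot_spectrogram",
    "plot_lfp", "plot_connectivity",
]

DEFAULT_BIN_MS = 5.0


def isi_cv(times):
    """Coefficient of variation of inter-spike intervals.

    NaN for cells with fewer than 3 spikes (fewer than 2 intervals do
    not define a spread).
    """
    times = np.asarray(times, dtype=float)
    if len(times) < 3:
        return float("nan")
    isi = np.diff(np.sort(times))
    m = isi.mean()
    return float(isi.std(ddof=0) / m) if m > 0 else float("nan")


def _binned_counts(trains, duration, bin_ms):
    edges = np.arange(0.0, duration + bin_ms, bin_ms)
    return np.array([np.histogram(t, bins=edges)[0] for t in trains],
                    dtype=float)


def golomb_synchrony(trains, duration, bin_ms=DEFAULT_BIN_MS):
    """Population synchrony: variance of the population-mean binned
    rate divided by the mean single-cell variance.

    1 for identical spike trains; ~1/N for N independent trains; NaN
    when undefined (no cell fires or a single cell).
    """
    trains = [np.asarray(t, dtype=float) for t in trains]
    if len(trains) < 2 or all(len(t) == 0 for t in trains):
        return float("nan")
    counts = _binned_counts(trains, duration, bin_ms)
    per_cell_var = counts.var(axis=1, ddof=0)
    denom = per_cell_var.mean()
    if denom == 0:
        return float("nan")
    return float(counts.mean(axis=0).var(ddof=0) / denom)


def spike_stats(output, pops, duration, bin_ms=DEFAULT_BIN_MS):
    """Per-population firing statistics.

    ``output`` is a SimOutput dict (or any mapping with spkt/spkid);
    ``pops`` maps population name -> {'cellGids': [...]}.  Returns per
    population: mean/median rate (Hz), rate quartiles, per-cell ISI CV
    list, and the synchrony index.
    """
    spikes = {}
    for t, g in zip(output["spkt"], output["spkid"]):
        spikes.setdefault(int(g), []).append(float(t))
    secs = duration / 1000.0
    stats = {}
    for pname, pop in pops.items():
        gids = pop["cellGids"] if isinstance(pop, dict) else list(pop)
        trains = [spikes.get(g, []) for g in gids]
        rates = np.array([len(t) / secs for t in trains]) \
            if gids else np.zeros(0)
        cvs = [isi_cv(t) for t in trains]
        stats[pname] = {
            "rates": [float(r) for r in rates],
            "meanRate": float(rates.mean()) if len(rates) else 0.0,
            "medianRate": float(np.median(rates)) if len(rates) else 0.0,
            "rateQuartiles": [float(q) for q in np.percentile(
                rates, [25, 50, 75])] if len(rates) else [0.0] * 3,
            "isiCV": cvs,
            "synchrony": golomb_synchrony(trains, duration, bin_ms),
        }
    return stats


def binned_rate(spike_times, duration, bin_ms, n_cells=1):
    """Population firing rate signal (Hz) on a regular time grid."""
    edges = np.arange(0.0, duration + bin_ms, bin_ms)
    counts, _ = np.histogram(np.asarray(spike_times, dtype=float),
                             bins=edges)
    return counts / n_cells / (bin_ms / 1000.0)


def rate_psd(x=None, spike_times=None, duration=None, bin_ms=DEFAULT_BIN_MS,
             fs=None, segment_s=1.0, n_cells=1):
    """Welch power spectral density of a rate signal or recorded trace.

    Either pass a signal ``x`` with its sampling rate ``fs`` (Hz), or
    spike times with the total ``duration`` (ms) to analyze the binned
    population rate.  Hann window, 50% overlap; density scaling so the
    integral of the PSD approximates the signal variance.
    """
    if x is None:
        if spike_times is None or duration is None:
            raise ValueError("need x+fs or spike_times+duration")
        x = binned_rate(spike_times, duration, bin_ms, n_cells)
        fs = 1000.0 / bin_ms
    x = np.asarray(x, dtype=float)
    if fs is None:
        raise ValueError("fs is required with an explicit signal")
    nperseg = int(round(segment_s * fs))
    if len(x) < nperseg:
        raise ValueError(
            f"signal ({len(x)} samples) shorter than one Welch segment "
            f"({nperseg} samples)")
    freqs, psd = sps.welch(x - x.mean(), fs=fs, window="hann",
                           nperseg=nperseg, noverlap=nperseg // 2,
                           detrend=False, scaling="density")
    return freqs, psd


def spectrogram(x, fs, window_ms=500.0, overlap=0.5):
    """Short-time Fourier magnitude² of a signal.

    Returns (times s, freqs Hz, S) with S of shape (freqs, times);
    column count floor((T - w)/hop) + 1.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_ms / 1000.0 * fs))
    if nperseg > len(x):
        raise ValueError("window longer than the signal")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap fraction must be in [0, 1)")
    noverlap = int(nperseg * overlap)
    freqs, times, S = sps.spectrogram(
        x - x.mean(), fs=fs, window="hann", nperseg=nperseg,
        noverlap=noverlap, detrend=False, mode="magnitude")
    return times, freqs, S ** 2


def connectivity_matrix(network, group_by="pop", value="count"):
    """Connection count (or mean weight) matrix.

    ``group_by='pop'``: entry (i, j) aggregates connections from
    population i to population j, in declaration order.
    ``group_by='cell'``: |cells|² matrix in gid order.
    Returns (matrix, labels).
    """
    if group_by == "pop":
        labels = list(network.pops)
        index = {}
        for pi, pname in enumerate(labels):
            for g in network.pops[pname]["cellGids"]:
                index[g] = pi
    else:
        labels = [c.gid for c in network.cells]
        index = {g: i for i, g in enumerate(labels)}
    n = len(labels)
    counts = np.zeros((n, n))
    weights = np.zeros((n, n))
    for conn in network.conns:
        i, j = index[conn.preGid], index[conn.postGid]
        counts[i, j] += 1
        weights[i, j] += conn.weight
    if value == "count":
        return counts, labels
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_w = np.where(counts > 0, weights / np.maximum(counts, 1), 0.0)
    return mean_w, labels


# ---------------------------------------------------------------------------
# figures (render to file; numbers live in the functions above)

def _savefig(fig, path):
    fig.savefig(path, dpi=120, bbox_inches="tight")
    import matplotlib.pyplot as plt
    plt.close(fig)
    return path


def plot_raster(output, pops=None, path="raster.png"):
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(output["spkt"], output["spkid"], ".", ms=2)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("cell gid")
    ax.set_title("spike raster")
    return _savefig(fig, path)


def plot_rate_stats(stats, path="rates.png"):
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4))
    names = list(stats)
    ax.boxplot([stats[p]["rates"] for p in names], tick_labels=names)
    ax.set_ylabel("firing rate (Hz)")
    return _savefig(fig, path)


def plot_psd(freqs, psd, path="psd.png", label=None):
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.semilogy(freqs, np.maximum(psd, 1e-300), label=label)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("power density")
    if label:
        ax.legend()
    return _savefig(fig, path)


def plot_spectrogram(times, freqs, S, path="spectrogram.png"):
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.pcolormesh(times, freqs, np.log10(np.maximum(S, 1e-300)),
                  shading="auto")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    return _savefig(fig, path)


def plot_lfp(output, path="lfp.png"):
    import matplotlib.pyplot as plt
    lfp = np.asarray(output.get("lfp", []))
    fig, ax = plt.subplots(figsize=(8, 4))
    t = output["t"]
    for e, row in enumerate(lfp):
        span = np.ptp(row) or 1.0
        ax.plot(t, row / span + e, lw=0.7)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("electrode")
    return _savefig(fig, path)


def plot_connectivity(matrix, labels, path="connectivity.png"):
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(np.asarray(matrix), cmap="viridis")
    ax.set_xticks(range(len(labels)), labels)
    ax.set_yticks(range(len(labels)), labels)
    ax.set_xlabel("post")
    ax.set_ylabel("pre")
    fig.colorbar(im, ax=ax)
    return _savefig(fig, path)
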