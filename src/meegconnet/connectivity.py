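"""Pairwise functional connectivity between channel or ROI time series.

Four estimators, all symmetric with a zero diagonal:

* ``xcorr`` — maximum absolute normalized cross-correlation over lags,
  per trial, trial-averaged; in [0, 1].
* ``plv`` — phase locking value computed over time within each trial from
  analytic-signal phases, trial-averaged; in [0, 1].
* ``mpc`` — mean phase coherence, |mean_t exp(i * dphi(t))| per trial,
  trial-averaged. With analytic-signal phase extraction this is the same
  statistic as within-trial PLV; both names are kept because both are
  established in the field.
* ``mi`` — histogram mutual information in bits with Miller-Madow bias
  correction, pooled over trials.

``plv_intertrial`` is the classic multi-trial variant: phase differences
are averaged across trials at each instant, giving a time-resolved
(Ns x Nc x Nc) coupling estimate that requires several trials.

Phase-based estimators assume band-limited input (filter first, e.g.
30-45 Hz for low gamma) and trim 5% of samples at each end to suppress
Hilbert-transform edge artifacts. Sliding-window application of any static
estimator yields a :class:`DynamicConnectivity`, which k-means can segment
into recurring connectivity states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert
from sklearn.cluster import KMeans

from .data_io import ConnectivityMatrix, DynamicConnectivity, Recording
from .errors import EstimatorError, ParameterError

logger = logging.getLogger("meegconnet")

__all__ = [
    "xcorr_matrix", "plv_static", "mpc_matrix", "mi_matrix",
    "plv_intertrial", "plv_intertrial_static", "sliding_window",
    "segment_states", "static_fc", "StateSegmentation", "EDGE_TRIM",
]

#: fraction of samples dropped at each end before phase averaging
EDGE_TRIM = 0.05


def _trim_slice(ns: int, frac: float = EDGE_TRIM) -> slice:
    cut = int(np.floor(ns * frac))
    return slice(cut, ns - cut if cut else ns)


def _phases(data: np.ndarray) -> np.ndarray:
    """Instantaneous phase per channel/trial via the analytic signal."""
    return np.angle(hilbert(data, axis=1))


def _finalize(values: np.ndarray) -> np.ndarray:
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    return values


def xcorr_matrix(rec: Recording, max_lag: int | None = None) -> ConnectivityMatrix:
    """Max-|normalized cross-correlation| over lags within +-max_lag.

    Signals are mean-removed per trial; the per-trial maxima are averaged
    across trials (preserving per-trial lag structure). Zero-variance
    channels get 0 with a warning.
    """
    nc, ns, nt = rec.data.shape
    if max_lag is None:
        max_lag = ns - 1
    max_lag = int(max_lag)
    if not 0 <= max_lag < ns:
        raise ParameterError(f"max_lag must lie in [0, {ns})")
    out = np.zeros((nc, nc))
    x = rec.data - rec.data.mean(axis=1, keepdims=True)
    norm = np.sqrt(np.sum(x ** 2, axis=1))  # (Nc, Nt)
    flat = norm == 0
    if flat.any():
        logger.warning(
            "zero-variance channel/trial(s) in xcorr; their pairs are set to 0"
        )
    nfft = int(2 ** np.ceil(np.log2(2 * ns - 1)))
    X = np.fft.rfft(x, n=nfft, axis=1)  # (Nc, F, Nt)
    lag_keep = np.r_[np.arange(0, max_lag + 1), np.arange(nfft - max_lag, nfft)]
    for i in range(nc):
        for j in range(i + 1, nc):
            acc = 0.0
            n_ok = 0
            for t in range(nt):
                if flat[i, t] or flat[j, t]:
                    continue
                cc = np.fft.irfft(X[i, :, t] * np.conj(X[j, :, t]), n=nfft)
                peak = np.abs(cc[lag_keep]).max() / (norm[i, t] * norm[j, t])
                acc += min(peak, 1.0)
                n_ok += 1
            out[i, j] = acc / n_ok if n_ok else 0.0
    return ConnectivityMatrix(
        _finalize(out + out.T), method="xcorr",
        node_labels=list(rec.channel_labels),
    )


def _phase_locking(rec: Recording, method: str) -> ConnectivityMatrix:
    nc, ns, nt = rec.data.shape
    keep = _trim_slice(ns)
    z = np.exp(1j * _phases(rec.data))[:, keep, :]  # (Nc, T, Nt)
    T = z.shape[1]
    # |mean_t z_i z_j*| per trial, then trial mean
    vals = np.abs(np.einsum("ist,jst->ijt", z, z.conj())) / T
    out = vals.mean(axis=2)
    return ConnectivityMatrix(
        _finalize(np.clip(out, 0.0, 1.0)), method=method,
        node_labels=list(rec.channel_labels),
    )


def plv_static(rec: Recording) -> ConnectivityMatrix:
    """Within-trial PLV over time, averaged across trials."""
    return _phase_locking(rec, "plv")


def mpc_matrix(rec: Recording) -> ConnectivityMatrix:
    """Mean phase coherence (time-domain phase-difference consistency)."""
    return _phase_locking(rec, "mpc")


def plv_intertrial(rec: Recording) -> np.ndarray:
    """Inter-trial PLV, shape (Ns, Nc, Nc).

    PLV(t, i, j) = |1/Nt * sum_trials exp(i(phi_i(t) - phi_j(t)))|.
    Requires several trials; use :func:`plv_static` for single-trial data.
    """
    if rec.n_trials < 2:
        raise EstimatorError(
            "inter-trial PLV needs Nt >= 2; for single-trial data use "
            "plv_static (PLV over time within the trial)"
        )
    z = np.exp(1j * _phases(rec.data))  # (Nc, Ns, Nt)
    vals = np.abs(np.einsum("ist,jst->sij", z, z.conj())) / rec.n_trials
    vals = 0.5 * (vals + np.swapaxes(vals, 1, 2))
    idx = np.arange(rec.n_channels)
    vals[:, idx, idx] = 0.0
    return np.clip(vals, 0.0, 1.0)


def plv_intertrial_static(rec: Recording) -> ConnectivityMatrix:
    """Time-averaged inter-trial PLV as a static matrix (edges trimmed)."""
    vals = plv_intertrial(rec)
    keep = _trim_slice(vals.shape[0])
    return ConnectivityMatrix(
        _finalize(vals[keep].mean(axis=0)), method="plv_intertrial",
        node_labels=list(rec.channel_labels),
    )


def default_mi_bins(n_obs: int) -> int:
    return int(min(64, max(2, np.ceil(np.sqrt(n_obs / 5)))))


def mi_matrix(rec: Recording, n_bins: int | None = None) -> ConnectivityMatrix:
    """Histogram mutual information in bits, pooled over time and trials.

    Miller-Madow bias correction is applied and negative corrected values
    are clipped to zero. Default bin count ceil(sqrt(N/5)), capped at 64.
    """
    nc = rec.n_channels
    n_obs = rec.n_samples * rec.n_trials
    if n_bins is None:
        n_bins = default_mi_bins(n_obs)
    n_bins = int(n_bins)
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    if n_obs < 5 * n_bins ** 2:
        logger.warning(
            "MI with %d bins on only %d samples is noisy (recommend "
            ">= %d samples)", n_bins, n_obs, 5 * n_bins ** 2,
        )
    x = rec.data.reshape(nc, n_obs)
    out = np.zeros((nc, nc))
    ln2 = np.log(2.0)
    for i in range(nc):
        for j in range(i + 1, nc):
            h, _, _ = np.histogram2d(x[i], x[j], bins=n_bins)
            p = h / n_obs
            px = p.sum(axis=1)
            py = p.sum(axis=0)
            nz = p > 0
            mi = np.sum(
                p[nz] * np.log(p[nz] / np.outer(px, py)[nz])
            ) / ln2
            kx = int((px > 0).sum())
            ky = int((py > 0).sum())
            kxy = int(nz.sum())
            mi += (kx + ky - kxy - 1) / (2.0 * n_obs * ln2)
            out[i, j] = max(mi, 0.0)
    return ConnectivityMatrix(
        _finalize(out + out.T), method="mi",
        node_labels=list(rec.channel_labels),
    )


_STATIC_METHODS = {
    "xcorr": xcorr_matrix,
    "plv": plv_static,
    "mpc": mpc_matrix,
    "mi": mi_matrix,
    "plv_intertrial": plv_intertrial_static,
}


def static_fc(rec: Recording, method: str, **method_args) -> ConnectivityMatrix:
    """Dispatch to a static connectivity estimator by name."""
    try:
        fn = _STATIC_METHODS[method]
    except KeyError:
        raise ParameterError(
            f"unknown connectivity method {method!r}; expected one of "
            f"{sorted(_STATIC_METHODS)}"
        )
    return fn(rec, **method_args)


def sliding_window(
    rec: Recording, method: str, window: int, step: int, **method_args
) -> DynamicConnectivity:
    """Apply a static estimator in sliding windows.

    Nw = floor((Ns - window)/step) + 1 windows of ``window`` samples
    starting every ``step`` samples.
    """
    window, step = int(window), int(step)
    if window > rec.n_samples:
        raise ParameterError(
            f"window of {window} samples exceeds signal length {rec.n_samples}"
        )
    if window < 2:
        raise ParameterError("window must be >= 2 samples")
    if step < 1:
        raise ParameterError("step must be >= 1")
    starts = np.arange(0, rec.n_samples - window + 1, step)
    slices = np.empty((len(starts), rec.n_channels, rec.n_channels))
    band = None
    for w, s in enumerate(starts):
        sub = rec.with_data(rec.data[:, s:s + window, :], baseline_span=None,
                            onset_index=None)
        cm = static_fc(sub, method, **method_args)
        slices[w] = cm.values
        band = cm.band
    return DynamicConnectivity(
        slices, method=method, window_starts=starts,
        window_length=window, step=step, band=band,
        node_labels=list(rec.channel_labels),
    )


@dataclass
class StateSegmentation:
    """k-means segmentation of dynamic connectivity into states."""

    labels: np.ndarray
    centroids: np.ndarray  # (K, Nc, Nc), symmetric, zero diagonal
    inertia: float

    @property
    def n_states(self) -> int:
        return self.centroids.shape[0]


def segment_states(
    dyn: DynamicConnectivity, k: int, seed: int = 0, n_init: int = 50
) -> StateSegmentation:
    """Cluster windowed connectivity matrices into k recurring states.

    k-means (k-means++ init, ``n_init`` restarts, deterministic given
    ``seed``) on the vectorized upper triangles; centroids are reassembled
    into symmetric zero-diagonal matrices.
    """
    k = int(k)
    if not 1 <= k <= dyn.n_windows:
        raise ParameterError(
            f"k must lie in [1, Nw={dyn.n_windows}], got {k}"
        )
    n = dyn.n_nodes
    iu = np.triu_indices(n, k=1)
    X = dyn.values[:, iu[0], iu[1]]
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    centroids = np.zeros((k, n, n))
    centroids[:, iu[0], iu[1]] = km.cluster_centers_
    centroids += np.swapaxes(centroids, 1, 2)
    return StateSegmentation(
        labels=labels.astype(int), centroids=centroids,
        inertia=float(km.inertia_),
    )
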