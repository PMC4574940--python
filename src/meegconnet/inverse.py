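"""Distributed inverse solutions: MNE, weighted MNE and LORETA.

Given a fixed-orientation lead field G (Nc sensors x Ndip sources) and a
noise covariance C estimated from the pre-stimulus baseline, the sensor
data are first whitened (y_w = L^-1 y with C = L L^T) and sources estimated
with the Tikhonov-regularized minimum-norm family

    s_hat = W G_w^T (G_w W G_w^T + lambda * mu * I)^-1 y_w

where W encodes the prior:

* MNE:    W = I                      (amplitude-minimal solution)
* wMNE:   W = diag(||g_i||^(-2*gamma))   (depth weighting, default
          gamma = 0.5, counteracting the bias toward superficial sources)
* LORETA: W = (B^T B)^-1 with B = I - D^-1 A, a discrete spatial Laplacian
          on the k-nearest-neighbour graph (k = 6) of the source positions
          (smoothness prior).

``mu = trace(G_w W G_w^T)/Nc`` makes lambda dimensionless; the default
lambda = 1/SNR^2 with SNR = 3 (lambda ~ 0.111) follows common practice in
minimum-norm source imaging. The same linear operator is applied to every
sample and trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .data_io import Recording, ScoutAtlas, ChannelLayout
from .errors import ParameterError, ShapeError, StateError, ValidationError

import logging

logger = logging.getLogger("meegconnet")

__all__ = [
    "LeadField", "NoiseCovariance", "InverseConfig", "SourceEstimate",
    "noise_covariance", "solve_inverse", "aggregate_rois", "toy_forward",
]


@dataclass
class LeadField:
    """Gain matrix (Nc x Ndip) for fixed-orientation sources."""

    gain: np.ndarray
    source_positions: np.ndarray

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.source_positions = np.asarray(self.source_positions, dtype=float)
        if self.gain.ndim != 2:
            raise ShapeError("gain must be 2-D (Nc, Ndip)")
        if self.source_positions.shape != (self.gain.shape[1], 3):
            raise ShapeError("source_positions must be (Ndip, 3)")
        if not np.isfinite(self.gain).all():
            raise ValidationError("non-finite gain value")
        norms = np.linalg.norm(self.gain, axis=0)
        if (norms == 0).any():
            raise ValidationError(
                f"all-zero gain column(s): {np.flatnonzero(norms == 0)[:5]}"
            )

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


@dataclass
class NoiseCovariance:
    """Symmetric PSD sensor noise covariance (Nc x Nc)."""

    cov: np.ndarray

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=float)
        n = self.cov.shape[0]
        if self.cov.shape != (n, n):
            raise ShapeError("cov must be square")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10, rtol=1e-8):
            raise ValidationError("covariance must be symmetric")
        self.cov = 0.5 * (self.cov + self.cov.T)
        w = np.linalg.eigvalsh(self.cov)
        if w.min() < -1e-10 * max(np.trace(self.cov), 1e-300):
            raise ValidationError("covariance is not positive semi-definite")

    def whitener(self) -> np.ndarray:
        """L^-1 from the Cholesky factor C = L L^T."""
        L = np.linalg.cholesky(self.cov)
        return linalg.solve_triangular(
            L, np.eye(L.shape[0]), lower=True
        )


@dataclass
class InverseConfig:
    """Inverse-operator settings.

    lambda_ >= 0 is the dimensionless Tikhonov parameter; ``snr`` (if set)
    overrides it with 1/snr^2. depth_gamma in [0, 1] is the wMNE depth
    exponent. loreta_k is the neighbour count of the Laplacian graph.
    """

    method: str = "mne"
    lambda_: float | None = None
    depth_gamma: float = 0.5
    snr: float | None = 3.0
    loreta_k: int = 6

    def __post_init__(self) -> None:
        if self.method not in ("mne", "wmne", "loreta"):
            raise ParameterError(
                f"unknown inverse method {self.method!r}; expected "
                "mne, wmne or loreta"
            )
        if self.lambda_ is None:
            snr = 3.0 if self.snr is None else float(self.snr)
            if snr <= 0:
                raise ParameterError("snr must be > 0")
            self.lambda_ = 1.0 / snr ** 2
        self.lambda_ = float(self.lambda_)
        if self.lambda_ < 0:
            raise ParameterError("lambda must be >= 0")
        if not 0 <= self.depth_gamma <= 1:
            raise ParameterError("depth_gamma must lie in [0, 1]")


@dataclass
class SourceEstimate:
    """Reconstructed source time courses, shape (Ndip, Ns, Nt)."""

    series: np.ndarray
    sfreq: float
    method: str
    source_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim == 2:
            self.series = self.series[:, :, np.newaxis]
        if self.series.ndim != 3:
            raise ShapeError("series must be (Ndip, Ns, Nt)")
        if not np.isfinite(self.series).all():
            raise ValidationError("non-finite source estimate")

    @property
    def n_sources(self) -> int:
        return self.series.shape[0]

    @property
    def n_samples(self) -> int:
        return self.series.shape[1]

    @property
    def n_trials(self) -> int:
        return self.series.shape[2]


def noise_covariance(rec: Recording) -> NoiseCovariance:
    """Empirical sensor covariance over the baseline span, pooled across
    trials, with diagonal loading eps = 1e-6 * mean(diag).

    The baseline must have been set (see :func:`preprocess.set_baseline`);
    spans shorter than the channel count yield a rank-deficient estimate
    and trigger a warning.
    """
    if rec.baseline_span is None:
        raise StateError(
            "no baseline span set; call set_baseline() before "
            "noise_covariance()"
        )
    s, e = rec.baseline_span
    seg = rec.data[:, s:e, :]  # (Nc, Nb, Nt)
    n_obs = seg.shape[1] * seg.shape[2]
    if seg.shape[1] < rec.n_channels:
        logger.warning(
            "baseline span of %d samples is shorter than the %d channels; "
            "covariance estimate will be poorly conditioned",
            seg.shape[1], rec.n_channels,
        )
    x = seg.reshape(rec.n_channels, n_obs)
    x = x - x.mean(axis=1, keepdims=True)
    cov = (x @ x.T) / max(n_obs - 1, 1)
    cov[np.diag_indices_from(cov)] += 1e-6 * np.mean(np.diag(cov))
    return NoiseCovariance(cov)


def _loreta_weight(positions: np.ndarray, k: int) -> np.ndarray:
    """(B^T B)^-1 for B = I - D^-1 A on the symmetrized kNN graph."""
    n = positions.shape[0]
    k = min(k, n - 1)
    d2 = np.sum((positions[:, None, :] - positions[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    A = np.zeros((n, n))
    for i in range(n):
        A[i, np.argsort(d2[i])[:k]] = 1.0
    A = np.maximum(A, A.T)  # symmetrize neighbourhoods
    deg = A.sum(axis=1)
    deg[deg == 0] = 1.0
    B = np.eye(n) - A / deg[:, None]
    BtB = B.T @ B
    # B annihilates locally-constant fields; ridge keeps the prior invertible
    BtB[np.diag_indices_from(BtB)] += 1e-8 * np.trace(BtB) / n
    return np.linalg.inv(BtB)


def compute_inverse_operator(
    lf: LeadField, cov: NoiseCovariance, cfg: InverseConfig
) -> np.ndarray:
    """The (Ndip x Nc) linear operator K mapping whitened-domain data to
    source amplitudes; apply to raw data as ``K @ whitener @ y``."""
    Wh = cov.whitener()
    Gw = Wh @ lf.gain
    nc, nd = Gw.shape
    if cfg.method == "mne":
        WGt = Gw.T
        GWGt = Gw @ Gw.T
    elif cfg.method == "wmne":
        norms = np.linalg.norm(lf.gain, axis=0)
        w = norms ** (-2.0 * cfg.depth_gamma)
        WGt = w[:, None] * Gw.T
        GWGt = Gw @ WGt
    else:  # loreta
        W = _loreta_weight(lf.source_positions, cfg.loreta_k)
        WGt = W @ Gw.T
        GWGt = Gw @ WGt
    mu = np.trace(GWGt) / nc
    M = GWGt + cfg.lambda_ * mu * np.eye(nc)
    if cfg.lambda_ == 0:
        rank = np.linalg.matrix_rank(M)
        if rank < nc:
            raise ParameterError(
                "gram matrix is singular at lambda = 0; use lambda > 0"
            )
    return WGt @ np.linalg.inv(M)


def solve_inverse(
    rec: Recording, lf: LeadField, cov: NoiseCovariance, cfg: InverseConfig
) -> SourceEstimate:
    """Estimate source time courses from sensor data.

    The operator is computed once and reused across all samples and trials
    (it is linear in the data).
    """
    if lf.n_channels != rec.n_channels:
        raise ShapeError(
            f"lead field has {lf.n_channels} channels, recording has "
            f"{rec.n_channels}"
        )
    if cov.cov.shape[0] != rec.n_channels:
        raise ShapeError("covariance does not match channel count")
    K = compute_inverse_operator(lf, cov, cfg)
    Wh = cov.whitener()
    KW = K @ Wh
    nc, ns, nt = rec.data.shape
    series = np.einsum("dc,cst->dst", KW, rec.data)
    return SourceEstimate(
        series, sfreq=rec.sfreq, method=cfg.method,
        source_positions=lf.source_positions,
    )


def aggregate_rois(src: SourceEstimate, atlas: ScoutAtlas) -> Recording:
    """Collapse source time courses into one trace per ROI.

    The ROI trace is the mean of its member sources after sign alignment:
    members anti-correlated with the ROI's first principal direction are
    flipped before averaging, so symmetric dipole orientations do not
    cancel. The output Recording carries roi labels as channels; its
    metadata records the aggregation convention.
    """
    atlas.validate_against(src.n_sources)
    ns, nt = src.n_samples, src.n_trials
    out = np.empty((atlas.n_rois, ns, nt))
    for r, members in enumerate(atlas.roi_members):
        block = src.series[members]  # (m, Ns, Nt)
        m = block.shape[0]
        if m == 1:
            out[r] = block[0]
            continue
        flat = block.reshape(m, ns * nt)
        centered = flat - flat.mean(axis=1, keepdims=True)
        # first left-singular vector = principal direction across members
        u = np.linalg.svd(centered, full_matrices=False)[0][:, 0]
        signs = np.where(u >= 0, 1.0, -1.0)
        if signs.sum() < 0:  # orient the PC with the member majority
            signs = -signs
        out[r] = np.tensordot(signs, block, axes=(0, 0)) / m
    rec = Recording(
        out, sfreq=src.sfreq, channel_labels=list(atlas.roi_labels)
    )
    return rec


def toy_forward(
    layout: ChannelLayout, n_sources: int, seed: int = 0,
    source_radius: float = 0.7,
) -> LeadField:
    """Spherical test lead field: sensors on the unit sphere, sources on an
    inner sphere, gain decaying with inverse squared distance.

    Deterministic given the seed. This is a synthetic fixture for tests and
    simulations; realistic lead fields come from BEM/FEM tools and are
    supplied as inputs.
    """
    if n_sources < 1:
        raise ParameterError("n_sources must be >= 1")
    rng = np.random.default_rng(seed)
    sens = np.asarray(layout.positions, dtype=float)
    norms = np.linalg.norm(sens, axis=1)
    norms[norms == 0] = 1.0
    sens = sens / norms[:, None]  # project onto the unit sphere
    # sources uniform on the inner sphere
    v = rng.normal(size=(n_sources, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    src = source_radius * v
    d = np.linalg.norm(sens[:, None, :] - src[None, :, :], axis=-1)
    gain = 1.0 / np.maximum(d, 1e-3) ** 2
    return LeadField(gain, source_positions=src)
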