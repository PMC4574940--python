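"""Domain containers and on-disk readers/writers.

The pipeline's central container is the :class:`Recording`: a
``channels x samples x trials`` array with a sampling rate, channel labels,
and optional stimulus-onset / baseline annotations. Trial-averaged data is
simply a Recording with a single trial. Connectivity results live in
:class:`ConnectivityMatrix` (static, ``Nc x Nc``) or
:class:`DynamicConnectivity` (windowed, ``Nw x Nc x Nc``).

On-disk dialects
----------------
* Recordings and adjacency matrices: an HDF5 container (datasets ``data``,
  ``sfreq``, ``labels``, optional ``onset``/``baseline``), or plain
  whitespace text for 2-D matrices.
* Channel locations: 4-column text, ``label x y z`` (or ``index x y z``).
* Scout atlases (cortical parcellations): JSON records with label, lobe,
  centroid and member source indices.
* Graphs: GraphML or a labelled edge list; metric tables: CSV.

All sample indices stored on disk are 0-based.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import networkx as nx
import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    FormatError,
    ParameterError,
    ShapeError,
    ValidationError,
)

logger = logging.getLogger("meegconnet")

LOBES = ("occipital", "parietal", "temporal", "central", "frontal")

#: methods a ConnectivityMatrix may be tagged with
FC_METHODS = ("xcorr", "plv", "mpc", "mi", "plv_intertrial")

_ASYMMETRY_TOL = 1e-8


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Multi-trial sensor (or ROI) time series.

    Parameters
    ----------
    data : ndarray, shape (Nc, Ns, Nt)
        Signal values (e.g. microvolts). A 2-D array is promoted to a
        single trial.
    sfreq : float
        Sampling frequency in Hz, > 0.
    channel_labels : sequence of str
        One unique label per channel.
    onset_index : int, optional
        Sample index of the stimulus onset.
    baseline_span : (int, int), optional
        Half-open ``[start, end)`` sample span of the pre-stimulus baseline.
    """

    data: np.ndarray
    sfreq: float
    channel_labels: Sequence[str]
    onset_index: int | None = None
    baseline_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[:, :, np.newaxis]
        if self.data.ndim != 3:
            raise ShapeError(
                f"recording data must be 2-D or 3-D, got {self.data.ndim}-D"
            )
        nc, ns, nt = self.data.shape
        if nc < 2:
            raise ValidationError(f"need at least 2 channels, got {nc}")
        if ns < 2:
            raise ValidationError(f"need at least 2 samples, got {ns}")
        if nt < 1:
            raise ValidationError("need at least 1 trial")
        self.channel_labels = [str(l) for l in self.channel_labels]
        if len(self.channel_labels) != nc:
            raise ValidationError(
                f"{len(self.channel_labels)} labels for {nc} channels"
            )
        if len(set(self.channel_labels)) != nc:
            raise ValidationError("channel labels must be unique")
        if not np.isfinite(self.data).all():
            ch, smp, _ = np.unravel_index(
                int(np.flatnonzero(~np.isfinite(self.data))[0]), self.data.shape
            )
            raise ValidationError(
                f"non-finite value at channel {self.channel_labels[ch]!r}, "
                f"sample {smp}"
            )
        self.sfreq = float(self.sfreq)
        if self.sfreq <= 0:
            raise ValidationError("sfreq must be > 0")
        if self.onset_index is not None:
            self.onset_index = int(self.onset_index)
            if not 0 <= self.onset_index < ns:
                raise ValidationError(
                    f"onset_index {self.onset_index} outside [0, {ns})"
                )
        if self.baseline_span is not None:
            s, e = (int(v) for v in self.baseline_span)
            if not (0 <= s < e <= ns):
                raise ParameterError(f"baseline span ({s}, {e}) outside [0, {ns}]")
            self.baseline_span = (s, e)

    # shape accessors -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (onset at t=0 when an onset is set)."""
        t = np.arange(self.n_samples) / self.sfreq
        if self.onset_index is not None:
            t -= self.onset_index / self.sfreq
        return t

    def with_data(self, data: np.ndarray, **changes) -> "Recording":
        """Copy of this recording with new data (and optional field changes)."""
        return replace(self, data=data, **changes)


@dataclass
class ChannelLayout:
    """Sensor labels with 3-D positions (arbitrary length units)."""

    labels: Sequence[str]
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ShapeError("positions must be (Nc, 3)")
        if len(self.labels) != self.positions.shape[0]:
            raise ValidationError("label count does not match position rows")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("duplicate channel labels in layout")
        if not np.isfinite(self.positions).all():
            raise ValidationError("non-finite channel position")

    @property
    def n_channels(self) -> int:
        return len(self.labels)


@dataclass
class ScoutAtlas:
    """Cortical parcellation: ROIs as labelled sets of source indices.

    Each ROI carries a centroid (used for node positions and for
    left/right hemisphere assignment) and a lobe tag from
    {occipital, parietal, temporal, central, frontal}.
    """

    roi_labels: Sequence[str]
    roi_members: Sequence[Sequence[int]]
    roi_centroids: np.ndarray
    lobes: Sequence[str]
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        self.roi_labels = [str(l) for l in self.roi_labels]
        n = len(self.roi_labels)
        if len(set(self.roi_labels)) != n:
            raise ValidationError("duplicate ROI labels")
        if len(self.roi_members) != n or len(self.lobes) != n:
            raise ValidationError("atlas field lengths disagree")
        self.roi_members = [
            np.asarray(m, dtype=int) for m in self.roi_members
        ]
        for lab, mem in zip(self.roi_labels, self.roi_members):
            if mem.size == 0:
                raise ValidationError(f"ROI {lab!r} has no member sources")
            if (mem < 0).any():
                raise ValidationError(f"ROI {lab!r} has negative member index")
        if not self.allow_overlap:
            flat = np.concatenate(self.roi_members)
            if len(np.unique(flat)) != flat.size:
                raise ValidationError(
                    "ROI member sets overlap (pass allow_overlap=True to permit)"
                )
        self.roi_centroids = np.asarray(self.roi_centroids, dtype=float)
        if self.roi_centroids.shape != (n, 3):
            raise ShapeError("roi_centroids must be (Nroi, 3)")
        self.lobes = [str(l) for l in self.lobes]
        bad = sorted(set(self.lobes) - set(LOBES))
        if bad:
            raise ValidationError(f"unknown lobe(s) {bad}; expected one of {LOBES}")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    def hemispheres(self) -> list[str]:
        """Hemisphere per ROI from the centroid x-sign (x<0 -> 'L')."""
        return ["L" if x < 0 else "R" for x in self.roi_centroids[:, 0]]

    def validate_against(self, n_sources: int) -> None:
        for lab, mem in zip(self.roi_labels, self.roi_members):
            if (mem >= n_sources).any():
                raise ValidationError(
                    f"ROI {lab!r} references source >= {n_sources}"
                )


def _check_square_fc(values: np.ndarray, method: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ShapeError("connectivity values must be square")
    if not np.isfinite(values).all():
        raise ValidationError("non-finite connectivity value")
    if not np.allclose(values, values.T, atol=1e-10, rtol=0):
        raise ValidationError("connectivity matrix must be symmetric")
    if np.abs(np.diag(values)).max(initial=0.0) > 0:
        raise ValidationError("connectivity diagonal must be zero")
    if method in ("plv", "mpc", "xcorr", "plv_intertrial"):
        if values.min() < -1e-12 or values.max() > 1 + 1e-9:
            raise ValidationError(f"{method} values must lie in [0, 1]")
    elif method == "mi":
        if values.min() < -1e-12:
            raise ValidationError("mutual information must be >= 0")
    return values


@dataclass
class ConnectivityMatrix:
    """Symmetric zero-diagonal functional-connectivity adjacency."""

    values: np.ndarray
    method: str
    band: tuple[float, float] | None = None
    node_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.method not in FC_METHODS:
            raise ParameterError(
                f"unknown method {self.method!r}; expected one of {FC_METHODS}"
            )
        self.values = _check_square_fc(self.values, self.method)
        n = self.values.shape[0]
        if self.node_labels is None:
            self.node_labels = [f"ch{i}" for i in range(n)]
        self.node_labels = [str(l) for l in self.node_labels]
        if len(self.node_labels) != n:
            raise ValidationError("node label count mismatch")
        if self.band is not None:
            lo, hi = (float(v) for v in self.band)
            if not 0 <= lo < hi:
                raise ParameterError(f"invalid band ({lo}, {hi})")
            self.band = (lo, hi)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class DynamicConnectivity:
    """Sliding-window sequence of connectivity matrices (Nw x Nc x Nc)."""

    values: np.ndarray
    method: str
    window_starts: np.ndarray | None = None
    window_length: int | None = None
    step: int | None = None
    band: tuple[float, float] | None = None
    node_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ShapeError("dynamic connectivity must be 3-D (Nw, Nc, Nc)")
        if self.values.shape[0] < 1:
            raise ValidationError("need at least one window")
        for w in range(self.values.shape[0]):
            _check_square_fc(self.values[w], self.method)
        n = self.values.shape[1]
        if self.node_labels is None:
            self.node_labels = [f"ch{i}" for i in range(n)]
        self.node_labels = [str(l) for l in self.node_labels]
        if len(self.node_labels) != n:
            raise ValidationError("node label count mismatch")
        if self.window_starts is not None:
            self.window_starts = np.asarray(self.window_starts, dtype=int)
            if self.window_starts.shape != (self.values.shape[0],):
                raise ValidationError("window_starts length mismatch")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def window(self, i: int) -> ConnectivityMatrix:
        return ConnectivityMatrix(
            self.values[i], method=self.method, band=self.band,
            node_labels=self.node_labels,
        )


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a Recording to the HDF5 container dialect."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("sfreq", data=rec.sfreq)
        f.create_dataset(
            "labels", data=np.array(rec.channel_labels, dtype="S")
        )
        if rec.onset_index is not None:
            f.create_dataset("onset", data=rec.onset_index)
        if rec.baseline_span is not None:
            f.create_dataset("baseline", data=np.asarray(rec.baseline_span))


def read_recording(
    path: str | Path,
    layout_path: str | Path | None = None,
    sfreq: float | None = None,
) -> Recording:
    """Read a Recording from HDF5 or whitespace text.

    HDF5 files must contain a ``data`` dataset (2-D or 3-D) plus ``sfreq``
    and ``labels``. A plain-text file is parsed as a 2-D channels x samples
    matrix promoted to a single trial; ``sfreq`` must then be given (it is
    not stored in the text dialect) and labels default to ``ch0..chN-1``.
    When ``layout_path`` is given, its labels are attached and must match
    the channel count.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if h5py.is_hdf5(path):
        with h5py.File(path, "r") as f:
            if "data" not in f:
                raise FormatError(f"{path}: HDF5 file lacks a 'data' dataset")
            data = np.asarray(f["data"])
            fs = float(np.asarray(f["sfreq"])) if "sfreq" in f else sfreq
            if fs is None:
                raise FormatError(f"{path}: no 'sfreq' dataset and none given")
            if "labels" in f:
                labels = [
                    l.decode() if isinstance(l, bytes) else str(l)
                    for l in np.asarray(f["labels"])
                ]
            else:
                labels = [f"ch{i}" for i in range(data.shape[0])]
            onset = int(np.asarray(f["onset"])) if "onset" in f else None
            baseline = (
                tuple(int(v) for v in np.asarray(f["baseline"]))
                if "baseline" in f
                else None
            )
    else:
        try:
            data = np.loadtxt(path, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: cannot parse as a numeric matrix: {exc}")
        if sfreq is None:
            raise ParameterError(
                "text recordings carry no sampling rate; pass sfreq="
            )
        fs = float(sfreq)
        labels = [f"ch{i}" for i in range(data.shape[0])]
        onset = baseline = None
    if layout_path is not None:
        layout = read_channel_locations(layout_path)
        if layout.n_channels != data.shape[0]:
            raise ValidationError(
                f"layout has {layout.n_channels} channels, data has "
                f"{data.shape[0]}"
            )
        labels = list(layout.labels)
    return Recording(
        data, sfreq=fs, channel_labels=labels,
        onset_index=onset, baseline_span=baseline,
    )


# ---------------------------------------------------------------------------
# channel locations
# ---------------------------------------------------------------------------

def read_channel_locations(path: str | Path) -> ChannelLayout:
    """Parse a 4-column channel location file: ``label|index  x  y  z``.

    Whitespace- or comma-delimited. Numeric first columns are taken as node
    numbers and converted to labels ``chN``.
    """
    path = Path(path)
    labels: list[str] = []
    rows: list[list[float]] = []
    with open(path) as f:
        for lineno, raw in enumerate(f, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 columns, got {len(parts)}"
                )
            lab = parts[0]
            try:
                xyz = [float(v) for v in parts[1:4]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad coordinate: {exc}")
            try:
                lab = f"ch{int(lab)}"
            except ValueError:
                pass
            labels.append(lab)
            rows.append(xyz)
    if not rows:
        raise FormatError(f"{path}: no channel rows found")
    try:
        return ChannelLayout(labels, np.array(rows))
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}")


def write_channel_locations(layout: ChannelLayout, path: str | Path) -> None:
    with open(path, "w") as f:
        for lab, (x, y, z) in zip(layout.labels, layout.positions):
            f.write(f"{lab} {x!r} {y!r} {z!r}\n")


# ---------------------------------------------------------------------------
# adjacency matrices
# ---------------------------------------------------------------------------

def _symmetrize(values: np.ndarray, origin: str) -> np.ndarray:
    scale = np.abs(values).max(initial=0.0) or 1.0
    asym = np.abs(values - np.swapaxes(values, -1, -2)).max(initial=0.0)
    if asym > _ASYMMETRY_TOL * scale:
        raise ValidationError(
            f"{origin}: adjacency asymmetry {asym:.3g} exceeds tolerance "
            f"{_ASYMMETRY_TOL:g} (relative); directed matrices are not "
            "supported"
        )
    values = 0.5 * (values + np.swapaxes(values, -1, -2))
    idx = np.arange(values.shape[-1])
    values[..., idx, idx] = 0.0
    return values


def write_adjacency(
    conn: ConnectivityMatrix | DynamicConnectivity, path: str | Path
) -> None:
    """Write a (dynamic) connectivity matrix to the HDF5 dialect."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("adjacency", data=conn.values)
        d.attrs["method"] = conn.method
        if conn.band is not None:
            d.attrs["band"] = np.asarray(conn.band)
        f.create_dataset(
            "labels", data=np.array(conn.node_labels, dtype="S")
        )
        if isinstance(conn, DynamicConnectivity):
            if conn.window_starts is not None:
                f.create_dataset("window_starts", data=conn.window_starts)
            if conn.window_length is not None:
                d.attrs["window_length"] = conn.window_length
            if conn.step is not None:
                d.attrs["step"] = conn.step


def read_adjacency(
    path: str | Path, method: str = "plv"
) -> ConnectivityMatrix | DynamicConnectivity:
    """Read a static (Nc x Nc) or dynamic (Nw x Nc x Nc) adjacency.

    Accepts the HDF5 dialect or a 2-D whitespace-text matrix. Inputs are
    symmetrized by averaging; asymmetry beyond 1e-8 (relative) is an error.
    ``method`` is a fallback tag for files that do not record one.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    meta: dict = {}
    if h5py.is_hdf5(path):
        with h5py.File(path, "r") as f:
            if "adjacency" not in f:
                raise FormatError(f"{path}: HDF5 file lacks 'adjacency'")
            d = f["adjacency"]
            values = np.asarray(d)
            method = str(d.attrs.get("method", method))
            if "band" in d.attrs:
                meta["band"] = tuple(float(v) for v in d.attrs["band"])
            if "labels" in f:
                meta["node_labels"] = [
                    l.decode() if isinstance(l, bytes) else str(l)
                    for l in np.asarray(f["labels"])
                ]
            if values.ndim == 3:
                if "window_starts" in f:
                    meta["window_starts"] = np.asarray(f["window_starts"])
                if "window_length" in d.attrs:
                    meta["window_length"] = int(d.attrs["window_length"])
                if "step" in d.attrs:
                    meta["step"] = int(d.attrs["step"])
    else:
        try:
            values = np.loadtxt(path, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: cannot parse as a numeric matrix: {exc}")
    values = np.asarray(values, dtype=float)
    if values.ndim not in (2, 3) or values.shape[-1] != values.shape[-2]:
        raise ShapeError(
            f"{path}: adjacency must be square 2-D or 3-D with square "
            f"trailing dims, got shape {values.shape}"
        )
    values = _symmetrize(values, str(path))
    if values.ndim == 2:
        return ConnectivityMatrix(values, method=method, **meta)
    return DynamicConnectivity(values, method=method, **meta)


# ---------------------------------------------------------------------------
# scout atlases
# ---------------------------------------------------------------------------

def write_scout_atlas(atlas: ScoutAtlas, path: str | Path) -> None:
    recs = [
        {
            "label": lab,
            "lobe": lobe,
            "centroid": [float(v) for v in cen],
            "members": [int(i) for i in mem],
        }
        for lab, lobe, cen, mem in zip(
            atlas.roi_labels, atlas.lobes, atlas.roi_centroids, atlas.roi_members
        )
    ]
    with open(path, "w") as f:
        json.dump({"rois": recs}, f, indent=1)


def read_scout_atlas(
    path: str | Path, n_sources: int | None = None
) -> ScoutAtlas:
    """Read a JSON scout atlas; optionally check member indices < n_sources."""
    path = Path(path)
    try:
        with open(path) as f:
            payload = json.load(f)
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path}: not a scout-atlas JSON file: {exc}")
    try:
        recs = payload["rois"]
        atlas = ScoutAtlas(
            roi_labels=[r["label"] for r in recs],
            roi_members=[r["members"] for r in recs],
            roi_centroids=np.array([r["centroid"] for r in recs], dtype=float),
            lobes=[r["lobe"] for r in recs],
        )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: malformed scout record: {exc}")
    if n_sources is not None:
        atlas.validate_against(n_sources)
    return atlas


# ---------------------------------------------------------------------------
# metric tables & graphs
# ---------------------------------------------------------------------------

def export_metrics_table(
    node_metrics: pd.DataFrame, atlas: ScoutAtlas | None, path: str | Path
) -> None:
    """Write per-node metrics to CSV: label, lobe, then one column per metric.

    Rows must align with the atlas ROI labels when an atlas is given; the
    lobe column is filled from the atlas (empty otherwise). Values are
    written with 12 significant digits so a re-read reproduces them.
    """
    table = node_metrics.copy()
    if "label" not in table.columns:
        table.insert(0, "label", table.index.astype(str))
    if atlas is not None:
        if list(table["label"]) != list(atlas.roi_labels):
            raise AlignmentError(
                "metric table rows do not align with atlas ROI labels"
            )
        table.insert(1, "lobe", list(atlas.lobes))
    else:
        table.insert(1, "lobe", "")
    table.to_csv(path, index=False, float_format="%.12g")


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise FormatError(f"{path}: metric table lacks a 'label' column")
    return df.set_index("label", drop=False)


def export_graph(graph, path: str | Path, fmt: str = "graphml") -> None:
    """Write a BrainGraph as GraphML (node attrs x,y,z,label,module,strength;
    edge attr weight) or as a ``label_i label_j weight`` edge list."""
    g = graph.to_networkx()
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "edgelist":
        with open(path, "w") as f:
            for u, v, d in g.edges(data=True):
                f.write(f"{u} {v} {d.get('weight', 1.0)!r}\n")
    else:
        raise ParameterError(f"unsupported graph format {fmt!r}")


def read_graphml(path: str | Path):
    """Read a GraphML file back into a BrainGraph."""
    from .graph_metrics import BrainGraph  # deferred: avoid import cycle

    g = nx.read_graphml(path)
    nodes = list(g.nodes)
    n = len(nodes)
    adj = np.zeros((n, n))
    index = {u: i for i, u in enumerate(nodes)}
    for u, v, d in g.edges(data=True):
        w = float(d.get("weight", 1.0))
        adj[index[u], index[v]] = adj[index[v], index[u]] = w
    labels = [str(g.nodes[u].get("label", u)) for u in nodes]
    if all("x" in g.nodes[u] for u in nodes):
        pos = np.array(
            [[float(g.nodes[u][k]) for k in "xyz"] for u in nodes]
        )
    else:
        pos = None
    return BrainGraph(adj, node_labels=labels, node_positions=pos)
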