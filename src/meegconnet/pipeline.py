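"""Configurable end-to-end pipeline runner.

A pipeline config (YAML or JSON) names an input recording (a file or a
simulation spec), an ordered list of stages, and an output directory.
Two canonical chains are supported, mirroring the scalp-level and
source-level analysis paths:

    filter -> fc -> graph                       (scalp networks)
    filter -> baseline -> inverse -> fc -> graph  (cortex networks)

The chain is type-checked before anything runs: each stage consumes the
artifact type the previous stage produced (recording -> recording for
preprocessing, recording -> connectivity for ``fc``, connectivity ->
graph for ``graph``). Every intermediate artifact is written to the
output directory, along with ``provenance.json`` recording package and
dependency versions, all parameters, the root seed, and the derived
per-stage seeds — enough to re-run the pipeline to identical outputs.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import connectivity, data_io, graph_metrics, inverse, preprocess
from . import surrogates as surrogate_stats
from . import synth
from .errors import ConfigError, MeegError
from .utils import spawn_seeds

logger = logging.getLogger("meegconnet")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

# artifact type produced by each stage given its input type
_STAGE_TYPES = {
    "filter": ("recording", "recording"),
    "resample": ("recording", "recording"),
    "baseline": ("recording", "recording"),
    "average": ("recording", "recording"),
    "inverse": ("recording", "recording"),  # ROI-level recording
    "fc": ("recording", "connectivity"),
    "graph": ("connectivity", "graph"),
}


class PipelineConfig:
    """Validated pipeline description; see :func:`load_config`."""

    def __init__(self, payload: dict, base_dir: Path | None = None):
        self.base = Path(base_dir) if base_dir else Path.cwd()
        if not isinstance(payload, dict):
            raise ConfigError("config must be a mapping")
        self.seed = int(payload.get("seed", 0))
        self.out_dir = Path(payload.get("out_dir", "meegconnet_out"))
        if not self.out_dir.is_absolute():
            self.out_dir = self.base / self.out_dir
        self.input = payload.get("input")
        if not isinstance(self.input, dict) or (
            "path" not in self.input and "simulate" not in self.input
        ):
            raise ConfigError(
                "config needs input: {path: ...} or input: {simulate: {...}}"
            )
        self.stages = payload.get("stages")
        if not isinstance(self.stages, list) or not self.stages:
            raise ConfigError("config needs a non-empty stages list")
        self.stages = [dict(s) for s in self.stages]
        self._validate_chain()

    def _validate_chain(self) -> None:
        current = "recording"
        for k, st in enumerate(self.stages):
            name = st.get("stage")
            if name not in _STAGE_TYPES:
                raise ConfigError(
                    f"stage {k}: unknown stage {name!r}; expected one of "
                    f"{sorted(_STAGE_TYPES)}"
                )
            need, out = _STAGE_TYPES[name]
            if need != current:
                raise ConfigError(
                    f"stage {k} ({name}) needs a {need} input but the "
                    f"previous stage produced a {current}"
                )
            if name == "inverse" and "leadfield" not in st:
                raise ConfigError(
                    f"stage {k} (inverse): a 'leadfield' path is required"
                )
            current = out

    def resolve(self, p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else self.base / q


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    text = path.read_text()
    payload = (
        json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    )
    return PipelineConfig(payload, base_dir=path.parent)


def _load_leadfield(path: Path) -> inverse.LeadField:
    import h5py

    with h5py.File(path, "r") as f:
        return inverse.LeadField(
            np.asarray(f["gain"]), np.asarray(f["positions"])
        )


def write_leadfield(lf: inverse.LeadField, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=lf.gain)
        f.create_dataset("positions", data=lf.source_positions)


def _input_recording(cfg: PipelineConfig, seed: int) -> data_io.Recording:
    if "path" in cfg.input:
        p = cfg.resolve(cfg.input["path"])
        if not p.exists():
            raise ConfigError(f"input recording not found: {p}")
        return data_io.read_recording(p, sfreq=cfg.input.get("sfreq"))
    sim = dict(cfg.input["simulate"])
    coupling = sim.pop("coupling", None)
    spec = synth.CouplingSpec(
        coupling=np.asarray(coupling, dtype=float) if coupling is not None else None,
        seed=seed, **sim,
    )
    return synth.simulate_sources(spec)


def run_pipeline(cfg: PipelineConfig) -> dict[str, str]:
    """Execute a validated pipeline; returns {artifact name: path}.

    Aborts on the first failing stage, naming it. All randomness derives
    from the config's root seed.
    """
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    seeds = spawn_seeds(cfg.seed, len(cfg.stages) + 1)
    artifacts: dict[str, str] = {}
    provenance = {
        "meegconnet": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "seed": cfg.seed,
        "stage_seeds": [int(s) for s in seeds[1:]],
        "input": cfg.input,
        "stages": cfg.stages,
    }

    def save(name: str, writer, *args) -> None:
        path = cfg.out_dir / name
        writer(*args, path)
        artifacts[name] = str(path)

    current = _input_recording(cfg, int(seeds[0]))
    save("input_recording.h5", data_io.write_recording, current)
    mask = None
    for k, st in enumerate(cfg.stages):
        name = st["stage"]
        seed = int(seeds[k + 1])
        try:
            if name == "filter":
                current = preprocess.fir_bandpass(
                    current, st["lo"], st["hi"], order=st.get("order"),
                    causal=bool(st.get("causal", False)),
                )
                save(f"stage{k}_filtered.h5", data_io.write_recording, current)
            elif name == "resample":
                current = preprocess.resample(current, st["sfreq"])
                save(f"stage{k}_resampled.h5", data_io.write_recording, current)
            elif name == "baseline":
                current = preprocess.set_baseline(
                    current, st["start"], st["end"]
                )
                save(f"stage{k}_baselined.h5", data_io.write_recording, current)
            elif name == "average":
                current = preprocess.average_trials(current)
                save(f"stage{k}_averaged.h5", data_io.write_recording, current)
            elif name == "inverse":
                lf = _load_leadfield(cfg.resolve(st["leadfield"]))
                icfg = inverse.InverseConfig(
                    method=st.get("method", "wmne"),
                    lambda_=st.get("lambda"),
                    snr=st.get("snr", 3.0),
                    depth_gamma=st.get("depth_gamma", 0.5),
                )
                cov = inverse.noise_covariance(current)
                est = inverse.solve_inverse(current, lf, cov, icfg)
                if "atlas" in st:
                    atlas = data_io.read_scout_atlas(
                        cfg.resolve(st["atlas"]), n_sources=lf.n_sources
                    )
                    current = inverse.aggregate_rois(est, atlas)
                else:
                    current = data_io.Recording(
                        est.series, sfreq=est.sfreq,
                        channel_labels=[f"src{i}" for i in range(est.n_sources)],
                    )
                save(f"stage{k}_sources.h5", data_io.write_recording, current)
            elif name == "fc":
                method = st.get("method", "plv")
                margs = {}
                if method == "xcorr" and "max_lag" in st:
                    margs["max_lag"] = st["max_lag"]
                if method == "mi" and "n_bins" in st:
                    margs["n_bins"] = st["n_bins"]
                if "window" in st:
                    conn = connectivity.sliding_window(
                        current, method, st["window"],
                        st.get("step", st["window"]), **margs,
                    )
                elif st.get("surrogates"):
                    mask, conn = surrogate_stats.significance_mask(
                        current, method,
                        n_surr=int(st["surrogates"]),
                        alpha=float(st.get("alpha", 0.05)),
                        seed=seed,
                        surrogate_mode=st.get("surrogate_mode", "univariate"),
                        **margs,
                    )
                    np.savetxt(
                        cfg.out_dir / f"stage{k}_pvalues.txt", mask.p_values
                    )
                    artifacts[f"stage{k}_pvalues.txt"] = str(
                        cfg.out_dir / f"stage{k}_pvalues.txt"
                    )
                else:
                    conn = connectivity.static_fc(current, method, **margs)
                current = conn
                save(f"stage{k}_adjacency.h5", data_io.write_adjacency, current)
            elif name == "graph":
                if isinstance(current, data_io.DynamicConnectivity):
                    conn = current.window(0)
                else:
                    conn = current
                g = graph_metrics.threshold_adjacency(
                    conn, mode=st.get("mode", "proportional"),
                    value=st.get("value", 1.0),
                )
                part = graph_metrics.detect_modules(g, seed=seed)
                nm = graph_metrics.node_metrics(g, part)
                gm = graph_metrics.global_metrics(g)
                save(
                    f"stage{k}_node_metrics.csv",
                    lambda nm_, p: data_io.export_metrics_table(nm_, None, p),
                    nm,
                )
                with open(cfg.out_dir / f"stage{k}_global_metrics.json", "w") as f:
                    json.dump(
                        {k_: v for k_, v in vars(gm).items()}, f, indent=1
                    )
                artifacts[f"stage{k}_global_metrics.json"] = str(
                    cfg.out_dir / f"stage{k}_global_metrics.json"
                )
                save(
                    f"stage{k}_network.graphml",
                    lambda g_, p: data_io.export_graph(g_, p, "graphml"),
                    g,
                )
                current = g
        except MeegError as exc:
            raise MeegError(f"stage {k} ({name}) failed: {exc}") from exc
    with open(cfg.out_dir / "provenance.json", "w") as f:
        json.dump(provenance, f, indent=1)
    artifacts["provenance.json"] = str(cfg.out_dir / "provenance.json")
    return artifacts
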