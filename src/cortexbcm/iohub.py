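"""Configuration, reproducibility and reporting glue.

A run is fully described by a YAML config (validated into the package's
parameter dataclasses, missing values filled from the documented defaults)
plus a root seed.  Every experiment writes a JSON manifest carrying the
complete resolved configuration, so any result directory can be reproduced
bit-for-bit by :func:`rerun_manifest` — the CSV outputs of a rerun are
byte-identical (the manifest's timestamps, of course, are not).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bcm import BCMParams
from .device import DeviceParams
from .network import (
    CrossbarConfig,
    CrossbarResult,
    RearingProtocol,
    TuningResult,
    run_crossbar_learning,
    run_rearing,
    selectivity_metrics,
    winner_orientation,
)
from .stdp import TripletParams

__all__ = [
    "Config",
    "RunManifest",
    "load_config",
    "save_config",
    "write_results",
    "rerun_manifest",
]

logger = logging.getLogger("cortexbcm")

_SECTIONS = {
    "device": DeviceParams,
    "triplet": TripletParams,
    "bcm": BCMParams,
    "crossbar": CrossbarConfig,
    "rearing": RearingProtocol,
}


@dataclass(frozen=True)
class Config:
    """Validated model + experiment configuration."""

    device: DeviceParams = field(default_factory=DeviceParams)
    triplet: TripletParams = field(default_factory=TripletParams)
    bcm: BCMParams = field(default_factory=BCMParams)
    crossbar: CrossbarConfig = field(default_factory=CrossbarConfig)
    rearing: RearingProtocol = field(default_factory=RearingProtocol)


def _build_section(name: str, cls, values: dict, context: dict):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - allowed
    if unknown:
        raise ValueError(
            f"config section '{name}': unknown field(s) {sorted(unknown)}"
        )
    kwargs = dict(values)
    # nested parameter objects assembled from already-built sections
    if name == "bcm":
        kwargs.setdefault("triplet", context["triplet"])
    if name == "crossbar":
        kwargs.setdefault("device", context["device"])
        kwargs.setdefault("bcm", context["bcm"])
    if "orientations" in kwargs:
        kwargs["orientations"] = tuple(kwargs["orientations"])
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"config section '{name}': {exc}") from exc


def load_config(path) -> Config:
    """Load and validate a YAML config; missing values become defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    built: dict = {}
    for name, cls in _SECTIONS.items():
        built[name] = _build_section(name, cls, raw.get(name) or {}, built)
    return Config(**built)


def _section_dict(obj, skip=()) -> dict:
    out = {}
    for f in dataclasses.fields(obj):
        if f.name in skip:
            continue
        v = getattr(obj, f.name)
        if isinstance(v, tuple):
            v = list(v)
        out[f.name] = v
    return out


def config_to_dict(config: Config) -> dict:
    """Plain-scalar dictionary form of a config (YAML/JSON serializable)."""
    return {
        "device": _section_dict(config.device),
        "triplet": _section_dict(config.triplet),
        "bcm": _section_dict(config.bcm, skip=("triplet",)),
        "crossbar": _section_dict(config.crossbar, skip=("device", "bcm")),
        "rearing": _section_dict(config.rearing),
    }


def save_config(config: Config, path) -> Path:
    """Write a config as YAML; load_config(save_config(c)) == c."""
    path = Path(path)
    path.write_text(yaml.safe_dump(config_to_dict(config), sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# result writers and manifests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a run (plus bookkeeping)."""

    kind: str                 # 'rearing' or 'crossbar'
    config: dict              # full resolved configuration snapshot
    seed: int
    version: str
    started: str
    finished: str
    outputs: tuple

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["outputs"] = list(d["outputs"])
        return json.dumps(d, indent=2, sort_keys=True)

    @staticmethod
    def from_json(text: str) -> "RunManifest":
        d = json.loads(text)
        d["outputs"] = tuple(d["outputs"])
        return RunManifest(**d)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    try:
        df.to_csv(path, index=False, float_format="%.10g")
    except OSError as exc:
        raise OSError(f"failed to write {path}: {exc}") from exc


def _write_map_png(grid: np.ndarray, path: Path, title: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3, 3))
    im = ax.imshow(grid, cmap="viridis")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def write_results(result, out_dir, *, images: bool = False, manifest: RunManifest | None = None) -> list[Path]:
    """Write an experiment result as CSV traces (+ optional PNG maps).

    Returns the inventory of written files.  File naming is deterministic;
    a rerun from the same manifest produces byte-identical CSVs.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    written: list[Path] = []

    if isinstance(result, TuningResult):
        for eye, grid in (("left", result.weight_left), ("right", result.weight_right)):
            p = out / f"weights_{eye}.csv"
            _write_csv(pd.DataFrame(grid), p)
            written.append(p)
            if images:
                png = out / f"weights_{eye}.png"
                _write_map_png(grid, png, f"{eye} eye")
                written.append(png)
        rates = pd.DataFrame(
            result.rate_trace,
            columns=[f"rho_y_{a}" for a in result.orientations],
        )
        rates.insert(0, "epoch", np.arange(len(rates)))
        p = out / "rates.csv"
        _write_csv(rates, p)
        written.append(p)
        theta = pd.DataFrame(
            {"epoch": np.arange(result.theta_trace.size), "theta": result.theta_trace}
        )
        p = out / "theta.csv"
        _write_csv(theta, p)
        written.append(p)
        metrics = selectivity_metrics(result)
        p = out / "metrics.json"
        p.write_text(json.dumps(metrics, indent=2, sort_keys=True))
        written.append(p)
    elif isinstance(result, CrossbarResult):
        w = pd.DataFrame(
            result.weight_trace, columns=[f"G_{i+1}_uS" for i in range(result.weight_trace.shape[1])]
        )
        w.insert(0, "epoch", np.arange(len(w)))
        p = out / "weights.csv"
        _write_csv(w, p)
        written.append(p)
        tr = pd.DataFrame(
            {
                "epoch": np.arange(result.rate_trace.size),
                "rho_y_Hz": result.rate_trace,
                "theta_Hz": result.theta_trace,
            }
        )
        p = out / "rates.csv"
        _write_csv(tr, p)
        written.append(p)
        if images:
            png = out / "weights_final.png"
            _write_map_png(result.final_G.reshape(3, 3), png, "final G (uS)")
            written.append(png)
    else:
        raise TypeError(f"unsupported result type: {type(result).__name__}")

    if manifest is not None:
        manifest = dataclasses.replace(
            manifest, outputs=tuple(str(p.name) for p in written) + ("manifest.json",)
        )
        p = out / "manifest.json"
        p.write_text(manifest.to_json())
        written.append(p)
    return written


def make_manifest(kind: str, config: Config, seed: int, started=None) -> RunManifest:
    now = datetime.datetime.now(datetime.timezone.utc).isoformat()
    return RunManifest(
        kind=kind,
        config=config_to_dict(config),
        seed=seed,
        version=__version__,
        started=started or now,
        finished=now,
        outputs=(),
    )


def config_from_dict(d: dict) -> Config:
    built: dict = {}
    for name, cls in _SECTIONS.items():
        built[name] = _build_section(name, cls, dict(d.get(name) or {}), built)
    return Config(**built)


def rerun_manifest(manifest_path, out_dir) -> list[Path]:
    """Re-execute the run a manifest describes and write its outputs anew."""
    manifest = RunManifest.from_json(Path(manifest_path).read_text())
    config = config_from_dict(manifest.config)
    if manifest.kind == "rearing":
        result = run_rearing(config.rearing, config.bcm)
    elif manifest.kind == "crossbar":
        result = run_crossbar_learning(config.crossbar)
    else:
        raise ValueError(f"unknown run kind {manifest.kind!r}")
    fresh = make_manifest(manifest.kind, config, manifest.seed)
    return write_results(result, out_dir, manifest=fresh)
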