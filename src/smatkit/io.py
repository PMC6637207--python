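"""Readers/writers: TIFF stacks + CSV manifests, metadata-stamped CSV tables,
and the flat YAML scenario format.

Every CSV the pipeline writes starts with ``#``-prefixed metadata lines
(tool version, seed, config hash) so a run is traceable from any of its
outputs; readers skip those lines transparently.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .kinetics import KineticParameters
from .quantify import ImageSeries
from .synthetic import ConditionSpec, SyntheticScenario

__all__ = [
    "config_hash",
    "write_csv",
    "read_csv",
    "read_stack",
    "load_manifest",
    "scenario_to_dict",
    "scenario_from_dict",
    "save_scenario",
    "load_scenario",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a table with ``#`` metadata header lines (version always added)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# smatkit_version: {__version__}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}: {v}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_stack(path) -> np.ndarray:
    """All pages of a (multi-page) grayscale TIFF as a (t, y, x) array."""
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.dtype not in (np.uint8, np.uint16):
        raise ValueError(
            f"{path}: unsupported bit depth {arr.dtype}; expected 8/16-bit unsigned")
    return arr


def load_manifest(stack_dir) -> list:
    """Time-lapse manifest + TIFFs -> list of :class:`ImageSeries`.

    The manifest (``manifest.csv``) has columns path, condition, replicate,
    field, times_min (semicolon-separated minutes, page order = time order).
    """
    stack_dir = Path(stack_dir)
    manifest = read_csv(stack_dir / "manifest.csv")
    series = []
    for row in manifest.itertuples():
        frames = list(read_stack(stack_dir / row.path))
        times = np.array([float(x) for x in str(row.times_min).split(";")])
        series.append(ImageSeries(row.condition, int(row.replicate),
                                  int(row.field), times, frames))
    return series


def load_dual_stain(image_dir) -> list:
    """Dual-stain manifest + 3-page TIFFs -> list of (image, condition)."""
    from .hcia import DualChannelCellImage

    image_dir = Path(image_dir)
    manifest = read_csv(image_dir / "manifest.csv")
    fields = []
    for row in manifest.itertuples():
        stack = read_stack(image_dir / row.path).astype(float)
        if stack.shape[0] != 3:
            raise ValueError(f"{row.path}: expected 3 channels, got {stack.shape[0]}")
        order = str(row.channel_order).split(";")
        ch = dict(zip(order, stack))
        fields.append((DualChannelCellImage(ch["sa"], ch["ph"], ch["nuc"]),
                       row.condition))
    return fields


# ---------------------------------------------------------------------------
# scenario serialization (flat YAML)
# ---------------------------------------------------------------------------

def _cond_to_dict(spec: ConditionSpec) -> dict:
    d = {"kf_d": spec.params.kf_d, "kr": spec.params.kr,
         "L_T": spec.params.L_T, "C0": spec.params.C0,
         "latent": list(spec.latent)}
    if spec.switch_time is not None:
        d["switch_time"] = spec.switch_time
        d["post_kf_d"] = spec.post_params.kf_d
        d["post_kr"] = spec.post_params.kr
        d["post_L_T"] = spec.post_params.L_T
    return d


def _cond_from_dict(d: dict) -> ConditionSpec:
    params = KineticParameters(d["kf_d"], d["kr"], d.get("L_T", 0.0),
                               d.get("C0", 1.0))
    post = None
    if "switch_time" in d:
        post = KineticParameters(d["post_kf_d"], d["post_kr"],
                                 d.get("post_L_T", 0.0))
    return ConditionSpec(params, switch_time=d.get("switch_time"),
                         post_params=post, latent=tuple(d.get("latent", (0, 0))))


_SCALAR_FIELDS = (
    "name", "mode", "noise_sd", "n_replicates", "n_fields", "cells_per_field",
    "background_fraction", "cell_peak", "hcia_cells_per_field",
    "hcia_fields_per_condition", "seed",
)
_TUPLE_FIELDS = ("frame_shape", "cell_radius_range", "hcia_frame_shape",
                 "hcia_cell_radius_range")


def scenario_to_dict(scn: SyntheticScenario) -> dict:
    d = {k: getattr(scn, k) for k in _SCALAR_FIELDS}
    d.update({k: list(getattr(scn, k)) for k in _TUPLE_FIELDS})
    d["times"] = [float(t) for t in scn.times]
    d["divergence_schedule"] = dict(scn.divergence_schedule)
    d["conditions"] = {name: _cond_to_dict(c)
                       for name, c in scn.conditions.items()}
    return d


def scenario_from_dict(d: dict) -> SyntheticScenario:
    kwargs = {k: d[k] for k in _SCALAR_FIELDS if k in d}
    kwargs.update({k: tuple(d[k]) for k in _TUPLE_FIELDS if k in d})
    kwargs["times"] = np.asarray(d["times"], dtype=float)
    kwargs["divergence_schedule"] = dict(d.get("divergence_schedule", {}))
    kwargs["conditions"] = {name: _cond_from_dict(c)
                            for name, c in d["conditions"].items()}
    return SyntheticScenario(**kwargs)


def save_scenario(scn: SyntheticScenario, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(scn), fh, sort_keys=True)


def load_scenario(path) -> SyntheticScenario:
    import yaml

    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))
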