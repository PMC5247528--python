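"""HDF5 scan-data and result files, plus complex-field rendering.

Scan files hold a minimal tree (all quantities SI, metres):

    /meta : wavelength, distance, det_psize (2,), frame_shape (2,),
            regime (string), version (string)
    /data : frames (J, R, C) float, positions (J, 2), masks
            ((J or 1), R, C)
    /truth (optional) : probe (modes, R, C) complex, object complex,
            object_origin, object_psize, positions, seed

Result files store each probe/object storage with its physical pixel
size and origin so coordinates survive a round trip, alongside the
error trace and the resolved engine parameters.

Rendering follows the standard complex-field colour convention: phase
maps to hue and modulus maps to luminance (normalized per image).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from typing import Dict, Optional, Tuple

import h5py
import numpy as np
from matplotlib.colors import hsv_to_rgb

from .containers import Container, Storage
from .engine import EngineParams, ErrorTrace
from .geometry import Geometry
from .model import FrameSet

__all__ = [
    "FORMAT_VERSION",
    "ScanFileError",
    "write_scan",
    "read_scan",
    "copy_scan",
    "write_result",
    "read_result",
    "render_complex",
    "save_png",
]

FORMAT_VERSION = "ptychokit-scan-1.0"
RESULT_VERSION = "ptychokit-result-1.0"

_DS_OPTS = dict(track_times=False)  # byte-deterministic files


class ScanFileError(IOError):
    """Malformed or incompatible scan/result file."""


def _require(group: h5py.Group, name: str):
    if name not in group:
        raise ScanFileError(
            f"mandatory dataset {group.name}/{name} missing from {group.file.filename}"
        )
    return group[name]


def write_scan(path, frames: FrameSet, truth: Optional[Dict] = None) -> None:
    """Write a scan dataset; write→read round-trips bit-exactly."""
    geom = frames.geometry
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.create_dataset("version", data=FORMAT_VERSION, **_DS_OPTS)
        meta.create_dataset("wavelength", data=geom.lam, **_DS_OPTS)
        meta.create_dataset("distance", data=geom.z, **_DS_OPTS)
        meta.create_dataset("det_psize", data=np.asarray(geom.dpsize), **_DS_OPTS)
        meta.create_dataset("frame_shape", data=np.asarray(geom.N), **_DS_OPTS)
        meta.create_dataset("regime", data=geom.regime, **_DS_OPTS)
        data = f.create_group("data")
        data.create_dataset("frames", data=frames.frames, **_DS_OPTS)
        data.create_dataset("masks", data=frames.masks, **_DS_OPTS)
        positions = truth["positions"] if truth and "positions" in truth else None
        if positions is None:
            raise ScanFileError("scan positions are required to write a scan file")
        data.create_dataset("positions", data=np.asarray(positions, float), **_DS_OPTS)
        if truth:
            tg = f.create_group("truth")
            for key, value in truth.items():
                if key == "positions":
                    continue
                tg.create_dataset(key, data=value, **_DS_OPTS)


def read_scan(path) -> Tuple[FrameSet, np.ndarray, Optional[Dict]]:
    """Read a scan file -> (FrameSet, positions, truth-or-None).

    Masks stored as (1, R, C) are kept shared-for-all-frames.  Rejects
    files of a different format version, naming the version found.
    """
    with h5py.File(path, "r") as f:
        meta = _require(f, "meta")
        version = _require(meta, "version")[()]
        version = version.decode() if isinstance(version, bytes) else str(version)
        if version != FORMAT_VERSION:
            raise ScanFileError(
                f"unsupported scan format version {version!r} (expected {FORMAT_VERSION!r})"
            )
        regime = _require(meta, "regime")[()]
        regime = regime.decode() if isinstance(regime, bytes) else str(regime)
        geom = Geometry(
            lam=float(_require(meta, "wavelength")[()]),
            z=float(_require(meta, "distance")[()]),
            dpsize=tuple(_require(meta, "det_psize")[:]),
            N=tuple(int(n) for n in _require(meta, "frame_shape")[:]),
            regime=regime,
        )
        data = _require(f, "data")
        frames = FrameSet(
            frames=_require(data, "frames")[:],
            masks=_require(data, "masks")[:],
            geometry=geom,
        )
        positions = _require(data, "positions")[:]
        truth = None
        if "truth" in f:
            truth = {key: f["truth"][key][()] for key in f["truth"]}
            truth["positions"] = positions.copy()
    return frames, positions, truth


def copy_scan(src, dst) -> None:
    """Copy a scan file wholesale, preserving unknown extra groups."""
    with h5py.File(src, "r") as fin, h5py.File(dst, "w") as fout:
        for key in fin:
            fin.copy(key, fout, name=key)


# ----------------------------------------------------------------------
# results
# ----------------------------------------------------------------------

def _write_container(group: h5py.Group, container: Container) -> None:
    for key, storage in container.storages.items():
        sg = group.create_group(key)
        sg.create_dataset("data", data=storage.data, **_DS_OPTS)
        sg.create_dataset("psize", data=storage.psize, **_DS_OPTS)
        sg.create_dataset("origin", data=storage.origin, **_DS_OPTS)


def _read_container(group: h5py.Group, entity: str) -> Container:
    container = Container(entity)
    for key in group:
        sg = group[key]
        storage = container.new_storage(key, psize=sg["psize"][:])
        storage.origin = sg["origin"][:]
        storage.data = sg["data"][:]
    return container


def write_result(
    path,
    probe: Container,
    obj: Container,
    trace: ErrorTrace,
    params: EngineParams,
) -> None:
    """Write reconstruction output with physical coordinates intact."""
    with h5py.File(path, "w") as f:
        f.create_dataset("version", data=RESULT_VERSION, **_DS_OPTS)
        _write_container(f.create_group("probe"), probe)
        _write_container(f.create_group("object"), obj)
        tg = f.create_group("trace")
        tg.create_dataset("fourier_error", data=np.asarray(trace.fourier_error), **_DS_OPTS)
        tg.create_dataset("exit_change", data=np.asarray(trace.exit_change), **_DS_OPTS)
        f.create_dataset("params", data=json.dumps(asdict(params), sort_keys=True), **_DS_OPTS)


def read_result(path) -> Dict:
    """Read a result file -> dict with probe/object Containers, trace, params."""
    with h5py.File(path, "r") as f:
        version = _require(f, "version")[()]
        version = version.decode() if isinstance(version, bytes) else str(version)
        if version != RESULT_VERSION:
            raise ScanFileError(
                f"unsupported result format version {version!r} (expected {RESULT_VERSION!r})"
            )
        probe = _read_container(_require(f, "probe"), "probe")
        obj = _read_container(_require(f, "object"), "object")
        trace = ErrorTrace(
            fourier_error=list(_require(f["trace"], "fourier_error")[:]),
            exit_change=list(_require(f["trace"], "exit_change")[:]),
        )
        params = EngineParams(**json.loads(_require(f, "params")[()]))
    return {"probe": probe, "object": obj, "trace": trace, "params": params}


# ----------------------------------------------------------------------
# rendering
# ----------------------------------------------------------------------

def render_complex(field: np.ndarray) -> np.ndarray:
    """Render a complex field as an RGB array in [0, 1].

    Hue encodes phase (``(phase + pi) / 2 pi``), luminance the modulus
    normalized to the array maximum, saturation 1.  An all-zero field
    renders black.  Invariant to global amplitude scaling.
    """
    field = np.asarray(field, dtype=complex)
    mod = np.abs(field)
    peak = mod.max()
    value = mod / peak if peak > 0 else np.zeros_like(mod)
    hue = (np.angle(field) + np.pi) / (2.0 * np.pi)
    hsv = np.stack([hue % 1.0, np.ones_like(hue), value], axis=-1)
    return hsv_to_rgb(hsv)


def save_png(path, rgb: np.ndarray) -> None:
    """Save an RGB float array in [0, 1] as an 8-bit PNG."""
    from PIL import Image

    arr = np.clip(np.rint(np.asarray(rgb) * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)
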