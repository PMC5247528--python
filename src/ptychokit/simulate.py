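"""Synthetic ptychographic experiments under the package's forward model.

Generates a fully specified dataset -- complex probe modes, complex
object, jittered raster scan positions, diffraction frames and detector
masks -- so the whole reconstruction stack is testable without any
experimental download.  The simulator runs the exact same forward model
(pod network, propagators, incoherent mode sums) that the engine
inverts; noise, dead pixels and a beamstop are optional.

The photon budget is defined as the total counts per frame for a fully
transparent object: the ground-truth probe is normalized to unit power
and scaled by ``sqrt(photons)``, so with unit transforms every frame of
a unit-modulus object integrates exactly to ``photons``.

One dataset seed fans out to named sub-seeds (probe, object, jitter,
noise, mask) through a fixed hash derivation, so toggling one stochastic
element never shifts the random streams of the others.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import Geometry
from .model import FrameSet, PodNetwork, ScanSpec, build_pods, model_intensity

__all__ = [
    "SimConfig",
    "derive_seed",
    "make_probe",
    "make_object",
    "make_positions",
    "simulate",
    "run_simulation",
]


def derive_seed(seed: int, name: str) -> int:
    """Stable named sub-seed (< 2**31) derived from one master seed."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class SimConfig:
    """Parameters of one synthetic scan.

    grid : scan grid shape (rows, cols) of the raster.
    step : raster step in metres; must stay below ``probe_diameter`` so
        adjacent illuminated areas overlap.
    jitter : positional jitter amplitude as a fraction of the step,
        in [0, 0.5); emulates acquisition on a non-periodic grid.
    photons : total photon budget per frame (transparent object).
    probe_kind : "aperture" (flat circular aperture, optionally
        propagated to the sample plane over ``aperture_distance``) or
        "focused" (aperture with a converging quadratic phase of focal
        length ``focal_length``).
    mode_powers : power fraction per probe mode, summing to 1.
    dead_fraction : i.i.d. dead-pixel probability (one draw per dataset).
    beamstop_radius : optional opaque central disc radius in pixels.
    noise : "none" or "poisson".
    """

    geometry: Geometry
    grid: Tuple[int, int] = (5, 5)
    step: float = 1e-5
    jitter: float = 0.1
    photons: float = 1e6
    probe_kind: str = "aperture"
    probe_diameter: float = 2.5e-5
    aperture_distance: float = 0.0
    focal_length: Optional[float] = None
    mode_powers: Tuple[float, ...] = (1.0,)
    dead_fraction: float = 0.0
    beamstop_radius: Optional[float] = None
    noise: str = "none"
    seed: int = 0

    def __post_init__(self):
        powers = np.asarray(self.mode_powers, dtype=float)
        if np.any(powers <= 0):
            raise ValueError("mode powers must be positive")
        self.mode_powers = tuple((powers / powers.sum()).tolist())
        if not 0 <= self.jitter < 0.5:
            raise ValueError("jitter must lie in [0, 0.5)")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.noise == "poisson" and self.photons <= 0:
            raise ValueError("poisson noise requires a positive photon budget")


def make_probe(config: SimConfig) -> np.ndarray:
    """Ground-truth probe-mode stack (modes, R, C), unit total power.

    Mode 0 is a circular aperture of ``probe_diameter`` (focused kinds
    add a converging quadratic phase), optionally near-field propagated
    to the sample plane.  Higher modes are smoothed random-phase
    perturbations orthogonalized against all earlier modes; each mode is
    scaled to its configured power fraction, so the output Gram matrix
    is diagonal with ``mode_powers`` on the diagonal.
    """
    geom = config.geometry
    R, C = geom.N
    psr, psc = geom.rpsize
    if config.probe_diameter > min(R * psr, C * psc):
        raise ValueError("probe diameter exceeds the real-space field of view")
    r = (np.arange(R) - R // 2) * psr
    c = (np.arange(C) - C // 2) * psc
    rho2 = r[:, None] ** 2 + c[None, :] ** 2
    disc = (rho2 <= (config.probe_diameter / 2.0) ** 2).astype(complex)
    if config.probe_kind == "focused":
        f = config.focal_length or 2.0 * config.probe_diameter
        disc *= np.exp(-1j * np.pi * rho2 / (geom.lam * f))
    elif config.probe_kind != "aperture":
        raise ValueError(f"unknown probe kind {config.probe_kind!r}")
    if config.aperture_distance:
        near = Geometry(lam=geom.lam, z=config.aperture_distance,
                        dpsize=geom.rpsize, N=geom.N, regime="nearfield")
        disc = near.fw(disc)

    rng = np.random.default_rng(derive_seed(config.seed, "probe"))
    modes = [disc / np.sqrt(np.sum(np.abs(disc) ** 2))]
    support = np.abs(disc) > 1e-3 * np.abs(disc).max()
    for _ in config.mode_powers[1:]:
        phase = gaussian_filter(rng.standard_normal((R, C)), sigma=2.0)
        cand = disc * np.exp(1j * 4.0 * phase) * support
        for prev in modes:  # Gram-Schmidt against earlier modes
            cand = cand - prev * np.vdot(prev, cand) / np.vdot(prev, prev)
        modes.append(cand / np.sqrt(np.sum(np.abs(cand) ** 2)))
    stack = np.stack(
        [m * np.sqrt(p) for m, p in zip(modes, config.mode_powers)]
    )
    return stack


def make_object(shape: Tuple[int, int], kind: str = "random_phase",
                seed: int = 0, t_low: float = 0.3) -> np.ndarray:
    """Deterministic synthetic object transmission with |o| <= 1.

    "bars": binary resolution-target stripes of decreasing pitch (values
    in {t_low, 1}); "random_phase": unit modulus with a smooth random
    phase; "lens_like": circular zone structure with mild absorption.
    """
    R, C = int(shape[0]), int(shape[1])
    rng = np.random.default_rng(seed)
    if kind == "bars":
        obj = np.full((R, C), 1.0, dtype=complex)
        col = 0
        pitch = max(R // 4, 2)
        while col < C and pitch >= 1:
            band = np.arange(R) % (2 * pitch) < pitch
            width = min(2 * pitch, C - col)
            obj[band, col : col + width] = t_low
            col += width + max(pitch // 2, 1)
            pitch = max(pitch // 2, 1)
            if pitch == 1 and col >= C:
                break
        return obj
    if kind == "random_phase":
        phase = gaussian_filter(rng.standard_normal((R, C)), sigma=3.0)
        phase *= np.pi / max(np.abs(phase).max(), 1e-12)
        return np.exp(1j * phase)
    if kind == "lens_like":
        r = np.arange(R) - R / 2.0
        c = np.arange(C) - C / 2.0
        rho2 = r[:, None] ** 2 + c[None, :] ** 2
        radius2 = (min(R, C) / 2.2) ** 2
        inside = rho2 <= radius2
        amp = np.where(inside, 1.0, 0.85)
        phase = np.where(inside, np.pi * rho2 / radius2, 0.0)
        return amp * np.exp(1j * phase)
    raise ValueError(f"unknown object kind {kind!r}")


def make_positions(config: SimConfig) -> np.ndarray:
    """Jittered raster scan positions (J, 2) in metres, centred on 0."""
    if config.step >= config.probe_diameter:
        warnings.warn(
            "scan step >= probe diameter: adjacent illuminations do not overlap",
            stacklevel=2,
        )
    G0, G1 = config.grid
    rows = (np.arange(G0) - (G0 - 1) / 2.0) * config.step
    cols = (np.arange(G1) - (G1 - 1) / 2.0) * config.step
    grid = np.stack(np.meshgrid(rows, cols, indexing="ij"), axis=-1).reshape(-1, 2)
    rng = np.random.default_rng(derive_seed(config.seed, "jitter"))
    jitter = rng.uniform(-config.jitter, config.jitter, size=grid.shape) * config.step
    return grid + jitter


def _scan_spec(config: SimConfig, positions: np.ndarray) -> ScanSpec:
    return ScanSpec(
        positions=positions,
        geometry=config.geometry,
        n_probe_modes=len(config.mode_powers),
    )


def _embed_centered(target: np.ndarray, source: np.ndarray, fill: complex = 1.0) -> None:
    """Write ``source`` centred into ``target`` (crop or pad as needed)."""
    target[...] = fill
    tr, tc = target.shape
    sr, sc = source.shape
    r = min(tr, sr)
    c = min(tc, sc)
    t0, t1 = (tr - r) // 2, (tc - c) // 2
    s0, s1 = (sr - r) // 2, (sc - c) // 2
    target[t0 : t0 + r, t1 : t1 + c] = source[s0 : s0 + r, s1 : s1 + c]


def simulate(
    probe: np.ndarray,
    obj: np.ndarray,
    positions: np.ndarray,
    config: SimConfig,
) -> Tuple[FrameSet, Dict]:
    """Forward-simulate diffraction frames from known probe and object.

    ``probe`` is a (modes, R, C) stack of unit total power; ``obj`` is
    embedded centred into the object buffer implied by the scan
    footprint (padded with 1 where smaller, cropped where larger).
    Returns the FrameSet (frames zeroed at masked pixels) and a
    ground-truth record holding exactly what was simulated.
    """
    probe = np.asarray(probe, dtype=complex)
    if probe.ndim == 2:
        probe = probe[None]
    if config.photons < 0:
        raise ValueError("photon budget must be nonnegative")
    J = len(positions)
    shape = config.geometry.N
    spec = _scan_spec(config, positions)
    blank = FrameSet(
        frames=np.zeros((J,) + tuple(shape)),
        masks=np.ones((1,) + tuple(shape)),
        geometry=config.geometry,
    )
    network = build_pods(spec, blank)

    scaled_probe = probe * np.sqrt(config.photons)
    probe_storage = next(iter(network.containers["probe"].storages.values()))
    probe_storage.data[...] = scaled_probe
    obj_storage = next(iter(network.containers["object"].storages.values()))
    embedded = np.empty(obj_storage.data.shape[1:], dtype=complex)
    _embed_centered(embedded, np.asarray(obj, dtype=complex))
    obj_storage.data[...] = embedded

    frames = np.empty((J,) + tuple(shape))
    for j in range(J):
        frames[j] = model_intensity(network.pods_of_frame(j))
    if config.noise == "poisson":
        rng = np.random.default_rng(derive_seed(config.seed, "noise"))
        frames = rng.poisson(frames).astype(float)

    mask = np.ones((1,) + tuple(shape))
    if config.dead_fraction > 0:
        rng = np.random.default_rng(derive_seed(config.seed, "mask"))
        mask[0][rng.random(shape) < config.dead_fraction] = 0.0
    if config.beamstop_radius:
        r = np.arange(shape[0]) - shape[0] // 2
        c = np.arange(shape[1]) - shape[1] // 2
        mask[0][r[:, None] ** 2 + c[None, :] ** 2 <= config.beamstop_radius**2] = 0.0
    frames *= mask  # invalid pixels carry 0

    truth = {
        "probe": scaled_probe,
        "object": embedded,
        "object_origin": obj_storage.origin.copy(),
        "object_psize": obj_storage.psize.copy(),
        "positions": np.asarray(positions, dtype=float),
        "seed": config.seed,
    }
    frameset = FrameSet(frames=frames, masks=mask, geometry=config.geometry)
    return frameset, truth


def object_shape_for(config: SimConfig, positions: Optional[np.ndarray] = None) -> Tuple[int, int]:
    """Pixel shape of the object buffer implied by the scan footprint."""
    if positions is None:
        positions = make_positions(config)
    spec = _scan_spec(config, positions)
    shape = config.geometry.N
    blank = FrameSet(
        frames=np.zeros((len(positions),) + tuple(shape)),
        masks=np.ones((1,) + tuple(shape)),
        geometry=config.geometry,
    )
    network = build_pods(spec, blank)
    return network.containers["object"].storages["o0"].data.shape[1:]


def run_simulation(config: SimConfig, object_kind: str = "random_phase"):
    """Full pipeline: probe, positions, object sized to the scan footprint,
    forward simulation.  Returns ``(frameset, truth)``."""
    positions = make_positions(config)
    probe = make_probe(config)
    shape = object_shape_for(config, positions)
    obj = make_object(shape, kind=object_kind, seed=derive_seed(config.seed, "object"))
    return simulate(probe, obj, positions, config)
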