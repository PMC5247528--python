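"""Declarative scan model and pod-network construction.

A :class:`ScanSpec` describes a scan declaratively: probe positions
``y_j``, sharing maps ``c(j)`` (which probe entity illuminates point j)
and ``d(j)`` (which object entity is exposed), a discrete wavelength
spectrum with weights, and mode counts for the mixed-state probe and
object.  :func:`build_pods` realizes it as a network of pods over the
five entity containers.

The forward model implemented by the network is the incoherent sum over
wavelengths and modes

    I_j(s) = sum_{lam, m, n} w(lam) * | D_lam { p_{c(j),m,lam}(x) *
                                               o_{d(j),n,lam}(x - y_j) } |^2

with a per-frame validity mask M_j(s).  Polychromatic illumination is a
finite weighted sum of wavelength layers, each with its own propagator;
the object's spectral response may either have one layer per wavelength
or be tied to a single shared layer (the default, a common
approximation for moderate bandwidth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .containers import ENTITIES, Container, Pod, View
from .geometry import Geometry

__all__ = ["ScanSpec", "FrameSet", "PodNetwork", "build_pods", "pod_exit_model", "model_intensity"]


@dataclass
class FrameSet:
    """Measured (or simulated) diffraction data of one scan.

    ``frames`` has shape (J, R, C), nonnegative where valid.  ``masks``
    is (J, R, C) for per-frame masks or (1, R, C) when all frames share
    one mask; 1 marks a valid pixel, 0 an invalid/blocked one.
    """

    frames: np.ndarray
    masks: np.ndarray
    geometry: Geometry

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.masks = np.asarray(self.masks, dtype=float)
        if self.frames.ndim != 3 or self.masks.ndim != 3:
            raise ValueError("frames and masks must be 3-D stacks (J, R, C)")
        if self.masks.shape[1:] != self.frames.shape[1:]:
            raise ValueError(
                f"mask frame shape {self.masks.shape[1:]} != frame shape {self.frames.shape[1:]}"
            )
        if self.masks.shape[0] not in (1, self.frames.shape[0]):
            raise ValueError("masks must have 1 or J layers")
        if np.any((self.frames < 0) & (self._mask_stack() > 0)):
            raise ValueError("frames must be nonnegative at valid pixels")

    def _mask_stack(self) -> np.ndarray:
        if self.masks.shape[0] == 1:
            return np.broadcast_to(self.masks, self.frames.shape)
        return self.masks

    def max_valid_power(self) -> float:
        """Largest per-frame photon total counting valid pixels only."""
        totals = np.sum(self._mask_stack() * self.frames, axis=(1, 2))
        return float(totals.max())

    @property
    def nframes(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> Tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class ScanSpec:
    """Declarative description of a (possibly composite) scan.

    ``probe_of`` / ``object_of`` map scan-point index j to the sharing
    keys c(j) and d(j); by default every point uses probe 0 and object
    0.  ``wavelengths`` lists (wavelength, weight) pairs with positive
    weights; they are normalized to sum to 1.
    """

    positions: np.ndarray  # (J, 2) metres
    geometry: Geometry
    probe_of: Optional[Sequence[int]] = None
    object_of: Optional[Sequence[int]] = None
    wavelengths: Optional[Sequence[Tuple[float, float]]] = None
    n_probe_modes: int = 1
    n_object_modes: int = 1
    tie_object_spectrum: bool = True

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        J = len(self.positions)
        self.probe_of = (
            np.zeros(J, dtype=int) if self.probe_of is None else np.asarray(self.probe_of, int)
        )
        self.object_of = (
            np.zeros(J, dtype=int) if self.object_of is None else np.asarray(self.object_of, int)
        )
        if len(self.probe_of) != J or len(self.object_of) != J:
            raise ValueError("probe_of / object_of must assign exactly one key per scan point")
        if self.wavelengths is None:
            self.wavelengths = [(self.geometry.lam, 1.0)]
        lams = [float(l) for l, _ in self.wavelengths]
        ws = np.array([float(w) for _, w in self.wavelengths])
        if np.any(ws <= 0):
            raise ValueError("wavelength weights must be positive")
        self.wavelengths = list(zip(lams, (ws / ws.sum()).tolist()))
        if self.n_probe_modes < 1 or self.n_object_modes < 1:
            raise ValueError("mode counts must be >= 1")

    @property
    def npods(self) -> int:
        return len(self.positions) * len(self.wavelengths) * self.n_probe_modes * self.n_object_modes

    def probe_layer(self, lam_idx: int, m: int) -> int:
        return lam_idx * self.n_probe_modes + m

    def object_layer(self, lam_idx: int, n: int) -> int:
        if self.tie_object_spectrum:
            return n
        return lam_idx * self.n_object_modes + n


@dataclass
class PodNetwork:
    """The realized model: pods plus the five entity containers."""

    pods: List[Pod]
    containers: Dict[str, Container]
    spec: ScanSpec
    frames: FrameSet

    def pods_of_frame(self, j: int) -> List[Pod]:
        return [p for p in self.pods if p.j == j and p.active]

    @property
    def frame_indices(self) -> List[int]:
        return sorted({p.j for p in self.pods if p.active})


def build_pods(spec: ScanSpec, frames: FrameSet) -> PodNetwork:
    """Build one pod per (j, wavelength, m, n) and reformat all containers.

    Probe views sit at the scan origin on the storage of sharing key
    c(j); object views are centred at ``-y_j`` on the storage of d(j),
    so the object shifts under a fixed probe.  Exit views are distinct
    per pod; diffraction and mask views are shared by all pods of one
    scan point.  After reformat the object buffers cover the union of
    the shifted footprints.
    """
    J = len(spec.positions)
    if J != frames.nframes:
        raise ValueError(f"{J} scan positions but {frames.nframes} frames")
    shape = frames.frame_shape
    geoms = [spec.geometry.with_wavelength(l) for l, _ in spec.wavelengths]
    # real-space sampling of the reference wavelength defines the shared grids
    rpsize = np.asarray(geoms[0].rpsize)
    dpsize = np.asarray(spec.geometry.dpsize)

    containers = {e: Container(e) for e in ENTITIES}
    for c in sorted(set(spec.probe_of)):
        containers["probe"].new_storage(f"p{c}", psize=rpsize)
    for d in sorted(set(spec.object_of)):
        containers["object"].new_storage(f"o{d}", psize=rpsize)
    containers["exit"].new_storage("ex", psize=rpsize)
    # detector-plane storages: centre of the frame is the optical axis
    det_origin = -(np.asarray(shape) // 2) * dpsize
    containers["diff"].new_storage("d0", psize=dpsize).origin = det_origin.copy()
    containers["mask"].new_storage("m0", psize=dpsize).origin = det_origin.copy()

    per_frame_masks = frames.masks.shape[0] == frames.nframes
    pods: List[Pod] = []
    origin2 = np.zeros(2)
    for j in range(J):
        y = spec.positions[j]
        diff_view = containers["diff"].add_view(
            View("diff", "d0", center=origin2, shape=shape, layer=j)
        )
        mask_view = containers["mask"].add_view(
            View("mask", "m0", center=origin2, shape=shape, layer=j if per_frame_masks else 0)
        )
        for li, (lam, w) in enumerate(spec.wavelengths):
            for m in range(spec.n_probe_modes):
                for n in range(spec.n_object_modes):
                    probe_view = containers["probe"].add_view(
                        View("probe", f"p{spec.probe_of[j]}", center=origin2,
                             shape=shape, layer=spec.probe_layer(li, m))
                    )
                    object_view = containers["object"].add_view(
                        View("object", f"o{spec.object_of[j]}", center=-y,
                             shape=shape, layer=spec.object_layer(li, n))
                    )
                    exit_view = containers["exit"].add_view(
                        View("exit", "ex", center=origin2, shape=shape, layer=len(pods))
                    )
                    pods.append(
                        Pod(
                            j=j, lam=li, m=m, n=n,
                            views={
                                "probe": probe_view,
                                "object": object_view,
                                "exit": exit_view,
                                "diff": diff_view,
                                "mask": mask_view,
                            },
                            geometry=geoms[li],
                            containers=containers,
                            weight=w,
                        )
                    )
    for c in containers.values():
        c.reformat()
    containers["diff"].storages["d0"].data[...] = frames.frames
    containers["mask"].storages["m0"].data[...] = frames.masks
    return PodNetwork(pods=pods, containers=containers, spec=spec, frames=frames)


def pod_exit_model(pod: Pod) -> np.ndarray:
    """Coherent exit-wave model p * o of one pod (elementwise product)."""
    return pod.probe * pod.object


def model_intensity(pods_j: Sequence[Pod]) -> np.ndarray:
    """Incoherent model intensity of one scan point.

    Sum over (wavelength, m, n) of ``weight * |fw(p * o)|**2``; the pods
    must all belong to the same scan point.
    """
    pods_j = [p for p in pods_j if p.active]
    if not pods_j:
        raise ValueError("model_intensity of an empty pod set")
    if len({p.j for p in pods_j}) != 1:
        raise ValueError("model_intensity expects pods of a single scan point")
    total = np.zeros(pods_j[0].views["diff"].shape, dtype=float)
    for pod in pods_j:
        total += pod.weight * np.abs(pod.fw(pod_exit_model(pod))) ** 2
    return total
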