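"""Difference-map reconstruction engine with mixed states and sharing.

The engine alternates two projections with difference-map feedback
(beta = 1 fixed):

Fourier-modulus update, per scan point j, simultaneously for all its
coherent channels (wavelength, m, n):

    phi   = 2 p o - psi
    Psi   = fw(phi)
    total = sum_{lam,m,n} w(lam) |Psi|^2
    Y     = 1 - M + M * sqrt(I / max(total, eps_floor))
    phi'  = bw(Psi * Y)
    psi  <- psi + phi' - p o

Invalid detector pixels (M = 0) pass the model through unchanged
(Y = 1 there), so masked data can never influence the reconstruction.

Overlap updates, accumulated through views into cloned containers, with
the sums restricted to the scan points that share each entity:

    o_d = sum_{i: d(i)=d; m} conj(p) psi / (sum |p|^2 + eps)
    p_c = sum_{i: c(i)=c; n} conj(o) psi / (sum |o|^2 + eps)

The regularizer ``eps`` is a relative floor: denominators are clamped
from below at ``eps`` times their mean, which removes division by zero
at uncovered or dark pixels while leaving every pixel above the floor
exactly unbiased (so a consistent reconstruction is a fixed point to
machine precision).  Uncovered object/probe pixels (denominator exactly
zero) keep their previous values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .containers import Container, Pod
from .model import PodNetwork, pod_exit_model

__all__ = [
    "EngineParams",
    "ErrorTrace",
    "DMEngine",
    "fourier_update",
    "object_update",
    "probe_update",
    "orthogonalize_modes",
    "fix_ambiguities",
]

logger = logging.getLogger("ptychokit.engine")


@dataclass
class EngineParams:
    """Difference-map engine configuration.

    numiter : total iterations.
    overlap_inner : alternations of object/probe update per iteration.
    probe_update_start : 1-based iteration at which probe updates begin;
        the default freezes the probe for the first iteration to keep it
        from collapsing against the flat object initialization.
    eps : relative denominator regularizer (scaled by the mean
        denominator at each use).
    clip_object : optional maximum object modulus.
    seed : seed for all randomized initialization.
    """

    numiter: int = 100
    overlap_inner: int = 1
    probe_update_start: int = 2
    eps: float = 1e-10
    clip_object: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if self.numiter < 0:
            raise ValueError("numiter must be >= 0")
        if self.eps < 0:
            raise ValueError("eps must be >= 0")


@dataclass
class ErrorTrace:
    """Per-iteration convergence record."""

    fourier_error: List[float] = field(default_factory=list)
    exit_change: List[float] = field(default_factory=list)

    def __len__(self):
        return len(self.fourier_error)


def _floor(denominator: np.ndarray, eps: float) -> np.ndarray:
    """Clamp a nonnegative denominator from below at eps times its mean."""
    mean = float(np.mean(denominator))
    floor = eps * mean if mean > 0 else eps
    return np.maximum(denominator, floor)


def fourier_update(pods_j: Sequence[Pod], eps: float = 1e-10) -> float:
    """Difference-map Fourier-modulus update for one scan point.

    Updates all exit waves of the scan point in place and returns the
    normalized masked mismatch of the *model* intensity,
    ``sum(M (sum_w |fw(p o)|^2 - I)^2) / sum(M I^2)``, for the error
    trace.  (The feedback field ``2 p o - psi`` keeps a structural
    residual at difference-map fixed points, so its intensity mismatch
    is not a convergence measure; the model intensity vanishes against
    the data exactly when the reconstruction is consistent.)
    """
    pods_j = [p for p in pods_j if p.active]
    if not pods_j:
        raise ValueError("fourier_update of an empty pod list")
    if len({p.j for p in pods_j}) != 1:
        raise ValueError("fourier_update expects pods of a single scan point")
    I = pods_j[0].diff
    M = pods_j[0].mask
    if np.any((I < 0) & (M > 0)):
        raise ValueError("negative measured intensity at valid pixels")

    models = [pod_exit_model(p) for p in pods_j]
    model_total = np.zeros_like(I)
    for p, po in zip(pods_j, models):
        model_total += p.weight * np.abs(p.fw(po)) ** 2
    Psis = [p.fw(2.0 * po - p.exit) for p, po in zip(pods_j, models)]
    total = np.zeros_like(I)
    for p, Psi in zip(pods_j, Psis):
        total += p.weight * np.abs(Psi) ** 2
    Y = 1.0 - M + M * np.sqrt(I / _floor(total, eps))
    for p, Psi, po in zip(pods_j, Psis, models):
        p.exit = p.exit + p.bw(Psi * Y) - po

    denom = float(np.sum(M * I**2))
    err = float(np.sum(M * (model_total - I) ** 2))
    return err / denom if denom > 0 else err


def _overlap_update(
    network: PodNetwork,
    target: str,
    source: str,
    eps: float,
    clip: Optional[float] = None,
) -> None:
    """Weighted-least-squares update of one entity from the exit waves.

    ``target`` is the entity being updated ('object' or 'probe'),
    ``source`` the other factor of the exit-wave product.  Numerator and
    denominator are accumulated through views into cloned containers and
    divided elementwise; the sharing restriction c(i)=c / d(i)=d is
    implicit in which storage each pod's view targets.
    """
    cont = network.containers[target]
    num = cont.clone("num").fill(0.0)
    den = cont.clone("den").fill(0.0)
    for pod in network.pods:
        if not pod.active:
            continue
        other = pod._get(source)
        psi = pod.exit
        view = pod.views[target]
        num.window(view)[...] += np.conj(other) * psi
        den.window(view)[...] += np.abs(other) ** 2
    num.reduce_sum()
    den.reduce_sum()
    for key, storage in cont.storages.items():
        d = den.storages[key].data.real
        n = num.storages[key].data
        covered = d > 0
        new = storage.data.copy()
        new[covered] = n[covered] / _floor(d, eps)[covered]
        if clip is not None:
            mod = np.abs(new)
            high = mod > clip
            new[high] *= clip / mod[high]
        storage.data = new


def object_update(network: PodNetwork, eps: float = 1e-10, clip: Optional[float] = None) -> None:
    """Overlap projection of the object entities (all storages, layers)."""
    _overlap_update(network, "object", "probe", eps, clip)


def probe_update(network: PodNetwork, eps: float = 1e-10) -> None:
    """Overlap projection of the probe entities (roles of p and o swapped)."""
    _overlap_update(network, "probe", "object", eps)


# ----------------------------------------------------------------------
# mode handling and gauge fixing
# ----------------------------------------------------------------------

def orthogonalize_modes(modes: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Orthogonalize a stack of mutually incoherent modes.

    Eigendecomposes the Hermitian Gram matrix ``G[a,b] = sum conj(p_a)
    p_b`` and rotates the modes into its eigenbasis.  Returns the
    rotated stack (mutually orthogonal, total power conserved) and the
    power fractions (eigenvalues / trace) sorted descending; the modes
    are returned in the same descending-power order.
    """
    modes = np.asarray(modes, dtype=complex)
    if modes.ndim != 3 or modes.shape[0] < 1:
        raise ValueError("expected a stack of at least one 2-D mode")
    G = np.tensordot(np.conj(modes), modes, axes=([1, 2], [1, 2]))
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals = np.maximum(vals[order], 0.0)
    vecs = vecs[:, order]
    rotated = np.tensordot(vecs.T, modes, axes=(1, 0))
    total = vals.sum()
    fractions = vals / total if total > 0 else vals
    return rotated, fractions


def orthogonalize_probe(network: PodNetwork, storage_key: Optional[str] = None) -> np.ndarray:
    """Orthogonalize the probe-mode layers of each wavelength in place.

    Returns the power fractions of the (first) probe storage's first
    wavelength block, sorted descending.
    """
    spec = network.spec
    M = spec.n_probe_modes
    keys = [storage_key] if storage_key else sorted(network.containers["probe"].storages)
    fractions = None
    for key in keys:
        storage = network.containers["probe"].storages[key]
        for li in range(len(spec.wavelengths)):
            sl = slice(spec.probe_layer(li, 0), spec.probe_layer(li, M - 1) + 1)
            rotated, frac = orthogonalize_modes(storage.data[sl])
            storage.data[sl] = rotated
            if fractions is None:
                fractions = frac
    return fractions


def _remove_phase_ramp(network: PodNetwork) -> None:
    """Fix the linear-phase-ramp gauge by centring the probe spectrum.

    A ramp ``exp(2 pi i v.x)`` on the probe compensated by the conjugate
    ramp on the object changes every frame only by a constant phase, so
    it is invisible to the data.  The gauge is fixed by demanding zero
    mean transverse spatial frequency of the probe: the far-field
    intensity centroid of all probe layers is computed and the
    corresponding ramp is divided out of the probe (and multiplied onto
    the object) on each storage's physical grid; exit waves pick up the
    per-frame constant phases to stay consistent.
    """
    probe_cont = network.containers["probe"]
    # power-weighted circular mean of the phase gradient = mean transverse
    # frequency; exact for |p| e^{2 pi i v.x} and insensitive to the
    # window truncation that biases a far-field centroid estimate
    acc = np.zeros(2, dtype=complex)
    psize = None
    for storage in probe_cont.storages.values():
        psize = storage.psize
        for layer in storage.data:
            acc[0] += np.sum(layer[1:, :] * np.conj(layer[:-1, :]))
            acc[1] += np.sum(layer[:, 1:] * np.conj(layer[:, :-1]))
    if np.all(np.abs(acc) == 0):
        return
    v = np.angle(acc) / (2.0 * np.pi * psize)
    for storage in probe_cont.storages.values():
        r, c = storage.grids()
        storage.data *= np.exp(-2j * np.pi * (v[0] * r + v[1] * c))
    for storage in network.containers["object"].storages.values():
        r, c = storage.grids()
        storage.data *= np.exp(2j * np.pi * (v[0] * r + v[1] * c))
    for pod in network.pods:  # p(x) o(x - y_j) gains exp(-2 pi i v.y_j)
        if pod.active:
            y = network.spec.positions[pod.j]
            pod.exit = pod.exit * np.exp(-2j * np.pi * float(v @ y))


def fix_ambiguities(
    network: PodNetwork,
    remove_phase: bool = True,
    remove_ramp: bool = True,
    coverage_quantile: float = 0.5,
) -> float:
    """Remove the inherent p*o gauge freedoms of the ptychographic model.

    Rescales the probe so its total power equals the maximum total frame
    intensity, applying the inverse scale to the object; optionally
    removes the linear-phase-ramp gauge (probe spectral centroid to
    zero) and sets the mean object phase over the well-covered region
    (illumination coverage >= ``coverage_quantile`` of its maximum) to
    zero.  Idempotent, invariant under the gauge (a p, o / a), and
    leaves all model intensities unchanged.  Returns the amplitude scale
    applied to the probe.
    """
    probe_cont = network.containers["probe"]
    obj_cont = network.containers["object"]
    power = probe_cont.total_power()
    if power <= 0:
        raise ValueError("probe has zero power; gauge undefined")
    target = network.frames.max_valid_power()
    a = np.sqrt(target / power)
    probe_cont.scale(a)
    obj_cont.scale(1.0 / a)
    # exit waves are gauge invariant (p*o unchanged) and need no rescale
    if remove_ramp:
        _remove_phase_ramp(network)
    if remove_phase:
        coverage = obj_cont.clone("coverage").fill(0.0)
        for pod in network.pods:
            if pod.active:
                coverage.window(pod.views["object"])[...] += np.abs(pod.probe) ** 2
        for key, storage in obj_cont.storages.items():
            cov = coverage.storages[key].data.real
            region = cov >= coverage_quantile * cov.max()
            mean = storage.data[region].sum()
            if np.abs(mean) > 0:
                phase = np.exp(-1j * np.angle(mean))
                storage.data *= phase
                probe_cont.scale(np.conj(phase))
    return a


# ----------------------------------------------------------------------
# iteration loop
# ----------------------------------------------------------------------

class DMEngine:
    """Simple difference-map engine over a pod network."""

    def __init__(self, network: PodNetwork, params: Optional[EngineParams] = None):
        self.network = network
        self.params = params or EngineParams()
        self.trace = ErrorTrace()
        self._iteration = 0
        self._by_frame = [
            (j, network.pods_of_frame(j)) for j in network.frame_indices
        ]

    # -- initialization -------------------------------------------------
    def initialize(self, probe_init: Optional[np.ndarray] = None) -> None:
        """Set starting probe, object and exit waves.

        ``probe_init`` is a (modes, R, C) stack (a single 2-D array is
        promoted to one mode).  Missing probe modes are filled with
        seeded random-phase copies at 1% relative power; extra object
        modes get a seeded 1% random phase perturbation to break the
        symmetry of the flat start.  All randomness derives from
        ``params.seed``.
        """
        net = self.network
        spec = net.spec
        rng = np.random.default_rng(self.params.seed)
        if probe_init is None:
            probe_init = self._default_probe()
        probe_init = np.asarray(probe_init, dtype=complex)
        if probe_init.ndim == 2:
            probe_init = probe_init[None]
        shape = net.frames.frame_shape
        for storage in net.containers["probe"].storages.values():
            for li in range(len(spec.wavelengths)):
                for m in range(spec.n_probe_modes):
                    if m < probe_init.shape[0]:
                        layer = probe_init[m]
                    else:
                        phase = rng.uniform(-np.pi, np.pi, size=shape)
                        layer = probe_init[0] * np.exp(1j * phase) * 0.1
                    storage.data[spec.probe_layer(li, m)] = layer
        for storage in net.containers["object"].storages.values():
            storage.data[...] = 1.0
            for li in range(len(spec.wavelengths)):
                for n in range(1, spec.n_object_modes):
                    layer = spec.object_layer(li, n)
                    perturb = rng.uniform(-0.01 * np.pi, 0.01 * np.pi, storage.data.shape[1:])
                    storage.data[layer] = storage.data[layer] * np.exp(1j * perturb)
        for pod in net.pods:
            if pod.active:
                pod.exit = pod_exit_model(pod)
        self._iteration = 0
        self.trace = ErrorTrace()

    def _default_probe(self) -> np.ndarray:
        """Power-matched flat circular aperture covering half the frame."""
        net = self.network
        R, C = net.frames.frame_shape
        r = np.arange(R) - R // 2
        c = np.arange(C) - C // 2
        disc = ((r[:, None] / (R / 4.0)) ** 2 + (c[None, :] / (C / 4.0)) ** 2 <= 1.0)
        probe = disc.astype(complex)
        target = net.frames.max_valid_power()
        power = float(np.sum(np.abs(probe) ** 2))
        if target > 0 and power > 0:
            probe *= np.sqrt(target / power)
        return probe

    # -- iteration ------------------------------------------------------
    def iterate(self, numiter: Optional[int] = None) -> ErrorTrace:
        """Run difference-map iterations; returns the cumulative trace.

        Each iteration applies the Fourier update to every scan point in
        ascending j order, then ``overlap_inner`` alternations of object
        and probe updates (the probe frozen before
        ``probe_update_start``).  Deterministic given seed and inputs.
        """
        p = self.params
        n = p.numiter if numiter is None else numiter
        exit_storage = self.network.containers["exit"].storages["ex"]
        for _ in range(n):
            self._iteration += 1
            before = exit_storage.data.copy()
            errs = [fourier_update(pods, eps=p.eps) for _, pods in self._by_frame]
            prev = float(np.sum(np.abs(before) ** 2))
            delta = float(np.sum(np.abs(exit_storage.data - before) ** 2))
            exit_change = delta / prev if prev > 0 else delta
            for _ in range(max(1, p.overlap_inner)):
                object_update(self.network, eps=p.eps, clip=p.clip_object)
                if self._iteration >= p.probe_update_start:
                    probe_update(self.network, eps=p.eps)
            fe = float(np.mean(errs))
            self.trace.fourier_error.append(fe)
            self.trace.exit_change.append(exit_change)
            logger.info("iter=%d fourier_error=%.6e exit_change=%.6e",
                        self._iteration, fe, exit_change)
        return self.trace
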