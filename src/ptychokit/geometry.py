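"""Scan geometry and coherent free-space propagators.

A :class:`Geometry` ties together the physical parameters of one
diffraction scan -- wavelength, sample-to-detector distance, detector
pixel size and frame shape -- and provides the forward/backward
propagator pair that pods use for coherent propagation.

Two regimes are supported:

``farfield``
    Fraunhofer diffraction: the detected field is the Fourier transform
    of the exit wave.  The real-space pixel size follows from the
    sampling relation ``v = s / (lambda * z)``: a detector pixel of size
    ``dpsize`` steps the spatial frequency by ``dpsize/(lambda*z)``, so
    the real-space field of view is ``lambda*z/dpsize`` and one
    real-space pixel is ``lambda*z/(N*dpsize)``.

``nearfield``
    Angular-spectrum propagation: a frequency-domain transfer function
    ``H(v) = exp(2*pi*i*z*sqrt(lambda**-2 - v**2))`` applied between two
    planes that share the same pixel grid (``rpsize == dpsize``).

All transforms are orthonormal (unitary) and zero-frequency-centred, so
photon counts are directly comparable between the sample and detector
planes and Parseval checks are exact to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

__all__ = ["Geometry", "GeometryError"]


class GeometryError(ValueError):
    """Invalid geometry parameters or field shapes."""


def _as_pair(value) -> Tuple[float, float]:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (2,))
    return (float(arr[0]), float(arr[1]))


def _centered_fft2(a: np.ndarray) -> np.ndarray:
    # ifftshift moves the array-centre sample to index 0, fftshift puts
    # zero frequency back at the centre (index N//2 for even N).
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(a), norm="ortho"))


def _centered_ifft2(a: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(a), norm="ortho"))


@dataclass(frozen=True)
class Geometry:
    """Physical geometry of one scan and its propagator pair.

    Parameters
    ----------
    lam : float
        Wavelength in metres (> 0).
    z : float
        Propagation distance in metres.  Any real value in the near
        field (backward propagation uses ``-z``); nonzero in the far
        field, where it enters the sampling relation.
    dpsize : float or pair of float
        Detector pixel size per axis in metres (> 0).
    N : pair of int
        Frame shape ``(rows, cols)`` in pixels, each >= 2.
    regime : {"farfield", "nearfield"}
    """

    lam: float
    z: float
    dpsize: Tuple[float, float]
    N: Tuple[int, int]
    regime: str = "farfield"

    def __post_init__(self):
        object.__setattr__(self, "dpsize", _as_pair(self.dpsize))
        object.__setattr__(self, "N", (int(self.N[0]), int(self.N[1])))
        if self.lam <= 0:
            raise GeometryError(f"wavelength must be positive, got {self.lam}")
        if min(self.dpsize) <= 0:
            raise GeometryError(f"detector pixel size must be positive, got {self.dpsize}")
        if min(self.N) < 2:
            raise GeometryError(f"frame shape components must be >= 2, got {self.N}")
        if self.regime not in ("farfield", "nearfield"):
            raise GeometryError(f"unknown regime {self.regime!r}")

    # ------------------------------------------------------------------
    # sampling relations
    # ------------------------------------------------------------------
    @property
    def rpsize(self) -> Tuple[float, float]:
        """Real-space (sample-plane) pixel size in metres per axis."""
        if self.regime == "farfield":
            return tuple(
                abs(self.lam * self.z) / (n * d) for n, d in zip(self.N, self.dpsize)
            )
        return self.dpsize

    def frequency_of_pixel(self, s) -> np.ndarray:
        """Spatial frequency ``v = s/(lam*z)`` of detector coordinate ``s`` (metres)."""
        if self.regime == "farfield" and self.z == 0:
            raise GeometryError("far-field sampling relation undefined for z = 0")
        return np.asarray(s, dtype=float) / (self.lam * self.z)

    def frequency_grid(self) -> Tuple[np.ndarray, np.ndarray]:
        """Centred spatial-frequency samples per axis (1/m), broadcastable to ``N``."""
        ps = self.rpsize
        vr = np.fft.fftshift(np.fft.fftfreq(self.N[0], d=ps[0]))
        vc = np.fft.fftshift(np.fft.fftfreq(self.N[1], d=ps[1]))
        return vr[:, None], vc[None, :]

    def with_wavelength(self, lam: float) -> "Geometry":
        """A copy of this geometry at another wavelength (propagators differ)."""
        return replace(self, lam=lam)

    # ------------------------------------------------------------------
    # far-field (Fraunhofer) propagators
    # ------------------------------------------------------------------
    def _check_shape(self, a: np.ndarray) -> np.ndarray:
        a = np.asarray(a)
        if a.shape != self.N:
            raise GeometryError(f"field shape {a.shape} does not match frame shape {self.N}")
        return a

    def fw_farfield(self, field: np.ndarray) -> np.ndarray:
        """Centred orthonormal 2-D Fourier transform of ``field``."""
        return _centered_fft2(self._check_shape(field))

    def bw_farfield(self, field: np.ndarray) -> np.ndarray:
        """Exact inverse of :meth:`fw_farfield`."""
        return _centered_ifft2(self._check_shape(field))

    # ------------------------------------------------------------------
    # near-field (angular spectrum) propagators
    # ------------------------------------------------------------------
    def transfer_function(self, z: float | None = None) -> np.ndarray:
        """Angular-spectrum transfer function H(v) on the centred frequency grid.

        ``H(v) = exp(2*pi*i*z*sqrt(lam**-2 - |v|**2))`` for propagating
        components; evanescent components (``|v| > 1/lam``) are set to
        exactly zero, a deterministic contract that also avoids overflow
        for negative ``z``.
        """
        if z is None:
            z = self.z
        vr, vc = self.frequency_grid()
        v2 = vr**2 + vc**2
        kz2 = self.lam**-2 - v2
        propagating = kz2 > 0
        H = np.zeros(self.N, dtype=complex)
        H[propagating] = np.exp(2j * np.pi * z * np.sqrt(kz2[propagating]))
        return H

    def fw_nearfield(self, field: np.ndarray, z: float | None = None) -> np.ndarray:
        """Angular-spectrum propagation over distance ``z`` (default: ``self.z``)."""
        field = self._check_shape(field)
        return _centered_ifft2(_centered_fft2(field) * self.transfer_function(z))

    def bw_nearfield(self, field: np.ndarray) -> np.ndarray:
        """Backward angular-spectrum propagation (distance ``-z``)."""
        return self.fw_nearfield(field, z=-self.z)

    # ------------------------------------------------------------------
    # regime dispatch used by pods
    # ------------------------------------------------------------------
    def fw(self, field: np.ndarray) -> np.ndarray:
        """Forward propagator for this geometry's regime."""
        if self.regime == "farfield":
            return self.fw_farfield(field)
        return self.fw_nearfield(field)

    def bw(self, field: np.ndarray) -> np.ndarray:
        """Backward propagator (exact inverse of :meth:`fw` on the propagating band)."""
        if self.regime == "farfield":
            return self.bw_farfield(field)
        return self.bw_nearfield(field)
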