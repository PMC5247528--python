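"""Storage abstraction: views, storages, containers and pods.

This layer decouples engine algebra from buffer indexing.  A *view* is a
placed rectangular region of interest: it binds a physical centre
coordinate (metres) to a pixel slice of a *storage*.  A storage is a
stack of 2-D layers living on a physical grid (pixel size + origin) that
grows on demand to cover its views.  A *container* holds all views and
storages of one entity; exactly five entity containers exist per
reconstruction: ``probe``, ``object``, ``exit``, ``diff`` and ``mask``.

A *pod* is the elementary unit of the forward model: one combination of
(scan point j, wavelength index, probe mode m, object mode n), equipped
with one view per entity and a propagator pair, i.e. everything needed
to perform one coherent propagation.

Coordinate convention: row-major arrays, axis 0 vertical; physical
coordinates refer to pixel centres; a storage's ``origin`` is the
physical coordinate of pixel (0, 0).  Pixel ranges are half-open.
Position-to-pixel mapping is round-to-nearest of ``(center - origin) /
psize`` with half-extent ``shape // 2``; sub-pixel remainders are
discarded (no sub-pixel interpolation).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

__all__ = [
    "View",
    "Storage",
    "Container",
    "Pod",
    "ENTITIES",
    "UnformattedError",
    "EmptyStorageError",
    "view_to_slice",
]

ENTITIES = ("probe", "object", "exit", "diff", "mask")

#: Default buffer fill per entity: empty space transmits for the object,
#: everything else starts dark.
DEFAULT_FILL = {"probe": 0.0, "object": 1.0, "exit": 0.0, "diff": 0.0, "mask": 0.0}

COMPLEX_ENTITIES = ("probe", "object", "exit")

_view_ids = itertools.count()


class UnformattedError(RuntimeError):
    """A view's slice exceeds its storage buffer; reformat the container first."""


class EmptyStorageError(RuntimeError):
    """A storage has no active views, so its extent is undefined."""


@dataclass
class View:
    """A placed rectangular region of interest on a storage.

    ``layer`` selects one 2-D layer of the storage stack; the model
    layer encodes mode and wavelength indices into it.
    """

    entity: str
    storage_key: str
    center: np.ndarray  # physical 2-vector, metres
    shape: Tuple[int, int]
    layer: int = 0
    active: bool = True
    id: int = field(default_factory=lambda: next(_view_ids))

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(2).copy()
        self.shape = (int(self.shape[0]), int(self.shape[1]))
        if min(self.shape) < 1:
            raise ValueError(f"view shape components must be >= 1, got {self.shape}")
        if not np.all(np.isfinite(self.center)):
            raise ValueError(f"view center must be finite, got {self.center}")


@dataclass
class Storage:
    """A stack of 2-D layers on a physical grid.

    ``data`` is ``None`` until the owning container is reformatted.
    ``origin`` is the physical coordinate of the centre of pixel (0, 0).
    """

    key: str
    psize: np.ndarray  # metres / pixel, per axis
    origin: np.ndarray = None
    fill: complex = 0.0
    dtype: np.dtype = np.complex128
    data: Optional[np.ndarray] = None

    def __post_init__(self):
        self.psize = np.broadcast_to(np.asarray(self.psize, dtype=float), (2,)).copy()
        if np.any(self.psize <= 0):
            raise ValueError(f"psize must be positive, got {self.psize}")
        if self.origin is None:
            self.origin = np.zeros(2)
        self.origin = np.asarray(self.origin, dtype=float).reshape(2).copy()

    @property
    def nlayers(self) -> int:
        return 0 if self.data is None else self.data.shape[0]

    @property
    def frame_shape(self) -> Tuple[int, int]:
        if self.data is None:
            raise UnformattedError(f"storage {self.key!r} has no buffer yet")
        return self.data.shape[1:]

    def grids(self) -> Tuple[np.ndarray, np.ndarray]:
        """Physical coordinates of pixel centres, broadcastable to the layer shape."""
        R, C = self.frame_shape
        r = self.origin[0] + np.arange(R) * self.psize[0]
        c = self.origin[1] + np.arange(C) * self.psize[1]
        return r[:, None], c[None, :]


def _pixel_start(view: View, storage: Storage) -> np.ndarray:
    idx = np.rint((view.center - storage.origin) / storage.psize).astype(int)
    half = np.asarray(view.shape, dtype=int) // 2
    return idx - half


def view_to_slice(view: View, storage: Storage) -> Tuple[int, int, int, int]:
    """Resolve a view to half-open pixel ranges ``(r0, r1, c0, c1)``.

    ``start = round((center - origin)/psize) - shape//2`` per axis,
    ``stop = start + shape``.  Raises :class:`UnformattedError` if the
    ranges exceed the storage buffer (the caller must reformat first).
    """
    if view.storage_key != storage.key:
        raise ValueError(f"view targets {view.storage_key!r}, not storage {storage.key!r}")
    start = _pixel_start(view, storage)
    stop = start + np.asarray(view.shape, dtype=int)
    if storage.data is None:
        raise UnformattedError(
            f"storage {storage.key!r} is unformatted; reformat the container first"
        )
    R, C = storage.data.shape[1:]
    if start[0] < 0 or start[1] < 0 or stop[0] > R or stop[1] > C:
        raise UnformattedError(
            f"view {view.id} slice rows [{start[0]},{stop[0]}) cols "
            f"[{start[1]},{stop[1]}) exceeds buffer {R}x{C} of storage "
            f"{storage.key!r}; reformat the container first"
        )
    return int(start[0]), int(stop[0]), int(start[1]), int(stop[1])


class Container:
    """All views and storages of one entity, with in-place maths.

    Engines clone containers to obtain accumulation buffers (e.g. the
    denominator of the overlap updates) that share shapes, origins and
    view resolution with the original but own independent data.
    """

    def __init__(self, entity: str, tag: str = ""):
        if entity not in ENTITIES:
            raise ValueError(f"unknown entity {entity!r}; expected one of {ENTITIES}")
        self.entity = entity
        self.tag = tag
        self.dtype = np.complex128 if entity in COMPLEX_ENTITIES else np.float64
        self.storages: Dict[str, Storage] = {}
        self.views: Dict[int, View] = {}

    # -- construction ---------------------------------------------------
    def new_storage(self, key: str, psize, fill=None) -> Storage:
        if key in self.storages:
            raise ValueError(f"storage {key!r} already exists in {self.entity} container")
        if fill is None:
            fill = DEFAULT_FILL[self.entity]
        s = Storage(key=key, psize=psize, fill=fill, dtype=self.dtype)
        self.storages[key] = s
        return s

    def add_view(self, view: View) -> View:
        if view.entity != self.entity:
            raise ValueError(f"view entity {view.entity!r} != container entity {self.entity!r}")
        if view.storage_key not in self.storages:
            raise KeyError(f"view targets unknown storage {view.storage_key!r}")
        self.views[view.id] = view
        return view

    # -- reformat -------------------------------------------------------
    def reformat(self) -> None:
        """Grow every storage to cover the union of its active views.

        Pre-existing data is preserved at unchanged physical
        coordinates; newly allocated area holds the storage's fill
        value.  Idempotent for a fixed set of views.
        """
        by_storage: Dict[str, list] = {k: [] for k in self.storages}
        for v in self.views.values():
            if v.active:
                by_storage[v.storage_key].append(v)
        for key, views in by_storage.items():
            self._reformat_storage(self.storages[key], views)

    def _reformat_storage(self, storage: Storage, views: list) -> None:
        if not views:
            raise EmptyStorageError(
                f"storage {storage.key!r} of {self.entity} container has no active views"
            )
        starts = np.array([_pixel_start(v, storage) for v in views])
        stops = starts + np.array([v.shape for v in views])
        lo = starts.min(axis=0)
        hi = stops.max(axis=0)
        nlayers = 1 + max(v.layer for v in views)
        if storage.data is not None:
            # never drop existing physical extent or layers
            lo = np.minimum(lo, 0)
            hi = np.maximum(hi, storage.data.shape[1:])
            nlayers = max(nlayers, storage.data.shape[0])
            if (
                nlayers == storage.data.shape[0]
                and np.all(lo == 0)
                and np.all(hi == storage.data.shape[1:])
            ):
                return  # already covering; idempotent no-op
        new = np.full(
            (nlayers, int(hi[0] - lo[0]), int(hi[1] - lo[1])),
            storage.fill,
            dtype=storage.dtype,
        )
        if storage.data is not None:
            L, R, C = storage.data.shape
            r0, c0 = int(-lo[0]), int(-lo[1])
            new[:L, r0 : r0 + R, c0 : c0 + C] = storage.data
        storage.data = new
        storage.origin = storage.origin + lo * storage.psize

    # -- data access ----------------------------------------------------
    def _resolve(self, view: View) -> Tuple[Storage, Tuple[int, int, int, int]]:
        if view.id not in self.views:
            raise KeyError(f"unknown view {view.id} for {self.entity} container")
        storage = self.storages[view.storage_key]
        return storage, view_to_slice(view, storage)

    def window(self, view: View) -> np.ndarray:
        """Writable numpy window of the view's layer (shares memory)."""
        storage, (r0, r1, c0, c1) = self._resolve(view)
        return storage.data[view.layer, r0:r1, c0:c1]

    def get_data(self, view: View) -> np.ndarray:
        """Copy of the 2-D data under the view."""
        return self.window(view).copy()

    def set_data(self, view: View, data) -> None:
        data = np.asarray(data)
        if data.shape != tuple(view.shape):
            raise ValueError(f"data shape {data.shape} != view shape {view.shape}")
        self.window(view)[...] = data

    __getitem__ = get_data
    __setitem__ = set_data

    # -- clone and maths ------------------------------------------------
    def clone(self, tag: str = "clone") -> "Container":
        """Deep-copied buffers; the original's views resolve into the clone."""
        c = Container(self.entity, tag=tag)
        for key, s in self.storages.items():
            cs = Storage(
                key=key, psize=s.psize, origin=s.origin, fill=s.fill, dtype=s.dtype
            )
            cs.data = None if s.data is None else s.data.copy()
            c.storages[key] = cs
        c.views = dict(self.views)
        return c

    def fill(self, value) -> "Container":
        for s in self.storages.values():
            if s.data is not None:
                s.data[...] = value
        return self

    def scale(self, a) -> "Container":
        for s in self.storages.values():
            if s.data is not None:
                s.data *= a
        return self

    def add(self, other: "Container") -> "Container":
        if set(self.storages) != set(other.storages):
            raise ValueError(
                f"incompatible storage sets: {sorted(self.storages)} vs {sorted(other.storages)}"
            )
        for key, s in self.storages.items():
            o = other.storages[key]
            if s.data is None or o.data is None or s.data.shape != o.data.shape:
                raise ValueError(f"storage {key!r} buffers incompatible for add")
            s.data += o.data
        return self

    def reduce_sum(self) -> "Container":
        """Cross-process summation hook; identity in single-process mode."""
        return self

    def total_power(self) -> float:
        """Sum of |data|^2 over all storages (photon-count style norm)."""
        return float(sum(np.sum(np.abs(s.data) ** 2) for s in self.storages.values()))


@dataclass
class Pod:
    """One coherent propagation channel of the ptychographic model.

    Indexed by scan point ``j``, wavelength index ``lam``, probe mode
    ``m`` and object mode ``n``; carries one view per entity, the
    wavelength weight of the incoherent spectral sum, and the
    propagator-owning geometry.
    """

    j: int
    lam: int
    m: int
    n: int
    views: Dict[str, View]
    geometry: object
    containers: Dict[str, Container]
    weight: float = 1.0
    active: bool = True

    def fw(self, field: np.ndarray) -> np.ndarray:
        return self.geometry.fw(field)

    def bw(self, field: np.ndarray) -> np.ndarray:
        return self.geometry.bw(field)

    def _get(self, entity: str) -> np.ndarray:
        return self.containers[entity].get_data(self.views[entity])

    def _set(self, entity: str, data) -> None:
        self.containers[entity].set_data(self.views[entity], data)

    probe = property(lambda self: self._get("probe"), lambda self, d: self._set("probe", d))
    object = property(lambda self: self._get("object"), lambda self, d: self._set("object", d))
    exit = property(lambda self: self._get("exit"), lambda self, d: self._set("exit", d))
    diff = property(lambda self: self._get("diff"), lambda self, d: self._set("diff", d))
    mask = property(lambda self: self._get("mask"), lambda self, d: self._set("mask", d))
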