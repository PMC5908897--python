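"""5D hyperstack container and ImageJ-dialect TIFF I/O.

The in-memory convention throughout the package is a single canonical axis
order ``(c, t, z, y, x)``: channel, time-stack, focal plane, image row,
image column.  On disk, the ImageJ hyperstack dialect stores one 2D (y, x)
page per (c, z, t) combination, interleaved with the channel index varying
fastest, then z, then t::

    page p  <->  (c, z, t)   with   p = t * (Z * C) + z * C + c

Dimension counts are carried in the ImageJ plain-text metadata block
(``images``/``channels``/``slices``/``frames``); physical calibration rides
on the TIFF resolution tags (x, y), the ImageJ ``spacing`` (z, micrometers)
and ``finterval`` (seconds per complete z-stack).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

from .errors import AddressError, DimensionError, LayoutError, RangeError, WriteError

__all__ = [
    "Hyperstack",
    "PlaneAddress",
    "read_imagej_tiff",
    "write_imagej_tiff",
    "get_plane",
    "crop",
    "page_to_address",
    "address_to_page",
]

#: voxel dtypes the ImageJ dialect supports
SUPPORTED_DTYPES = (np.uint8, np.uint16, np.float32)


@dataclass
class Hyperstack:
    """A 5D imaging volume with axis semantics (c, t, z, y, x).

    Parameters
    ----------
    data
        Voxel array of shape ``(C, T, Z, Y, X)``; dtype uint8, uint16 or
        float32.
    voxel_size_um
        Physical voxel size ``(x, y, z)`` in micrometers.
    stack_period_s
        Seconds per complete z-stack (volume rate = 1 / stack_period_s).
    channel_labels
        One label per channel; auto-filled as ``ch0, ch1, ...``.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    stack_period_s: float = 1.0
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise DimensionError(
                f"hyperstack data must be 5D (c,t,z,y,x); got {self.data.ndim}D"
            )
        if any(s < 1 for s in self.data.shape):
            raise DimensionError(f"all dimensions must be >= 1; got {self.data.shape}")
        if not any(self.data.dtype.type is t for t in SUPPORTED_DTYPES):
            raise DimensionError(
                f"dtype must be uint8, uint16 or float32; got {self.data.dtype}"
            )
        vx, vy, vz = self.voxel_size_um
        if not (vx > 0 and vy > 0 and vz > 0):
            raise DimensionError(f"voxel_size_um must be > 0; got {self.voxel_size_um}")
        if not self.stack_period_s > 0:
            raise DimensionError(f"stack_period_s must be > 0; got {self.stack_period_s}")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise DimensionError("channel_labels length must equal channel count")

    # -- convenience ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_stacks(self) -> int:
        return self.data.shape[1]

    @property
    def n_planes(self) -> int:
        return self.data.shape[2]

    def as_float32(self) -> "Hyperstack":
        """Return a float32 copy (identity if already float32)."""
        if self.data.dtype == np.float32:
            return self
        return replace(self, data=self.data.astype(np.float32))

    def with_data(self, data: np.ndarray) -> "Hyperstack":
        """New hyperstack with the same calibration but different voxels."""
        return replace(self, data=data)


@dataclass(frozen=True)
class PlaneAddress:
    """0-based (channel, time-stack, z-plane) address of one 2D page."""

    c: int
    t: int
    z: int


def page_to_address(p: int, n_channels: int, n_planes: int) -> tuple[int, int, int]:
    """Map a 0-based TIFF page index to (c, z, t) under ImageJ interleaving."""
    c = p % n_channels
    z = (p // n_channels) % n_planes
    t = p // (n_channels * n_planes)
    return c, z, t


def address_to_page(c: int, z: int, t: int, n_channels: int, n_planes: int) -> int:
    """Inverse of :func:`page_to_address`."""
    return t * (n_planes * n_channels) + z * n_channels + c


def get_plane(stack: Hyperstack, addr: PlaneAddress) -> np.ndarray:
    """Extract the single 2D (y, x) frame at the given (c, t, z) address."""
    C, T, Z = stack.shape[:3]
    if not (0 <= addr.c < C and 0 <= addr.t < T and 0 <= addr.z < Z):
        raise AddressError(
            f"address (c={addr.c}, t={addr.t}, z={addr.z}) outside shape (C={C}, T={T}, Z={Z})"
        )
    return stack.data[addr.c, addr.t, addr.z]


def crop(stack: Hyperstack, ranges: dict[str, tuple[int, int]]) -> Hyperstack:
    """Crop along any subset of axes with half-open 0-based intervals.

    ``ranges`` maps axis names among ``c, t, z, y, x`` to ``(start, stop)``.
    Calibration metadata is preserved; channel labels follow the c interval.
    """
    axes = "ctzyx"
    slicer: list[slice] = []
    for i, ax in enumerate(axes):
        n = stack.data.shape[i]
        lo, hi = ranges.get(ax, (0, n))
        if not (0 <= lo < hi <= n):
            raise RangeError(f"axis {ax!r}: interval [{lo},{hi}) invalid for size {n}")
        slicer.append(slice(lo, hi))
    unknown = set(ranges) - set(axes)
    if unknown:
        raise RangeError(f"unknown axes {sorted(unknown)}; expected subset of {list(axes)}")
    c_lo, c_hi = ranges.get("c", (0, stack.n_channels))
    return Hyperstack(
        data=stack.data[tuple(slicer)].copy(),
        voxel_size_um=stack.voxel_size_um,
        stack_period_s=stack.stack_period_s,
        channel_labels=stack.channel_labels[c_lo:c_hi],
    )


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def read_imagej_tiff(
    path,
    shape_override: tuple[int, int, int] | None = None,
) -> Hyperstack:
    """Read a multi-page TIFF in the ImageJ hyperstack dialect.

    Parameters
    ----------
    path
        TIFF file path.
    shape_override
        ``(C, T, Z)`` counts to use when the file carries no ImageJ
        dimension metadata (plain multi-page TIFFs).

    Raises
    ------
    DimensionError
        If dimension counts are neither present in metadata nor supplied.
    LayoutError
        If the page count does not equal ``C * Z * T``.
    """
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        arr = series.asarray()
        meta = tf.imagej_metadata or {}
        page0 = tf.pages[0]
        vx = vy = 1.0
        try:
            num, den = page0.tags["XResolution"].value
            if num:
                vx = den / num
            num, den = page0.tags["YResolution"].value
            if num:
                vy = den / num
        except KeyError:
            pass

    if arr.ndim == 2:
        arr = arr[None]
    Y, X = arr.shape[-2:]
    pages = arr.reshape(-1, Y, X)
    n_pages = pages.shape[0]

    if shape_override is not None:
        C, T, Z = shape_override
    elif meta:
        C = int(meta.get("channels", 1))
        Z = int(meta.get("slices", 1))
        T = int(meta.get("frames", 1))
        declared = meta.get("images")
        if declared is not None and int(declared) != C * Z * T:
            raise DimensionError(
                f"metadata contradictory: images={declared} but C*Z*T={C * Z * T}"
            )
    else:
        if n_pages != 1:
            raise DimensionError(
                "no ImageJ dimension metadata; supply shape_override=(C, T, Z)"
            )
        C, T, Z = 1, 1, 1

    if n_pages != C * Z * T:
        raise LayoutError(
            f"page count {n_pages} != C*Z*T = {C}*{Z}*{T} = {C * Z * T}"
        )

    # de-interleave: page order is c fastest, then z, then t
    data = pages.reshape(T, Z, C, Y, X).transpose(2, 0, 1, 3, 4).copy()

    vz = float(meta.get("spacing", 1.0)) or 1.0
    period = float(meta.get("finterval", 0.0)) or 1.0
    labels = _labels_from_info(meta.get("Info", ""), C)
    return Hyperstack(
        data=data,
        voxel_size_um=(vx, vy, vz),
        stack_period_s=period,
        channel_labels=labels,
    )


def write_imagej_tiff(stack: Hyperstack, path) -> None:
    """Write a hyperstack as an ImageJ-dialect multi-page TIFF.

    Pages are emitted in ImageJ interleave order (c fastest, then z, then
    t); metadata records C/Z/T, voxel size, and stack period so that
    :func:`read_imagej_tiff` round-trips bit-exactly.
    """
    vx, vy, vz = stack.voxel_size_um
    # tifffile's imagej writer expects TZCYX ordering
    data = np.ascontiguousarray(stack.data.transpose(1, 2, 0, 3, 4))
    info = "\n".join(
        f"channel_{i}={lbl}" for i, lbl in enumerate(stack.channel_labels)
    )
    try:
        tifffile.imwrite(
            path,
            data,
            imagej=True,
            resolution=(1.0 / vx, 1.0 / vy),
            metadata={
                "axes": "TZCYX",
                "spacing": vz,
                "unit": "um",
                "finterval": stack.stack_period_s,
                "Info": info,
            },
        )
    except OSError as exc:
        raise WriteError(f"cannot write {path}: {exc}") from exc


def _labels_from_info(info: str, n_channels: int) -> list[str]:
    labels = [f"ch{i}" for i in range(n_channels)]
    for line in str(info).splitlines():
        if "=" in line and line.startswith("channel_"):
            key, val = line.split("=", 1)
            try:
                i = int(key[len("channel_"):])
            except ValueError:
                continue
            if 0 <= i < n_channels:
                labels[i] = val
    return labels
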