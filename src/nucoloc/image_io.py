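"""Multi-channel z-stack and tabular I/O.

Images are carried through the pipeline as :class:`ImageStack` objects: a
4-D ``uint8`` array indexed ``(z, y, x, channel)`` together with the physical
voxel size ``(dz, dy, dx)`` in micrometres and a mapping from channel index
to fluorophore role.  Per-nucleus results travel as flat records written to
CSV; missing coefficients (e.g. a skipped Costes test) round-trip as empty
cells, never as zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

#: Channel roles understood by the pipeline.
ROLES = ("DAPI", "H3K4m3", "PMP22", "LMNB1")

#: Acquisition voxel size (dz, dy, dx) in µm used when none is supplied.
DEFAULT_VOXEL_SIZE = (1.00, 0.379, 0.379)


@dataclass
class ImageStack:
    """A multi-channel 3-D intensity stack with physical metadata.

    Parameters
    ----------
    voxels
        ``uint8`` array of shape ``(z, y, x, channel)``; intensities in [0, 255].
    voxel_size
        ``(dz, dy, dx)`` in µm; every component must be positive.
    channel_roles
        Mapping ``channel index -> role``; roles must be unique and drawn
        from :data:`ROLES`.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    channel_roles: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(f"voxels must be 4-D (z, y, x, channel), got shape {self.voxels.shape}")
        if self.voxels.dtype != np.uint8:
            self.voxels = _to_uint8(self.voxels)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be three positive lengths, got {self.voxel_size}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        roles = dict(self.channel_roles)
        for idx, role in roles.items():
            if role not in ROLES:
                raise ValueError(f"unknown channel role {role!r}; expected one of {ROLES}")
            if not 0 <= idx < self.voxels.shape[3]:
                raise ValueError(f"channel index {idx} out of range for {self.voxels.shape[3]} channels")
        if len(set(roles.values())) != len(roles):
            raise ValueError("channel_roles must be injective (one channel per role)")
        self.channel_roles = roles

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.voxels.shape

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[3]

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in µm³."""
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def channel(self, role: str) -> np.ndarray:
        """Return the 3-D ``(z, y, x)`` array for a named role."""
        for idx, r in self.channel_roles.items():
            if r == role:
                return self.voxels[..., idx]
        raise KeyError(f"no channel with role {role!r}; declared roles: {sorted(self.channel_roles.values())}")

    def has_role(self, role: str) -> bool:
        return role in self.channel_roles.values()


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    """Cast to 8-bit, max-normalizing anything outside [0, 255]."""
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        return arr
    arr = arr.astype(np.float64)
    lo, hi = float(arr.min(initial=0.0)), float(arr.max(initial=0.0))
    if lo < 0 or hi > 255:
        if hi > lo:
            arr = (arr - min(lo, 0.0)) * (255.0 / (hi - min(lo, 0.0)))
        else:
            arr = np.zeros_like(arr)
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def read_stack(
    path: str | Path,
    channel_roles: Mapping[int, str],
    voxel_size: Sequence[float] = DEFAULT_VOXEL_SIZE,
) -> ImageStack:
    """Read a multi-page TIFF as an :class:`ImageStack`.

    Accepted on-disk layouts: ``(y, x)`` single plane single channel,
    ``(z, y, x)`` single channel, ``(y, x, c)`` single plane when the last
    axis has at most 8 entries, and ``(z, y, x, c)``.  Intensities outside
    the 8-bit range are max-normalized to [0, 255] and cast.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValueError
        If the declared role map names more channels than the file holds.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[np.newaxis, :, :, np.newaxis]
    elif arr.ndim == 3:
        if arr.shape[-1] <= 8:  # heuristics: channel-last single plane
            arr = arr[np.newaxis, ...]
        else:
            arr = arr[..., np.newaxis]
    elif arr.ndim != 4:
        raise ValueError(f"cannot interpret TIFF with {arr.ndim} dimensions as a z-stack")
    n_chan = arr.shape[-1]
    if channel_roles and max(channel_roles) >= n_chan:
        raise ValueError(
            f"role map names channel {max(channel_roles)} but file has only {n_chan} channel(s)"
        )
    return ImageStack(voxels=arr, voxel_size=tuple(voxel_size), channel_roles=dict(channel_roles))


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as an 8-bit channel-last TIFF."""
    tifffile.imwrite(Path(path), stack.voxels)


def write_label_map(labels: np.ndarray, path: str | Path) -> None:
    """Write a 3-D integer label map as a 16-bit TIFF."""
    tifffile.imwrite(Path(path), np.asarray(labels).astype(np.uint16))


# ---------------------------------------------------------------------------
# Tabular results
# ---------------------------------------------------------------------------

def write_results(records: Sequence[Mapping[str, object]], path: str | Path,
                  columns: Sequence[str] | None = None) -> None:
    """Write per-nucleus result rows to CSV with a deterministic column order.

    The column order is *columns* if given, otherwise the order of first
    appearance across records.  Missing values (``None``/NaN) become empty
    cells; floats are written at 6 significant digits.
    """
    if columns is None:
        columns = []
        for rec in records:
            for key in rec:
                if key not in columns:
                    columns.append(key)
    df = pd.DataFrame(list(records), columns=list(columns))
    df.to_csv(Path(path), index=False, float_format="%.6g", na_rep="")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_results`; empty cells become NaN."""
    return pd.read_csv(Path(path))


def records_equal(a: Mapping[str, object], b: Mapping[str, object],
                  sig: int = 6) -> bool:
    """Compare two records up to float formatting at *sig* significant digits."""
    if set(a) != set(b):
        return False
    for key in a:
        va, vb = a[key], b[key]
        fa = isinstance(va, (int, float, np.floating, np.integer))
        fb = isinstance(vb, (int, float, np.floating, np.integer))
        if fa and fb:
            va, vb = float(va), float(vb)
            if math.isnan(va) and math.isnan(vb):
                continue
            if va == vb == 0:
                continue
            scale = max(abs(va), abs(vb))
            if scale and abs(va - vb) / scale > 10 ** (1 - sig):
                return False
        elif (va is None or (fa and math.isnan(float(va)))) and (vb is None or (fb and math.isnan(float(vb)))):
            continue
        elif str(va) != str(vb):
            return False
    return True
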