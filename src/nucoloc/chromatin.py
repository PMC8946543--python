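"""Euchromatin/heterochromatin classification and signal masks.

Chromatin classes are read off the DAPI counterstain inside a nuclear ROI:
DAPI-dark heterochromatin (HC) is every voxel at or above 150 arbitrary
units, DAPI-light euchromatin (EC) lies in [50, 150), and voxels below 50
belong to neither class (interchromatin space / background).  Signal masks
for H3K4me3, PMP22 and Lamin B1 are fixed-threshold binarizations (Otsu is
available as an alternative); the comparisons are inclusive at the stated
boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict

import numpy as np
from skimage.filters import threshold_otsu

__all__ = ["ChromatinConfig", "ChromatinMaskSet", "classify_chromatin",
           "make_signal_mask", "build_mask_set"]


@dataclass
class ChromatinConfig:
    """Thresholds for chromatin classes and signal masks (8-bit units)."""

    dark_threshold: float = 150.0   # HC: intensity >= dark_threshold
    light_min: float = 50.0         # EC: light_min <= intensity < dark_threshold
    dark_max: float = 255.0
    signal_mask_method: str = "fixed"            # "fixed" | "otsu"
    signal_thresholds: Dict[str, float] = field(
        default_factory=lambda: {"H3K4m3": 50.0, "PMP22": 50.0, "LMNB1": 50.0})
    #: When True, the total-chromatin operand keeps sub-light nuclear DAPI.
    tc_includes_sub_light: bool = False

    def __post_init__(self) -> None:
        if not self.light_min < self.dark_threshold <= self.dark_max:
            raise ValueError(
                f"need light_min < dark_threshold <= dark_max, got "
                f"({self.light_min}, {self.dark_threshold}, {self.dark_max})")
        if self.signal_mask_method not in ("fixed", "otsu"):
            raise ValueError(f"unknown signal_mask_method {self.signal_mask_method!r}")


@dataclass
class ChromatinMaskSet:
    """Binary masks for one nuclear ROI (all subsets of the ROI)."""

    ec_dapi_light: np.ndarray
    hc_dapi_dark: np.ndarray
    ec_h3k4m3: np.ndarray | None = None
    pmp22: np.ndarray | None = None
    lmnb1: np.ndarray | None = None


def classify_chromatin(dapi: np.ndarray, cfg: ChromatinConfig | None = None,
                       roi: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Split nuclear DAPI into (euchromatin, heterochromatin) masks.

    A voxel is heterochromatic iff its intensity lies in
    ``[dark_threshold, dark_max]`` and euchromatic iff it lies in
    ``[light_min, dark_threshold)``; darker voxels belong to neither mask.
    *roi* optionally restricts both masks to the nuclear mask.
    """
    cfg = cfg or ChromatinConfig()
    dapi = np.asarray(dapi)
    hc = (dapi >= cfg.dark_threshold) & (dapi <= cfg.dark_max)
    ec = (dapi >= cfg.light_min) & (dapi < cfg.dark_threshold)
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        hc &= roi
        ec &= roi
    return ec, hc


def make_signal_mask(channel: np.ndarray, cfg: ChromatinConfig | None = None,
                     role: str = "PMP22",
                     roi: np.ndarray | None = None) -> np.ndarray:
    """Binarize a cleared nuclear channel (threshold inclusive).

    With the (default) fixed method the per-role threshold from
    ``cfg.signal_thresholds`` is used; with ``otsu`` the threshold is fit on
    the ROI voxels.  An all-zero channel under Otsu yields an empty mask and
    a warning rather than an error.
    """
    cfg = cfg or ChromatinConfig()
    channel = np.asarray(channel)
    roi = np.ones(channel.shape, dtype=bool) if roi is None else np.asarray(roi, dtype=bool)
    if cfg.signal_mask_method == "otsu":
        vals = channel[roi]
        if vals.size == 0 or not np.any(vals):
            warnings.warn(f"all-zero {role} channel: Otsu mask is empty", stacklevel=2)
            return np.zeros(channel.shape, dtype=bool)
        if vals.min() == vals.max():
            thr = float(vals.min())
        else:
            thr = float(threshold_otsu(vals))
    else:
        thr = float(cfg.signal_thresholds.get(role, 50.0))
    return (channel >= thr) & roi


def build_mask_set(crop, roi: np.ndarray,
                   cfg: ChromatinConfig | None = None) -> ChromatinMaskSet:
    """All chromatin and signal masks for one cleared nucleus crop.

    *crop* is an :class:`~nucoloc.image_io.ImageStack` whose channels were
    zeroed outside the nuclear mask *roi*.
    """
    cfg = cfg or ChromatinConfig()
    ec, hc = classify_chromatin(crop.channel("DAPI"), cfg, roi=roi)
    masks = ChromatinMaskSet(ec_dapi_light=ec, hc_dapi_dark=hc)
    for attr, role in (("ec_h3k4m3", "H3K4m3"), ("pmp22", "PMP22"), ("lmnb1", "LMNB1")):
        if crop.has_role(role):
            setattr(masks, attr, make_signal_mask(crop.channel(role), cfg, role, roi=roi))
    return masks
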