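"""Peripheral-versus-central intensity profiles.

For every z-plane of a nucleus two straight vectors are traced through the
in-plane centroid: a longitudinal vector along the principal axis of the
nuclear mask and a transverse vector perpendicular to it.  Intensities are
sampled at 1-pixel steps within the mask.  Each transverse vector is split
into three equal-length sectors (distal two thirds peripheral, middle third
central); each longitudinal vector into four quarters (distal two quarters
peripheral, middle two central).  Peripheral and central samples are pooled
over planes, giving one peripheral and one central mean per channel per
nucleus.

The vectors are deterministic surrogates for hand-traced lines: anchored at
the per-plane mask centroid along per-plane principal axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SectorProfile", "trace_vector", "sector_assign",
           "peripheral_central_summary", "save_intensity_heatmap"]

VECTOR_KINDS = ("longitudinal", "transverse")


@dataclass
class SectorProfile:
    """Pooled peripheral/central samples of one channel in one nucleus."""

    channel_role: str
    vector_kind: str                    # "longitudinal" | "transverse" | "pooled"
    peripheral_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    central_values: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def peripheral_mean(self) -> float:
        return float(self.peripheral_values.mean()) if self.peripheral_values.size else float("nan")

    @property
    def central_mean(self) -> float:
        return float(self.central_values.mean()) if self.central_values.size else float("nan")


def _plane_axes(mask2d: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centroid and (principal, perpendicular) unit vectors of a 2-D mask."""
    pts = np.argwhere(mask2d).astype(np.float64)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    minor = np.array([-major[1], major[0]])
    return centroid, major, minor


def trace_vector(channel: np.ndarray, mask: np.ndarray, z: int,
                 kind: str = "longitudinal") -> np.ndarray:
    """Ordered intensity samples along a straight line through plane *z*.

    The line passes through the in-plane centroid along the mask's principal
    axis (``longitudinal``) or its perpendicular (``transverse``), sampled
    at 1-pixel steps (nearest voxel) and clipped to the mask extent.

    Raises
    ------
    ValueError
        If *kind* is unknown or plane *z* holds no mask voxels.
    """
    if kind not in VECTOR_KINDS:
        raise ValueError(f"kind must be one of {VECTOR_KINDS}, got {kind!r}")
    m = np.asarray(mask, dtype=bool)[z]
    if not m.any():
        raise ValueError(f"no mask voxels on plane {z}")
    img = np.asarray(channel)[z]
    centroid, major, minor = _plane_axes(m)
    direction = major if kind == "longitudinal" else minor

    def march(sign: int) -> list[float]:
        vals = []
        step = 1
        while True:
            pos = centroid + sign * step * direction
            iy, ix = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= iy < m.shape[0] and 0 <= ix < m.shape[1]) or not m[iy, ix]:
                break
            vals.append(float(img[iy, ix]))
            step += 1
        return vals

    cy, cx = int(round(centroid[0])), int(round(centroid[1]))
    centre = [float(img[cy, cx])] if m[cy, cx] else []
    return np.array(march(-1)[::-1] + centre + march(+1), dtype=np.float64)


def sector_assign(samples: np.ndarray,
                  kind: str = "transverse") -> tuple[np.ndarray, np.ndarray]:
    """Split an ordered sample vector into (peripheral, central) values.

    Transverse vectors: three equal sectors, distal thirds peripheral; a
    remainder of one sample goes to the central sector, a remainder of two
    adds one sample to the left peripheral sector as well, so sector sizes
    never differ by more than one.  Longitudinal vectors: four quarters,
    distal quarters peripheral; remainders are assigned outward first
    (left peripheral, right peripheral, then left central).

    Raises
    ------
    ValueError
        With fewer than 4 samples or an unknown kind.
    """
    samples = np.asarray(samples, dtype=np.float64)
    n = samples.size
    if n < 4:
        raise ValueError(f"need >= 4 samples, got {n}")
    if kind == "transverse":
        base, rem = divmod(n, 3)
        p_left = base + (1 if rem == 2 else 0)
        centre = base + (1 if rem >= 1 else 0)
    elif kind == "longitudinal":
        base, rem = divmod(n, 4)
        p_left = base + (1 if rem >= 1 else 0)
        p_right = base + (1 if rem >= 2 else 0)
        centre = 2 * base + (1 if rem == 3 else 0)
    else:
        raise ValueError(f"kind must be one of {VECTOR_KINDS}, got {kind!r}")
    if kind == "transverse":
        peripheral = np.concatenate([samples[:p_left], samples[p_left + centre:]])
        central = samples[p_left:p_left + centre]
    else:
        peripheral = np.concatenate([samples[:p_left], samples[n - p_right:]])
        central = samples[p_left:p_left + centre]
    return peripheral, central


def peripheral_central_summary(channel: np.ndarray, mask: np.ndarray,
                               channel_role: str = "",
                               kind: str = "pooled") -> SectorProfile:
    """Pooled peripheral/central profile of one channel over all planes.

    Raw samples (not per-plane means) are pooled across every plane with
    mask voxels and, for ``kind="pooled"``, across both vector kinds.
    Planes whose vectors are shorter than 4 samples are skipped.
    """
    kinds = VECTOR_KINDS if kind == "pooled" else (kind,)
    mask = np.asarray(mask, dtype=bool)
    periph, centr = [], []
    for z in range(mask.shape[0]):
        if not mask[z].any():
            continue
        for k in kinds:
            samples = trace_vector(channel, mask, z, kind=k)
            if samples.size < 4:
                continue
            p, c = sector_assign(samples, kind=k)
            periph.append(p)
            centr.append(c)
    return SectorProfile(
        channel_role=channel_role, vector_kind=kind,
        peripheral_values=np.concatenate(periph) if periph else np.empty(0),
        central_values=np.concatenate(centr) if centr else np.empty(0),
    )


def save_intensity_heatmap(channel_plane: np.ndarray, path,
                           title: str = "") -> None:
    """Save a 2-D intensity heatmap of one nuclear plane as PNG.

    A flat stand-in for interactive 3-D surface renderings: same
    information (per-pixel intensity of a central plane), reproducible
    output.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(np.asarray(channel_plane), cmap="viridis", vmin=0, vmax=255)
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8, label="intensity (a.u.)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
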