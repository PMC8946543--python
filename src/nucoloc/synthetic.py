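"""Ground-truthed synthetic Wt/TrJ-like confocal scenes.

Generates multi-channel z-stacks of Schwann-cell-like nuclei with a known
voxel-level ground truth, so that segmentation, chromatin classification,
spatial profiling and colocalization can all be validated without real
acquisitions.  Nuclei are axis-aligned ellipsoids, elongated along x the way
Schwann-cell nuclei are elongated along the fiber axis, placed on a jittered
grid so overlap is impossible by construction.

Each nucleus is partitioned into three chromatin compartments:

* **euchromatin (EC)** — DAPI-light voxels; carries the H3K4me3 signal,
* **heterochromatin (HC)** — bright DAPI blobs with no H3K4me3,
* **interchromatin pockets** — dim sub-threshold DAPI, no H3K4me3; these
  host the PMP22 voxels that should co-occur with neither chromatin class.

PMP22- and Lamin-B1-positive voxels are drawn from these compartments with
configurable colocalization quotas and a configurable fraction placed in the
peripheral shell (outer third of the normalized elliptical radius).  The
returned :class:`GroundTruth` records the *realized* per-nucleus overlap and
peripheral fractions, which downstream recovery tests compare against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List

import numpy as np

from .image_io import ImageStack

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "TrueNucleus",
    "PlacementError",
    "generate_scene",
    "genotype_preset",
]

#: Outer-shell boundary on the normalized elliptical radius; the outer third
#: of the radius counts as "peripheral", mirroring thirds-based sectoring.
SHELL_RADIUS = 2.0 / 3.0


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed without overlap in the field."""


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic genotype scene.

    Intensity levels are mean 8-bit intensities of the corresponding
    compartment before read noise; fractions are in [0, 1].
    """

    n_nuclei: int = 10
    genotype: str = "Wt"
    volume_mean: float = 280.0          # µm³
    volume_sd: float = 45.0             # µm³
    pmp22_nuclear_level: float = 70.0
    lmnb1_level: float = 110.0
    dapi_level: float = 95.0            # EC-core DAPI (DAPI-light range)
    h3k4m3_level: float = 130.0
    peripheral_fraction_pmp22: float = 0.75
    peripheral_fraction_lmnb1: float = 0.90
    coloc_fraction_pmp22_ec: float = 0.75
    coloc_fraction_pmp22_hc: float = 0.10
    hc_fraction: float = 0.18
    noise_sd: float = 6.0
    seed: int = 0

    # Secondary knobs (defaults emulate the per-nucleus acquisition regime:
    # 0.1 µm pixels, 0.21 µm z-step).
    voxel_size: tuple[float, float, float] = (0.21, 0.1, 0.1)
    elongation: float = 3.0             # rx / ry semi-axis ratio
    z_semiaxis_um: float = 2.6          # fixed z semi-axis (flattened nuclei)
    hc_dapi_level: float = 200.0        # DAPI-dark blob intensity
    dapi_shell_level: float = 55.0      # peripheral DAPI-light intensity
    dim_dapi_level: float = 35.0        # interchromatin (sub-light) DAPI
    h3k4m3_shell_factor: float = 0.55   # peripheral attenuation of H3K4me3
    pmp22_positive_fraction: float = 0.15
    lmnb1_positive_fraction: float = 0.12
    coloc_fraction_pmp22_lmnb1: float | None = None
    cytoplasm_pmp22_level: float = 40.0
    hc_blob_radius_vox: tuple[float, float, float] = (5.0, 10.0, 10.0)  # ~1 µm blobs
    level_jitter_sd: float = 0.08       # per-nucleus multiplicative spread
    dapi_jitter_sd: float = 0.03        # smaller: DAPI counterstain is stable
    field_shape: tuple[int, int, int] | None = None

    def validate(self) -> None:
        fracs = {
            "peripheral_fraction_pmp22": self.peripheral_fraction_pmp22,
            "peripheral_fraction_lmnb1": self.peripheral_fraction_lmnb1,
            "coloc_fraction_pmp22_ec": self.coloc_fraction_pmp22_ec,
            "coloc_fraction_pmp22_hc": self.coloc_fraction_pmp22_hc,
            "hc_fraction": self.hc_fraction,
            "pmp22_positive_fraction": self.pmp22_positive_fraction,
            "lmnb1_positive_fraction": self.lmnb1_positive_fraction,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.coloc_fraction_pmp22_ec + self.coloc_fraction_pmp22_hc > 1.0 + 1e-12:
            raise ValueError("coloc_fraction_pmp22_ec + coloc_fraction_pmp22_hc must be <= 1")
        for name in ("pmp22_nuclear_level", "lmnb1_level", "dapi_level", "h3k4m3_level",
                     "hc_dapi_level", "dapi_shell_level", "dim_dapi_level"):
            level = getattr(self, name)
            if not 0.0 <= level <= 255.0:
                raise ValueError(f"{name} must be in [0, 255], got {level}")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be non-negative")
        if self.volume_mean <= 0 or self.volume_sd < 0 or self.noise_sd < 0:
            raise ValueError("volume_mean must be positive; sd values non-negative")


@dataclass
class TrueNucleus:
    """Ground truth for one generated nucleus."""

    label: int
    center_vox: tuple[float, float, float]
    semiaxes_um: tuple[float, float, float]        # (rz, ry, rx)
    volume_analytic: float                          # 4/3·π·a·b·c, µm³
    voxel_count: int
    volume_voxelized: float                         # voxel_count × voxel volume
    hc_fraction_actual: float
    ec_count: int
    hc_count: int
    dim_count: int
    pmp22_count: int
    lmnb1_count: int
    frac_pmp22_in_ec: float
    frac_pmp22_in_hc: float
    frac_pmp22_in_lmnb1: float
    frac_lmnb1_in_pmp22: float
    frac_pmp22_peripheral: float
    frac_lmnb1_peripheral: float


@dataclass
class GroundTruth:
    """Voxel-level truth for a generated scene."""

    label_map: np.ndarray           # int32 (z, y, x); 0 = background
    compartments: np.ndarray        # uint8 (z, y, x); 0 bg, 1 EC, 2 HC, 3 dim
    pmp22_mask: np.ndarray          # bool (z, y, x) nuclear PMP22-positive
    lmnb1_mask: np.ndarray          # bool (z, y, x)
    shell_mask: np.ndarray          # bool; outer-third shell of any nucleus
    nuclei: List[TrueNucleus] = field(default_factory=list)
    config: SyntheticConfig | None = None

    EC, HC, DIM = 1, 2, 3


def genotype_preset(name: str) -> SyntheticConfig:
    """Return the default scene configuration for a genotype.

    The TrJ preset encodes the phenotype directions: more nuclei per field,
    smaller nuclei, higher nuclear PMP22 and DAPI, lower Lamin B1 and
    H3K4me3, a larger heterochromatin fraction and weaker PMP22–EC /
    stronger PMP22–HC colocalization than wild type.
    """
    if name == "Wt":
        return SyntheticConfig(
            n_nuclei=10, genotype="Wt",
            volume_mean=280.0, volume_sd=45.0,
            pmp22_nuclear_level=70.0, lmnb1_level=110.0,
            dapi_level=95.0, h3k4m3_level=130.0,
            coloc_fraction_pmp22_ec=0.75, coloc_fraction_pmp22_hc=0.10,
            hc_fraction=0.18,
        )
    if name == "TrJ":
        return SyntheticConfig(
            n_nuclei=14, genotype="TrJ",
            volume_mean=170.0, volume_sd=30.0,
            pmp22_nuclear_level=100.0, lmnb1_level=80.0,
            dapi_level=110.0, h3k4m3_level=100.0,
            coloc_fraction_pmp22_ec=0.60, coloc_fraction_pmp22_hc=0.22,
            hc_fraction=0.25,
        )
    raise ValueError(f"unknown genotype {name!r}; expected 'Wt' or 'TrJ'")


# ---------------------------------------------------------------------------
# Internal helpers
# ---------------------------------------------------------------------------

def _pick(rng: np.random.Generator, pool: np.ndarray, k: int) -> np.ndarray:
    """Choose k distinct entries from a flat-index pool (all if k >= size)."""
    if k >= pool.size:
        return pool
    return rng.choice(pool, size=k, replace=False)


def _pick_with_region(rng: np.random.Generator, shell_pool: np.ndarray,
                      core_pool: np.ndarray, k: int, k_shell: int) -> np.ndarray:
    """Choose k voxels honouring a shell quota, spilling over when a region
    pool is too small."""
    k_shell = min(k_shell, k)
    take_shell = min(k_shell, shell_pool.size)
    take_core = min(k - take_shell, core_pool.size)
    chosen = [
        _pick(rng, shell_pool, take_shell),
        _pick(rng, core_pool, take_core),
    ]
    short = k - take_shell - take_core
    if short > 0:  # spill into whatever is left, regardless of region
        used = np.concatenate(chosen) if chosen else np.empty(0, dtype=np.int64)
        remaining = np.setdiff1d(np.concatenate([shell_pool, core_pool]), used,
                                 assume_unique=False)
        chosen.append(_pick(rng, remaining, min(short, remaining.size)))
    return np.concatenate(chosen).astype(np.int64)


def _place_centers(cfg: SyntheticConfig, semiaxes_vox: np.ndarray,
                   rng: np.random.Generator):
    """Place nucleus centers; returns (field_shape, centers).

    With no explicit ``field_shape`` nuclei go on a jittered grid sized from
    the largest nucleus, which cannot overlap.  With an explicit shape,
    rejection sampling is used and :class:`PlacementError` raised on failure.
    """
    n = cfg.n_nuclei
    max_ax = semiaxes_vox.max(axis=0) if n else np.array([1.0, 1.0, 1.0])
    margin = np.array([4.0, 14.0, 14.0])
    if cfg.field_shape is None:
        cell = np.ceil(2 * max_ax + margin).astype(int)
        ncols = max(1, math.ceil(math.sqrt(n))) if n else 1
        nrows = max(1, math.ceil(n / ncols)) if n else 1
        shape = (int(cell[0]), int(nrows * cell[1]), int(ncols * cell[2]))
        centers = []
        for i in range(n):
            row, col = divmod(i, ncols)
            base = np.array([cell[0] / 2, (row + 0.5) * cell[1], (col + 0.5) * cell[2]])
            slack = np.maximum(cell / 2 - semiaxes_vox[i] - 1.0, 0.0)
            jitter = rng.uniform(-1, 1, size=3) * np.minimum(slack, margin / 4)
            centers.append(base + jitter)
        return shape, np.array(centers).reshape(n, 3)
    shape = tuple(int(s) for s in cfg.field_shape)
    centers: list[np.ndarray] = []
    for i in range(n):
        ax = semiaxes_vox[i]
        lo, hi = ax + 1.0, np.array(shape) - ax - 1.0
        if np.any(hi <= lo):
            raise PlacementError(f"nucleus {i} does not fit in field {shape}")
        for _ in range(200):
            cand = rng.uniform(lo, hi)
            ok = all(
                np.sum(((cand - c) / (ax + semiaxes_vox[j] + 1.0)) ** 2) > 1.0
                for j, c in enumerate(centers)
            )
            if ok:
                centers.append(cand)
                break
        else:
            raise PlacementError(
                f"could not place nucleus {i} without overlap in field {shape}"
            )
    return shape, np.array(centers).reshape(n, 3)


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------

def generate_scene(cfg: SyntheticConfig) -> tuple[ImageStack, GroundTruth]:
    """Render one genotype scene and its voxel-level ground truth.

    The same seed always yields a bit-identical stack.  Read noise is
    additive Gaussian with sd ``cfg.noise_sd``, clipped to [0, 255]; at
    ``noise_sd=0`` every intensity is exactly its compartment level times
    the per-nucleus jitter factor.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    dz, dy, dx = cfg.voxel_size
    n = cfg.n_nuclei

    # Per-nucleus geometry: fixed z semi-axis, elongation e = rx/ry, so the
    # in-plane axes follow from the sampled volume V = 4/3·π·rz·ry·rx.
    volumes = rng.normal(cfg.volume_mean, cfg.volume_sd, size=n)
    volumes = np.clip(volumes, 0.35 * cfg.volume_mean, None)
    rz = np.full(n, cfg.z_semiaxis_um)
    ry = np.sqrt(volumes / ((4.0 / 3.0) * math.pi * rz * cfg.elongation))
    rx = cfg.elongation * ry
    semiaxes_um = np.stack([rz, ry, rx], axis=1)
    semiaxes_vox = semiaxes_um / np.array([dz, dy, dx])

    shape, centers = _place_centers(cfg, semiaxes_vox, rng)
    label_map = np.zeros(shape, dtype=np.int32)
    compartments = np.zeros(shape, dtype=np.uint8)
    pmp22_mask = np.zeros(shape, dtype=bool)
    lmnb1_mask = np.zeros(shape, dtype=bool)
    shell_mask = np.zeros(shape, dtype=bool)
    dapi = np.zeros(shape, dtype=np.float32)
    h3k = np.zeros(shape, dtype=np.float32)
    pmp = np.zeros(shape, dtype=np.float32)
    lmn = np.zeros(shape, dtype=np.float32)
    cyto = np.zeros(shape, dtype=np.float32)  # extranuclear PMP22, applied last

    nuclei: List[TrueNucleus] = []
    for i in range(n):
        center, ax = centers[i], semiaxes_vox[i]
        lo = np.maximum(np.floor(center - 1.45 * ax - 1).astype(int), 0)
        hi = np.minimum(np.ceil(center + 1.45 * ax + 2).astype(int), shape)
        zz, yy, xx = np.meshgrid(*(np.arange(lo[d], hi[d]) for d in range(3)),
                                 indexing="ij")
        r = np.sqrt(((zz - center[0]) / ax[0]) ** 2
                    + ((yy - center[1]) / ax[1]) ** 2
                    + ((xx - center[2]) / ax[2]) ** 2)
        box = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        inside = r <= 1.0
        halo = (r > 1.0) & (r <= 1.4)
        n_vox = int(inside.sum())
        if n_vox == 0:
            continue
        label = i + 1
        label_map[box][inside] = label
        shell = inside & (r > SHELL_RADIUS)
        shell_mask[box] |= shell

        flat_inside = np.flatnonzero(inside.ravel())
        flat_shell = np.flatnonzero((inside & (r > SHELL_RADIUS)).ravel())
        flat_core = np.flatnonzero((inside & (r <= SHELL_RADIUS)).ravel())

        # --- heterochromatin blobs, trimmed to the exact voxel target -----
        # Blob centres stay off the extreme rim (r <= 0.85) so the bright
        # DAPI-dark signal does not sit on the nuclear border.
        centre_pool = np.flatnonzero((inside & (r <= 0.85)).ravel())
        if centre_pool.size == 0:
            centre_pool = flat_inside
        hc_flat = _make_hc(rng, inside, r.shape, centre_pool,
                           int(round(cfg.hc_fraction * n_vox)),
                           cfg.hc_blob_radius_vox)
        hc_local = np.zeros(r.shape, dtype=bool)
        hc_local.ravel()[hc_flat] = True

        # --- PMP22 placement with compartment and shell quotas ------------
        n_pos = int(round(cfg.pmp22_positive_fraction * n_vox))
        q_ec = int(round(cfg.coloc_fraction_pmp22_ec * n_pos))
        q_hc = int(round(cfg.coloc_fraction_pmp22_hc * n_pos))
        q_dim = max(n_pos - q_ec - q_hc, 0)
        not_hc = np.setdiff1d(flat_inside, hc_flat, assume_unique=False)
        not_hc_shell = np.intersect1d(not_hc, flat_shell, assume_unique=False)
        not_hc_core = np.intersect1d(not_hc, flat_core, assume_unique=False)
        pf = cfg.peripheral_fraction_pmp22
        pmp_ec = _pick_with_region(rng, not_hc_shell, not_hc_core, q_ec,
                                   int(round(pf * q_ec)))
        hc_shell = np.intersect1d(hc_flat, flat_shell, assume_unique=False)
        hc_core = np.intersect1d(hc_flat, flat_core, assume_unique=False)
        pmp_hc = _pick_with_region(rng, hc_shell, hc_core, q_hc,
                                   int(round(pf * q_hc)))
        rem_shell = np.setdiff1d(not_hc_shell, pmp_ec, assume_unique=False)
        rem_core = np.setdiff1d(not_hc_core, pmp_ec, assume_unique=False)
        dim_flat = _pick_with_region(rng, rem_shell, rem_core, q_dim,
                                     int(round(pf * q_dim)))
        dim_local = np.zeros(r.shape, dtype=bool)
        dim_local.ravel()[dim_flat] = True
        pmp_flat = np.concatenate([pmp_ec, pmp_hc, dim_flat]).astype(np.int64)
        pmp_local = np.zeros(r.shape, dtype=bool)
        pmp_local.ravel()[pmp_flat] = True

        # --- Lamin B1 ring -------------------------------------------------
        n_lmn = int(round(cfg.lmnb1_positive_fraction * n_vox))
        lmn_parts = []
        if cfg.coloc_fraction_pmp22_lmnb1 is not None and pmp_flat.size:
            k_on_pmp = int(round(cfg.coloc_fraction_pmp22_lmnb1 * pmp_flat.size))
            lmn_parts.append(_pick(rng, pmp_flat, min(k_on_pmp, n_lmn)))
        taken = lmn_parts[0] if lmn_parts else np.empty(0, dtype=np.int64)
        free_shell = np.setdiff1d(flat_shell, taken, assume_unique=False)
        free_core = np.setdiff1d(flat_core, taken, assume_unique=False)
        k_rest = n_lmn - taken.size
        if k_rest > 0:
            lmn_parts.append(_pick_with_region(
                rng, free_shell, free_core, k_rest,
                int(round(cfg.peripheral_fraction_lmnb1 * k_rest))))
        lmn_flat = (np.concatenate(lmn_parts).astype(np.int64)
                    if lmn_parts else np.empty(0, dtype=np.int64))
        lmn_local = np.zeros(r.shape, dtype=bool)
        lmn_local.ravel()[lmn_flat] = True

        ec_local = inside & ~hc_local & ~dim_local
        comp_local = np.zeros(r.shape, dtype=np.uint8)
        comp_local[ec_local] = GroundTruth.EC
        comp_local[hc_local] = GroundTruth.HC
        comp_local[dim_local] = GroundTruth.DIM
        compartments[box][inside] = comp_local[inside]
        pmp22_mask[box] |= pmp_local
        lmnb1_mask[box] |= lmn_local

        # --- intensities ----------------------------------------------------
        jit = float(np.clip(rng.normal(1.0, cfg.level_jitter_sd), 0.8, 1.2))
        jit_dapi = float(np.clip(rng.normal(1.0, cfg.dapi_jitter_sd), 0.9, 1.1))
        core_ec = ec_local & (r <= SHELL_RADIUS)
        shell_ec = ec_local & (r > SHELL_RADIUS)
        dview = dapi[box]
        dview[core_ec] = cfg.dapi_level * jit_dapi
        dview[shell_ec] = cfg.dapi_shell_level * jit_dapi
        dview[hc_local] = cfg.hc_dapi_level * jit_dapi
        dview[dim_local] = cfg.dim_dapi_level * jit_dapi
        hview = h3k[box]
        hview[core_ec] = cfg.h3k4m3_level * jit
        hview[shell_ec] = cfg.h3k4m3_level * cfg.h3k4m3_shell_factor * jit
        cview = cyto[box]
        cview[halo] = np.maximum(cview[halo], cfg.cytoplasm_pmp22_level * jit)
        pview = pmp[box]
        pview[pmp_local] = cfg.pmp22_nuclear_level * jit
        lview = lmn[box]
        lview[lmn_local] = cfg.lmnb1_level * jit

        # --- realized ground-truth fractions -------------------------------
        def _frac(num: int, den: int) -> float:
            return num / den if den else float("nan")

        pmp_in_ec = int(np.intersect1d(pmp_flat, np.flatnonzero(ec_local.ravel())).size)
        pmp_in_hc = int(np.intersect1d(pmp_flat, hc_flat).size)
        pmp_in_lmn = int(np.intersect1d(pmp_flat, lmn_flat).size)
        pmp_shell = int(np.intersect1d(pmp_flat, flat_shell).size)
        lmn_shell = int(np.intersect1d(lmn_flat, flat_shell).size)
        nuclei.append(TrueNucleus(
            label=label,
            center_vox=tuple(float(c) for c in center),
            semiaxes_um=tuple(float(s) for s in semiaxes_um[i]),
            volume_analytic=float((4.0 / 3.0) * math.pi * np.prod(semiaxes_um[i])),
            voxel_count=n_vox,
            volume_voxelized=float(n_vox * dz * dy * dx),
            hc_fraction_actual=_frac(len(hc_flat), n_vox),
            ec_count=int(ec_local.sum()),
            hc_count=len(hc_flat),
            dim_count=len(dim_flat),
            pmp22_count=len(pmp_flat),
            lmnb1_count=len(lmn_flat),
            frac_pmp22_in_ec=_frac(pmp_in_ec, len(pmp_flat)),
            frac_pmp22_in_hc=_frac(pmp_in_hc, len(pmp_flat)),
            frac_pmp22_in_lmnb1=_frac(pmp_in_lmn, len(pmp_flat)),
            frac_lmnb1_in_pmp22=_frac(pmp_in_lmn, len(lmn_flat)),
            frac_pmp22_peripheral=_frac(pmp_shell, len(pmp_flat)),
            frac_lmnb1_peripheral=_frac(lmn_shell, len(lmn_flat)),
        ))

    outside = label_map == 0  # cytoplasmic PMP22 never overwrites a nucleus
    pmp[outside] = np.maximum(pmp[outside], cyto[outside])
    canvas = np.stack([dapi, h3k, pmp, lmn], axis=-1)
    if cfg.noise_sd > 0:
        canvas += rng.standard_normal(canvas.shape, dtype=np.float32) * np.float32(cfg.noise_sd)
    canvas = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    stack = ImageStack(
        voxels=canvas,
        voxel_size=cfg.voxel_size,
        channel_roles={0: "DAPI", 1: "H3K4m3", 2: "PMP22", 3: "LMNB1"},
    )
    truth = GroundTruth(
        label_map=label_map, compartments=compartments,
        pmp22_mask=pmp22_mask, lmnb1_mask=lmnb1_mask,
        shell_mask=shell_mask, nuclei=nuclei, config=replace(cfg),
    )
    return stack, truth


def _make_hc(rng: np.random.Generator, inside: np.ndarray, shape, flat_inside,
             target: int, blob_radius) -> np.ndarray:
    """Grow heterochromatin as ellipsoidal blobs until exactly *target*
    nuclear voxels are covered (the final blob is trimmed, farthest voxels
    first, to land on the target)."""
    if target <= 0:
        return np.empty(0, dtype=np.int64)
    rz, ry, rx = blob_radius
    hc = np.zeros(shape, dtype=bool)
    count = 0
    for _ in range(10_000):
        if count >= target:
            break
        c_flat = int(rng.choice(flat_inside))
        cz, cy, cx = np.unravel_index(c_flat, shape)
        lo = np.maximum([cz - int(rz) - 1, cy - int(ry) - 1, cx - int(rx) - 1], 0)
        hi = np.minimum([cz + int(rz) + 2, cy + int(ry) + 2, cx + int(rx) + 2], shape)
        zz, yy, xx = np.meshgrid(*(np.arange(lo[d], hi[d]) for d in range(3)),
                                 indexing="ij")
        d2 = (((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)
        box = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        blob = (d2 <= 1.0) & inside[box] & ~hc[box]
        new = int(blob.sum())
        if new == 0:
            continue
        if count + new > target:  # trim farthest-from-centre voxels
            excess = count + new - target
            dist = d2[blob]
            order = np.argsort(dist, kind="stable")[::-1]
            keep_idx = np.flatnonzero(blob.ravel())
            drop = keep_idx[order[:excess]]
            blob_flat = blob.ravel().copy()
            blob_flat[drop] = False
            blob = blob_flat.reshape(blob.shape)
            new = target - count
        view = hc[box]
        view |= blob
        count += new
    return np.flatnonzero(hc.ravel())
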