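"""Colocalization coefficients: Manders split coefficients, rank
correlations, and the Costes block-scrambling significance test.

Manders split coefficients are co-occurrence fractions: ``M1`` is the
fraction of the *query* channel's summed intensity that falls where the
*reference* channel is positive, ``M2`` the converse.  Binary masks are
treated as {0, 1} intensities, so on masks the coefficients reduce to area
fractions.  A channel whose summed intensity is zero has no defined
fraction; the coefficient is returned as NaN (flagged), never as 0, so an
empty channel cannot masquerade as anticolocalization.

Correlations are rank-based (Spearman's rho and Kendall's tau-b).  Pixel
intensities from these stains are far from normal, so Pearson's r is not
part of the reported set; it is available only as the optional engine of
the classical Costes null.

The Costes test scrambles square pixel blocks of one channel within the ROI
bounding box and reports the percentage of scrambles whose correlation with
the unscrambled partner falls below the observed correlation; values above
the pass threshold (default 95%) indicate non-chance colocalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "PAIRINGS",
    "CostesConfig",
    "ColocCoefficients",
    "manders_pair",
    "spearman_rho",
    "kendall_taub",
    "costes_test",
    "coloc_pairings",
]

#: The five channel pairings analysed per nucleus.
PAIRINGS = ("EC_vs_TC", "EC_vs_HC", "PMP22_vs_EC", "PMP22_vs_HC", "PMP22_vs_LMNB1")


@dataclass
class CostesConfig:
    """Costes randomization parameters (block size in pixels)."""

    block_size: int = 3
    n_scrambles: int = 100
    seed: int = 0
    pass_threshold: float = 95.0
    use_pearson: bool = False   # classical Costes engine; rank-based default

    def __post_init__(self) -> None:
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.n_scrambles < 20:
            raise ValueError("n_scrambles must be >= 20")


@dataclass
class ColocCoefficients:
    """Per-nucleus summary of one channel pairing (median across slices)."""

    pairing: str
    M1: float
    M2: float
    rho: float
    tau: float
    costes_p: float     # percent, [0, 100]
    n_slices: int


def _above(x: np.ndarray, threshold: float) -> np.ndarray:
    """Partner/self criterion: strictly positive at threshold 0, inclusive
    at an explicit positive threshold."""
    return x > 0 if threshold <= 0 else x >= threshold


def manders_pair(reference: np.ndarray, query: np.ndarray,
                 ref_threshold: float = 0.0, query_threshold: float = 0.0,
                 roi: np.ndarray | None = None) -> Tuple[float, float]:
    """Manders split coefficients of *query* against *reference*.

    ``M1 = Σ query over {reference positive} / Σ query`` restricted to the
    query's own positive voxels; ``M2`` swaps the roles.  Exact role-swap
    symmetry holds: ``manders_pair(A, B)[0] == manders_pair(B, A)[1]``.

    Raises
    ------
    ValueError
        On shape mismatch, or when both channels are entirely empty.
    """
    ref = np.asarray(reference, dtype=np.float64)
    qry = np.asarray(query, dtype=np.float64)
    if ref.shape != qry.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {qry.shape}")
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        ref = np.where(roi, ref, 0.0)
        qry = np.where(roi, qry, 0.0)
    ref_sel = _above(ref, ref_threshold)
    qry_sel = _above(qry, query_threshold)
    denom_q = qry[qry_sel].sum()
    denom_r = ref[ref_sel].sum()
    if denom_q == 0 and denom_r == 0:
        raise ValueError("both channels empty: Manders coefficients undefined")
    m1 = qry[qry_sel & ref_sel].sum() / denom_q if denom_q > 0 else float("nan")
    m2 = ref[ref_sel & qry_sel].sum() / denom_r if denom_r > 0 else float("nan")
    return float(m1), float(m2)


def _masked_pair(a: np.ndarray, b: np.ndarray,
                 roi: np.ndarray | None) -> Tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if roi is None:
        return a.ravel(), b.ravel()
    roi = np.asarray(roi, dtype=bool)
    return a[roi], b[roi]


def spearman_rho(a: np.ndarray, b: np.ndarray,
                 roi: np.ndarray | None = None) -> float:
    """Spearman rank correlation over ROI voxels (average ranks on ties).

    Returns NaN (flagged by a warning) when either channel is constant.
    """
    x, y = _masked_pair(a, b, roi)
    if x.size < 3:
        raise ValueError(f"need >= 3 voxels in roi, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant channel: Spearman rho undefined", stacklevel=2)
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def kendall_taub(a: np.ndarray, b: np.ndarray,
                 roi: np.ndarray | None = None) -> float:
    """Kendall tau-b (tie-corrected) over ROI voxels; NaN when constant."""
    x, y = _masked_pair(a, b, roi)
    if x.size < 3:
        raise ValueError(f"need >= 3 voxels in roi, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant channel: Kendall tau undefined", stacklevel=2)
        return float("nan")
    return float(stats.kendalltau(x, y, variant="b").statistic)


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of two pre-ranked vectors."""
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy))


def costes_test(a: np.ndarray, b: np.ndarray, roi: np.ndarray,
                cfg: CostesConfig | None = None) -> float:
    """Costes randomization significance for one 2-D slice, in percent.

    The ROI bounding box of channel *a* is tiled into ``block_size`` squares
    (edge blocks padded with zeros and scrambled with the rest), the blocks
    are permuted uniformly ``n_scrambles`` times, and each scramble's
    correlation with the unscrambled *b* over the ROI is compared with the
    observed correlation.  Returns ``100 × #{r_scramble < r_observed} /
    n_scrambles``; seeded and reproducible.

    Raises
    ------
    ValueError
        If the ROI bounding box holds fewer than 16 blocks.
    """
    cfg = cfg or CostesConfig()
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    roi = np.asarray(roi, dtype=bool)
    if a.ndim != 2 or a.shape != b.shape or a.shape != roi.shape:
        raise ValueError("costes_test expects matching 2-D arrays")
    if not roi.any():
        raise ValueError("empty ROI")
    ys, xs = np.where(roi)
    y0, y1, x0, x1 = ys.min(), ys.max() + 1, xs.min(), xs.max() + 1
    bs = cfg.block_size
    ny = -((y1 - y0) // -bs)
    nx = -((x1 - x0) // -bs)
    if ny * nx < 16:
        raise ValueError(f"ROI too small for Costes test: {ny * nx} blocks < 16")

    pad_a = np.zeros((ny * bs, nx * bs))
    pad_a[: y1 - y0, : x1 - x0] = a[y0:y1, x0:x1]
    pad_roi = np.zeros((ny * bs, nx * bs), dtype=bool)
    pad_roi[: y1 - y0, : x1 - x0] = roi[y0:y1, x0:x1]
    b_roi = b[roi]
    rank_b = stats.rankdata(b_roi)

    def corr_with_b(avals: np.ndarray) -> float:
        if cfg.use_pearson:
            if avals.std() == 0 or b_roi.std() == 0:
                return float("nan")
            return float(np.corrcoef(avals, b_roi)[0, 1])
        return _rank_corr(stats.rankdata(avals), rank_b)

    r_obs = corr_with_b(a[roi])
    if np.isnan(r_obs):
        warnings.warn("constant channel in ROI: Costes test undefined", stacklevel=2)
        return float("nan")

    # (ny, bs, nx, bs) -> (ny*nx, bs, bs) block view for permutation
    blocks = pad_a.reshape(ny, bs, nx, bs).swapaxes(1, 2).reshape(ny * nx, bs, bs)
    rng = np.random.default_rng(cfg.seed)
    n_below = 0
    scr = np.empty_like(pad_a)
    for _ in range(cfg.n_scrambles):
        perm = rng.permutation(ny * nx)
        shuffled = blocks[perm].reshape(ny, nx, bs, bs).swapaxes(1, 2)
        scr[:] = shuffled.reshape(ny * bs, nx * bs)
        r = corr_with_b(scr[pad_roi])
        if not np.isnan(r) and r < r_obs:
            n_below += 1
    return 100.0 * n_below / cfg.n_scrambles


# ---------------------------------------------------------------------------
# The five per-nucleus pairings
# ---------------------------------------------------------------------------

def _pairing_operands(crop, masks, chrom_cfg, roi):
    """Build (reference, query, ref_thr, query_thr) per pairing.

    Signal-level pairings use the cleared raw channels with the per-role
    signal thresholds as partner/self criteria; mask pairings use the binary
    masks directly.  The total-chromatin operand is DAPI restricted to
    EC ∪ HC unless the config keeps sub-light nuclear voxels.
    """
    thr = chrom_cfg.signal_thresholds
    dapi = crop.channel("DAPI").astype(np.float64)
    ops: Dict[str, tuple] = {}
    if crop.has_role("H3K4m3"):
        h3k = crop.channel("H3K4m3").astype(np.float64)
        if chrom_cfg.tc_includes_sub_light:
            tc = np.where(roi, dapi, 0.0)
            tc_thr = 0.0
        else:
            tc = np.where(masks.ec_dapi_light | masks.hc_dapi_dark, dapi, 0.0)
            tc_thr = chrom_cfg.light_min
        ops["EC_vs_TC"] = (tc, h3k, tc_thr, thr.get("H3K4m3", 50.0))
        if masks.ec_h3k4m3 is not None:
            ops["EC_vs_HC"] = (masks.hc_dapi_dark, masks.ec_h3k4m3, 0.0, 0.0)
    if crop.has_role("PMP22"):
        pmp = crop.channel("PMP22").astype(np.float64)
        if crop.has_role("H3K4m3"):
            ops["PMP22_vs_EC"] = (pmp, crop.channel("H3K4m3").astype(np.float64),
                                  thr.get("PMP22", 50.0), thr.get("H3K4m3", 50.0))
        if masks.pmp22 is not None:
            ops["PMP22_vs_HC"] = (masks.pmp22, masks.hc_dapi_dark, 0.0, 0.0)
        if crop.has_role("LMNB1"):
            ops["PMP22_vs_LMNB1"] = (pmp, crop.channel("LMNB1").astype(np.float64),
                                     thr.get("PMP22", 50.0), thr.get("LMNB1", 50.0))
    return ops


def coloc_pairings(crop, masks, roi: np.ndarray,
                   chrom_cfg=None, costes_cfg: CostesConfig | None = None,
                   min_voxels_per_slice: int = 8) -> Dict[str, ColocCoefficients]:
    """All five pairings for one cleared nucleus crop.

    Coefficients are computed per z-slice over the nuclear ROI and
    summarized per nucleus as the median across slices (NaN slices
    ignored); the Costes test runs once per pairing, on the usable slice
    nearest the middle of the nucleus.  Pairings whose channels are absent
    are skipped with a warning.
    """
    from .chromatin import ChromatinConfig  # local import avoids a cycle

    chrom_cfg = chrom_cfg or ChromatinConfig()
    costes_cfg = costes_cfg or CostesConfig()
    roi = np.asarray(roi, dtype=bool)
    ops = _pairing_operands(crop, masks, chrom_cfg, roi)
    skipped = [p for p in PAIRINGS if p not in ops]
    if skipped:
        warnings.warn(f"pairings skipped (missing channels): {skipped}", stacklevel=2)

    slice_counts = roi.reshape(roi.shape[0], -1).sum(axis=1)
    usable = np.flatnonzero(slice_counts >= min_voxels_per_slice)
    results: Dict[str, ColocCoefficients] = {}
    mid = usable[np.argmin(np.abs(usable - usable.mean()))] if usable.size else None
    for pairing, (ref, qry, t_ref, t_qry) in ops.items():
        m1s, m2s, rhos, taus = [], [], [], []
        for z in usable:
            rz = roi[z]
            try:
                m1, m2 = manders_pair(ref[z], qry[z], t_ref, t_qry, roi=rz)
            except ValueError:
                m1 = m2 = float("nan")
            m1s.append(m1)
            m2s.append(m2)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rhos.append(spearman_rho(ref[z], qry[z], roi=rz))
                taus.append(kendall_taub(ref[z], qry[z], roi=rz))
        costes_p = float("nan")
        if mid is not None:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    costes_p = costes_test(np.asarray(ref[mid], dtype=np.float64),
                                           np.asarray(qry[mid], dtype=np.float64),
                                           roi[mid], costes_cfg)
            except ValueError as exc:
                warnings.warn(f"Costes test skipped for {pairing}: {exc}", stacklevel=2)
        results[pairing] = ColocCoefficients(
            pairing=pairing,
            M1=_nanmedian(m1s), M2=_nanmedian(m2s),
            rho=_nanmedian(rhos), tau=_nanmedian(taus),
            costes_p=costes_p, n_slices=int(usable.size),
        )
    return results


def _nanmedian(values: Iterable[float]) -> float:
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size == 0 or np.all(np.isnan(arr)):
        return float("nan")
    return float(np.nanmedian(arr))
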