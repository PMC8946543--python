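"""End-to-end orchestration: simulate/segment/classify/profile/colocalize/compare.

A single :class:`RunConfig` drives the whole analysis for both genotypes.
One global seed fans out to fixed per-stage child seeds (scene generation,
Costes scrambling, bootstrap CIs), so identical config + seed reproduces
every output byte for byte while each stage stays independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .chromatin import ChromatinConfig, build_mask_set
from .coloc import PAIRINGS, ColocCoefficients, CostesConfig, coloc_pairings
from .image_io import ROLES, ImageStack, read_stack, write_label_map, write_results
from .profiles import peripheral_central_summary
from .segmentation import (NucleusRecord, SegmentationConfig, crop_nucleus,
                           measure_nuclei, segment_nuclei)
from .stats import compare_groups
from .synthetic import SyntheticConfig, generate_scene, genotype_preset

log = logging.getLogger("nucoloc")

# Fixed child-seed offsets for the per-stage generators.
SEED_SCENE = {"Wt": 11, "TrJ": 12}
SEED_COSTES = 21
SEED_BOOTSTRAP = 31


@dataclass
class GenotypeInput:
    """Where one genotype's stack comes from: a TIFF or a synthetic preset."""

    genotype: str
    path: str | None = None
    channel_roles: Dict[int, str] = field(default_factory=dict)
    synthetic: SyntheticConfig | None = None

    def validate(self) -> None:
        if (self.path is None) == (self.synthetic is None):
            raise ValueError(
                f"genotype {self.genotype!r}: exactly one of a stack path or a "
                "synthetic preset must be given")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    inputs: List[GenotypeInput] = field(default_factory=list)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    chromatin: ChromatinConfig = field(default_factory=ChromatinConfig)
    costes: CostesConfig = field(default_factory=CostesConfig)
    voxel_size: tuple[float, float, float] = (0.21, 0.1, 0.1)
    output_dir: str = "nucoloc_out"
    seed: int = 0
    crop_margin: int = 2

    def validate(self) -> None:
        if not self.inputs:
            raise ValueError("no genotype inputs configured")
        for gi in self.inputs:
            gi.validate()


def config_from_dict(raw: Mapping) -> RunConfig:
    """Build a :class:`RunConfig` from a parsed YAML/JSON mapping."""
    inputs = []
    for g in raw.get("inputs", []):
        syn = g.get("synthetic")
        syn_cfg = None
        if syn is not None:
            preset = syn.get("preset", g.get("genotype", "Wt"))
            syn_cfg = genotype_preset(preset)
            for key, val in syn.items():
                if key == "preset":
                    continue
                if not hasattr(syn_cfg, key):
                    raise ValueError(f"unknown synthetic field {key!r}")
                setattr(syn_cfg, key, tuple(val) if isinstance(val, list) else val)
        inputs.append(GenotypeInput(
            genotype=g["genotype"],
            path=g.get("path"),
            channel_roles={int(k): v for k, v in g.get("channel_roles", {}).items()},
            synthetic=syn_cfg,
        ))
    cfg = RunConfig(inputs=inputs)
    for section, cls in (("segmentation", SegmentationConfig),
                         ("chromatin", ChromatinConfig),
                         ("costes", CostesConfig)):
        if section in raw:
            setattr(cfg, section, cls(**raw[section]))
    for key in ("voxel_size", "output_dir", "seed", "crop_margin"):
        if key in raw:
            val = raw[key]
            setattr(cfg, key, tuple(val) if isinstance(val, list) else val)
    return cfg


# ---------------------------------------------------------------------------
# Per-nucleus analysis
# ---------------------------------------------------------------------------

def analyse_nucleus(stack: ImageStack, labels: np.ndarray, record: NucleusRecord,
                    genotype: str, chrom_cfg: ChromatinConfig,
                    costes_cfg: CostesConfig, margin: int = 2) -> Dict[str, object]:
    """One flat result row for a segmented nucleus.

    Crops the nucleus, clears extranuclear signal, classifies chromatin,
    computes pooled peripheral/central means per channel and the five
    colocalization pairings (slice-median coefficients, one Costes run).
    """
    crop, mask = crop_nucleus(stack, labels, record.label, margin=margin)
    masks = build_mask_set(crop, mask, chrom_cfg)
    row: Dict[str, object] = {
        "nucleus_id": record.label,
        "genotype": genotype,
        "voxel_count": record.voxel_count,
        "volume_um3": record.volume,
        "centroid_z": record.centroid[0],
        "centroid_y": record.centroid[1],
        "centroid_x": record.centroid[2],
    }
    for role in ROLES:
        row[f"mean_{role}"] = record.mean_intensity.get(role, float("nan"))
    for role in ROLES:
        if stack.has_role(role):
            prof = peripheral_central_summary(crop.channel(role), mask, role)
            row[f"peripheral_mean_{role}"] = prof.peripheral_mean
            row[f"central_mean_{role}"] = prof.central_mean
        else:
            row[f"peripheral_mean_{role}"] = float("nan")
            row[f"central_mean_{role}"] = float("nan")
    per_nucleus_costes = dataclasses.replace(
        costes_cfg, seed=costes_cfg.seed + record.label)
    coefs = coloc_pairings(crop, masks, mask, chrom_cfg, per_nucleus_costes)
    for pairing in PAIRINGS:
        c = coefs.get(pairing)
        for name in ("M1", "M2", "rho", "tau", "costes_p"):
            row[f"{pairing}_{name}"] = getattr(c, name) if c else float("nan")
        row[f"{pairing}_n_slices"] = c.n_slices if c else 0
    return row


def analyse_stack(stack: ImageStack, genotype: str,
                  seg_cfg: SegmentationConfig, chrom_cfg: ChromatinConfig,
                  costes_cfg: CostesConfig,
                  margin: int = 2) -> tuple[np.ndarray, List[Dict[str, object]]]:
    """Segment one genotype stack and analyse every nucleus."""
    labels = segment_nuclei(stack, seg_cfg)
    records = measure_nuclei(stack, labels)
    log.info("%s: %d nuclei segmented", genotype, len(records))
    rows = []
    for rec in records:
        try:
            rows.append(analyse_nucleus(stack, labels, rec, genotype,
                                        chrom_cfg, costes_cfg, margin))
        except Exception as exc:  # noqa: BLE001 - annotate failing nucleus
            raise RuntimeError(
                f"per-nucleus analysis failed at stage 'coloc/profile' for "
                f"genotype {genotype!r}, nucleus {rec.label}") from exc
    return labels, rows


#: Per-nucleus measures compared between genotypes.
COMPARED_MEASURES = (
    ["volume_um3"]
    + [f"mean_{r}" for r in ROLES]
    + [f"peripheral_mean_{r}" for r in ROLES]
    + [f"central_mean_{r}" for r in ROLES]
    + [f"{p}_{c}" for p in PAIRINGS for c in ("M1", "M2", "rho", "tau")]
)


def genotype_comparisons(nuclei: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Wt-vs-TrJ Mann–Whitney comparison of every per-nucleus measure,
    plus within-genotype peripheral-vs-central contrasts per channel."""
    out = []
    wt = nuclei[nuclei["genotype"] == "Wt"]
    trj = nuclei[nuclei["genotype"] == "TrJ"]
    for i, measure in enumerate(COMPARED_MEASURES):
        if measure not in nuclei.columns:
            continue
        x = wt[measure].to_numpy(dtype=float)
        y = trj[measure].to_numpy(dtype=float)
        if np.sum(~np.isnan(x)) < 3 or np.sum(~np.isnan(y)) < 3:
            continue
        cmp_ = compare_groups(x, y, measure, seed=seed + SEED_BOOTSTRAP + i)
        out.append({
            "measure": measure, "contrast": "Wt_vs_TrJ",
            "n_wt": cmp_.n_wt, "n_trj": cmp_.n_trj,
            "median_wt": cmp_.median_wt, "median_trj": cmp_.median_trj,
            "ci95_wt_lo": cmp_.ci95_wt[0] if cmp_.ci95_wt else float("nan"),
            "ci95_wt_hi": cmp_.ci95_wt[1] if cmp_.ci95_wt else float("nan"),
            "ci95_trj_lo": cmp_.ci95_trj[0] if cmp_.ci95_trj else float("nan"),
            "ci95_trj_hi": cmp_.ci95_trj[1] if cmp_.ci95_trj else float("nan"),
            "U": cmp_.U, "p_two_tailed": cmp_.p_two_tailed,
            "shapiro_p_wt": cmp_.shapiro_p_wt, "shapiro_p_trj": cmp_.shapiro_p_trj,
        })
    for j, (genotype, sub) in enumerate((("Wt", wt), ("TrJ", trj))):
        for k, role in enumerate(ROLES):
            p_col, c_col = f"peripheral_mean_{role}", f"central_mean_{role}"
            if p_col not in sub.columns or len(sub) < 3:
                continue
            p_vals = sub[p_col].to_numpy(dtype=float)
            c_vals = sub[c_col].to_numpy(dtype=float)
            if np.all(np.isnan(p_vals)) or np.all(np.isnan(c_vals)):
                continue
            cmp_ = compare_groups(p_vals, c_vals, f"{role}_P_vs_C_{genotype}",
                                  seed=seed + SEED_BOOTSTRAP + 100 + 10 * j + k)
            out.append({
                "measure": f"{role}_peripheral_vs_central", "contrast": genotype,
                "n_wt": cmp_.n_wt, "n_trj": cmp_.n_trj,
                "median_wt": cmp_.median_wt, "median_trj": cmp_.median_trj,
                "ci95_wt_lo": cmp_.ci95_wt[0] if cmp_.ci95_wt else float("nan"),
                "ci95_wt_hi": cmp_.ci95_wt[1] if cmp_.ci95_wt else float("nan"),
                "ci95_trj_lo": cmp_.ci95_trj[0] if cmp_.ci95_trj else float("nan"),
                "ci95_trj_hi": cmp_.ci95_trj[1] if cmp_.ci95_trj else float("nan"),
                "U": cmp_.U, "p_two_tailed": cmp_.p_two_tailed,
                "shapiro_p_wt": cmp_.shapiro_p_wt, "shapiro_p_trj": cmp_.shapiro_p_trj,
            })
    return pd.DataFrame(out)


def run_pipeline(cfg: RunConfig) -> Dict[str, object]:
    """Run the full analysis; returns the machine-readable run summary.

    Writes per-nucleus tables (``nuclei.csv``), group comparisons
    (``comparisons.csv``), label maps and a ``summary.json`` under
    ``cfg.output_dir``.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_rows: List[Dict[str, object]] = []
    stage_counts: Dict[str, int] = {}
    for gi in cfg.inputs:
        if gi.synthetic is not None:
            scene_cfg = dataclasses.replace(
                gi.synthetic,
                seed=cfg.seed + SEED_SCENE.get(gi.genotype, 19))
            stack, _truth = generate_scene(scene_cfg)
        else:
            stack = read_stack(gi.path, gi.channel_roles, cfg.voxel_size)
            if not stack.has_role("DAPI"):
                raise ValueError(f"genotype {gi.genotype!r}: no DAPI channel declared")
        costes_cfg = dataclasses.replace(cfg.costes, seed=cfg.seed + SEED_COSTES)
        labels, rows = analyse_stack(stack, gi.genotype, cfg.segmentation,
                                     cfg.chromatin, costes_cfg, cfg.crop_margin)
        write_label_map(labels, out / f"labels_{gi.genotype}.tif")
        for row in rows:
            row["nucleus_id"] = f"{gi.genotype}_{row['nucleus_id']}"
        all_rows.extend(rows)
        stage_counts[gi.genotype] = len(rows)

    write_results(all_rows, out / "nuclei.csv")
    nuclei = pd.DataFrame(all_rows)
    comparisons = genotype_comparisons(nuclei, seed=cfg.seed) if len(nuclei) else pd.DataFrame()
    comparisons.to_csv(out / "comparisons.csv", index=False, float_format="%.6g")
    summary = {
        "version": __version__,
        "seed": cfg.seed,
        "nuclei_per_genotype": stage_counts,
        "n_pairings": len(PAIRINGS),
        "measures_compared": int(len(comparisons)),
        "config": {
            "segmentation": dataclasses.asdict(cfg.segmentation),
            "chromatin": dataclasses.asdict(cfg.chromatin),
            "costes": dataclasses.asdict(cfg.costes),
            "voxel_size": list(cfg.voxel_size),
            "crop_margin": cfg.crop_margin,
        },
        "outputs": ["nuclei.csv", "comparisons.csv", "summary.json"],
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
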