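# nucoloc

Quantitative confocal image analysis of Schwann-cell (SC) nuclei, built for
comparing wild-type (Wt) and Trembler-J-like (TrJ) mouse sciatic nerves.
TrJ mice carry the PMP22 L16P point mutation modelling CMT1E neuropathy;
their SC nuclei are more numerous, smaller, richer in nuclear PMP22 and
DAPI, and poorer in Lamin B1 and the euchromatic mark H3K4me3.  `nucoloc`
turns the image-analysis protocol behind such findings into a tested,
scriptable pipeline:

1. **3-D nucleus segmentation** on the DAPI channel — Gaussian blur
   (σ = 5 px) on a duplicate, intensity window [30, 255], 26-connected
   components; volumes in µm³ and per-channel nuclear mean intensities
   measured on the raw channels.
2. **Chromatin classification** — heterochromatin (HC) = DAPI ≥ 150,
   euchromatin (EC) = 50 ≤ DAPI < 150, per nuclear ROI; binary signal
   masks for H3K4me3, PMP22 and Lamin B1.
3. **Peripheral vs central profiling** — longitudinal and transverse
   vectors through each plane's centroid, split into thirds (transverse)
   or quarters (longitudinal); distal sectors are peripheral.
4. **Colocalization** per nucleus for five pairings (EC–TC, EC–HC,
   PMP22–EC, PMP22–HC, PMP22–LaminB1): Manders split coefficients

   M1 = Σᵢ Qᵢ·[Rᵢ > 0] / Σᵢ Qᵢ,  M2 = Σᵢ Rᵢ·[Qᵢ > 0] / Σᵢ Rᵢ ∈ [0, 1],

   Spearman ρ and Kendall τ_b rank correlations, and the Costes
   block-scrambling significance (3×3-px blocks, 100 scrambles, pass
   threshold 95%), computed per z-slice and summarized by the per-nucleus
   median.
5. **Group statistics** — two-tailed Mann–Whitney U per measure, medians
   with bootstrap percentile 95% CIs, Shapiro–Wilk p recorded per group.

No real acquisitions ship with the package; a **synthetic scene
generator** builds ground-truthed Wt/TrJ-like multi-channel z-stacks
(ellipsoidal nuclei, HC blobs, peripheral Lamin B1/PMP22, configurable
overlap quotas) so every stage is validated by parameter recovery.  See
`docs/methods.md` for the model, parameters and limitations.

## Worked example

Ten synthetic nuclei per genotype, full pipeline, fixed seed:

```python
import pandas as pd
from nucoloc import GenotypeInput, RunConfig, genotype_preset, run_pipeline

inputs = []
for name in ("Wt", "TrJ"):
    preset = genotype_preset(name)
    preset.n_nuclei = 10
    inputs.append(GenotypeInput(genotype=name, synthetic=preset))

summary = run_pipeline(RunConfig(inputs=inputs, output_dir="example_out", seed=1))
print("nuclei per genotype:", summary["nuclei_per_genotype"])

comp = pd.read_csv("example_out/comparisons.csv")
rows = comp[comp["measure"].isin(
    ["volume_um3", "mean_PMP22", "mean_LMNB1", "EC_vs_HC_rho", "PMP22_vs_EC_M2"])]
print(rows[["measure", "median_wt", "median_trj", "U", "p_two_tailed"]]
      .to_string(index=False))
```

prints

```
nuclei per genotype: {'Wt': 10, 'TrJ': 10}
       measure  median_wt  median_trj   U  p_two_tailed
    volume_um3 300.361000  191.214000  95      0.000769
    mean_PMP22  13.912500   19.236600   0      0.000183
    mean_LMNB1  15.219300   11.055600 100      0.000183
  EC_vs_HC_rho  -0.831572   -0.653891   0      0.000183
PMP22_vs_EC_M2   0.738407    0.529636 100      0.000183
```

Reading the table: TrJ nuclear volumes are smaller (median 191 vs
300 µm³), nuclear PMP22 is brighter and Lamin B1 dimmer in TrJ, EC and HC
anticolocalize in both genotypes (median ρ < 0, more strongly in Wt), and
the fraction of nuclear PMP22 co-occurring with euchromatin (pairing iii,
M2) is higher in Wt (0.74) than TrJ (0.53) — each contrast significant by
the two-tailed Mann–Whitney test at α = 0.05.  `example_out/` also holds
the per-nucleus table (`nuclei.csv`), label maps and a JSON run summary.

The same run is available from the shell:

```bash
nucoloc simulate --genotype TrJ --n-nuclei 10 --seed 1 --out scene/
nucoloc run --config run.yaml        # simulate -> segment -> ... -> compare
nucoloc segment --stack scene/scene_TrJ.tif --out seg/
```

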