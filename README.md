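# radialpos

Quantification of the **radial nuclear position of chromosome
territories** from fluorescence in situ hybridization (FISH) images —
the analysis behind statements like "chromosome 18 sits at the nuclear
periphery in proliferating fibroblasts and relocates to the interior in
quiescence".

It is written for cell/nuclear-organization labs that have two-channel
images (DAPI counterstain + whole-chromosome paint) and want the two
standard read-outs:

1. **2D erosion analysis.** Each flattened, DAPI-defined nucleus is
   divided into five concentric shells of **equal area** (shell 1 =
   periphery, shell 5 = interior) by ranking nucleus pixels on their
   Euclidean distance transform and cutting the ranking into equal
   blocks. For each shell the percentage of probe signal is divided by
   the percentage of DAPI signal,

   `profile_k = (probe_k / Σ probe) / (DAPI_k / Σ DAPI)`, k = 1..5,

   giving a per-nucleus DNA-normalized radial profile; cohorts of 50–70
   nuclei are summarized as mean ± SEM, compared per shell between
   conditions with unpaired, unequal-variance (Welch) two-tailed
   t-tests at P < 0.05, and classified peripheral / intermediate /
   interior (P / IM / I) by the profile's center-of-mass index.

2. **3D distance analysis.** In structurally preserved nuclei imaged as
   confocal stacks (0.2 μm axial step), the distance in μm from each
   territory's geometric center to the nearest nuclear periphery is
   measured in three dimensions, reported raw and normalized by nuclear
   size ((major+minor)/2 or major axis alone), and summarized as
   frequency distributions — the relative ordering of chromosomes is
   checked to be invariant to the normalization choice.

A fully seeded **synthetic-data generator** (elliptical nuclei with
jitter and noise, Gaussian-blob territories placed at a known radial
fraction) makes every stage testable against ground truth without
microscope data. See `docs/methods.md` for the model, parameter
defaults, calibration of the P/IM/I thresholds, and limitations.

## Worked example

Two synthetic cohorts of 60 nuclei each: one with the territory at
radial fraction 0.85 (peripheral, proliferating-like) and one at 0.30
(interior, quiescent-like):

```python
import numpy as np
import radialpos as rp

before = rp.analyze_cohort_2d(
    rp.SyntheticSpec(radial_fraction=0.85, n_nuclei=60, seed=1), "proliferating")
after = rp.analyze_cohort_2d(
    rp.SyntheticSpec(radial_fraction=0.30, n_nuclei=60, seed=2), "quiescent")

for cohort in (before, after):
    call = rp.classify_position(cohort)
    print(f"{cohort.condition:>13}: n={cohort.n}  "
          f"mean profile = {np.round(cohort.mean, 3)}  "
          f"-> {call.label} (com_index = {call.com_index:.2f})")

print("shell  t       df     p          significant")
for c in rp.compare_cohorts(before, after):
    print(f"{c.shell}      {c.t_stat:+.2f}  {c.df:5.1f}  {c.p_value:.3g}   {c.significant}")
```

prints

```
proliferating: n=60  mean profile = [1.162 1.276 1.206 0.884 0.47 ]  -> P (com_index = 2.64)
    quiescent: n=60  mean profile = [0.254 0.363 0.65  1.267 2.468]  -> I (com_index = 4.07)
shell  t       df     p          significant
1      +179.29  113.0  1.27e-140   True
2      +108.41  114.8  1.79e-117   True
3      +62.26   95.8  2.68e-79   True
4      -82.49  116.5  3.6e-105   True
5      -127.91   81.3  1.77e-95   True
```

The peripheral cohort's profile peaks in shells 1–3 and is called P;
the interior cohort peaks in shell 5 and is called I; every shell
differs significantly between the two — the signature of a
repositioning event. A flat profile of 1.0 would mean the probe is
distributed like bulk DNA.

The same pipeline is available from the shell:

```sh
radialpos simulate-2d --n 60 --r 0.85 --seed 1 --out cohortA/
radialpos cohort --manifest cohortA/manifest.csv --out profilesA.csv
radialpos compare --a profilesA.csv --b profilesB.csv --out welch.csv
radialpos classify --cohort profilesA.csv
radialpos simulate-3d --n 20 --r 0.5 --seed 1 --out stacks/
radialpos radial3d --manifest stacks/manifest.csv --out distances.csv
```

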