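# faractin

Per-cell quantification of **F-actin redistribution (FAR)** in two-channel
fluorescence microscopy, with replicate-level statistics, a donor × sample
crossmatch read-out, and a synthetic image generator that makes the whole
analysis reproducible without patient material.

## The scientific problem

Primary focal segmental glomerulosclerosis (FSGS) is a podocytopathy believed
to be driven, in many patients, by circulating permeability factors (CPF) in
plasma, and it frequently recurs after kidney transplantation (rFSGS).  A
sensitive in-vitro read-out of CPF activity is cytoskeletal injury of cultured
podocytes: exposure to CPF-containing plasma redistributes filamentous actin
(phalloidin stain) away from homogeneous cytoplasmic stress fibers toward the
nuclear region.

The FAR assay quantifies this per cell.  For an annotated cell with
background-subtracted actin intensity `I(x)`, a DAPI-derived nuclear mask `N`
and a thresholded F-actin⁺ mask `A` inside the cell outline:

    FAR% = 100 · Σ_{x ∈ N ∩ A} I(x) / Σ_{x ∈ A} I(x)

i.e. the percentage of cellular F-actin intensity located in the nucleus
(an optional `whole_cell` denominator sums over the full outline instead).
Per-cell values are averaged within each independent replicate; groups are
compared against the pooled-donor-plasma (PDP) control on replicate means
(N = 3) with an unpaired Student's t-test, or Dunnett's many-to-one procedure
when several samples share one control.  The donor × patient-sample grid of
group means with significance flags is the "virtual crossmatch": it shows
which donor podocyte lines are susceptible to which patient plasmas.

## Worked example

The numbered scripts under `analysis/` run the full synthetic study: a
5-donor × (PDP control + 4 patient samples) × 3-replicate design with 30
annotated cells per replicate and known ground-truth nuclear actin fractions
ρ ∈ {0.15, 0.25, 0.40}:

```bash
python analysis/01_simulate_study.py --seed 1   # images + ROIs + manifest
python analysis/02_quantify_far.py              # per-cell FAR
python analysis/03_group_stats.py               # replicate stats vs PDP
python analysis/04_crossmatch_matrix.py         # crossmatch heatmap + CSV
```

With `--seed 1` the measured mean FAR% per group is

```
sample   P1A   P2A   P3A   P4A   PDP
donor
D1      38.8  40.3  14.4  39.8  14.3
D2      39.8  40.1  14.3  40.0  13.9
D3      14.2  14.3  14.4  14.3  14.3
D4      40.1  40.1  13.9  40.1  14.1
D5      23.4  24.0  14.4  23.7  14.3
```

recovering the generator's ground truth (100·ρ = 15 / 25 / 40) to within
~1.5 percentage points, and the crossmatch matrix flags exactly the injured
combinations:

```
sample        P1A        P2A      P3A        P4A
donor
D1      38.8 ****  40.3 ****  14.4 ns  39.8 ****
D2      39.8 ****  40.1 ****  14.3 ns  40.0 ****
D3        14.2 ns    14.3 ns  14.4 ns    14.3 ns
D4      40.1 ****  40.1 ****  13.9 ns  40.1 ****
D5      23.4 ****  24.0 ****  14.4 ns  23.7 ****
```

Donor D3 is designed as CPF-resistant (ρ stays at baseline for every sample)
and sample P3A as non-injurious — both come out uniformly non-significant,
while every elevated-ρ group is detected.  Stars follow the boundary-inclusive
ladder *P* ≤ .05 / .01 / .001 / .0001.

The same stages are available as a CLI (`faractin simulate | quantify |
stats | crossmatch`) for running on real TIFF + ImageJ-ROI datasets via a
study manifest.

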