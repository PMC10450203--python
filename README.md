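# rnapalm

Single-molecule-tracking PALM analysis of RNA polymerase (RNAP) spatial
organization in *Escherichia coli*, centred on strains in which most of the
seven chromosomal ribosomal RNA operons (*rrn*) have been deleted (Δ5 keeps
*rrnC* + *rrnB*, Δ6 keeps only *rrnE*). The package is for microbiologists and
biophysicists who want to simulate, analyse or re-analyse this kind of data:
it provides the complete computational pipeline — synthetic-data generation,
localization, tracking, mobility mixture fitting, spatial statistics,
clustering, co-localization, and the gene-dosage occupancy bookkeeping —
as a tested library plus numbered analysis scripts.

## What it computes

**Apparent diffusion and the two-gamma mixture.** Each track's apparent
diffusion coefficient is estimated from its first n = 4 single-frame steps,

    D* = (1 / (4 n Δt)) Σᵢ [(x_{i+1} − x_i)² + (y_{i+1} − y_i)²],

so for a Brownian track D* ~ Gamma(shape n, mean D_app), with
D_app = D_true + σ_loc²/Δt. A population of chromosome-bound (immobile) and
promoter-searching (mobile) RNAPs gives the two-gamma mixture

    p(x) = f · γ(x | D_imm, 4) + (1 − f) · γ(x | D_mob, 4),

fitted by unbinned maximum likelihood with D_imm fixed at a control value
(0.09 μm²/s, localization-error dominated) and (f, D_mob) free.

**Spatial statistics.** Localizations are pooled across cells in normalized
coordinates (l along the long axis, w across the cell) into heatmaps,
immobile-minus-mobile difference maps and long-axis profiles; the
*exterior-25% fraction* is the share of molecules whose folded coordinate
min(l, 1−l) lies within 0.25 of a pole (0.5 for a uniform distribution).

**Clustering and pair correlation.** DBSCAN (ϵ = 20 nm, MinPts = 4) with
core / directly-reachable / noise roles summarizes cluster sizes; the pair
correlation g(r) divides the observed pair-distance histogram by the mean
histogram of uniform points drawn in the 3D volume of revolution of the cell
boundary and projected to 2D, so confinement artefacts cancel and g ≡ 1 for
a uniform pattern. Co-localization with *rrn* FISH foci is the fraction of
queries within 200 nm of a focus, against a null of uniform draws in the
nucleoid area (the cell outline shrunk to 75% in length and width).

**Occupancy bookkeeping.** Per-cell gene copies follow the
replication-dependent dosage formula copies = 2^((C(1−m′)+D)/τ) with map
position m′ ∈ [0, 1] from *oriC*; summing over a strain's operon positions
gives its *rrn* copies per cell, and the interpolated count of
*rrn*-engaged RNAPs (N_r) divided by that gives the loading per operon,
reported as a percentage of the 72 RNAPs/operon seen at maximal growth.

**Synthetic data.** A four-population Monte-Carlo model (mobile molecules
uniform in a prolate-spheroid nucleoid; *rrn*-bound molecules in Gaussian
clusters on the pole-proximal nucleoid periphery at genomic-distance-mapped
positions; small clusters with exponentially distributed sizes; uniform
whole-cell noise), a two-species Brownian track generator, and a frame
renderer for the localization code.

## Worked example

```
python analysis/01_simulate_strains.py
python analysis/03_spatial_maps.py
python analysis/06_occupancy_table.py
```

prints, among other lines:

```
WT: exterior-25% fraction 60.9% (immobile) vs 25.2% (mobile); immobile profile peak at l_folded = 0.11
D5: exterior-25% fraction 70.3% (immobile) vs 25.2% (mobile); immobile profile peak at l_folded = 0.11
...
strain medium  doubling_time_min  n_rrnap  ori_copies  rrn_copies  rnap_per_rrn  occupancy_pct
    WT  M9Glu               47.0    397.0         2.9        17.5            23             32
    D5  M9Glu               57.0    238.0         2.5         4.8            50             69
    D6  M9Glu               73.0    122.0         2.2         2.0            61             85
    WT    RDM               36.0    805.0         3.7        22.0            37             51
    D5    RDM               46.0    420.0         2.9         5.6            75            104
    D6    RDM               51.0    320.0         2.7         2.5           128            178
```

Reading: immobile RNAPs in the Δ5 configuration concentrate at the
pole-proximal positions of the two remaining operons (larger exterior-25%
fraction than the wild type, whose seven operon sites spread further toward
mid-cell), and the occupancy table shows the deletion strains compensating
by loading their remaining operons far more heavily — up to 128 RNAPs per
operon in Δ6 in rich medium, 178% of the maximal-growth-rate reference and
close to the ~135-RNAP physical packing ceiling for a 40 bp footprint.
`analysis/02_mobility_fit.py` links a simulated movie back into tracks and
recovers `f_immobile = 47.8%` (truth 48.2%) with `D_mobile = 0.359 μm²/s`;
`analysis/04_clustering_paircorr.py` shows short-range g(r) increasing from
wild type (2.6) to Δ5 (4.6) to Δ6 (7.5).

A `rnapalm` console script exposes the same steps on CSV files
(`rnapalm fit-mobility`, `cluster`, `gr`, `coloc`, `heatmap`, `occupancy`,
`simulate-cells`); see `rnapalm --help`.

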