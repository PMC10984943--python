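# ectcraft

Downstream spatial analysis of deconvolved spatial transcriptomics:
from per-spot cell-type abundances to cellular niches, EcoCellTypes and
survival-linked cohort stratification.

## The problem

Spot-based spatial transcriptomics (e.g. 10x Visium, 55 µm spots)
measures mixtures of cells. Deconvolution tools such as cell2location
estimate, for every spot, the abundance of each cell type from a
single-cell reference — but the biology of the tumor microenvironment
lives one level higher: *which cell types co-occur, where, and with what
clinical consequence?* `ectcraft` answers that question for
multi-patient studies of the breast-cancer microenvironment (and any
comparable design). It provides:

- **Pseudo-single-cell maps** — abundance rows are discretised to
  integer cell counts (rounding up per cell type, down for cancer
  cells) and each counted cell is drawn inside its spot with a 40 µm
  jitter, giving single-cell-like section plots.
- **Cell-type distance statistics** — per section, the Euclidean
  distance from every pseudo-cell to the nearest pseudo-cell of every
  other type; cell types ranked by median distance to an anchor
  (typically cancer cells).
- **Niches** — spot compositions are mapped to isometric log-ratio
  (ILR) coordinates, a batch-balanced kNN graph is built across all
  sections (k nearest neighbours within *every* section, absorbing
  per-patient batch shifts), and Leiden community detection at
  resolution 0.6 yields communities of spots with a shared cell-type
  composition across patients. New sections can be labeled by nearest
  niche centroid.
- **EcoCellTypes (ECTs)** — the niche × cell-type mean-composition
  matrix is centered/scaled per cell type and cell-type profiles are
  clustered (Euclidean distance, Ward linkage); each resulting group of
  co-occurring cell types is an ECT.
- **Cohort stratification and survival** — bulk cell-type fractions are
  aggregated to ECT fractions, patients clustered (correlation
  distance, Ward) or median-stratified, compared with Kaplan–Meier
  curves and the log-rank test, and modeled with multivariate Cox
  regression.
- **Annotation transfer and enrichment** — pathologist GeoJSON
  compartment polygons are transferred to spots on a majority-area
  basis (cancer label wins above 30% coverage), and cell-state
  enrichment per compartment is tested with one-versus-all Wilcoxon
  rank-sum tests.
- **A synthetic-data generator** — multi-section studies with planted
  niches, co-occurrence blocks, annotations and survival effects, so
  the entire pipeline is testable without access to patient data.

## The core statistics

A spot composition `p = (p_1, …, p_D)` is embedded as
`ilr(p) = V · ln p`, where `V` is a (D−1)×D orthonormal Helmert-type
contrast basis (rows sum to zero). This is an isometry of the Aitchison
geometry: ILR Euclidean distance equals the compositional
(clr-difference) distance, and per-section multiplicative batch effects
become rigid translations, which the batch-balanced kNN graph then
absorbs. Niches are Leiden communities (RBConfiguration modularity,
resolution 0.6) of that graph; ECTs are the Ward/Euclidean clusters of
the per-cell-type z-scored niche-mean profiles; the log-rank statistic
is the classical observed-minus-expected form with hypergeometric
variance.

## Worked example

```python
import numpy as np
from ectcraft import (SimConfig, generate_sections, generate_cohort, fit_niches,
                      build_ect_model, ect_fractions, median_stratify, km_logrank)

config = SimConfig(n_sections=4, spots_per_section=600, n_cell_types=12,
                   n_niches=5, niche_center_concentration=300.0,
                   n_ect_blocks=4, seed=0)
study = generate_sections(config)
sections = [s for s, _ in study]

model = fit_niches(sections, k_within_batch=3, resolution=0.6, seed=0)
print(f"{model.n_niches} niches over {len(model.niche_labels)} spots")

ect = build_ect_model(model.niche_labels, sections, k="auto")
print(f"{ect.n_ect} EcoCellTypes:")
for ect_id, members in ect.membership_frame().groupby("ect_id")["cell_type"].apply(list).items():
    print(f"  ECT{ect_id}: {', '.join(members)}")

cohort, truth = generate_cohort(config, n_samples=300,
                                effect=[2.0, 0.0, 0.0, 0.0], seed=1)
fractions = ect_fractions(cohort[list(config.cell_types())],
                          {t: b + 1 for t, b in truth.ect_membership.items()})
groups = median_stratify(fractions["ECT1"].to_numpy())
res = km_logrank(cohort["time"], cohort["event"], groups)
print(f"log-rank chi2 = {res.statistic:.2f}, p = {res.p_value:.2e}")
```

prints

```
5 niches over 2400 spots
4 EcoCellTypes:
  ECT1: Cancer cells, TGFb-myCAF, Wound-myCAF
  ECT2: Detox-iCAF, IL-iCAF, Normal epithelial
  ECT3: Contractile-CAP, Myoepithelial, Universal fibroblasts
  ECT4: ECM-myCAF, IFNab-myCAF, IFNg-iCAF
log-rank chi2 = 30.72, p = 2.98e-08
```

The niche pipeline recovers all five planted spot communities; the
automatic dendrogram cut groups the twelve cell types into the four
planted co-occurrence blocks; and median stratification on the ECT that
carries a planted +2 log-hazard coefficient separates the cohort's
survival curves decisively.

A command-line interface mirrors the library:

```bash
ectcraft simulate --out study/ --sections 4 --spots 600 --seed 0
ectcraft validate study/
ectcraft niches study/ --resolution 0.6 --k 3 --seed 0 --out run/
ectcraft ect study/ --labels run/niche_labels.tsv --out run/
```

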