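# isoassign

Geographic assignment of wide-ranging animals from multi-element stable
isotope profiles of inert tissue.

Stable isotope ratios (δ¹³C, δ¹⁵N, δ²H, δ¹⁸O, in per mil relative to the
VPDB, AIR and VSMOW scales) in hair integrate broad biogeochemical
gradients across a predator's foraging range. Where those gradients are
spatially structured, the isotope profile of an individual becomes a
forensic tracer of its region of origin — useful for delineating
management units and checking the provenance of harvested animals.
`isoassign` implements the full analysis chain for this idea, developed
around marine apex predators sampled across very large ranges:

1. **Calibration** — two-point normalization of raw instrument deltas to
   the international scales through calibrated keratin reference
   materials (comparative equilibration for non-exchangeable hydrogen).
2. **Cohort screening** — deduplication, removal of small subpopulations,
   and the adult-vs-cub contrast: a two-factor MANOVA (Pillai's trace
   V = tr(H(H+E)⁻¹), Type II, subpopulation partialled out) plus
   per-isotope ANOVAs. Nursing young are enriched in ¹⁵N and depleted in
   ¹³C and ²H, so cubs are excluded from spatial analyses.
3. **Grouping** — hierarchical clustering (Ward / average / complete) of
   per-subpopulation medians of z-scaled isotope values, linkage chosen
   by cophenetic correlation, group count by mean silhouette width.
4. **QDA** — quadratic discriminant analysis with leave-one-out
   cross-validation, producing per-class and overall accuracy tables
   against subpopulations and grouped subpopulations.
5. **Isoscapes** — per-isotope interpolated surfaces: IQR outlier fence,
   70/30 stratified split, planar detrending, Matérn ("K-Bessel")
   semivariograms γ(h) = c₀ + c·[1 − (2^{1−ν}/Γ(ν))(h/a)^ν K_ν(h/a)]
   fit by weighted least squares, ordinary kriging, and an empirical-
   Bayes-style bootstrap over record subsets that propagates
   semivariogram uncertainty into the prediction standard error.
6. **Spatial clusters** — partitioning around medoids (PAM, exact
   BUILD+SWAP) and clara (PAM on subsamples) over the z-scaled isoscape
   stack, k selected by average silhouette width with an elbow curve.
7. **Assignment** — multivariate-normal likelihood assignment of
   held-out individuals to spatial clusters (equal priors), with
   accuracy tables and best:second odds ratios.

A first-class synthetic-data generator (`isoassign.synthetic`) produces
subpopulation polygons, spatially correlated isotope surfaces, and
adult/cub records with the statistical structure the pipeline assumes,
so every stage is testable end to end without restricted field data.

## Worked example

Three isotopically distinct regions, sampled, kriged, clustered and
recovered by assignment:

```python
from isoassign import Grid
from isoassign.synthetic import (three_plateau_scenario, generate_subpops,
                                 generate_fields, generate_bears)
from isoassign.cohort import cohort_report
from isoassign.isoscape import (stratified_split, outlier_filter,
                                ebk_surface, align_rasters)
from isoassign.clusters import build_cluster_raster
from isoassign.assignment import cluster_stats, evaluate_accuracy

sc = three_plateau_scenario(seed=42)
polygons = generate_subpops(sc)
grid = Grid.from_bbox(sc.bbox, 1.5)
fields = generate_fields(sc, grid)
records = generate_bears(sc, polygons, fields)

print(cohort_report(records).round(3).to_string(index=False))

adults = records[records.age_class == "adult"].reset_index(drop=True)
train, test = stratified_split(adults, 0.7, seed=42)
isotopes = ["d13C", "d15N", "d2H"]
surfaces = []
for iso in isotopes:
    kept, _ = outlier_filter(train, iso)
    surfaces.append(ebk_surface(kept, iso, grid, n_sims=10,
                                subset_size=100, seed=42))
stack = align_rasters(surfaces)
craster = build_cluster_raster(stack, isotopes, k="auto", seed=42)
print(f"k = {craster.k}, mean silhouette = {craster.avg_silhouette:.3f}")
stats = cluster_stats(train, craster, isotopes)
print(evaluate_accuracy(test, stats, craster, isotopes).to_frame().round(1))
```

Output:

```
                    term statistic   value  approx_F  df1  df2     p
       age|subpopulation  pillai_V   0.635    88.399    4  203 0.000
age|subpopulation (d13C)         F 108.173   108.173    1  206 0.000
age|subpopulation (d15N)         F 104.931   104.931    1  206 0.000
 age|subpopulation (d2H)         F 165.435   165.435    1  206 0.000
age|subpopulation (d18O)         F   0.193     0.193    1  206 0.661
k = 3, mean silhouette = 0.640
            n  accuracy_pct
1        17.0          88.2
2        20.0         100.0
3        17.0          88.2
overall  54.0          92.6
```

Reading it: the age contrast is strongly significant multivariately and
for δ¹³C, δ¹⁵N and δ²H but not δ¹⁸O (the generator gives cubs no ¹⁸O
offset); silhouette selection recovers the three planted regions from
the kriged stack; and 92.6% of held-out individuals are assigned back to
the spatial cluster containing their capture location.

The same pipeline is scriptable from the shell:

```sh
isoassign synth --seed 1 --out-dir run/
isoassign -v run-all --seed 1 --out-dir run/
```

which writes records and polygons (CSV/GeoJSON), per-isotope prediction
and standard-error surfaces (plain-text ASCII grids), dendrograms
(Newick), cluster rasters, Table-style accuracy CSVs and a JSON run
manifest.

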