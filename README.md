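# pedbc

Body-composition reference curves and cluster profiling for pediatric
cohorts.

Body weight alone is a blunt health indicator in children: the same BMI can
hide very different mixes of fat, muscle and bone. `pedbc` is for
researchers working with school-cohort bioimpedance (BIA) data who want to
(a) build age- and sex-specific reference models for body-composition
indices, (b) standardize children against those references, and (c) find
subpopulations — in particular the high-fat / average-muscle profile that
carries elevated metabolic risk despite an unremarkable muscle mass.

## The model

For each component mass *M* (fat, lean, muscle, bone, total body water) the
index is *M*/height² (kg/m²): FMI, LMI, MMI, BNI, TWI; BMI is treated the
same way. Per sex and index, observations are binned by integer age and
three scores — mean, mean + 1SD, mean − 1SD — are each fitted with a
least-squares cubic in age:

    score(a) = c0 + c1·a + c2·a² + c3·a³

At an age rounded to 0.1 years the reference is
μ(a) = mean-curve(a) and σ(a) = (upper(a) − lower(a))/2, and a child's
z-score is (x − μ(a))/σ(a). Z-scored indices feed the downstream pipeline:
nearly collinear indices (LMI/MMI/TWI, pairwise r > 0.99) collapse to MMI;
Ward hierarchical clustering on (z-BMI, z-FMI, z-MMI, z-BNI) is cut at
k = 5 (k-means as sensitivity check); clusters are compared on health
indicators by ANOVA, chi-square and mixed-effects regression with a random
intercept per child. Wrist-device activity/sleep data pass a wear-time
screen (edge-day trimming, monitored-time > 0.8 and activity > 0.1 of the
day, ±2SD outlier trimming) before entering as per-year means, and missing
indicators are imputed by kNN (k = 5; chained-equation PMM and
complete-case analysis as sensitivity routes).

Since cohort data of this kind are not redistributable, the package
includes a synthetic generator (`pedbc.synthetic`) producing three-wave
cohorts with exact BIA mass identities, a planted five-cluster structure,
11-day device traces and realistic missingness — everything needed to run
and test the full pipeline.

## Worked example

```python
import pedbc as pb

params = pb.CohortParams(seed=1)          # study-scale defaults
cohort, truth = pb.generate_cohort(params)
print(f"{len(cohort)} subject-wave observations of "
      f"{cohort.subject_id.nunique()} children")

df = pb.add_bci_columns(cohort)           # bmi, fmi, lmi, mmi, bni, twi
model = pb.BCIReferenceModel().fit(df)    # sex x index cubic reference
Z = model.transform(df)                   # z_bmi ... z_twi
print("r(z_BMI, z_FMI) = %.2f" % Z[["z_bmi", "z_fmi"]].corr().iloc[0, 1])

features = pb.prune_collinear(Z.drop(columns=["subject_id", "wave"]))
result = pb.canonical_order(pb.ward_cluster(Z[features], k=5))
print(result.centroids.round(2))
print("ARI vs planted labels = %.2f"
      % pb.adjusted_rand(result.labels, cohort.subject_id.map(truth)))
```

Output:

```
918 subject-wave observations of 353 children
r(z_BMI, z_FMI) = 0.97
         z_bmi  z_fmi  z_mmi  z_bni
cluster
1        -1.27  -1.21  -1.18  -1.28
2        -0.40  -0.43  -0.29  -0.38
3         0.38   0.28   0.48   0.44
4         1.19   0.96   1.39   1.23
5         0.80   1.29  -0.04  -0.20
ARI vs planted labels = 0.85
```

Reading the centroid table: clusters 1–4 move from low to high on *all*
indices together, while cluster 5 pairs a high fat index (z-FMI 1.29) with
near-average muscle and bone (z-MMI −0.04, z-BNI −0.20) — the imbalanced,
higher-risk profile. The z-BMI/z-FMI correlation of 0.97 shows adiposity,
not lean mass, drives BMI variation in children. The adjusted Rand index
of 0.85 measures recovery of the generator's planted labels after the full
fit-and-standardize pipeline.

A command-line interface mirrors the library
(`pedbc simulate | reference | screen | impute | cluster | compare`); run
`pedbc --help` for details.

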