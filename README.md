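# patchmeta

Tools for asking what drives **occupancy**, **mean abundance**, and
**abundance variability** across a fragmented network of habitat patches —
the classic question for a metapopulation at a species' range margin,
where patch area, isolation, habitat quality and microclimate compete as
explanations. The package was built around the study design of a bivoltine
butterfly monitored in ~50 dry-grassland patches over 12 years (two flight
periods per year, summer-only monitoring in later years), but every stage
is generic: bring a patch table and a survey table, or simulate both.

## What it computes

**Connectivity.** Each patch gets the abundance-weighted exponential-kernel
connectivity index

&nbsp;&nbsp;&nbsp;&nbsp;*S<sub>i</sub>* = Σ<sub>j≠i</sub> e<sup>−α d<sub>ij</sub></sup> *N<sub>j</sub>*

with *d<sub>ij</sub>* the Euclidean distance in meters and *N<sub>j</sub>*
the adult count at patch *j* (observed; mean-imputed for unsurveyed years;
a fallback estimate for patches outside the monitoring). The default decay
α = 0.0034 m⁻¹ corresponds to a 295 m mean movement distance. *S<sub>i</sub>*
is computed per year and generation and averaged per generation.

**Responses.** Per patch and generation: occupancy fraction (occupied
years / surveyed years) with a conservative false-absence correction — a
zero count is a true absence only when an adjacent surveyed occasion was
also zero; mean abundance across years (zeros included), log-transformed
with a +0.1 offset; and the CV of abundance (sample SD / mean),
log-transformed. Never-occupied patches stay in the occupancy model but
are excluded from the abundance and CV models.

**Inference.** Six main effects (area, connectivity, grazing as two
dummies vs "never", host-plant density, mean and SD of solar irradiance)
plus four connectivity interactions define 194 marginality-respecting
candidate models. Occupancy is fitted by a grouped binomial-logit GLM
(IRLS, written here), abundance responses by Gaussian ML. Models are
ranked by AICc = −2logL + 2k + 2k(k+1)/(n−k−1), weighted by Akaike
weights, and averaged over the 95% cumulative-weight confidence set;
reported per term: standardized averaged coefficient, unconditional SE,
and sum-of-weights importance.

**Synthetic data.** A first-class generator draws landscapes calibrated to
the field summaries of the motivating system (log-normal areas,
zero-inflated host cover, clustered patch placement that reproduces the
connectivity distribution) and simulates occupancy/count dynamics from
known standardized coefficients, so the whole pipeline is validated by
parameter recovery.

## Worked example

`examples/04_full_analysis.py` simulates the default 50-patch study and
runs the full pipeline (the synthetic truth is host +0.85, area +0.6,
connectivity:host −0.7 on the occupancy logit):

```
summer occupancy model: n = 50 patches, 13 models in the 95% confidence set
                          term  estimate    se  importance
                          area     0.802 0.179       1.000
                  connectivity     0.090 0.177       1.000
             grazing_sometimes     0.182 0.313       0.261
                grazing_always     0.149 0.271       0.261
                  host_density     0.708 0.137       1.000
                      irr_mean    -0.002 0.030       0.304
                        irr_sd    -0.007 0.029       0.253
connectivity:grazing_sometimes     0.053 0.121       0.028
   connectivity:grazing_always     0.050 0.117       0.028
     connectivity:host_density    -0.604 0.169       0.994
         connectivity:irr_mean    -0.016 0.031       0.121
           connectivity:irr_sd    -0.001 0.005       0.053
```

The three true drivers come back with the right sign and magnitude and
importance ≈ 1, while the null terms shrink toward zero with low
importance. The negative connectivity:host coefficient is the rescue
effect: host density matters most in isolated patches. Other capabilities
are shown one per script in `examples/` (simulation, connectivity,
responses, a scaled-down recovery study); each prints what it computes and
what the numbers mean.

A thin CLI wraps the same library:

```bash
patchmeta simulate --out data/ --seed 1
patchmeta analyze --patches data/patches.csv --surveys data/surveys.csv --out results/
patchmeta recover --replicates 20 --out recovery/ --seed 1
```

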