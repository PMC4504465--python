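# myofat

Automated quantification of fatty infiltration in muscle from T1-weighted
MRI, for researchers studying muscular dystrophies (e.g. FSHD) where muscle
is progressively replaced by fat and the **intramuscular fat fraction** is
the quantitative outcome of interest.

## What it computes

On each axial slice of a limb volume the pipeline runs:

1. **Tissue clustering** — 3-class k-means on pixel intensities. Under T1
   contrast the clusters map to background/bone/vessels (dark), muscle
   (mid-gray) and adipose tissue (bright).
2. **Morphological cleanup** — bright vessel lumina are closed out of the
   fat class and the thin skin rim is stripped from the muscle class,
   preserving the morphology of the muscle compartment.
3. **Active contours (snakes)** — a closed polygon of N = 50 control
   points minimizes the discrete energy

   ε = Σᵢ α·‖pᵢ−pᵢ₋₁‖² + β·‖pᵢ₋₁−2pᵢ+pᵢ₊₁‖² + γ·E_image(pᵢ)

   with (α, β, γ) = (0.1, 0.6, 0.3), fitted greedily to the outer limb
   boundary and to the fascia (muscle-compartment) boundary.
4. **Compartments** — subcutaneous fat (SAT) is the fat class between the
   two contours; intramuscular fat (IMAT) and muscle are the fat and
   muscle classes inside the fascia, excluding the detected bone.
5. **Fat fraction** — per slice, `|IMAT| / (|IMAT| + |muscle|)` by pixel
   count; per volume, the mean over the 20 middle slices. Slices where
   severe infiltration makes the SAT/IMAT delimitation untrustworthy are
   flagged and routed to a manual-contour fallback.

Alongside the imaging pipeline, `myofat.cohort_stats` implements the
cohort-level analyses used with it: k-means clustering of per-muscle
visual scores (grades 1–4) into imaging patterns, left/right asymmetry and
STIR-hyperintensity summaries, ICC(2,1) reproducibility with per-subject
CV, Spearman correlation with Bonferroni correction, Student's t-test, and
the linear-vs-logarithmic R² comparison between mean visual score and fat
fraction.

Because real patient images cannot ship with the code, `myofat.phantom`
renders synthetic thigh slices with exact ground truth — SAT ring, skin,
femur (cortical + marrow), "moth-eaten" fat speckle at a controllable
fraction, a proximal→distal infiltration gradient, Rician noise and a
smooth bias field — plus synthetic cohort score tables with known cluster
structure. Every stage is tested against those ground truths.

## Worked example

```python
import myofat as mf

spec = mf.PhantomSpec(gradient=(0.116, 0.272), n_slices=8,
                      noise_sigma=110/15, seed=11)   # SNR ≈ 15
vol, truth = mf.make_thigh_phantom(spec)
res = mf.segment_volume(vol, mf.PipelineConfig(seed=4))
for i, (e, t) in enumerate(zip(res.result.per_slice_fraction,
                               truth.true_fat_fraction_per_slice)):
    print(f"{i:5d}  {e:9.4f}  {t:.4f}")
print(f"aggregate fat fraction: {res.result.aggregate_fraction:.4f}")
```

prints

```
    0     0.1173  0.1160
    1     0.1381  0.1384
    2     0.1614  0.1606
    3     0.1858  0.1829
    4     0.2008  0.2051
    5     0.2256  0.2275
    6     0.2467  0.2498
    7     0.2733  0.2720
aggregate fat fraction: 0.1936
```

Each row is one slice: the automatically estimated intramuscular fat
fraction next to the phantom's true fraction (the infiltration gradient
rises from ≈ 11.6% proximally to ≈ 27.2% distally). The aggregate is the
mean over the analyzed slices; with a taller stack it would cover the 20
middle slices only.

The same pipeline is available from the shell:

```bash
myofat phantom make --config spec.yaml --seed 5 --out phantom_dir/
myofat segment run --in phantom_dir/phantom.nii.gz --seed 1 --out results_dir/
myofat cohort cluster --scores scores.csv --region thigh --k 3 --seed 0
myofat cohort icc --ratings ratings.csv
```

`segment run` writes per-slice fractions (`fractions.csv`), compartment
label maps (NIfTI), contour polygons (CSV) and a JSON run manifest with the
configuration hash and seed; its exit status signals when slices need
manual correction (`myofat segment manual`).

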