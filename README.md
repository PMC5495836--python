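# oiconnect

Resting-state functional connectivity from multispectral intrinsic optical
signal (OIS) imaging of the rodent cortex — spectral unmixing, nuisance
regression, seed-based correlation mapping with FDR + cluster-extent
thresholding, group statistics, and connectivity-feature machine learning —
together with a ground-truth synthetic cohort generator that makes every
stage testable end to end.

## Who this is for

Labs doing wide-field optical imaging of rodent cortex (and methodologists
evaluating such pipelines) who need a reproducible path from raw
multispectral reflectance movies to group-level connectivity statistics.
The emulated study design is a two-group comparison: sham-injected control
pups versus an inflammatory white-matter-injury model in which
interhemispheric (homotopic) coupling degrades with lesion severity.

## The analysis in brief

1. **Unmixing.** Reflectance at λ = 525/590/630 nm is converted to optical
   density, ΔOD = log₁₀(I₀/I), and to oxy-/deoxy-hemoglobin concentration
   changes through the modified Beer–Lambert model
   ΔOD(λ,t) = Σᵢ εᵢ(λ) ΔCᵢ(t) D(λ), solved per pixel by Moore–Penrose
   pseudoinverse.
2. **Preprocessing.** Per-pixel GLM regression of physiological nuisance
   (heart rate, respiration, ECG, respiration rate, global cortical mean);
   11×11 Gaussian smoothing (σ = 3 px) renormalized over the cortex mask;
   zero-phase fourth-order Butterworth band-pass, 0.009–0.08 Hz; projective
   registration to a seed atlas.
3. **Connectivity.** Seed time courses (17-pixel seeds; motor, cingulate,
   somatosensory, retrosplenial × hemisphere), Pearson r with Fisher
   z = ½ ln((1+r)/(1−r)), normalized seed-to-pixel maps, group one-sample
   t-maps with a Benjamini–Hochberg height threshold (q = 0.05) and a 5%
   cluster-extent filter. The **spatial extent** of a network is the
   fraction of cortex pixels surviving both thresholds.
4. **Group statistics.** Mann–Whitney rank-sum tests, BH-FDR adjustment,
   Hedges' g, Fisher's exact mid-P.
5. **Machine learning.** 56 seed-pair Fisher-z features (both contrasts)
   feed an RBF-kernel SVM (injury classification, repeated stratified
   10-fold CV with inner-fold grid search) and a Bayesian-regularized
   two-layer network (20 tanh hidden units) predicting fractional lesion
   volume.
6. **Histology.** Ventricular volume from serial coronal sections
   (threshold → binarize → fill holes → count → convert at 228 px/mm), and
   the fractional (ventricle/brain) volume used as the lesion covariate.

Details, defaults, and design rationale are in `docs/methods.md`.

## Worked example

Simulate a small cohort and compare homotopic connectivity between a
control and an injured subject:

```python
from oiconnect.pipeline import RunConfig, analyze_subject
from oiconnect.seed_fc import homotopic_connectivity
from oiconnect.synthetic import CohortDesign, simulate_cohort

# a small desk-scale cohort: 3 control + 3 injured pups, 3-minute records
design = CohortDesign(shape=(64, 64), n_frames=900, include_optics=False)
cohort = simulate_cohort(n_control=3, n_injured=3, design=design, rng_seed=42)
config = RunConfig(design=design, do_unmix=False)

for i in (0, 3):  # first control, first injured
    subject = cohort.subject(i)
    result = analyze_subject(subject, cohort.atlas, config)
    z = homotopic_connectivity(result.matrices["HbO2"], cohort.atlas)
    pairs = ", ".join(f"{l[:-2]}={v:.2f}" for (l, r), v in z.items())
    print(f"{subject.subject_id} ({subject.truth.group}, "
          f"lesion {subject.truth.lesion_fraction:.2f}): homotopic z: {pairs}")
```

prints

```
ctl00 (control, lesion 0.00): homotopic z: M=0.28, C=1.15, S=0.88, R=0.88
inj03 (injured, lesion 0.70): homotopic z: M=-0.03, C=0.45, S=-0.12, R=0.16
```

The control animal shows the coupled bilateral networks the generator
encodes (Fisher z around 0.9 corresponds to r ≈ 0.7, with per-subject
variability); in the injured animal, a lesion fraction of 0.70 attenuates
interhemispheric coupling to ≈ 30% of its control value and the homotopic
z values collapse toward zero.

The same chain scales to full studies with `oiconnect run --config
cohort.yaml --out runs/demo/` (or `pipeline.run_pipeline`), which writes
per-subject connectivity CSVs, group spatial-extent and statistics tables,
SVM/ANN reports, heatmap figures via `oiconnect report`, and a checksummed
manifest.

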