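# semadapt

Region selection and repetition-suppression (fMRI-adaptation) analysis for
studies of abstract and concrete semantic categories — with synthetic
generators for every input, so the full chain runs and is testable without
any external data.

## Who this is for

Cognitive-neuroscience groups running ROI-based fMRI-adaptation experiments
on semantic knowledge. The package covers two jobs that are usually done with
one-off scripts:

1. **A-priori ROI selection** from published coordinates plus a
   meta-analytic database characterization. Per candidate region it computes
   five indexes:
   - *correction-level index* ∈ [−1, 1]: mean of coded correction levels of
     the contributing contrasts (voxel-level = 1, cluster-level = 0.5,
     uncorrected = −1; unknown excluded);
   - *semantics/control sensitivity index* ∈ [−1, 1]: mean of coded contrast
     classes (concrete semantic = 1, abstract semantic = 0.5, control = −1),
     with the median MNI coordinate of the contributing foci mapped onto an
     atlas parcel (Talairach inputs are converted with the Brett
     piecewise-affine transform; foci closer than 10 mm are merged by single
     linkage);
   - *domain-heterogeneity* W = (n_micro/total_micro + n_macro/total_macro) /
     n_domains of the region;
   - *domain specificity* = W × P, with P the activation likelihood of a
     domain in the region;
   - *control-type mean* ∈ [−1, 1]: mean of coded paradigm control types
     (semantic = 1, mixed = 0.5, control = −1).

   Regions with control-type mean > 0.6 (semantic) or < −0.6 (control) that
   also pass concordance and specificity filters on the *semantic-control
   differential* (sensitivity index − control-type mean) form the final ROI
   sets.

2. **Adaptation analysis** of subject × ROI × condition BOLD estimates from a
   prime–target passive reading design (Same Category, Different Category,
   and a Same Word baseline isolating word-form repetition): SVD eigenvariate
   extraction per ROI, per-subject baseline-subtracted contrasts
   (SC − SW, DC − SW; a *smaller* SC − SW value = stronger adaptation), a
   CONDITION × DOMAIN × ROI linear mixed model with a participant random
   intercept (REML) reporting ICC = σ²_subject/(σ²_subject + σ²_residual)
   and Wald tests, Bonferroni-corrected ROI-specific interaction probes, and
   post-hoc category ANOVAs/t-tests with Cohen's d.

## Worked example

```python
from semadapt.pipeline import PipelineConfig, run_pipeline

manifest = run_pipeline(PipelineConfig(outdir="demo_run", seed=11,
                                       bold={"n_subjects": 24}))
print(manifest["stages_run"])
print(manifest["notes"]["planted_adaptation"])
```

prints

```
['simulate', 'index', 'select', 'design', 'analyze']
{'166|EM': -2800.0, '166|ATT': -2750.0, '46|BIOL': -3400.0, '46|ART': -2900.0}
```

i.e. all five stages ran, and the simulator planted adaptation effects
(negative Same-Category − Same-Word shifts, in arbitrary BOLD units) for the
emotion/attitude categories in one selected semantic region (atlas parcel
166) and for the concrete categories in another (parcel 46). `demo_run/`
then holds, among others, `rois.tsv` (selected regions with classes and an
exclusion audit), `design.tsv` (two runs × 54 trials: 24 Same Category,
24 Different Category, 6 Same Word each, jittered 3/5/7 s intervals),
`lmm_variance.json` (this run: `"icc": 0.0085` — between-subject variability
is negligible, as expected when the subject intercept cancels in
baseline-subtracted contrasts), `roi_interactions.tsv`, and `posthoc.tsv`
with the per-category comparisons. In `roi_interactions.tsv` exactly the two
planted regions are significant after Bonferroni correction, in the
Same-Category condition and with opposite signs of the abstract − concrete
difference (−1241.2, p = 0.017 in parcel 166; +3341.9, p = 8.0e-10 in
parcel 46): the region adapted by abstract categories shows the lower
abstract contrast, the region adapted by concrete categories the lower
concrete contrast.

Every stage is also exposed on the command line:

```bash
semadapt simulate corpus --n-contrasts 195 --seed 1 --out corpus.tsv
semadapt index-literature --corpus corpus.tsv --atlas atlas.nii.gz --out regions.tsv
semadapt run --config pipeline.yaml
```

## Layout

- `semadapt.simulate` — generators: literature corpus, region profiles,
  label atlas (NIfTI), stimulus lexicon with matched psycholinguistic
  attributes, BOLD betas with planted adaptation, and a contrast-level
  mixed-model generator for parameter-recovery studies
- `semadapt.literature` — coordinate transform, coding rules, focus merging,
  atlas lookup, region scores
- `semadapt.brainmap` — W, domain specificity, control-type mean
- `semadapt.selection` — semantic-control differential and the selection rule
- `semadapt.design` — pair construction, run assembly, matching verification
- `semadapt.analysis` — eigenvariates, contrasts, mixed model, post hocs
- `semadapt.pipeline` / `semadapt.cli` — orchestration, manifests, CLI

See `docs/methods.md` for the modeling assumptions and numerical choices.
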