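# dualproc

Dissociating **recollection** and **familiarity** in recognition memory, and
relating each process to the integrity of medial-temporal-lobe (MTL)
structures, is a classic problem in neuropsychology: dual-process theories
hold that the hippocampus (HPC) supports recollection while parahippocampal
cortices support familiarity, but testing this requires estimating the two
processes from behavior and relating them to graded, normatively scaled
measures of regional damage in small patient cohorts.

`dualproc` implements that full analysis pipeline for researchers working
with patient/control recognition-memory studies:

1. **Dual-process signal-detection (DPSD) ROC fitting.** Confidence-rating
   responses (6-point scale, 80 targets/80 foils per condition) are cumulated
   into ROCs and fit with the DPSD model

   `H_i = R + (1 − R)·Φ(d′ − c_i)`,  `FA_i = Φ(−c_i)`,

   yielding a recollection probability `R` and familiarity discriminability
   `d′` per participant × material, by sum-of-squared-error minimisation on
   the cumulative ROC points (multinomial maximum likelihood optional).
2. **Response-deadline procedure (RDP).** Old/new d′ per deadline;
   `familiarity = d′(short)`, `recollection = d′(long) − d′(short)`.
3. **Normative volumetry.** ROI volumes divided by total intracranial
   volume, Z-scored against control norms, lesions called at `Z < −1.67`,
   hemispheres averaged for continuous analyses.
4. **Inference.** Behavioral Z-scoring against control norms; multiple
   imputation by chained equations for missing control scores (range of F
   and p reported across imputations); mixed between×within ANOVAs;
   per-ROI linear mixed models of `score_z ~ volume_z × Process ×
   Material × Paradigm` with participant random effects, Type-III F tests
   with Satterthwaite degrees of freedom, and Freedman–Lane permutation
   p-values; Pearson χ² (no continuity correction) and Mann–Whitney U for
   demographics.
5. **Synthetic cohorts with known ground truth.** A seeded generator plants
   configurable volume→recollection and volume→familiarity slopes, so every
   stage is testable by parameter recovery and the pipeline's
   double-dissociation logic can be validated end to end.

## Worked example

Fit the DPSD model to one condition's confidence counts (here simulated
from the model with `R = 0.35`, `d′ = 1.1`, 80 targets/80 foils):

```python
import numpy as np
from dualproc import ConfidenceCounts, DPSDModel
from dualproc.cohort import dpsd_confidence_probs, DEFAULT_CRITERIA

rng = np.random.default_rng(42)
p_t, p_f = dpsd_confidence_probs(0.35, 1.1, DEFAULT_CRITERIA)
counts = ConfidenceCounts(tuple(rng.multinomial(80, p_t)),
                          tuple(rng.multinomial(80, p_f)))
print(DPSDModel(counts).fit(seed=0).summary())
```

```
Dual-process signal-detection fit
=================================
objective       : sse = 0.000970
converged       : True (10 restarts)
recollection R  : 0.3198
familiarity d'  : 1.0692
criteria        : -0.889, -0.365, 0.206, 0.672, 1.153
predicted H     : 0.637, 0.765, 0.868, 0.948, 0.983
predicted FA    : 0.124, 0.251, 0.418, 0.643, 0.813
```

The fitted `R` (0.32) and `d′` (1.07) recover the generating values to
within sampling error at 80 trials; the five criteria carve the strength
axis into the six confidence categories.

The full pipeline — generate a cohort, fit both paradigms, Z-score volumes
and behavior, run the categorical ANOVAs and the four per-ROI mixed models —
is one call (or `dualproc run-all --outdir runs/demo --seed 11` from the
shell):

```python
from dualproc import RunConfig, run_pipeline
bundle = run_pipeline(RunConfig(outdir="runs/demo", seed=11))
print(bundle["table2"].query("roi == 'HPC'").head(2))
```

`table2_continuous.csv` then holds one row per ROI model and
Volume-involving effect (effect, df1, df2, F, p), `table1_categorical.csv`
the lesion-group ANOVAs with F/p ranges across imputations, and
`recovery_report.csv` the bias/RMSE of every estimate against the
generator's ground truth. A `manifest.json` records the seed and a
configuration hash so identical configs rerun identically.

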