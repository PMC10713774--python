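# dmnstrat

Data-driven stratification of schizophrenia cohorts from resting-state
EEG functional connectivity within the default mode network (DMN).

Clinical heterogeneity is a central obstacle in psychosis research:
patients who share a diagnosis may differ in the underlying network
pathology. `dmnstrat` implements an unsupervised pipeline that asks
whether such biological subgroups exist in a cohort's resting-state DMN
connectivity, and whether the subgroups it finds are clinically
meaningful — without ever using clinical information to form them.

The pipeline, per frequency band (delta 1.5–4, theta 4–8, alpha 8–12,
beta 12–30 Hz):

1. **Connectivity.** Each participant's six DMN region-of-interest (ROI)
   time series (bilateral medial prefrontal, precuneus, lateral
   parietal) are band-pass filtered, cut into forty 8-s epochs, and the
   epoch-averaged **phase lag index** is computed for all 15 ROI pairs:

       PLI(i, j) = | ⟨ sign( sin(φᵢ(t) − φⱼ(t)) ) ⟩ₜ |

   where φ is the instantaneous (analytic-signal) phase. PLI ignores
   zero-lag coupling, which makes it robust to volume conduction.
2. **Reduction.** PCA is fitted on the full cohort (patients *and*
   controls); the component count k minimizes an AIC built on the
   probabilistic-PCA likelihood (small-sample corrected). Clustering
   uses at most ⌊log₂ n_patients⌋ components (5 for 37 patients), the
   2^d sample-size rule for mixture models.
3. **Subgrouping.** Patient scores are clustered with a Gaussian mixture
   model fitted by EM with ridge-regularized covariances (λ·I added at
   every M-step). K = 1..8 and λ are chosen by leave-one-out
   cross-validated held-out log-likelihood; the whole selection is
   repeated 50 times and a cluster count is only reported if it wins
   ≥ 90% of repeats. Patients are assigned by posterior probability.
4. **Validation.** Subgroups are compared on every demographic,
   connectivity, cognitive and psychopathological variable (χ²/Fisher,
   Welch t or Mann–Whitney U as appropriate; Benjamini–Hochberg FDR
   within each modality), and a linear SVM tests whether the PANSS
   sub-scores (positive/negative/general) or five a-priori cognitive
   measures predict subgroup membership: leave-one-out accuracy, with
   significance from a Monte Carlo permutation test
   (p = (b+1)/(m+1), m = 1000 permutations).

Because clinical EEG of this kind cannot be shared, the package ships a
**synthetic cohort generator**: band-limited coupled-oscillator ROI
signals with controllable per-pair coupling strength κ and phase lag δ,
a planted 19/18 patient subgroup split, and clinical scores whose means
shift with the planted label. Every stage of the pipeline is tested
against this generator and against brute-force oracles.

## Worked example

```python
from dmnstrat import RunConfig, run_pipeline
from dmnstrat.simulate import SimulationConfig

config = RunConfig(K_grid=range(1, 7), n_repeats=20, n_permutations=1000,
                   seed=1, simulation=SimulationConfig(seed=7920))
report = run_pipeline(config)
print(report.summary())
```

This simulates the default cohort (37 patients with a 19/18 subgroup
split planted in the theta- and beta-band coupling, 97 controls) and
runs the full analysis. The run above printed:

```
dmnstrat run 697afe58eeaa1f71 (seed 1): 37 patients, 97 controls
  delta: no stable subgroups (not stable (modal K in 85% of runs))
  theta: no stable subgroups (not stable (modal K in 70% of runs))
  alpha: no stable subgroups (stable at K*=1)
  beta: K*=2 stable (100% of runs), sizes 19/18
    panss: LOOCV accuracy 59.5% (p = 0.2038)
    cognition: LOOCV accuracy 73.0% (p = 0.01099)
```

Reading it: the beta band stabilizes at two clusters whose sizes match
the planted 19/18 split exactly (adjusted Rand index 1.0 vs the ground
truth, recorded in the JSON report), and the cognitive profile predicts
those subgroups well above chance (73.0%, permutation p ≈ 0.011) while
the PANSS profile does not — for this simulated cohort the planted
psychopathology effects happen to be too weak to exploit. The bands
without planted structure report no stable subgroups, one by stably
selecting a single cluster and two by failing the 90% stability gate.
The theta band, which does carry planted structure, *also* fails the
gate here (its true cluster count wins only 70% of the repeated
selections): at 37 patients the stability criterion is deliberately
conservative, and which structured bands clear it varies from cohort to
cohort — run the same config with a different simulation seed and theta
recovers while beta near-misses. That per-band, per-cohort variability
is a property of the method worth seeing, not a defect of the
simulation.

The `examples/` directory walks through each capability separately
(generator, PLI features, AIC order selection, stability-gated
clustering, clinical validation, full pipeline). A thin CLI mirrors the
stages (`dmnstrat simulate | connectivity | reduce | cluster | compare |
predict | run`); see `dmnstrat --help`.

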