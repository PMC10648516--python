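# netseg

Resting-state brain **system segregation** analysis for aging and dementia
cohorts: a synthetic-cohort generator, the RSFC denoising sequence,
connectivity-matrix construction, the segregation statistic with its
system-type and block decompositions, and covariate-controlled inference
(OLS, random-intercept mixed models, Freedman–Lane permutation tests).

The package is aimed at researchers who want to study — or stress-test
analysis code for — the dissociation between adult aging and Alzheimer's
dementia severity in large-scale functional brain network organization:
aging primarily weakens **within-system** coupling of association systems,
while dementia severity (Clinical Dementia Rating, CDR) is most prominent
among **between-system** interactions and touches both association and
sensory-motor systems. Because the clinical imaging data that motivate this
design are access-restricted, `netseg` ships a first-class synthetic cohort
generator so that every stage of the pipeline is verifiable end to end with
no download.

## The statistic

For a node×node matrix of Fisher z-transformed Pearson correlations (with
negative values set to zero and the diagonal excluded), brain system
segregation is

    segregation = (Z̄_w − Z̄_b) / Z̄_w

where `Z̄_w` is the mean connectivity over all *W* within-system node pairs
and `Z̄_b` the mean over all *B* between-system node pairs. A system
disconnected from all others yields the maximum of 1; a matrix with no
modular differentiation yields 0. System-type segregation (association vs
sensory-motor) replaces the pooled means with a mean-of-means over the
per-system within (`W_s`) and between (`B_s`) averages — both readings are
implemented as deliberately distinct code paths.

## Worked example

```python
import netseg as ns

config = ns.PipelineConfig(cohort=ns.CohortSpec(size=300), seed=42)
report = ns.run_pipeline(config)
print(report.n_analyzed, "subjects analyzed,", report.n_excluded, "excluded by QC")

ols = report.model_results["assoc_segregation"]
print("age beta = %.5f, t = %.2f, partial r = %.3f"
      % (ols.coefficients["age"], ols.t_values["age"], ols.partial_r["age"]))
```

With the default generator this prints (seed 42):

```
299 subjects analyzed, 1 excluded by QC
age beta = -0.00107, t = -7.44, partial r = -0.399
```

i.e. each additional year of age lowers association-system segregation by
about 0.001 after controlling for CDR, gender, post-scrubbing head motion
and education — the injected aging effect, recovered through the full
denoise → network → segregation → regression chain. The same report carries
the sensory-motor models (age effect null by construction), the mixed-model
interactions and the per-block permutation tests.

The same stages are scriptable from the shell:

```bash
netseg simulate --out-dir sim --size 50 --seed 7
netseg denoise --timeseries sim/sub-0001_timeseries.tsv \
               --motion sim/sub-0001_motion.tsv \
               --tissue sim/sub-0001_tissue.tsv --out clean.tsv
netseg netbuild --timeseries clean.tsv --out matrix.tsv
netseg segregate --matrix matrix.tsv --partition sim/partition.tsv \
                 --out seg.tsv --blocks blocks.tsv
netseg run --config pipeline.json
```

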