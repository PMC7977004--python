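# drdscore

Genomic DNA-damage-response features and a linear risk score for predicting
initial platinum resistance in high-grade serous ovarian cancer (HGSOC).

Roughly a quarter of HGSOC patients relapse within six months of their last
platinum dose (platinum-resistant by the GCIG criterion), and no single
genomic marker — *BRCA1/2* status, HRD score, TMB — predicts this reliably.
This package reimplements, as a reusable and fully testable pipeline, a
published approach that combines fourteen DNA-damage-related genomic
features per tumor into one linear predictor:

* **HRD score** — the genomic-scar sum LOH + TAI + LST computed from
  allele-specific copy-number segments, with the conventional HRD-high
  threshold of 42;
* **MHID** — the count of microhomology deletions (indels whose breakpoints
  share flanking sequence identity, the footprint of microhomology-mediated
  end joining);
* **copy-number change load**, **duplication load in 1–100 kb**, **SNV
  load**, **neoantigen count** (consumed as an input);
* eight mutational-signature exposures (**AC1, AC4, AC7, AC10, AC12, AC18,
  AC20, AC24**) obtained by non-negative least squares against a 30-column
  signature matrix.

The published predictor is the linear combination

```
DRDscore = −0.00133·HRD + 0.000969·MHID + 0.0003·CN_load
           − 0.00078·DUP_1_100KB − 0.00024·SNV_load + 0.000013·NEOANTIGENS
           − 0.000085·AC1 + 0.00046·AC4 − 0.0013·AC7 + 0.00138·AC10
           + 0.00041·AC12 + 0.000678·AC18 − 0.00093·AC20 − 0.00081356·AC24
```

with scores strictly above 0.7584 predicting resistance.  The package
applies this formula verbatim, supports refitting the coefficients by
L1-penalized logistic regression with leave-one-out cross-validation
(`DRDModel.fit()`), and evaluates cohorts with exact Clopper–Pearson
intervals, rank-based AUC, Fisher and Mann–Whitney tests.

Because the original patient-level data are access-restricted, the package
ships a synthetic-cohort generator (`drdscore.simulate`) that emits
VCF/segment/SV files with *planted, exactly recoverable* feature values on
a desk-scale mini-genome, so every stage — parsing, scar scoring, catalog
construction, NNLS, scoring, refitting, evaluation — is verifiable end to
end. See `docs/methods.md` for the model details and the generator's
deliberate compromises.

## Worked example

Simulate the discovery-preset cohort (38 platinum-sensitive, 19 resistant),
recompute one patient's features from the emitted files, and score them:

```python
from pyfaidx import Fasta
from drdscore import (GeneratorConfig, simulate_cohort,
                      compute_patient_features, drdscore, classify)
from drdscore.simulate import DESK_SCALE_SCARS

cohort = simulate_cohort(GeneratorConfig.discovery(seed=1), "demo")
patient = cohort.patients[0]
fv = compute_patient_features(
    patient.vcf_path, patient.segments_path,
    Fasta(str(cohort.reference.fasta_path)), cohort.reference.ann,
    sv_path=patient.sv_path, scars=DESK_SCALE_SCARS,
    neoantigens=patient.truth["NEOANTIGENS"])
print(fv.as_series().to_string())
print(f"DRDscore = {drdscore(fv):.6f}")
print(f"call     = {classify(drdscore(fv)).label}")
```

prints

```
HRD            103.000000
MHID            17.000000
CN_load        119.000000
DUP_1_100KB      5.000000
SNV_load       377.000000
NEOANTIGENS     16.000000
AC1             45.361230
AC4             14.274066
AC7              0.692114
AC10            74.595797
AC12             0.000000
AC18             0.000000
AC20             0.000000
AC24             5.521594
DRDscore = -0.078728
call     = sensitive-predicted
```

The integer features (HRD, MHID, CN_load, DUP_1_100KB, SNV_load,
NEOANTIGENS) equal the generator's planted truth exactly; the AC exposures
are NNLS estimates and carry sampling noise.  Evaluating the published
validation-cohort confusion counts (10 of 11 resistant and 1 of 31
sensitive patients above threshold):

```python
from drdscore import confusion_stats
truth = ["resistant"] * 11 + ["sensitive"] * 31
pred = ["resistant"] * 10 + ["sensitive"] + ["resistant"] + ["sensitive"] * 30
print(confusion_stats(pred, truth).summary())
```

```
Evaluation (positive class: resistant)
  n = 42  (resistant 11, sensitive 31)
  confusion: TP=10 FN=1 FP=1 TN=30
  sensitivity: 90.91% (95% CI, 58.72%-99.77%)
  specificity: 96.77% (95% CI, 83.30%-99.92%)
  accuracy: 95.24% (95% CI, 83.84%-99.42%)
```

A `drd` console script wraps the same steps
(`drd simulate / scar / features / score / evaluate`); see `drd --help`.

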