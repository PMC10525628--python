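# ctrval

Validation toolkit for automatic cardiothoracic-ratio (CTR) measurement.

Automatic CTR readers segment the lungs and heart on a frontal chest
radiograph and report

    CTR = (MLD + MRD) / GT,

the maximum horizontal reach of the cardiac silhouette left (MLD) and
right (MRD) of the body midline over the greatest transverse diameter of
the thoracic cavity (GT), with cardiomegaly defined as CTR > 0.50.
Before such a reader can be used clinically it must be validated the way
reading studies validate human observers: agreement with expert
radiologists on the continuous measurement, and a multi-reader test of
the binary diagnosis against a defensible reference standard.  `ctrval`
implements that whole pipeline for biostatisticians and imaging
researchers running (or planning) such studies:

* **`ctrval.geometry`** — MLD/MRD/GT/CTR from binary lung/heart masks
  (8-bit PNG pairs), with an exhaustively verified per-row measurement
  convention;
* **`ctrval.agreement`** — Bland–Altman mean differences and 95% limits
  of agreement with parametric or bootstrap CIs, MAE/RMSE, ICC(2,1) with
  F-based CIs, and a paired case-bootstrap comparison of two ICCs;
* **`ctrval.consensus`** — binary reference standards: two-class
  Dawid–Skene EM fusion of expert label sets at a CTR cutoff, and the
  per-case median reference;
* **`ctrval.reader_test`** — sensitivity/specificity/PPV/NPV/accuracy
  with Wilson CIs, decision-level pooling of multiple readers, and a
  one-sided cluster-bootstrap non-inferiority test at a 10-point margin;
* **`ctrval.design`** — minimum sample size for a Bland–Altman agreement
  study by exact chi–normal integration, with a Monte-Carlo cross-check;
* **`ctrval.synth`** — a calibrated synthetic-study generator (160 cases
  in four pathology strata, 2 experts x 2 sessions, 5 readers, 1 model)
  so the full pipeline runs and is testable without patient data;
* **`ctrval.pipeline` / the `ctrval` CLI** — end-to-end orchestration
  with provenance logging and report tables.

## Worked example

Generate a synthetic validation study and run the analyses (all commands
are deterministic given the seed):

```bash
ctrval simulate --seed 7 --out demo
ctrval samplesize --mu 0.00175 --sd 0.04108 --delta 0.15
ctrval agreement  --measurements demo/measurements.csv --model demo/model.csv --seed 7 --out demo/agreement.csv
ctrval readertest --measurements demo/measurements.csv --model demo/model.csv --seed 7 --out demo/readertest.csv
```

The sample-size call prints

```
minimum sample size: 23  (per-limit allocation)
  per-limit convention: n = 23; joint convention: n = 22
```

— with an expected mean difference of 0.00175, SD of differences 0.04108
and a maximum allowed difference of ±0.15, 23 paired measurements suffice
for both 95% limits of agreement to stay inside the allowed band with
95% power (the two lines are the two conventions for splitting the type
II error across the limits; see `docs/methods.md`).

The agreement step prints

```
ICC radiologists 0.972 vs model 0.975 (delta -0.004, bootstrap p = 0.186)
```

and writes the Bland–Altman table:

```
   scale   n  mean_diff  loa_lower  loa_upper    mae   rmse
absolute 160     0.0054    -0.0236     0.0345 0.0122 0.0157
relative 160     1.0206    -4.8535     6.8947 0.0122 0.0157
```

Read: the model measures CTR 0.0054 higher than the experts on average
(+1.0% on the relative scale), with 95% of disagreements between −0.024
and +0.034 CTR units, and its agreement with the radiologists
(ICC 0.975) is statistically indistinguishable from the radiologists'
agreement with each other (ICC 0.972, bootstrap p = 0.186).

The reader test (Dawid–Skene reference at cutoff 0.50, five pooled
readers, margin 10 points, one-sided 0.025) reports per metric:

```
     metric  model_value  readers_value   delta  p_noninferiority  non_inferior
sensitivity       0.9898         0.9633  0.0265            0.0005          True
specificity       0.9032         0.9452 -0.0419            0.0263         False
        ppv       0.9417         0.9652 -0.0235            0.0005          True
        npv       0.9825         0.9421  0.0403            0.0005          True
   accuracy       0.9562         0.9562  0.0000            0.0005          True
```

Read: the model is non-inferior to the pooled readers for sensitivity,
PPV, NPV and accuracy; for specificity the one-sided p (0.0263) misses
the 0.025 cutoff, so non-inferiority is not demonstrated for that metric
in this study.

`ctrval run --seed 7 --out results/` executes everything at once and
writes `table1.csv` (Bland–Altman strata), `table2.csv` (ICC grid),
`table3.csv` / `appendix.csv` (diagnostic grids at both cutoffs and both
references), per-case reference and audit files, Bland–Altman plots, and
a `provenance.json` stage log.

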