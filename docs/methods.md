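# Methods

## The decision problem

In multiple myeloma, acute kidney failure is most often caused by cast
nephropathy (CN): precipitation of monoclonal free light chains (LC) in the
renal tubules. CN is the lesion with the worst untreated prognosis and the
one for which rapid LC-lowering therapy (and possibly mechanical LC removal)
matters most, but the confirmatory test — kidney biopsy — is invasive and
often contraindicated by bleeding risk. The package implements and validates
a non-invasive rule built on the quotient

    Q = involved LC in urine (mg/dL) / eGFR (mL/min/1.73 m²)

CN combines unusually severe filtration loss with unusually heavy urinary LC
excretion, so Q separates CN from the other paraprotein-associated kidney
diseases (AL amyloidosis, monoclonal Ig deposition disease, LC proximal
tubulopathy, and paraprotein-independent lesions).

## The rule

With the involved (monoclonal) LC isotype known:

* **lambda LC:** positive iff `Q > 2`;
* **kappa LC:** positive iff `Q > 5`, or `1 < Q <= 5` and 24-h proteinuria
  `< 8000 mg`.

All comparisons are strict. The kappa branch has two equivalent published
wordings ("Q in 1–5 with low proteinuria, or Q > 5" vs "Q > 1 with low
proteinuria, or Q > 5"); under the strict-inequality convention with the
interval realized as `(1, 5]` they are logically identical, which the test
suite verifies on an exhaustive boundary grid. A kappa patient whose quotient
falls inside `(1, 5]` without a recorded 24-h proteinuria is *unclassifiable*
and is excluded with a logged reason, never coerced. The quotient is
undefined at eGFR ≤ 0 (anuria); such patients need a biopsy and the code
raises rather than guessing. Cut points are configuration
(`RuleThresholds`), not constants, so threshold sensitivity analyses are
possible; the defaults are the published limits.

## Renal function

eGFR comes from the CKD-EPI serum-creatinine equation. The source analysis
names "the CKD-EPI formula" without a version; we default to the 2009
equation with race factor 1.0 (standard European laboratory practice during
the study window, 2019–2023) and expose the 2021 race-free refit via
configuration — the choice shifts eGFR by a few percent and can move
borderline quotients, which is why the version is echoed in every report.
Because each branch of the equation is a pure power law, the inverse
(creatinine from eGFR) is closed-form and exact; the generator uses it so
every synthetic patient carries a creatinine consistent with its sampled
eGFR, and the forward∘inverse identity is tested to 1e-8 relative on a grid.

## Diagnostic accuracy

Sensitivity, specificity, PPV and NPV are the defining ratios of the 2×2
table of rule call vs biopsy diagnosis. Design choices:

* **Confidence intervals:** Clopper–Pearson exact at 95% by default. The
  original report prints none; exact intervals are the conservative standard
  at these denominators (18–49) and are clearly an extension of ours.
* **Undefined metrics:** a zero denominator (e.g. PPV with no positive
  calls) is reported as not-available, never as 0 or 1.
* **ROC:** computed on the raw quotient with higher-is-diseased orientation.
  Ties are grouped at one operating point and the trapezoidal AUC then equals
  the Mann–Whitney concordance with ½ credit for ties (property-tested
  against exhaustive pair counting). The kappa stratum's compound rule
  (quotient plus proteinuria) is not a pure threshold of the score, so it is
  evaluated as a point estimate, not forced onto the single-score ROC.
* **Stratification:** all / kappa / lambda; the overall table is by
  construction the cell-wise sum of the strata.

## Group comparisons

Per-group (CN / ALA / MIDD / Others) summaries are median (IQR) with
quartiles by linear interpolation between order statistics (numpy default,
"type 7") — fixed explicitly because the same convention calibrates the
generator. The omnibus test across the four groups is Kruskal–Wallis on
mid-ranks with tie correction; significant variables are followed by Dunn's
post hoc z tests (pooled mid-ranks, tie-corrected standard error, two-sided
normal p) with Benjamini–Hochberg adjustment *within one variable* (6 pairs),
matching how the original per-variable tables are reported. Two-sample mean
comparisons (e.g. CN vs all other kidney disease on creatinine) use Welch's
t-test — group variances are conspicuously unequal — with the pooled variant
retained because it underlies the classical `t² = F` identity used as an
internal cross-check. Sidedness of Dunn p-values (two-sided) and the
adjustment family are our choices where the source is silent.

## Synthetic cohorts

The validation study's raw data are available only on request, so all
testing runs on simulated cohorts that reproduce its *marginal* structure:

* group sizes 18 (CN), 13 (ALA), 3 (MIDD), 33 (Others);
* kappa fraction 11/18 within CN and 27/49 in the pooled non-CN groups (the
  per-group non-CN composition was not reported, so all three share the
  pooled value);
* sex ratio 24 F / 43 M; age median 72 within range 38–90, drawn from a
  triangular distribution whose mode is solved so the median lands exactly,
  rounded to whole years;
* eGFR, involved serum FLC and involved urine LC per group as log-normals.
  Log-normality is the natural family here: all variables are positive and
  right-skewed (reported group means sit far above medians). Given a target
  median m and IQR, the log-scale sigma has the closed form
  `sigma = asinh(IQR / 2m) / z_0.75`, the unique non-negative solution of
  `IQR = 2 m sinh(z_0.75 sigma)`; a plug-back oracle verifies it to 1e-9.
* proteinuria as a log-normal matched to the reported group *means* (CN
  3929, other kidney disease 2565 mg/24 h) with log-sigma 1.0 — no spread
  was published, making this the weakest-calibrated variable;
* serum creatinine back-filled through the exact CKD-EPI inverse.

Variables are independent within a patient by default; no joint statistics
were published, so the `log_corr_egfr_urine` hook (a log-scale Gaussian
copula between eGFR and urine LC) is labelled extrapolation and off by
default. A cohort is a pure function of (spec, seed).

**What the generator does and does not emulate.** It reproduces per-group
marginals, not the joint distribution of a real cohort: the per-patient
quotient median it implies is the ratio of medians (e.g. 171.5/7.5 ≈ 22.9
for CN), which need not equal — and here does not equal — the reported
median of per-patient quotients (33.1), since median(X/Y) ≠
median(X)/median(Y) for dependent or even independent X, Y. Consequently
synthetic accuracy is *not* expected to reproduce the observed 85.7%
specificity exactly; only conservative behavioural bounds are asserted
(sensitivity ≥ 0.90 over 10⁴ CN draws, specificity ≥ 0.70 over 10⁴ non-CN
draws), and the exact replication of the reported metrics goes through the
observed 2×2 counts instead. Passing tests therefore demonstrate correctness
of the machinery and plausibility of the calibration, not clinical
performance on new patients.

The MIDD group deserves a caveat: its published IQRs derive from three
patients, and the serum-FLC row (median 95.5, IQR 1124.6) implies a
log-sigma ≈ 3.7. The calibration uses these values as printed, but MIDD is
excluded from the tight (2%) large-n recovery checks because the sample-IQR
standard error at such sigmas exceeds the band even at 10⁵ draws; it remains
in the group-ordering check (median quotient CN > MIDD > ALA ≥ Others).

## Numerical and I/O conventions

* Cohorts are delimited text (comma default, tab accepted) with a fixed
  header vocabulary; decimal points mandatory. Floats are written with
  `repr` and parsed with round-trip precision, so write→read is the exact
  identity. Provenance (observed/synthetic) and the generator seed travel in
  `#` comment header lines.
* A row with creatinine but no eGFR is completed through the CKD-EPI forward
  map (idempotent). When both are present they must agree within 5%
  relative; strict mode errors on conflict, lenient mode keeps the supplied
  eGFR (the analysis-bearing quantity) and logs.
* Free-text histology is normalized case-insensitively against a synonym
  table (e.g. "LCDD" → MIDD); unmatched text folds into `other` with the
  subtype retained.
* Reported-precision rounding (3 decimals; one decimal on percentages) is a
  presentation layer only — stored values are full precision.

## Problem sizes used in checks

Statistical checks run at sizes chosen to make their tolerances meaningful:
calibration recovery at 10⁵ draws per group (2% band), rule bounds at 10⁴
patients per arm, Kruskal–Wallis null calibration at 2,000 replicates of
4×15, oracle equivalences at a few hundred random small instances each.

## Known limitations

* Single time point (at biopsy); no longitudinal modelling.
* The generator cannot reproduce within-patient dependence between labs, and
  its proteinuria calibration is mean-only.
* No alternative non-invasive comparator (urinary albumin fraction) beyond
  the scope note; no DeLong AUC comparisons or decision-curve analysis.
* The quotient is undefined in anuria, and the rule's false positives
  concentrate in LC proximal tubulopathy — both inherited from the method
  itself, not artifacts of this implementation.
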