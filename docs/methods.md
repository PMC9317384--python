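# Methods

`ocadx` implements the analysis chain used to diagnose ultra-mild
oculocutaneous albinism (OCA) in patients whose only overt sign is foveal
hypoplasia with mildly reduced acuity: electrophysiological demonstration
of optic-pathway misrouting from monocular pattern-onset VEPs, trio-based
prioritization and cis/trans phasing of TYR variants (in particular the
hypomorphic haplotype p.[Ser192Tyr;Arg402Gln] in trans with a pathogenic
variant), microsatellite haplo-identity of sibling pairs, and the Kruijt
major/minor clinical criteria.  This note records the models, the
parameters that matter, and the design choices made where the published
procedure left them open.

## VEP misrouting analysis

### Signal model and simulator

In albinism, temporal retinal fibres decussate abnormally at the chiasm,
so a monocularly stimulated eye drives the contralateral occipital cortex
more strongly than the ipsilateral one.  The simulator encodes exactly
this: for eye *e* ∈ {OS, OD} and hemisphere *h* ∈ {left, right}, the mean
stimulus-locked response on every electrode of hemisphere *h* is

    μ(e, h, t) = A · w(e, h) · k(t)

with evoked amplitude *A* (default 5 µV at the kernel peak) and weights
`w(contralateral) = (1 + a)/2`, `w(ipsilateral) = (1 − a)/2` under
misrouting (lateralization index *a* ∈ [0, 1], default 0.5, laterality
flipping between eyes), and `w = 1/2` everywhere under normal routing.
The total interhemispheric signal energy is thus independent of *a*; only
its lateralization changes.

The evoked kernel `k(t)` is a difference of two gamma-shaped lobes, the
standard parametric morphology for transient evoked responses: a positive
lobe normalized to peak 1 at the pattern-onset latency (default 100 ms)
minus an undershoot of relative amplitude 0.35 peaking at 185 ms.  Each
lobe is `(t/τ)^p · exp(p(1 − t/τ))`, causal and identically zero for
t ≤ 0, so the pre-stimulus baseline is exactly flat in the noise-free
limit.  The composite peak sits a few milliseconds before the nominal
positive-lobe latency because the undershoot's rising edge overlaps it.
All shape parameters are exposed (`KernelShape`); the closed form makes
the windowed-mean oracle in the acceptance suite exact.

Noise is additive, independent across trials and channels: Gaussian
white, or the default 1/f + white mixture (half the variance spectrally
shaped to a 1/f power spectrum, analytic variance normalization, no
realisation-dependent scaling).  The per-trial, per-channel standard
deviation defaults to 20 µV — with ~498 trials and 9 electrodes per side
this puts the trial-averaged differential signal at a signal-to-noise
ratio of ≈ 5.9, a realistic regime for a cooperative pediatric recording
session.  Trial counts are drawn per eye from N(498, 51²), rounded and
floored at 1, mirroring the acquisition protocol (40 ms ON / 440 ms OFF
pattern-onset cycle at 500 Hz sampling; when rendering continuous
records, onsets are spaced 480 ms apart, wide enough that consecutive
responses do not overlap the analysis windows).

A single seed drives one `SeedSequence` per cohort, with per-subject
substreams, so cohorts are bit-reproducible.  For Monte-Carlo evaluation
the simulator offers `trial_mode="average"`: the trial count *n* is drawn
exactly as usual, but the stack holds the trial average directly, with
noise drawn at sd/√n.  Because both noise models are Gaussian and
averaging is linear, this is the exact sampling distribution of the mean
at a small fraction of the cost; per-trial simulation remains the default
and is what the unit and oracle tests exercise.

What the simulator does *not* emulate: volume conduction/head geometry
(electrodes are 9 synthetic left labels OL1–OL9 and 9 right OR1–OR9, not
the study's 128-channel net), ocular or movement artifacts, latency
jitter across trials, and between-subject variability in kernel shape.
Passing tests therefore demonstrate the correctness and operating
characteristics of the *analysis*, not the realism of any single EEG
record.

### Preprocessing

Continuous records are high-pass filtered at 0.1 Hz with a
Blackman-windowed sinc FIR (transition bandwidth 0.2 Hz, kernel length
⌈5.5·fs/0.2⌉ forced odd, applied as zero-phase 'same' convolution), then
epoched from −0.2 to 0.4 s around each onset under a half-open sampling
convention (`[start, end)`; 300 samples at 500 Hz; the t = 0 sample
belongs to the epoch).  Onsets whose window would overrun the record are
dropped with a warning.  Baseline correction subtracts the per-trial,
per-channel mean over [−0.05, 0] s.  The trial average is low-pass
filtered at 35 Hz with a 4th-order Butterworth applied forward-backward
(zero phase; the order was an open choice and is configurable).  Whether
the low-pass precedes or follows averaging is immaterial up to edge
effects since every stage is linear; it is applied after averaging by
default and the choice is configurable.  Re-referencing (none / CZ /
common average) is offered but irrelevant downstream: the differential
activity is invariant to any common reference, which the invariant suite
checks.

### Misrouting indexes

With a left set OL and right set OR of occipital electrodes, the
differential activity of eye *e* is `D_e(t) = mean_OL(t) − mean_OR(t)`.
Two indexes summarize the interocular asymmetry:

* **chiasm coefficient** `CC = mean_[0.07,0.1s] D_OS − mean_[0.07,0.1s] D_OD`
  (µV).  Under the simulator contract `D_OS = −aA·k`, `D_OD = +aA·k`, so
  `CC = −2aA·k̄` — negative exactly when the contralateral hemisphere
  dominates.  The eye-difference form makes the group-level paired t-test
  on (mean D_OS, mean D_OD) equal a one-sample test of CC against zero,
  and the coefficient flips sign exactly under either an eye-label swap
  or a montage swap.  A normalized-product variant of the coefficient was
  considered and rejected: it loses the µV scale and the paired-t
  equivalence.
* **interocular correlation**: Pearson r between `D_OS(t)` and `D_OD(t)`
  across the samples in [0.07, 0.3] s; misrouting drives it negative.

Analysis windows are closed intervals sampled at the native rate with a
half-sample tolerance, so the sample at exactly 0.07 s belongs to both
windows.

Significance of r: band-limited EEG samples are strongly autocorrelated
(the 35 Hz low-pass alone leaves ≈ 2–3 effectively independent samples
per 30 ms), so a t-test with the naive n − 2 degrees of freedom is
anti-conservative — on simulated normal-routing cohorts it flags ~13 % of
subjects instead of the nominal ≤ 5 %.  The default p-value therefore
uses the Bartlett effective sample size,
`n_eff = n / (1 + 2·Σ_k (1 − k/n)·ρ_x(k)·ρ_y(k))` estimated from sample
autocorrelations up to lag n/3 and clipped to [3, n], with df =
n_eff − 2.  This brings the false-positive rate to ≈ 2 % while leaving
detection of genuinely misrouted subjects essentially unchanged
(r ≈ −0.9 survives any reasonable df).  The textbook sample-wise p is
available via `autocorr_correction=False` and is the form checked against
the direct-formula oracle in the tests.

A subject is classified **misrouted** iff r < 0, p ≤ α (default 0.05,
two-tailed, no multiple-testing correction across subjects) and CC < 0.
If either differential trace has zero variance in the correlation window
the correlation is undefined and the classification is *indeterminate* —
never silently "not misrouted".  Group inference is a two-tailed paired
t-test of the per-subject windowed means (df = n − 1; a cohort of eight
reports t(7)).

Operating characteristics, recomputed by `scripts/acceptance.py` on 200
cohorts of 8 subjects each (trial-averaged mode, default conditions):
≥ 99 % of misrouted subjects detected, 100 % of misrouted cohorts
rejected by the group test at α = 0.001, ~1–2 % false positives on
normal-routing cohorts.

## Variant prioritization and phasing

### Retention cascade

A variant survives filtering iff all of:

1. consequence in {missense, frameshift, inframe indel, nonsense,
   synonymous, splice-site ±20 bp, start loss};
2. gene on the foveal-hypoplasia panel (shipped as editable TSV:
   TYR/OCA2/TYRP1/SLC45A2/SLC38A8/DCT autosomal-recessive, PAX6
   autosomal-dominant, GPR143 X-linked);
3. maximum minor-allele frequency across the four population sources
   (1000 Genomes, EVS, dbSNP, in-house cohort) ≤ 0.01 for AR genes and
   ≤ 0.001 for AD genes.  The maximum (strictest) aggregation was chosen
   over per-source testing and is configurable; X-linked genes use the AR
   ceiling (recessive in hemizygous males).  A MAF missing from a source
   means "absent from that database" and counts as 0, with an audit note;
4. zero homozygotes/hemizygotes in gnomAD;
5. known pathogenic in ClinVar/HGMD **or** called damaging by ≥ 3 of the
   6 predictors (PolyPhen-2, SIFT, MutationTaster, MutationAssessor,
   FATHMM, FATHMM-MKL); synonymous and splice-site variants additionally
   require a damaging splice prediction;
6. ACMG class P, LP or VUS (the class is consumed as an input column —
   ACMG criterion evaluation is out of scope, as are variant calling and
   CNV detection).

The two common TYR polymorphisms Ser192Tyr (MAF ≈ 25 %) and Arg402Gln
(≈ 18 %) would fail rules 3–6 yet are exactly what the diagnosis hinges
on; they are always retained and tagged `manual-inspection`, bypassing
rules 3–6.  Every decision carries a per-variant audit record, and
tightening any MAF ceiling can only shrink the retained set (override
excepted) — a property test.

### Segregation phasing

For each proband-carried variant the phaser enumerates the transmissions
compatible with the trio genotypes: a parent can transmit the alternate
allele iff Het or Hom, and *must* iff Hom.  Hom proband variants sit on
both alleles; a Het variant is resolved to one parental allele when
exactly one origin is compatible — which covers both the textbook case
(other parent WT) and the obligate-transmitter case (one parent Hom, so
the other parent necessarily contributed the reference allele).  When
both origins remain possible the variant is phase-ambiguous.  This
per-variant rule is provably equivalent to brute-force enumeration of all
allele assignments, and the test suite checks that equivalence on 1,000
random Mendelian-consistent trios.  Mendelian-inconsistent trios raise an
error naming the variant: the pipeline's logic is segregation-based, so
de novo variants are surfaced rather than phased.

An affected parent without genotyped grandparents can still be phased by
*reverse segregation* through their child: once the child's trio is
resolved, the allele the parent transmitted is known in full, and the
parent's second allele follows from their own genotypes (Hom → both
alleles, Het → the untransmitted allele).  This is the cascade-diagnosis
path used when a proband's affected father enters the cohort.

### Diagnostic classification

With pathogenic set P and hypomorphic pair H = {Ser192Tyr, Arg402Gln}:

* `biallelic_pathogenic` — each allele carries ≥ 1 variant from P;
* `pathogenic_trans_hypomorphic` — one allele carries a variant from P
  and the *other* carries both members of H;
* `carrier_only` — at least one "disease allele" (a variant from P, or
  the complete pair H in cis) but no diagnostic configuration.  Lone
  polymorphisms — even both of them in trans — do not make a carrier;
* `none` — nothing of the above.

Unresolved phase is handled by enumerating every placement of the
ambiguous variants.  If all placements agree, that class is reported; if
they disagree on whether a molecular diagnosis exists at all, the
classification is `ambiguous_requires_haplotyping`; if every placement is
diagnostic but the mechanism differs, the less specific
`pathogenic_trans_hypomorphic` is reported.  The classifier is symmetric
under swapping the parental labels (property-tested).

## Microsatellite haplo-identity

Nine STR markers flanking TYR (a ~4.5 Mb interval on 11q14) are treated
as one non-recombinant linkage block — with < 5 cM expected across the
interval the no-recombination assumption is the same one the original
sibling analysis makes, and it is the module's main documented
limitation.  At each marker the child's unordered genotype is decomposed
into one paternal plus one maternal allele; a unique value decomposition
is *resolved*, several are *ambiguous*, none is *inconsistent*
(non-Mendelian, excluded from the verdict and reported).  A marker is
*concordant* when both parents are heterozygous and both siblings
resolved to the same transmitted value for each parent, *discordant* when
resolved transmissions differ.  Verdict: any discordant marker ⇒
`non_identical`; otherwise ≥ 1 concordant ⇒ `identical`; otherwise
`uninformative`.  Swapping the siblings never changes the verdict.

Haplo-identity feeds back into phasing: when two affected siblings are
haplo-identical across the block *and* share the proband's genotype
configuration, an ambiguous member of the hypomorphic pair must travel
with the shared parental haplotype, so it is placed in cis with the
already-resolved other member, on the allele opposite the pathogenic
variant.  The module reports genetic evidence only; combining it with
phenotype concordance is left to the reporting layer, which is where the
clinical argument belongs.

The packaged STR table for the sister pair is a **synthetic stand-in**
(the original fragment sizes are not public): allele sizes were chosen so
that 8 of 9 markers are fully informative and the sisters are
haplo-identical, the published verdict for that family.

## Kruijt criteria and cohort summary

Major criteria: foveal hypoplasia of Thomas grade ≥ 2; misrouting; ocular
hypopigmentation.  The published restatement of the third criterion is
ambiguous; it is implemented as *iris transillumination OR fundus
hypopigmentation grade ≥ 2* (the OR-reading), which is a design decision,
not a quotation of the original grading scheme — the original iris-grade
and hair-colorimetry instruments are not reproduced.  Minor criteria:
nystagmus, skin/hair hypopigmentation (a boolean input; the source data
report it qualitatively), fundus grade exactly 1, foveal hypoplasia grade
exactly 1.  Clinical diagnosis: ≥ 3 major, or ≥ 2 major and ≥ 2 minor.
With a molecular diagnosis: ≥ 1 major or ≥ 2 minor.  The with-molecular
verdict never falls below the clinical one, and adding any criterion
never revokes a diagnosis (both property-tested).  In the integrated
dossier, `has_molecular_dx` is true exactly when the genotype
classification is `biallelic_pathogenic` or
`pathogenic_trans_hypomorphic`.

Cohort summaries pool both eyes for the mean BCVA (16 values for eight
patients) and also report the per-patient-mean variant; on the packaged
table both equal 0.20 LogMAR.  The mean age reported is the one the table
implies (16.5 y); the source publication prints 16.3 y for the same
eight ages, a discrepancy the summary does not attempt to reconcile.

## Numerical and interface choices

* Half-open epochs `[start, end)`; closed analysis windows with a
  half-sample tolerance; 300 samples per epoch at 500 Hz.
* Zero-phase filtering everywhere (symmetric-FIR 'same' convolution for
  the high-pass; `sosfiltfilt` for the Butterworth low-pass); filters
  validated against their designed frequency responses, not against
  hard-coded outputs.
* Degenerate inputs are flagged, not coerced: zero-variance correlation →
  indeterminate; missing phenotype field → "unassessable" naming the
  field; Mendelian inconsistency → error naming the variant; per-family
  failures never abort a cohort run.
* Genotypes are coded WT/Het/Hom; X-linked hemizygous males are encoded
  Hom.
* File formats: VCF v4.2 + 6-column PED (pysam), TSV tables (pandas),
  montage YAML, epoch stacks as `.npz` + JSON sidecar.  EDF is read
  through mne (optional `edf` extra); EDF export is not provided.
  Every writer round-trips through its reader (tested).
* Monte-Carlo problem sizes: 200 replicate cohorts × 8 subjects per
  routing condition, trial-averaged simulation mode; oracle equivalence
  on 1,000 random trios and 300 further trios in the unit suite.

## Known limitations

* The simulator's electrode model is two labelled pools, not a head
  model; topographic analyses are out of scope.
* Artifact handling (ASR, line-noise removal, bad-channel interpolation)
  is not re-implemented; the preprocessing accepts pre-cleaned data.
* The Bartlett correction assumes weak stationarity within the analysis
  window; heavy non-stationarity would call for a block-resampling test
  instead.
* The STR module handles exactly two siblings and no recombination;
  larger sibships or recombination-aware phasing are not supported.
* The in-house control-cohort comparison (absence of the
  pathogenic + haplotype combination among controls) depends on private
  data; only the query logic exists here.
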