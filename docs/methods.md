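# Methods

## The measurement model

An indel marker assay amplifies a presence allele that a diploid
genotype carries in 0, 1 or 2 copies; the readout is a quantification
cycle Cq, with one cycle corresponding to a factor (1+E) of starting
template (E = amplification efficiency increment).  Because absolute Cq
depends on input mass and instrument, all inference is on differences:

* ΔCq = Cq(marker) − Cq(reference assay) within one sample, where the
  reference targets an invariant locus present in two copies in every
  human genome;
* ΔΔCq = ΔCq(post-transplant) − ΔCq(pre-transplant recipient), the
  pre-transplant sample acting as the 100%-recipient calibrator;
* percent recipient chimerism = 100 · (1+E)^(−ΔΔCq).

With E = 1 (perfect doubling, the default) one ΔΔCq cycle halves the
estimate.  Estimates above 100% (negative ΔΔCq) are clipped to 100 and
flagged rather than renormalised, since only the recipient fraction is
reported.  Zygosity cancels between pre and post as long as it is the
same in both samples, which is why the assay need not distinguish
heterozygous from homozygous carriers; this cancellation is exact in
the model and is asserted by test.

## Typing calls

A subject's marker is called from the mean Cq of its amplified
replicate wells (per-replicate voting is not used):

* no amplification in any replicate → **negative**;
* mean raw Cq outside the assay's preset window (default 15–38 cycles)
  → **atypical** (possible non-specific amplification, excluded);
* otherwise by ΔCq against the reference: ≤ `positive_dcq_max`
  (default 3 cycles) → **positive**; ≥ `negative_dcq_min` (default 6)
  → **negative**; the open band between → **atypical**.

The three thresholds are per-assay configurable; the kit vendor's
preset values are not public, so the defaults encode the trichotomy
with a 3-cycle ambiguous band.  A sample whose reference assay never
amplifies raises a QC error — it is an invalid sample, not a negative
marker.  Whether the kit's positivity rule uses ΔCq or an absolute Cq
cutoff is not documented; the ΔCq-band reading is this package's
choice.

A marker is *recipient-specific* when positive in the recipient and
negative in the donor (the monitoring direction), *donor-specific* for
the converse, *non-informative* when concordant, *indeterminate* when
either call is atypical.  Indeterminate markers are excluded from
informativity counts and from set-cover coverage.

## Marker-subset selection

`select_covering_markers` does greedy max-coverage: repeatedly add the
marker that is recipient-specific for the most yet-uncovered pairs,
ties broken lexicographically for determinism.  Greedy is exactly
optimal for k = 1 and carries the standard (1 − 1/e) guarantee for
larger k; it is *not* always equal to the exhaustive optimum (the usual
max-coverage counterexamples apply), so the tests assert the guarantee,
not equality, against a brute-force oracle on small instances.

## The synthetic-data generator

Genotypes: unrelated subjects draw copies ~ Binomial(2, q) per marker
(Hardy–Weinberg) with q the population presence-allele frequency;
sibling pairs draw two parents under HWE and transmit one allele from
each parent per child; parent/child pairs fix the donor as the parent
and give the child one parental plus one population allele.  The
shipped 39-marker panel uses a uniform placeholder q = 0.25 because the
real per-marker frequencies are unpublished; every frequency is
user-overridable.  Under this placeholder the per-marker
recipient-specific probability for unrelated pairs is
(1−(1−q)²)(1−q)² ≈ 0.246, so a 39-marker screen misses a pair with
probability ≈ 1.6 × 10⁻⁵ — consistent with full-cohort informativity.

qPCR wells: a well loaded with m ng DNA contains
N_g = ⌊1000·m / 6.6⌋ diploid genomes (6.6 pg per diploid genome; 10 ng
→ 1515).  For a mixture with recipient fraction f, the marker template
rate is λ = N_g · [f·z_recipient + (1−f)·z_donor] · p_det and the
reference rate λ_ref = N_g · 2 · p_det, with z the copy number and
p_det a per-copy detection/usability probability thinning the Poisson
rate.  Detected copies k ~ Poisson(λ); k = 0 is a non-amplified well;
otherwise Cq = c0 − log(k)/log(1+E) + N(0, σ).  λ is linear in f, so
mixing f recipient is exactly mixing (1−f) donor.

Defaults and their rationale:

| parameter | default | meaning |
|---|---|---|
| `c0` | 38 cycles | Cq of a single detected copy; typical single-template qPCR, only Cq differences matter downstream |
| `efficiency_increment` | 1 | perfect doubling per cycle |
| `cq_noise_sd` | 0.15 cycles | Gaussian jitter per well |
| `p_det` | 0.7 | per-copy detection probability |
| `genome_mass_pg` | 6.6 | pg per diploid genome |

`p_det` and `cq_noise_sd` are calibrated so a 10 ng titration shows
roughly 50% well dropout at ≤ 0.2% recipient DNA (0% wells included)
and near-universal amplification at ≥ 0.3%; both are explicit
parameters, never hard-coded in analysis code.  A `deterministic`
switch replaces the Poisson draw by k := λ exactly so closed-form
identities (e.g. exact recovery of f, ΔCq = 1 for a pure heterozygous
recipient) hold to floating point.

What the generator does *not* model: multiplex competition between
primers, PCR inhibitors, plate-position effects, inter-run drift and
real amplification-curve chemistry.  Passing tests therefore establish
the correctness of the analysis pipeline and the statistical behaviour
of Poisson-limited detection, not the performance of any particular
instrument or kit on clinical material.

## The virtual-mixture validation study

The titration twin simulates recipient DNA titrated into donor DNA over
seven recipient-specific markers (recipient heterozygous, donor
non-carrier), one mixture sample per (level × marker), each with its
own pure-recipient calibrator.  Every sample is measured in **three
replicate aliquots** aggregated by mean Cq — the standard qPCR
triplicate; a within-sample CV across aliquots is only defined with at
least two, and replicate aggregation on the Cq scale is robust to
single-well dropout.  Study sizes: the high range uses levels
1/5/10/20/40/60/80/100% (56 samples), the low range 0.1–0.9% in 0.1%
steps (63 samples) with its correlation averaged over 20 seeds because
single-seed r is dominated by Poisson sampling of a handful of template
copies.  The dropout study allocates 16 single wells as 6/5/5 across
the 0/0.1/0.2% levels (the published design states only the 16-well
total); with λ = 1515·f·0.7 the expected dropout count is 8.3/16.  The
limit-of-detection study runs one 7-marker sample per level from 0.3 to
0.9% and reports the lowest level from which every sample (100 seeded
repetitions) is detected by at least one marker well; at 0.3%,
P(all seven wells empty) = e^(−7·3.18) ≈ 2 × 10⁻¹⁰.

A noise decomposition of the high-range correlation under these
defaults: the ΔΔCq chain touches four mean Cq values, so its Gaussian
standard deviation is 2σ/√3 ≈ 0.17 cycles, a ≈ 12% multiplicative
error on the estimate, which puts the expected high-range r near 0.99
with residual seed-to-seed spread of a few thousandths.

## Numerical and interface choices

* Cq values are carried at full precision; `repr`-based CSV round-trips
  are lossless.  An empty Cq cell canonically encodes no amplification;
  "Undetermined" and "NA" are normalised on input.
* Replicates are explicit by column, never inferred from row order.
* The percent scale is [0, 100] with statuses (NOT_DETECTED, atypical)
  carried separately from values, so dropout handling is explicit in
  every downstream statistic (correlations exclude non-values).
* Bland–Altman limits use mean ± 2·SD (sample SD, n−1), not ±1.96.
* The two-group comparison of informativity counts is Mann–Whitney U
  with the tie-corrected normal approximation; p-values are reported
  but nothing in the package branches on them.
* CV is reported unitless (SD/mean over per-marker percents).
* Single RNG stream per run, split deterministically per study in the
  acceptance script; identical seeds reproduce plates bit for bit.

## Known limitations

* Placeholder allele frequencies make cohort-level informativity counts
  realistic in structure but not numerically faithful to any specific
  population.
* Zygosity correction beyond pre/post cancellation is not modelled
  (hom/het indistinguishability is inherent to presence/absence qPCR).
* Donor-specific markers are classified but not used to quantify
  recipient chimerism by complement; only the recipient-specific
  direction is quantified.
* A single-copy well sits at the upper edge of the default Cq window
  (c0 = 38 against a 15–38 window), so borderline one-copy wells can be
  excluded as atypical under noise — mirroring how very late Cq values
  are treated in practice, but worth remembering when tightening
  windows.
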