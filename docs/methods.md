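# Methods

This note documents the models implemented in `omicounts`, the
assumptions they make, the defaults of the synthetic data generator, and
the design choices taken where the problem is genuinely open.

## 1. Absolute transcript quantification (`omicounts.mt`)

**Model.**  Sequencing reads are assumed proportional to the nucleotide
mass of their template.  With an internal standard of `I_M` molecules
and length `I_Nt` nt drawing `I_R` reads, and `ΣT_R` transcriptome-mapped
reads, the starting transcriptome size is

    ΣT_Nt = I_M · I_Nt · ΣT_R / I_R   [nt]

and per-feature molecule counts follow from RPKM
(`RPKM_i = reads_i · 10⁹ / (length_i · ΣT_R)`):

    T_M,i = RPKM_i / 10⁹ · ΣT_Nt .

These two equations satisfy an exact algebraic identity,
`Σ_i T_M,i · length_i = ΣT_Nt`, which the test suite asserts to 1e-9
relative tolerance on random tables — any implementation change that
breaks nucleotide conservation is caught immediately.

**Assumptions and choices.**
* The RPKM denominator contains transcriptome-mapped reads only; spike-in
  (and, in real data, rRNA) reads are excluded.
* One spike-in species per sample; `I_R` is pooled.
* ORF-group length is the mean of member lengths.  Groups are formed at
  100 % sequence identity, so members share their length and the mean is
  exact; the choice only matters if a caller supplies inconsistent groups.
* Counts are measured in the extraction aliquot and multiplied by the
  aliquot factor (default 10: a 6 ml aliquot of a 60 ml sample) to give
  molecules per sample.
* Externally estimated abundances (e.g. posterior means from a
  probabilistic mapper) can be supplied through `quantify_mt`'s
  `rpkm_column` argument; the built-in path computes plain RPKM.

**Failure modes.**  `I_R = 0` is a hard error (the calibration is
undefined), as is a zero read total for RPKM.

## 2. Absolute protein quantification (`omicounts.mp`)

**Model.**  The total protein approach assumes LFQ intensity is
proportional to the protein's injected mass.  Mass fractions
`LFQ_i / ΣLFQ` are converted to molar fractions by molecular weight and
anchored to grams by the *detected protein mass*:

    detected_mass = total_mass · Σ_id (BPI_i · Mass_i) / Σ_all (BPI_j · Mass_j)

where `total_mass` is Bradford concentration × sample volume and the
sums run over identified vs all MS peaks.  Copy numbers are

    copy_i = (LFQ_i / ΣLFQ) / MW_i · detected_mass · N_A .

The detected-mass correction acknowledges that in a community the
reference proteome is incomplete: only the identified share of the
injected mass should be distributed over quantified proteins.  A direct
consequence — asserted as the *mass closure* invariant — is
`Σ copy_i · MW_i / N_A = detected_mass` exactly.

**Assumptions and choices.**
* Molecular weights use average (not monoisotopic) residue masses with
  one water term; no post-translational mass shifts.  Ambiguous residues
  B and Z take the mean of their candidate masses, X counts 110.0 Da;
  a `strict` policy that rejects them is available.  The table is
  cross-checked against an independent implementation in the tests.
* ORF-group MW is the mean of member MWs (members are near-identical).
* Fractions are computed over detected (LFQ > 0) entries; undetected
  proteins get copy number 0, not missing.
* Per-cell normalisation is omitted on purpose: a heterogeneous
  community has no meaningful single cell count.
* Reconciling an extraction aliquot to the full sample is exposed as
  `aliquot_scale` (default 1, i.e. the Bradford concentration is assumed
  aliquot-invariant and multiplied by the full sample volume).

## 3. Integration (`omicounts.integrate`)

Pipeline order: unique-hit filter → log10(x + 1) → minimum expression
thresholds → outlier-sample removal → dual-singleton pairing →
replicate averaging.

* Thresholds default to log10 ≥ 5 (MT) and ≥ 8 (MP), **inclusive** at
  the boundary.  They are applied per replicate sample, before
  averaging.
* Outlier screening defaults to a manual sample list; an automated
  assist projects standardised log-profiles onto the first two principal
  components and flags samples farther than 3 robust (MAD-scaled) SDs
  from the median centre.  At that cutoff the false-flag rate on
  homogeneous Gaussian profiles is ~1–3 % (asserted < 5 % over 200
  simulations).  The manual list is always honoured, because outlier
  calls on real experiments are usually judgement calls that must be
  reproducible.
* Only ORFs whose group is a singleton in *both* layers are paired:
  grouped features are sums over genes and cannot be compared
  gene-to-gene across layers.
* Replicates are averaged on the linear (molecules) scale — absolute
  counts are the quantity of interest; geometric (log-scale) averaging
  is available via `average_log`.

## 4. Dynamics (`omicounts.dynamics`)

* **Ratios**: per-ORF protein/RNA on replicate means, summarised per
  MAG (median, quartiles) with an optional pooled bacterial summary.
* **Gene-wise PCC**: Pearson r of log10 replicate means across time;
  series with < 3 points are skipped and counted; zero-variance series
  yield a missing value, never ±1.
* **Monomial fit**: OLS of log10(protein) on log10(RNA).  The symbol
  `a` of the power law appears as the intercept on the log scale, so
  the record stores `a_log10` and exposes `a = 10**a_log10`.  MAG × time
  cells need ≥ 30 gene pairs by default (configurable); the estimator is
  verified against closed-form normal equations to 1e-8.
* **k trajectory**: degree-3 polynomial least squares of k on time —
  flexible enough for two bends, stiff enough not to chase noise at 7
  time points.  Prediction outside the fitted time range is refused.
* **Kendall τ**: τ-b with tie correction via scipy, verified exactly
  against an O(n²) concordant/discordant pair-counting oracle for
  n ≤ 50 with and without ties.
* **Marker profiles**: summed transcript molecules over marker genes per
  pathway and time, with cubic smoothing of the log10 sums for display.

## 5. Synthetic data generator (`omicounts.simulate`)

The generator emulates the statistical structure the analysis assumes,
at desk scale, with known ground truth:

* **Community**: 7 populations by default (6 bacterial, 1 archaeal),
  500 ORFs each, 7 time points (13–43 h, 5 h steps, named t2..t8),
  triplicates A–C.  ORF lengths are lognormal with median 900 nt,
  rounded to whole codons; nt and aa sequences are consistent
  (aa = nt/3 − 1); ~4 % of ORFs are exact duplicates, producing
  multi-member ORF-groups for the collapsing/singleton logic.
* **RNA**: per-ORF log10 copies are Normal(8.0, 0.8) per population,
  plus a per-time wander (sd 0.3) and replicate noise (sd 0.3), all on
  the log10 scale.  The heavy-tailed spread and the replicate noise
  level are chosen to reproduce the multi-order-of-magnitude expression
  range and a between-replicate R² ≈ 0.85 typical of such experiments;
  totals land near 10¹²–10¹³ transcripts per sample.
* **Protein**: `protein = a(t) · RNA^k(t) · 10^N(0, mp_noise_sd)`,
  computed from the *realised* replicate RNA, so the monomial law holds
  within replicates and replicate averaging does not attenuate the
  fitted slope.  When a population specifies a `median_ratio_target`
  (10³ bacterial, 10⁴ archaeal by default), the scale constant is
  derived per time point as
  `a_log10 = log10(target) + (1 − k_t) · mean_log10_RNA`, which pins the
  median protein-to-RNA ratio at the target for any k; an explicit
  `true_a_log10` overrides this with a constant intercept.
* **Sequencing**: reads are multinomial over nucleotide mass
  (molecules × length) of the 1/10 aliquot, with the spike-in competing
  at `I_M · I_Nt` (defaults 10¹⁰ molecules × 994 nt — the standard's
  true length and dose are experiment-specific inputs, not constants).
  `read_sampling="expected"` replaces sampling with exact expectations;
  this is the mode used to demonstrate that the quantification chain
  inverts the generative model exactly.
* **Proteomics**: per-ORFG LFQ ∝ protein mass with log10 noise
  (sd 0.2); detection is Bernoulli (default 0.8).  The Bradford table
  encodes the exact total protein mass.  The peak table is constructed
  so its identified intensity×mass share equals
  `identified_peak_fraction × detected-mass share`, making the
  detected-mass correction exact by construction when the fraction is 1.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: sequence-composition biases (GC, mappability,
rRNA carry-over), protease and transmembrane-extraction biases in
proteomics, chimeric assembly artifacts, and any systematic
(non-multiplicative) measurement error.  Recovery results on synthetic
data certify the *estimators*, not the wet-lab protocol.

## 6. Numerical choices and problem sizes

* All randomness flows from one integer seed through
  `numpy.random.default_rng`; derived streams use fixed small offsets.
  Identical configuration + seed reproduces identical output bytes.
* Tabular I/O is TSV with 17-significant-digit floats (lossless round
  trip at 15 digits is asserted); every file carries a `#` provenance
  header with tool version and seed.
* Conservation identities are asserted at 1e-9 relative tolerance,
  noiseless round trips at 1e-6, oracle equivalences at 1e-8.
* The recovery studies in the test suite use 500 genes per population,
  7 time points, log10 noise 0.2 and 100 seeds for the k-recovery sweep;
  ratio-regime checks use 200 genes per population through the full
  observation chain.  These sizes give comfortable statistical margins
  (e.g. the OLS standard error of k at 500 genes and noise 0.2 is
  ≈ 0.011, versus the ±0.05 acceptance band) while keeping the whole
  suite in the tens of seconds.

## 7. Known limitations

* The spike-in model assumes the standard is affected by extraction and
  sequencing exactly like native transcripts (added before extraction,
  no degradation differential).
* The TPA inherits LFQ's proportionality assumption; saturation and
  peptide-level biases are not modelled.
* The detected-mass correction distributes identified mass over detected
  proteins; when identification is weak the per-protein copy numbers are
  conservatively low rather than re-inflated.
* The monomial law is fitted across genes within a population at a fixed
  time; it is a population-level summary, not a per-gene kinetic model.
  Translation/degradation rate estimation (change-point analysis) is out
  of scope.
* The PCA screen assumes roughly elliptical sample clouds in PC space;
  exotic batch structures need the manual list.
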