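# Methods

## The measurement model

A pulsed-SILAM experiment feeds animals a heavy-lysine diet for a labeling
window; proteins synthesized during the window carry Lys(6) (+6.0201 Da per
lysine, set as a variable modification in the upstream search). The pipeline
consumes post-search PSM tables — peptide sequence, modifications, claimed
protein accessions, spectral count, sample id — and assumes identifications
are already FDR-controlled upstream. Spectral counts are used as the
abundance proxy throughout; no MS1-intensity quantification and no
cross-run normalization is attempted (none is applied in the study design
this package models).

Every PSM receives two calls:

- **label call** — labeled iff ≥ 1 Lys(6) modification; the mass shift is
  6.0201 × (number of labeled lysines). A peptide without lysine can never
  be labeled but still counts in peptidome denominators by default.
- **specificity call** — each terminus is tryptic if it coincides with a
  trypsin cleavage site (after K/R, not before P), a protein terminus, or
  position 2 of a Met-initiated protein (Met-excision allowance). Both
  termini tryptic → fully tryptic; exactly one → semi-tryptic; none →
  non-tryptic. Peptides occurring at several positions take the call that
  maximizes specificity (ties: leftmost) and are flagged multi-mapped;
  peptides not found in any claimed protein are `unmapped`, not an error.

Shared peptides (substring of > 1 database protein) are excluded from
per-protein aggregation under the default unique-peptides-only policy
(`all_mapped` duplicates them instead); they still count in peptidome-level
statistics.

## Estimators and tests

**Labeled-proteome fraction** (per group): proteins with ≥ 1 labeled peptide
in ≥ 2 animals (the consistency rule) over all detected proteins. Per-animal
fractions and their mean ± SD are reported alongside. The labeled-peptidome
fraction uses distinct peptides (a spectral-count-weighted variant is also
emitted). Per-protein incorporation is labeled/total spectral counts
(distinct-peptide-weighted variant emitted too); cumulative frequency curves
and a two-sample Kolmogorov–Smirnov distance support group comparisons.

**Regulation**: per protein and layer, NSP (labeled) and N-NSP (unlabeled)
spectral counts are summed per animal; ratios divide counts pooled across
animals (no pseudocounts). Zero denominators are categorical: Control = 0
with LPS evidence → `exclusive_LPS` (and symmetrically), both zero →
`not_testable`. Significance is a two-sample pooled-variance (Student's)
t-test on per-animal sums (Welch available); the up/down call requires the
NSP ratio beyond 1.5-fold *and* p ≤ 0.05. The call is driven by the NSP
quantity — the newly-synthesized pool is where condition effects on
synthesis appear — with the N-NSP ratio and p-value reported alongside. No
multiple-testing correction is applied to per-protein tests; a one-way
ANOVA + Bonferroni helper exists for group-level comparisons.

Degenerate t-test inputs are integer-count realities: two identical
zero-variance samples give p = 1.0, perfectly separated zero-variance
samples give p = 0.0, and fewer than two animals per group is `not
testable` rather than an exception.

**Turnover**: the score of a protein in a group is the summed spectral count
(and distinct count) of its peptides with ≥ 1 non-tryptic terminus.
Semi-tryptic peptides count: endogenous proteolysis in a trypsin-digested
sample typically leaves one tryptic and one non-tryptic terminus. Raw
counts, no library-size scaling by default (an optional per-sample total
scaling exists but is off). Each non-tryptic terminus maps a cleavage site:
a peptide starting at position p with a non-tryptic N-terminus records a cut
after residue p − 1; a non-tryptic C-terminus at q records a cut after q.

**Phosphosites**: peptide-level phospho positions are translated to protein
coordinates through the specificity call's mapping; observations below the
localization threshold (Ascore ≥ 1000 by default — the search engine's
maximal confidence, used as the automated surrogate for manual validation)
are discarded; duplicates merge keeping the maximal score. A site is
disease-specific when it has an LPS-only layer, no Control-only layer, and
no layer observed in both conditions — the conservative resolution that
keeps disease- and control-specificity mutually exclusive when evidence is
split across layers; for single-layer analyses this reduces to "detected
under LPS, never in Control".

## The synthetic generator

The generator emulates what a database search exports, not spectra. Defaults
describe a mid-size study: 500 proteins of 250–450 residues (composition
tuned so K+R ≈ 12%, giving usable tryptic peptides), 3 animals per group,
and per-group labeling probabilities taken from the published per-layer
newly-synthesized fractions in the `fig1_fractions` preset
(31/29/34% control, 16/18/16% LPS).

Key mechanisms and the reasoning behind them:

- **Coupled pool membership.** Each protein (and each peptide) draws one
  latent uniform shared across groups; it is in the newly-synthesized pool
  of group *g* iff u < p(g). Marginal fractions are exact per group while
  pools nest across conditions — a protein synthesized under Control keeps
  being synthesized under LPS whenever the LPS probability allows, which is
  what biology does and what makes condition contrasts meaningful.
- **Labeling.** Within a newly-synthesized protein, each lysine-containing
  peptide is labeled with probability 0.6 (all its lysines carry +6.0201).
  Together with a per-peptide detection probability of 0.8 per animal, these
  two values were fixed once by an a-priori power calculation so that a
  4-fold synthesis suppression is detectable at n = 3 animals with the
  t-test machinery above.
- **Spectral counts.** 1 + NegBin with var = μ + αμ² (defaults μ = 3,
  α = 0.5): overdispersed counts with a floor of 1, since a detected peptide
  has at least one spectrum.
- **Condition effects.** A configurable fraction of proteins is modulated:
  in LPS groups their labeled-peptide counts are binomially thinned by the
  fold change, so the expected count scales exactly and a thinned-to-zero
  peptide simply goes undetected. Unlabeled counts are untouched.
- **Turnover.** With a per-group probability, a sampled tryptic peptide also
  emits a truncated copy (cut at a random internal position, verified to
  classify as semi-/non-tryptic against the parent protein).
- **Phosphosites.** Candidate sites are placed on S/T/Y positions covered by
  an observable peptide (Poisson number per protein); each site is detected
  per sample with a condition-specific probability, and a configurable
  fraction is LPS-only. Localization scores are 1000 (optionally a fraction
  at 500 to exercise the filter).
- **Peptidome mode.** For experiments on the distinct-peptide labeling rate,
  `peptidome_label_prob` assigns labels per distinct peptide at a marginal
  rate p over *all* peptides: since only lysine-containing peptides can
  carry the tag, they are labeled at the rescaled rate p·N_total/N_K
  computed on the realized peptide universe. This keeps the generator's
  invariant (labels imply lysine) while making the marginal rate exactly the
  configured value.

Everything the pipeline estimates is recoverable from the emitted truth
JSON (pool membership per group, modulated proteins, true sites), which is
what the recovery tests and `scripts/acceptance.py` score against.

What the generator does **not** emulate: peptide-level detectability biases
(length/charge/hydrophobicity), shared peptides between homologs, decoy or
FDR structure, chromatographic batch effects, and within-sample mixtures of
labeled and unlabeled copies of the same peptide species (a labeled peptide
is consistently labeled within a group). Passing recovery tests therefore
demonstrates correctness of the estimators under the stated statistical
model, not robustness to every artifact of real LC-MS/MS data.

## Numerical and policy choices

- Modification vocabulary: label-K6 (+6.0201, K), phospho (+79.9663, S/T/Y),
  carbamidomethyl (+57.0215, C); printed deltas matched within ±0.01 Da
  (search-engine exports round to two decimals).
- Thresholds: fold 1.5, p 0.05, Ascore 1000 (read as ≥), consistency
  ≥ 2 animals, max missed cleavages 2 — all configurable in `RunConfig`.
- Coordinates are 1-based inclusive everywhere; tables are UTF-8 TSV with
  `#` comments; decimal points only.
- Determinism: a fixed generator seed reproduces datasets byte for byte;
  pipeline outputs are byte-identical across runs on identical inputs (the
  run report carries wall-clock timings and is excluded from that
  guarantee).
- Problem sizes in the validation experiments (500 proteins × 10 seeds for
  proteome-fraction recovery, ~2 000 distinct peptides for the peptidome
  rate, 20 × 300 proteins for error/power characteristics) were chosen to
  put Monte-Carlo error well below the tolerances being checked.

## Known limitations

- Spectral counting saturates for very abundant proteins; ratios from
  summed counts inherit that compression.
- The t-test on per-animal counts is a pragmatic mirror of the study's
  statistics, not an optimal count model (a negative-binomial GLM would be
  the modern choice and is deliberately out of scope).
- Exclusive-synthesis calls are sensitive to detection dropout at low
  coverage; they are reported with the underlying counts so users can apply
  their own evidence thresholds.
- Cleavage-site inference reports observed termini only; it does not infer
  protease identity or distinguish in-vivo proteolysis from in-sample
  degradation.
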