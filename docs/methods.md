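# Methods

## Deconvolution model

The analysis treats a xenograft proteomics measurement as a mixture of
two sequence sources — human (tumour-cell) and mouse (host-stroma)
proteins — observed only through tryptic peptides. The merged
two-species database defines the resolution limit: a peptide sequence
derivable (under the digestion model) from proteins of exactly one
species is species-specific evidence; one derivable from both is
species-indistinguishable and is analysed as its own cohort rather than
being assigned.

The digestion model is fully specific trypsin: cleavage C-terminal to K
or R except when the next residue is proline, with up to
`max_missed_cleavages` uncut internal sites (default 2). Peptides are
length-filtered to 6–50 residues — the usual detectable tryptic range;
the bounds are configuration, not biology, and can be widened. Because
isoleucine and leucine are isobaric, MS/MS cannot distinguish an I↔L
substitution; peptide sequences are therefore canonicalized with I/L
folded together by default (`il_equivalent`). This is the conservative
choice: it moves I/L-only ortholog differences into the
indistinguishable class instead of letting them masquerade as
species-specific evidence. Peptides containing the undefined residue X
are excluded from the index entirely — an undefined position cannot
support a species call.

The unambiguity rule applied before quantitation has two clauses:
species-unambiguous (all database matches in one species) and
protein-unambiguous (within that species, exactly one accession).
Peptides failing only the second clause — shared by same-species
paralogues — are counted separately (`ambiguous_within_species_count`)
rather than silently merged into either paralogue.

Material declared single-species (an adjacent-normal vs tumour run
contains no mouse tissue) cannot legitimately produce other-species
hits; the partition report flags such rows as false-positive
identifications instead of dropping them quietly.

## Quantitation

Normalization emulates the reference-run behaviour of label-free
alignment software. The reference is the sample whose log-abundance
vector has minimal summed absolute deviation from the per-peptide median
profile; every other sample is multiplied by exp(−median log-ratio to
the reference), the median taken over peptides detected (> 0) in both
samples. The median makes the estimate robust to a minority of genuinely
differential peptides; zeros are treated as below detection limit and
excluded from ratio estimation but preserved in the rescaled table
(absence in an aligned label-free table is informative, not missing at
random).

Protein abundance per sample is the **sum** of its unique peptides'
abundances. Sum rather than mean matches the convention of the
label-free software family this mirrors; a mean roll-up is available via
the per-peptide table for sensitivity analysis. The maximum fold change
of a protein places the condition means in a condition-vs-condition
matrix and takes the largest larger/smaller ratio over all pairs; it is
computed on normalized linear-scale means, is invariant to condition
relabelling and global rescaling, and is always ≥ 1. A zero condition
mean yields an infinite fold change with the offending condition named
in a warning. The coefficient of variation is the n−1 sample standard
deviation over the mean, undefined (reported missing) for fewer than two
values or non-positive mean.

## Statistics

All tests run on natural-log abundances: the log transform stabilises
the multiplicative variance of label-free intensities and puts the
ANOVA on the same scale as the fold-change criterion. Zeros are imputed
at half the protein's smallest positive abundance before the log.

* Independent groups: classical one-way fixed-effects ANOVA
  (`scipy.stats.f_oneway`), with degenerate cases handled explicitly —
  all groups constant and equal gives p = 1, constant but different
  gives p = 0.
* Matched samples: within-subject repeated-measures ANOVA computed from
  sums of squares (conditions, subjects, error), valid for k ≥ 2
  conditions. For two conditions F equals the squared paired-t
  statistic; this identity, and agreement with
  `statsmodels.stats.anova.AnovaRM` at k = 3, are enforced by tests.
  Subjects missing a condition are dropped from the paired test and
  counted (mirroring a 9-of-10 matched design); p-values below the
  smallest positive normal double are floored there and flagged.

The differential-expression call requires, with inclusive thresholds,
p ≤ 0.05, ≥ 2 unique peptides, and ≥ 1.5 maximum fold change. No
multiple-testing correction is applied by default — the pipeline mirrors
a raw-p workflow — but Benjamini–Hochberg adjustment is available
(`DECriteria(fdr_adjust=True)`); with it the p clause applies to the
adjusted values, and the passing set can only shrink.

Cross-generation stability (F1 vs F2) is summarised by direction counts
and per-protein > 2-fold flags. The stability verdict considers only the
subset higher in the later generation: proteins that *rose* over an
additional engraftment and did not exceed 2-fold indicate a proteome
that is drifting minimally.

## Descriptive views

PCA treats samples as observations of row-centred log protein
abundances; scores come from the SVD and are made deterministic by
forcing each component's largest-magnitude loading positive. The usable
rank is min(n_samples − 1, n_proteins); requests beyond it are reduced
with a warning. Clustering is agglomerative average linkage under
1 − Pearson correlation between samples (so the distance lies in
[0, 2]); a zero-variance sample has no defined correlation and is an
error naming the sample. Violin plots are reduced to their data
contract: the per-protein, per-condition CV table is exported and any
plotting layer can render it.

## Synthetic-study generator

`simulate_study` emulates the statistical structure the analysis
assumes, with these choices:

* **Orthology.** Mouse sequences are per-residue substitutions of their
  human counterparts at an identity drawn per protein from a mixture
  (default components 0.60/0.78/0.85/0.93/0.99 with weights
  0.10/0.20/0.30/0.25/0.15, mean ≈ 0.85). A mixture rather than a single
  rate: the indistinguishable-peptide fraction depends on the spread,
  not just the mean. K/R/P positions are as mutable as any other, so
  cleavage patterns can diverge between orthologs.
* **Design.** 10 subjects by default; 9 matched adjacent-normal
  specimens (matched_fraction 0.9); 10 tumours; 10 PDX per generation,
  9 patient-matched plus one from an unmatched subject.
* **Compartments.** Each protein belongs to a cancer (epithelial) or
  stromal compartment; the stromal share of the proteome equals
  `stromal_fraction_pdx` (default 0.4). Patient samples express both
  compartments from human sequences, weighted by
  `stromal_fraction_tumour` (default 0.5 — pancreatic tumours are
  strongly desmoplastic). In PDX samples the human stroma is replaced by
  the mouse orthologs of the stromal proteins at weight
  `stromal_fraction_pdx`; consequently the mouse-origin fraction of rows
  detected in PDX samples tracks `stromal_fraction_pdx`, and setting it
  to 0 produces xenografts with no mouse material. Replacement is binary
  per compartment, not a per-cell simulation — sufficient for testing
  deconvolution logic that sees only sequences and abundances.
* **Abundance.** Per-protein baselines are log-normal (default
  ln-scale μ = 13.8, σ = 1.2, i.e. intensities around 10⁶). Per-sample
  multiplicative noise is mean-1 log-normal with a condition-specific CV
  (defaults 0.45 adjacent-normal, 0.30 tumour, 0.25 PDX: the tumour
  group less variable than the heterogeneous adjacent-normal tissue, and
  the PDX arms tightest). Planted effects multiply one arm of
  `de_conditions` by a fold drawn from `de_fold_range`
  (lower bound ≥ the 1.5 reporting threshold), on cancer-compartment
  proteins only, so they are visible to the human-specific analysis. Up
  to 10 distinct peptides per protein are emitted, each with a fixed
  log-normal ionization efficiency and 10% CV measurement noise, and
  every sample carries a planted log-normal scale factor (σ = 0.25) for
  normalization to remove. Matched-accession sets on each row come from
  an index lookup over the merged database, emulating a search engine
  reporting every database match.
* **Ground truth** records planted folds, noise-free condition-mean
  ratios (which equal the planted fold whenever the compared conditions
  weight the cancer compartment equally), per-row species of origin, and
  the sample scale factors. Identical config and seed reproduce the
  outputs exactly.

What the generator does **not** emulate: real ortholog substitution
patterns (substitutions are i.i.d. uniform, real ones are clustered and
biochemically constrained), semi-tryptic and modified peptides, missing
values that are not left-censoring, retention-time alignment errors,
shared-peptide quantitative interference, or FDR-controlled
identification. Passing recovery tests therefore demonstrates that the
pipeline's logic is correct under its own assumptions, not that those
assumptions hold for any particular instrument or search engine.

## Problem sizes and calibration checks

The test and acceptance workloads are sized for quick, repeatable runs:
null calibration uses a 2,000-protein study with 10-vs-10 samples and a
flat CV of 0.3 (the human-specific cohort then yields roughly 1,100
tested proteins, and the fraction at p ≤ 0.05 is required to sit within
three binomial standard errors of 0.05); parameter recovery plants forty
3-fold effects in a 300-protein study (observed sensitivity ≈ 88–93%
with ≤ 3% unplanted calls across seeds); oracle-equivalence checks run
hundreds of random small proteomes against brute-force substring
enumeration; monotonicity of the indistinguishable fraction is checked
on 40-protein studies across identity levels 0.60/0.85/0.99.

## Known limitations

* Classification is exact-match under the digestion model; a peptide
  observed with a modification or a non-tryptic terminus is UNMAPPED
  rather than resolved.
* The two-clause unambiguity rule discards paralogue-shared peptides
  from protein quantitation; proteins identified only by shared
  peptides are absent from results rather than reported as groups.
* The repeated-measures ANOVA assumes sphericity; for two conditions
  (the package's primary use) sphericity is vacuous, but k > 2 paired
  designs receive no Greenhouse–Geisser correction.
* Normalization assumes the majority of peptides are non-differential
  between samples; global composition shifts are absorbed into the
  scale factors by design.
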