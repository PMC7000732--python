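# Methods

This note documents the models, numerical choices, and simulator
assumptions behind `bridgedms`, and what the test suite does and does
not establish.

## Coordinate-based pairing

Both mates of one sequencing cluster inherit the cluster's physical
flow-cell position, which Illumina writes into the FASTQ identifier.
Pairing therefore keys on the full coordinate tuple
`(flowcell, lane, tile, x, y)` rather than `(x, y)` alone: the extra
fields cost nothing and make collisions across lanes or flow cells
impossible by construction.  Only the CASAVA ≥ 1.8 identifier dialect is
supported, and qualities are decoded as Phred+33 only; older dialects
raise errors rather than being auto-detected, because silent
mis-decoding is strictly worse than a hard failure.

A coordinate duplicated *within* one file cannot occur on a real flow
cell, so it is treated as evidence of corrupt input: every record
sharing the duplicated key is discarded and counted as a collision.
Each mate is filtered independently and survivors are paired; a read
lost on one mate leaves its partner unmatched rather than invalidating
it retroactively.  Pairing output is sorted by key, making the result
independent of record order in either file (the simulator shuffles both
files independently to exercise exactly this).

## Trimming and filtering

Each mate is trimmed to the region strictly between two anchor
sequences.  The 5′ anchor is scanned over offsets 0–6 (absorbing the
0–3 nt frame-shifting spacers inserted during amplicon preparation,
plus slack); the 3′ anchor is then *required at the fixed offset*
implied by the expected inner length.  This fixed-spacing check is what
makes indel rejection well-defined: if the 3′ anchor exists but at a
different spacing, the read gained or lost bases between the anchors and
is rejected as `indel`; if either anchor is absent, `anchor_not_found`.
Anchor matching is exact by default — the anchors are short and no
mismatch tolerance is obviously correct — with a configurable mismatch
allowance (`AnchorSpec.max_mismatches`).

The Q ≥ 20 filter is applied as a **per-base minimum over the retained
region only**.  Trimming first is the point of the 5′-focused design:
it rescues reads whose 3′ tails are poor while still guaranteeing that
every base actually used for variant calling meets the floor.  A
mean-quality mode is available (`quality_filter(..., mode="mean")`) for
users who prefer the laxer reading.

All coordinates and offsets are 0-based with half-open intervals.

## Variant calling and enrichment

Codons are extracted at configured offsets into the sense-strand inner
sequences (reverse-read inners are reverse-complemented, and their
quality lists reversed, before calling) and translated with the standard
genetic code; any `N` inside a codon rejects the call rather than
guessing.  Variant keys are amino-acid strings by default, with
codon-string keys retained for nucleotide-level analyses such as
CAI-versus-enrichment.

Enrichment is the plain frequency ratio
`(n_to/N_to)/(n_from/N_from)` — not a fold-change normalized to ≥ 1 —
so a depleted wild type can legitimately have a rate below 1.  Variants
below the minimum naive count (default 15 reads) carry no rate at all
instead of a noisy one; variants absent from the sorted population have
rate 0.  Under this definition the naive-frequency-weighted mean rate
over a closed population is exactly 1, which the suite asserts.

Fold ratios between class maxima are reported at one decimal place.

## Carryover

Stop-containing variants are complete loss-of-function, so their reads
in sorted rounds measure nonspecific carryover.  The estimator is
`λ_k = f_{k+1}/f_k` on the per-round fraction of reads containing at
least one stop (computed over the configured loci only; the rest of the
gene is constant).  The simulator implements the matching minimal model:
per sort round the stop-read mass is multiplied by exactly λ and the
functional variants share the remaining mass in proportion to
frequency × fitness.  This keeps the estimator's target identical to the
simulator's parameter, which is what makes λ recovery a meaningful
closed-loop test; users should read λ̂ as "per-round survival of null
variants", nothing more.

## Error-rate summaries

Predicted error for a region is the **arithmetic mean of per-base error
probabilities, converted to Q afterwards** — never the mean of Q scores,
which differs and flatters mixed-quality regions (half Q20/half Q40
gives mean-error Q ≈ 23, not 30).  Observed error is the mismatch
fraction at construct-constant bases flanking the mutated codons;
`N` calls are excluded from numerator and denominator, and indel-bearing
reads never reach this stage.  The double-observation error model for
overlapping designs is `e²` (independent observations).

## Fitness networks

Nodes are variants with defined rate ≥ threshold (default 1); edges join
pairs at Hamming distance exactly 1 and carry the lower-rate endpoint.
Distance-1 neighbours are found by wildcard bucketing — masking one
position at a time and grouping identical masked strings — which is
exact (two distinct equal-length strings share a masked form iff they
differ at precisely the masked position) and near-linear in practice;
the O(n²) all-pairs scan remains the test oracle.  Level binning for 3-D
layouts is deliberately left to configuration: rates are exported as
node attributes (GraphML / edge TSV) and layout is out of scope.

## Binding fits

The one-site model `y = Bmax·L/(Kd+L)` is fit by weighted least squares
(`scipy.optimize.curve_fit`, non-negative bounds).  "Instrumental"
weighting is under-specified in vendor software; here it means per-point
σ proportional to the signal, `σᵢ = max(yᵢ, ε)` with ε the smallest
positive response — the counting-statistics intuition for scintillation
data — and explicit per-point σ takes precedence when supplied.  This
weighting makes the fit invariant under joint rescaling of y and Bmax.
Initialisation: `Bmax₀ = max(y)`, `Kd₀ =` the concentration whose
response is nearest `Bmax₀/2`; robust for saturating designs.  Fits need
≥ 4 points and a not-identically-zero response; background subtraction
retains (but flags) negative values rather than clipping, which would
bias the low-concentration tail.  Replicates are pooled into one fit by
default.

## The simulator

`sim_dms` emulates a five-site NNS sort-seq screen read by 2 × 75 bp
paired-end sequencing, with the two variable loci split 2|3 across the
mates near their 5′ ends.  Defaults: wild type `TQWLH` (codons
ACC CAG TGG CTG CAC), 2 000-template library, four sort rounds,
10⁵ reads/round, carryover 0.3, per-position quality declining linearly
38 → 25 so the variable region sits near Q35, substitution probability
`10^(-Q/10)` per base.  Where a scale was not externally fixed, values
were chosen once as representative of a small NextSeq amplicon screen.
Library genotypes are drawn uniformly from the 32 NNS codons per site
(so amino-acid multiplicity follows NNS degeneracy and TAG is the only
reachable stop); fitness is log-normal per variant (σ = 1 by default,
spanning roughly two orders of magnitude), stops fixed at 0, wild type
pinned at 1 as the reference.  The constant gene context around the
loci is an arbitrary fixed sequence — the algorithms are indifferent to
its identity — and the flanks double as known-truth bases for observed
error.

Read identifiers encode the true template index in the instrument field
and every pair gets a unique coordinate (collisions only when injected),
so mispairing is auditable exactly.  One seed determines all output;
gzip output pins the header timestamp so identical content is
byte-identical.

What the simulator does **not** model: PCR amplification bias and
chimeras, index hopping, cluster-density effects, instrument-specific
error motifs, or quality-score miscalibration.  Passing tests therefore
demonstrate correctness of the *data processing* under the stated
generative model, not robustness to every real-world artefact; on real
data the observed error analysis is the intended check on quality-score
optimism.

## Problem sizes used in checks

The automated checks run the pipeline end-to-end at 10⁵ read pairs for
pairing exactness, 10⁵ reads/round for carryover recovery, 10⁶ sampled
reads for rank-correlation of enrichment against true fitness, 500
variants for the network oracle, and 200 synthetic datasets for binding
parameter recovery — sizes at which the relevant sampling errors are a
few percent and the checks are decisive yet quick on a single CPU.

## Known limitations

* Only CASAVA ≥ 1.8 headers and Phred+33 are accepted (by design).
* Anchor search is exact-match by default; heavily error-prone data
  (long-read, ancient DNA) would need the mismatch allowance and would
  weaken indel detection accordingly.
* Enrichment is single-ratio (naive → PSk); regression-based multi-round
  scoring is out of scope.
* The packaged CAI reference is the highly-expressed yeast gene set;
  other organisms require supplying `CAIReference.from_frequencies`.
* Carryover estimation assumes stop variants are fully null; read
  errors that create or destroy stop codons bias λ̂ at very low stop
  fractions (visible in the PS3/PS4 rounds of deep simulations).
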