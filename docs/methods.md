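# Methods

## Model and assumptions

`recodon` treats transgene recoding as constrained sampling: a coding
sequence for a fixed protein is drawn codon-by-codon from the host's
synonymous-codon distribution, subject to a hard exclusion rule set
evaluated on the DNA sequence.  Three assumptions shape the design:

* **Codon choice is positionally independent.**  The Monte Carlo sampler
  draws each codon from the per-amino-acid allowed distribution with no
  pair or neighbour coupling.  Real genomes show codon-pair bias; the
  repair loop's local resampling compensates only for the features the
  screen detects.
* **Structural risk is modelled as exact-match sequence features.**
  Hairpin stems are exact reverse-complement matches (no G·U wobble, no
  mismatches, loop length unconstrained); no thermodynamic folding is
  computed.  This makes every rule checkable by an exhaustive oracle, at
  the cost of missing near-complementary stems.
* **The exclusion list is the specification of "safe".**  A sequence is
  accepted exactly when the screen is clean and global G+C lies in the
  target window.  The default motif set (below) is a documented default,
  not a claim of completeness, and is fully user-replaceable.

## Threshold semantics

The rare-codon cutoff (default 0.20) applies to the *relative synonymous
frequency* — a codon's share within its amino-acid family — not to
absolute per-thousand usage.  Only the per-family fraction makes one
cutoff meaningful across 2- and 6-codon families.  Codons are kept when
f(c) ≥ threshold and survivors are renormalized.  Two safety rules keep
every protein encodable: single-codon amino acids (Met, Trp) always
survive, and if an entire family falls below threshold the
maximum-frequency codon is retained (ties: lexicographically first).
Families with zero training counts get uniform frequencies, so sparse
training sets never divide by zero.

## Screening rules and coordinates

All coordinates are 0-based, half-open, forward strand.  Defaults:

| rule              | default | rationale |
|-------------------|---------|-----------|
| excluded motifs   | AATAAA, AATAAT (polyadenylation); ATTTA (AU-rich instability); GTAAGT, TTNCAG (splice donor/acceptor consensus) | canonical plant-expression hazards; replaceable via a motif TSV |
| forbidden sites   | GCGGCCGC (NotI), TTAATTAA (PacI) | cloning flanks must remain unique; both are their own reverse complements, so strand is moot |
| min A/T run       | 6       | conventional gene-synthesis screening value |
| min direct repeat | 10 bp   | conventional screening value |
| min palindrome    | 8 bp    | conventional screening value |
| min stem          | 12 bp   | the double-stranded-RNA stem length treated as a silencing hazard |
| G+C window        | 55 ± 3% | the GC-rich host's coding average |
| strands           | forward only | the excluded signals act at the mRNA level; configurable |

Motif scanning expands IUPAC degeneracy and reports *overlapping*
occurrences (regex lookahead).  "Maximal, reported once" is made precise
for the pair finders: for direct repeats, each maximal equality run at
spacing d contributes one violation with arm length min(run, d) (an arm
longer than d would overlap its partner); for inverted repeats, each
maximal complementarity run on an anti-diagonal contributes one stem whose
arms stop at the centre.  Both finders use k-mer seed-and-extend; the test
suite re-derives every hit set with independent full-scan oracles
(per-offset equality arrays, anti-diagonal scans, substring enumeration)
on hundreds of random sequences.

A palindrome is an inverted repeat with zero loop; both finders are
provided because the two categories carry different default lengths (8 vs
12), and the suite asserts the containment relation between them.

## The repair loop

`repair()` alternates screening and local resampling:

1. Codons overlapping any violation (expanded one codon each side, mates
   included) are redrawn from the allowed distribution.
2. G+C steering: when global G+C is outside the window, each candidate
   codon's probability is tilted by exp(β·gc(codon)) with
   β = clip(0.5·(target − current), ±5), and a random 8% of all codons is
   additionally redrawn each round.  Incremental subset moves — rather
   than re-rolling the whole sequence — preserve cleanliness already
   achieved while the G+C drifts; a whole-sequence re-roll would have to
   land clean and in-window in a single draw, which empirically stalls
   above the window on GC-rich allowed sets.
3. Candidates are scored lexicographically by (violation count,
   |GC − target|); the best ever seen is retained and returned on
   non-convergence.  The best score is monotone by construction.
4. **Escalation.**  After 25 rounds without improvement the search resumes
   from the best candidate and resamples violation windows from the *full*
   synonymous family (uniform, still tilted).  This automates the manual
   refinement step a human designer performs with rarer codons, and is
   required in principle: threshold filtering can collapse a family to one
   codon (e.g. Arg → CGC), making certain residue contexts spell a
   violation under every allowed assignment.

`design()` wraps filter → reverse-translate → repair with independent
seeded restarts (default 8, per-restart seed = seed + index; default
max_rounds 10 000) and returns the first converged or best-scoring result.
In practice designs of 50–300 residues converge in ~5–90 rounds.

Some inputs are unsatisfiable outright: the heptapeptide **VFQHMCS** has
zero clean codings under the default rules — all 384 codon assignments
were enumerated; TTNCAG forces Gln→CAA, after which either His codon
completes a forced 8 bp palindrome with Met's fixed ATG and the invariant
prefixes of Cys codons.  Such contexts occur in roughly 0.1% of uniform
random proteins; `design()` then reports `converged=False` with the best
candidate and its residual violations, which is the honest outcome for a
demanding degenerate exclusion list.

## Construct finalization

`finalize_construct` appends tandem stop codons (default TAA+TGA — the
pair is configurable) and NotI/PacI flanks, then re-screens the insert to
confirm each site occurs exactly once.  Two stops guard against
read-through; an internal flank site is an error listing positions.

## Verification metrics

GC content is 100·(G+C)/length to one decimal.  Identity between a native
gene and its recoding is *positional* (matches/length, case-insensitive):
synonymous recoding preserves length, so gaps cannot arise; a
Needleman–Wunsch global alignment (match 1, mismatch −1, gap −2, identity
= matches/columns, via Biopython's PairwiseAligner) is the general-case
fallback for unequal lengths.  Identity is computed on the bare ORF,
without stops or flanks.  `codon_change_summary` verifies synonymy and
breaks base changes down by codon position; third-position changes
dominate because that is where degeneracy lives.

## qPCR mathematics

* **Efficiency**: least-squares slope of C_T vs log10(input);
  E = 10^(−1/slope) − 1 (slope −3.3219 ⇔ 100%).  Requires ≥ 3 points
  spanning ≥ 2 decades; zero-variance input is rejected.
* **Comparative C_T**: fold of B over A is (1+E)^(Ct_A − Ct_B).  The
  direct ΔCt form is the default because in a co-bombardment the two
  plasmids are delivered in equimolar amounts — the input itself is the
  normalizer.  Supplying reference-gene Cts switches to the ΔΔCt form
  (1+E)^(−ΔΔCt).  Reciprocity holds exactly.
* **Relative copy number**: 2^(−ΔΔCt) against a single-copy calibrator
  line with a genomic reference amplicon.
* **Primer design**: both transgene-specific pairs use the same template
  coordinates, so amplicon lengths are identical by construction; each
  primer's 3′-terminal base sits on a transgene-specific polymorphism in
  the 3′ region of the CDS (default: final third), so against the wrong
  template every primer carries a 3′-terminal mismatch.  Melting
  temperatures use the Wallace rule 2(A+T)+4(G+C) — a deliberately simple,
  dependency-free rule adequate for balancing pairs (default spread
  ≤ 6 °C), not for absolute prediction; the search scans polymorphic
  anchor pairs left-to-right and returns the first geometry meeting the
  amplicon window (default 70–180 bp) and Tm spread, which makes results
  deterministic.

## Synthetic data: what it emulates, what it does not

The CDS generator models a GC-rich monocot host: amino-acid composition
enriched for Ala/Gly/Pro/Arg (as GC-rich genomes are), per-family GC3
preferences drawn once per gene set from a Beta distribution
(concentration 8) around `gc3_bias`, and skewed within-subset codon
weights (C- over G-ending, T- over A-ending, mirroring the rarity of
A-ending codons).  `gc3_bias = 0.53` (the default) was calibrated once so
a 71-gene training set reproduces the ~55.7% G+C of the host condition;
low settings (≈ 0.2 and ≈ 0.0) produce native-like genes near 45% and
37–40% G+C — the generator's composition floor keeps it from reaching
36.5% exactly, which the acceptance report states as the measured value.
Ct simulation plants a known fold difference as a mean ΔCt of
log(fold)/log(1+E) plus Gaussian replicate noise, and builds dilution
series with the theoretically correct slope.

Not emulated: codon-pair bias, between-gene GC heterogeneity, real
amino-acid ordering, cDNA-synthesis bias, pipetting covariance between
wells.  Tests passing on these fixtures demonstrate the machinery —
tallying, filtering, scanning, repair, estimator math — is correct; they
do not demonstrate performance on any particular real genome.

Planted-feature fixtures (`plant_features`) return a manifest of
ground-truth violations and *reject* plantings whose flanking context
would extend the feature (an adjacent A/T base after an A/T run, a
complementary base pair around a palindrome), so manifest coordinates are
exact rather than hopeful; clean backbones come from rejection sampling
against the screen (cap 1000 tries).

## Problem sizes used by the checks

The acceptance script redesigns a 550-codon firefly-scale gene and a
311-codon Renilla-scale gene, measures convergence over 100 random
proteins of 50–300 residues (restarts 8, max_rounds 300–500), and
averages 1000 simulated Ct experiments per fold estimate; the test suite
additionally checks every scanner against its oracle on 200 random 500-nt
sequences and design round-trips on 500 random proteins.  These sizes were
chosen to match the scale of the original genes and give sub-percent Monte
Carlo error on the estimator checks.

## Known limitations

* Exact-match structure rules miss wobble-paired or bulged stems; no
  minimum-free-energy folding.
* The motif screen is forward-strand by default; antisense-acting motifs
  require `scan_both_strands`.
* Escalated repair may place sub-threshold (rare) codons inside a few
  stubborn windows; strict rare-codon avoidance and motif freedom can be
  jointly unsatisfiable (see the VFQHMCS example), and motif freedom is
  given priority.
* Wallace-rule Tm ignores nearest-neighbour thermodynamics and salt; swap
  in a better rule if absolute Tm matters.
* `positional_identity` is the right metric only for equal-length
  synonymous pairs; the global-alignment fallback uses simple linear gap
  costs.
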