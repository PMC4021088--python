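# recodon

Silencing-resistant transgene design: host-biased constrained reverse
translation, excluded-feature screening with iterative repair, and the
comparative-C<sub>T</sub> math for transgene-discriminating qPCR.

## The problem

Reporter and effector transgenes from distant taxa — the classic example is
firefly luciferase (*luc*, 45% G+C) or *Renilla* luciferase (Ren*luc*,
36.5% G+C) expressed in a GC-rich monocot such as sugarcane (coding
sequences averaging ~55.7% G+C) — are frequently expressed poorly and
silenced.  Beyond rare codons, AT-rich foreign coding sequences harbour
features the host's RNA machinery misreads: cryptic polyadenylation
signals (AATAAA-class) that truncate transcripts, AU-rich instability
elements (ATTTA), cryptic splice sites, and repeats or self-complementary
regions whose transcripts fold into double-stranded stems that can trigger
post-transcriptional silencing.

`recodon` rebuilds a coding sequence for such a protein from the host's
codon-usage statistics while excising every feature on a configurable
exclusion list, and supplies the quantification math used to verify the
result: because a recoding is only ~75% nucleotide-identical to its native
gene, allele-specific primer pairs anchored on the differences can measure
native and synthetic transcript levels separately in one cDNA pool.

## The procedure

1. **Codon usage** — tally a `CodonUsageTable` from host CDS (FASTA) or a
   Kazusa-style export; per-amino-acid relative synonymous frequencies
   f(c) are renormalized within each codon family.
2. **Rare-codon filter** — discard codons with f(c) below a threshold
   (default 20%), renormalize the survivors (`AllowedCodonSet`).
3. **Monte Carlo reverse translation** — draw each codon independently
   from the allowed distribution of its residue (seeded, reproducible).
4. **Screen** — locate all excluded features: IUPAC motifs (overlapping
   matches), A/T runs ≥ 6, direct repeats ≥ 10 bp, palindromes ≥ 8 bp,
   inverted-repeat stems ≥ 12 bp, forbidden restriction sites
   (NotI/PacI), and a global G+C window (55 ± 3% by default).
5. **Repair** — resample only the codons overlapping violations (± one
   codon of context), with exponential G+C tilt steering the sequence into
   the target window; candidates are scored by (violation count,
   |GC − target|) and the best is kept.  When the score stalls, sampling
   widens to the full synonymous family — the automated analogue of manual
   refinement with rarer codons.
6. **Finalize** — append tandem stop codons and NotI/PacI cloning flanks,
   re-screening for site uniqueness.

For verification, `gc_content`, `positional_identity` / `global_identity`
and `codon_change_summary` reproduce the sequence-level numbers reported
for such designs, and the qPCR module implements dilution-series
efficiency (E = 10^(−1/slope) − 1), comparative-C<sub>T</sub> fold change
((1+E)^ΔCt, with a ΔΔCt form) and 2^(−ΔΔCt) relative copy number.

## Worked example

Everything below is generated — no downloads.  Build a GC-rich host-like
usage table, then redesign a low-GC native-like gene:

```python
from recodon import design, build_usage_table, synthetic_cds_set
from recodon.metrics import gc_content

table, _ = build_usage_table(synthetic_cds_set(71, 300, seed=11))
native = synthetic_cds_set(1, 550, gc3_bias=0.20, seed=102)[0]
res = design(native, table, seed=1)
print("native GC:", gc_content(native))
print("designed GC:", res.metrics["gc_percent"])
print("converged:", res.converged, "| violations:", len(res.violations_remaining))
print("nucleotide identity:", res.metrics["identity_to_reference"], "%")
```

```
native GC: 43.8
designed GC: 57.7
converged: True | violations: 0
nucleotide identity: 76.5 %
```

The 550-codon native-like gene (43.8% G+C) is lifted into the host window
with zero remaining violations; the design keeps 100% protein identity
while sharing only ~76% of its nucleotides with the input — the
polymorphisms that make transgene-specific qPCR primers possible.

The same pipeline from the shell:

```bash
recodon fixtures --kind cds-set --n 71 --seed 11 --out host_cds.fa
recodon usage-table --cds host_cds.fa --out sugarcane_like.tsv
recodon fixtures --kind protein --n 180 --seed 4 --out protein.fa
recodon design --in protein.fa --table sugarcane_like.tsv --seed 7 \
    --out designed.fa --report report.tsv
# protein_fixture: converged=True GC=53.0% violations=0
```

Subcommands: `usage-table`, `screen`, `design`, `metrics`, `primers`,
`qpcr-efficiency`, `qpcr-fold`, `fixtures` (each documents its defaults in
`--help`).

## Layout

```
src/recodon/
  genetics.py   genetic code, translation, alphabet utilities
  usage.py      codon-usage tables, Kazusa parsing, rare-codon filter
  screen.py     motif/run/repeat/palindrome/stem finders, constraint set
  optimize.py   reverse translation, iterative repair, full design()
  metrics.py    GC, positional/global identity, codon-change summary
  qpcr.py       discriminating primers, efficiency, comparative CT
  simulate.py   seeded synthetic data (proteins, CDS sets, Ct data)
  io.py         FASTA / TSV / YAML-config round-trips
  cli.py        the `recodon` command
```

See `docs/methods.md` for the model, parameter defaults and their
rationale, numerical choices, and known limitations.
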