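# Methods

## The reference anchor

The package anchors everything to the 73-base Humanin gene as given in the
rCRS (NC_012920), positions 2633–2705: 24 codons plus a single terminal
thymine that acts as an incomplete stop codon (completed to UAA by
polyadenylation of the transcript). The bundled sequence is

```
ATGGCTCCACGAGGGTTCAGCTGTCTCTTACTTTTAACCAGTGAAATTGACCTGCCCGTGAAGAGGCGGGCAT
```

It is internally cross-validated at package-test time: it is exactly 73
bases, translates under the standard code to `MAPRGFSCLLLLTSEIDLPVKRRA`,
ends in the single-T stop, and reproduces the codon consequences of all
five bundled haplogroup-defining variants (T2638C synonymous, C2639T→P3S,
A2672G→S14G, G2701A synonymous, G2702A→A24T). Any one of these constraints
pins the printed bases; jointly they leave no freedom.

## Ungapped best-fit scan

The locator counts exact base matches of the query at every ungapped offset
of the target and returns the maximum; ties break to the smallest start
coordinate so output is deterministic. IUPAC ambiguity codes (including N)
never match, on either side: the statistic is a count of bases in common,
not a probabilistic identity. Only the forward strand is scanned here —
mtDNA submissions are conventionally heavy-strand oriented like the rCRS —
and the circularity of the molecule is ignored, a documented limitation
that is immaterial for a locus ~2.6 kb from the origin.

Two calibration facts characterize the statistic on the *MT-RNR2* length
scale (1,559 nt): a pure-random background yields a best fit of about 30/73
(~40%), because the maximum of ~1,487 correlated Binomial(73, 0.25) draws
sits roughly three standard deviations above the mean of 18.25; and a
30%-diverged planted copy yields about 50/73 — the binomial expectation
73 × 0.7 = 51.1 — because the planted offset dominates the background
maximum. The default hit threshold of 0.60 sits between these two regimes;
it is a package choice (no numeric cut-off is canonical), exposed as
`--hit-threshold`.

## Gapped refinement

The ungapped scan is blind to indels, so hits are refined by a small
dynamic-programming alignment of the full query against the window
`[anchor.start − band, anchor.end + band]` (band default 12; the window is
clipped at target boundaries and this is noted). Scoring is +1 match, −1
mismatch, −2 per gapped base with linear gap cost; the window bases outside
the fitted query extent are free overhang and do not count as insertions —
this is a fitting alignment, not a strict global one, so an indel-free copy
reports `net_indel = 0` regardless of the band. Among equal-scoring
alignments the DP prefers fewer gapped bases (so an in-frame 3-base event
is never fragmented into spurious gap pairs), and the traceback prefers
substitutions over gaps, which places remaining ties deterministically.
The scoring was chosen so that any single indel up to the band size is
always recovered at low divergence; the DP score is cross-checked in the
test suite against an independent pairwise aligner configured with the
same scoring.

## Classification

The three pseudogene criteria are applied in fixed precedence:

1. **Frameshift** (`net_indel % 3 != 0`) — reported first because a shifted
   frame corrupts all downstream codon evidence.
2. **Start loss** — the target codon aligned to query codon 1 must be ATG;
   `--lenient-start` additionally accepts ATA/ATT (mitochondrial
   initiation convention). Strict ATG is the default because the canonical
   gene starts with ATG in essentially all functional vertebrate copies.
3. **Premature stop** — translation from the aligned start; a stop before
   codon 20 (configurable `premature_cutoff`) pseudogenizes. A stop in
   [20, 24) is `AMBIGUOUS` rather than a hard call: how short is
   pseudogenizing is genuinely open, given that a 25-residue peptide (one
   in-frame codon longer, as in the Tuatara) still counts as functional.
   A stop within `max_extra_residues` (default 3) of the expected length
   24 + net_indel/3 is `FUNCTIONAL`.

A trailing 1- or 2-base remainder counts as an incomplete terminal stop
only when the reading frame truly reaches the end of the target; a
mid-sequence search window that runs out (the stop search extends 9 bases
past the aligned region) yields `AMBIGUOUS` with a "no stop located" note.
Codons containing ambiguity codes translate to X and never count as stops,
so a single N cannot fabricate a pseudogene call.

Genetic codes: table 1 (standard) is the default everywhere, including
NUMT mode — nuclear transcripts are cytoplasmically translated — and it is
the only reading consistent with the canonical 24-residue peptide; under
table 2 (vertebrate mitochondrial) the same region stops at the codon-22
AGG, a discrepancy the package surfaces rather than resolves (`--code 2`).

## Variant calling and the bundled annotation table

Substitution calling requires a gap-free 73-base region so the rCRS codon
frame is exact; indel-bearing samples are deliberately routed to the
classifier instead and tallied in cohort summaries under their gene status.
Codon arithmetic is fixed by the frame: position *p* lies in codon
`(p − 2633) div 3 + 1`, position `(p − 2633) mod 3 + 1`. Position 2705 is
inside the incomplete terminal stop and is labelled `stop-region`;
ambiguity-code sample bases are preserved as the alt allele with
consequence `indeterminate`. Labels are plain `T2638C` style with an HGVS
option. The bundled table carries the five haplogroup-defining variants
with their GenBank carrier counts; it is a TSV users can extend.

One documented source discrepancy: the A24T consequence of G2702A is
sometimes described as a glycine-to-adenine change in secondary prose; the
codon arithmetic (GCA→ACA, alanine→threonine at residue 24) and the
reference peptide fix it as A24T, which is what this package reports.

## NUMT screening

Long sequences are scanned on both strands (reverse strand via reverse
complement, coordinates mirrored back to the forward strand), every window
at or above the reporting threshold (default 0.60) is kept, and overlapping
windows collapse to the best-identity representative (ties leftmost, then
'+' strand) — a rule chosen for determinism and idempotence. Each surviving
hit is classified with table 1. Strand symmetry (scanning the reverse
complement flips strands and mirrors coordinates) is a tested invariant.

## The synthetic generator

The generator emulates the observed classes of real sequences: functional
homologs at controlled divergence, start-loss, premature stops, ±1/±2
frameshifting indels, in-frame 3-base indels, and human-like cohorts with
per-record independent variant carriage. Defaults: background length 1,559
(the human *MT-RNR2* scale on which the 40% background figure is observed),
uniform base composition, substitutions uniform over the three alternative
bases (the simplest null consistent with an exact-match statistic;
transition bias is a config hook, not a default).

Two deliberate modelling choices keep the recorded truth label the *actual*
label of the emitted sequence:

- Divergence is conditioned on the intended class: substitutions that would
  destroy the start codon or create an in-frame stop are resampled
  codon-wise, and the terminal thymine is exempt. This mirrors purifying
  selection — a diverged homolog that is still functional by definition
  carries none of the three pseudogenizing marks. Unconditioned per-site
  substitution is available separately (`mutate_sequence`) and is what the
  null calibrations use.
- The two background bases immediately downstream of an embedded copy are
  set to complete the terminal T into a full stop codon, emulating the
  in-situ termination context; otherwise a functional copy planted in
  uniform noise would lack a stop in ~50% of replicates for reasons that
  have nothing to do with the gene.

In-frame indel events are codon-aligned and inserted codons are resampled
away from stops, so a "functional, one codon longer" truth cannot silently
become a premature stop. Frameshifting events are placed uniformly inside
the copy, clear of the start codon.

What the generator does **not** emulate: phylogenetically realistic
substitution processes (no rate heterogeneity, no tree), rRNA secondary
structure constraints, GenBank submission artifacts (duplicates,
truncations), and NUMT insertion mechanics. Passing the synthetic suite
therefore demonstrates correctness of the locating/classification machinery
under the stated noise model, not performance on arbitrary real data.

## Problem sizes and determinism

The test suite uses 1,000 random instances (≤300 nt) for brute-force oracle
equivalence, 500 seeded cases for truth-label recovery (≥95% required
overall, 100% at divergence 0; anchors that fall below the hit threshold
count as failures, which is why the overall rate is not 100% — a mid-copy
indel plus 15% divergence can legitimately push ungapped identity below
0.60), all 219 possible single substitutions for variant round-trips, and a
10,000-record cohort for frequency recovery within exact binomial 95%
intervals. The acceptance script uses 1,000 backgrounds and 500 planted
replicates. Everything is seeded; the same seed gives byte-identical
FASTA output.

## Known limitations

- Single best hit per target in the locator (multiple mitochondrial copies
  in one record would need the NUMT scanner).
- No wrap-around scanning of circular genomes.
- Haplogroup information is annotation lookup only; the package does not
  call haplogroups.
- The premature/ambiguous boundary (codon 20) and the functional length
  tolerance (±3 residues) are operational conventions, configurable but
  not biologically derived.
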