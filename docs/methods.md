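# Methods

This note documents the models and procedures implemented in `clashkit`, the
defaults and why they were chosen, the numerical choices that affect results,
and what the simulation-based tests do and do not demonstrate.

## Read preprocessing

A CLASH read is modeled as `5' [adaptor] [barcode/UMI] insert [3' adaptor] 3'`.
Stages run in the physical order of that layout:

1. **5′ trim.** An optional fixed 5′ adaptor is removed (longest suffix of the
   adaptor found at the read start, mismatch rate ≤ 0.1). The barcode pattern
   is then consumed: `N` positions are stored as the UMI, fixed positions must
   match exactly; a fixed-base mismatch or a too-short read discards the read
   (tallied per reason).
2. **3′ trim.** The leftmost occurrence of a 3′-adaptor prefix that runs
   through the read end (or a full internal occurrence) is removed, requiring
   ≥ 3 matching bases and a mismatch rate ≤ 0.1. These partial-match defaults
   are this package's own choice; they make single-base sequencing errors in
   the adaptor non-fatal while keeping spurious trims of ≥ 3-nt coincidental
   suffixes the only false-positive mode (probability 4⁻³ per read end).
3. **Filter.** Keep reads with `min_len ≤ length ≤ max_len` (defaults 17–70 nt,
   the usual CLASH size selection) and **mean** Phred ≥ `min_phred`
   (default 30). Mean-quality filtering was chosen over per-base rules because
   it is a single interpretable parameter; the threshold is inclusive (a read
   at exactly Q30 passes).
4. **Collapse.** Reads with identical sequence — and identical UMI, when the
   barcode pattern contains `N` — merge into one unique read carrying a count
   and the list of member read ids. UMIs distinguish molecules; no UMI error
   correction or clustering is attempted. Output order: descending count, then
   sequence.

Phred scores use the Sanger +33 encoding exclusively; Q relates to error
probability as accuracy = 1 − 10^(−Q/10).

## Chimera search

References are RNA (T→U on load; `N` allowed in reads but never matching, and
rejected in references). Both fragments map **sense** to their references —
the chimeric cDNA contains both molecules' sequences — and complementarity
between the two molecules is assessed only by the energy model, never by
reverse-complement mapping.

An exact k-mer index seeds all searches. Defaults: k = 12 for strict mode;
k = 8 for the aligned modes so that a fragment of the minimum length (16 nt)
still contains an exact seed after one substitution or indel anywhere in it.
Completeness of seed-and-extend is checked against an all-substrings
brute-force oracle in the test suite.

* **strict** — for every guide, every exact occurrence of the full guide
  sequence in the read is considered; the occurrence must sit at one end of
  the read and the entire remainder must match some target exactly with
  length ≥ `min_fragment_len`. Junction overlap and gap are fixed at 0. All
  qualifying interpretations are returned.
* **scored** — fragments are found by Smith–Waterman local alignment
  (Biopython's PairwiseAligner; +1 match, −2 mismatch, −5 gap open, −2 gap
  extend — these values are this package's own and are recorded in the
  run-parameters table) against every reference sharing a seed with the read.
  Hits must score above `min_fragment_len × 0.8` and span ≥ `min_fragment_len`
  on the read; at most `max_hits_per_fragment` (default 10) are kept per side.
  Fragment pairs are accepted in either ligation order with junction overlap
  ≤ `max_overlap` (default 4 nt) and gap ≤ `max_gap_between` (default 4 in
  aligned modes); `combined_score = reg_score + tgt_score − overlap`. The
  single highest-scoring interpretation is kept, ties broken by guide name,
  then target name, then orientation and spans.
* **exhaustive** — all valid fragment pairings are reported, **plus** all
  intact-guide (strict) interpretations, deduplicated. The union is what makes
  the stringency ordering structural: every strict candidate is an exhaustive
  candidate with identical spans, and every scored result is an element of the
  exhaustive list. Without the union, a gapped alignment can legitimately
  extend a fragment a few bases across the ligation junction (any extension
  with net positive score), occasionally pushing the junction overlap past
  `max_overlap` and losing an interpretation that strict mode finds.

`min_fragment_len` defaults to 16 nt: long enough that an exact 16-mer shared
with a transcriptome-scale reference set by chance is rare, short enough to
keep miRNA-sized guide fragments discoverable.

## Duplex free energy

For each candidate, the guide fragment and target fragment (reference
sequences at the hit spans) are folded as an intermolecular duplex:
antiparallel base pairs only (Watson–Crick + G·U), no intramolecular
structure, no accessibility term — so absolute values are not comparable to
tools that model target-site accessibility, but the *ranking* of candidate
interactions is.

The energy of a pairing `(i₁,j₁)…(i_k,j_k)` (i ascending, j descending) is

```
ΔG = init + term(first pair) + term(last pair)
     + Σ over consecutive pairs: stack(step)            if adjacent on both strands
                                 bulge(da+db)           if unpaired on one side only
                                 internal(da+db)        otherwise
```

with `bulge(L) = 3.30 + 0.50·L`, `internal(L) = 1.00 + 0.50·L` (affine;
loops > 30 nt disallowed), duplex initiation +4.10 and a +0.50 penalty per
AU/GU terminal pair. Stacking energies are Turner-2004-style RNA/RNA values
including G·U wobble steps, shipped as a versioned TSV
(`clashkit/data/rna_duplex_params.tsv`); the 5′GC3′/3′CG5′ step is the most
stabilizing entry (−3.40 kcal/mol). The single-nucleotide-bulge special case
of tabulated models (retaining the flanking stack) is deliberately not
modeled.

The minimum-energy structure is found by an O(n·m·L²) dynamic program over
"last pair" states, with the loop-window minimum vectorized. A hybrid whose
best total ΔG is not negative is reported as having **no stable duplex** and
its ΔG is recorded as 0.0 for ranking purposes. Ties are broken toward
structures with more pairs, then toward the leftmost structure; energies are
compared with a 10⁻⁶ kcal/mol tolerance. The DP is validated against
exhaustive enumeration of all pairings for short sequences, and its energies
are symmetric in the argument order (the parameter table satisfies the
180°-rotation identity `E(XY/ZW) = E(WZ/YX)`).

Identical fragment pairs are folded once (memoized). Fragments are capped at
200 nt, far above any read-derived fragment.

## Aggregation and reporting

Interactions are keyed by (guide, target). Sites merge when target-reference
spans overlap by ≥ 1 nt (single-linkage over sorted spans); the merged site
reports the span hull, the summed read count over distinct supporting unique
reads, and the ΔG/diagram of its best (lowest-ΔG) member. A unique read
supporting the same pair through several interpretations is counted once for
that pair; in exhaustive mode one read may legitimately support several
*different* pairs, and the per-read table preserves the full
read→interpretation mapping so nothing is double-counted silently.

All CSVs use 1-based inclusive coordinates (headers say so), RFC-4180
quoting, and documented sort keys, making runs byte-reproducible. Region
annotation labels each site with the region containing the majority of its
span; exact boundary ties go to the downstream-most region; transcripts
absent from the region table are `unannotated`. Region output is raw site
counts per label — no enrichment statistic is computed.

## Simulator

The generator draws everything from one `numpy.random.default_rng(seed)`
(PCG64), so a seed fully determines the library bytes. It emulates:

* guides of 19–31 nt and targets of 200–1500 nt (uniform lengths, uniform
  base composition);
* one planted site per target: the reverse complement of a full guide,
  assigned round-robin so planted fragments are unique across targets
  whenever targets do not outnumber guides, with an optional number of
  substitutions in the site;
* chimeric reads = full guide + planted site with random flanks (≤ 8 nt each
  side), in guide-first or target-first order (30 % target-first), capped at
  the 70-nt size selection; assembled as barcode/UMI + insert + 3′ adaptor
  with Q40 qualities;
* optional random-ligation decoys (guide + uniformly random target fragment)
  recorded in the manifest as `decoy`;
* background reads, half single-reference fragments and half uniform random
  sequence;
* substitution errors at a configurable per-base rate (Q20 at errored
  positions); indels are off by default so strict-mode recovery is provable.

The full guide is used as the guide fragment because Argonaute-loaded small
RNAs are intact molecules — and because the strict mode requires an intact
guide by definition.

What the simulator does **not** emulate: realistic base composition and
transcript-abundance skews, per-cycle error profiles, partial guide fragments,
PCR-duplicate families beyond identical copies, or ligation-junction
microhomology biases. Perfect recovery on simulated data therefore
demonstrates algorithmic correctness (trimming, search, span arithmetic,
accounting), not expected sensitivity on real libraries, where guide
truncation and errors move reads from the strict tier into the aligned tiers.

## Test and validation sizes

Oracle checks run at sizes where brute force is exact and fast: 500 random
read/reference instances for the fragment search and 200 sequence pairs of
length ≤ 6 for the duplex DP. Recovery, containment, energy-ordering,
count-conservation and determinism checks use simulated libraries of 60–200
chimeras over 12–20 guides and targets — large enough that every code path
(both orientations, junction overlaps, multimapping decoys, UMI collapsing)
is exercised on every run, and chosen as this package's own test conditions.

## Known limitations

* No accessibility/ensemble term in the energy model (ranking tool, not a
  ΔG oracle); no temperature dependence; no pseudoknots.
* Aligned modes keep one best local alignment per (read, reference), so two
  fragments of the *same* reference inside one read are only resolved by the
  exact/strict paths.
* No paired-end input, genome-coordinate (spliced) mapping, SAM/BAM output,
  or UMI error correction.
* Mean-quality filtering does not trim low-quality ends; reads failing the
  threshold are dropped whole.
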