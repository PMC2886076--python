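# Methods

This document describes the models implemented in `crispratlas`, the default
parameters with units and rationale, and the design and limits of the
synthetic-world generator used for validation.

## 1. CRISPR array detection (`crispr_detect`)

Seed-and-extend, run on both strands of every contig:

1. **Seeding.** Exact 8-mer words recurring at a spacing compatible with a
   repeat-spacer period are chained into candidate arrays. Accepted spacing
   between consecutive seed occurrences is `[period_min, 2 * period_max]` =
   [38, 172] bp, i.e. the shortest repeat+spacer period through one skipped
   unit of the longest.
2. **Extension.** Candidate repeat columns are extended outward one column at
   a time. A column is accepted while at most one member row deviates from
   the majority base (unanimity is required with only two rows). Extension
   defines the exact repeat boundaries.
3. **Fuzzy rescue.** The consensus of the extended repeats is re-scanned
   (`rescue_pad` = 1500 bp on each side) for degenerate copies at Hamming
   identity ≥ 0.6 (≥ 0.75 for edge repeats), recovering decayed terminal
   repeats that seeding misses.
4. **Assembly.** Repeat runs separated by ≤ `max_disrupt_gap` = 2000 bp are
   merged into one array with the intervening insertion recorded as a
   disrupted segment (IS elements sit inside arrays without splitting them).
5. **Selection.** Overlapping candidates are resolved globally by
   (more repeats, higher summed identity, leftmost start).

An array needs ≥ `min_repeats` = 3 repeat units at ≥ `min_repeat_identity` =
0.8 consensus identity; repeat length 23–47 bp and spacer length 19–48 bp are
accepted. Orientation is `unknown` until leader calling (§3).

Terminal degeneracy (`flag_terminal_degeneracy`): a terminal repeat is
degenerate when it differs from the consensus in its distal third while the
internal repeats average ≥ 0.9 identity — the signature of an eroding,
no-longer-used array end.

`palindromicity` scores the best non-crossing intramolecular pairing
(Nussinov-style, minimum loop 3) per position. Watson–Crick pairs only by
default; G·U wobble is an opt-in flag (`include_gu=True`) because wobble
pairing breaks reverse-complement score symmetry.

## 2. Core genome and locus anchoring (`locus_map`)

Orthologs are reciprocal best hits (RBH) of protein similarity (global
pairwise alignment, BLOSUM62, similarity normalised to [0, 1]), with
`min_similarity` = 0.6 and length difference ≤ 20 %. Pairs are refined by
synteny: a pair is kept if a neighbouring pair (±2 genes) supports it or its
similarity exceeds the 95th percentile of the pair set. Core families take
exactly one member per genome and must be consistent across all genome pairs.

A detected array is anchored to a locus name by the nearest flanking anchor
genes within 30 kb: *cysD*–*cysJ* → CRISPR1, *cysJ*–*ygcF* → CRISPR2,
*clpS*–tRNA-Ser → CRISPR3, tRNA-Ser–*infA* → CRISPR4. When a core-genome is
supplied, CDS anchors must belong to it (tRNA genes are matched by product).
Arrays without a matching anchor pair are reported as `unanchored`.

## 3. Leader calling (`find_leader`)

For each locus, the two 200 bp flanks of every array are compared across
genomes. The leader is the flank whose cross-genome conservation exceeds the
other by ≥ `asymmetry_margin` = 0.15 and is ≥ `conservation_floor` = 0.70:
leaders are vertically inherited and conserved, while the distal
(trailer-side) flank drifts. The leader side fixes transcription orientation
(leader = 5′), after which spacer indices are counted from the leader and
terminal-degeneracy flags become 5′/3′ meaningful.

## 4. cas operon annotation (`cas_annot`)

Two bundled reference operons (synthetic stand-in sequences with realistic
lengths): an 8-gene *Ecoli*-type system (cas1–3, cse1–4, cas5, cas2) and a
6-gene *Ypest*-type system (cas1, cas3, csy1–4).

- **CDS calls**: annotated proteins in ±10 kb of each array are matched to
  references at similarity ≥ 0.35.
- **Pseudogene scan**: the whole genome is translated in six frames; exact
  amino-acid seed words are extended without gaps (hard stop at `*`,
  ≥ 20 aa, similarity ≥ 0.35). Segments for one reference within 3 kb form a
  locus; a locus is called at reference coverage ≥ 0.3. Needing multiple
  frames ⇒ frameshift; split by a stop ⇒ internal stop; coverage < 0.8 ⇒
  truncation — any defect makes the call `pseudo`. To suppress chance
  matches in megabase-scale scans (short ~0.4-similarity segments arise by
  chance), a locus must additionally reach similarity ≥ 0.7 **or** coverage
  ≥ 0.6; genuine recent relics retain near-exact identity over their
  surviving segments.
- **Operon status**: `complete` (all canonical genes intact, co-oriented),
  `partial` (anything detected but not complete — decayed or fragmentary),
  `absent`. The densest call cluster is the operon; it is assigned the locus
  of the nearest array within 5 kb. Remaining calls are kept as strays.

## 5. Spacer atlas and polarity (`spacer_protospacer`)

Spacers are clustered strand-blind (canonical key = lexicographic min of
sequence and reverse complement). A cluster is a **singleton** when its
occurrences come from one effective strain group — near-identical strains
(§7) count as one observation, so recently duplicated genomes do not
fabricate "shared" spacers.

**Polarity.** New spacers are acquired at the leader, so strain-specific
(singleton) spacers should sit leader-proximal. Statistic: mean leader index
of singleton occurrences − mean leader index of shared occurrences (negative
= singletons closer to the leader). The null permutes singleton/shared
labels within each array; `p_perm` is the one-sided lower-tail probability
with add-one smoothing, and a central 95 % null band is reported. Default
`n_perm` = 10 000.

**Proto-spacer search.** A spacer of length L matches a target window at
identity > 0.95 (strict), i.e. ≤ 1 mismatch for a 32-mer. The search
partitions the query into ⌊max_mismatches⌋+1 disjoint exact chunks
(pigeonhole: one chunk must match exactly), locates chunk hits in a sorted
k-mer index and verifies by Hamming count; both strands; `N` never matches.
This is exactly equivalent to the exhaustive sliding-window scan (tested
against it) but near-linear in practice. Chromosome self-matches exclude the
array spans themselves (±100 bp) so spacers do not "hit" their own array.

Hits are classified by target: `phage`, `plasmid`, `prophage` (chromosome
hit inside an annotated prophage span), `cas` (inside a cas gene span), else
`chromosome`. A hit is **genic** when it overlaps an annotated gene by ≥ 1 bp
and **coding-strand** when its strand equals that of the maximally
overlapping gene. Percentages are integers rounded half-up.

**Anti-CRISPR.** An array is flagged when ≥ 1 of its spacers matches a cas
reference gene of subtype S at proto-spacer stringency while the genome's S
operon is `absent` — a self-incompatible arrangement that only survives when
the targeted system is gone. Matches in genomes where S is present are
reported separately as conflicts, never as flags. By default any non-absent
status blocks flagging (conservative); `accept_partial_relic=True` treats
fully-pseudogenised partials as absent.

## 6. Divergence statistics (`evo_stats`)

Distances are **p-distances** over per-genome concatenations of equal-length
core families (gap/N columns excluded). At the distances of interest
(~2×10⁻⁴) multiple-hit corrections are negligible (< 0.02 % relative), so
model-dependent ML distances are not needed; a Jukes–Cantor toggle is
provided for larger distances.

- **Grouping**: single-linkage components of the graph with edges
  d < 0.0002 (0.02 %; strict inequality). Groups of near-identical strains
  feed the singleton definition (§5).
- **Molecular clock**: t = d / μ with μ = 7.6×10⁻¹⁰ substitutions/site/year;
  at d = 0.0002 this gives ≈ 2.6×10⁵ years.
- **Conservative neutral dating**: per-site per-generation polymorphism
  input r = (U/G)(1 + ρ) with genomic mutation rate U = 10⁻³ per
  generation, genome size G = 5×10⁶ bp and recombination:mutation
  polymorphism ratio ρ = 2.5; generations = d/r (≈ 2.9×10⁵ at d = 0.0002),
  converted to years at 40 h/generation and 8766 h/year (≈ 1.3×10³ years).
  This deliberately assumes every mutation ever produced is retained, hence
  a hard lower bound on elapsed generations.
- **Repeat-count correlation**: squared Pearson correlation of paired locus
  repeat counts with a label-permutation p-value (one-sided, add-one
  smoothed) replacing any parametric assumption.

## 7. Synthetic worlds (`synthetic_data`)

The generator produces genomes whose planted arrays are **detectable by
construction**, with a machine-readable truth set (arrays with exact
repeat/spacer coordinates, leaders, cas statuses, element classes, spacer
provenance, anti-CRISPR and self-target records).

Key design points:

- **Boundary-column guarantee.** The detector's column extension stops when
  more than one row deviates. The generator assigns the sequence positions
  immediately flanking every repeat (spacer edge characters, the leader's
  last and the trailer's first character) so that no base occurs in more
  than m−2 of the m flanking rows. Extension therefore halts exactly at the
  true repeat boundary — for the full array and for any subset of rows the
  detector might assemble.
- **No spurious seeds.** All 8-mers of both repeat consensi (IUPAC expanded)
  and their reverse complements are excluded from spacers, leaders, flanks,
  IS and gap sequence, so seeding cannot fire outside planted arrays.
- **Strain panel.** Six strains diverge from one ancestor at 5×10⁻⁴
  substitutions/site (pairwise ≈ 10⁻³) plus one twin at 5×10⁻⁵
  (the close pair for grouping). CDS mutations are stop-safe; planted
  arrays are protected in the twin.
- **Arrays.** CRISPR1/2 share one repeat consensus, CRISPR3/4 another;
  CRISPR1 is universal, the others strain-dependent. Per-locus spacer pools
  are shared across strains (leader-ordered, oldest distal); each strain
  adds private leader-proximal spacers. One array carries an IS insertion,
  distal terminal repeats are degenerate (5 mismatches in the distal
  third), one genome carries cas-derived spacers with its cognate operon
  deleted (anti-CRISPR), and one genome carries a prophage copy matched by
  its own spacer (self-target). With `acquisition_mode="uniform"` spacer
  order is shuffled, removing the polarity signal (null control).
- **Proto-spacers.** A configurable fraction of spacers is excised from pool
  elements (70/20/10 % phage/plasmid/chromosome), with 0/1/2 planted
  mismatches (60/20/20 %), a genic fraction and a coding-strand fraction.
  2-mismatch plantings are designed *unrecoverable* at the 0.95 threshold.
- **cas operons.** Strains carry the *Ecoli* operon intact, pseudogenised
  (alternating internal stops and frameshift deletions), or deleted; one
  strain carries the *Ypest* operon beside CRISPR3.

All randomness flows from a single integer seed through per-concern child
generators; identical seeds give byte-identical worlds.

**Limitations.** The generator models point substitution only (no
rearrangement, gene gain/loss beyond the planted events, or real
recombination); mobile elements are random sequence with gene annotations
rather than realistic phage genomes; cas references are synthetic stand-ins;
leaders are conserved verbatim up to strain divergence. These are deliberate:
the worlds isolate the behaviours the pipeline claims to measure.

## 8. Numerical conventions

- Percentages reported as integers are rounded **half-up** (`round_half_up`),
  matching report-style arithmetic (e.g. 505/594 → 85 %).
- Permutation p-values use add-one smoothing: p = (hits + 1) / (n_perm + 1),
  never exactly zero.
- Proto-spacer identity uses strict `>` 0.95 so a 32-mer admits at most one
  mismatch.
- Distance threshold comparisons use strict `<` (a pair exactly at 0.0002 is
  not grouped).
- All derived random seeds are drawn below 2³¹.
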