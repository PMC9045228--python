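# Methods

## The combinatorial model

A shufflon with *n* invertible cassettes is modelled as a signed permutation:
an ordered list of cassette ids, each with an orientation. Position 0 is the
cassette adjacent to the constant *pilV* region; the constant region fixes an
absolute frame, so conformations are compared element-wise and no quotient by
global flips is taken. The shufflase move is a contiguous block reversal
`invert_block(conf, i, j)`: positions i..j appear in reversed order with every
orientation flipped. Which site pairs may actually recombine in a given
plasmid is not modelled; every contiguous block reversal is allowed, which is
the least-restrictive reading of inversion "independently or in groups" and
generates the full signed-permutation space — n!·2^n states, verified
exhaustively against brute-force generation for n ≤ 4 and equal to the
published 384-state count for four cassettes. Enumeration is a breadth-first
closure from the identity with a visited set keyed on the canonical text form
(`"1+,3-,2+,4-"`), returned in lexicographic key order so output is
reproducible. n = 0 is a legal degenerate locus everywhere except
`active_variant`, which is undefined on an empty arrangement.

The active variant of a conformation is the label of the position-0
cassette's plus-strand ORF when that cassette is in '+' orientation, else its
minus-strand ORF — the C-terminus fused in frame to PilV. By symmetry each of
the 2n variants is active in exactly (n−1)!·2^(n−1) states; this uniform
partition is asserted in tests.

## Locus segmentation

An sfx site is held as a 31-bp footprint: 12-bp left arm, 7-bp core, 12-bp
right arm, with the variable triplet at right-arm positions 7–9 (the e/f/g
repeats: GTG, ATC, TCG). Coordinates are 0-based half-open; minus-strand
sites are reported by their plus-strand footprint. Detection requires an
exact core match plus a right-arm template match (`N` wildcards at the
triplet; `max_mismatches` substitutions allowed elsewhere, default 0) on
either strand; the left arm is nonconserved and is recorded but never
matched. Overlapping candidates resolve leftmost-first. The bundled default
consensus (`core=GTGCCAC`, arm template `GCAGTTNNNGGC`) is a synthetic
default used by the data generator; analyses of a real plasmid must supply
that plasmid's own consensus — nothing in detection hard-codes any
particular plasmid's letters.

Cassettes are the intervals strictly between consecutive site cores, so each
cassette carries the upstream site's right arm and the downstream site's
left arm; these move with the cassette during inversion, as the arms do in
the natural system. The constant 5' region ends at the first core and the
3' region (toward *rci*) begins after the last core. The pilV reading frame
is taken from the annotated CDS start when GenBank features exist, else from
an explicit `constant5_hint`; it is never inferred by longest-ORF scanning.
Translation uses the bacterial genetic code (table 11) and reported variant
lengths exclude the stop codon.

## Junction signatures and counting

Each (cassette, orientation) pair yields one footprint: the last `c` bases
of the constant side — ending at the 3' boundary of the first core, core
included — concatenated with the first `k − c` bases of the cassette in that
orientation. Defaults are k = 39 and c = 19 (12 bp upstream of the core +
the 7-bp core), so 20 cassette-side bases carry the discriminating sequence
while the constant-side anchor keeps the footprint specific to the pilV
junction. If any two footprints (or a footprint and another's reverse
complement) collide, k grows symmetrically — one base per side — until all
are unique, and the final k is reported. Uniqueness is additionally verified
exhaustively in tests: over all 384 conformation sequences of the synthetic
locus, each footprint occurs in exactly the conformations whose active
variant bears its label.

Counting is exact substring matching of each footprint and its reverse
complement against raw FASTQ reads (optionally gzipped, multiple files
pooled per sample), with no quality or length filtering. The default
`per_read` mode counts a read at most once per variant; `per_occurrence`
counts every hit. Reads positive for two or more distinct variants are
tallied as ambiguous and excluded from counts — with verified-unique
footprints these can only arise from chimeric or error-bearing reads.
Relative abundance is each variant's count divided by the total
footprint-positive reads.

Enrichment between a donor and a transconjugant sample is defined here — it
is a package definition, flagged as such in output headers — as
log2((f_trans + ε)/(f_donor + ε)) with pseudocount ε defaulting to one read
in the shallower sample (1/min total_positive). Conjugation frequency is
transconjugants per recipient CFU; when no transconjugant is observed or the
ratio falls below the limit of detection (defaults 1 × 10⁻⁸ for in vitro,
1 × 10⁻⁵ for in vivo assays), the value is reported at the limit with a
censoring flag rather than as zero.

## The synthetic data layer

The generator emits a locus with the TP114 architecture: a 345-codon
constant PilV coding region whose in-frame tail is the first site's left arm
and core; n cassettes (default 4) each built as upstream right arm +
plus-strand ORF + stop + spacer + reverse-complemented minus-strand ORF
ending in the downstream left arm, so both orientations splice in frame onto
the constant region and terminate at a stop; and n+1 sfx sites whose
variable triplets cycle GTG/ATC/TCG. Variable C-terminus lengths are drawn
uniformly from 69–113 codons (the TP114 range); ORF interiors are uniform
random sense codons, left arms are rejection-sampled so no reading frame
gains a premature stop, and background/spacer sequence is uniform random.
Defaults of 60 bp 5' flank, 21–60 bp spacers and a 240 bp 3' region are
arbitrary realistic paddings. Everything is deterministic given the seed,
and a ground-truth record (coordinates, ORF lengths, labels) accompanies
every locus.

Population dynamics are simulated per cell: each of `n_cells` cells starts
at the identity conformation and at each of `n_steps` steps applies, with
probability `inversion_prob`, one block reversal drawn uniformly over all
contiguous position pairs. The move set is symmetric, so the stationary law
is uniform over all n!·2^n states; `inversion_prob = 0` models a
shufflase-deletion population locked in its starting conformation. The true
per-generation inversion rate of Rci is unknown, so `inversion_prob` is a
free parameter, not an estimate.

Transfer selection is deterministic: transconjugant variant frequencies are
f(v)·w(v) normalised, where w are non-negative per-variant compatibility
weights toward a given recipient.

Reads are single-end, drawn by choosing each read's source conformation
multinomially, a uniform start position and strand, and independent
substitution errors at `error_rate` (default 0.001; no indels, no PCR bias,
constant base qualities). Because every conformation sequence has the same
length and the junction sits at a fixed coordinate, each variant's chance
that a read spans its footprint is identical, so footprint counting is an
unbiased estimator of the variant marginal; errors thin all variants by the
same factor (1−e)^k. What the simulator does not emulate — indels, quality
degradation, PCR chimeras, amplicon primer structure — means passing tests
demonstrate correctness of the counting logic and its sampling statistics,
not robustness to every real library artefact.

## Problem sizes and tolerances

Statistical checks run at depth 10⁴–10⁵ reads, 2 × 10³–2 × 10⁴ cells and
100–300 dynamic steps; these scales keep the full suite fast while leaving
every assertion's tolerance at 3 standard errors of the relevant binomial or
multinomial quantity (via the delta method for log2 ratios). Frequency-sum
checks use an accumulation tolerance of 10⁻¹². The enrichment-recovery check
uses weights spaced 2× with a donor skewed as w^(−1/2) so both samples keep
every variant at measurable frequency — otherwise the log2 variance of the
rarest variant would swamp the rank comparison.

## Known limitations

- Exact-match counting only; a single substitution inside a footprint drops
  the read (uniformly across variants). Mismatch-tolerant matching is not
  implemented.
- The reachability of the full 384-state space assumes all block reversals
  are permitted; a plasmid whose sfx-site orientations restrict the move set
  would occupy a subgroup, and the enumeration would need a restricted move
  list (the API takes the move set from the model's cassette count, not from
  site sequences).
- Paired-end merging, UMI handling, and replicate-level significance testing
  are out of scope; replicate tables are summarised as mean ± SD in figures
  only.
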