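# shufflon

Combinatorial modelling and sequencing-based quantification of **shufflon
multiple-DNA-inversion systems** — the biological switches that I-complex
conjugative plasmids (IncI1, IncI2, IncK, ...) use to swap the C-terminal
adhesin domain of their minor pilin PilV and thereby retarget conjugative
transfer toward different recipient bacteria.

A shufflon is a set of *n* invertible DNA cassettes at the 3' end of the
*pilV* gene, separated by *sfx* recombination sites (a conserved 7-bp core
flanked by a conserved 12-bp right arm with a variable 3-bp triplet, and a
nonconserved 12-bp left arm). A tyrosine recombinase, the shufflase Rci,
recombines pairs of sites and inverts the intervening cassettes singly or in
blocks. Each cassette carries two convergent ORFs, so the cassette adjacent
to the constant *pilV* region determines which of 2*n* PilV variants the
cell expresses. For the TP114-like four-cassette architecture this package
models, the reachable state space is the full set of signed permutations,

&nbsp;&nbsp;&nbsp;&nbsp;|conformations| = *n*! · 2<sup>*n*</sup> = 384 for *n* = 4,

partitioned uniformly into 8 active-variant classes of 48 states.

The package is aimed at people analysing amplicon or whole-plasmid
sequencing of shufflon-bearing plasmids. It provides:

- `shufflon.model` — the signed-permutation model: block inversions,
  exhaustive conformation enumeration, active-variant rules;
- `shufflon.locus` — GenBank/FASTA parsing, sfx-site motif scanning,
  segmentation of the locus into cassettes, translation of the constant
  PilV region and every variant C-terminus;
- `shufflon.quantify` — per-variant **junction footprints** (39-bp k-mers
  spanning the *pilV* 3' end / cassette junction), exact-match counting
  directly in raw FASTQ reads on both strands, relative abundances,
  donor-vs-transconjugant enrichment (pseudocounted log2 frequency ratio),
  and conjugation frequencies (transconjugants per recipient CFU with
  limit-of-detection censoring);
- `shufflon.simulate` — a fully synthetic data layer: locus generator,
  per-cell inversion dynamics, variant-specific transfer selection, and a
  substitution-error read simulator with per-read ground truth;
- a `shufflon` command-line interface over all of the above.

## Worked example

Simulate a four-cassette locus, generate reads from a known variant mixture,
and quantify it back:

```sh
shufflon simulate-locus --seed 1 --out-prefix locus
shufflon signatures locus.gb --out sigs.fasta
# -> "# 8 signatures at k=39"
shufflon simulate-reads --locus-seed 1 --freqs "A=0.45,B'=0.30,C=0.15,D=0.10" \
    --depth 20000 --seed 2 --out reads.fastq.gz
shufflon quantify --signatures sigs.fasta --reads reads.fastq.gz \
    --sample demo --out counts.tsv
cat counts.tsv
```

```
# n_reads_scanned=20000 total_positive=632 ambiguous=0 unmatched=19368
sample	variant	count	frequency
demo	A	285	0.4509493670886076
demo	A'	0	0.0
demo	B	0	0.0
demo	B'	193	0.30537974683544306
demo	C	91	0.1439873417721519
demo	C'	0	0.0
demo	D	63	0.09968354430379747
demo	D'	0	0.0
```

Of 20,000 whole-locus reads, 632 span the junction and carry a variant
footprint; their relative abundances (0.451, 0.305, 0.144, 0.100) recover
the simulated mixture (0.45, 0.30, 0.15, 0.10) to within binomial sampling
noise. Variants absent from the mixture are reported at exactly zero.

Conjugation-frequency bookkeeping with censoring:

```sh
shufflon conj-freq --transconjugants 25 --recipients 2.1e7
# -> 1.190e-06	censored=false
```

Enumerating the state space:

```sh
shufflon enumerate --n 4 | wc -l
# -> 384
```

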