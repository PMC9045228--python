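"""Synthetic shufflon data: locus generation, population dynamics, reads.

Everything the analysis pipeline consumes can be generated here with no
external data: a TP114-like locus (a constant 5' pilV region whose tail
carries the first sfx site, then n invertible cassettes each encoding two
convergent stop-terminated ORFs, separated by sfx sites whose variable
triplets cycle over the e/f/g repeats), per-cell inversion dynamics under a
shufflase of tunable activity, variant-specific transfer selection, and
substitution-error FASTQ reads with per-read ground truth.

All simulators are pure functions of their inputs and an explicit seed.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .model import (
    DEFAULT_LABELS,
    CassetteSpec,
    Conformation,
    ShufflonModel,
    enumerate_conformations,
    active_variant,
    invert_block,
)
from .locus import (
    ARM_LEN,
    CORE_LEN,
    DEFAULT_CONSENSUS,
    SITE_LEN,
    SfxConsensus,
    SfxSite,
    ShufflonLocus,
    TRIPLET_LABELS,
    conformation_sequence,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "PopulationState",
    "CompatibilityWeights",
    "generate_locus",
    "simulate_dynamics",
    "simulate_selection",
    "simulate_reads",
    "population_from_variant_freqs",
    "variant_marginal",
    "locus_to_fasta",
    "locus_to_genbank",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
STOPS = ("TAA", "TAG", "TGA")
#: the three IncI2-family variable triplets, cycled over consecutive sites
TRIPLET_CYCLE = ("GTG", "ATC", "TCG")

_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters for the synthetic locus and reads.

    Defaults mirror the TP114 architecture: four cassettes, a 345-codon
    constant PilV N-terminus, variable C-termini of 69-113 residues, and
    Illumina-like 150-bp single-end reads with a low substitution error rate.
    """

    n_cassettes: int = 4
    constant5_codons: int = 345
    variant_codon_range: tuple[int, int] = (69, 113)
    sfx_consensus: SfxConsensus = DEFAULT_CONSENSUS
    read_length: int = 150
    error_rate: float = 0.001
    depth: int = 10_000
    seed: int = 0
    flank5_len: int = 60
    constant3_len: int = 240
    spacer_range: tuple[int, int] = (21, 60)

    def __post_init__(self) -> None:
        lo, hi = self.variant_codon_range
        if self.n_cassettes < 0 or self.constant5_codons < 10:
            raise ValueError("n_cassettes must be >= 0 and constant region >= 10 codons")
        if not (5 <= lo <= hi):
            raise ValueError(f"variant codon range must satisfy 5 <= min <= max, got {lo, hi}")
        if not (0 <= self.error_rate < 0.25):
            raise ValueError(f"error_rate must be in [0, 0.25), got {self.error_rate}")
        if self.read_length <= 0 or self.depth <= 0:
            raise ValueError("read_length and depth must be positive")


@dataclass
class GroundTruth:
    """Everything the generator knows about the locus it emitted."""

    seed: int
    cds_start: int
    site_coords: list[tuple[int, int]]
    cassette_coords: list[tuple[int, int]]
    orf_lengths_aa: dict[str, int]
    labels: list[tuple[str, str]]
    locus_length: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass
class PopulationState:
    """Empirical distribution over shufflon conformations."""

    freq: dict[Conformation, float]

    def __post_init__(self) -> None:
        total = sum(self.freq.values())
        if self.freq and abs(total - 1.0) > 1e-9:
            raise ValueError(f"conformation frequencies must sum to 1, got {total}")


@dataclass(frozen=True)
class CompatibilityWeights:
    """Relative transfer efficiency of each PilV variant toward one recipient."""

    w: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.w.values()):
            raise ValueError("weights must be non-negative")
        if not any(v > 0 for v in self.w.values()):
            raise ValueError("at least one weight must be positive")


# ---------------------------------------------------------------------------
# locus generation


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return bytes(BASES[rng.integers(0, 4, size=n)]).decode()


def _sense_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_SENSE_CODONS, size=n)) if n else ""


def _has_frame0_stop(seq: str) -> bool:
    return any(seq[i : i + 3] in STOPS for i in range(0, len(seq) - 2, 3))


def _right_arm(consensus: SfxConsensus, triplet: str) -> str:
    tmpl = consensus.right_arm_template
    return tmpl[:6] + triplet + tmpl[9:]


def _left_arm_for_minus_orf(rng: np.random.Generator) -> str:
    """Left arm whose reverse complement is stop-free in frame 0."""
    while True:
        arm = _random_seq(rng, ARM_LEN)
        if not _has_frame0_stop(str(Seq(arm).reverse_complement())):
            return arm


def generate_locus(config: GeneratorConfig | None = None) -> tuple[ShufflonLocus, GroundTruth]:
    """Emit a TP114-like shufflon locus plus its full ground truth.

    Layout: 5' flank | constant pilV coding (ending with the first site's
    left arm + core, in frame) | n cassettes separated by site cores, each
    cassette carrying the upstream site's right arm, a plus-strand ORF, a
    spacer, a convergent minus-strand ORF and the downstream site's left
    arm | the last site's right arm | 3' constant region toward rci.
    Deterministic given ``config.seed``.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_cassettes
    if n > len(DEFAULT_LABELS):
        raise ValueError(f"at most {len(DEFAULT_LABELS)} cassettes supported")
    consensus = config.sfx_consensus
    core = consensus.core
    lo, hi = config.variant_codon_range

    # constant coding region: ATG + sense codons, tail overwritten with the
    # first site's left arm + core; resample the arm until the frame stays
    # stop-free across the straddling codons
    coding_len = 3 * config.constant5_codons
    if coding_len < SITE_LEN:
        raise ValueError("constant region too short to carry the first sfx site tail")
    body = "ATG" + _sense_codons(rng, config.constant5_codons - 1)
    for _ in range(1000):
        left0 = _random_seq(rng, ARM_LEN)
        coding = body[: coding_len - ARM_LEN - CORE_LEN] + left0 + core
        if "*" not in str(Seq(coding).translate(table=11)):
            break
    else:  # pragma: no cover - vanishingly unlikely
        raise RuntimeError("could not build a stop-free constant region tail")

    right_arms = [_right_arm(consensus, TRIPLET_CYCLE[i % 3]) for i in range(n + 1)]
    labels = list(DEFAULT_LABELS[:n])

    parts = [_random_seq(rng, config.flank5_len), coding]
    cds_start = config.flank5_len
    pos = config.flank5_len + coding_len  # == first core end
    site_core_starts = [pos - CORE_LEN]
    cassette_coords: list[tuple[int, int]] = []
    orf_lengths: dict[str, int] = {}

    for i in range(1, n + 1):
        len_plus = int(rng.integers(lo, hi + 1))
        len_minus = int(rng.integers(lo, hi + 1))
        lp, lm = labels[i - 1]
        orf_lengths[lp], orf_lengths[lm] = len_plus, len_minus

        plus_part = (
            right_arms[i - 1]
            + _sense_codons(rng, len_plus - ARM_LEN // 3)
            + str(rng.choice(STOPS))
        )
        left_i = _left_arm_for_minus_orf(rng)
        minus_orf = (
            str(Seq(left_i).reverse_complement())
            + _sense_codons(rng, len_minus - ARM_LEN // 3)
            + str(rng.choice(STOPS))
        )
        spacer = _random_seq(rng, int(rng.integers(*config.spacer_range)))
        cassette = plus_part + spacer + str(Seq(minus_orf).reverse_complement())

        cassette_coords.append((pos, pos + len(cassette)))
        parts.append(cassette)
        pos += len(cassette)
        site_core_starts.append(pos)
        parts.append(core)
        pos += CORE_LEN

    parts.append(right_arms[n])
    parts.append(_random_seq(rng, config.constant3_len))
    sequence = "".join(parts)

    sites = []
    for idx, cs in enumerate(site_core_starts):
        start, end = cs - ARM_LEN, cs + CORE_LEN + ARM_LEN
        left = sequence[start:cs]
        right = sequence[cs + CORE_LEN : end]
        triplet = right[6:9]
        sites.append(
            SfxSite(
                start=start,
                end=end,
                strand="+",
                core_seq=core,
                left_arm=left,
                right_arm=right,
                variable_triplet=triplet,
                triplet_label=TRIPLET_LABELS.get(triplet),
            )
        )

    cassettes = tuple(
        (
            (start, end),
            CassetteSpec(
                id=i + 1,
                label_plus=labels[i][0],
                label_minus=labels[i][1],
                length_bp=end - start,
            ),
        )
        for i, (start, end) in enumerate(cassette_coords)
    )
    locus = ShufflonLocus(
        sequence=sequence,
        sites=tuple(sites),
        constant5=(0, sites[0].core_start),
        cassettes=cassettes,
        constant3=(sites[-1].core_end, len(sequence)),
        cds_start=cds_start,
    )
    truth = GroundTruth(
        seed=config.seed,
        cds_start=cds_start,
        site_coords=[(s.start, s.end) for s in sites],
        cassette_coords=cassette_coords,
        orf_lengths_aa=orf_lengths,
        labels=labels,
        locus_length=len(sequence),
    )
    return locus, truth


# ---------------------------------------------------------------------------
# population dynamics


def simulate_dynamics(
    model: ShufflonModel,
    n_cells: int,
    n_steps: int,
    inversion_prob: float,
    seed: int = 0,
) -> PopulationState:
    """Per-cell shufflon rearrangement under a shufflase of given activity.

    Every cell starts at the identity conformation. At each step a cell
    recombines with probability ``inversion_prob``, applying one block
    reversal with the block chosen uniformly over all contiguous position
    pairs. ``inversion_prob = 0`` models the shufflase deletion: the
    population stays locked in its starting conformation. The move set is
    symmetric, so the chain's stationary law is uniform over all states.
    """
    if n_cells <= 0 or n_steps <= 0:
        raise ValueError("n_cells and n_steps must be positive")
    if not (0.0 <= inversion_prob <= 1.0):
        raise ValueError("inversion_prob must be in [0, 1]")
    states = enumerate_conformations(model)
    index = {c.canonical_key: i for i, c in enumerate(states)}
    moves = [(i, j) for i in range(model.n) for j in range(i, model.n)]
    transition = np.empty((len(states), len(moves)), dtype=np.int32)
    for si, conf in enumerate(states):
        for mi, (i, j) in enumerate(moves):
            transition[si, mi] = index[invert_block(conf, i, j).canonical_key]

    rng = np.random.default_rng(seed)
    cell_states = np.full(n_cells, index[model.identity_conformation().canonical_key], dtype=np.int32)
    if moves and inversion_prob > 0:
        for _ in range(n_steps):
            mask = rng.random(n_cells) < inversion_prob
            k = int(mask.sum())
            if k:
                cell_states[mask] = transition[
                    cell_states[mask], rng.integers(0, len(moves), size=k)
                ]
    counts = np.bincount(cell_states, minlength=len(states))
    return PopulationState(
        freq={states[i]: counts[i] / n_cells for i in np.flatnonzero(counts)}
    )


def variant_marginal(population: PopulationState, model: ShufflonModel) -> dict[str, float]:
    """Collapse a conformation distribution to active-variant frequencies."""
    out: dict[str, float] = {lab: 0.0 for lab in model.variant_labels}
    for conf, f in population.freq.items():
        out[active_variant(conf, model)] += f
    return out


def population_from_variant_freqs(
    model: ShufflonModel, freqs: Mapping[str, float]
) -> PopulationState:
    """One canonical conformation per variant: that cassette first, rest in order.

    Useful when only variant frequencies (not full conformation
    distributions) are specified.
    """
    total = sum(freqs.values())
    if total <= 0:
        raise ValueError("variant frequencies must have positive total")
    conf_freq: dict[Conformation, float] = {}
    for label, f in freqs.items():
        if f == 0:
            continue
        target = None
        for c in model.cassettes:
            if c.label_plus == label:
                target, ori = c, "+"
                break
            if c.label_minus == label:
                target, ori = c, "-"
                break
        if target is None:
            raise KeyError(f"no cassette carries variant {label!r}")
        rest = tuple((c.id, "+") for c in model.cassettes if c.id != target.id)
        conf_freq[Conformation(((target.id, ori),) + rest)] = f / total
    return PopulationState(freq=conf_freq)


# ---------------------------------------------------------------------------
# transfer selection


def simulate_selection(
    donor_variant_freq: Mapping[str, float],
    weights: CompatibilityWeights | Mapping[str, float],
) -> dict[str, float]:
    """Deterministic variant-specific transfer: f_trans(v) ∝ f(v) * w(v)."""
    w = weights.w if isinstance(weights, CompatibilityWeights) else weights
    total_in = sum(donor_variant_freq.values())
    if abs(total_in - 1.0) > 1e-9:
        raise ValueError(f"donor frequencies must sum to 1, got {total_in}")
    raw = {v: f * w.get(v, 0.0) for v, f in donor_variant_freq.items()}
    z = sum(raw.values())
    if z <= 0:
        raise ValueError("no variant both present in the donor and transfer-competent")
    return {v: x / z for v, x in raw.items()}


# ---------------------------------------------------------------------------
# read simulation


_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


def _open_text_write(path: Path):
    """Text writer; gzip output uses a zeroed mtime so identical content
    yields identical bytes (the determinism contract)."""
    if path.suffix == ".gz":
        import io

        gz = gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"), mtime=0)
        return io.TextIOWrapper(gz)
    return open(path, "w")


def simulate_reads(
    locus: ShufflonLocus,
    population: PopulationState | Mapping[str, float],
    config: GeneratorConfig,
    fastq_path: str | Path,
    truth_path: str | Path | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw single-end reads from a conformation mixture, with errors.

    Each read's source conformation is drawn multinomially from the
    population; the start position and strand are uniform; substitution
    errors are independent per base at ``config.error_rate``; base qualities
    are a uniform high constant. The returned truth table records every
    read's source conformation, active variant, start, strand and error
    count. Deterministic given the seed (``config.seed`` unless overridden).
    """
    model = locus.to_model()
    if not isinstance(population, PopulationState):
        population = population_from_variant_freqs(model, population)
    confs = sorted(population.freq, key=lambda c: c.canonical_key)
    probs = np.array([population.freq[c] for c in confs])
    probs = probs / probs.sum()
    seqs = [conformation_sequence(locus, c) for c in confs]
    labels = [active_variant(c, model) for c in confs]
    rl = config.read_length
    if any(rl > len(s) for s in seqs):
        raise ValueError(f"read_length {rl} exceeds the conformation sequence length")

    rng = np.random.default_rng(config.seed if seed is None else seed)
    src = rng.choice(len(confs), size=config.depth, p=probs)
    seq_arrays = [np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs]
    starts = rng.integers(0, [len(seqs[i]) - rl + 1 for i in src])
    strands = rng.integers(0, 2, size=config.depth)
    qual = "I" * rl

    fastq_path = Path(fastq_path)
    rows = []
    with _open_text_write(fastq_path) as fh:
        for ridx in range(config.depth):
            ci, start, minus = int(src[ridx]), int(starts[ridx]), bool(strands[ridx])
            read = seq_arrays[ci][start : start + rl]
            if minus:
                read = np.frombuffer(
                    bytes(read).translate(_COMPLEMENT)[::-1], dtype=np.uint8
                )
            n_err = rng.binomial(rl, config.error_rate) if config.error_rate else 0
            if n_err:
                read = read.copy()
                pos = rng.choice(rl, size=n_err, replace=False)
                for p in pos:
                    choices = BASES[BASES != read[p]]
                    read[p] = rng.choice(choices)
            name = f"read_{ridx}"
            fh.write(f"@{name}\n{bytes(read).decode()}\n+\n{qual}\n")
            rows.append(
                {
                    "read_id": name,
                    "conformation": confs[ci].canonical_key,
                    "variant": labels[ci],
                    "start": start,
                    "strand": "-" if minus else "+",
                    "n_errors": int(n_err),
                }
            )
    truth = pd.DataFrame(rows)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return truth


# ---------------------------------------------------------------------------
# locus writers


def locus_to_fasta(locus: ShufflonLocus, path: str | Path, name: str = "synthetic_shufflon") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(locus.sequence), 70):
            fh.write(locus.sequence[i : i + 70] + "\n")


def locus_to_genbank(locus: ShufflonLocus, path: str | Path, name: str = "synthetic_shufflon") -> None:
    """Write the locus with pilV-constant CDS and misc_recomb site features."""
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    record = SeqRecord(
        Seq(locus.sequence), id=name, name=name[:16], description="synthetic shufflon locus"
    )
    record.annotations["molecule_type"] = "DNA"
    record.features.append(
        SeqFeature(
            SimpleLocation(locus.cds_start, locus.sites[0].core_end, strand=1),
            type="CDS",
            qualifiers={"gene": ["pilV"], "note": ["constant region"]},
        )
    )
    for i, s in enumerate(locus.sites):
        record.features.append(
            SeqFeature(
                SimpleLocation(s.start, s.end, strand=1 if s.strand == "+" else -1),
                type="misc_recomb",
                qualifiers={"note": [f"sfx site {i}"]},
            )
        )
    for (start, end), spec in locus.cassettes:
        record.features.append(
            SeqFeature(
                SimpleLocation(start, end, strand=1),
                type="misc_feature",
                qualifiers={
                    "note": [f"invertible segment {spec.id} ({spec.label_plus}/{spec.label_minus})"]
                },
            )
        )
    SeqIO.write(record, str(path), "genbank")
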