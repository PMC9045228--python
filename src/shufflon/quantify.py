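"""Junction-signature generation and read-based pilV variant quantification.

Each (cassette, orientation) pair expressible at the front of the shufflon
yields a short junction footprint — by default 39 bp spanning the pilV 3' end
and the adjacent cassette — that is unique to one variant. Counting these
footprints directly in raw FASTQ reads (both strands, exact match) gives
per-variant read counts; relative abundance is each variant's count over the
total footprint-positive reads. Donor-vs-transconjugant enrichment is
reported as a pseudocounted log2 frequency ratio, and conjugation frequency
as transconjugants per recipient CFU with limit-of-detection censoring.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from math import log2
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .locus import ShufflonLocus

__all__ = [
    "VariantSignature",
    "CountTable",
    "AbundanceTable",
    "EnrichmentResult",
    "ConjugationFrequency",
    "SignatureCollisionError",
    "UndefinedAbundanceError",
    "make_signatures",
    "count_footprints",
    "relative_abundance",
    "enrichment",
    "conjugation_frequency",
    "signatures_to_fasta",
    "counts_to_frame",
]

DEFAULT_K = 39
DEFAULT_C = 19  # constant-side bases: 12 bp upstream of the core + the 7-bp core

#: in vitro / in vivo limits of detection for conjugation frequency
LOD_IN_VITRO = 1e-8
LOD_IN_VIVO = 1e-5


class SignatureCollisionError(ValueError):
    """Two variants share an irreducibly identical junction footprint."""


class UndefinedAbundanceError(ValueError):
    """No read matched any signature: relative abundance is undefined."""


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class VariantSignature:
    """The k-bp footprint identifying one variant at the pilV junction."""

    label: str
    kmer: str
    c: int  # bases contributed by the constant side (core included)

    @property
    def k(self) -> int:
        return len(self.kmer)


@dataclass
class CountTable:
    counts: dict[str, int]
    n_reads_scanned: int
    ambiguous: int = 0

    @property
    def total_positive(self) -> int:
        return sum(self.counts.values())

    @property
    def unmatched(self) -> int:
        return self.n_reads_scanned - self.total_positive - self.ambiguous


@dataclass
class AbundanceTable:
    freq: dict[str, float]
    total_positive: int


@dataclass
class EnrichmentResult:
    log2fc: dict[str, float]
    pseudocount: float


@dataclass(frozen=True)
class ConjugationFrequency:
    value: float
    censored: bool


# ---------------------------------------------------------------------------
# signatures


def _junction_kmers(locus: ShufflonLocus, k: int, c: int) -> list[VariantSignature]:
    const_end = locus.sites[0].core_end
    if c < 1 or c >= k:
        raise ValueError(f"require 1 <= c < k, got c={c}, k={k}")
    if const_end < c:
        raise ValueError("constant region shorter than the constant-side window")
    const_side = locus.sequence[const_end - c : const_end]
    sigs = []
    for idx, (_, spec) in enumerate(locus.cassettes):
        for ori, label in (("+", spec.label_plus), ("-", spec.label_minus)):
            cass = locus.cassette_seq(idx, ori)
            if len(cass) < k - c:
                raise ValueError(
                    f"cassette {spec.id} ({len(cass)} bp) shorter than the "
                    f"cassette-side window ({k - c} bp)"
                )
            sigs.append(VariantSignature(label=label, kmer=const_side + cass[: k - c], c=c))
    return sigs


def make_signatures(
    locus: ShufflonLocus, k: int = DEFAULT_K, c: int = DEFAULT_C, max_k: int = 101
) -> list[VariantSignature]:
    """One junction footprint per (cassette, orientation) pair — 2n in total.

    Each footprint is the last ``c`` constant-side bases (ending at the first
    core's 3' boundary, core included) followed by the first ``k - c`` bases
    of the cassette in the given orientation. Footprints must be pairwise
    distinct and distinct from each other's reverse complements; on a
    collision ``k`` is grown symmetrically (one base each side) until unique.
    """
    while True:
        sigs = _junction_kmers(locus, k, c)
        kmers = [s.kmer for s in sigs]
        pool = kmers + [_revcomp(m) for m in kmers]
        if len(set(pool)) == 2 * len(kmers):
            return sigs
        if k + 2 > max_k:
            dupes = {m for m in kmers if kmers.count(m) > 1}
            raise SignatureCollisionError(
                f"footprints not unique at k<={max_k}; colliding labels: "
                f"{sorted(s.label for s in sigs if s.kmer in dupes)}"
            )
        k += 2
        c += 1


# ---------------------------------------------------------------------------
# counting


def _iter_fastq(paths: Sequence[str | Path]):
    """Yield read sequences from one or more FASTQ(.gz) files."""
    for path in paths:
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            idx = 0
            while True:
                header = fh.readline()
                if not header:
                    break
                seq = fh.readline().rstrip("\n")
                plus = fh.readline()
                qual = fh.readline().rstrip("\n")
                if not header.startswith("@") or not plus.startswith("+") or not qual:
                    raise ValueError(f"{path}: malformed FASTQ record at index {idx}")
                if len(qual) != len(seq):
                    raise ValueError(
                        f"{path}: sequence/quality length mismatch at record {idx}"
                    )
                yield seq.upper()
                idx += 1


def count_footprints(
    reads: str | Path | Sequence[str | Path],
    signatures: Sequence[VariantSignature],
    max_mismatches: int = 0,
    count_mode: str = "per_read",
) -> CountTable:
    """Count variant footprints directly in raw FASTQ reads.

    A read is positive for a variant when it, or its reverse complement,
    contains that variant's footprint as an exact substring (mismatched
    matching is not supported; ``max_mismatches`` must be 0). Reads positive
    for two or more distinct variants are tallied as ambiguous and excluded.
    ``per_read`` counts each read at most once per variant; ``per_occurrence``
    counts every occurrence on both strands. No quality or length filtering
    is applied.
    """
    if max_mismatches != 0:
        raise NotImplementedError("only exact footprint matching is supported")
    if count_mode not in {"per_read", "per_occurrence"}:
        raise ValueError(f"unknown count_mode {count_mode!r}")
    if not signatures:
        raise ValueError("no signatures supplied")
    kmers = [(s.label, s.kmer, _revcomp(s.kmer)) for s in signatures]
    if len({s.label for s in signatures}) != len(signatures):
        raise ValueError("signature labels must be distinct")

    if isinstance(reads, (str, Path)):
        reads = [reads]

    counts = {s.label: 0 for s in signatures}
    n_scanned = 0
    ambiguous = 0
    for seq in _iter_fastq(reads):
        n_scanned += 1
        if count_mode == "per_read":
            hits = [label for label, fwd, rev in kmers if fwd in seq or rev in seq]
            if len(hits) == 1:
                counts[hits[0]] += 1
            elif len(hits) > 1:
                ambiguous += 1
        else:
            occ = {
                label: seq.count(fwd) + seq.count(rev) for label, fwd, rev in kmers
            }
            positive = [label for label, n in occ.items() if n > 0]
            if len(positive) == 1:
                counts[positive[0]] += occ[positive[0]]
            elif len(positive) > 1:
                ambiguous += 1
    return CountTable(counts=counts, n_reads_scanned=n_scanned, ambiguous=ambiguous)


# ---------------------------------------------------------------------------
# abundances / enrichment / conjugation frequency


def relative_abundance(table: CountTable) -> AbundanceTable:
    """Per-variant frequency among footprint-positive reads."""
    total = table.total_positive
    if total == 0:
        raise UndefinedAbundanceError(
            "no read matched any variant footprint; relative abundance undefined"
        )
    return AbundanceTable(
        freq={label: n / total for label, n in table.counts.items()},
        total_positive=total,
    )


def enrichment(
    donor: AbundanceTable, trans: AbundanceTable, pseudocount: float | None = None
) -> EnrichmentResult:
    """Pseudocounted log2 ratio of transconjugant over donor frequencies.

    The default pseudocount is one read in the shallower sample,
    ``1 / min(total_positive)``, so a variant absent from one table gets a
    finite, depth-calibrated fold change. Variants missing from either table
    enter with frequency 0.
    """
    if pseudocount is None:
        pseudocount = 1.0 / min(donor.total_positive, trans.total_positive)
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    labels = sorted(set(donor.freq) | set(trans.freq))
    log2fc = {
        lab: log2(
            (trans.freq.get(lab, 0.0) + pseudocount)
            / (donor.freq.get(lab, 0.0) + pseudocount)
        )
        for lab in labels
    }
    return EnrichmentResult(log2fc=log2fc, pseudocount=pseudocount)


def conjugation_frequency(
    transconjugant_cfu: float, recipient_cfu: float, lod: float = LOD_IN_VITRO
) -> ConjugationFrequency:
    """Transconjugants per recipient CFU, floored at the limit of detection.

    When no transconjugant is observed, or the ratio falls below ``lod``, the
    value is reported as ``lod`` with ``censored=True``.
    """
    if transconjugant_cfu < 0 or recipient_cfu <= 0:
        raise ValueError("CFU counts must be non-negative and recipients positive")
    if lod <= 0:
        raise ValueError("limit of detection must be positive")
    value = transconjugant_cfu / recipient_cfu
    if transconjugant_cfu == 0 or value < lod:
        return ConjugationFrequency(value=lod, censored=True)
    return ConjugationFrequency(value=value, censored=False)


# ---------------------------------------------------------------------------
# output helpers


def signatures_to_fasta(signatures: Iterable[VariantSignature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in signatures:
            fh.write(f">{s.label} k={s.k} c={s.c}\n{s.kmer}\n")


def counts_to_frame(
    table: CountTable,
    abundance: AbundanceTable | None = None,
    sample: str = "sample",
) -> pd.DataFrame:
    rows = []
    for label in sorted(table.counts):
        rows.append(
            {
                "sample": sample,
                "variant": label,
                "count": table.counts[label],
                "frequency": abundance.freq[label] if abundance else float("nan"),
            }
        )
    return pd.DataFrame(rows)
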