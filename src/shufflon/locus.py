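"""Shufflon locus parsing: sfx-site detection, segmentation, ORF extraction.

The physical locus is the 3' end of *pilV*: a constant coding region whose
tail carries the first *sfx* recombination site, then n invertible cassettes
separated by further sfx sites, then the region running toward *rci*. An sfx
site is a 31-bp footprint: a nonconserved 12-bp left arm, a conserved 7-bp
core where crossover occurs, and a conserved 12-bp right arm whose positions
7-9 hold a variable triplet (the e/f/g repeats of IncI2 shufflons).

Coordinates are 0-based half-open throughout; minus-strand sites are reported
by their plus-strand footprint. Cassettes are the intervals strictly between
consecutive site cores, so each cassette carries the right arm of the
upstream site and the left arm of the downstream one — these move with the
cassette during inversion, as in the natural system.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .model import DEFAULT_LABELS, CassetteSpec, Conformation, ShufflonModel

__all__ = [
    "SfxConsensus",
    "SfxSite",
    "ShufflonLocus",
    "VariantProtein",
    "LocusFormatError",
    "InsufficientSitesError",
    "AnnotationError",
    "DEFAULT_CONSENSUS",
    "read_locus",
    "find_sfx_sites",
    "build_locus",
    "extract_variants",
    "consensus_matrix",
    "conformation_sequence",
    "sites_to_bed",
    "variants_to_fasta",
]

ARM_LEN = 12
CORE_LEN = 7
SITE_LEN = 2 * ARM_LEN + CORE_LEN  # 31
#: 1-based positions of the variable triplet within the right arm
TRIPLET_SLICE = slice(6, 9)
#: the e/f/g variable triplets of the IncI2 repeat family
TRIPLET_LABELS = {"GTG": "e", "ATC": "f", "TCG": "g"}

BACTERIAL_TABLE = 11


class LocusFormatError(ValueError):
    """Unparsable or empty locus file."""


class InsufficientSitesError(ValueError):
    """Fewer than two sfx sites: no cassette can be delimited."""


class AnnotationError(ValueError):
    """Locus features inconsistent with the shufflon architecture."""


@dataclass(frozen=True)
class SfxConsensus:
    """Search model for sfx sites.

    ``core`` must match exactly; ``right_arm_template`` is matched at its
    non-``N`` positions with at most ``max_mismatches`` substitutions. The
    left arm is nonconserved and recorded but never matched.
    """

    core: str
    right_arm_template: str
    left_arm_len: int = ARM_LEN
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        if len(self.core) != CORE_LEN:
            raise ValueError(f"core must be {CORE_LEN} bp, got {self.core!r}")
        if len(self.right_arm_template) != ARM_LEN:
            raise ValueError(
                f"right arm template must be {ARM_LEN} bp, got {self.right_arm_template!r}"
            )


#: bundled synthetic consensus used by the data generator; real analyses
#: should supply the consensus of their own plasmid
DEFAULT_CONSENSUS = SfxConsensus(core="GTGCCAC", right_arm_template="GCAGTTNNNGGC")


@dataclass(frozen=True)
class SfxSite:
    start: int  # footprint start (left-arm start), 0-based
    end: int  # footprint end (right-arm end), half-open
    strand: str
    core_seq: str
    left_arm: str
    right_arm: str
    variable_triplet: str
    triplet_label: str | None = None

    def __post_init__(self) -> None:
        if self.end - self.start != SITE_LEN:
            raise ValueError(f"sfx footprint must span {SITE_LEN} bp")

    @property
    def core_start(self) -> int:
        """Plus-strand coordinate of the core, regardless of site strand."""
        return self.start + ARM_LEN if self.strand == "+" else self.start + ARM_LEN

    @property
    def core_end(self) -> int:
        return self.core_start + CORE_LEN


@dataclass(frozen=True)
class VariantProtein:
    label: str
    aa_seq: str

    @property
    def length_aa(self) -> int:
        return len(self.aa_seq)


@dataclass(frozen=True)
class ShufflonLocus:
    """A segmented shufflon locus.

    ``constant5`` runs from the locus start to the first site core;
    ``cassettes`` are ``((start, end), CassetteSpec)`` pairs between
    consecutive cores; ``constant3`` runs from the last core end to the locus
    end. ``cds_start`` anchors the pilV reading frame.
    """

    sequence: str
    sites: tuple[SfxSite, ...]
    constant5: tuple[int, int]
    cassettes: tuple[tuple[tuple[int, int], CassetteSpec], ...]
    constant3: tuple[int, int]
    cds_start: int = 0

    @property
    def n_cassettes(self) -> int:
        return len(self.cassettes)

    def cassette_seq(self, index: int, orientation: str = "+") -> str:
        (start, end), _ = self.cassettes[index]
        seg = self.sequence[start:end]
        return seg if orientation == "+" else str(Seq(seg).reverse_complement())

    @property
    def core_seq(self) -> str:
        first = self.sites[0]
        return self.sequence[first.core_start : first.core_end]

    def to_model(self) -> ShufflonModel:
        return ShufflonModel(tuple(spec for _, spec in self.cassettes))


# ---------------------------------------------------------------------------
# reading


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_locus(path: str | Path, format: str | None = None):
    """Read a locus record from GenBank or FASTA (optionally gzipped).

    Returns ``(sequence, features)`` where ``features`` is the record's
    Biopython feature list (empty for FASTA); ``misc_recomb`` features, when
    present, can seed site detection instead of a motif scan.
    """
    path = Path(path)
    if format is None:
        stem = path.name[:-3] if path.name.endswith(".gz") else path.name
        ext = Path(stem).suffix.lower()
        format = "genbank" if ext in {".gb", ".gbk", ".genbank"} else "fasta"
    if format not in {"genbank", "fasta"}:
        raise LocusFormatError(f"unsupported format {format!r}")
    try:
        with _open_maybe_gzip(path) as fh:
            record = next(SeqIO.parse(fh, format), None)
    except (ValueError, StopIteration) as exc:
        raise LocusFormatError(f"could not parse {path} as {format}: {exc}") from exc
    if record is None or len(record.seq) == 0:
        raise LocusFormatError(f"{path}: no sequence found")
    return str(record.seq).upper(), list(record.features)


# ---------------------------------------------------------------------------
# site detection


def _arm_mismatches(arm: str, template: str) -> int:
    return sum(1 for a, t in zip(arm, template) if t != "N" and a != t)


def _scan_strand(sequence: str, consensus: SfxConsensus) -> list[tuple[int, int]]:
    """Yield (footprint_start, arm_mismatches) for core-anchored matches."""
    hits = []
    core = consensus.core
    pos = sequence.find(core, ARM_LEN)
    while pos != -1:
        start = pos - ARM_LEN
        end = pos + CORE_LEN + ARM_LEN
        if end <= len(sequence):
            arm = sequence[pos + CORE_LEN : end]
            mm = _arm_mismatches(arm, consensus.right_arm_template)
            if mm <= consensus.max_mismatches:
                hits.append((start, mm))
        pos = sequence.find(core, pos + 1)
    return hits


def find_sfx_sites(
    sequence: str, consensus: SfxConsensus = DEFAULT_CONSENSUS
) -> list[SfxSite]:
    """Motif-scan both strands for sfx sites.

    The 7-bp core must match exactly; the right arm matches the template at
    non-wildcard positions with at most ``consensus.max_mismatches``
    substitutions. Overlapping candidates are resolved leftmost-first.
    Returned sites are sorted by plus-strand footprint start.
    """
    sequence = sequence.upper()
    rc = str(Seq(sequence).reverse_complement())
    n = len(sequence)
    candidates: list[tuple[int, str]] = []
    for start, _ in _scan_strand(sequence, consensus):
        candidates.append((start, "+"))
    for start_rc, _ in _scan_strand(rc, consensus):
        # mirror the footprint back to plus-strand coordinates
        candidates.append((n - (start_rc + SITE_LEN), "-"))
    candidates.sort()

    sites: list[SfxSite] = []
    last_end = -1
    for start, strand in candidates:
        if start < last_end:  # overlap: leftmost-first wins
            continue
        end = start + SITE_LEN
        footprint = sequence[start:end]
        oriented = footprint if strand == "+" else str(Seq(footprint).reverse_complement())
        left, core, right = (
            oriented[:ARM_LEN],
            oriented[ARM_LEN : ARM_LEN + CORE_LEN],
            oriented[ARM_LEN + CORE_LEN :],
        )
        triplet = right[TRIPLET_SLICE]
        sites.append(
            SfxSite(
                start=start,
                end=end,
                strand=strand,
                core_seq=core,
                left_arm=left,
                right_arm=right,
                variable_triplet=triplet,
                triplet_label=TRIPLET_LABELS.get(triplet),
            )
        )
        last_end = end
    return sites


# ---------------------------------------------------------------------------
# segmentation


def build_locus(
    sequence: str,
    sites: Sequence[SfxSite],
    constant5_hint: int = 0,
    labels: Sequence[tuple[str, str]] | None = None,
) -> ShufflonLocus:
    """Segment a sequence into constant regions and cassettes.

    Cassettes are the intervals strictly between consecutive site cores;
    ``constant5`` ends at the first core, ``constant3`` begins after the last.
    ``constant5_hint`` is the pilV CDS start anchoring the reading frame —
    taken from annotation when available, never inferred from ORF scans.
    """
    if len(sites) < 2:
        raise InsufficientSitesError(
            f"need at least 2 sfx sites to delimit a cassette, got {len(sites)}"
        )
    sites = tuple(sorted(sites, key=lambda s: s.start))
    sequence = sequence.upper()
    if labels is None:
        labels = DEFAULT_LABELS
    cassettes = []
    for idx in range(len(sites) - 1):
        start = sites[idx].core_end
        end = sites[idx + 1].core_start
        if end <= start:
            raise AnnotationError(f"sites {idx} and {idx + 1} leave no cassette between cores")
        lp, lm = labels[idx]
        spec = CassetteSpec(id=idx + 1, label_plus=lp, label_minus=lm, length_bp=end - start)
        cassettes.append(((start, end), spec))
    return ShufflonLocus(
        sequence=sequence,
        sites=sites,
        constant5=(0, sites[0].core_start),
        cassettes=tuple(cassettes),
        constant3=(sites[-1].core_end, len(sequence)),
        cds_start=constant5_hint,
    )


# ---------------------------------------------------------------------------
# translation


def _translate(seq: str, table: int = BACTERIAL_TABLE) -> str:
    return str(Seq(seq).translate(table=table))


def extract_variants(
    locus: ShufflonLocus, genetic_code: int = BACTERIAL_TABLE
) -> tuple[str, list[VariantProtein]]:
    """Translate the constant pilV region and every variant C-terminus.

    The constant region runs in frame from the CDS start to the first core's
    end (the crossover boundary); each cassette then contributes, per
    orientation, the in-frame continuation up to its stop codon — the
    C-terminus fused to PilV when that cassette sits first in that
    orientation. Stop codons are excluded from reported lengths.
    """
    first_core_end = locus.sites[0].core_end
    const_nt = locus.sequence[locus.cds_start : first_core_end]
    if len(const_nt) % 3 != 0:
        raise AnnotationError(
            f"constant region length {len(const_nt)} is not a multiple of 3; "
            "check the CDS start / frame hint"
        )
    const_aa = _translate(const_nt, genetic_code)
    if "*" in const_aa:
        raise AnnotationError("internal stop codon in the constant pilV region")

    variants: list[VariantProtein] = []
    for idx, (_, spec) in enumerate(locus.cassettes):
        for ori, label in (("+", spec.label_plus), ("-", spec.label_minus)):
            cseq = locus.cassette_seq(idx, ori)
            aa = _translate(cseq[: len(cseq) - len(cseq) % 3], genetic_code)
            stop = aa.find("*")
            if stop == -1:
                raise AnnotationError(
                    f"cassette {spec.id} orientation {ori}: no in-frame stop codon"
                )
            variants.append(VariantProtein(label=label, aa_seq=aa[:stop]))
    return const_aa, variants


# ---------------------------------------------------------------------------
# consensus


def consensus_matrix(sites: Sequence[SfxSite]) -> pd.DataFrame:
    """Position-frequency matrix over the 31-bp footprints of aligned sites.

    Rows A/C/G/T hold per-position counts; the returned frame carries the
    majority-consensus string and per-position conservation flags as
    ``df.attrs['consensus']`` / ``df.attrs['conserved']``.
    """
    if not sites:
        raise ValueError("need at least one site")
    seqs = [s.left_arm + s.core_seq + s.right_arm for s in sites]
    if any(len(s) != SITE_LEN for s in seqs):
        raise ValueError("all sites must have 31-bp footprints")
    bases = "ACGT"
    counts = np.zeros((4, SITE_LEN), dtype=int)
    for s in seqs:
        for j, b in enumerate(s):
            counts[bases.index(b), j] += 1
    df = pd.DataFrame(counts, index=list(bases), columns=range(1, SITE_LEN + 1))
    consensus = "".join(bases[i] for i in counts.argmax(axis=0))
    conserved = (counts.max(axis=0) == len(seqs)).tolist()
    df.attrs["consensus"] = consensus
    df.attrs["conserved"] = conserved
    return df


# ---------------------------------------------------------------------------
# conformation sequences


def conformation_sequence(locus: ShufflonLocus, conf: Conformation) -> str:
    """Full locus sequence of one shufflon conformation.

    The constant flanks and site cores are fixed; cassette slots are filled
    with the (possibly inverted) cassettes in the conformation's order. The
    identity conformation reproduces ``locus.sequence`` exactly.
    """
    if len(conf) != locus.n_cassettes:
        raise ValueError(
            f"conformation has {len(conf)} cassettes, locus has {locus.n_cassettes}"
        )
    id_to_index = {spec.id: i for i, (_, spec) in enumerate(locus.cassettes)}
    core = locus.core_seq
    parts = [locus.sequence[: locus.sites[0].core_end]]
    for cid, ori in conf:
        parts.append(locus.cassette_seq(id_to_index[cid], ori))
        parts.append(core)
    parts.append(locus.sequence[locus.sites[-1].core_end :])
    return "".join(parts)


# ---------------------------------------------------------------------------
# tabular / FASTA output


def sites_to_bed(sites: Sequence[SfxSite], name: str = "locus") -> pd.DataFrame:
    """Sites as a BED-like table (chrom, start, end, name, score, strand)."""
    return pd.DataFrame(
        {
            "chrom": name,
            "start": [s.start for s in sites],
            "end": [s.end for s in sites],
            "name": [
                f"sfx_{i}" + (f"_{s.triplet_label}" if s.triplet_label else "")
                for i, s in enumerate(sites)
            ],
            "score": 0,
            "strand": [s.strand for s in sites],
        }
    )


def variants_to_fasta(
    constant_aa: str, variants: Iterable[VariantProtein], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(f">pilV_constant length={len(constant_aa)}\n{constant_aa}\n")
        for v in variants:
            fh.write(f">pilV_{v.label} length={v.length_aa}\n{v.aa_seq}\n")
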