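"""Combinatorial model of a shufflon multiple-DNA-inversion system.

A shufflon is a set of n invertible DNA cassettes downstream of the constant
5' region of the minor-pilin gene *pilV*, separated by site-specific
recombination (*sfx*) sites. The shufflase Rci recombines pairs of sites and
thereby reverses the block of cassettes between them: the cassettes in the
block appear in reversed order with every orientation flipped. A
*conformation* is one arrangement (order + orientation) of the cassettes; the
cassette adjacent to the constant region determines which of its two
convergent ORFs is fused in frame to PilV and hence which adhesin variant the
cell expresses.

Closing the identity arrangement under all contiguous block reversals
generates every signed permutation of the n cassettes: n! * 2**n states
(384 for n = 4), partitioned uniformly into 2n active-variant classes.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "CassetteSpec",
    "ShufflonModel",
    "Conformation",
    "invert_block",
    "enumerate_conformations",
    "active_variant",
    "count_active_variants",
    "tp114_like_model",
]

#: default variant labels in cassette order, two convergent ORFs per cassette
DEFAULT_LABELS = (
    ("A", "A'"),
    ("B", "B'"),
    ("C", "C'"),
    ("D", "D'"),
    ("E", "E'"),
    ("F", "F'"),
    ("G", "G'"),
    ("H", "H'"),
)


@dataclass(frozen=True)
class CassetteSpec:
    """One invertible cassette carrying two convergent variant ORFs.

    ``label_plus`` is the variant expressed when the cassette sits adjacent
    to the constant region in '+' orientation, ``label_minus`` in '-'.
    """

    id: int
    label_plus: str
    label_minus: str
    length_bp: int = 1

    def __post_init__(self) -> None:
        if self.label_plus == self.label_minus:
            raise ValueError(
                f"cassette {self.id}: convergent ORF labels must differ "
                f"({self.label_plus!r})"
            )
        if self.length_bp <= 0:
            raise ValueError(f"cassette {self.id}: length_bp must be positive")


@dataclass(frozen=True)
class ShufflonModel:
    """An ordered collection of cassettes; position 0 abuts the constant region."""

    cassettes: tuple[CassetteSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "cassettes", tuple(self.cassettes))
        ids = [c.id for c in self.cassettes]
        if len(set(ids)) != len(ids):
            raise ValueError(f"cassette ids must be distinct, got {ids}")
        labels = [lab for c in self.cassettes for lab in (c.label_plus, c.label_minus)]
        if len(set(labels)) != len(labels):
            raise ValueError(f"variant labels must be unique across the model: {labels}")

    @property
    def n(self) -> int:
        return len(self.cassettes)

    def cassette_by_id(self, cid: int) -> CassetteSpec:
        for c in self.cassettes:
            if c.id == cid:
                return c
        raise KeyError(f"no cassette with id {cid}")

    @property
    def variant_labels(self) -> tuple[str, ...]:
        """All 2n variant labels, in (cassette, +/-) order."""
        return tuple(
            lab for c in self.cassettes for lab in (c.label_plus, c.label_minus)
        )

    def identity_conformation(self) -> "Conformation":
        return Conformation(tuple((c.id, "+") for c in self.cassettes))


@dataclass(frozen=True, order=True)
class Conformation:
    """A signed permutation of cassette ids: ((id, '+'|'-'), ...).

    Equality is element-wise on the arrangement; the constant pilV region
    fixes an absolute frame, so no quotient by global flips is taken.
    """

    arrangement: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "arrangement", tuple(map(tuple, self.arrangement)))
        for cid, ori in self.arrangement:
            if ori not in ("+", "-"):
                raise ValueError(f"orientation must be '+' or '-', got {ori!r}")

    def __len__(self) -> int:
        return len(self.arrangement)

    def __iter__(self) -> Iterator[tuple[int, str]]:
        return iter(self.arrangement)

    @property
    def canonical_key(self) -> str:
        """Compact serialisation, e.g. ``"1+,3-,2+,4-"``; injective by construction."""
        return ",".join(f"{cid}{ori}" for cid, ori in self.arrangement)

    @classmethod
    def from_key(cls, key: str) -> "Conformation":
        """Parse the ``"1+,3-,2+"`` text form."""
        key = key.strip()
        if not key:
            return cls(())
        arrangement = []
        for tok in key.split(","):
            tok = tok.strip()
            if len(tok) < 2 or tok[-1] not in "+-":
                raise ValueError(f"malformed conformation token {tok!r} in {key!r}")
            arrangement.append((int(tok[:-1]), tok[-1]))
        return cls(tuple(arrangement))

    def __str__(self) -> str:
        return self.canonical_key


def invert_block(conf: Conformation, i: int, j: int) -> Conformation:
    """Reverse positions i..j inclusive, flipping every orientation.

    This is the Rci move: recombination between the sfx sites flanking the
    block inverts the intervening DNA, so cassette order reverses and each
    cassette's strand flips. The operation is an involution.
    """
    n = len(conf)
    if not (0 <= i <= j < n):
        raise IndexError(f"block [{i}, {j}] out of range for {n} cassettes")
    arr = conf.arrangement
    flipped = tuple(
        (cid, "-" if ori == "+" else "+") for cid, ori in reversed(arr[i : j + 1])
    )
    return Conformation(arr[:i] + flipped + arr[j + 1 :])


def enumerate_conformations(model: ShufflonModel) -> list[Conformation]:
    """All conformations reachable from the identity by block reversals.

    Breadth-first closure with a visited set keyed on ``canonical_key``;
    the result is sorted lexicographically on the key for reproducible
    iteration. For n >= 1 the closure is the full signed-permutation group
    element set: n! * 2**n states. n = 0 yields the single empty conformation.
    """
    start = model.identity_conformation()
    seen: dict[str, Conformation] = {start.canonical_key: start}
    queue = deque([start])
    n = model.n
    while queue:
        conf = queue.popleft()
        for i in range(n):
            for j in range(i, n):
                nxt = invert_block(conf, i, j)
                if nxt.canonical_key not in seen:
                    seen[nxt.canonical_key] = nxt
                    queue.append(nxt)
    return [seen[k] for k in sorted(seen)]


def active_variant(conf: Conformation, model: ShufflonModel) -> str:
    """Variant label fused in frame to the constant pilV region.

    The cassette at position 0 contributes its plus-strand ORF when in '+'
    orientation, its minus-strand ORF otherwise.
    """
    if len(conf) == 0:
        raise ValueError("empty conformation has no active variant")
    cid, ori = conf.arrangement[0]
    cassette = model.cassette_by_id(cid)
    return cassette.label_plus if ori == "+" else cassette.label_minus


def count_active_variants(model: ShufflonModel) -> int:
    """Number of distinct variants expressible over all conformations (2n)."""
    if model.n == 0:
        return 0
    return len({active_variant(c, model) for c in enumerate_conformations(model)})


def tp114_like_model(n_cassettes: int = 4) -> ShufflonModel:
    """A model with the TP114 architecture: n cassettes, labels A/A', B/B', ...

    Four cassettes give 384 conformations and eight PilV variants.
    """
    if n_cassettes > len(DEFAULT_LABELS):
        raise ValueError(f"no default labels beyond {len(DEFAULT_LABELS)} cassettes")
    return ShufflonModel(
        tuple(
            CassetteSpec(id=i + 1, label_plus=lp, label_minus=lm)
            for i, (lp, lm) in enumerate(DEFAULT_LABELS[:n_cassettes])
        )
    )
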