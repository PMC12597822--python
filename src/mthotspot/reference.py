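"""Circular mitochondrial genome coordinate system.

Human mtDNA is a closed circle of 16,569 bp; positions follow the rCRS
convention: 1-based, closed intervals, with ``m.N`` denoting position ``N``
(so ``m.1227`` is position 1227). The origin sits between positions 16569
and 1, and intervals (notably the control region) may wrap across it.

The :class:`MtReference` object bundles the sequence, the gene map, the
hypermutable blacklist and the control region, and provides the position
lookups shared by the filtering, hotspot and annotation stages:
trinucleotide contexts (wrap-aware), gene assignment, and region membership.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import cached_property
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(BASES)}

#: All 64 trinucleotide contexts in lexicographic order.
CONTEXTS = ["".join(t) for t in itertools.product(BASES, repeat=3)]
CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXTS)}

#: Hypermutable regions excluded from somatic calls, 1-based closed.
DEFAULT_BLACKLIST = ((513, 525), (3105, 3109))

#: rCRS control region (D-loop), wrapping the origin.
DEFAULT_CONTROL_REGION = (16024, 576)

RCRS_LENGTH = 16569


class PositionError(ValueError):
    """Raised for positions outside ``1..length``."""


def _interval_contains(start: int, end: int, pos: int) -> bool:
    """Membership in a closed interval; ``start > end`` means it wraps the origin."""
    if start <= end:
        return start <= pos <= end
    return pos >= start or pos <= end


@dataclass(frozen=True)
class Gene:
    """A gene on the mitochondrial genome (1-based closed interval)."""

    name: str
    start: int
    end: int
    strand: str  # "H" (heavy) or "L" (light)

    def __post_init__(self) -> None:
        if self.strand not in ("H", "L"):
            raise ValueError(f"strand must be 'H' or 'L', got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError(f"gene {self.name}: coordinates must be >= 1")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def contains(self, pos: int) -> bool:
        return _interval_contains(self.start, self.end, pos)

    def positions(self, length: int) -> np.ndarray:
        """1-based positions covered by the gene, in genomic order."""
        if not self.wraps:
            return np.arange(self.start, self.end + 1)
        return np.concatenate(
            [np.arange(self.start, length + 1), np.arange(1, self.end + 1)]
        )


@dataclass
class MtReference:
    """Circular mtDNA reference: sequence, gene map, blacklist, control region.

    Parameters
    ----------
    sequence
        Upper-case string over ``{A, C, G, T}``; its length defines the
        coordinate system.
    genes
        Gene annotations. Overlapping genes are resolved deterministically:
        a position in several genes is assigned to the gene with the smallest
        start (ties broken by name). Override by reordering/renaming genes.
    blacklist
        Closed intervals excluded from somatic calling.
    control_region
        Closed interval, wrapping the origin when ``start > end``.
    """

    sequence: str
    genes: Sequence[Gene]
    blacklist: tuple[tuple[int, int], ...] = DEFAULT_BLACKLIST
    control_region: tuple[int, int] = DEFAULT_CONTROL_REGION

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set(BASES):
            bad = sorted(set(self.sequence) - set(BASES))
            raise ValueError(f"sequence contains non-ACGT characters: {bad}")
        for g in self.genes:
            if not g.wraps and not (1 <= g.start <= g.end <= self.length):
                raise ValueError(f"gene {g.name} outside reference bounds")
        # Precedence order: smallest start first, then name.
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.name))

    # -- basic accessors -------------------------------------------------

    @property
    def length(self) -> int:
        return len(self.sequence)

    def _check(self, pos: int) -> None:
        if not 1 <= pos <= self.length:
            raise PositionError(f"position {pos} outside 1..{self.length}")

    def base(self, pos: int) -> str:
        self._check(pos)
        return self.sequence[pos - 1]

    def trinucleotide_context(self, pos: int) -> str:
        """Reference 3-mer centred on ``pos``, wrapping circularly at the origin."""
        self._check(pos)
        left = self.length if pos == 1 else pos - 1
        right = 1 if pos == self.length else pos + 1
        s = self.sequence
        return s[left - 1] + s[pos - 1] + s[right - 1]

    def in_blacklist(self, pos: int) -> bool:
        self._check(pos)
        return bool(self._blacklist_mask[pos - 1])

    def in_control_region(self, pos: int) -> bool:
        self._check(pos)
        return bool(self._control_mask[pos - 1])

    def gene_at(self, pos: int) -> str | None:
        """Gene name at ``pos`` (smallest-start precedence), or None if intergenic."""
        self._check(pos)
        idx = self._gene_index[pos - 1]
        return None if idx < 0 else self.genes[idx].name

    def gene(self, name: str) -> Gene:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def gene_positions(self, name: str) -> np.ndarray:
        return self.gene(name).positions(self.length)

    # -- vectorized views (cached; used by the hotspot stage) ------------

    @cached_property
    def _seq_codes(self) -> np.ndarray:
        return np.frombuffer(
            self.sequence.encode(), dtype=np.uint8
        ).copy().view(np.uint8)

    @cached_property
    def context_codes(self) -> np.ndarray:
        """Per-position context index into :data:`CONTEXTS` (0..63), wrap-aware."""
        codes = np.empty(self.length, dtype=np.int64)
        lut = np.zeros(256, dtype=np.int64)
        for b, i in _BASE_CODE.items():
            lut[ord(b)] = i
        c = lut[self._seq_codes]
        codes[:] = 16 * np.roll(c, 1) + 4 * c + np.roll(c, -1)
        return codes

    @cached_property
    def _gene_index(self) -> np.ndarray:
        """0-based position -> index into ``self.genes`` or -1 (intergenic)."""
        idx = np.full(self.length, -1, dtype=np.int64)
        # Iterate in reverse precedence so highest-precedence genes write last.
        for gi in range(len(self.genes) - 1, -1, -1):
            idx[self.genes[gi].positions(self.length) - 1] = gi
        return idx

    @cached_property
    def gene_index_array(self) -> np.ndarray:
        """Read-only view of the per-position gene index (-1 = intergenic)."""
        a = self._gene_index.copy()
        a.flags.writeable = False
        return a

    @cached_property
    def _blacklist_mask(self) -> np.ndarray:
        return self._mask(self.blacklist)

    @cached_property
    def _control_mask(self) -> np.ndarray:
        return self._mask([self.control_region])

    def _mask(self, intervals: Iterable[tuple[int, int]]) -> np.ndarray:
        m = np.zeros(self.length, dtype=bool)
        for start, end in intervals:
            if start <= end:
                m[start - 1 : end] = True
            else:  # wraps origin
                m[start - 1 :] = True
                m[:end] = True
        return m

    def excluded_mask(self) -> np.ndarray:
        """Positions removed before hotspot testing (control region + blacklist)."""
        return self._blacklist_mask | self._control_mask


# ---------------------------------------------------------------------------
# Construction helpers


def load_rcrs_gene_map() -> list[Gene]:
    """The bundled 37-gene rCRS annotation (NC_012920.1 coordinates)."""
    genes: list[Gene] = []
    text = (
        resources.files("mthotspot.data").joinpath("rcrs_genes.tsv").read_text()
    )
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        name, start, end, strand = line.split("\t")
        genes.append(Gene(name, int(start), int(end), strand))
    return genes


def synthetic_genome_sequence(
    length: int = RCRS_LENGTH, seed: int = 0, base_probs: Sequence[float] | None = None
) -> str:
    """Seeded random sequence with mtDNA-like base composition.

    A stand-in for the rCRS nucleotide sequence (which is not bundled);
    default base frequencies approximate the reference strand composition
    (A 0.31, C 0.31, G 0.13, T 0.25).
    """
    if base_probs is None:
        base_probs = (0.309, 0.313, 0.131, 0.247)
    rng = np.random.default_rng(seed)
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=base_probs)])


def load_reference(
    sequence: str | None = None,
    fasta: str | None = None,
    genes: Sequence[Gene] | None = None,
    seed: int = 0,
) -> MtReference:
    """Full-length mtDNA reference with the real rCRS gene map.

    Provide the nucleotide sequence as a string or FASTA path; if neither is
    given a seeded synthetic sequence of rCRS length is used (contexts are
    then synthetic, coordinates and gene structure are real).
    """
    if fasta is not None:
        from Bio import SeqIO

        record = next(SeqIO.parse(fasta, "fasta"))
        sequence = str(record.seq)
    if sequence is None:
        sequence = synthetic_genome_sequence(seed=seed)
    if len(sequence) != RCRS_LENGTH:
        raise ValueError(
            f"expected a {RCRS_LENGTH}-bp sequence, got {len(sequence)} bp"
        )
    return MtReference(sequence=sequence, genes=list(genes or load_rcrs_gene_map()))


def toy_reference(seed: int = 0, length: int = 2000) -> MtReference:
    """Small synthetic circular genome (4 genes) for fast tests and examples."""
    genes = [
        Gene("TY-RNR1", 121, 520, "H"),
        Gene("TY-ND1", 561, 1100, "H"),
        Gene("TY-ND2", 1090, 1500, "H"),  # overlaps TY-ND1 to exercise precedence
        Gene("TY-CYB", 1550, 1850, "L"),
    ]
    return MtReference(
        sequence=synthetic_genome_sequence(length=length, seed=seed),
        genes=genes,
        blacklist=((41, 50),),
        control_region=(1900, 100),
    )
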