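"""Reference sequences and informative CpG/GpC site indexing.

In a NOMe experiment the two informative dinucleotide classes on a molecule
are CpG (endogenous DNA methylation, HCG context) and GpC (M.CviPI
accessibility labeling, GCH context).  A cytosine sitting in a GCG
trinucleotide belongs to both classes at once, so enzymatic and endogenous
methylation cannot be told apart there; such sites are indexed but flagged
ambiguous and excluded from every analysis set.

Coordinates are 0-based, half-open throughout the library.  All calls from
either bisulfite strand are projected onto the top-strand cytosine of the
dinucleotide, so molecules of opposite strands share matrix columns.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator

from pyfaidx import Fasta

__all__ = [
    "SiteKind",
    "SiteContext",
    "GenomicInterval",
    "ReferenceSequence",
    "DinucleotideSite",
    "SiteIndex",
    "load_reference",
    "index_sites",
    "classify_context",
]

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class SiteKind(str, enum.Enum):
    CPG = "CPG"
    GPC = "GPC"


class SiteContext(str, enum.Enum):
    VALID = "VALID"
    AMBIGUOUS_GCG = "AMBIGUOUS_GCG"


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"interval end ({self.end}) must be >= start ({self.start})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:  # 1-based inclusive, for human-readable output
        return f"{self.contig}:{self.start + 1}-{self.end}"


@dataclass
class ReferenceSequence:
    """A slice of reference sequence anchored at ``origin_offset`` on its contig."""

    name: str
    bases: str
    origin_offset: int = 0

    def __post_init__(self) -> None:
        self.bases = self.bases.upper()
        bad = set(self.bases) - set("ACGTN")
        if bad:
            raise ValueError(f"non-nucleotide characters in reference: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.name, self.origin_offset,
                               self.origin_offset + len(self.bases))

    @property
    def non_n_fraction(self) -> float:
        if not self.bases:
            return 1.0
        return 1.0 - self.bases.count("N") / len(self.bases)

    def base_at(self, pos: int) -> str:
        """Base at absolute contig coordinate ``pos``."""
        i = pos - self.origin_offset
        if not 0 <= i < len(self.bases):
            raise IndexError(f"position {pos} outside {self.interval}")
        return self.bases[i]


@dataclass(frozen=True)
class DinucleotideSite:
    """One informative dinucleotide, anchored at its top-strand cytosine.

    ``top_g_pos`` is the coordinate of the paired top-strand guanine that is
    interrogated when the evidence comes from an original-bottom-strand
    molecule (the bottom-strand cytosine base-pairs with that guanine).

    ``context`` classifies the top-strand trinucleotide; ``ob_context``
    classifies the bottom-strand trinucleotide around that partner cytosine.
    The two are independent: a top-valid CpG followed by C (C·G·C) has a
    bottom partner sitting in G·C·G, so bottom-strand molecules cannot
    attribute its state unambiguously and report it as missing.
    """

    pos: int
    kind: SiteKind
    context: SiteContext
    ob_context: SiteContext = SiteContext.VALID

    @property
    def top_g_pos(self) -> int:
        return self.pos + 1 if self.kind is SiteKind.CPG else self.pos - 1

    @property
    def is_valid(self) -> bool:
        return self.context is SiteContext.VALID


@dataclass
class SiteIndex:
    """Ordered CpG/GpC sites over a reference interval."""

    interval: GenomicInterval
    sites: list[DinucleotideSite] = field(default_factory=list)

    def __iter__(self) -> Iterator[DinucleotideSite]:
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    def of_kind(self, kind: SiteKind, valid_only: bool = True) -> list[DinucleotideSite]:
        return [
            s for s in self.sites
            if s.kind is kind and (s.is_valid or not valid_only)
        ]

    def analysis_sites(self) -> list[DinucleotideSite]:
        """All sites retained for analysis (ambiguous GCG excluded)."""
        return [s for s in self.sites if s.is_valid]

    def positions(self, kind: SiteKind) -> list[int]:
        return [s.pos for s in self.of_kind(kind)]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.sites:
            key = f"{s.kind.value}:{s.context.value}"
            out[key] = out.get(key, 0) + 1
        return out

    def to_bed(self) -> str:
        """BED representation, one line per indexed site (0-based half-open)."""
        lines = []
        for s in self.sites:
            lines.append(
                f"{self.interval.contig}\t{s.pos}\t{s.pos + 1}"
                f"\t{s.kind.value}:{s.context.value}"
            )
        return "\n".join(lines) + ("\n" if lines else "")


def load_reference(fasta_path: str, contig: str,
                   interval: GenomicInterval | None = None) -> ReferenceSequence:
    """Load an uppercase reference slice from a local FASTA file.

    Raises ``KeyError`` for a missing contig and ``ValueError`` for an
    interval outside the contig bounds.
    """
    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    if contig not in fasta:
        raise KeyError(
            f"contig {contig!r} not found in {fasta_path} "
            f"(available: {', '.join(list(fasta.keys())[:5])})"
        )
    record = fasta[contig]
    n = len(record)
    if interval is None:
        interval = GenomicInterval(contig, 0, n)
    if interval.end > n:
        raise ValueError(
            f"interval {interval} out of bounds for contig {contig!r} "
            f"of length {n}"
        )
    bases = str(record[interval.start:interval.end])
    return ReferenceSequence(contig, bases, origin_offset=interval.start)


def _context_at(bases: str, i: int, kind: SiteKind) -> SiteContext:
    # GCG trinucleotide around the cytosine makes the site both CpG and GpC;
    # an undetermined flank (sequence edge) is classified from available bases.
    if kind is SiteKind.CPG:
        flank_is_g = i > 0 and bases[i - 1] == "G"
    else:
        flank_is_g = i + 1 < len(bases) and bases[i + 1] == "G"
    return SiteContext.AMBIGUOUS_GCG if flank_is_g else SiteContext.VALID


def _ob_context_at(bases: str, i: int, kind: SiteKind) -> SiteContext:
    # mirror rule on the bottom strand: the partner cytosine (pairing the
    # site's top guanine) lies in bottom-strand G.C.G iff the top strand has
    # a C two bases 3' of a CpG cytosine, or two bases 5' of a GpC cytosine
    if kind is SiteKind.CPG:
        flank_is_c = i + 2 < len(bases) and bases[i + 2] == "C"
    else:
        flank_is_c = i >= 2 and bases[i - 2] == "C"
    return SiteContext.AMBIGUOUS_GCG if flank_is_c else SiteContext.VALID


def index_sites(ref: ReferenceSequence) -> SiteIndex:
    """Enumerate every CpG and GpC dinucleotide of a reference slice.

    CG yields a CPG site at the C; GC yields a GPC site at the C (the second
    base).  Dinucleotides containing N yield no site.
    """
    bases = ref.bases
    off = ref.origin_offset
    sites: list[DinucleotideSite] = []
    for i in range(len(bases) - 1):
        pair = bases[i:i + 2]
        if pair == "CG":
            sites.append(DinucleotideSite(
                off + i, SiteKind.CPG,
                _context_at(bases, i, SiteKind.CPG),
                _ob_context_at(bases, i, SiteKind.CPG)))
        if pair == "GC":
            sites.append(DinucleotideSite(
                off + i + 1, SiteKind.GPC,
                _context_at(bases, i + 1, SiteKind.GPC),
                _ob_context_at(bases, i + 1, SiteKind.GPC)))
    return SiteIndex(interval=ref.interval, sites=sites)


def classify_context(ref: ReferenceSequence, pos: int, kind: SiteKind) -> SiteContext:
    """Context of the dinucleotide of ``kind`` whose cytosine sits at ``pos``."""
    i = pos - ref.origin_offset
    bases = ref.bases
    if not 0 <= i < len(bases) or bases[i] != "C":
        raise ValueError(f"no cytosine at position {pos}")
    if kind is SiteKind.CPG:
        if i + 1 >= len(bases) or bases[i + 1] != "G":
            raise ValueError(f"position {pos} is not a CpG cytosine")
    else:
        if i == 0 or bases[i - 1] != "G":
            raise ValueError(f"position {pos} is not a GpC cytosine")
    return _context_at(bases, i, kind)
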