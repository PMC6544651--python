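"""Per-molecule methylation calls from Sanger clones or aligned bisulfite reads.

Bisulfite chemistry is strand-asymmetric: on an original-top (OT) molecule an
unmethylated cytosine reads as T at the reference C, while on an
original-bottom (OB) molecule the converted cytosine sits on the bottom
strand and shows up — in top-strand coordinates — as A at the paired
reference G.  Every call is therefore projected onto the top-strand cytosine
of its dinucleotide so that molecules of either strand share columns.

Two evidence paths feed the same :class:`MoleculeCall` representation:

* Sanger clones (FASTA) are aligned to the amplicon reference with
  bisulfite-aware scoring; orientation and bisulfite strand are inferred per
  clone from which of the four (orientation x conversion-pattern) trials
  scores best.
* Aligned short reads (BAM/SAM, produced upstream by a bisulfite aligner)
  are interrogated through their aligned pairs; mates of a fragment are
  merged into one molecule.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pysam
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
import pandas as pd

from .reference import (
    GenomicInterval,
    ReferenceSequence,
    SiteIndex,
    SiteKind,
    reverse_complement,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CallState",
    "BisulfiteStrand",
    "Orientation",
    "MoleculeSource",
    "QCThresholds",
    "QCReport",
    "BisulfiteAlignment",
    "MoleculeCall",
    "ExtractionFilters",
    "align_clone",
    "qc_conversion",
    "call_sites_from_alignment",
    "extract_sanger",
    "infer_bisulfite_strand",
    "merge_mates",
    "extract_region",
    "calls_to_frame",
    "calls_from_frame",
    "qc_to_frame",
]


class CallState(str, enum.Enum):
    METHYLATED = "METHYLATED"
    UNMETHYLATED = "UNMETHYLATED"
    MISSING = "MISSING"


class BisulfiteStrand(str, enum.Enum):
    OT = "OT"
    OB = "OB"
    UNKNOWN = "UNKNOWN"


class Orientation(str, enum.Enum):
    FORWARD = "FORWARD"
    REVERSE_COMPLEMENT = "REVERSE_COMPLEMENT"


class MoleculeSource(str, enum.Enum):
    SANGER = "SANGER"
    HTS = "HTS"


@dataclass
class QCThresholds:
    """Molecule retention thresholds.

    min_conversion: minimum bisulfite conversion rate estimated at HCH
    cytosines (H = A/C/T), i.e. cytosines informative for neither CpG
    methylation nor GpC accessibility.
    """

    min_conversion: float = 0.95
    min_identity: float = 0.90
    min_base_quality: int = 13


@dataclass
class QCReport:
    molecule_id: str
    hch_conversion_rate: float | None
    identity_rate: float
    n_sites_called: int
    passed: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class BisulfiteAlignment:
    """A clone placed on the reference, in top-strand coordinates.

    ``pairs`` holds (absolute reference position, read base) for every
    aligned, non-gap column, with the read base expressed in top-strand
    orientation.  ``orientation`` records whether the clone was
    reverse-complemented to map; ``strand`` records which conversion pattern
    (C->T = OT, G->A = OB) the scoring favoured — the two are independent.
    """

    molecule_id: str
    orientation: Orientation
    strand: BisulfiteStrand
    pairs: list[tuple[int, str]]
    score: float
    identity: float

    @property
    def span(self) -> tuple[int, int]:
        return self.pairs[0][0], self.pairs[-1][0] + 1


@dataclass
class MoleculeCall:
    molecule_id: str
    source: MoleculeSource
    bisulfite_strand: BisulfiteStrand
    span: GenomicInterval
    states: dict[int, CallState]
    qc: QCReport | None = None

    def n_called(self) -> int:
        return sum(1 for s in self.states.values() if s is not CallState.MISSING)


# ---------------------------------------------------------------------------
# Sanger clone path
# ---------------------------------------------------------------------------

def _substitution_matrix(converted_from: str, converted_to: str):
    """Match/mismatch matrix where the bisulfite transition scores as a match."""
    mat = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            mat[a, b] = 2.0 if a == b else -3.0
    for b in "ACGTN":
        mat["N", b] = 0.0
        mat[b, "N"] = 0.0
    mat[converted_from, converted_to] = 2.0
    return mat


_MAT_CT = _substitution_matrix("C", "T")  # OT evidence: ref C read as T
_MAT_GA = _substitution_matrix("G", "A")  # OB evidence: ref G read as A


def _make_aligner(matrix) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -8.0
    aligner.extend_gap_score = -2.0
    # clone is global within the reference: free end gaps on the reference
    if hasattr(aligner, "open_end_insertion_score"):
        aligner.open_end_insertion_score = 0.0
        aligner.extend_end_insertion_score = 0.0
    else:  # pre-rename Bio.Align attribute names
        aligner.target_end_open_gap_score = 0.0
        aligner.target_end_extend_gap_score = 0.0
    return aligner


def _aligned_pairs(alignment, origin_offset: int) -> list[tuple[int, str]]:
    pairs: list[tuple[int, str]] = []
    t_blocks, q_blocks = alignment.aligned
    query = str(alignment.query)
    for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks):
        for k in range(t1 - t0):
            pairs.append((origin_offset + t0 + k, query[q0 + k]))
    return pairs


def _identity(pairs: list[tuple[int, str]], ref: ReferenceSequence,
              strand: BisulfiteStrand) -> float:
    """Match rate over aligned columns whose reference base is not the
    convertible base of the scored strand (C for OT, G for OB)."""
    skip = "C" if strand is BisulfiteStrand.OT else "G"
    n = matches = 0
    for pos, base in pairs:
        r = ref.base_at(pos)
        if r == skip or r == "N" or base == "N":
            continue
        n += 1
        matches += base == r
    return matches / n if n else 1.0


def align_clone(clone_seq: str, ref: ReferenceSequence,
                molecule_id: str = "clone") -> BisulfiteAlignment:
    """Place one bisulfite-converted clone on the reference.

    Four trials are scored: the clone as given and reverse-complemented, each
    under C->T (OT) and G->A (OB) bisulfite-aware scoring.  The best-scoring
    trial fixes both the mapping orientation and the bisulfite strand of the
    evidence.  Ties keep the earlier trial in the fixed order (FORWARD before
    REVERSE_COMPLEMENT, OT before OB).
    """
    clone_seq = clone_seq.upper()
    if len(clone_seq) < 20:
        raise ValueError(
            f"clone {molecule_id!r} too short to align ({len(clone_seq)} < 20 bp)"
        )
    trials = [
        (Orientation.FORWARD, BisulfiteStrand.OT, clone_seq, _MAT_CT),
        (Orientation.FORWARD, BisulfiteStrand.OB, clone_seq, _MAT_GA),
        (Orientation.REVERSE_COMPLEMENT, BisulfiteStrand.OT,
         reverse_complement(clone_seq), _MAT_CT),
        (Orientation.REVERSE_COMPLEMENT, BisulfiteStrand.OB,
         reverse_complement(clone_seq), _MAT_GA),
    ]
    best = None
    for orientation, strand, seq, matrix in trials:
        aligner = _make_aligner(matrix)
        alignment = next(iter(aligner.align(ref.bases, seq)))
        if best is None or alignment.score > best[0]:
            best = (alignment.score, orientation, strand, alignment)
    score, orientation, strand, alignment = best
    pairs = _aligned_pairs(alignment, ref.origin_offset)
    identity = _identity(pairs, ref, strand)
    return BisulfiteAlignment(
        molecule_id=molecule_id,
        orientation=orientation,
        strand=strand,
        pairs=pairs,
        score=float(score),
        identity=identity,
    )


def _is_hch_top(ref: ReferenceSequence, pos: int) -> bool:
    """Top-strand cytosine in neither CpG nor GpC context."""
    if ref.base_at(pos) != "C":
        return False
    i = pos - ref.origin_offset
    prev_g = i > 0 and ref.bases[i - 1] == "G"
    next_g = i + 1 < len(ref.bases) and ref.bases[i + 1] == "G"
    return not prev_g and not next_g


def _is_hch_bottom(ref: ReferenceSequence, pos: int) -> bool:
    """Bottom-strand cytosine (top-strand G at ``pos``) in HCH context.

    The bottom-strand C pairs the top G; its 5' neighbour pairs the top base
    at pos+1 and its 3' neighbour the top base at pos-1, so the bottom
    context is GpC iff ref[pos+1] == C and CpG iff ref[pos-1] == C.
    """
    if ref.base_at(pos) != "G":
        return False
    i = pos - ref.origin_offset
    gpc = i + 1 < len(ref.bases) and ref.bases[i + 1] == "C"
    cpg = i > 0 and ref.bases[i - 1] == "C"
    return not gpc and not cpg


def qc_conversion(alignment: BisulfiteAlignment, ref: ReferenceSequence,
                  site_index: SiteIndex,
                  thresholds: QCThresholds | None = None) -> QCReport:
    """Estimate bisulfite conversion at HCH cytosines and decide retention.

    Conversion rate = converted / (converted + retained) at cytosines of the
    molecule's strand that are neither CpG nor GpC context.  With no HCH
    position covered the rate is undefined and the molecule passes with a
    flag (the criterion is vacuous, not failed).
    """
    thresholds = thresholds or QCThresholds()
    if alignment.strand is BisulfiteStrand.OB:
        is_hch, retained, converted = _is_hch_bottom, "G", "A"
    else:
        is_hch, retained, converted = _is_hch_top, "C", "T"
    n_conv = n_ret = 0
    for pos, base in alignment.pairs:
        if is_hch(ref, pos):
            if base == converted:
                n_conv += 1
            elif base == retained:
                n_ret += 1
    reasons: list[str] = []
    rate: float | None
    if n_conv + n_ret == 0:
        rate = None
        reasons.append("no HCH cytosines covered; conversion undefined")
        conv_ok = True
    else:
        rate = n_conv / (n_conv + n_ret)
        conv_ok = rate >= thresholds.min_conversion
        if not conv_ok:
            reasons.append(
                f"incomplete conversion ({rate:.3f} < {thresholds.min_conversion})"
            )
    ident_ok = alignment.identity >= thresholds.min_identity
    if not ident_ok:
        reasons.append(
            f"low identity ({alignment.identity:.3f} < {thresholds.min_identity})"
        )
    valid_pos = {s.pos for s in site_index.analysis_sites()}
    valid_g = {s.top_g_pos for s in site_index.analysis_sites()}
    interrogated = valid_g if alignment.strand is BisulfiteStrand.OB else valid_pos
    n_sites = sum(1 for pos, _ in alignment.pairs if pos in interrogated)
    return QCReport(
        molecule_id=alignment.molecule_id,
        hch_conversion_rate=rate,
        identity_rate=alignment.identity,
        n_sites_called=n_sites,
        passed=conv_ok and ident_ok,
        reasons=reasons,
    )


def call_sites_from_alignment(alignment: BisulfiteAlignment,
                              site_index: SiteIndex,
                              qc: QCReport | None = None) -> MoleculeCall:
    """Project a clone alignment onto the site index.

    OT evidence reads the top-strand cytosine (C = methylated,
    T = unmethylated); OB evidence reads the paired top-strand guanine
    (G = methylated, A = unmethylated).  Anything else, and any site outside
    the aligned span, is MISSING.
    """
    lookup = dict(alignment.pairs)
    ob = alignment.strand is BisulfiteStrand.OB
    states: dict[int, CallState] = {}
    for site in site_index.analysis_sites():
        if ob and not site.ob_context.value == "VALID":
            # bottom-strand partner cytosine is context-ambiguous
            states[site.pos] = CallState.MISSING
            continue
        probe = site.top_g_pos if ob else site.pos
        base = lookup.get(probe)
        if ob:
            state = {"G": CallState.METHYLATED, "A": CallState.UNMETHYLATED}
        else:
            state = {"C": CallState.METHYLATED, "T": CallState.UNMETHYLATED}
        states[site.pos] = state.get(base, CallState.MISSING)
    start, end = alignment.span
    return MoleculeCall(
        molecule_id=alignment.molecule_id,
        source=MoleculeSource.SANGER,
        bisulfite_strand=alignment.strand,
        span=GenomicInterval(site_index.interval.contig, start, end),
        states=states,
        qc=qc,
    )


def extract_sanger(clones_fasta: str | Path, ref: ReferenceSequence,
                   site_index: SiteIndex,
                   thresholds: QCThresholds | None = None,
                   ) -> tuple[list[MoleculeCall], list[QCReport]]:
    """Align, QC and call every clone of a FASTA file; failing clones are
    dropped from the call list but kept in the QC report list."""
    thresholds = thresholds or QCThresholds()
    calls: list[MoleculeCall] = []
    reports: list[QCReport] = []
    for record in SeqIO.parse(str(clones_fasta), "fasta"):
        try:
            alignment = align_clone(str(record.seq), ref, molecule_id=record.id)
        except ValueError as exc:
            reports.append(QCReport(record.id, None, 0.0, 0, False, [str(exc)]))
            continue
        report = qc_conversion(alignment, ref, site_index, thresholds)
        reports.append(report)
        if not report.passed:
            logger.info("clone %s rejected: %s", record.id, "; ".join(report.reasons))
            continue
        call = call_sites_from_alignment(alignment, site_index, qc=report)
        if call.n_called() == 0:
            logger.info("clone %s rejected: no informative site covered", record.id)
            continue
        calls.append(call)
    calls.sort(key=lambda c: (c.span.start, c.molecule_id))
    return calls, reports


# ---------------------------------------------------------------------------
# High-throughput (BAM/SAM) path
# ---------------------------------------------------------------------------

@dataclass
class ExtractionFilters:
    min_mapping_quality: int = 20
    min_base_quality: int = 13
    min_called_sites: int = 1


_STRAND_TAGS = (
    ("YD", {"f": BisulfiteStrand.OT, "r": BisulfiteStrand.OB}),   # bwa-meth
    ("XG", {"CT": BisulfiteStrand.OT, "GA": BisulfiteStrand.OB}),  # bismark
)


def infer_bisulfite_strand(read: pysam.AlignedSegment,
                           ref: ReferenceSequence) -> BisulfiteStrand:
    """Bisulfite strand of a mapped read: aligner tag if present, otherwise
    the dominant conversion pattern (C->T mismatches = OT, G->A = OB); a tie
    (including 0-0) is UNKNOWN."""
    for tag, mapping in _STRAND_TAGS:
        if read.has_tag(tag):
            value = read.get_tag(tag)
            if value in mapping:
                return mapping[value]
    seq = read.query_sequence
    ct = ga = 0
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        try:
            rbase = ref.base_at(rpos)
        except IndexError:
            continue
        qbase = seq[qpos]
        if rbase == "C" and qbase == "T":
            ct += 1
        elif rbase == "G" and qbase == "A":
            ga += 1
    if ct > ga:
        return BisulfiteStrand.OT
    if ga > ct:
        return BisulfiteStrand.OB
    return BisulfiteStrand.UNKNOWN


def _call_read(read: pysam.AlignedSegment, site_index: SiteIndex,
               strand: BisulfiteStrand, min_baseq: int) -> MoleculeCall:
    seq = read.query_sequence
    quals = read.query_qualities
    lookup: dict[int, str] = {}
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if quals is not None and quals[qpos] < min_baseq:
            continue
        lookup[rpos] = seq[qpos]
    ob = strand is BisulfiteStrand.OB
    states: dict[int, CallState] = {}
    for site in site_index.analysis_sites():
        if ob and not site.ob_context.value == "VALID":
            states[site.pos] = CallState.MISSING
            continue
        probe = site.top_g_pos if ob else site.pos
        base = lookup.get(probe)
        if ob:
            mapping = {"G": CallState.METHYLATED, "A": CallState.UNMETHYLATED}
        else:
            mapping = {"C": CallState.METHYLATED, "T": CallState.UNMETHYLATED}
        states[site.pos] = mapping.get(base, CallState.MISSING)
    return MoleculeCall(
        molecule_id=read.query_name,
        source=MoleculeSource.HTS,
        bisulfite_strand=strand,
        span=GenomicInterval(site_index.interval.contig,
                             read.reference_start, read.reference_end),
        states=states,
    )


def merge_mates(call_a: MoleculeCall, call_b: MoleculeCall) -> MoleculeCall:
    """Merge the two mate calls of a fragment into one molecule.

    Disjoint sites take the defined value; overlapping sites that agree keep
    it; disagreeing overlaps become MISSING (conservative).
    """
    if call_a.bisulfite_strand is not call_b.bisulfite_strand:
        raise ValueError(
            f"mates of {call_a.molecule_id!r} disagree on bisulfite strand"
        )
    states: dict[int, CallState] = {}
    for pos in call_a.states:
        a, b = call_a.states[pos], call_b.states[pos]
        if a is CallState.MISSING:
            states[pos] = b
        elif b is CallState.MISSING or a is b:
            states[pos] = a
        else:
            states[pos] = CallState.MISSING
    span = GenomicInterval(
        call_a.span.contig,
        min(call_a.span.start, call_b.span.start),
        max(call_a.span.end, call_b.span.end),
    )
    return MoleculeCall(
        molecule_id=call_a.molecule_id,
        source=call_a.source,
        bisulfite_strand=call_a.bisulfite_strand,
        span=span,
        states=states,
    )


def _read_passes(read: pysam.AlignedSegment, filters: ExtractionFilters) -> bool:
    return not (
        read.is_unmapped
        or read.is_duplicate
        or read.is_secondary
        or read.is_supplementary
        or read.mapping_quality < filters.min_mapping_quality
    )


def extract_region(path: str | Path, interval: GenomicInterval,
                   site_index: SiteIndex, ref: ReferenceSequence,
                   filters: ExtractionFilters | None = None,
                   ) -> list[MoleculeCall]:
    """One merged MoleculeCall per fragment overlapping ``interval``.

    BAM input must be coordinate-sorted and indexed (random access); plain
    SAM is scanned linearly.  Reads failing the flag/quality filters, reads
    of undeterminable bisulfite strand and fragments whose mates disagree on
    strand are excluded with a logged count.  Output is ordered by
    (span start, molecule id).
    """
    filters = filters or ExtractionFilters()
    path = str(path)
    mode = "r" if path.endswith(".sam") else "rb"
    n_filtered = n_unknown = n_strand_conflict = 0
    per_fragment: dict[str, list[MoleculeCall]] = {}
    with pysam.AlignmentFile(path, mode) as af:
        if mode == "rb":
            reads = af.fetch(interval.contig, interval.start, interval.end)
        else:
            reads = (
                r for r in af
                if not r.is_unmapped
                and r.reference_name == interval.contig
                and r.reference_start < interval.end
                and r.reference_end > interval.start
            )
        for read in reads:
            if not _read_passes(read, filters):
                n_filtered += 1
                continue
            strand = infer_bisulfite_strand(read, ref)
            if strand is BisulfiteStrand.UNKNOWN:
                n_unknown += 1
                continue
            call = _call_read(read, site_index, strand, filters.min_base_quality)
            per_fragment.setdefault(read.query_name, []).append(call)
    molecules: list[MoleculeCall] = []
    for name in per_fragment:
        parts = per_fragment[name]
        if len(parts) == 1:
            merged = parts[0]
        else:
            try:
                merged = parts[0]
                for part in parts[1:]:
                    merged = merge_mates(merged, part)
            except ValueError:
                n_strand_conflict += 1
                continue
        if merged.n_called() >= filters.min_called_sites:
            molecules.append(merged)
    if n_filtered or n_unknown or n_strand_conflict:
        logger.info(
            "extract_region %s: %d reads filtered, %d unknown strand, "
            "%d strand-conflicting fragments dropped",
            interval, n_filtered, n_unknown, n_strand_conflict,
        )
    molecules.sort(key=lambda c: (c.span.start, c.molecule_id))
    return molecules


# ---------------------------------------------------------------------------
# Tabular round-trip
# ---------------------------------------------------------------------------

def calls_to_frame(calls: list[MoleculeCall], site_index: SiteIndex) -> pd.DataFrame:
    """Long-format call table: one row per (molecule, analysis site)."""
    kind_of = {s.pos: s.kind.value for s in site_index.analysis_sites()}
    rows = []
    for call in calls:
        for pos in sorted(call.states):
            rows.append({
                "molecule_id": call.molecule_id,
                "source": call.source.value,
                "strand": call.bisulfite_strand.value,
                "span_start": call.span.start,
                "span_end": call.span.end,
                "site_pos": pos,
                "kind": kind_of[pos],
                "state": call.states[pos].value,
            })
    return pd.DataFrame(
        rows,
        columns=["molecule_id", "source", "strand", "span_start", "span_end",
                 "site_pos", "kind", "state"],
    )


def calls_from_frame(frame: pd.DataFrame, contig: str) -> list[MoleculeCall]:
    calls = []
    for mol_id, grp in frame.groupby("molecule_id", sort=False):
        first = grp.iloc[0]
        states = {
            int(r.site_pos): CallState(r.state) for r in grp.itertuples()
        }
        calls.append(MoleculeCall(
            molecule_id=str(mol_id),
            source=MoleculeSource(first.source),
            bisulfite_strand=BisulfiteStrand(first.strand),
            span=GenomicInterval(contig, int(first.span_start), int(first.span_end)),
            states=states,
        ))
    calls.sort(key=lambda c: (c.span.start, c.molecule_id))
    return calls


def qc_to_frame(reports: list[QCReport]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "molecule_id": r.molecule_id,
            "hch_conversion_rate": r.hch_conversion_rate,
            "identity_rate": r.identity_rate,
            "n_sites_called": r.n_sites_called,
            "pass": r.passed,
            "reasons": "; ".join(r.reasons),
        }
        for r in reports
    ], columns=["molecule_id", "hch_conversion_rate", "identity_rate",
                "n_sites_called", "pass", "reasons"])
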