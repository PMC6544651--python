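"""End-to-end NOMe chemistry simulator with planted ground truth.

The generative model mirrors the assay: each molecule is drawn from an
epistate (a subpopulation with a fixed nucleosome arrangement); M.CviPI
methylates accessible GpC cytosines with probability ``labeling_efficiency``
and leaks onto protected ones with probability ``protected_leak``; CpG sites
carry endogenous methylation with probability ``cpg_meth_prob``; bisulfite
then converts unmethylated cytosines to T with probability
``conversion_rate`` (methylated cytosines escape conversion except for a
small ``conversion_failure``); finally uniform substitution sequencing error
is applied.  Original-bottom (OB) molecules go through the same chemistry on
the bottom strand and are emitted as that strand read 5'->3'.

Everything is seeded; the planted truth (epistate label, strand, per-site
methylation, nucleosome intervals) is retained so downstream recovery can be
measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .reference import (
    GenomicInterval,
    ReferenceSequence,
    SiteIndex,
    SiteKind,
    index_sites,
    reverse_complement,
)

__all__ = [
    "Epistate",
    "SimulationConfig",
    "TrueMolecule",
    "SimulatedDataset",
    "make_reference",
    "simulate_molecules",
    "apply_chemistry",
    "simulate_dataset",
    "write_fasta",
    "write_sam",
]

_BASES = np.array(list("ACGT"))


@dataclass
class Epistate:
    """A molecule subpopulation with a fixed planted nucleosome arrangement.

    ``nucleosomes`` are 0-based half-open intervals in reference coordinates;
    GpC sites inside them are protected from M.CviPI.
    """

    label: str
    fraction: float
    nucleosomes: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class SimulationConfig:
    epistates: list[Epistate]
    n_molecules: int = 100
    cpg_meth_prob: float = 0.15
    labeling_efficiency: float = 0.85
    protected_leak: float = 0.02
    conversion_rate: float = 0.99
    conversion_failure: float = 0.005
    seq_error: float = 0.001
    ot_fraction: float = 0.5
    layout: str = "FULL_LENGTH"  # or "PAIRED"
    read_length: int = 150
    fragment_length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(e.fraction for e in self.epistates)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"epistate fractions must sum to 1, got {total}")
        for name in ("cpg_meth_prob", "labeling_efficiency", "protected_leak",
                     "conversion_rate", "conversion_failure", "seq_error",
                     "ot_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.layout not in ("FULL_LENGTH", "PAIRED"):
            raise ValueError(f"unknown read layout {self.layout!r}")


@dataclass
class TrueMolecule:
    molecule_id: str
    epistate: str
    strand: str  # "OT" or "OB"
    span: GenomicInterval
    site_states: dict[int, bool]  # site pos -> methylated (truth)
    nucleosomes: list[tuple[int, int]]


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    reference: ReferenceSequence
    site_index: SiteIndex
    molecules: list[TrueMolecule]
    observed: dict[str, str]  # molecule_id -> sequence as sequenced

    def truth_frame(self) -> pd.DataFrame:
        kind_of = {s.pos: s.kind.value for s in self.site_index.analysis_sites()}
        rows = []
        for mol in self.molecules:
            for pos in sorted(mol.site_states):
                if pos not in kind_of:
                    continue  # ambiguous GCG sites carry no analysable truth
                rows.append({
                    "molecule_id": mol.molecule_id,
                    "epistate": mol.epistate,
                    "strand": mol.strand,
                    "site_pos": pos,
                    "kind": kind_of[pos],
                    "methylated": int(mol.site_states[pos]),
                })
        return pd.DataFrame(rows, columns=["molecule_id", "epistate", "strand",
                                           "site_pos", "kind", "methylated"])

    def nucleosomes_bed(self) -> str:
        lines = []
        for epi in self.config.epistates:
            for start, end in epi.nucleosomes:
                lines.append(
                    f"{self.reference.name}\t{start}\t{end}\tNUCLEOSOME:{epi.label}"
                )
        return "\n".join(lines) + ("\n" if lines else "")


def make_reference(length: int, gc: float = 0.5, seed: int = 0,
                   name: str = "simref") -> ReferenceSequence:
    """Random reference with the requested expected GC fraction (seeded)."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = rng.choice(_BASES, size=length, p=p)
    return ReferenceSequence(name, "".join(bases))


def _in_any(pos: int, intervals: list[tuple[int, int]]) -> bool:
    return any(a <= pos < b for a, b in intervals)


def simulate_molecules(config: SimulationConfig, site_index: SiteIndex,
                       rng: np.random.Generator | None = None,
                       ) -> list[TrueMolecule]:
    """Draw per-molecule epistates, strands, spans and true site methylation.

    GpC sites outside the epistate's nucleosomes are methylated with the
    labeling efficiency, inside with the leak probability; CpG sites follow
    the endogenous methylation probability.  An ambiguous GCG position can
    receive either mark (logical OR); it is excluded from analyses anyway.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    interval = site_index.interval
    for epi in config.epistates:
        for a, b in epi.nucleosomes:
            if a < interval.start or b > interval.end:
                raise ValueError(
                    f"nucleosome [{a},{b}) of epistate {epi.label!r} outside "
                    f"reference interval {interval}")
    fractions = np.array([e.fraction for e in config.epistates])
    labels = np.array([e.label for e in config.epistates])
    molecules: list[TrueMolecule] = []
    span_len = len(interval)
    for i in range(config.n_molecules):
        epi = config.epistates[int(rng.choice(len(labels), p=fractions))]
        strand = "OT" if rng.random() < config.ot_fraction else "OB"
        if config.layout == "PAIRED":
            frag = min(config.fragment_length, span_len)
            start = interval.start + int(rng.integers(0, span_len - frag + 1))
            span = GenomicInterval(interval.contig, start, start + frag)
        else:
            span = interval
        states: dict[int, bool] = {}
        for site in site_index:
            meth = False
            if site.kind is SiteKind.GPC or site.context.value == "AMBIGUOUS_GCG":
                p = (config.protected_leak if _in_any(site.pos, epi.nucleosomes)
                     else config.labeling_efficiency)
                meth = meth or rng.random() < p
            if site.kind is SiteKind.CPG:
                meth = meth or rng.random() < config.cpg_meth_prob
            if site.pos in states:
                states[site.pos] = states[site.pos] or meth
            else:
                states[site.pos] = meth
        molecules.append(TrueMolecule(
            molecule_id=f"mol{i:05d}",
            epistate=epi.label,
            strand=strand,
            span=span,
            site_states=states,
            nucleosomes=list(epi.nucleosomes),
        ))
    return molecules


def apply_chemistry(mol: TrueMolecule, ref: ReferenceSequence,
                    config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> str:
    """Bisulfite-convert one molecule and return it as sequenced.

    OT molecules come back as the converted top strand; OB molecules as the
    converted bottom strand read 5'->3' (the reverse complement
    representation).  Cytosines at no indexed site are unmethylated by
    construction (HCH) and convert at the full rate.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    a = mol.span.start - ref.origin_offset
    b = mol.span.end - ref.origin_offset
    top = ref.bases[a:b]
    # map a top-strand G coordinate to the methylation truth of the paired
    # bottom-strand cytosine (shared with the top-strand site state)
    sites = index_sites(ref)
    # one bottom cytosine can pair the guanine of both a CpG and a GpC
    # (top-strand C.G.C); the processes acting on it combine by OR
    g_state: dict[int, bool] = {}
    for s in sites:
        # the bottom cytosine exists on the fragment iff the top guanine does,
        # even when the site's top cytosine falls just outside the fragment
        if not mol.span.start <= s.top_g_pos < mol.span.end:
            continue
        state = mol.site_states.get(s.pos, False)
        g_state[s.top_g_pos] = g_state.get(s.top_g_pos, False) or state
    if mol.strand == "OT":
        seq = list(top)
        for i, base in enumerate(seq):
            if base != "C":
                continue
            meth = mol.site_states.get(mol.span.start + i, False)
            seq[i] = _convert(base, meth, config, rng)
    else:
        seq = list(reverse_complement(top))
        n = len(seq)
        for j, base in enumerate(seq):
            if base != "C":
                continue
            t = mol.span.start + (n - 1 - j)  # paired top-strand G coordinate
            meth = g_state.get(t, False)
            seq[j] = _convert(base, meth, config, rng)
    if config.seq_error > 0:
        for i in range(len(seq)):
            if rng.random() < config.seq_error:
                others = [x for x in "ACGT" if x != seq[i]]
                seq[i] = others[int(rng.integers(0, 3))]
    return "".join(seq)


def _convert(base: str, methylated: bool, config: SimulationConfig,
             rng: np.random.Generator) -> str:
    if methylated:
        return "T" if rng.random() < config.conversion_failure else "C"
    return "T" if rng.random() < config.conversion_rate else "C"


def simulate_dataset(config: SimulationConfig, ref: ReferenceSequence,
                     site_index: SiteIndex | None = None) -> SimulatedDataset:
    """Run the full generative pipeline under one seeded RNG."""
    site_index = site_index if site_index is not None else index_sites(ref)
    rng = np.random.default_rng(config.seed)
    molecules = simulate_molecules(config, site_index, rng)
    observed = {m.molecule_id: apply_chemistry(m, ref, config, rng)
                for m in molecules}
    return SimulatedDataset(config=config, reference=ref,
                            site_index=site_index, molecules=molecules,
                            observed=observed)


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------

def write_fasta(path: str | Path, records: dict[str, str] | ReferenceSequence,
                width: int = 80) -> None:
    if isinstance(records, ReferenceSequence):
        records = {records.name: records.bases}
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_sam(dataset: SimulatedDataset, path: str | Path) -> None:
    """Emit the simulated molecules as SAM with bwa-meth-style YD strand tags.

    FULL_LENGTH molecules become single-end reads; PAIRED molecules become a
    proper pair covering the two fragment ends.  Reads are stored in forward
    genome orientation (OB single-end reads carry the reverse flag) with
    ungapped CIGARs and constant high base quality, and are emitted sorted
    by coordinate.
    """
    ref = dataset.reference
    contig_len = ref.origin_offset + len(ref.bases)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": ref.name, "LN": contig_len}],
    }
    reads = []
    for mol in dataset.molecules:
        obs = dataset.observed[mol.molecule_id]
        # forward-genome-orientation sequence of the fragment
        fwd = obs if mol.strand == "OT" else reverse_complement(obs)
        yd = "f" if mol.strand == "OT" else "r"
        if dataset.config.layout == "PAIRED":
            rl = min(dataset.config.read_length, len(fwd))
            tlen = len(fwd)
            r1 = (mol.molecule_id, 99, mol.span.start, fwd[:rl], yd, tlen, True,
                  mol.span.end - rl)
            r2 = (mol.molecule_id, 147, mol.span.end - rl, fwd[-rl:], yd,
                  -tlen, False, mol.span.start)
            reads.extend([r1, r2])
        else:
            flag = 0 if mol.strand == "OT" else 16
            reads.append((mol.molecule_id, flag, mol.span.start, fwd, yd, 0,
                          None, None))
    reads.sort(key=lambda r: (r[2], r[0]))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for name, flag, pos, seq, yd, tlen, _, mate_pos in reads:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = name
            rec.flag = flag
            rec.reference_id = 0
            rec.reference_start = pos
            rec.mapping_quality = 60
            rec.cigarstring = f"{len(seq)}M"
            rec.query_sequence = seq
            rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            if mate_pos is not None:
                rec.next_reference_id = 0
                rec.next_reference_start = mate_pos
                rec.template_length = tlen
            rec.set_tag("YD", yd)
            out.write(rec)
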