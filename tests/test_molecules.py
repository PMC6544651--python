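"""Clone alignment, conversion QC, site calling, strand inference, extraction."""

import numpy as np
import pysam
import pytest

from nomefoot.molecules import (
    BisulfiteAlignment,
    BisulfiteStrand,
    CallState,
    ExtractionFilters,
    MoleculeCall,
    MoleculeSource,
    Orientation,
    QCThresholds,
    align_clone,
    call_sites_from_alignment,
    calls_from_frame,
    calls_to_frame,
    extract_region,
    extract_sanger,
    infer_bisulfite_strand,
    merge_mates,
    qc_conversion,
)
from nomefoot.reference import (
    GenomicInterval,
    ReferenceSequence,
    index_sites,
    reverse_complement,
)
from nomefoot.simulate import (
    Epistate,
    SimulationConfig,
    simulate_dataset,
    write_fasta,
    write_sam,
)

REF60 = ReferenceSequence(
    "amp", "ATTGCAATCGTTAATGCTTAACGATTAGCTTATCGAATTGCATTACGTTAATGCATTAA")


def convert_all(bases: str) -> str:
    return bases.replace("C", "T")


class TestAlignClone:
    def test_identical_clone_maps_forward(self):
        a = align_clone(REF60.bases, REF60, "c")
        assert a.orientation is Orientation.FORWARD
        assert a.identity == 1.0

    def test_full_conversion_scores_as_matches(self):
        a = align_clone(convert_all(REF60.bases), REF60, "c")
        assert a.orientation is Orientation.FORWARD
        assert a.strand is BisulfiteStrand.OT
        assert a.identity == 1.0
        # every aligned column, conversions included, scored as a match
        b = align_clone(REF60.bases, REF60, "c")
        assert a.score == b.score

    def test_reverse_complement_of_converted_ref(self):
        clone = reverse_complement(convert_all(REF60.bases))
        a = align_clone(clone, REF60, "c")
        assert a.orientation is Orientation.REVERSE_COMPLEMENT
        assert a.identity == 1.0

    def test_converted_bottom_strand_is_ob(self):
        # chemistry on the bottom strand, sequenced 5'->3' of that strand
        bottom = reverse_complement(REF60.bases)
        clone = convert_all(bottom)
        a = align_clone(clone, REF60, "c")
        assert a.strand is BisulfiteStrand.OB
        assert a.identity == 1.0

    def test_short_clone_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            align_clone("ACGTACGT", REF60, "c")


# HCH-only reference: cytosines at 1, 4, 7, ... each in A.C.T context
HCH_REF = ReferenceSequence("h", "ACT" * 10)
HCH_POS = [1 + 3 * k for k in range(10)]


def _alignment(read_bases: dict[int, str], ref: ReferenceSequence,
               strand=BisulfiteStrand.OT) -> BisulfiteAlignment:
    pairs = [(i, read_bases.get(i, ref.bases[i])) for i in range(len(ref.bases))]
    return BisulfiteAlignment("m", Orientation.FORWARD, strand, pairs,
                              score=0.0, identity=1.0)


class TestConversionQC:
    def test_full_conversion_passes(self):
        aln = _alignment({p: "T" for p in HCH_POS}, HCH_REF)
        report = qc_conversion(aln, HCH_REF, index_sites(HCH_REF))
        assert report.hch_conversion_rate == 1.0
        assert report.passed

    def test_incomplete_conversion_fails(self):
        reads = {p: "T" for p in HCH_POS[:7]}
        reads.update({p: "C" for p in HCH_POS[7:]})  # 3 of 10 retained
        report = qc_conversion(_alignment(reads, HCH_REF), HCH_REF,
                               index_sites(HCH_REF))
        assert report.hch_conversion_rate == pytest.approx(0.7)
        assert not report.passed
        assert any("incomplete conversion" in r for r in report.reasons)

    def test_no_hch_cytosines_passes_with_flag(self):
        ref = ReferenceSequence("r", "ATTGGATTAA")  # no cytosine at all
        report = qc_conversion(_alignment({}, ref), ref, index_sites(ref))
        assert report.hch_conversion_rate is None
        assert report.passed
        assert report.reasons  # flagged as undefined

    def test_low_identity_fails(self):
        aln = _alignment({p: "T" for p in HCH_POS}, HCH_REF)
        aln.identity = 0.5
        report = qc_conversion(aln, HCH_REF, index_sites(HCH_REF))
        assert not report.passed


# one valid GpC (pos 3) and one valid CpG (pos 8): TTGC...ACG
SITE_REF = ReferenceSequence("s", "TTGCATTACGTT")


class TestCallSites:
    def test_forward_reads_cytosine_state(self):
        idx = index_sites(SITE_REF)
        aln = _alignment({3: "C", 8: "T"}, SITE_REF)
        call = call_sites_from_alignment(aln, idx)
        assert call.states[3] is CallState.METHYLATED     # labeled GpC
        assert call.states[8] is CallState.UNMETHYLATED   # converted CpG

    def test_ob_reads_partner_guanine(self):
        idx = index_sites(SITE_REF)
        # GpC at 3 has its guanine at 2; CpG at 8 has its guanine at 9
        aln = _alignment({2: "A", 9: "G"}, SITE_REF, strand=BisulfiteStrand.OB)
        call = call_sites_from_alignment(aln, idx)
        assert call.states[3] is CallState.UNMETHYLATED
        assert call.states[8] is CallState.METHYLATED

    def test_site_outside_span_is_missing(self):
        idx = index_sites(SITE_REF)
        pairs = [(i, SITE_REF.bases[i]) for i in range(5)]  # covers pos 0-4
        aln = BisulfiteAlignment("m", Orientation.FORWARD, BisulfiteStrand.OT,
                                 pairs, 0.0, 1.0)
        call = call_sites_from_alignment(aln, idx)
        assert call.states[8] is CallState.MISSING
        assert call.states[3] is not CallState.MISSING

    def test_ob_skips_bottom_ambiguous_site(self):
        ref = ReferenceSequence("r", "AACGCATT")  # CpG at 2, bottom partner in GCG
        idx = index_sites(ref)
        aln = _alignment({3: "G"}, ref, strand=BisulfiteStrand.OB)
        call = call_sites_from_alignment(aln, idx)
        assert call.states[2] is CallState.MISSING


def _segment(header, name="r1", flag=0, pos=0, seq="ACGT", mapq=60, tags=()):
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.flag = flag
    rec.reference_id = 0
    rec.reference_start = pos
    rec.mapping_quality = mapq
    rec.cigarstring = f"{len(seq)}M"
    rec.query_sequence = seq
    rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    for tag, value in tags:
        rec.set_tag(tag, value)
    return rec


@pytest.fixture
def sam_header():
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "amp", "LN": len(REF60.bases)}]})


class TestStrandInference:
    def test_tag_passthrough(self, sam_header):
        read = _segment(sam_header, seq=REF60.bases[:20], tags=[("YD", "r")])
        assert infer_bisulfite_strand(read, REF60) is BisulfiteStrand.OB

    def test_ct_mismatches_imply_ot(self, sam_header):
        seq = convert_all(REF60.bases[:30])
        read = _segment(sam_header, seq=seq)
        assert infer_bisulfite_strand(read, REF60) is BisulfiteStrand.OT

    def test_ga_mismatches_imply_ob(self, sam_header):
        seq = REF60.bases[:30].replace("G", "A")
        read = _segment(sam_header, seq=seq)
        assert infer_bisulfite_strand(read, REF60) is BisulfiteStrand.OB

    def test_tie_is_unknown(self, sam_header):
        read = _segment(sam_header, seq=REF60.bases[:20])  # 0-0 tie
        assert infer_bisulfite_strand(read, REF60) is BisulfiteStrand.UNKNOWN


def _call(states, start, end, mol="m", strand=BisulfiteStrand.OT):
    return MoleculeCall(mol, MoleculeSource.HTS, strand,
                        GenomicInterval("amp", start, end), dict(states))


class TestMergeMates:
    def test_disjoint_union(self):
        a = _call({3: CallState.METHYLATED, 8: CallState.MISSING}, 0, 5)
        b = _call({3: CallState.MISSING, 8: CallState.UNMETHYLATED}, 6, 12)
        merged = merge_mates(a, b)
        assert merged.states == {3: CallState.METHYLATED,
                                 8: CallState.UNMETHYLATED}
        assert (merged.span.start, merged.span.end) == (0, 12)

    def test_agreement_kept_disagreement_missing(self):
        a = _call({3: CallState.METHYLATED, 8: CallState.METHYLATED}, 0, 12)
        b = _call({3: CallState.METHYLATED, 8: CallState.UNMETHYLATED}, 0, 12)
        merged = merge_mates(a, b)
        assert merged.states[3] is CallState.METHYLATED
        assert merged.states[8] is CallState.MISSING

    def test_strand_mismatch_raises(self):
        a = _call({3: CallState.METHYLATED}, 0, 5)
        b = _call({3: CallState.METHYLATED}, 0, 5, strand=BisulfiteStrand.OB)
        with pytest.raises(ValueError, match="strand"):
            merge_mates(a, b)


@pytest.fixture
def simulated_sam(tmp_path, sim_reference, sim_index):
    config = SimulationConfig(
        epistates=[Epistate("nuc", 1.0, [(500, 650)])],
        n_molecules=10, labeling_efficiency=1.0, protected_leak=0.0,
        conversion_rate=1.0, conversion_failure=0.0, seq_error=0.0,
        cpg_meth_prob=0.3, layout="PAIRED", read_length=150,
        fragment_length=400, seed=9)
    dataset = simulate_dataset(config, sim_reference, sim_index)
    path = tmp_path / "reads.sam"
    write_sam(dataset, path)
    return path, dataset


class TestExtractRegion:
    def test_empty_region(self, simulated_sam, sim_index, sim_reference, tmp_path):
        path, _ = simulated_sam
        empty = GenomicInterval(sim_reference.name, 0, 1)
        # shift interval past all reads by using a disjoint contig region
        calls = extract_region(path, GenomicInterval("other", 0, 100),
                               sim_index, sim_reference)
        assert calls == []

    def test_all_fragments_recovered(self, simulated_sam, sim_index, sim_reference):
        path, dataset = simulated_sam
        calls = extract_region(path, sim_index.interval, sim_index, sim_reference)
        assert len(calls) == len(dataset.molecules)
        assert [c.molecule_id for c in calls] == sorted(
            (c.molecule_id for c in calls),
            key=lambda m: (next(x.span.start for x in calls
                                if x.molecule_id == m), m))

    def test_duplicates_and_low_mapq_excluded(self, tmp_path, sim_reference,
                                              sim_index, simulated_sam):
        src, _ = simulated_sam
        path = tmp_path / "dups.sam"
        with pysam.AlignmentFile(str(src)) as fh:
            header = fh.header
            reads = list(fh)
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for read in reads:
                read.flag |= 0x400  # mark everything duplicate
                out.write(read)
        calls = extract_region(path, sim_index.interval, sim_index, sim_reference)
        assert calls == []

    def test_bam_path_matches_sam_path(self, tmp_path, simulated_sam,
                                       sim_index, sim_reference):
        sam_path, _ = simulated_sam
        bam_path = tmp_path / "reads.bam"
        pysam.sort("-o", str(bam_path), str(sam_path))
        pysam.index(str(bam_path))
        from_sam = extract_region(sam_path, sim_index.interval, sim_index,
                                  sim_reference)
        from_bam = extract_region(bam_path, sim_index.interval, sim_index,
                                  sim_reference)
        t1 = calls_to_frame(from_sam, sim_index)
        t2 = calls_to_frame(from_bam, sim_index)
        assert t1.equals(t2)

    def test_extraction_is_deterministic(self, simulated_sam, sim_index,
                                         sim_reference):
        path, _ = simulated_sam
        t1 = calls_to_frame(extract_region(path, sim_index.interval, sim_index,
                                           sim_reference), sim_index)
        t2 = calls_to_frame(extract_region(path, sim_index.interval, sim_index,
                                           sim_reference), sim_index)
        assert t1.to_csv(index=False) == t2.to_csv(index=False)


class TestStrandSymmetry:
    def test_ot_and_ob_project_identically(self, tmp_path, sim_reference,
                                           sim_index, perfect_config):
        """With perfect chemistry the same underlying methylation yields the
        same projected states from either strand, at every site informative
        on both strands."""
        cfg_ot = perfect_config(n_molecules=5, ot_fraction=1.0, seed=77)
        cfg_ob = perfect_config(n_molecules=5, ot_fraction=0.0, seed=77)
        ds_ot = simulate_dataset(cfg_ot, sim_reference, sim_index)
        ds_ob = simulate_dataset(cfg_ob, sim_reference, sim_index)
        # same seed and draw order -> identical per-site truth
        for a, b in zip(ds_ot.molecules, ds_ob.molecules):
            assert a.site_states == b.site_states
        fa_ot, fa_ob = tmp_path / "ot.fa", tmp_path / "ob.fa"
        write_fasta(fa_ot, ds_ot.observed)
        write_fasta(fa_ob, ds_ob.observed)
        calls_ot, _ = extract_sanger(fa_ot, sim_reference, sim_index)
        calls_ob, _ = extract_sanger(fa_ob, sim_reference, sim_index)
        both_strand_sites = {
            s.pos for s in sim_index.analysis_sites()
            if s.ob_context.value == "VALID"
        }
        assert len(calls_ot) == len(calls_ob) == 5
        for a, b in zip(calls_ot, calls_ob):
            assert a.bisulfite_strand is BisulfiteStrand.OT
            assert b.bisulfite_strand is BisulfiteStrand.OB
            for pos in both_strand_sites:
                if (a.states[pos] is not CallState.MISSING
                        and b.states[pos] is not CallState.MISSING):
                    assert a.states[pos] is b.states[pos]


def test_calls_roundtrip_through_frame(simulated_sam, sim_index, sim_reference):
    path, _ = simulated_sam
    calls = extract_region(path, sim_index.interval, sim_index, sim_reference)
    frame = calls_to_frame(calls, sim_index)
    back = calls_from_frame(frame, sim_reference.name)
    assert [c.molecule_id for c in back] == [c.molecule_id for c in calls]
    assert all(a.states == b.states for a, b in zip(back, calls))
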