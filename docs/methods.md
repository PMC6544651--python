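# Methods

## The measurement model

A NOMe experiment reads two epigenetic layers off the same bisulfite-
converted molecule. M.CviPI methylates cytosines of GpC dinucleotides in
accessible chromatin but cannot reach DNA wrapped around a nucleosome;
endogenous methyltransferases maintain CpG methylation. Bisulfite converts
unmethylated cytosines to uracil (read as T) and leaves methylated cytosines
intact. A sequenced molecule therefore encodes accessibility at GCH
positions and endogenous methylation at HCG positions (H = A/C/T), while
HCH cytosines should always read T and estimate the conversion rate.

All calls are projected onto the top-strand cytosine of their dinucleotide.
Evidence from an original-top (OT) molecule is read at that cytosine
(C = methylated, T = unmethylated); evidence from an original-bottom (OB)
molecule is read at the paired top-strand guanine (G = methylated,
A = unmethylated), assuming symmetric methylation of the palindromic CpG
and GpC dinucleotides.

### Context filtering, on both strands

A cytosine inside a GCG trinucleotide is simultaneously CpG and GpC; its
methylation cannot be attributed to either process, so such sites are
indexed, counted and excluded from every analysis set (the field's standard
convention). The same ambiguity arises independently on the bottom strand:
in a top-strand C·G·C configuration, the single bottom-strand cytosine
pairing the central guanine belongs to both a bottom-strand CpG and a
bottom-strand GpC. Sites whose bottom-strand counterpart is ambiguous stay
in the analysis set (OT molecules read them normally) but OB molecules
report them as missing. Without this per-strand rule, OB evidence would
systematically misattribute marks at such sites. Dinucleotides containing N
yield no site; a site at the edge of the loaded sequence is classified from
the available bases only.

## Molecule extraction

**Sanger clones.** Each clone is placed on the amplicon reference with a
global(clone)-in-local(reference) pairwise alignment under bisulfite-aware
scoring: match +2, mismatch −3, gap open −8 / extend −2, free end gaps on
the reference, and the bisulfite transition scored as a match. Four trials
are run — the clone as given and reverse-complemented, each under C→T (OT)
and G→A (OB) scoring — because mapping orientation and bisulfite strand are
independent degrees of freedom: a clone may be an OT molecule sequenced in
reverse orientation. The best score fixes both; ties keep the earlier trial
in a fixed order (FORWARD before REVERSE_COMPLEMENT, OT before OB), making
the choice deterministic.

**QC.** Conversion is estimated at HCH cytosines of the molecule's strand
as converted / (converted + retained); molecules below 0.95 are dropped
("incomplete conversion"), as are molecules below 0.90 identity (computed
over aligned columns whose reference base is not the convertible base of
the strand). A molecule covering no HCH cytosine passes with a flag — the
criterion is vacuous, not failed. Both thresholds are configuration, not
constants; the defaults are conventional values for bisulfite work.

**Aligned reads.** BAM/SAM reads are interrogated through their aligned
pairs (no realignment). Bisulfite strand comes from aligner tags when
present (`YD` f/r, `XG` CT/GA) and otherwise from the dominant mismatch
pattern (C→T vs G→A); ties are UNKNOWN and excluded, because mis-stranding
flips methylation polarity. Default filters: mapping quality ≥ 20, no
duplicates/secondary/supplementary, base quality ≥ 13 at interrogated
positions, ≥ 1 called analysis site. Mates of a fragment are merged: sites
covered by one mate take its value, agreeing overlaps keep the value,
disagreeing overlaps become missing (conservative, rather than
first-mate-wins). Fragments whose mates imply different strands are dropped
and counted. Output ordering is (span start, molecule id), so extraction is
byte-deterministic.

## Matrices, smoothing, clustering

The molecule × site matrix holds 1 (methylated), 0 (unmethylated) or NaN
per VALID site of one variable (CpG or GpC). The clustering window *W*
(default 60 bp, useful range 20–160) replaces the entry at site *p* by the
molecule's mean over its called sites in the inclusive interval
[p − W/2, p + W/2]; a 140 nt window at 200 bp averages sites from 130 to
270 bp. When *W* is below the minimum inter-site gap the smoothed matrix
equals the raw one; when *W* spans the whole locus every defined entry is
the molecule mean.

Molecules are ordered by agglomerative hierarchical clustering (average
linkage) on Euclidean distances over shared called columns, rescaled by
sqrt(n_total / n_shared) so sparsely overlapping pairs are not spuriously
close; pairs sharing no column get the matrix maximum (logged). Leaf order
is made deterministic by putting the subtree with the lower mean value
first (ties: lexicographically smallest molecule id), and the input is
sorted by id first, so the ordering is invariant to row permutation.
Molecules with fewer than 3 informative columns are appended after the
clustered ones in id order rather than placed unreliably.

## Footprint calling

On the raw GpC states of one molecule, a candidate window [x, x + L) within
the covered span qualifies as nucleosome-bound when it contains at least
`min_sites` called GpCs (default 3 — guards against vacuous calls in
GpC-poor windows) and the protected fraction among them is ≥ s. Defaults
L = 140 bp (nucleosome footprint plus linker; useful range 100–160) and
s = 0.7 (range 0.5–1). The inequality is non-strict so that s = 1.0 remains
satisfiable by fully protected windows. Qualification only changes at
offsets where a called site enters or leaves the window, so the
implementation evaluates only those breakpoints; this is exactly equivalent
to scanning every integer offset, and a property test plus the acceptance
script verify the equivalence against brute-force enumeration. Maximal
unions of overlapping qualifying windows are reported as single calls
(matching the solid-bar rendering; no attempt is made to segment long
protected runs into individual nucleosomes). The reported supporting
fraction is the best qualifying window's fraction, so every call satisfies
fraction ≥ s even after merging. Accessible regions (candidate NDRs) use
the identical rule with the methylated fraction, exposed as a separate
operation so it can be disabled.

## Population profiles

Per-site percentages use called molecules only; occupancy = 100 − GpC
percent methylation, so occupancy + methylation = 100 at every covered GpC
site by construction. The locus trendline is an ordinary least-squares
polynomial of order 6 (reduced to n − 1 when fewer points are available,
logged). Metagene profiles pool per-site counts into half-open 10 bp bins
of TSS-relative position over ±500 bp: rel = pos − tss on + strand,
tss − pos on −, bin = floor(rel / width). Pooling is count-weighted
(heavily covered sites weigh more) rather than per-gene mean-of-means,
matching count-based binning; sites near two anchors contribute to both
(standard metagene double counting, logged). Anchors on contigs absent from
the data are skipped and logged.

## The simulator

The generator mirrors the assay, stage by stage: molecules draw an epistate
(label, mixture fraction, planted nucleosome intervals), a bisulfite strand
(OT fraction, default 0.5) and a span (full-length for Sanger mode, a
placed fragment for paired-end mode). GpC sites outside the epistate's
nucleosomes methylate with the labeling efficiency (default 0.85), inside
with the protected leak (default 0.02); CpG sites methylate with
`cpg_meth_prob` (default 0.15, promoter-like hypomethylation matching the
regulatory loci this analysis targets). Labeling efficiency and leak are
plausible literature-scale values — the chemistry efficiencies are exposed
in the config precisely because they are not universal constants.
Bisulfite conversion then hits unmethylated cytosines with rate 0.99
(methylated ones escape except for a 0.005 failure rate), uniform
substitution error is applied (0.001 Sanger, 0.005 short-read), and OB
molecules are emitted as the converted bottom strand read 5'→3'. SAM output
stores reads in forward genome orientation with proper-pair flags, ungapped
CIGARs, constant base quality and `YD` strand tags. Everything is driven by
one seeded generator, so every stage is reproducible.

What the simulator does **not** model: PCR amplification and cloning bias,
indels and soft-clipping, position-dependent quality, chimeric fragments,
partial nucleosome unwrapping, strand-asymmetric methylation, and linker
DNA structure. Passing recovery tests therefore demonstrates correctness of
the extraction/calling logic under the stated chemistry model, not
robustness to every artifact of real libraries.

## Numerical and interface choices

* Coordinates are 0-based half-open internally and in BED output; 1-based
  inclusive only on the CLI and in human-readable positions of CSV site
  tables.
* Percentages are plain floats in [0, 100]; uncovered sites have blank
  percentages rather than 0, so downstream averaging cannot mistake absence
  for hypomethylation.
* Problem sizes in tests and the acceptance script (1.2–2 kb references,
  10–200 molecules, 500 oracle instances) were chosen as the smallest sizes
  at which every behaviour under test is exercised with comfortable
  statistical margins.
* The whole pipeline is deterministic for fixed seeds; a byte-level check
  of SAM/CSV/BED outputs is part of the test suite.

## Known limitations

* The nucleosome caller reports protected intervals, not positioned
  nucleosomes; a 300 bp protected run is one call, not two nucleosomes.
* No probabilistic/HMM footprint inference; the sliding-window rule is
  deliberately the transparent, parameter-explicit formulation.
* Clone alignment assumes an ungapped-ish amplicon relationship; heavily
  rearranged clones fail identity QC rather than being rescued.
* Metagene profiles require user-supplied anchors and per-site counts;
  there is no genome-wide discovery mode.
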