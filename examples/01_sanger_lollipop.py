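"""Single-locus NOMe-PCR style analysis from simulated Sanger clones.

Simulates an amplicon whose molecules all carry one nucleosome over the
locus center, runs the full clone pipeline (align, QC, call, cluster, call
footprints) and renders the lollipop figure.
"""

from pathlib import Path

from nomefoot import (
    AnalysisParams,
    SiteKind,
    build_matrix,
    call_footprints,
    cluster_molecules,
    export_site_csv,
    extract_sanger,
    index_sites,
    render_lollipop,
    smooth_windowed,
)
from nomefoot.analysis import footprints_to_bed
from nomefoot.simulate import (
    Epistate,
    SimulationConfig,
    make_reference,
    simulate_dataset,
    write_fasta,
)

out = Path("example_output")
out.mkdir(exist_ok=True)

ref = make_reference(1200, gc=0.5, seed=4)
sites = index_sites(ref)
config = SimulationConfig(
    epistates=[Epistate("mono_nucleosome", 1.0, [(450, 600)])],
    n_molecules=15,
    seed=4,
)
dataset = simulate_dataset(config, ref, sites)
write_fasta(out / "clones.fa", dataset.observed)

calls, qc = extract_sanger(out / "clones.fa", ref, sites)
print(f"{len(calls)} of {len(qc)} clones pass QC "
      f"(conversion >= 0.95 at HCH cytosines, identity >= 0.90)")

matrix_cpg = build_matrix(calls, sites, SiteKind.CPG)
matrix_gpc = build_matrix(calls, sites, SiteKind.GPC)
params = AnalysisParams()  # window 60, region size 140, stringency 0.7
ordering = cluster_molecules(smooth_windowed(matrix_gpc,
                                             params.clustering_window))
footprints = call_footprints(matrix_gpc, params)
nuc = [f for f in footprints if f.kind == "NUCLEOSOME"]
print(f"{len(nuc)} nucleosome calls across {len(calls)} molecules; "
      f"planted nucleosome at [450, 600)")
for call in nuc[:3]:
    print(f"  {call.molecule_id}: [{call.interval.start}, {call.interval.end}) "
          f"protected fraction {call.fraction:.2f}")

(out / "lollipop.svg").write_text(
    render_lollipop(matrix_cpg, matrix_gpc, ordering, footprints))
(out / "footprints.bed").write_text(footprints_to_bed(footprints))
export_site_csv(matrix_gpc).to_csv(out / "gpc_sites.csv", index=False)
print(f"wrote {out}/lollipop.svg, footprints.bed, gpc_sites.csv")
# Each nucleosome call marks >= 140 bp where >= 70% of called GpCs are
# unmethylated, i.e. protected from M.CviPI -- the footprint of a nucleosome.
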