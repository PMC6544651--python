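"""Detecting coexisting nucleosome configurations in one molecule population.

Simulates a locus where 60% of molecules carry an open NDR at the center and
40% have it occluded by a nucleosome (the situation at bivalent promoters),
then classifies single molecules by their accessible-region calls.
"""

from pathlib import Path

from nomefoot import AnalysisParams, SiteKind, build_matrix, extract_region, index_sites
from nomefoot.analysis import call_accessible_regions
from nomefoot.simulate import (
    Epistate,
    SimulationConfig,
    make_reference,
    simulate_dataset,
    write_sam,
)

out = Path("example_output")
out.mkdir(exist_ok=True)

NDR = (700, 900)
flanks = [(150, 550), (1050, 1450)]
ref = make_reference(2000, gc=0.5, seed=8)
sites = index_sites(ref)
config = SimulationConfig(
    epistates=[
        Epistate("ndr_open", 0.6, list(flanks)),
        Epistate("occluded", 0.4, [flanks[0], (600, 1000), flanks[1]]),
    ],
    n_molecules=200,
    seed=8,
)
dataset = simulate_dataset(config, ref, sites)
write_sam(dataset, out / "mixture.sam")
calls = extract_region(out / "mixture.sam", sites.interval, sites, ref)

matrix = build_matrix(calls, sites, SiteKind.GPC)
params = AnalysisParams()
n_open = 0
for mol_id, row in matrix.values.iterrows():
    accessible = call_accessible_regions(
        mol_id, matrix.positions, row.to_numpy(float), matrix.spans[mol_id],
        params.region_size, params.stringency, params.min_sites_per_window)
    if any(c.interval.start < NDR[1] and c.interval.end > NDR[0]
           for c in accessible):
        n_open += 1

truth_open = sum(m.epistate == "ndr_open" for m in dataset.molecules)
print(f"planted open-NDR molecules: {truth_open}/200 "
      f"(mixture fraction 0.6)")
print(f"molecules with an ACCESSIBLE call over the NDR: {n_open}/200 "
      f"({n_open / 200:.2f})")
# Close agreement between the two numbers shows that per-molecule
# accessible-region calls can resolve subpopulations that a
# population-averaged profile would blur into ~60% intermediate occupancy.
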