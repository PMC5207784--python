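"""Simulate a cohort with known truth and recover it end to end.

Draws per-gene diplotypes from the built-in ethnicity-stratified
frequency tables, renders them to endpoint fluorescence and quadruplicate
Ct values with realistic noise, then runs the full pipeline (cluster
genotyping -> ddCt copy numbers -> star-allele calling -> phenotypes) and
compares against the generating truth."""

from pgxpanel import SimulationConfig, simulate_cohort
from pgxpanel.pipeline import run_pipeline

config = SimulationConfig(seed=7)  # default sizes: 126/179/201 subjects
sim = simulate_cohort(config)
print(f"simulated {sim.sample_sheet.shape[0] - 1} subjects + 1 calibrator")

results = run_pipeline(
    fluorescence=sim.fluorescence,
    ct=sim.ct,
    calibrator_id=config.calibrator_id,
)

truth = sim.truth[sim.truth["ethnicity"] != "calibrator"]
merged = truth.merge(results, on=["sample_id", "gene"], suffixes=("_true", "_called"))
by_gene = (merged["diplotype_true"] == merged["diplotype_called"]).groupby(merged["gene"]).mean()
print("\nper-gene diplotype recovery:")
print(by_gene.to_string(float_format="{:.3f}".format))
print("\nA value of 1.000 means every simulated subject's diplotype —")
print("including duplications, *36 hybrids and *5 deletions — was")
print("reconstructed exactly from the noisy synthetic measurements.")
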