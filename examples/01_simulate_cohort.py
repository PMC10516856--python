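"""Generate a small synthetic claims cohort and write the standard CSVs.

The generator plants, per patient, a C50 index diagnosis, stage evidence
(paired metastatic codes for stage-IV patients), cyclic chemotherapy claims
forming known lines of therapy, surgery, and Poisson utilization events with
gamma-distributed costs — and exports the ground truth it used, so each
downstream algorithm can be validated by recovery.
"""

from pathlib import Path

from tnbc_claims import SimulationConfig, simulate, write_claims

cfg = SimulationConfig(
    n_patients=100,
    seed=42,
    contaminant_fractions={
        "screening_only": 0.05,
        "hormone_therapy_user": 0.05,
        "pre2012_activity": 0.03,
    },
)
patients, truth = simulate(cfg)

outdir = Path("scratch/example_cohort")
outdir.mkdir(parents=True, exist_ok=True)
write_claims(patients, outdir / "claims.csv", outdir / "demographics.csv")
truth.to_frame().to_csv(outdir / "ground_truth.csv", index=False)

n_claims = sum(len(p.claims) for p in patients)
n_met = sum(1 for t in truth.records.values() if t.true_stage == "metastatic")
n_cont = sum(1 for t in truth.records.values() if t.is_contaminant)
print(f"wrote {len(patients)} patients / {n_claims} claims to {outdir}")
print(f"true metastatic: {n_met}, planted contaminants: {n_cont}")
print("Each contaminant violates exactly one eligibility rule; the cohort")
print("selection example shows them being rejected for that rule alone.")
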