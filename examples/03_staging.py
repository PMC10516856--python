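"""Claims-based staging: metastatic vs early/locally advanced at index.

A patient is called metastatic (stage IV) when two qualifying claims —
metastatic ICD-10 codes C76-C80 (except C77.3) or configured
metastatic-management procedure codes — occur at least 15 days apart within
a window from 30 days before to 183 days after the index date.
"""

from tnbc_claims import MoleculeCatalog, classify_stage, make_fixture

catalog = MoleculeCatalog()

for name in ("met_two_c78", "c773_only"):
    (patient,) = make_fixture(name)
    index = patient.claims[0].service_date
    label = classify_stage(patient, index, catalog)
    print(f"{name:12s} -> {label.stage:25s} evidence claims: {len(label.evidence)}")

print()
print("Two C78 claims 30 days apart satisfy the rule; C77.3 (axillary-node")
print("secondaries, regional rather than distant spread) never counts, so")
print("that patient stays early/locally advanced.")
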