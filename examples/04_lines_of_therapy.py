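"""Line-of-therapy construction and sequential vs progression tagging.

Two rules split a patient's chemotherapy claims into lines: a claim for a
molecule outside the current regimen 60+ days after the line started opens
a new line (treatment switch), and any drug claim 120+ days after the
previous one opens a new line (treatment gap).  For early-stage patients a
follow-on regimen within 45 days of the previous regimen's end is a planned
sequential treatment; beyond 45 days it marks progressive disease.
"""

from tnbc_claims import (
    MoleculeCatalog,
    build_lines,
    inclusion_drug_claims,
    make_fixture,
    tag_sequential_or_progression,
)

catalog = MoleculeCatalog()

for name in ("switch_day70", "gap_130", "sequential_27d"):
    (patient,) = make_fixture(name)
    lines = build_lines(inclusion_drug_claims(patient.claims, catalog), catalog)
    desc = " | ".join(
        f"L{ln.line_index} {ln.label} {ln.start_date}..{ln.end_date}"
        f" ({ln.start_trigger.value})"
        for ln in lines
    )
    regimens = [r for ln in lines for r in ln.regimens]
    tags, flag = tag_sequential_or_progression(regimens)
    print(f"{name:15s} {desc}")
    print(f"{'':15s} tags: {[t.value for t in tags]}, progression={flag}")

print()
print("AC followed by paclitaxel at day 70 is a switch (new line); the same")
print("molecule after a 130-day silence is a gap-triggered line; a taxane 27")
print("days after AC ends is a new line tagged as planned sequential therapy.")
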