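"""Gene commanding heights and the master regulator, per condition.

Uses the canonical three-condition fixture (reference NN, disease IN,
treated IT). Because each condition carries a different co-expression
block, the top of the hierarchy is condition-specific: the disease
installs its own master regulator.
"""
from gfabric import compute_fabric, compute_hierarchy, make_three_condition_fixture

study, _ = make_three_condition_fixture(seed=7)
for label in ("NN", "IN", "IT"):
    hier = compute_hierarchy(compute_fabric(study[label]))
    top5 = ", ".join(f"{g} ({hier.gch[g]:.1f})" for g in hier.top(5))
    print(f"{label}: GMR = {hier.gmr}  (GCH = {hier.gch[hier.gmr]:.2f})")
    print(f"    top 5 by GCH: {top5}")
print()
print("GCH = (REC + 1) * exp(4<COR^2> - 1): a gene scores high when its")
print("expression is tightly controlled AND strongly coordinated with the")
print("rest of the transcriptome; 1.0 is the neutral baseline.")
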