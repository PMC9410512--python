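"""Treatment-recovery metrics on the three-condition fixture.

The fixture's 40-gene pathway is dysregulated in the disease condition
(IN) and partially restored by the treatment (IT): 7 down- and 5
up-regulated genes recover, 2 genes are newly down-regulated, 1 stays
down. The script categorizes every gene, then prints GER (gene-count
recovery), PRE (restoration of the weighted pathway regulation), and CPR
(reduction of the pathway transcriptomic distance) with its outcome class.
"""
from gfabric import (
    GeneSetCollection,
    analyze_recovery,
    compare_conditions,
    compute_fabric,
    make_three_condition_fixture,
)

study, truth = make_three_condition_fixture(seed=7)
fabrics = {k: compute_fabric(v) for k, v in study.items()}
reg_in = compare_conditions(fabrics["NN"], fabrics["IN"])
reg_it = compare_conditions(fabrics["NN"], fabrics["IT"])
sets = GeneSetCollection({truth.set_name: truth.pathway})

report = analyze_recovery(reg_in, reg_it, sets=sets)
print("recovery categories (disease letter, treated letter; X = neutral):")
print({c: n for c, n in report.counts.items() if n})
print(f"\nGER (all genes) = {report.ger:.2f}%")

scoped = analyze_recovery(reg_in, reg_it, scope=truth.pathway)
print(f"GER (designed pathway only) = {scoped.ger:.2f}%")
row = report.pathway_table.iloc[0]
print(f"\npathway '{report.pathway_table.index[0]}' "
      f"({int(row['n_quantified'])} genes):")
print(f"  WPR disease -> treated: {row['WPR_disease']:.2f} -> "
      f"{row['WPR_treated']:.2f}   PRE = {row['PRE']:.2f}%")
print(f"  PTD disease -> treated: {row['PTD_disease']:.2f} -> "
      f"{row['PTD_treated']:.2f}   CPR = {row['CPR']:.2f}%  "
      f"({row['outcome']})")
print("\n100% would be a perfect return to the reference transcriptome;")
print("negative values would mean the treatment made the pathway worse.")
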