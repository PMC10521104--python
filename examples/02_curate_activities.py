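"""Reduce raw bioactivity rows to per-(structure, target) activity labels.

Rows outside the "Single Protein" assay format, with qualified relations,
disallowed activity types or unconvertible units are dropped; the rest are
normalized to nM and labelled active (<= 1000 nM) or inactive, with
majority vote across duplicates and exact ties discarded.
"""
from ligscreen.curation import filter_chembl, label_ligands
from ligscreen.models import ActivityRow

rows = [
    ActivityRow("m1", "KIN1", "kinase 1", "Homo sapiens", "Single Protein",
                "IC50", 500.0, "nM", "=", smiles="CCO", canonical_key="CCO"),
    ActivityRow("m1", "KIN1", "kinase 1", "Homo sapiens", "Single Protein",
                "IC50", 0.8, "uM", "=", smiles="CCO", canonical_key="CCO"),
    ActivityRow("m1", "KIN1", "kinase 1", "Homo sapiens", "Protein Complex",
                "IC50", 5.0, "nM", "=", smiles="CCO", canonical_key="CCO"),
    ActivityRow("m2", "KIN1", "kinase 1", "Homo sapiens", "Single Protein",
                "Ki", 50000.0, "nM", "=", smiles="CCN", canonical_key="CCN"),
    ActivityRow("m3", "KIN1", "kinase 1", "Homo sapiens", "Single Protein",
                "Kd", 2000.0, "nM", ">", smiles="CCC", canonical_key="CCC"),
]
drop_log = []
kept = filter_chembl(rows, drop_log=drop_log)
print(f"retained {len(kept)} of {len(rows)} rows; dropped: {drop_log}")
for lig in label_ligands(kept):
    print(f"{lig.canonical_key} @ {lig.target_id}: {lig.label} "
          f"({lig.n_supporting_rows} rows)")
# CCO is active at KIN1 (500 nM and 800 nM, both <= 1000 nM; the complex-format
# row never votes); CCN is inactive; CCC is censored (">") and discarded.
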