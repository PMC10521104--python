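"""Five-fingerprint 2D Tanimoto screen of the scaffold against references.

A pair is a 2D hit only when all five coefficients reach their thresholds
(MACCS >= 0.7, ECFP4 >= 0.3, ECFP6 >= 0.4, FCFP4 >= 0.3, FCFP6 >= 0.4).
"""
from rdkit import Chem

from ligscreen.fingerprints import fingerprint_set, screen_2d
from ligscreen.states import enumerate_states, oxindole_state_space
from ligscreen.synthetic import make_analogs

base = enumerate_states(oxindole_state_space())[0]
refs = {"analog_1": make_analogs(base.smiles, 1)[0],
        "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
        "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C"}
queries = {base.item_id: fingerprint_set(Chem.MolFromSmiles(base.smiles))}
references = {k: fingerprint_set(Chem.MolFromSmiles(s)) for k, s in refs.items()}
for row in screen_2d(queries, references):
    tcs = " ".join(f"{k}={v:.2f}" for k, v in row.tc.items())
    print(f"{row.query_id} vs {row.reference_id:>9}: {tcs} -> "
          f"{'HIT' if row.pass_2d else 'no'}")
# The single-substituent analog shares the scaffold and passes every
# threshold; unrelated drugs fail the MACCS >= 0.7 cut (and others).
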