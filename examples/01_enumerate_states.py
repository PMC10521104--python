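"""Enumerate the tautomer/stereo state space of the oxindole query scaffold.

The scaffold is an indolin-2-one linked to a pyrazolone through a
methylene; two tautomer sites (indole lactam/imino-ol, five pyrazolone
proton placements) and one stereocenter give 2 x 5 x 2 = 20 states.
"""
from ligscreen.states import enumerate_states, oxindole_state_space

items = enumerate_states(oxindole_state_space())
print(f"{len(items)} states, {len({i.canonical_key for i in items})} distinct structures\n")
for it in items[:6]:
    print(f"{it.item_id:>12}  {'/'.join(it.site_states):24} "
          f"{it.stereo_config[0]:12}  {it.canonical_key}")
print("...")
# Each line is one tautomer/enantiomer: its display id, the proton placement
# labels at the two tautomer sites, the enantiomer label, and the canonical
# isomeric SMILES used as the cross-database join key.
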