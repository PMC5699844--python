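"""Wash raw SMILES and compute the 29 physicochemical descriptors.

The wash keeps the largest fragment, ionizes strong acids/bases as at pH 7,
and canonicalizes; descriptors are then computed on the washed structure.
"""

from allocomp import compute_descriptors, wash

for raw in ["CC(=O)O", "CCN.Cl", "CC(=O)Nc1ccc(O)cc1", "c1ccccc1"]:
    washed = wash(raw)
    v = compute_descriptors(washed)
    d = v.as_dict()
    print(f"{raw:24} -> {washed}")
    print(
        f"   heavy atoms {v.a_heavy:3d} | aromatic fraction {d['a_aro/HA']:.2f} | "
        f"donors {v.a_don} | acceptors {v.a_acc} | rotatable {v.b_1rotN} | "
        f"SlogP {v.SlogP:+.2f} | net charge {v.FCharge:+d}"
    )

print(
    "\nEach line shows size, aromaticity, hydrogen-bonding capacity, "
    "flexibility,\nlipophilicity and formal charge of the washed species — "
    "the quantities later\ncompared between the allosteric and competitive sets."
)
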