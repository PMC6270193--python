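"""Split lupane triterpenoids into core + R1 + R2 at the C-28/C-3 cut.

Betulinic acid and betulin share the pentacyclic lupane skeleton and
differ only at C-28 (carboxyl vs hydroxymethyl); derivatives vary at the
3-O position as well. The cut rule severs the exocyclic C-17 to C-28
bond (R1) and the C3—O bond (R2, so the ester oxygen travels with the
substituent).
"""

from fragqsar import lupane_cut_rule, parse_smiles, split_molecule
from fragqsar.fragmentation import BETULIN_SMILES, BETULINIC_ACID_SMILES

rule = lupane_cut_rule()
molecules = {
    "betulinic acid": BETULINIC_ACID_SMILES,
    "betulin": BETULIN_SMILES,
    "3-O-acetyl betulinic acid": (
        "CC(=C)C1CCC2(C(O)=O)CCC3(C)C(CCC4C5(C)CCC(OC(C)=O)C(C)(C)C5CCC34C)C12"
    ),
}

for name, smi in molecules.items():
    mol = parse_smiles(smi, name)
    fs = split_molecule(mol, rule)
    print(f"{name}:")
    print(f"  R1 (C-28 side): {fs.fragment_smiles('R1')}")
    print(f"  R2 (3-O side) : {fs.fragment_smiles('R2')}")
    print(f"  atoms conserved: {fs.atom_balance_ok}")
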