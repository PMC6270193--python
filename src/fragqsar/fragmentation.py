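"""Structure input and R-group decomposition of a congeneric series.

Each molecule of the series is split into three pieces — a common core
plus two substituent fragments (R1, R2) — by cutting two declared acyclic
single bonds. For the lupane triterpenoids this is the classic cut at the
C-28 side chain (R1, borne on C-17) and the C3—O bond (R2, so the ester /
ether oxygen travels with the substituent, matching how R-groups such as
—OCOCH3 are written).

The cut sites are declared, not detected: a :class:`CutRule` carries a
core pattern written as SMILES/SMARTS in which two dummy atoms with atom
maps 1 and 2 mark where the substituents attach. The bond from each
mapped dummy to its core neighbour is the bond that gets cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional

from rdkit import Chem
from rdkit.Chem import rdPartialCharges

__all__ = [
    "CutRule",
    "FragmentSet",
    "LUPANE_CORE_SMILES",
    "lupane_cut_rule",
    "parse_structures",
    "parse_smiles",
    "split_molecule",
    "assign_partial_charges",
    "CoreNotFoundError",
    "AmbiguousCoreError",
    "RecordParseError",
    "UnsupportedAtomError",
]

#: Lupane (lup-20(29)-ene) pentacyclic skeleton with attachment dummies:
#: map 1 = C-17 attachment of the C-28 substituent (R1), map 2 = C-3
#: attachment of the 3-O substituent (R2).
LUPANE_CORE_SMILES = (
    "CC(=C)C1CCC2([*:1])CCC3(C)C(CCC4C5(C)CCC([*:2])C(C)(C)C5CCC34C)C12"
)

#: SMILES of betulinic acid and betulin built from the same skeleton.
BETULINIC_ACID_SMILES = (
    "CC(=C)C1CCC2(C(O)=O)CCC3(C)C(CCC4C5(C)CCC(O)C(C)(C)C5CCC34C)C12"
)
BETULIN_SMILES = (
    "CC(=C)C1CCC2(CO)CCC3(C)C(CCC4C5(C)CCC(O)C(C)(C)C5CCC34C)C12"
)


class CoreNotFoundError(ValueError):
    """The cut rule's core pattern does not match the molecule."""


class AmbiguousCoreError(ValueError):
    """The core pattern matches with more than one distinct cut-bond set."""


class RecordParseError(ValueError):
    """An input record could not be parsed; carries its index."""

    def __init__(self, index: int, message: str):
        self.index = index
        super().__init__(f"record {index}: {message}")


class UnsupportedAtomError(ValueError):
    """An element without partial-charge parameters was encountered."""


@dataclass
class CutRule:
    """Declared core pattern plus two labeled cut bonds.

    ``core_pattern`` is SMILES/SMARTS text containing dummy atoms with
    atom maps 1 (R1 site) and 2 (R2 site); each dummy must have exactly
    one neighbour. When the pattern is matched against a molecule, the
    dummies land on the first substituent atoms and the bonds from those
    atoms back into the core are the bonds that get cut.
    """

    core_pattern: str
    name: str = "cut-rule"
    _query: Optional[Chem.Mol] = field(default=None, repr=False, compare=False)

    def query_mol(self) -> Chem.Mol:
        if self._query is None:
            q = Chem.MolFromSmiles(self.core_pattern)
            if q is None:
                q = Chem.MolFromSmarts(self.core_pattern)
            if q is None:
                raise ValueError(f"unparseable core pattern: {self.core_pattern!r}")
            # dummy atoms must act as wildcards during substructure search
            params = Chem.AdjustQueryParameters.NoAdjustments()
            params.makeDummiesQueries = True
            q = Chem.AdjustQueryProperties(q, params)
            maps = [a.GetAtomMapNum() for a in q.GetAtoms() if a.GetAtomicNum() == 0]
            if sorted(maps) != [1, 2]:
                raise ValueError(
                    "core pattern needs exactly two dummy atoms with maps 1 and 2"
                )
            object.__setattr__(self, "_query", q)
        return self._query


def lupane_cut_rule() -> CutRule:
    """The built-in C-28 / C-3 cut rule for the lupane series."""
    return CutRule(core_pattern=LUPANE_CORE_SMILES, name="lupane-C28-C3")


@dataclass
class FragmentSet:
    """A molecule decomposed into common core plus labeled R-groups.

    Fragment molecules carry one attachment dummy atom each (isotope and
    atom map record the label number); the core carries two.
    """

    parent_name: str
    core: Chem.Mol
    fragments: Dict[str, Chem.Mol]

    def heavy_atoms(self, mol: Chem.Mol) -> int:
        return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 0)

    @property
    def atom_balance_ok(self) -> bool:
        """Core + fragment real-atom counts must equal the parent's."""
        total = self.heavy_atoms(self.core) + sum(
            self.heavy_atoms(m) for m in self.fragments.values()
        )
        return total == self._parent_heavy

    _parent_heavy: int = 0

    def fragment_smiles(self, label: str) -> str:
        return Chem.MolToSmiles(self.fragments[label])


def parse_smiles(text: str, name: str = "") -> Chem.Mol:
    """Parse one SMILES string into a sanitized molecule."""
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {text!r}")
    if name:
        mol.SetProp("_Name", name)
    return mol


def parse_structures(path, format: Literal["smiles", "sdf"] = "smiles") -> List[Chem.Mol]:
    """Read a SMILES file (one record per line, optional name column) or
    an SDF V2000 file into sanitized molecules, preserving input order."""
    mols: List[Chem.Mol] = []
    if format == "smiles":
        with open(path) as fh:
            lines = [ln.strip() for ln in fh]
        records = [(i, ln) for i, ln in enumerate(lines) if ln and not ln.startswith("#")]
        if not records:
            raise ValueError(f"no records in {path}")
        for idx, ln in records:
            parts = ln.split(None, 1)
            try:
                mols.append(parse_smiles(parts[0], parts[1].strip() if len(parts) > 1 else f"mol{idx}"))
            except ValueError as exc:
                raise RecordParseError(idx, str(exc)) from exc
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        empty = True
        for idx, mol in enumerate(supplier):
            empty = False
            if mol is None:
                raise RecordParseError(idx, "unparseable SDF record")
            mols.append(mol)
        if empty:
            raise ValueError(f"no records in {path}")
    else:
        raise ValueError(f"unknown format {format!r}")
    return mols


def _cut_bonds_for_match(mol: Chem.Mol, query: Chem.Mol, match: tuple) -> dict:
    """Map label -> (substituent_atom, core_atom) bond for one core match."""
    bonds = {}
    for qatom in query.GetAtoms():
        if qatom.GetAtomicNum() != 0:
            continue
        label = f"R{qatom.GetAtomMapNum()}"
        nbrs = qatom.GetNeighbors()
        if len(nbrs) != 1:
            raise ValueError(f"dummy for {label} must have exactly one neighbour")
        sub_atom = match[qatom.GetIdx()]
        core_atom = match[nbrs[0].GetIdx()]
        bond = mol.GetBondBetweenAtoms(sub_atom, core_atom)
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            raise ValueError(f"{label} cut bond must be an acyclic single bond")
        bonds[label] = (sub_atom, core_atom)
    return bonds


def split_molecule(mol: Chem.Mol, rule: CutRule) -> FragmentSet:
    """Split a molecule into core + R1 + R2 at the rule's declared bonds.

    Raises :class:`CoreNotFoundError` when the pattern does not match and
    :class:`AmbiguousCoreError` when symmetric matches select different
    bonds to cut.
    """
    query = rule.query_mol()
    # uniquify=False: symmetric matches over the same atom set can still
    # select different bonds to cut, and that ambiguity must be caught
    matches = mol.GetSubstructMatches(query, uniquify=False, useChirality=False)
    if not matches:
        raise CoreNotFoundError(
            f"core pattern {rule.name!r} not found in "
            f"{mol.GetProp('_Name') if mol.HasProp('_Name') else Chem.MolToSmiles(mol)}"
        )
    bond_sets = []
    for match in matches:
        bonds = _cut_bonds_for_match(mol, query, match)
        key = tuple(sorted((lbl, *pair) for lbl, pair in bonds.items()))
        if key not in [b[0] for b in bond_sets]:
            bond_sets.append((key, bonds))
    if len(bond_sets) > 1:
        raise AmbiguousCoreError(
            f"core pattern matches {len(bond_sets)} distinct cut-bond sets: "
            + "; ".join(str(k) for k, _ in bond_sets)
        )
    bonds = bond_sets[0][1]

    bond_ids = []
    dummy_labels = []
    labels_in_order = []
    for label in sorted(bonds):  # R1 then R2
        sub_atom, core_atom = bonds[label]
        bond_ids.append(mol.GetBondBetweenAtoms(sub_atom, core_atom).GetIdx())
        num = int(label[1:])
        dummy_labels.append((num, num))
        labels_in_order.append(label)

    cut = Chem.FragmentOnBonds(mol, bond_ids, addDummies=True, dummyLabels=dummy_labels)
    pieces = Chem.GetMolFrags(cut, asMols=True, sanitizeFrags=True)

    core = None
    fragments: Dict[str, Chem.Mol] = {}
    for piece in pieces:
        dummies = [a for a in piece.GetAtoms() if a.GetAtomicNum() == 0]
        for d in dummies:  # record the label as an atom map too
            d.SetAtomMapNum(d.GetIsotope())
        if len(dummies) == 2:
            core = piece
        elif len(dummies) == 1:
            fragments[f"R{dummies[0].GetIsotope()}"] = piece
        else:  # pragma: no cover - cannot happen with two declared cuts
            raise RuntimeError("unexpected fragment with no attachment dummy")
    if core is None or set(fragments) != {"R1", "R2"}:
        raise RuntimeError("split did not yield core + R1 + R2")

    name = mol.GetProp("_Name") if mol.HasProp("_Name") else Chem.MolToSmiles(mol)
    fs = FragmentSet(parent_name=name, core=core, fragments=fragments)
    fs._parent_heavy = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 0)
    return fs


def assign_partial_charges(mol: Chem.Mol, add_hs: bool = True) -> Chem.Mol:
    """Assign Gasteiger (PEOE) partial charges to every atom.

    Returns a copy (with explicit hydrogens when ``add_hs``) whose atoms
    carry a ``partial_charge`` double property; the charges sum to the
    molecule's net formal charge to within the iteration tolerance.
    """
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            raise UnsupportedAtomError(
                "dummy attachment atoms carry no charge parameters; cap them first"
            )
    work = Chem.AddHs(mol) if add_hs else Chem.Mol(mol)
    try:
        rdPartialCharges.ComputeGasteigerCharges(work, throwOnParamFailure=True)
    except Exception as exc:
        raise UnsupportedAtomError(str(exc)) from exc
    for atom in work.GetAtoms():
        q = atom.GetDoubleProp("_GasteigerCharge")
        if not add_hs:
            q += atom.GetDoubleProp("_GasteigerHCharge")
        atom.SetDoubleProp("partial_charge", q)
    return work
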