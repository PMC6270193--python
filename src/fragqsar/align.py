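"""Deterministic canonical 3-D poses for substituent fragments.

The point of a fragment-based ("topomer") CoMFA is that whole-molecule
alignment is never needed: every fragment is given a single, rule-based
3-D pose, so graph-identical fragments always produce identical field
descriptors no matter which parent molecule they came from.

The pose rules here are a documented, self-contained scheme:

1. the fragment graph is canonically reordered (so the pose is a function
   of the graph, not of the parent's atom numbering), its attachment
   dummy is capped with a carbon standing in for the core attachment
   atom, and one conformer is built by seeded distance-geometry
   embedding followed by force-field relaxation;
2. every acyclic rotatable torsion is set to 180° (anti), walking
   outward from the attachment atom;
3. the pose is rigidly canonicalized: attachment atom at the origin,
   open-valence direction (toward the core) along +X, the azimuthal
   rotation fixed by the highest-canonical-rank neighbour, and the
   residual mirror ambiguity resolved by the sign of the first
   out-of-plane atom in rank order.

Ring conformations are kept as embedded (flagged, not canonicalized).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolTransforms

from .fragmentation import assign_partial_charges

__all__ = [
    "Fragment3D",
    "embed_3d",
    "canonicalize_pose",
    "canonical_torsions",
    "topomer_pose",
    "EmbeddingError",
    "DEFAULT_EMBED_SEED",
]

#: Default distance-geometry seed; any fixed value works, it only has to
#: be the same everywhere so identical fragments embed identically.
DEFAULT_EMBED_SEED = 20130822

_COLLINEAR_TOL = 1e-6


class EmbeddingError(RuntimeError):
    """Distance-geometry embedding failed after bounded retries."""


@dataclass
class Fragment3D:
    """A fragment with one canonical conformer.

    ``mol`` is the capped fragment (attachment dummy replaced by a carbon
    representing the core side, explicit hydrogens added) carrying one
    conformer and Gasteiger charges. ``attachment_idx`` is the fragment
    atom bonded to the cap; after canonicalization it sits at the origin
    with the cap along +X. ``field_mask`` excludes the cap carbon and its
    hydrogens from field evaluation.
    """

    mol: Chem.Mol
    attachment_idx: int
    cap_idx: int
    provenance: str = ""
    flags: List[str] = dc_field(default_factory=list)

    @property
    def coords(self) -> np.ndarray:
        return self.mol.GetConformer().GetPositions()

    def set_coords(self, xyz: np.ndarray) -> None:
        conf = self.mol.GetConformer()
        for i, p in enumerate(xyz):
            conf.SetAtomPosition(i, p.tolist())

    @property
    def charges(self) -> np.ndarray:
        return np.array(
            [a.GetDoubleProp("partial_charge") for a in self.mol.GetAtoms()]
        )

    @property
    def elements(self) -> List[str]:
        return [a.GetSymbol() for a in self.mol.GetAtoms()]

    @property
    def field_mask(self) -> np.ndarray:
        """True for atoms that contribute to the fields (cap excluded)."""
        mask = np.ones(self.mol.GetNumAtoms(), dtype=bool)
        mask[self.cap_idx] = False
        for nbr in self.mol.GetAtomWithIdx(self.cap_idx).GetNeighbors():
            if nbr.GetAtomicNum() == 1:
                mask[nbr.GetIdx()] = False
        return mask

    @property
    def open_valence_direction(self) -> np.ndarray:
        xyz = self.coords
        v = xyz[self.cap_idx] - xyz[self.attachment_idx]
        return v / np.linalg.norm(v)

    def copy(self) -> "Fragment3D":
        return Fragment3D(
            mol=Chem.Mol(self.mol),
            attachment_idx=self.attachment_idx,
            cap_idx=self.cap_idx,
            provenance=self.provenance,
            flags=list(self.flags),
        )


def _canonical_ranks(mol: Chem.Mol) -> List[int]:
    return list(Chem.CanonicalRankAtoms(mol, breakTies=False))


def _rank_order(mol: Chem.Mol) -> List[int]:
    """Atom indices sorted by descending canonical rank, index tiebreak."""
    ranks = _canonical_ranks(mol)
    return sorted(range(mol.GetNumAtoms()), key=lambda i: (-ranks[i], i))


def embed_3d(fragment: Chem.Mol, seed: int = DEFAULT_EMBED_SEED) -> Fragment3D:
    """Build one deterministic conformer for a fragment with a dummy.

    The fragment's single attachment dummy is replaced by a carbon cap,
    hydrogens are made explicit, one conformer is generated with seeded
    ETKDG distance geometry, relaxed with MMFF94 (UFF fallback), and
    Gasteiger charges are assigned on the capped structure. The fragment
    graph is canonically reordered first so that isomorphic fragments
    from different parents yield byte-identical input to the embedder.
    """
    dummies = [a.GetIdx() for a in fragment.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 1:
        raise ValueError("fragment must carry exactly one attachment dummy")
    provenance = fragment.GetProp("_Name") if fragment.HasProp("_Name") else ""

    # canonical graph round-trip: pose becomes a function of the graph only
    smi = Chem.MolToSmiles(fragment)
    work = Chem.MolFromSmiles(smi)
    if work is None:  # pragma: no cover - canonical SMILES always reparses
        raise ValueError(f"fragment SMILES round-trip failed: {smi}")

    rw = Chem.RWMol(work)
    cap_idx = next(a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() == 0)
    cap = rw.GetAtomWithIdx(cap_idx)
    cap.SetAtomicNum(6)
    cap.SetIsotope(0)
    cap.SetAtomMapNum(0)
    cap.SetNoImplicit(False)
    Chem.SanitizeMol(rw)
    capped = Chem.AddHs(rw.GetMol())

    attachment_idx = next(
        n.GetIdx()
        for n in capped.GetAtomWithIdx(cap_idx).GetNeighbors()
        if n.GetAtomicNum() != 1
    )

    params = AllChem.ETKDGv3()
    params.useRandomCoords = False
    conf_ok = -1
    for attempt in range(5):
        params.randomSeed = int(seed) + attempt
        conf_ok = AllChem.EmbedMolecule(capped, params)
        if conf_ok == 0:
            break
    if conf_ok != 0:
        raise EmbeddingError(f"embedding failed for {smi}")
    try:
        if AllChem.MMFFHasAllMoleculeParams(capped):
            AllChem.MMFFOptimizeMolecule(capped, maxIters=500)
        else:
            AllChem.UFFOptimizeMolecule(capped, maxIters=500)
    except Exception:  # keep the raw DG geometry if relaxation fails
        pass

    charged = assign_partial_charges(Chem.RemoveHs(capped), add_hs=True)
    # assign_partial_charges(AddHs) preserves atom order of the capped mol
    if charged.GetNumAtoms() == capped.GetNumAtoms():
        for a_src, a_dst in zip(charged.GetAtoms(), capped.GetAtoms()):
            a_dst.SetDoubleProp("partial_charge", a_src.GetDoubleProp("partial_charge"))
    else:  # pragma: no cover - defensive
        raise RuntimeError("charge assignment changed the atom count")

    frag = Fragment3D(
        mol=capped,
        attachment_idx=attachment_idx,
        cap_idx=cap_idx,
        provenance=provenance or smi,
    )
    ringy = any(
        b.IsInRing() for b in capped.GetBonds()
    )
    if ringy:
        frag.flags.append("ring-conformation-as-embedded")
    return frag


def _rotation_onto_x(v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector v onto +X."""
    x = np.array([1.0, 0.0, 0.0])
    c = float(np.dot(v, x))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:  # antiparallel: rotate pi about Y
        return np.diag([-1.0, 1.0, -1.0])
    axis = np.cross(v, x)
    axis /= np.linalg.norm(axis)
    s = float(np.sqrt(1 - c * c))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def canonicalize_pose(frag: Fragment3D) -> Fragment3D:
    """Rigidly move a fragment into its canonical frame (idempotent).

    Attachment atom → origin; open-valence (cap) direction → +X; rotation
    about X fixed by putting the highest-canonical-rank neighbour of the
    attachment atom at azimuth 0 (in the +Y half-plane); mirror ambiguity
    resolved by requiring the first out-of-plane atom in canonical-rank
    order to have non-negative Z. Fragments whose atoms are all collinear
    with X keep only the translation + axis alignment and are flagged.
    """
    out = frag.copy()
    xyz = out.coords - out.coords[out.attachment_idx]
    v = xyz[out.cap_idx]
    v = v / np.linalg.norm(v)
    xyz = xyz @ _rotation_onto_x(v).T

    order = _rank_order(out.mol)
    nbrs = [
        n.GetIdx()
        for n in out.mol.GetAtomWithIdx(out.attachment_idx).GetNeighbors()
        if n.GetIdx() != out.cap_idx
    ]
    # azimuth reference: highest-rank neighbour with off-axis geometry,
    # falling back to any off-axis atom in rank order
    candidates = [i for i in order if i in nbrs] + [
        i for i in order if i not in nbrs and i not in (out.attachment_idx, out.cap_idx)
    ]
    ref = None
    for i in candidates:
        if np.hypot(xyz[i, 1], xyz[i, 2]) > _COLLINEAR_TOL:
            ref = i
            break
    if ref is None:
        out.flags.append("collinear-degenerate")
        out.set_coords(xyz)
        return out

    phi = np.arctan2(xyz[ref, 2], xyz[ref, 1])  # rotate ref into +Y, z=0
    c, s = np.cos(-phi), np.sin(-phi)
    rot_x = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    xyz = xyz @ rot_x.T

    for i in order:
        if abs(xyz[i, 2]) > _COLLINEAR_TOL:
            if xyz[i, 2] < 0:
                xyz[:, 2] = -xyz[:, 2]
            break

    out.set_coords(xyz)
    return out


def _bfs_bond_order(mol: Chem.Mol, start: int) -> List[Tuple[int, int]]:
    """Acyclic rotatable bonds as (near, far) pairs in BFS order from start."""
    from collections import deque

    dist = {start: 0}
    dq = deque([start])
    while dq:
        u = dq.popleft()
        for nbr in mol.GetAtomWithIdx(u).GetNeighbors():
            v = nbr.GetIdx()
            if v not in dist:
                dist[v] = dist[u] + 1
                dq.append(v)

    ranks = _canonical_ranks(mol)
    bonds = []
    for b in mol.GetBonds():
        if b.IsInRing() or b.GetBondType() != Chem.BondType.SINGLE:
            continue
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        deg_i = sum(1 for _ in mol.GetAtomWithIdx(i).GetNeighbors())
        deg_j = sum(1 for _ in mol.GetAtomWithIdx(j).GetNeighbors())
        if deg_i < 2 or deg_j < 2:
            continue
        near, far = (i, j) if dist.get(i, 0) <= dist.get(j, 0) else (j, i)
        bonds.append((dist.get(near, 0), -ranks[near], near, far))
    bonds.sort()
    return [(near, far) for _, _, near, far in bonds]


def _torsion_reference(mol: Chem.Mol, center: int, exclude: int) -> Optional[int]:
    ranks = _canonical_ranks(mol)
    nbrs = [
        n.GetIdx()
        for n in mol.GetAtomWithIdx(center).GetNeighbors()
        if n.GetIdx() != exclude
    ]
    if not nbrs:
        return None
    nbrs.sort(key=lambda i: (-ranks[i], i))
    heavy = [i for i in nbrs if mol.GetAtomWithIdx(i).GetAtomicNum() > 1]
    return heavy[0] if heavy else nbrs[0]


def canonical_torsions(frag: Fragment3D) -> Fragment3D:
    """Set every acyclic rotatable torsion to 180° (anti).

    Bonds are processed outward from the attachment atom (BFS order,
    canonical-rank tiebreak); for each bond the torsion is defined by the
    highest-canonical-rank heavy neighbour on each side. Fragments with
    no rotatable bonds are returned unchanged.
    """
    out = frag.copy()
    mol = out.mol
    conf = mol.GetConformer()
    for near, far in _bfs_bond_order(mol, out.attachment_idx):
        a = _torsion_reference(mol, near, far)
        d = _torsion_reference(mol, far, near)
        if a is None or d is None:
            continue
        try:
            rdMolTransforms.SetDihedralDeg(conf, a, near, far, d, 180.0)
        except ValueError:  # collinear or ring-constrained torsion
            out.flags.append(f"torsion-unset-{near}-{far}")
    return out


def topomer_pose(fragment: Chem.Mol, seed: int = DEFAULT_EMBED_SEED) -> Fragment3D:
    """Full pose pipeline: embed → canonical frame → anti torsions → frame."""
    frag = embed_3d(fragment, seed=seed)
    frag = canonicalize_pose(frag)
    frag = canonical_torsions(frag)
    return canonicalize_pose(frag)


def write_aligned_sdf(path, frags: Dict[str, Fragment3D], seed: int) -> None:
    """Write canonical fragment poses to an SDF with provenance props."""
    writer = Chem.SDWriter(str(path))
    try:
        for label, frag in frags.items():
            mol = Chem.Mol(frag.mol)
            mol.SetProp("_Name", f"{frag.provenance}:{label}")
            mol.SetProp("fragment_label", label)
            mol.SetProp("embed_seed", str(seed))
            mol.SetProp("pose_flags", ",".join(frag.flags) or "none")
            writer.write(mol)
    finally:
        writer.close()
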