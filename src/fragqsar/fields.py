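"""CoMFA-style steric and electrostatic grid fields for aligned fragments.

At each point of a rectilinear lattice, a probe atom (sp³ carbon, +1 e by
convention) interacts with every fragment atom:

* steric: Lennard-Jones, Σᵢ εᵢⱼ[(rₘᵢₙ,ᵢⱼ/d)¹² − 2(rₘᵢₙ,ᵢⱼ/d)⁶] with
  Lorentz–Berthelot combination, clamped at +clamp (default 30 kcal/mol);
* electrostatic: Coulomb with distance-dependent dielectric ε = d,
  332.0·Σᵢ qᵢ·q_probe/dᵢ², clamped at ±clamp.

Lattice points where the steric clamp is reached ("inside" the fragment)
are masked; their electrostatic values are replaced by the column mean
during matrix assembly so the descriptor matrix stays rectangular.

Per-compound rows concatenate [R1 steric | R1 electrostatic | R2 steric |
R2 electrostatic] on per-label grids shared across the series, so
columns are comparable between compounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .align import Fragment3D

__all__ = [
    "GridSpec",
    "ProbeParams",
    "FieldBlock",
    "LJ_TABLE",
    "COULOMB_CONSTANT",
    "make_grid",
    "steric_field",
    "electrostatic_field",
    "compute_field_block",
    "build_descriptor_matrix",
    "assemble_matrix",
    "write_cube",
]

#: kcal·Å·mol⁻¹·e⁻² Coulomb prefactor (Tripos convention).
COULOMB_CONSTANT = 332.0

#: Element → (vdW radius Rmin/2 in Å, well depth ε in kcal/mol).
#: Tripos-style van der Waals parameters for the elements that occur in
#: typical medicinal-chemistry substituents; anything else is an error.
LJ_TABLE: Dict[str, Tuple[float, float]] = {
    "H": (1.50, 0.042),
    "C": (1.70, 0.107),
    "N": (1.55, 0.095),
    "O": (1.52, 0.116),
    "S": (1.80, 0.314),
    "F": (1.47, 0.109),
    "Cl": (1.75, 0.314),
    "Br": (1.85, 0.434),
    "I": (1.98, 0.623),
}


class UnsupportedElementError(KeyError):
    """An element has no Lennard-Jones parameters in the built-in table."""


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned rectilinear lattice: point (i,j,k) = origin + spacing·(i,j,k)."""

    origin: Tuple[float, float, float]
    spacing: float
    dims: Tuple[int, int, int]

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("dims must each be >= 1")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All lattice points, shape (n_points, 3), index-major in (i,j,k)."""
        nx, ny, nz = self.dims
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        return np.asarray(self.origin) + self.spacing * idx


@dataclass(frozen=True)
class ProbeParams:
    """CoMFA probe: sp³ carbon with +1 charge, ±30 kcal/mol clamp."""

    lj_epsilon: float = 0.107
    lj_rmin: float = 1.70
    probe_charge: float = 1.0
    clamp: float = 30.0

    def __post_init__(self):
        if min(self.lj_epsilon, self.lj_rmin, self.clamp) <= 0:
            raise ValueError("probe parameters must be positive")


@dataclass
class FieldBlock:
    """Steric + electrostatic values of one fragment on one grid."""

    grid: GridSpec
    steric: np.ndarray
    electrostatic: np.ndarray
    inside_mask: np.ndarray


def make_grid(
    fragments: Sequence[Fragment3D], spacing: float = 2.0, padding: float = 4.0
) -> GridSpec:
    """Shared grid covering all fragments' atoms plus padding on each side.

    The origin is snapped down to a multiple of the spacing so the grid —
    and hence every descriptor column — is reproducible no matter which
    fragments were seen first.
    """
    if not fragments:
        raise ValueError("at least one fragment is required")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    all_xyz = np.vstack([f.coords for f in fragments])
    lo = all_xyz.min(axis=0) - padding
    hi = all_xyz.max(axis=0) + padding
    origin = np.floor(lo / spacing) * spacing
    dims = tuple(int(np.ceil((h - o) / spacing)) + 1 for h, o in zip(hi, origin))
    return GridSpec(origin=tuple(float(x) for x in origin), spacing=float(spacing), dims=dims)


def _lj_params(elements: Iterable[str]) -> Tuple[np.ndarray, np.ndarray]:
    radii, eps = [], []
    for el in elements:
        if el not in LJ_TABLE:
            raise UnsupportedElementError(
                f"no Lennard-Jones parameters for element {el!r}"
            )
        r, e = LJ_TABLE[el]
        radii.append(r)
        eps.append(e)
    return np.array(radii), np.array(eps)


def _distances(frag: Fragment3D, grid: GridSpec) -> Tuple[np.ndarray, np.ndarray]:
    """(points × atoms) distance matrix over field-contributing atoms."""
    mask = frag.field_mask
    xyz = frag.coords[mask]
    pts = grid.points()
    d = np.linalg.norm(pts[:, None, :] - xyz[None, :, :], axis=2)
    return d, mask


def steric_field(
    frag: Fragment3D, grid: GridSpec, probe: ProbeParams = ProbeParams()
) -> np.ndarray:
    """Lennard-Jones probe energy at every lattice point, clamped at +clamp."""
    d, mask = _distances(frag, grid)
    radii, eps = _lj_params(np.array(frag.elements)[mask])
    rmin_ij = radii + probe.lj_rmin  # Lorentz: sum of radii
    eps_ij = np.sqrt(eps * probe.lj_epsilon)  # Berthelot: geometric mean
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        ratio6 = (rmin_ij[None, :] / d) ** 6
        contrib = eps_ij[None, :] * (ratio6**2 - 2.0 * ratio6)
    # a lattice point on an atom center contributes +inf, not NaN
    contrib = np.where(np.isfinite(contrib), contrib, np.inf)
    e = contrib.sum(axis=1)
    return np.minimum(e, probe.clamp)


def electrostatic_field(
    frag: Fragment3D, grid: GridSpec, probe: ProbeParams = ProbeParams()
) -> np.ndarray:
    """Coulomb probe energy (distance-dependent dielectric), clamped ±clamp."""
    d, mask = _distances(frag, grid)
    q = frag.charges[mask]
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = COULOMB_CONSTANT * q[None, :] * probe.probe_charge / d**2
    # on an atom center the sign of the charge decides the clamp direction
    contrib = np.where(np.isnan(contrib), 0.0, contrib)
    e = contrib.sum(axis=1)
    e = np.where(np.isnan(e), 0.0, e)
    return np.sign(e) * np.minimum(np.abs(e), probe.clamp)


def compute_field_block(
    frag: Fragment3D, grid: GridSpec, probe: ProbeParams = ProbeParams()
) -> FieldBlock:
    steric = steric_field(frag, grid, probe)
    elec = electrostatic_field(frag, grid, probe)
    inside = steric >= probe.clamp
    return FieldBlock(grid=grid, steric=steric, electrostatic=elec, inside_mask=inside)


ColumnMeta = Tuple[str, str, int]  # (fragment label, field kind, lattice index)


def build_descriptor_matrix(
    series: Sequence[Dict[str, Fragment3D]],
    grids: Dict[str, GridSpec],
    probe: ProbeParams = ProbeParams(),
    labels: Sequence[str] = ("R1", "R2"),
) -> Tuple[np.ndarray, List[ColumnMeta]]:
    """Assemble the per-compound descriptor matrix for a series.

    ``series`` holds one mapping label → aligned fragment per compound;
    ``grids`` one shared grid per label. Rows follow input order; columns
    are [label, steric | electrostatic] blocks, lattice-index-major.
    Electrostatic values at steric-clamped points are imputed with the
    column mean over non-clamped compounds.
    """
    for i, compound in enumerate(series):
        for label in labels:
            if label not in compound:
                raise ValueError(f"compound {i} is missing fragment {label!r}")

    blocks: Dict[str, List[FieldBlock]] = {lbl: [] for lbl in labels}
    for compound in series:
        for label in labels:
            blocks[label].append(compute_field_block(compound[label], grids[label], probe))
    return assemble_matrix(blocks, grids, labels)


def assemble_matrix(
    blocks: Dict[str, List[FieldBlock]],
    grids: Dict[str, GridSpec],
    labels: Sequence[str] = ("R1", "R2"),
) -> Tuple[np.ndarray, List[ColumnMeta]]:
    """Stack per-compound field blocks into the descriptor matrix.

    Same column layout and inside-mask imputation as
    :func:`build_descriptor_matrix`; split out so callers that cache
    per-fragment field blocks can reuse the assembly step.
    """
    columns: List[np.ndarray] = []
    meta: List[ColumnMeta] = []
    for label in labels:
        fb = blocks[label]
        ster = np.vstack([b.steric for b in fb])
        elec = np.vstack([b.electrostatic for b in fb])
        inside = np.vstack([b.inside_mask for b in fb])
        # impute electrostatics inside the steric envelope with column means
        elec = elec.copy()
        for j in range(elec.shape[1]):
            col_inside = inside[:, j]
            if col_inside.any():
                outside = ~col_inside
                fill = elec[outside, j].mean() if outside.any() else 0.0
                elec[col_inside, j] = fill
        n_pts = grids[label].n_points
        columns.append(ster)
        meta.extend((label, "steric", k) for k in range(n_pts))
        columns.append(elec)
        meta.extend((label, "electrostatic", k) for k in range(n_pts))
    X = np.hstack(columns)
    return X, meta


def write_cube(path, values: np.ndarray, grid: GridSpec, frag: Fragment3D = None, comment: str = "field") -> None:
    """Write one scalar lattice field as a Gaussian cube file (Bohr units)."""
    bohr = 1.0 / 0.529177210903
    nx, ny, nz = grid.dims
    if frag is not None:
        mask = frag.field_mask
        numbers = [
            a.GetAtomicNum() for a, m in zip(frag.mol.GetAtoms(), mask) if m
        ]
        coords = frag.coords[mask]
    else:
        numbers, coords = [], np.zeros((0, 3))
    with open(path, "w") as fh:
        fh.write(f"{comment}\nfragment field lattice\n")
        ox, oy, oz = (c * bohr for c in grid.origin)
        fh.write(f"{len(numbers):5d} {ox:11.6f} {oy:11.6f} {oz:11.6f}\n")
        s = grid.spacing * bohr
        fh.write(f"{nx:5d} {s:11.6f} {0.0:11.6f} {0.0:11.6f}\n")
        fh.write(f"{ny:5d} {0.0:11.6f} {s:11.6f} {0.0:11.6f}\n")
        fh.write(f"{nz:5d} {0.0:11.6f} {0.0:11.6f} {s:11.6f}\n")
        for num, (x, y, z) in zip(numbers, coords * bohr):
            fh.write(f"{num:5d} {0.0:11.6f} {x:11.6f} {y:11.6f} {z:11.6f}\n")
        vol = values.reshape(nx, ny, nz)
        for i in range(nx):
            for j in range(ny):
                row = vol[i, j]
                for k0 in range(0, nz, 6):
                    fh.write(
                        " ".join(f"{v:12.5e}" for v in row[k0 : k0 + 6]) + "\n"
                    )
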