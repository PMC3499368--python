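"""Structural comparison utilities: superposition RMSD and cavity volume.

PDB reading goes through gemmi; superposition is the least-squares Kabsch
rotation (with reflection correction) over backbone atoms of residues
paired by global sequence alignment of the chains; cavity volume is a
VOIDOO-style grid calculation - points farther than probe radius plus van
der Waals radius from every atom, not reachable from outside the bounding
box by flood fill, counted times the grid-cell volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike

import gemmi
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.ndimage import label as ndi_label

__all__ = [
    "Atom",
    "StructureModel",
    "SuperpositionResult",
    "CavityResult",
    "read_structure",
    "write_structure",
    "superpose",
    "cavity_volume",
    "VDW_RADII",
]

#: Van der Waals radii in angstroms (Bondi 1964, with common metals).
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "MG": 1.73, "ZN": 1.39, "FE": 1.40, "CA": 2.31, "NA": 2.27, "K": 2.75,
}
_DEFAULT_VDW = 1.70

BACKBONE_ATOMS = ("N", "CA", "C", "O")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M",
}


@dataclass
class Atom:
    name: str
    residue_name: str
    residue_number: int
    chain: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    altloc: str = ""
    element: str = ""
    is_hetero: bool = False
    is_water: bool = False

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class StructureModel:
    """Atom records of one model, with per-chain extracted sequences."""

    atoms: list[Atom]
    name: str = ""

    def chains(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.chain not in seen:
                seen.append(a.chain)
        return seen

    def chain_sequence(self, chain: str) -> tuple[str, list[int]]:
        """One-letter sequence of a chain plus the residue numbers used."""
        residues: dict[int, str] = {}
        for a in self.atoms:
            if a.chain == chain and not a.is_water and a.residue_name in _THREE_TO_ONE:
                residues.setdefault(a.residue_number, _THREE_TO_ONE[a.residue_name])
        numbers = sorted(residues)
        return "".join(residues[n] for n in numbers), numbers

    def coordinates(
        self,
        chain: str | None = None,
        atom_names: tuple[str, ...] | None = None,
        include_hetero: bool = False,
        include_water: bool = False,
        include_hydrogens: bool = False,
    ) -> np.ndarray:
        out = []
        for a in self.atoms:
            if chain is not None and a.chain != chain:
                continue
            if atom_names is not None and a.name not in atom_names:
                continue
            if a.is_water and not include_water:
                continue
            if a.is_hetero and not a.is_water and not include_hetero:
                continue
            if a.element.upper() == "H" and not include_hydrogens:
                continue
            out.append((a.x, a.y, a.z))
        return np.array(out, dtype=float).reshape(-1, 3)

    def atom_lookup(self, chain: str) -> dict[tuple[int, str], Atom]:
        return {
            (a.residue_number, a.name): a
            for a in self.atoms
            if a.chain == chain and not a.is_water
        }


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # applied after rotation: x' = R x + t
    rmsd: float
    n_atoms: int
    selection: str

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class CavityResult:
    volume: float  # cubic angstroms
    probe_radius: float
    grid_spacing: float
    n_cavity_points: int
    note: str = ""


class PDBFormatError(ValueError):
    pass


def read_structure(path: str | PathLike, altloc_policy: str = "highest_occupancy") -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    Alternate locations are resolved by keeping the highest-occupancy
    conformer (ties broken toward altloc 'A'); waters and heteroatoms are
    flagged rather than dropped.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as err:
        raise PDBFormatError(f"cannot parse PDB file {path}: {err}") from err
    if len(st) == 0:
        raise PDBFormatError(f"no models in PDB file {path}")
    st.setup_entities()
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            is_water = residue.is_water()
            is_het = residue.het_flag == "H"
            by_name: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = by_name.get(atom.name)
                if prev is None:
                    by_name[atom.name] = atom
                elif altloc_policy == "highest_occupancy":
                    if atom.occ > prev.occ or (
                        atom.occ == prev.occ and (atom.altloc or "Z") < (prev.altloc or "Z")
                    ):
                        by_name[atom.name] = atom
            for atom in by_name.values():
                atoms.append(
                    Atom(
                        name=atom.name,
                        residue_name=residue.name,
                        residue_number=residue.seqid.num,
                        chain=chain.name,
                        x=atom.pos.x, y=atom.pos.y, z=atom.pos.z,
                        occupancy=atom.occ,
                        altloc=atom.altloc or "",
                        element=atom.element.name.upper(),
                        is_hetero=is_het,
                        is_water=is_water,
                    )
                )
    if not atoms:
        raise PDBFormatError(f"no atoms found in {path}")
    return StructureModel(atoms=atoms, name=str(path))


def write_structure(model: StructureModel, path: str | PathLike) -> None:
    """Write atoms back out in PDB format (3-decimal coordinates)."""
    st = gemmi.Structure()
    st.name = model.name or "minspec"
    md = gemmi.Model("1")
    # gemmi containers copy on add_*, so assemble residues and chains fully
    # before inserting them.
    chain_order: list[str] = []
    per_chain: dict[str, dict[tuple[int, str], gemmi.Residue]] = {}
    for a in model.atoms:
        if a.chain not in per_chain:
            per_chain[a.chain] = {}
            chain_order.append(a.chain)
        key = (a.residue_number, a.residue_name)
        res = per_chain[a.chain].get(key)
        if res is None:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, " ")
            res.het_flag = "H" if a.is_hetero or a.is_water else "A"
            per_chain[a.chain][key] = res
        atom = gemmi.Atom()
        atom.name = a.name
        atom.pos = gemmi.Position(a.x, a.y, a.z)
        atom.occ = a.occupancy
        if a.element:
            atom.element = gemmi.Element(a.element.capitalize())
        res.add_atom(atom)
    for chain_name in chain_order:
        chain = gemmi.Chain(chain_name)
        for res in per_chain[chain_name].values():
            chain.add_residue(res)
        md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rotation/translation mapping ``moving`` onto ``fixed``.

    Returns ``(R, t, rmsd)`` with ``det(R) = +1`` (reflections corrected).
    """
    if moving.shape != fixed.shape or moving.shape[0] < 3:
        raise ValueError("need matched point sets with at least 3 points")
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    a = moving - mc
    b = fixed - fc
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise ValueError("point selection is (near-)collinear; superposition is ill-posed")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    t = fc - r @ mc
    moved = a @ r.T
    rmsd = float(np.sqrt(((moved - b) ** 2).sum() / len(a)))
    return r, t, rmsd


def _pair_residues(seq_a: str, nums_a: list[int], seq_b: str, nums_b: list[int]):
    """Global alignment of chain sequences; returns paired residue numbers."""
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    aln = aligner.align(seq_a, seq_b)[0]
    pairs = []
    for (s_a, e_a), (s_b, e_b) in zip(*aln.aligned):
        for i in range(e_a - s_a):
            pairs.append((nums_a[s_a + i], nums_b[s_b + i]))
    return pairs


def superpose(
    a: StructureModel,
    b: StructureModel,
    chain_a: str | None = None,
    chain_b: str | None = None,
    atom_names: tuple[str, ...] = BACKBONE_ATOMS,
) -> SuperpositionResult:
    """Optimal rigid-body superposition of ``b``'s selection onto ``a``'s.

    Residues are paired by global sequence alignment of the two chains
    (BLOSUM62; gapped positions excluded), then the Kabsch rotation is
    computed over the selected atom names (default: backbone N, CA, C, O).
    """
    chain_a = chain_a or a.chains()[0]
    chain_b = chain_b or b.chains()[0]
    if chain_a not in a.chains():
        raise ValueError(f"chain {chain_a!r} not in first structure; has {a.chains()}")
    if chain_b not in b.chains():
        raise ValueError(f"chain {chain_b!r} not in second structure; has {b.chains()}")
    seq_a, nums_a = a.chain_sequence(chain_a)
    seq_b, nums_b = b.chain_sequence(chain_b)
    if not seq_a or not seq_b:
        raise ValueError("one of the chains has no polymer residues")
    lookup_a = a.atom_lookup(chain_a)
    lookup_b = b.atom_lookup(chain_b)
    fixed, moving = [], []
    for num_a, num_b in _pair_residues(seq_a, nums_a, seq_b, nums_b):
        for name in atom_names:
            at_a = lookup_a.get((num_a, name))
            at_b = lookup_b.get((num_b, name))
            if at_a is not None and at_b is not None:
                fixed.append(at_a.xyz)
                moving.append(at_b.xyz)
    if len(fixed) < 3:
        raise ValueError(f"only {len(fixed)} matched atoms; need >= 3")
    fixed = np.vstack(fixed)
    moving = np.vstack(moving)
    r, t, rmsd = kabsch(moving, fixed)
    return SuperpositionResult(
        rotation=r,
        translation=t,
        rmsd=rmsd,
        n_atoms=len(fixed),
        selection=f"{'/'.join(atom_names)} of {chain_a}~{chain_b} paired residues",
    )


# ---------------------------------------------------------------------------
# cavity volume
# ---------------------------------------------------------------------------

def cavity_volume(
    model: StructureModel,
    probe_radius: float = 1.4,
    grid_spacing: float = 0.5,
    include_hetero: bool = False,
    include_hydrogens: bool = False,
    padding: float = 2.0,
) -> CavityResult:
    """Probe-accessible volume of enclosed cavities.

    A grid point is probe-accessible when its distance to every atom
    center is at least that atom's van der Waals radius plus
    ``probe_radius``; accessible points reachable from the bounding-box
    exterior by 6-connected flood fill are bulk solvent, and the remaining
    accessible points are cavity. ``volume = count * spacing**3``.

    Note the probe default: 1.4 angstrom is the conventional water probe
    *radius*; pass ``probe_radius=0.7`` to read the figure as a diameter.
    """
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    if not (0.2 <= grid_spacing <= 1.0):
        raise ValueError("grid spacing must lie in [0.2, 1.0] angstroms")
    coords = []
    radii = []
    for a in model.atoms:
        if a.is_water:
            continue
        if a.is_hetero and not include_hetero:
            continue
        if a.element.upper() == "H" and not include_hydrogens:
            continue
        coords.append((a.x, a.y, a.z))
        radii.append(VDW_RADII.get(a.element.upper(), _DEFAULT_VDW))
    if not coords:
        return CavityResult(0.0, probe_radius, grid_spacing, 0, note="no atoms")
    coords = np.asarray(coords)
    radii = np.asarray(radii)
    lo = coords.min(axis=0) - (radii.max() + probe_radius + padding)
    hi = coords.max(axis=0) + (radii.max() + probe_radius + padding)
    axes = [np.arange(lo[d], hi[d] + grid_spacing, grid_spacing) for d in range(3)]
    nx, ny, nz = (len(ax) for ax in axes)

    # Mark probe-excluded points atom by atom on the local subgrid.
    mask = np.ones((nx, ny, nz), dtype=bool)
    for center, rad in zip(coords, radii):
        r = rad + probe_radius
        slices = []
        local = []
        for d, ax in enumerate(axes):
            i0 = int(np.searchsorted(ax, center[d] - r))
            i1 = int(np.searchsorted(ax, center[d] + r, side="right"))
            slices.append(slice(i0, i1))
            local.append(ax[i0:i1] - center[d])
        dx, dy, dz = np.meshgrid(*local, indexing="ij", sparse=True)
        blocked = dx * dx + dy * dy + dz * dz < r * r
        mask[tuple(slices)] &= ~blocked

    structure6 = np.zeros((3, 3, 3), dtype=bool)
    structure6[1, 1, :] = structure6[1, :, 1] = structure6[:, 1, 1] = True
    labels, _ = ndi_label(mask, structure=structure6)
    exterior = set()
    for sl in (labels[0, :, :], labels[-1, :, :], labels[:, 0, :],
               labels[:, -1, :], labels[:, :, 0], labels[:, :, -1]):
        exterior.update(np.unique(sl))
    exterior.discard(0)
    cavity = mask & ~np.isin(labels, sorted(exterior))
    count = int(cavity.sum())
    note = "" if count else "no enclosed cavity found"
    return CavityResult(
        volume=count * grid_spacing ** 3,
        probe_radius=probe_radius,
        grid_spacing=grid_spacing,
        n_cavity_points=count,
        note=note,
    )
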