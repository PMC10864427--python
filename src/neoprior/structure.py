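"""Structural metrics for peptide-HLA class I models.

Geometric sanity checks of a modelled or simulated peptide-HLA complex:
the Calpha distance between the P2 and P9 anchor residues (an extended
binder in the class I groove spans roughly 16 A or more), the number of
inter-chain atom contacts, the number of hydrogen bonds, and the MM/GBSA
binding free energy averaged over a trajectory time window (per-frame
dG = G_complex - G_receptor - G_ligand, conventionally averaged over the
final stretch of the production run, e.g. 80-100 ns of a 100 ns
trajectory).

Structures are biotite ``AtomArray`` objects (one frame) or
``AtomArrayStack`` (multi-model PDB mapped to frames); energies are
:class:`EnergySeries` read from a simple TSV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile
from scipy.spatial import cKDTree


def read_structure(path: str):
    """Read a PDB file; multi-model files yield an ``AtomArrayStack``."""
    pdb = PDBFile.read(path)
    structure = pdb.get_structure()
    if isinstance(structure, AtomArrayStack) and structure.stack_depth() == 1:
        return structure[0]
    return structure


def detect_peptide_chain(atoms: AtomArray, min_res: int = 8, max_res: int = 12) -> str:
    """Auto-detect the peptide chain: the shortest chain of 8-12 residues."""
    best = None
    for chain in np.unique(atoms.chain_id):
        mask = atoms.chain_id == chain
        n_res = len(np.unique(atoms.res_id[mask]))
        if min_res <= n_res <= max_res and (best is None or n_res < best[1]):
            best = (chain, n_res)
    if best is None:
        raise ValueError(
            f"no chain with {min_res}-{max_res} residues; name the peptide "
            "chain explicitly"
        )
    return str(best[0])


def _chain(atoms: AtomArray, chain_id: str) -> AtomArray:
    mask = atoms.chain_id == chain_id
    if not mask.any():
        raise ValueError(f"chain {chain_id!r} not present in the structure")
    return atoms[mask]


def anchor_distance(
    atoms: AtomArray,
    peptide_chain: str | None = None,
    from_pos: int = 2,
    to_pos: int = 9,
) -> float:
    """Calpha-Calpha distance (A) between two peptide anchor positions.

    Defaults to P2-P9, the canonical anchors buried in the class I
    groove.  Positions index residues within the peptide chain in residue
    order (1-based), independent of the author numbering.
    """
    chain = peptide_chain or detect_peptide_chain(atoms)
    pep = _chain(atoms, chain)
    res_ids = np.unique(pep.res_id)
    coords = []
    for label, pos in (("P%d" % from_pos, from_pos), ("P%d" % to_pos, to_pos)):
        if not 1 <= pos <= len(res_ids):
            raise ValueError(
                f"{label}: peptide chain {chain} has only {len(res_ids)} residues"
            )
        res_mask = (pep.res_id == res_ids[pos - 1]) & (pep.atom_name == "CA")
        if not res_mask.any():
            raise ValueError(
                f"{label}: residue {res_ids[pos - 1]} of chain {chain} has no CA atom"
            )
        coords.append(pep.coord[res_mask][0])
    return float(np.linalg.norm(coords[0] - coords[1]))


def count_contacts(
    atoms: AtomArray,
    chain_a: str,
    chain_b: str,
    cutoff: float = 4.5,
    heavy_only: bool = True,
) -> int:
    """Number of inter-chain atom pairs within ``cutoff`` A (inclusive).

    Hydrogens are excluded when ``heavy_only`` (the default, the common
    convention for contact counts).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    a = _chain(atoms, chain_a)
    b = _chain(atoms, chain_b)
    if heavy_only:
        a = a[a.element != "H"]
        b = b[b.element != "H"]
    if len(a) == 0 or len(b) == 0:
        return 0
    tree_a = cKDTree(a.coord)
    tree_b = cKDTree(b.coord)
    return int(tree_a.count_neighbors(tree_b, r=cutoff))


_POLAR = ("N", "O")
_DH_BOND_MAX = 1.3  # A; covalent N-H / O-H bond detection


def count_hbonds(
    atoms: AtomArray,
    donor_chain: str,
    acceptor_chain: str,
    d_cutoff: float = 3.5,
    angle_cutoff: float = 120.0,
    distance_only: bool = False,
) -> int:
    """Count donor->acceptor hydrogen bonds between two chains.

    Donors are N/O atoms of ``donor_chain`` bearing a covalent hydrogen;
    acceptors are N/O atoms of ``acceptor_chain``.  A bond requires
    heavy-atom (D...A) distance <= ``d_cutoff`` and a D-H...A angle >=
    ``angle_cutoff`` for at least one hydrogen on the donor.  Each
    donor-acceptor pair counts at most once.

    Structures stripped of hydrogens cannot support the angle term; pass
    ``distance_only=True`` to fall back to counting polar-polar pairs
    within the distance cutoff.
    """
    donors_all = _chain(atoms, donor_chain)
    acceptors_all = _chain(atoms, acceptor_chain)
    donor_heavy = donors_all[np.isin(donors_all.element, _POLAR)]
    acceptors = acceptors_all[np.isin(acceptors_all.element, _POLAR)]
    if len(donor_heavy) == 0 or len(acceptors) == 0:
        return 0

    if distance_only:
        tree_d = cKDTree(donor_heavy.coord)
        tree_a = cKDTree(acceptors.coord)
        return int(tree_d.count_neighbors(tree_a, r=d_cutoff))

    hydrogens = donors_all[donors_all.element == "H"]
    if len(hydrogens) == 0:
        raise ValueError(
            "donor chain carries no hydrogens; re-run with distance_only=True "
            "to use the distance-only fallback"
        )
    count = 0
    cos_max = np.cos(np.deg2rad(angle_cutoff))
    for d_xyz in donor_heavy.coord:
        h_dist = np.linalg.norm(hydrogens.coord - d_xyz, axis=1)
        h_coords = hydrogens.coord[h_dist <= _DH_BOND_MAX]
        if len(h_coords) == 0:
            continue
        for a_xyz in acceptors.coord:
            if np.linalg.norm(a_xyz - d_xyz) > d_cutoff:
                continue
            # angle at H between H->D and H->A; linear bond = 180 degrees
            v1 = d_xyz - h_coords
            v2 = a_xyz - h_coords
            cos = np.sum(v1 * v2, axis=1) / (
                np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
            )
            if np.any(cos <= cos_max):
                count += 1
    return count


@dataclass
class EnergySeries:
    """Per-frame MM/GBSA energy components (kcal/mol) over simulation time."""

    time_ns: np.ndarray
    g_complex: np.ndarray
    g_receptor: np.ndarray
    g_ligand: np.ndarray

    def __post_init__(self) -> None:
        arrays = [
            np.asarray(a, dtype=float)
            for a in (self.time_ns, self.g_complex, self.g_receptor, self.g_ligand)
        ]
        n = len(arrays[0])
        if any(len(a) != n for a in arrays):
            raise ValueError("energy components must have equal length")
        if n and np.any(np.diff(arrays[0]) <= 0):
            raise ValueError("frame times must be strictly increasing")
        self.time_ns, self.g_complex, self.g_receptor, self.g_ligand = arrays

    def __len__(self) -> int:
        return len(self.time_ns)

    @property
    def dg(self) -> np.ndarray:
        """Per-frame binding free energy: G_complex - G_receptor - G_ligand."""
        return self.g_complex - self.g_receptor - self.g_ligand

    @classmethod
    def from_tsv(cls, path: str) -> "EnergySeries":
        df = pd.read_csv(path, sep="\t")
        required = ["time_ns", "g_complex", "g_receptor", "g_ligand"]
        if not set(required) <= set(df.columns):
            raise ValueError(f"energy TSV {path} needs columns {required}")
        return cls(*(df[c].to_numpy() for c in required))

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(
            {
                "time_ns": self.time_ns,
                "g_complex": self.g_complex,
                "g_receptor": self.g_receptor,
                "g_ligand": self.g_ligand,
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class WindowStats:
    mean: float
    sd: float
    n_frames: int


def mmgbsa_window(
    series: EnergySeries, window: tuple[float, float] = (80.0, 100.0)
) -> WindowStats:
    """Mean and sample SD of per-frame dG inside a closed time window.

    Frames with ``window[0] <= t <= window[1]`` (both ends inclusive)
    enter the average; everything earlier — the equilibration stretch —
    is excluded.
    """
    lo, hi = window
    if hi < lo:
        raise ValueError("window end precedes window start")
    mask = (series.time_ns >= lo) & (series.time_ns <= hi)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"no frames inside the window [{lo}, {hi}] ns")
    dg = series.dg[mask]
    sd = float(np.std(dg, ddof=1)) if n > 1 else 0.0
    return WindowStats(mean=float(dg.mean()), sd=sd, n_frames=n)
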