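"""Atom polarity classification and lipid-facing polar residue detection.

Folded membrane proteins present an almost exclusively hydrophobic
surface to the lipid bilayer; a polar or charged side chain exposed to
the bilayer core is the misfolding cue targeted by membrane quality
control.  This module operationalizes that concept on a membrane-oriented
structure (membrane normal = z axis):

* every atom is assigned one polarity class — hydrophobic carbons (no
  covalently bonded N/O), polar groups of Ser/Thr/Asn/Gln/His plus the
  backbone, and charged groups of Asp/Glu (negative) and Lys/Arg
  (positive);
* each residue gets a lipid-exposure score in [0, 1]: side-chain
  solvent-accessible surface area (rolling probe, 1.4 Å) relative to the
  same side chain computed in isolation;
* residues that are polar/charged, inside the membrane slab, and exposed
  above a threshold are flagged as candidate lipid-facing degrons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.spatial import cKDTree

__all__ = [
    "MembraneSlab",
    "PolarityAnnotation",
    "ResidueFlag",
    "read_structure",
    "classify_atoms",
    "lipid_exposure",
    "polar_exposed_residues",
    "write_class_bfactor_pdb",
]

BOND_CUTOFF = 1.8  # Angstrom; covers covalent C-N / C-O, not 1-3 neighbors
BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}
SASA_POINTS = 1000  # fixed Fibonacci sampling -> deterministic exposures

HYDROPHOBIC = "hydrophobic_carbon"
POLAR = "polar"
POSITIVE = "positive"
NEGATIVE = "negative"
OTHER = "other"

#: residues whose side-chain N/O count as (uncharged) polar groups
POLAR_SIDECHAIN_RES = {"SER", "THR", "ASN", "GLN", "HIS"}
NEGATIVE_RES = {"ASP", "GLU"}
POSITIVE_RES = {"LYS", "ARG"}

CLASS_CODES = {HYDROPHOBIC: 1.0, POLAR: 2.0, POSITIVE: 3.0,
               NEGATIVE: 4.0, OTHER: 0.0}


@dataclass(frozen=True)
class MembraneSlab:
    """Hydrophobic membrane slab along z (default 30 Å total thickness)."""

    z_center: float = 0.0
    half_thickness: float = 15.0

    def __post_init__(self) -> None:
        if self.half_thickness <= 0:
            raise ValueError("half_thickness must be positive")

    def contains(self, z: float) -> bool:
        return abs(z - self.z_center) <= self.half_thickness


@dataclass
class PolarityAnnotation:
    atoms: struc.AtomArray
    atom_class: np.ndarray          # str per atom
    n_unresolved: int = 0           # atoms whose element could not be read

    def class_counts(self) -> dict[str, int]:
        names, counts = np.unique(self.atom_class, return_counts=True)
        return dict(zip(names.tolist(), counts.tolist()))


@dataclass(frozen=True)
class ResidueFlag:
    chain_id: str
    res_id: int
    res_name: str
    polarity: str        # worst-case side-chain class (negative/positive/polar)
    exposure: float
    in_slab: bool


def read_structure(path, model: int = 1) -> struc.AtomArray:
    """Read a PDB file: first model, first altloc, hydrogens retained
    (they are ignored by classification and surface computation)."""
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=model, altloc="first")
    return atoms


def _elements(atoms: struc.AtomArray) -> tuple[np.ndarray, int]:
    elems = np.array([e.strip().upper() for e in atoms.element])
    n_unresolved = 0
    for i, e in enumerate(elems):
        if not e:
            name = atoms.atom_name[i].strip()
            guess = next((c for c in name if c.isalpha()), "")
            elems[i] = guess.upper()
            if not elems[i]:
                n_unresolved += 1
    return elems, n_unresolved


def classify_atoms(atoms: struc.AtomArray) -> PolarityAnnotation:
    """Assign every atom exactly one polarity class.

    Carbons with no covalently bonded (<= 1.8 Å) N or O are hydrophobic.
    N/O atoms are classed by chemical group: side-chain O of Asp/Glu
    negative, side-chain N of Lys/Arg positive, backbone N/O and
    side-chain N/O of Ser/Thr/Asn/Gln/His polar; carbons bonded to a
    classed N/O inherit the class (charge beats polar).  Everything else,
    including hydrogens, sulfur and unresolvable atoms, is 'other'.
    """
    n = atoms.array_length()
    elems, n_unresolved = _elements(atoms)
    classes = np.full(n, OTHER, dtype=object)

    is_no = (elems == "N") | (elems == "O")
    is_c = elems == "C"

    # anchor classes for N/O atoms
    for i in np.where(is_no)[0]:
        name = atoms.atom_name[i].strip()
        res = atoms.res_name[i].strip().upper()
        sidechain = name not in BACKBONE_NAMES
        if sidechain and res in NEGATIVE_RES and elems[i] == "O":
            classes[i] = NEGATIVE
        elif sidechain and res in POSITIVE_RES and elems[i] == "N":
            classes[i] = POSITIVE
        elif not sidechain:
            classes[i] = POLAR  # backbone amide/carbonyl
        elif res in POLAR_SIDECHAIN_RES:
            classes[i] = POLAR
        # else: e.g. Tyr OH, Trp NE1, waters -> other (not in the scheme)

    # covalent neighbors among heavy atoms
    heavy = elems != "H"
    tree = cKDTree(atoms.coord[heavy])
    heavy_idx = np.where(heavy)[0]
    pairs = tree.query_pairs(BOND_CUTOFF, output_type="ndarray")
    neighbors: dict[int, list[int]] = {}
    for a, b in pairs:
        ia, ib = heavy_idx[a], heavy_idx[b]
        neighbors.setdefault(ia, []).append(ib)
        neighbors.setdefault(ib, []).append(ia)

    priority = {NEGATIVE: 3, POSITIVE: 2, POLAR: 1, OTHER: 0}
    for i in np.where(is_c)[0]:
        nbrs = neighbors.get(i, [])
        no_nbrs = [j for j in nbrs if is_no[j]]
        if not no_nbrs:
            classes[i] = HYDROPHOBIC
        else:
            best = max((classes[j] for j in no_nbrs),
                       key=lambda c: priority[c])
            classes[i] = best  # carbon inherits its group's class

    return PolarityAnnotation(atoms=atoms, atom_class=classes,
                              n_unresolved=n_unresolved)


def _sidechain_mask(atoms: struc.AtomArray) -> np.ndarray:
    names = np.char.strip(atoms.atom_name.astype(str))
    elems, _ = _elements(atoms)
    return ~np.isin(names, list(BACKBONE_NAMES)) & (elems != "H")


def _sasa(atoms: struc.AtomArray) -> np.ndarray:
    vals = struc.sasa(atoms, probe_radius=1.4, point_number=SASA_POINTS,
                      vdw_radii="Single")
    return np.nan_to_num(vals, nan=0.0)


def lipid_exposure(
    atoms: struc.AtomArray,
    slab: MembraneSlab | None = None,
) -> list[dict]:
    """Per-residue relative side-chain exposure and slab membership.

    Exposure = side-chain SASA in the full structure divided by the SASA
    of the same side chain with the rest of the structure removed (the
    residue keeps its own backbone), so 0 = fully buried, 1 = as exposed
    as the isolated residue.  Glycine, lacking a side chain, falls back
    to its CA atom (flagged).  When no slab is given, one is centered on
    the coordinate centroid.
    """
    if slab is None:
        slab = MembraneSlab(z_center=float(atoms.coord[:, 2].mean()))
    full_sasa = _sasa(atoms)
    side = _sidechain_mask(atoms)

    out: list[dict] = []
    for res in struc.residue_iter(atoms):
        chain = str(res.chain_id[0])
        res_id = int(res.res_id[0])
        res_name = str(res.res_name[0])
        res_mask = ((atoms.chain_id == chain) & (atoms.res_id == res_id)
                    & (atoms.res_name == res_name))
        sc_mask = res_mask & side
        gly_surrogate = False
        if not sc_mask.any():
            sc_mask = res_mask & (
                np.char.strip(atoms.atom_name.astype(str)) == "CA")
            gly_surrogate = True
        if not sc_mask.any():
            continue
        iso_sasa = _sasa(atoms[res_mask])
        iso_side = sc_mask[res_mask]
        ref = float(iso_sasa[iso_side].sum())
        obs = float(full_sasa[sc_mask].sum())
        exposure = obs / ref if ref > 0 else 0.0
        centroid_z = float(atoms.coord[sc_mask, 2].mean())
        out.append({
            "chain_id": chain,
            "res_id": res_id,
            "res_name": res_name,
            "exposure": exposure,
            "in_slab": slab.contains(centroid_z),
            "sidechain_z": centroid_z,
            "gly_surrogate": gly_surrogate,
        })
    return out


def polar_exposed_residues(
    atoms: struc.AtomArray,
    slab: MembraneSlab | None = None,
    exposure_min: float = 0.25,
    annotation: PolarityAnnotation | None = None,
) -> list[ResidueFlag]:
    """Rank candidate lipid-facing polar residues.

    A residue is flagged when its side chain contains at least one
    polar/positive/negative atom, its side-chain centroid lies inside the
    membrane slab, and its relative exposure is >= ``exposure_min``.
    Purely hydrophobic residues never appear.  Sorted by exposure,
    descending.
    """
    if annotation is None:
        annotation = classify_atoms(atoms)
    exposures = lipid_exposure(atoms, slab)
    side = _sidechain_mask(atoms)
    priority = {NEGATIVE: 3, POSITIVE: 2, POLAR: 1}

    flags: list[ResidueFlag] = []
    for rec in exposures:
        res_mask = ((atoms.chain_id == rec["chain_id"])
                    & (atoms.res_id == rec["res_id"])
                    & (atoms.res_name == rec["res_name"]))
        sc_classes = annotation.atom_class[res_mask & side]
        polar_classes = [c for c in sc_classes if c in priority]
        if not polar_classes:
            continue
        if not rec["in_slab"] or rec["exposure"] < exposure_min:
            continue
        worst = max(polar_classes, key=lambda c: priority[c])
        flags.append(ResidueFlag(
            chain_id=rec["chain_id"], res_id=rec["res_id"],
            res_name=rec["res_name"], polarity=worst,
            exposure=rec["exposure"], in_slab=rec["in_slab"],
        ))
    flags.sort(key=lambda f: -f.exposure)
    return flags


def write_class_bfactor_pdb(atoms: struc.AtomArray,
                            annotation: PolarityAnnotation, path) -> None:
    """Write a PDB with the polarity class encoded in the B-factor column
    (0 other, 1 hydrophobic, 2 polar, 3 positive, 4 negative)."""
    arr = atoms.copy()
    codes = np.array([CLASS_CODES[c] for c in annotation.atom_class])
    arr.set_annotation("b_factor", codes)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))
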