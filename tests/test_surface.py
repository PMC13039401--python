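"""Atom polarity classification and lipid-exposure scoring."""

import numpy as np
import pytest
import biotite.structure as struc
from scipy.spatial import cKDTree

from memdegron.simulate import BundleSimConfig, gen_helix_bundle
from memdegron.surface import (
    HYDROPHOBIC,
    NEGATIVE,
    OTHER,
    POLAR,
    POSITIVE,
    MembraneSlab,
    classify_atoms,
    lipid_exposure,
    polar_exposed_residues,
    read_structure,
    write_class_bfactor_pdb,
)


def _residue(res_name, atoms_spec, chain="A", res_id=1):
    """Build an AtomArray from (name, element, xyz) triples."""
    atoms = [
        struc.Atom(np.array(xyz, dtype=float), chain_id=chain,
                   res_id=res_id, res_name=res_name, atom_name=name,
                   element=element, hetero=False)
        for name, element, xyz in atoms_spec
    ]
    return struc.array(atoms)


# idealized residues with realistic covalent distances (~1.5 A)
LEU = _residue("LEU", [
    ("N", "N", (0.0, 0.0, 0.0)),
    ("CA", "C", (1.46, 0.0, 0.0)),
    ("C", "C", (2.0, 1.4, 0.0)),
    ("O", "O", (1.6, 2.3, 0.7)),
    ("CB", "C", (2.0, -0.9, 1.1)),
    ("CG", "C", (2.0, -2.4, 0.9)),
    ("CD1", "C", (2.6, -3.1, 2.1)),
    ("CD2", "C", (0.6, -2.95, 0.7)),
])

SER = _residue("SER", [
    ("N", "N", (0.0, 0.0, 0.0)),
    ("CA", "C", (1.46, 0.0, 0.0)),
    ("C", "C", (2.0, 1.4, 0.0)),
    ("O", "O", (1.6, 2.3, 0.7)),
    ("CB", "C", (2.0, -0.9, 1.1)),
    ("OG", "O", (1.7, -2.25, 1.0)),
])

ASP = _residue("ASP", [
    ("N", "N", (0.0, 0.0, 0.0)),
    ("CA", "C", (1.46, 0.0, 0.0)),
    ("C", "C", (2.0, 1.4, 0.0)),
    ("O", "O", (1.6, 2.3, 0.7)),
    ("CB", "C", (2.0, -0.9, 1.1)),
    ("CG", "C", (2.0, -2.4, 0.9)),
    ("OD1", "O", (2.9, -3.0, 1.5)),
    ("OD2", "O", (1.2, -3.0, 0.1)),
])

LYS = _residue("LYS", [
    ("N", "N", (0.0, 0.0, 0.0)),
    ("CA", "C", (1.46, 0.0, 0.0)),
    ("C", "C", (2.0, 1.4, 0.0)),
    ("O", "O", (1.6, 2.3, 0.7)),
    ("CB", "C", (2.0, -0.9, 1.1)),
    ("CG", "C", (2.0, -2.4, 0.9)),
    ("CD", "C", (2.6, -3.1, 2.1)),
    ("CE", "C", (2.6, -4.6, 2.0)),
    ("NZ", "N", (3.2, -5.2, 3.2)),
])


def _classes(atoms):
    ann = classify_atoms(atoms)
    return dict(zip(atoms.atom_name.tolist(), ann.atom_class.tolist()))


class TestClassification:
    def test_leu_sidechain_is_hydrophobic(self):
        cls = _classes(LEU)
        for name in ("CG", "CD1", "CD2"):
            assert cls[name] == HYDROPHOBIC
        # backbone amide/carbonyl group is polar, including bonded carbons
        assert cls["N"] == POLAR and cls["O"] == POLAR
        assert cls["CA"] == POLAR and cls["C"] == POLAR
        assert cls["CB"] == HYDROPHOBIC

    def test_ser_hydroxyl_and_bonded_carbon_polar(self):
        cls = _classes(SER)
        assert cls["OG"] == POLAR
        assert cls["CB"] == POLAR  # bonded to OG, not hydrophobic

    def test_asp_carboxylate_negative(self):
        cls = _classes(ASP)
        assert cls["OD1"] == NEGATIVE and cls["OD2"] == NEGATIVE
        assert cls["CG"] == NEGATIVE  # carboxylate carbon

    def test_lys_amine_positive(self):
        cls = _classes(LYS)
        assert cls["NZ"] == POSITIVE
        assert cls["CE"] == POSITIVE  # carbon of the amine group
        assert cls["CD"] == HYDROPHOBIC  # beyond the bonded neighbor

    def test_every_atom_has_exactly_one_class(self):
        atoms, _ = gen_helix_bundle(BundleSimConfig())
        ann = classify_atoms(atoms)
        assert len(ann.atom_class) == atoms.array_length()
        valid = {HYDROPHOBIC, POLAR, POSITIVE, NEGATIVE, OTHER}
        assert set(ann.atom_class.tolist()) <= valid

    def test_rigid_body_invariance(self):
        atoms, _ = gen_helix_bundle(BundleSimConfig())
        ann0 = classify_atoms(atoms)
        theta = 0.7
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1.0],
        ])
        moved = atoms.copy()
        moved.coord = atoms.coord @ rot.T + np.array([5.0, -3.0, 12.0])
        ann1 = classify_atoms(moved)
        assert ann0.atom_class.tolist() == ann1.atom_class.tolist()

    def test_class_counts_survive_pdb_roundtrip(self, tmp_path):
        atoms, _ = gen_helix_bundle(BundleSimConfig())
        ann = classify_atoms(atoms)
        path = tmp_path / "bundle.pdb"
        write_class_bfactor_pdb(atoms, ann, path)
        reread = read_structure(path)
        ann2 = classify_atoms(reread)
        assert ann.class_counts() == ann2.class_counts()


def oracle_sasa(atoms, probe=1.4, n_points=400):
    """Independent rolling-probe surface: uniform golden-spiral points on
    each expanded sphere, counting points outside every other sphere."""
    radii = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
    r = np.array([radii.get(e.upper(), 1.7) for e in atoms.element])
    coords = atoms.coord
    expanded = r + probe
    k = np.arange(n_points)
    phi = np.pi * (3.0 - np.sqrt(5.0))
    zs = 1.0 - 2.0 * (k + 0.5) / n_points
    rho = np.sqrt(1.0 - zs**2)
    sphere = np.stack([rho * np.cos(phi * k), rho * np.sin(phi * k), zs],
                      axis=1)
    tree = cKDTree(coords)
    out = np.zeros(len(coords))
    max_r = expanded.max()
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * sphere
        nbrs = [j for j in tree.query_ball_point(coords[i],
                                                 expanded[i] + max_r)
                if j != i]
        if nbrs:
            d = np.linalg.norm(pts[:, None, :] - coords[nbrs][None, :, :],
                               axis=2)
            free = (d >= expanded[nbrs][None, :]).all(axis=1)
        else:
            free = np.ones(n_points, dtype=bool)
        out[i] = free.mean() * 4.0 * np.pi * expanded[i] ** 2
    return out


def oracle_exposure(atoms):
    """Exposure ratios recomputed with the independent SASA oracle."""
    backbone = {"N", "CA", "C", "O", "OXT"}
    full = oracle_sasa(atoms)
    result = {}
    for res in struc.residue_iter(atoms):
        chain, res_id = str(res.chain_id[0]), int(res.res_id[0])
        mask = (atoms.chain_id == chain) & (atoms.res_id == res_id)
        side = mask & ~np.isin(atoms.atom_name, list(backbone))
        if not side.any():
            continue
        iso = oracle_sasa(atoms[mask])
        ref = iso[~np.isin(atoms[mask].atom_name, list(backbone))].sum()
        result[(chain, res_id)] = full[side].sum() / ref if ref > 0 else 0.0
    return result


class TestExposure:
    def test_isolated_helix_everything_exposed(self):
        atoms, _ = gen_helix_bundle(
            BundleSimConfig(n_helices=1, plant_residue=None))
        records = lipid_exposure(atoms)
        mid = [r for r in records if abs(r["sidechain_z"]) < 8]
        assert mid and all(r["exposure"] > 0.3 for r in mid)

    def test_exposure_bounded_by_one(self):
        atoms, _ = gen_helix_bundle(BundleSimConfig())
        for rec in lipid_exposure(atoms):
            assert rec["exposure"] <= 1.0 + 0.05

    def test_burial_monotone_when_helices_added(self):
        single, _ = gen_helix_bundle(
            BundleSimConfig(n_helices=1, plant_residue=None))
        bundle, _ = gen_helix_bundle(
            BundleSimConfig(n_helices=4, plant_residue=None))
        exp_single = {r["res_id"]: r["exposure"]
                      for r in lipid_exposure(single)}
        # helix A of the bundle has the same geometry relative to itself
        exp_bundle = {
            r["res_id"]: r["exposure"]
            for r in lipid_exposure(bundle) if r["chain_id"] == "A"
        }
        for res_id, e_b in exp_bundle.items():
            assert e_b <= exp_single[res_id] + 0.05

    def test_agrees_with_independent_sasa_oracle(self):
        atoms, truth = gen_helix_bundle(BundleSimConfig())
        ours = {(r["chain_id"], r["res_id"]): r["exposure"]
                for r in lipid_exposure(atoms)}
        reference = oracle_exposure(atoms)
        for key, ref_val in reference.items():
            assert ours[key] == pytest.approx(ref_val, abs=0.05)

    def test_slab_membership(self):
        atoms, _ = gen_helix_bundle(BundleSimConfig(n_res=40))
        slab = MembraneSlab(0.0, 15.0)
        for rec in lipid_exposure(atoms, slab):
            assert rec["in_slab"] == (abs(rec["sidechain_z"]) <= 15.0)


class TestPolarExposed:
    def test_outward_gln_is_the_only_flag(self):
        atoms, truth = gen_helix_bundle(
            BundleSimConfig(plant_face="outward"))
        flags = polar_exposed_residues(atoms)
        assert len(flags) == 1
        f = flags[0]
        assert (f.chain_id, f.res_id, f.res_name) == (
            truth["chain_id"], truth["res_id"], "GLN")
        assert f.polarity == POLAR

    def test_all_leu_bundle_yields_nothing(self):
        atoms, _ = gen_helix_bundle(BundleSimConfig(plant_residue=None))
        assert polar_exposed_residues(atoms) == []

    def test_inward_gln_buried_below_threshold(self):
        atoms, _ = gen_helix_bundle(BundleSimConfig(plant_face="inward"))
        assert polar_exposed_residues(atoms) == []

    def test_flag_set_shrinks_with_threshold(self):
        atoms, _ = gen_helix_bundle(BundleSimConfig(plant_face="outward"))
        sizes = [len(polar_exposed_residues(atoms, exposure_min=e))
                 for e in (0.0, 0.25, 0.5, 0.99)]
        assert sizes == sorted(sizes, reverse=True)

    def test_out_of_slab_polar_residue_not_flagged(self):
        atoms, truth = gen_helix_bundle(
            BundleSimConfig(plant_face="outward"))
        slab = MembraneSlab(z_center=100.0, half_thickness=5.0)
        assert polar_exposed_residues(atoms, slab) == []
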