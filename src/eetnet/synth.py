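"""Synthetic structures with analytic ground truth.

Fixtures are emitted as minimal-but-valid mmCIF (or fixed-column PDB) using
the same chemical-component codes as the shipped cofactor table, so tests
exercise the production reader instead of a private bypass.  All geometry is
deterministic given the spec parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import UsageError
from .structure_io import Atom, Chain, Residue, StructureModel

__all__ = [
    "FixtureSpec",
    "IDEAL_RING",
    "ideal_ring_radius",
    "make_dimer_fixture",
    "make_stack_fixture",
    "make_ring_fixture",
    "make_two_domain_cluster",
    "make_census_scene",
    "build_fixture",
    "write_mmcif",
    "write_pdb",
    "write_ground_truth",
]

#: idealized planar chlorin macrocycle (z = 0, Mg at origin, NB -y, ND +y).
#: The Qy axis (NB -> ND) is +y; the ring normal is +z.
IDEAL_RING: dict[str, np.ndarray] = {
    name: np.array(xyz, dtype=float)
    for name, xyz in {
        "MG": (0.0, 0.0, 0.0),
        "NA": (-2.05, 0.0, 0.0),
        "NC": (2.05, 0.0, 0.0),
        "NB": (0.0, -2.05, 0.0),
        "ND": (0.0, 2.05, 0.0),
        "CHA": (-2.4, 2.4, 0.0),
        "CHB": (-2.4, -2.4, 0.0),
        "CHC": (2.4, -2.4, 0.0),
        "CHD": (2.4, 2.4, 0.0),
        "C1D": (-1.1, 3.0, 0.0),
        "C4D": (1.1, 3.0, 0.0),
        "C1B": (-1.1, -3.0, 0.0),
        "C4B": (1.1, -3.0, 0.0),
        "C1A": (-3.0, 1.1, 0.0),
        "C4A": (-3.0, -1.1, 0.0),
        "C1C": (3.0, -1.1, 0.0),
        "C4C": (3.0, 1.1, 0.0),
    }.items()
}

_CLASS_CODE = {"chl_a": "CLA", "chl_b": "CHL"}

_ELEMENT = {"MG": "MG", "N": "N", "C": "C", "O": "O", "S": "S"}


def ideal_ring_radius() -> float:
    """Largest atom distance from Mg in the ideal ring (the template extent)."""
    return max(float(np.linalg.norm(p)) for p in IDEAL_RING.values())


def _element_of(atom_name: str) -> str:
    if atom_name == "MG":
        return "MG"
    return atom_name[0]


def rot_x(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def rot_y(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def rot_z(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _chlorin_residue(
    chain_id: str,
    number: int,
    cls: str = "chl_a",
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
) -> Residue:
    rotation = np.eye(3) if rotation is None else rotation
    translation = np.zeros(3) if translation is None else np.asarray(translation, float)
    res = Residue(chain_id=chain_id, name=_CLASS_CODE[cls], number=number, het=True)
    for name, pos in IDEAL_RING.items():
        res.atoms.append(
            Atom(name=name, element=_element_of(name), position=rotation @ pos + translation)
        )
    return res


@dataclass
class FixtureSpec:
    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for key, value in self.params.items():
            if isinstance(value, (int, float)) and not isinstance(value, bool):
                if key in {"R", "spacing", "intra_spacing", "inter_gap", "radius"} and value <= 0:
                    raise UsageError(f"fixture parameter {key} must be positive, got {value}")


# ---------------------------------------------------------------------------
# dimer
# ---------------------------------------------------------------------------

_KAPPA_LAYOUTS = {"collinear", "parallel", "perpendicular", "angle"}


def make_dimer_fixture(
    R: float,
    kappa_target: str = "parallel",
    classes: tuple[str, str] = ("chl_a", "chl_a"),
    angle: float | None = None,
) -> tuple[StructureModel, dict]:
    """Two complete chlorin residues with Mg-Mg = *R* and a prescribed
    orientation factor.

    Layouts (first dipole along +y):

    * ``collinear``: separation along y, parallel dipoles -> kappa = -2
    * ``parallel``: separation along x, parallel dipoles -> kappa = +1
    * ``perpendicular``: separation along y, second dipole rotated to +z -> 0
    * ``angle``: separation along x, second molecule rotated by *angle*
      about the separation axis -> kappa = cos(angle)
    """
    if R <= 3.0:
        raise UsageError(f"dimer separation R must exceed 3 A, got {R}")
    if kappa_target not in _KAPPA_LAYOUTS:
        raise UsageError(f"unknown kappa target {kappa_target!r}")
    if kappa_target == "angle":
        if angle is None:
            raise UsageError("kappa_target='angle' requires the angle argument")
        rotation, translation = rot_x(angle), np.array([R, 0.0, 0.0])
        kappa = float(np.cos(np.deg2rad(angle)))
    elif kappa_target == "collinear":
        rotation, translation = np.eye(3), np.array([0.0, R, 0.0])
        kappa = -2.0
    elif kappa_target == "parallel":
        rotation, translation = np.eye(3), np.array([R, 0.0, 0.0])
        kappa = 1.0
    else:  # perpendicular
        rotation, translation = rot_x(90.0), np.array([0.0, R, 0.0])
        kappa = 0.0

    model = StructureModel(
        chains=[
            Chain(id="A", residues=[_chlorin_residue("A", 101, classes[0])]),
            Chain(id="B", residues=[_chlorin_residue("B", 101, classes[1], rotation, translation)]),
        ]
    )
    truth = {
        "spec": asdict(FixtureSpec("dimer", {"R": R, "kappa_target": kappa_target,
                                             "angle": angle, "classes": list(classes)})),
        "mg_mg": R,
        "kappa": kappa,
        "site_ids": [f"A:101:{_CLASS_CODE[classes[0]]}", f"B:101:{_CLASS_CODE[classes[1]]}"],
    }
    return model, truth


# ---------------------------------------------------------------------------
# stack / ring
# ---------------------------------------------------------------------------


def make_stack_fixture(
    n: int, spacing: float, tilt_deg: float = 0.0, seed: int = 0
) -> tuple[StructureModel, dict]:
    """*n* chlorins stacked along z with parallel (optionally tilted) planes."""
    rng = np.random.default_rng(seed)
    chain = Chain(id="S")
    for i in range(n):
        if tilt_deg:
            axis_angle = rng.uniform(0, 360)
            rotation = rot_z(axis_angle) @ rot_x(rng.uniform(-tilt_deg, tilt_deg)) @ rot_z(-axis_angle)
        else:
            rotation = np.eye(3)
        chain.residues.append(
            _chlorin_residue("S", 101 + i, "chl_a", rotation, np.array([0.0, 0.0, i * spacing]))
        )
    model = StructureModel(chains=[chain])
    truth = {
        "spec": asdict(FixtureSpec("stack", {"n": n, "spacing": spacing,
                                             "tilt_deg": tilt_deg}, seed)),
        "site_ids": [f"S:{101 + i}:CLA" for i in range(n)],
        "spacing": spacing,
    }
    return model, truth


def make_ring_fixture(n: int, radius: float) -> tuple[StructureModel, dict]:
    """*n* chlorins evenly spaced on a circle, dipoles tangential."""
    chain = Chain(id="R")
    for i in range(n):
        theta = 360.0 * i / n
        rotation = rot_z(theta)
        center = rot_z(theta) @ np.array([radius, 0.0, 0.0])
        chain.residues.append(_chlorin_residue("R", 101 + i, "chl_a", rotation, center))
    model = StructureModel(chains=[chain])
    truth = {
        "spec": asdict(FixtureSpec("ring", {"n": n, "radius": radius})),
        "site_ids": [f"R:{101 + i}:CLA" for i in range(n)],
    }
    return model, truth


# ---------------------------------------------------------------------------
# two-domain cluster
# ---------------------------------------------------------------------------


def make_two_domain_cluster(
    n_d: int,
    n_a: int,
    intra_spacing: float = 10.0,
    inter_gap: float = 30.0,
    seed: int = 0,
):
    """Two spatially separated pigment clusters with a labeled partition.

    Returns ``(model, partition, ground_truth)`` where *partition* maps each
    site id to ``domD`` / ``domA``.
    """
    from .rates import DomainPartition

    if n_d < 1 or n_a < 1:
        raise UsageError("both clusters need at least one pigment")
    if inter_gap < intra_spacing:
        raise UsageError(
            f"inter_gap ({inter_gap}) must be >= intra_spacing ({intra_spacing}); "
            "clusters would overlap"
        )
    rng = np.random.default_rng(seed)
    chains = [Chain(id="D"), Chain(id="E")]
    mapping: dict[str, str] = {}
    for i in range(n_d):
        rotation = rot_z(rng.uniform(0, 360)) @ rot_x(rng.uniform(-30, 30))
        chains[0].residues.append(
            _chlorin_residue("D", 101 + i, "chl_a", rotation,
                             np.array([i * intra_spacing, 0.0, 0.0]))
        )
        mapping[f"D:{101 + i}:CLA"] = "domD"
    x0 = (n_d - 1) * intra_spacing + inter_gap
    for j in range(n_a):
        rotation = rot_z(rng.uniform(0, 360)) @ rot_x(rng.uniform(-30, 30))
        chains[1].residues.append(
            _chlorin_residue("E", 101 + j, "chl_a", rotation,
                             np.array([x0 + j * intra_spacing, 0.0, 0.0]))
        )
        mapping[f"E:{101 + j}:CLA"] = "domA"
    model = StructureModel(chains=chains)
    partition = DomainPartition(mapping=mapping)
    truth = {
        "spec": asdict(FixtureSpec("two_domain_cluster",
                                   {"n_d": n_d, "n_a": n_a,
                                    "intra_spacing": intra_spacing,
                                    "inter_gap": inter_gap}, seed)),
        "domains": {"domD": sorted(k for k, v in mapping.items() if v == "domD"),
                    "domA": sorted(k for k, v in mapping.items() if v == "domA")},
        "inter_gap": inter_gap,
    }
    return model, partition, truth


# ---------------------------------------------------------------------------
# census scene
# ---------------------------------------------------------------------------

_GENERIC_COFACTOR_ATOMS = ("C1", "C2", "C3", "C4", "C5")

_LIGAND_GEOMETRY = {
    # resname -> (donor atom, scaffold atoms placed around the donor)
    "HIS": ("NE2", ("CA", "CB", "CG", "ND1", "CD2", "CE1")),
    "ASN": ("OD1", ("CA", "CB", "CG", "ND2")),
}


def _generic_cofactor(chain_id: str, number: int, code: str, origin: np.ndarray) -> Residue:
    res = Residue(chain_id=chain_id, name=code, number=number, het=True)
    for i, name in enumerate(_GENERIC_COFACTOR_ATOMS):
        res.atoms.append(Atom(name=name, element="C", position=origin + np.array([1.4 * i, 0, 0])))
    return res


def _ligand_residue(
    chain_id: str, number: int, resname: str, donor_position: np.ndarray
) -> Residue:
    if resname not in _LIGAND_GEOMETRY:
        raise UsageError(f"unsupported ligand residue {resname!r} (use HIS or ASN)")
    donor, scaffold = _LIGAND_GEOMETRY[resname]
    res = Residue(chain_id=chain_id, name=resname, number=number, het=False)
    res.atoms.append(Atom(name=donor, element=_element_of(donor), position=donor_position))
    for i, name in enumerate(scaffold):
        offset = np.array([1.2 + 0.8 * i, 0.6, 1.0])
        res.atoms.append(
            Atom(name=name, element=_element_of(name), position=donor_position + offset)
        )
    return res


def make_census_scene(
    counts: dict[str, int],
    ligands: Sequence[tuple[int, str, float]] = (),
    stack: tuple[int, float] | None = None,
    seed: int = 0,
) -> tuple[StructureModel, dict]:
    """Scene with exact known class counts, axial-ligand geometry, and an
    optional parallel chlorin stack.

    *counts* maps cofactor class to the number of copies (chlorophylls are
    placed on a wide grid, far apart, so no accidental pairs arise).
    *ligands* entries are ``(chl_index, resname, distance)``: a HIS/ASN donor
    atom placed axially at *distance* from that chlorophyll's Mg.
    *stack* is ``(n, spacing)``: extra chl_a residues in a parallel stack.
    """
    code_for = {
        "chl_a": "CLA",
        "chl_b": "CHL",
        "carotenoid:beta_carotene": "BCR",
        "carotenoid:diadinoxanthin": "DD6",
        "carotenoid:neoxanthin": "NEX",
        "quinone": "PQN",
        "fes_cluster": "SF4",
        "lipid": "LHG",
    }
    grid = 30.0
    chl_chain = Chain(id="A")
    other_chain = Chain(id="C")
    protein_chain = Chain(id="P")
    chl_positions: list[np.ndarray] = []
    number = 101
    idx = 0
    for cls in ("chl_a", "chl_b"):
        for _ in range(counts.get(cls, 0)):
            origin = np.array([grid * (idx % 10), grid * (idx // 10), 0.0])
            chl_chain.residues.append(_chlorin_residue("A", number, cls, None, origin))
            chl_positions.append(origin)
            number += 1
            idx += 1
    number = 201
    for cls, code in code_for.items():
        if cls in ("chl_a", "chl_b"):
            continue
        for _ in range(counts.get(cls, 0)):
            origin = np.array([grid * (idx % 10), grid * (idx // 10), 0.0])
            other_chain.residues.append(_generic_cofactor("C", number, code, origin))
            number += 1
            idx += 1

    truth_ligands = []
    for lig_number, (chl_index, resname, distance) in enumerate(ligands, start=1):
        if chl_index >= len(chl_positions):
            raise UsageError(f"ligand target index {chl_index} out of range")
        mg = chl_positions[chl_index]
        donor, _ = _LIGAND_GEOMETRY.get(resname, (None, None))
        if donor is None:
            raise UsageError(f"unsupported ligand residue {resname!r}")
        donor_position = mg + np.array([0.0, 0.0, distance])
        protein_chain.residues.append(
            _ligand_residue("P", lig_number, resname, donor_position)
        )
        truth_ligands.append(
            {"chl_site": f"A:{101 + chl_index}:{chl_chain.residues[chl_index].name}",
             "resname": resname, "donor": donor, "distance": distance,
             "ligand_number": lig_number}
        )

    chains = [c for c in (chl_chain, other_chain, protein_chain) if c.residues]
    stack_truth = None
    if stack is not None:
        n_stack, spacing = stack
        stack_model, st = make_stack_fixture(n_stack, spacing, seed=seed)
        # keep the stack well away from the grid
        for res in stack_model.chains[0].residues:
            for atom in res.atoms:
                atom.position = atom.position + np.array([0.0, -200.0, 0.0])
        chains.append(stack_model.chains[0])
        stack_truth = {"n": n_stack, "spacing": spacing, "site_ids": st["site_ids"]}

    model = StructureModel(chains=chains)
    truth = {
        "spec": asdict(FixtureSpec("census_scene",
                                   {"counts": dict(counts),
                                    "ligands": [list(l) for l in ligands],
                                    "stack": list(stack) if stack else None}, seed)),
        "counts": dict(counts),
        "ligands": truth_ligands,
        "stack": stack_truth,
    }
    return model, truth


def build_fixture(spec: FixtureSpec):
    """Rebuild a fixture from its recorded spec (reproducibility entry point)."""
    p = dict(spec.params)
    if spec.kind == "dimer":
        return make_dimer_fixture(p["R"], p["kappa_target"],
                                  tuple(p.get("classes", ("chl_a", "chl_a"))),
                                  p.get("angle"))
    if spec.kind == "stack":
        return make_stack_fixture(p["n"], p["spacing"], p.get("tilt_deg", 0.0), spec.seed)
    if spec.kind == "ring":
        return make_ring_fixture(p["n"], p["radius"])
    if spec.kind == "two_domain_cluster":
        return make_two_domain_cluster(p["n_d"], p["n_a"], p["intra_spacing"],
                                       p["inter_gap"], spec.seed)
    if spec.kind == "census_scene":
        return make_census_scene(p["counts"],
                                 [tuple(l) for l in p.get("ligands") or []],
                                 tuple(p["stack"]) if p.get("stack") else None,
                                 spec.seed)
    raise UsageError(f"unknown fixture kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_MMCIF_HEADER = """\
data_eetnet_fixture
#
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_comp_id
_atom_site.auth_asym_id
_atom_site.auth_atom_id
_atom_site.pdbx_PDB_model_num
"""


def write_mmcif(model: StructureModel, path: str | Path) -> Path:
    """Serialize *model* as a minimal valid PDBx/mmCIF file."""
    path = Path(path)
    lines = [_MMCIF_HEADER]
    serial = 1
    for chain in model.chains:
        for res in chain.residues:
            group = "HETATM" if res.het else "ATOM"
            for atom in res.atoms:
                lines.append(
                    f"{group} {serial} {atom.element or atom.name[0]} {atom.name} . "
                    f"{res.name} {chain.id} 1 {res.number} ? "
                    f"{atom.position[0]:.3f} {atom.position[1]:.3f} {atom.position[2]:.3f} "
                    f"{atom.occupancy:.2f} 0.00 {res.number} {res.name} {chain.id} "
                    f"{atom.name} 1\n"
                )
                serial += 1
    lines.append("#\n")
    path.write_text("".join(lines))
    return path


def write_pdb(model: StructureModel, path: str | Path) -> Path:
    """Serialize *model* in fixed-column PDB format."""
    path = Path(path)
    lines = []
    serial = 1
    for chain in model.chains:
        for res in chain.residues:
            record = "HETATM" if res.het else "ATOM  "
            for atom in res.atoms:
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                lines.append(
                    f"{record}{serial:5d} {name}{'':1s}{res.name:>3s} {chain.id[0]}"
                    f"{res.number:4d}{res.icode or '':1s}   "
                    f"{atom.position[0]:8.3f}{atom.position[1]:8.3f}{atom.position[2]:8.3f}"
                    f"{atom.occupancy:6.2f}{0.0:6.2f}          "
                    f"{atom.element:>2s}\n"
                )
                serial += 1
    lines.append("END\n")
    path.write_text("".join(lines))
    return path


def write_ground_truth(truth: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
    return path
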