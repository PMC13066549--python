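"""Structural census: stoichiometry, distances, axial ligands, clusters.

All distance operations are symmetric and invariant under rigid motion;
pair finding is validated against brute-force enumeration in the tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, PartitionError, ResidueLookupError, UsageError
from .pigment_model import PigmentSite, ring_plane_normal
from .structure_io import CHLOROPHYLL_CLASSES, CofactorInventory, StructureModel

__all__ = [
    "PigmentRatio",
    "LigandCall",
    "pigment_ratio",
    "mg_mg_distance",
    "min_residue_distance",
    "axial_ligand",
    "find_chl_pairs",
    "find_parallel_clusters",
    "binding_site_inventory",
    "classify_chains",
]


@dataclass
class PigmentRatio:
    reference: str
    values: dict[str, float]  # rounded, reference = 100
    unrounded: dict[str, float]

    def __post_init__(self) -> None:
        assert self.values.get(self.reference) == 100


def _round_ratio(value: float) -> float:
    """Nearest integer, except one decimal place for values below 1."""
    if value < 1.0:
        return round(value, 1)
    return float(round(value))


def pigment_ratio(inventory: CofactorInventory | dict, reference: str) -> PigmentRatio:
    """Per-class abundances normalized to 100 units of *reference*.

    Accepts either an inventory or a plain ``class -> count`` mapping.
    """
    counts = inventory if isinstance(inventory, dict) else inventory.class_counts
    ref = counts.get(reference, 0)
    if ref <= 0:
        raise UsageError(f"reference class {reference!r} has zero count")
    unrounded = {cls: 100.0 * n / ref for cls, n in counts.items()}
    values = {cls: _round_ratio(v) for cls, v in unrounded.items()}
    values[reference] = 100.0
    return PigmentRatio(reference=reference, values=values, unrounded=unrounded)


def mg_mg_distance(site_i: PigmentSite, site_j: PigmentSite) -> float:
    if site_i.mg_position is None or site_j.mg_position is None:
        raise GeometryError("both sites need a Mg position")
    return float(np.linalg.norm(site_i.mg_position - site_j.mg_position))


_BACKBONE = {"N", "CA", "C", "O", "OXT"}


def min_residue_distance(
    model: StructureModel,
    res_i: tuple[str, int],
    res_j: tuple[str, int],
    atom_filter: str = "heavy",
) -> float:
    """Minimum pairwise atom distance between two residues.

    *atom_filter*: ``all`` (every atom), ``heavy`` (drop hydrogens),
    ``sidechain`` (heavy atoms excluding the peptide backbone).
    """
    if atom_filter not in {"all", "heavy", "sidechain"}:
        raise UsageError(f"unknown atom filter {atom_filter!r}")

    def atoms_of(key):
        res = model.get_residue(*key)
        if res is None:
            raise ResidueLookupError(f"residue {key} not found")
        atoms = res.atoms
        if atom_filter in {"heavy", "sidechain"}:
            atoms = [a for a in atoms if a.element.upper() not in {"H", "D"}]
        if atom_filter == "sidechain":
            atoms = [a for a in atoms if a.name not in _BACKBONE]
        if not atoms:
            raise GeometryError(f"residue {key}: no atoms left under filter {atom_filter!r}")
        return np.array([a.position for a in atoms])

    a, b = atoms_of(res_i), atoms_of(res_j)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


@dataclass
class LigandCall:
    site_id: str
    ligand: tuple[str, int, str] | None  # (chain, resnum, resname)
    donor_atom: str | None
    distance: float | None


_DONOR_ELEMENTS = {"N", "O", "S"}


def axial_ligand(
    site: PigmentSite,
    model: StructureModel,
    cutoff: float = 3.0,
    exclude_codes: frozenset[str] = frozenset({"CLA", "CHL"}),
) -> LigandCall:
    """Nearest N/O/S donor atom to the site's Mg within *cutoff* Angstrom.

    The chlorin's own atoms (and atoms of other chlorophyll residues) are
    never candidates.  Returns a no-ligand call when nothing qualifies.
    """
    mg = site.mg_position
    best: tuple[float, tuple[str, int, str], str] | None = None
    for res in model.residues():
        if res.name in exclude_codes:
            continue
        for atom in res.atoms:
            if atom.element.upper() not in _DONOR_ELEMENTS:
                continue
            d = float(np.linalg.norm(atom.position - mg))
            if d <= cutoff and (best is None or d < best[0]):
                best = (d, (res.chain_id, res.number, res.name), atom.name)
    if best is None:
        return LigandCall(site_id=site.site_id, ligand=None, donor_atom=None, distance=None)
    return LigandCall(site_id=site.site_id, ligand=best[1], donor_atom=best[2],
                      distance=best[0])


def axial_ligand_table(
    sites: list[PigmentSite],
    model: StructureModel,
    cutoff: float = 3.0,
    exclude_codes: frozenset[str] = frozenset({"CLA", "CHL"}),
) -> list[LigandCall]:
    """Vectorized :func:`axial_ligand` over many sites (KD-tree backed)."""
    from scipy.spatial import cKDTree

    candidates: list[tuple[np.ndarray, tuple[str, int, str], str]] = []
    for res in model.residues():
        if res.name in exclude_codes:
            continue
        for atom in res.atoms:
            if atom.element.upper() in _DONOR_ELEMENTS:
                candidates.append((atom.position, (res.chain_id, res.number, res.name),
                                   atom.name))
    if not candidates:
        return [LigandCall(s.site_id, None, None, None) for s in sites]
    tree = cKDTree(np.array([c[0] for c in candidates]))
    calls = []
    for site in sites:
        d, idx = tree.query(site.mg_position)
        if d <= cutoff:
            _, residue, donor = candidates[idx]
            calls.append(LigandCall(site.site_id, residue, donor, float(d)))
        else:
            calls.append(LigandCall(site.site_id, None, None, None))
    return calls


def find_chl_pairs(
    sites: list[PigmentSite], mg_cutoff: float = 12.0
) -> list[tuple[str, str, float]]:
    """All unordered site pairs with Mg-Mg distance <= cutoff, sorted by
    distance (ties by site ids)."""
    pairs = []
    for a, b in itertools.combinations(sorted(sites, key=lambda s: s.site_id), 2):
        d = mg_mg_distance(a, b)
        if d <= mg_cutoff:
            pairs.append((a.site_id, b.site_id, d))
    return sorted(pairs, key=lambda p: (p[2], p[0], p[1]))


def fold_angle_deg(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between plane normals folded to [0, 90] degrees."""
    c = abs(float(np.clip(np.dot(n1, n2), -1.0, 1.0)))
    return float(np.degrees(np.arccos(c)))


def find_parallel_clusters(
    sites: list[PigmentSite], mg_cutoff: float = 12.0, max_angle: float = 30.0
) -> list[list[str]]:
    """Connected clusters (size >= 2) of sites whose rings stack: Mg-Mg
    within cutoff and folded normal angle <= max_angle."""
    import networkx as nx

    normals = {s.site_id: ring_plane_normal(s) for s in sites}
    g = nx.Graph()
    g.add_nodes_from(normals)
    for a, b in itertools.combinations(sites, 2):
        if mg_mg_distance(a, b) <= mg_cutoff and \
                fold_angle_deg(normals[a.site_id], normals[b.site_id]) <= max_angle:
            g.add_edge(a.site_id, b.site_id)
    clusters = [sorted(c) for c in nx.connected_components(g) if len(c) >= 2]
    return sorted(clusters)


def binding_site_inventory(
    sites: list[PigmentSite],
    partition: dict[str, str],
    core_label: str = "core",
    declared_labels: list[str] | None = None,
) -> dict:
    """Per-domain chlorophyll counts plus min/max over non-core domains.

    *declared_labels* may add empty domains (count 0) beyond those used.
    """
    labels = set(partition.values()) | set(declared_labels or [])
    counts: dict[str, int] = {label: 0 for label in labels}
    for site in sites:
        if site.site_id not in partition:
            raise PartitionError(f"site {site.site_id} is not covered by the partition")
        counts[partition[site.site_id]] += 1
    antenna = {k: v for k, v in counts.items() if k != core_label}
    return {
        "per_domain": counts,
        "antenna_min": min(antenna.values()) if antenna else None,
        "antenna_max": max(antenna.values()) if antenna else None,
    }


def classify_chains(model: StructureModel) -> dict[str, str]:
    """Heuristic chain classification from mmCIF entity descriptions.

    Chains whose entity description mentions a photosystem core subunit
    (``Psa``) are labeled ``core``; light-harvesting entities (``Lhc``,
    ``light-harvesting``, ``chlorophyll a-b binding``) are labeled
    ``antenna``; everything else is ``other``.
    """
    out: dict[str, str] = {}
    for chain, desc in model.chain_descriptions.items():
        text = (desc or "").lower()
        if "psa" in text or "photosystem i p" in text or "reaction center" in text:
            out[chain] = "core"
        elif "lhc" in text or "light-harvesting" in text or "light harvesting" in text \
                or "chlorophyll a-b binding" in text:
            out[chain] = "antenna"
        else:
            out[chain] = "other"
    return out
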