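"""Reading atomic models, classifying cofactors, and table export.

Coordinate parsing is delegated to Bio.PDB (mmCIF and fixed-column PDB);
the parsed hierarchy is flattened into a small immutable-ish model that the
rest of the pipeline consumes.  Alternate conformers are collapsed
deterministically: the highest-occupancy location wins, ties broken by the
alphabetically first altloc identifier.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import yaml

from .errors import StructureParseError, UsageError

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "CofactorTable",
    "CofactorEntry",
    "CofactorInventory",
    "PIGMENT_CLASSES",
    "CAROTENOID_CLASSES",
    "CHLOROPHYLL_CLASSES",
    "default_cofactor_table",
    "read_structure",
    "classify_cofactors",
    "export_tables",
    "load_rate_matrix_csv",
    "load_inventory_json",
]

#: closed vocabulary of cofactor classes
PIGMENT_CLASSES = frozenset(
    {
        "chl_a",
        "chl_b",
        "carotenoid:diadinoxanthin",
        "carotenoid:neoxanthin",
        "carotenoid:beta_carotene",
        "quinone",
        "fes_cluster",
        "lipid",
        "other",
    }
)

CAROTENOID_CLASSES = frozenset(
    {
        "carotenoid:diadinoxanthin",
        "carotenoid:neoxanthin",
        "carotenoid:beta_carotene",
    }
)

CHLOROPHYLL_CLASSES = frozenset({"chl_a", "chl_b"})


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # (3,) float64, Angstrom
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureParseError(
                f"atom {self.name!r}: coordinates must be 3 finite numbers"
            )


@dataclass
class Residue:
    chain_id: str
    name: str  # 3-letter chemical-component code
    number: int
    icode: str = ""
    het: bool = False
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def atom_positions(self) -> dict[str, np.ndarray]:
        return {a.name: a.position for a in self.atoms}


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class StructureModel:
    """Flat chain/residue/atom model with deterministic ordering."""

    chains: list[Chain] = field(default_factory=list)
    #: chain id -> entity description (when the source format provides one)
    chain_descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str, str, str]] = set()
        for res in self.residues():
            for a in res.atoms:
                k = (res.chain_id, res.number, res.icode, a.altloc, a.name)
                if k in seen:
                    raise StructureParseError(f"duplicate atom key {k}")
                seen.add(k)

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains:
            yield from chain.residues

    def nonpolymer_residues(self) -> Iterator[Residue]:
        for res in self.residues():
            if res.het:
                yield res

    def get_residue(self, chain_id: str, number: int, icode: str = "") -> Residue | None:
        for chain in self.chains:
            if chain.id != chain_id:
                continue
            for res in chain.residues:
                if res.number == number and res.icode == icode:
                    return res
        return None

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())


# ---------------------------------------------------------------------------
# cofactor classification
# ---------------------------------------------------------------------------


@dataclass
class CofactorTable:
    """Mapping of chemical-component codes to cofactor classes."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        for code, cls in self.mapping.items():
            if cls not in PIGMENT_CLASSES:
                raise UsageError(
                    f"cofactor table: class {cls!r} for code {code!r} is not in "
                    f"the closed vocabulary {sorted(PIGMENT_CLASSES)}"
                )

    def __contains__(self, code: str) -> bool:
        return code in self.mapping

    def __getitem__(self, code: str) -> str:
        return self.mapping[code]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CofactorTable":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise UsageError(f"cofactor table {path}: expected a flat mapping")
        return cls({str(k): str(v) for k, v in data.items()})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.mapping, fh, sort_keys=True)


def default_cofactor_table() -> CofactorTable:
    """Table shipped with the package (``data/cofactor_table.yaml``)."""
    path = Path(__file__).parent / "data" / "cofactor_table.yaml"
    return CofactorTable.from_yaml(path)


@dataclass(frozen=True)
class CofactorEntry:
    chain_id: str
    number: int
    code: str
    cls: str


@dataclass
class CofactorInventory:
    entries: list[CofactorEntry]
    unmapped: list[tuple[str, int, str]]  # (chain, resnum, code)

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries:
            counts[e.cls] = counts.get(e.cls, 0) + 1
        return counts

    @property
    def chain_counts(self) -> dict[str, dict[str, int]]:
        counts: dict[str, dict[str, int]] = {}
        for e in self.entries:
            counts.setdefault(e.chain_id, {})
            counts[e.chain_id][e.cls] = counts[e.chain_id].get(e.cls, 0) + 1
        return counts

    def count(self, cls: str) -> int:
        return self.class_counts.get(cls, 0)

    def to_json_dict(self) -> dict:
        return {
            "entries": [
                {"chain": e.chain_id, "number": e.number, "code": e.code, "class": e.cls}
                for e in self.entries
            ],
            "unmapped": [list(u) for u in self.unmapped],
            "class_counts": self.class_counts,
        }

    @classmethod
    def from_json_dict(cls, data: Mapping) -> "CofactorInventory":
        entries = [
            CofactorEntry(d["chain"], int(d["number"]), d["code"], d["class"])
            for d in data["entries"]
        ]
        unmapped = [(u[0], int(u[1]), u[2]) for u in data["unmapped"]]
        return cls(entries=entries, unmapped=unmapped)


def classify_cofactors(model: StructureModel, table: CofactorTable) -> CofactorInventory:
    """Classify every non-polymer residue of *model* against *table*.

    Codes absent from the table are reported in ``unmapped`` rather than
    dropped, so classified + unmapped always partitions the non-polymer set.
    """
    if not table.mapping:
        raise UsageError("cofactor table is empty")
    entries: list[CofactorEntry] = []
    unmapped: list[tuple[str, int, str]] = []
    for res in model.nonpolymer_residues():
        if res.name in table:
            entries.append(CofactorEntry(res.chain_id, res.number, res.name, table[res.name]))
        else:
            unmapped.append((res.chain_id, res.number, res.name))
    return CofactorInventory(entries=entries, unmapped=unmapped)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".cif", ".mmcif"}:
        return "mmcif"
    if suffix in {".pdb", ".ent"}:
        return "pdb"
    with open(path) as fh:
        head = fh.read(4096)
    if head.lstrip().startswith("data_") or "_atom_site." in head:
        return "mmcif"
    return "pdb"


def _select_altloc(bio_atom):
    """Return the chosen Atom child: highest occupancy, ties -> first altloc."""
    if not bio_atom.is_disordered():
        return bio_atom
    children = sorted(
        bio_atom.child_dict.values(),
        key=lambda a: (-(a.get_occupancy() if a.get_occupancy() is not None else 0.0),
                       a.get_altloc()),
    )
    return children[0]


def _convert_bio_model(bio_model) -> StructureModel:
    chains: list[Chain] = []
    for bio_chain in bio_model:
        chain = Chain(id=bio_chain.id)
        for bio_res in bio_chain:
            hetflag, resnum, icode = bio_res.id
            het = hetflag.strip() != ""
            res = Residue(
                chain_id=bio_chain.id,
                name=bio_res.get_resname().strip(),
                number=int(resnum),
                icode=icode.strip(),
                het=het,
            )
            for bio_atom in bio_res:
                atom = _select_altloc(bio_atom)
                occ = atom.get_occupancy()
                res.atoms.append(
                    Atom(
                        name=atom.get_name().strip(),
                        element=(atom.element or "").strip(),
                        position=np.array(atom.get_coord(), dtype=float),
                        occupancy=float(occ) if occ is not None else 1.0,
                        altloc=atom.get_altloc().strip(),
                    )
                )
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            chains.append(chain)
    return StructureModel(chains=chains)


def _read_entity_descriptions(path: Path) -> dict[str, str]:
    """Best-effort chain -> entity description map from an mmCIF file."""
    from Bio.PDB.MMCIF2Dict import MMCIF2Dict

    try:
        d = MMCIF2Dict(str(path))
    except Exception:  # pragma: no cover - malformed auxiliary categories
        return {}
    try:
        ent_ids = d["_entity.id"]
        descriptions = d["_entity.pdbx_description"]
        asym_entity = dict(zip(d["_struct_asym.id"], d["_struct_asym.entity_id"]))
    except KeyError:
        return {}
    ent_desc = dict(zip(ent_ids, descriptions))
    # map label_asym -> auth_asym when available
    label_to_auth: dict[str, str] = {}
    if "_atom_site.label_asym_id" in d and "_atom_site.auth_asym_id" in d:
        for lab, auth in zip(d["_atom_site.label_asym_id"], d["_atom_site.auth_asym_id"]):
            label_to_auth.setdefault(lab, auth)
    out: dict[str, str] = {}
    for asym, ent in asym_entity.items():
        chain = label_to_auth.get(asym, asym)
        desc = ent_desc.get(ent, "")
        if chain not in out or not out[chain]:
            out[chain] = desc
    return out


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read an atomic model from mmCIF or PDB into a :class:`StructureModel`.

    Highest-occupancy alternate conformers are selected deterministically.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    if format == "auto":
        format = _sniff_format(path)
    if format not in {"mmcif", "pdb"}:
        raise UsageError(f"unknown structure format {format!r} (use mmcif/pdb/auto)")

    from Bio.PDB import MMCIFParser, PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if format == "mmcif":
                parser = MMCIFParser(QUIET=True)
            else:
                parser = PDBParser(QUIET=True)
            bio_structure = parser.get_structure(path.stem, str(path))
        except Exception as exc:
            raise StructureParseError(f"failed to parse {path} as {format}: {exc}") from exc

    bio_models = list(bio_structure)
    if not bio_models:
        return StructureModel(chains=[])
    model = _convert_bio_model(bio_models[0])
    if format == "mmcif":
        model.chain_descriptions = _read_entity_descriptions(path)
    return model


# ---------------------------------------------------------------------------
# table export
# ---------------------------------------------------------------------------


def _export_rate_matrix_csv(rm, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["donor", "acceptor", "V_cm-1", "rate_ps-1", "tau_ps", "level"])
        n = len(rm.labels)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                k = rm.k[i, j]
                v = rm.couplings[i, j] if rm.couplings is not None else ""
                tau = 1.0 / k if k > 0 else ""
                writer.writerow([rm.labels[i], rm.labels[j], repr(float(v)) if v != "" else "n/a",
                                 repr(float(k)), repr(float(tau)) if tau != "" else "inf",
                                 rm.level])


def load_rate_matrix_csv(path: str | Path):
    """Read back a rate-matrix edge list written by :func:`export_tables`."""
    from .rates import RateMatrix

    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append(row)
    labels = sorted({r["donor"] for r in rows} | {r["acceptor"] for r in rows})
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    k = np.zeros((n, n))
    couplings = np.zeros((n, n))
    has_v = False
    level = rows[0]["level"] if rows else "pairwise"
    for r in rows:
        i, j = index[r["donor"]], index[r["acceptor"]]
        k[i, j] = float(r["rate_ps-1"])
        if r["V_cm-1"] != "n/a":
            couplings[i, j] = float(r["V_cm-1"])
            has_v = True
    return RateMatrix(labels=labels, k=k, level=level,
                      couplings=couplings if has_v else None)


def load_inventory_json(path: str | Path) -> CofactorInventory:
    with open(path) as fh:
        return CofactorInventory.from_json_dict(json.load(fh))


def _export_binned_graphml(binned, path: Path) -> None:
    import networkx as nx

    g = nx.Graph() if binned.undirected else nx.DiGraph()
    for e in binned.edges:
        g.add_edge(e.donor, e.acceptor, tau_ps=float(e.tau_ps), bin=e.bin)
    nx.write_graphml(g, path)


def export_tables(obj, path: str | Path, format: str) -> Path:
    """Serialize a pipeline product (rate matrix / inventory / binned edges /
    Hamiltonian) to ``csv``, ``json`` or ``graphml``."""
    from .coupling import Hamiltonian
    from .pathways import BinnedEdgeList
    from .rates import RateMatrix

    path = Path(path)
    if isinstance(obj, RateMatrix):
        if format == "csv":
            _export_rate_matrix_csv(obj, path)
        elif format == "json":
            with open(path, "w") as fh:
                json.dump(
                    {
                        "labels": obj.labels,
                        "k_ps": obj.k.tolist(),
                        "level": obj.level,
                        "couplings_cm": None if obj.couplings is None else obj.couplings.tolist(),
                    },
                    fh,
                )
        else:
            raise UsageError(f"RateMatrix cannot be exported as {format!r}")
    elif isinstance(obj, CofactorInventory):
        if format == "json":
            with open(path, "w") as fh:
                json.dump(obj.to_json_dict(), fh, indent=1)
        elif format == "csv":
            with open(path, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["chain", "number", "code", "class"])
                for e in obj.entries:
                    writer.writerow([e.chain_id, e.number, e.code, e.cls])
        else:
            raise UsageError(f"CofactorInventory cannot be exported as {format!r}")
    elif isinstance(obj, BinnedEdgeList):
        if format == "graphml":
            _export_binned_graphml(obj, path)
        elif format == "csv":
            with open(path, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["donor", "acceptor", "tau_ps", "bin"])
                for e in obj.edges:
                    writer.writerow([e.donor, e.acceptor, repr(float(e.tau_ps)), e.bin])
        else:
            raise UsageError(f"BinnedEdgeList cannot be exported as {format!r}")
    elif isinstance(obj, Hamiltonian):
        if format == "csv":
            with open(path, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["site_id"] + obj.site_ids)
                for sid, row in zip(obj.site_ids, obj.matrix):
                    writer.writerow([sid] + [repr(float(x)) for x in row])
        else:
            raise UsageError(f"Hamiltonian cannot be exported as {format!r}")
    else:
        raise UsageError(f"unsupported export type {type(obj).__name__}")
    return path
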