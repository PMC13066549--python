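"""Geometric pigment sites, spectral parameters, and transition charges.

Chlorophyll-class cofactors become :class:`PigmentSite` nodes carrying the
central Mg, the two dipole-anchor ring nitrogens (NB/ND), all four ring
nitrogens and the named macrocycle atoms used by the transition-charge
coupling.  The Qy transition dipole points along NB -> ND by default.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .constants import EA_TO_DEBYE
from .errors import GeometryError, ParameterError, UsageError
from .structure_io import CHLOROPHYLL_CLASSES, CofactorInventory, StructureModel

__all__ = [
    "PigmentSite",
    "ClassParams",
    "SiteParams",
    "TransitionChargeTemplate",
    "RING_ATOM_NAMES",
    "default_site_params",
    "default_templates",
    "extract_pigment_sites",
    "assign_transition_dipole",
    "ring_plane_normal",
]

#: chlorin macrocycle atom names retained for transition-charge evaluation
RING_ATOM_NAMES = frozenset(
    {
        "MG",
        "NA", "NB", "NC", "ND",
        "C1A", "C2A", "C3A", "C4A",
        "C1B", "C2B", "C3B", "C4B",
        "C1C", "C2C", "C3C", "C4C",
        "C1D", "C2D", "C3D", "C4D",
        "CHA", "CHB", "CHC", "CHD",
    }
)

#: maximum Mg-N distance for a nitrogen to count as a ring nitrogen
MG_N_CUTOFF = 2.6


@dataclass
class PigmentSite:
    site_id: str
    cls: str
    mg_position: np.ndarray
    nb_position: np.ndarray
    nd_position: np.ndarray
    ring_nitrogens: dict[str, np.ndarray]
    all_ring_atoms: dict[str, np.ndarray]
    chain_id: str = ""
    residue_number: int = 0
    domain_label: str | None = None

    def __post_init__(self) -> None:
        self.mg_position = np.asarray(self.mg_position, dtype=float)
        self.nb_position = np.asarray(self.nb_position, dtype=float)
        self.nd_position = np.asarray(self.nd_position, dtype=float)
        if np.allclose(self.nb_position, self.nd_position):
            raise GeometryError(f"{self.site_id}: NB and ND coincide")


@dataclass(frozen=True)
class ClassParams:
    site_energy: float  # cm^-1
    dipole_strength: float  # Debye
    lineshape_fwhm: float  # cm^-1
    stokes_shift: float  # cm^-1

    def __post_init__(self) -> None:
        if min(self.site_energy, self.dipole_strength, self.stokes_shift) < 0 \
                or self.lineshape_fwhm <= 0:
            raise ParameterError("class parameters must be positive (fwhm > 0)")


@dataclass
class SiteParams:
    """Per-class spectral parameters plus global temperature and screening."""

    classes: dict[str, ClassParams]
    temperature: float = 300.0
    screening_factor: float = 0.8

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ParameterError(f"temperature must be > 0 K, got {self.temperature}")
        if not (0.0 < self.screening_factor <= 1.5):
            raise ParameterError(
                f"screening factor must lie in (0, 1.5], got {self.screening_factor}"
            )

    def for_class(self, cls: str) -> ClassParams:
        try:
            return self.classes[cls]
        except KeyError:
            raise ParameterError(f"no spectral parameters for class {cls!r}") from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SiteParams":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        classes = {
            name: ClassParams(
                site_energy=float(p["site_energy"]),
                dipole_strength=float(p["dipole_strength"]),
                lineshape_fwhm=float(p["lineshape_fwhm"]),
                stokes_shift=float(p["stokes_shift"]),
            )
            for name, p in data["classes"].items()
        }
        return cls(
            classes=classes,
            temperature=float(data.get("temperature", 300.0)),
            screening_factor=float(data.get("screening_factor", 0.8)),
        )

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "classes": {
                name: {
                    "site_energy": p.site_energy,
                    "dipole_strength": p.dipole_strength,
                    "lineshape_fwhm": p.lineshape_fwhm,
                    "stokes_shift": p.stokes_shift,
                }
                for name, p in self.classes.items()
            },
            "temperature": self.temperature,
            "screening_factor": self.screening_factor,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def default_site_params() -> SiteParams:
    return SiteParams.from_yaml(Path(__file__).parent / "data" / "site_params.yaml")


@dataclass
class TransitionChargeTemplate:
    """Per-class atomic transition charges (e) with a nominal dipole (D)."""

    charges: dict[str, list[tuple[str, float]]]
    nominal_dipole: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls, pairs in self.charges.items():
            total = sum(q for _, q in pairs)
            if abs(total) > 1e-6:
                raise UsageError(
                    f"transition charges for {cls!r} sum to {total:.2e} e (must be 0)"
                )

    def for_class(self, cls: str) -> list[tuple[str, float]]:
        try:
            return self.charges[cls]
        except KeyError:
            raise UsageError(f"no transition-charge template for class {cls!r}") from None

    @classmethod
    def from_csv(cls, path: str | Path, classes: tuple[str, ...] = ("chl_a", "chl_b")):
        """Read a single (atom_name, charge) CSV and apply it to *classes*."""
        pairs: list[tuple[str, float]] = []
        nominal = None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    if "nominal_dipole_debye:" in line:
                        nominal = float(line.split(":", 1)[1])
                    continue
                if not line or line.lower().startswith("atom_name"):
                    continue
                name, charge = next(csv.reader([line]))
                pairs.append((name.strip(), float(charge)))
        return cls(
            charges={c: list(pairs) for c in classes},
            nominal_dipole={c: nominal for c in classes} if nominal else {},
        )


def default_templates() -> TransitionChargeTemplate:
    return TransitionChargeTemplate.from_csv(
        Path(__file__).parent / "data" / "tresp_chlorin.csv"
    )


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


@dataclass
class SkipRecord:
    site_id: str
    reason: str


def site_id_for(chain_id: str, number: int, code: str) -> str:
    return f"{chain_id}:{number}:{code}"


def extract_pigment_sites(
    model: StructureModel, inventory: CofactorInventory
) -> tuple[list[PigmentSite], list[SkipRecord]]:
    """Build one :class:`PigmentSite` per chlorophyll-class cofactor.

    Residues without a resolvable Mg or NB/ND anchors, or whose ring
    nitrogens are implausibly far from Mg, are skipped with a reason.
    Output order is (chain, residue number), independent of input order.
    """
    sites: list[PigmentSite] = []
    skips: list[SkipRecord] = []
    for entry in sorted(inventory.entries, key=lambda e: (e.chain_id, e.number)):
        if entry.cls not in CHLOROPHYLL_CLASSES:
            continue
        sid = site_id_for(entry.chain_id, entry.number, entry.code)
        res = model.get_residue(entry.chain_id, entry.number)
        if res is None:
            skips.append(SkipRecord(sid, "residue not found in model"))
            continue
        positions = res.atom_positions()
        mg = positions.get("MG")
        if mg is None:
            skips.append(SkipRecord(sid, "missing Mg"))
            continue
        nitrogens = {n: positions[n] for n in ("NA", "NB", "NC", "ND") if n in positions}
        far = [n for n, p in nitrogens.items() if np.linalg.norm(p - mg) > MG_N_CUTOFF]
        if far:
            skips.append(SkipRecord(sid, f"ring nitrogens too far from Mg: {sorted(far)}"))
            continue
        if "NB" not in nitrogens or "ND" not in nitrogens:
            skips.append(SkipRecord(sid, "missing dipole anchors NB/ND"))
            continue
        if len(nitrogens) < 2:
            skips.append(SkipRecord(sid, "fewer than 2 ring nitrogens"))
            continue
        ring_atoms = {n: p for n, p in positions.items() if n in RING_ATOM_NAMES}
        sites.append(
            PigmentSite(
                site_id=sid,
                cls=entry.cls,
                mg_position=mg,
                nb_position=nitrogens["NB"],
                nd_position=nitrogens["ND"],
                ring_nitrogens=nitrogens,
                all_ring_atoms=ring_atoms,
                chain_id=entry.chain_id,
                residue_number=entry.number,
            )
        )
    return sites, skips


def assign_transition_dipole(
    site: PigmentSite, params: SiteParams, convention: str = "nb_to_nd"
) -> tuple[np.ndarray, float]:
    """Unit Qy direction and magnitude (Debye) for *site*.

    The direction follows the NB -> ND nitrogen axis (configurable to the
    reverse); the magnitude is the class dipole strength.
    """
    vec = site.nd_position - site.nb_position
    if convention == "nd_to_nb":
        vec = -vec
    elif convention != "nb_to_nd":
        raise UsageError(f"unknown dipole convention {convention!r}")
    norm = np.linalg.norm(vec)
    if norm < 1e-9:
        raise GeometryError(f"{site.site_id}: zero-length NB->ND vector")
    return vec / norm, params.for_class(site.cls).dipole_strength


def ring_plane_normal(site: PigmentSite) -> np.ndarray:
    """Unit normal of the least-squares plane through the ring nitrogens.

    Sign convention: positive z component; if the normal is perpendicular
    to z, positive x decides.
    """
    pts = np.array(list(site.ring_nitrogens.values()))
    if len(pts) < 3:
        raise GeometryError(f"{site.site_id}: need >=3 ring nitrogens for a plane")
    centered = pts - pts.mean(axis=0)
    _, s, vh = np.linalg.svd(centered)
    if s[1] < 1e-9:  # rank < 2: collinear points
        raise GeometryError(f"{site.site_id}: ring nitrogens are collinear")
    normal = vh[2]
    if normal[2] < 0 or (abs(normal[2]) < 1e-12 and normal[0] < 0):
        normal = -normal
    return normal / np.linalg.norm(normal)


def geometric_dipole(
    positions: dict[str, np.ndarray], charges: list[tuple[str, float]]
) -> np.ndarray:
    """Dipole (Debye) of a charge set evaluated on named atom positions."""
    mu = np.zeros(3)
    for name, q in charges:
        if name in positions:
            mu += q * positions[name]
    return mu * EA_TO_DEBYE
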