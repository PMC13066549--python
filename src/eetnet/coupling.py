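"""Excitonic couplings (point-dipole and transition-charge) and the
site-basis Hamiltonian.

Both coupling routes share the same screening factor.  The transition-charge
sum rescales the template so the geometric dipole evaluated on the actual
residue equals the configured class dipole strength; this makes the two
routes agree in the well-separated limit and gives both the same quadratic
scaling in dipole strength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import DIPOLE_COUPLING_CM, TRESP_COULOMB_CM
from .errors import CouplingError, GeometryError, UsageError
from .pigment_model import (
    PigmentSite,
    SiteParams,
    TransitionChargeTemplate,
    assign_transition_dipole,
    geometric_dipole,
)

__all__ = [
    "Hamiltonian",
    "kappa",
    "dipole_coupling",
    "tresp_coupling",
    "build_hamiltonian",
]

#: fraction of template atoms that may be missing before a pair errors out
MAX_MISSING_FRACTION = 0.2


@dataclass
class Hamiltonian:
    site_ids: list[str]
    matrix: np.ndarray  # (n, n) cm^-1, symmetric

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.site_ids)
        if self.matrix.shape != (n, n):
            raise UsageError("Hamiltonian matrix shape does not match site list")
        if not np.all(np.isfinite(self.matrix)):
            raise CouplingError("Hamiltonian contains non-finite entries")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9):
            raise CouplingError("Hamiltonian is not symmetric")

    def index(self, site_id: str) -> int:
        return self.site_ids.index(site_id)

    def submatrix(self, ids: list[str]) -> np.ndarray:
        idx = [self.index(s) for s in ids]
        return self.matrix[np.ix_(idx, idx)]

    def block(self, row_ids: list[str], col_ids: list[str]) -> np.ndarray:
        ri = [self.index(s) for s in row_ids]
        ci = [self.index(s) for s in col_ids]
        return self.matrix[np.ix_(ri, ci)]


def kappa(d_i: np.ndarray, d_j: np.ndarray, r: np.ndarray) -> float:
    """Orientation factor d_i.d_j - 3 (d_i.r_hat)(d_j.r_hat)."""
    r = np.asarray(r, dtype=float)
    norm = np.linalg.norm(r)
    if norm < 1e-9:
        raise GeometryError("zero separation vector")
    d_i = np.asarray(d_i, float) / np.linalg.norm(d_i)
    d_j = np.asarray(d_j, float) / np.linalg.norm(d_j)
    r_hat = r / norm
    return float(d_i @ d_j - 3.0 * (d_i @ r_hat) * (d_j @ r_hat))


def dipole_coupling(site_i: PigmentSite, site_j: PigmentSite, params: SiteParams) -> float:
    """Screened point-dipole coupling in cm^-1 (Mg-to-Mg separation)."""
    r = site_j.mg_position - site_i.mg_position
    dist = np.linalg.norm(r)
    if dist < 1e-9:
        raise GeometryError(
            f"zero Mg-Mg distance between {site_i.site_id} and {site_j.site_id}"
        )
    d_i, mu_i = assign_transition_dipole(site_i, params)
    d_j, mu_j = assign_transition_dipole(site_j, params)
    k = kappa(d_i, d_j, r)
    r_nm = dist / 10.0
    return params.screening_factor * DIPOLE_COUPLING_CM * k * mu_i * mu_j / r_nm**3


def _resolved_charges(
    site: PigmentSite, template: list[tuple[str, float]], target_dipole: float
) -> tuple[np.ndarray, np.ndarray]:
    """Template charges placed on the residue, rescaled to the class dipole.

    Missing atoms (up to 20% of the template) are dropped and the remaining
    charges re-neutralized.
    """
    resolved = [(n, q) for n, q in template if n in site.all_ring_atoms]
    missing = len(template) - len(resolved)
    if missing > MAX_MISSING_FRACTION * len(template):
        raise CouplingError(
            f"{site.site_id}: {missing}/{len(template)} template atoms missing"
        )
    charges = np.array([q for _, q in resolved])
    if missing:
        warnings.warn(
            f"{site.site_id}: dropping {missing} missing template atoms and "
            "re-neutralizing",
            stacklevel=2,
        )
        charges = charges - charges.mean()  # restore neutrality after drops
    positions = np.array([site.all_ring_atoms[n] for n, _ in resolved])
    mu = geometric_dipole(
        {n: p for (n, _), p in zip(resolved, positions)},
        [(n, q) for (n, _), q in zip(resolved, charges)],
    )
    mu_norm = np.linalg.norm(mu)
    if mu_norm < 1e-9:
        raise CouplingError(f"{site.site_id}: transition-charge dipole vanished")
    return positions, charges * (target_dipole / mu_norm)


def coulomb_sum(
    pos_i: np.ndarray, q_i: np.ndarray, pos_j: np.ndarray, q_j: np.ndarray
) -> float:
    """Unscreened Coulomb interaction of two point-charge sets, in cm^-1
    (charges in e, positions in Angstrom)."""
    pos_i = np.atleast_2d(np.asarray(pos_i, float))
    pos_j = np.atleast_2d(np.asarray(pos_j, float))
    q_i = np.atleast_1d(np.asarray(q_i, float))
    q_j = np.atleast_1d(np.asarray(q_j, float))
    d = np.linalg.norm(pos_i[:, None, :] - pos_j[None, :, :], axis=-1)
    if np.any(d < 1e-6):
        raise GeometryError("overlapping atoms in Coulomb sum")
    return TRESP_COULOMB_CM * float(np.sum(q_i[:, None] * q_j[None, :] / d))


def tresp_coupling(
    site_i: PigmentSite,
    site_j: PigmentSite,
    templates: TransitionChargeTemplate,
    params: SiteParams,
) -> float:
    """Screened transition-charge Coulomb coupling in cm^-1."""
    pos_i, q_i = _resolved_charges(
        site_i, templates.for_class(site_i.cls), params.for_class(site_i.cls).dipole_strength
    )
    pos_j, q_j = _resolved_charges(
        site_j, templates.for_class(site_j.cls), params.for_class(site_j.cls).dipole_strength
    )
    try:
        v = coulomb_sum(pos_i, q_i, pos_j, q_j)
    except GeometryError:
        raise GeometryError(
            f"overlapping atoms between {site_i.site_id} and {site_j.site_id}"
        ) from None
    return params.screening_factor * v


def build_hamiltonian(
    sites: list[PigmentSite],
    params: SiteParams,
    method: str = "tresp",
    templates: TransitionChargeTemplate | None = None,
) -> Hamiltonian:
    """Site-basis Hamiltonian: class site energies on the diagonal, pairwise
    couplings (chosen method) off-diagonal.  Site order is (chain, resnum)."""
    if not sites:
        raise UsageError("need at least one pigment site")
    if method not in {"tresp", "dipole"}:
        raise UsageError(f"unknown coupling method {method!r}")
    if method == "tresp" and templates is None:
        from .pigment_model import default_templates

        templates = default_templates()
    ordered = sorted(sites, key=lambda s: (s.chain_id, s.residue_number, s.site_id))
    n = len(ordered)
    h = np.zeros((n, n))
    for i, site in enumerate(ordered):
        h[i, i] = params.for_class(site.cls).site_energy
    for i in range(n):
        for j in range(i + 1, n):
            try:
                if method == "dipole":
                    v = dipole_coupling(ordered[i], ordered[j], params)
                else:
                    v = tresp_coupling(ordered[i], ordered[j], templates, params)
            except (GeometryError, CouplingError) as exc:
                raise type(exc)(
                    f"coupling failed for pair ({ordered[i].site_id}, "
                    f"{ordered[j].site_id}): {exc}"
                ) from exc
            h[i, j] = h[j, i] = v
    return Hamiltonian(site_ids=[s.site_id for s in ordered], matrix=h)
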