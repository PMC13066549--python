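"""Pairwise Förster rates and domain-level generalized-Förster rates.

Lineshapes are unit-area Gaussians with class-level widths; the donor
emission is red-shifted by the class Stokes shift.  The golden-rule rate in
practical units is ``k[ps^-1] = FORSTER_RATE_CM * V[cm^-1]^2 * J[cm]``.

Domain-level rates diagonalize the intra-domain blocks of the Hamiltonian,
couple exciton states through the inter-domain block, thermally average over
donor excitons, and sum over acceptor excitons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import FORSTER_RATE_CM, FWHM_TO_SIGMA, K_B_CM
from .coupling import Hamiltonian
from .errors import ParameterError, PartitionError, UsageError
from .pigment_model import PigmentSite, SiteParams

__all__ = [
    "Lineshape",
    "RateMatrix",
    "DomainPartition",
    "spectral_overlap",
    "forster_rate",
    "pairwise_rate_matrix",
    "exciton_states",
    "boltzmann_populations",
    "gf_rate",
    "gf_rate_matrix",
]


@dataclass(frozen=True)
class Lineshape:
    """Unit-area Gaussian lineshape on the wavenumber axis."""

    center: float  # cm^-1
    sigma: float  # cm^-1
    role: str = "absorption"  # or "emission"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ParameterError(f"lineshape sigma must be > 0, got {self.sigma}")
        if self.role not in {"absorption", "emission"}:
            raise ParameterError(f"unknown lineshape role {self.role!r}")

    @classmethod
    def absorption(cls, energy: float, fwhm: float) -> "Lineshape":
        return cls(center=energy, sigma=fwhm * FWHM_TO_SIGMA, role="absorption")

    @classmethod
    def emission(cls, energy: float, fwhm: float, stokes_shift: float) -> "Lineshape":
        return cls(center=energy - stokes_shift, sigma=fwhm * FWHM_TO_SIGMA, role="emission")

    def value(self, nu: np.ndarray) -> np.ndarray:
        z = (np.asarray(nu, float) - self.center) / self.sigma
        return np.exp(-0.5 * z * z) / (self.sigma * math.sqrt(2.0 * math.pi))


def spectral_overlap(donor: Lineshape, acceptor: Lineshape) -> float:
    """Closed-form overlap integral of two unit-area Gaussians, in cm."""
    var = donor.sigma**2 + acceptor.sigma**2
    delta = donor.center - acceptor.center
    return math.exp(-(delta**2) / (2.0 * var)) / math.sqrt(2.0 * math.pi * var)


def forster_rate(v: float, j: float) -> float:
    """Golden-rule rate in ps^-1 from a coupling (cm^-1) and overlap (cm)."""
    if j < 0:
        raise ParameterError(f"spectral overlap must be >= 0, got {j}")
    return FORSTER_RATE_CM * v * v * j


@dataclass
class RateMatrix:
    """Directional rates k[i, j]: donor i -> acceptor j, in ps^-1."""

    labels: list[str]
    k: np.ndarray
    level: str = "pairwise"  # or "domain"
    couplings: np.ndarray | None = None  # cm^-1, pairwise only

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        n = len(self.labels)
        if self.k.shape != (n, n):
            raise UsageError("rate matrix shape does not match labels")
        if np.any(self.k < 0) or np.any(np.diag(self.k) != 0):
            raise ParameterError("rates must be >= 0 with a zero diagonal")

    @property
    def tau(self) -> np.ndarray:
        """Time constants in ps (inf where the rate is zero)."""
        with np.errstate(divide="ignore"):
            return np.where(self.k > 0, 1.0 / self.k, np.inf)

    def rate(self, donor: str, acceptor: str) -> float:
        return float(self.k[self.labels.index(donor), self.labels.index(acceptor)])

    def time_constant(self, donor: str, acceptor: str) -> float:
        return float(self.tau[self.labels.index(donor), self.labels.index(acceptor)])


@dataclass
class DomainPartition:
    """Total mapping of site ids onto domain labels."""

    mapping: dict[str, str]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        used = sorted(set(self.mapping.values()))
        if not self.labels:
            self.labels = used
        missing = set(used) - set(self.labels)
        if missing:
            raise PartitionError(f"domain labels used but not declared: {sorted(missing)}")

    def sites_in(self, label: str) -> list[str]:
        return sorted(s for s, l in self.mapping.items() if l == label)

    def validate_covers(self, site_ids: list[str]) -> None:
        missing = [s for s in site_ids if s not in self.mapping]
        if missing:
            raise PartitionError(f"partition does not cover sites: {missing[:5]}")

    @classmethod
    def from_chain_tsv(cls, path, sites: list[PigmentSite]) -> "DomainPartition":
        """Build a site partition from a 2-column chain -> label TSV."""
        chain_label: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) != 2:
                    raise UsageError(f"bad partition line: {line!r}")
                chain_label[parts[0]] = parts[1]
        mapping = {}
        for site in sites:
            if site.chain_id not in chain_label:
                raise PartitionError(f"no domain label for chain {site.chain_id!r}")
            mapping[site.site_id] = chain_label[site.chain_id]
        return cls(mapping=mapping)


def _class_of(sites: list[PigmentSite]) -> dict[str, str]:
    return {s.site_id: s.cls for s in sites}


def pairwise_rate_matrix(
    sites: list[PigmentSite], h: Hamiltonian, params: SiteParams
) -> RateMatrix:
    """Förster rates between every ordered site pair.

    Donor emission uses the donor class energy minus its Stokes shift;
    acceptor absorption sits at the acceptor class energy.  Forward and
    backward rates are both stored (the matrix is directional).
    """
    cls = _class_of(sites)
    ids = h.site_ids
    n = len(ids)
    k = np.zeros((n, n))
    for i in range(n):
        p_i = params.for_class(cls[ids[i]])
        emission = Lineshape.emission(p_i.site_energy, p_i.lineshape_fwhm, p_i.stokes_shift)
        for j in range(n):
            if i == j:
                continue
            p_j = params.for_class(cls[ids[j]])
            absorption = Lineshape.absorption(p_j.site_energy, p_j.lineshape_fwhm)
            k[i, j] = forster_rate(h.matrix[i, j], spectral_overlap(emission, absorption))
    return RateMatrix(labels=list(ids), k=k, level="pairwise", couplings=h.matrix.copy())


def exciton_states(h_domain: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (ascending) and orthonormal coefficients of a symmetric
    intra-domain Hamiltonian block.

    Column ``coeffs[:, M]`` is state M; the sign is fixed by making the
    largest-magnitude coefficient positive.
    """
    h_domain = np.asarray(h_domain, dtype=float)
    if not np.allclose(h_domain, h_domain.T, atol=1e-9):
        raise UsageError("domain Hamiltonian block must be symmetric")
    energies, coeffs = np.linalg.eigh(h_domain)
    for m in range(coeffs.shape[1]):
        lead = np.argmax(np.abs(coeffs[:, m]))
        if coeffs[lead, m] < 0:
            coeffs[:, m] = -coeffs[:, m]
    return energies, coeffs


def boltzmann_populations(energies: np.ndarray, temperature: float) -> np.ndarray:
    """Normalized Boltzmann weights of exciton energies (cm^-1) at T (K)."""
    if temperature <= 0:
        raise ParameterError(f"temperature must be > 0, got {temperature}")
    e = np.asarray(energies, dtype=float)
    w = np.exp(-(e - e.min()) / (K_B_CM * temperature))
    return w / w.sum()


def _domain_spectral_params(
    site_ids: list[str], cls: dict[str, str], params: SiteParams
) -> tuple[float, float]:
    """(class-average fwhm, majority-class Stokes shift) for a domain."""
    classes = [cls[s] for s in site_ids]
    fwhm = float(np.mean([params.for_class(c).lineshape_fwhm for c in classes]))
    majority = max(sorted(set(classes)), key=classes.count)
    return fwhm, params.for_class(majority).stokes_shift


def gf_rate(
    donor_label: str,
    acceptor_label: str,
    h: Hamiltonian,
    partition: DomainPartition,
    params: SiteParams,
    sites: list[PigmentSite],
) -> float:
    """Generalized-Förster rate (ps^-1) from one domain to another.

    Intra-domain blocks are diagonalized; exciton-exciton couplings are the
    coefficient-weighted sums over the inter-domain block; donor excitons are
    Boltzmann-weighted; acceptor excitons are summed.
    """
    donor_sites = partition.sites_in(donor_label)
    acceptor_sites = partition.sites_in(acceptor_label)
    if not donor_sites or not acceptor_sites:
        raise PartitionError(
            f"empty domain in pair ({donor_label!r}, {acceptor_label!r})"
        )
    if set(donor_sites) & set(acceptor_sites):
        raise PartitionError(
            f"domains {donor_label!r} and {acceptor_label!r} overlap"
        )
    cls = _class_of(sites)

    e_d, c_d = exciton_states(h.submatrix(donor_sites))
    e_a, c_a = exciton_states(h.submatrix(acceptor_sites))
    v_block = h.block(donor_sites, acceptor_sites)
    v_mn = c_d.T @ v_block @ c_a  # exciton-exciton couplings

    fwhm_d, stokes_d = _domain_spectral_params(donor_sites, cls, params)
    fwhm_a, _ = _domain_spectral_params(acceptor_sites, cls, params)
    populations = boltzmann_populations(e_d, params.temperature)

    total = 0.0
    for m in range(len(e_d)):
        emission = Lineshape.emission(e_d[m], fwhm_d, stokes_d)
        for n_ in range(len(e_a)):
            absorption = Lineshape.absorption(e_a[n_], fwhm_a)
            total += populations[m] * forster_rate(
                v_mn[m, n_], spectral_overlap(emission, absorption)
            )
    return float(total)


def gf_rate_matrix(
    sites: list[PigmentSite],
    h: Hamiltonian,
    partition: DomainPartition,
    params: SiteParams,
) -> RateMatrix:
    """Domain-level rate matrix over every ordered pair of domain labels."""
    partition.validate_covers(h.site_ids)
    labels = sorted(set(partition.mapping.values()))
    n = len(labels)
    k = np.zeros((n, n))
    for i, donor in enumerate(labels):
        for j, acceptor in enumerate(labels):
            if i == j:
                continue
            k[i, j] = gf_rate(donor, acceptor, h, partition, params, sites)
    return RateMatrix(labels=labels, k=k, level="domain")
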