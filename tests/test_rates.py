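import copy
import math

import numpy as np
import pytest
import scipy.constants as sc
from scipy.stats import linregress

from conftest import random_rotation, sites_of, transform_model
from eetnet.coupling import build_hamiltonian
from eetnet.errors import ParameterError, PartitionError, UsageError
from eetnet.rates import (
    DomainPartition,
    Lineshape,
    RateMatrix,
    boltzmann_populations,
    exciton_states,
    forster_rate,
    gf_rate,
    gf_rate_matrix,
    pairwise_rate_matrix,
    spectral_overlap,
)
from eetnet.synth import make_dimer_fixture, make_two_domain_cluster

# constant oracles derived from base constants inside the test
ORACLE_RATE_CONST = 4 * math.pi**2 * (sc.c * 100.0) * 1e-12  # ps^-1 per (cm^-1)^2 cm
ORACLE_KB_CM = sc.k / (sc.h * sc.c * 100.0)


class TestSpectralOverlap:
    def test_identical_gaussians(self):
        d = Lineshape(center=15000.0, sigma=100.0, role="emission")
        a = Lineshape(center=15000.0, sigma=100.0)
        j = spectral_overlap(d, a)
        assert j == pytest.approx(1.0 / math.sqrt(2 * math.pi * 20000.0), rel=1e-12)
        assert j == pytest.approx(2.82e-3, rel=1e-2)

    def test_monotone_decay_with_detuning(self):
        a = Lineshape(center=15000.0, sigma=120.0)
        values = [
            spectral_overlap(Lineshape(center=15000.0 + delta, sigma=90.0, role="emission"), a)
            for delta in (0, 100, 300, 900, 2000, 5000)
        ]
        assert all(x > y for x, y in zip(values, values[1:]))
        assert values[-1] < 1e-30

    def test_closed_form_matches_quadrature(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            sd, sa = rng.uniform(50, 500, size=2)
            delta = rng.uniform(0, 2.0 * (sd + sa))
            d = Lineshape(center=15000.0, sigma=sd, role="emission")
            a = Lineshape(center=15000.0 - delta, sigma=sa)
            lo = min(d.center, a.center) - 12 * max(sd, sa)
            hi = max(d.center, a.center) + 12 * max(sd, sa)
            nu = np.linspace(lo, hi, 100_000)
            j_quad = np.trapezoid(d.value(nu) * a.value(nu), nu)
            assert spectral_overlap(d, a) == pytest.approx(j_quad, rel=1e-8)

    def test_unit_area(self):
        shape = Lineshape(center=15000.0, sigma=200.0)
        nu = np.linspace(12000, 18000, 200_000)
        assert np.trapezoid(shape.value(nu), nu) == pytest.approx(1.0, rel=1e-9)

    def test_nonpositive_sigma_errors(self):
        with pytest.raises(ParameterError):
            Lineshape(center=15000.0, sigma=0.0)


class TestForsterRate:
    def test_constant_oracle(self):
        k = forster_rate(10.08, 2.0e-3)
        assert k == pytest.approx(ORACLE_RATE_CONST * 10.08**2 * 2.0e-3, rel=1e-12)
        assert k == pytest.approx(0.240, rel=2e-2)
        assert 1.0 / k == pytest.approx(4.2, rel=2e-2)

    def test_zero_coupling(self):
        assert forster_rate(0.0, 1e-3) == 0.0

    def test_quadratic_in_coupling(self):
        assert forster_rate(3.0, 1e-3) == pytest.approx(9 * forster_rate(1.0, 1e-3))

    def test_negative_overlap_errors(self):
        with pytest.raises(ParameterError):
            forster_rate(1.0, -1e-3)


class TestPairwiseRates:
    def test_degenerate_dimer_detailed_balance(self, params):
        model, _ = make_dimer_fixture(12.0, "parallel")
        sites, _ = sites_of(model)
        h = build_hamiltonian(sites, params, method="dipole")
        rm = pairwise_rate_matrix(sites, h, params)
        assert rm.k[0, 1] == pytest.approx(rm.k[1, 0], rel=1e-12)
        assert rm.k[0, 1] > 0

    def test_forward_and_backward_differ_for_mixed_classes(self, params):
        model, _ = make_dimer_fixture(12.0, "parallel", classes=("chl_a", "chl_b"))
        sites, _ = sites_of(model)
        h = build_hamiltonian(sites, params, method="dipole")
        rm = pairwise_rate_matrix(sites, h, params)
        # downhill b -> a is faster than uphill a -> b under a Stokes shift
        i_a = rm.labels.index(sites[0].site_id)
        i_b = rm.labels.index(sites[1].site_id)
        assert rm.k[i_b, i_a] > rm.k[i_a, i_b]

    def test_r6_distance_law(self, params):
        radii = np.arange(15.0, 61.0, 5.0)
        rates = []
        for r in radii:
            model, _ = make_dimer_fixture(float(r), "parallel")
            sites, _ = sites_of(model)
            h = build_hamiltonian(sites, params, method="dipole")
            rm = pairwise_rate_matrix(sites, h, params)
            rates.append(rm.k[0, 1])
        slope = linregress(np.log(radii), np.log(rates)).slope
        assert slope == pytest.approx(-6.00, abs=0.02)

    def test_tau_is_inverse_rate(self, params):
        model, _ = make_dimer_fixture(14.0, "parallel")
        sites, _ = sites_of(model)
        h = build_hamiltonian(sites, params, method="dipole")
        rm = pairwise_rate_matrix(sites, h, params)
        assert rm.tau[0, 1] == pytest.approx(1.0 / rm.k[0, 1])
        assert np.isinf(rm.tau[0, 0])

    def test_rate_matrix_validation(self):
        with pytest.raises(ParameterError):
            RateMatrix(labels=["a", "b"], k=np.array([[0.0, -1.0], [1.0, 0.0]]))
        with pytest.raises(UsageError):
            RateMatrix(labels=["a"], k=np.zeros((2, 2)))

    def test_rigid_motion_invariance(self, params, templates):
        model, partition, _ = make_two_domain_cluster(3, 3, 10.0, 30.0, seed=8)
        rng = np.random.default_rng(21)
        moved = transform_model(model, random_rotation(rng), rng.normal(size=3) * 30)
        sites0, _ = sites_of(model)
        sites1, _ = sites_of(moved)
        rm0 = pairwise_rate_matrix(sites0, build_hamiltonian(sites0, params, "tresp", templates), params)
        rm1 = pairwise_rate_matrix(sites1, build_hamiltonian(sites1, params, "tresp", templates), params)
        assert np.allclose(rm1.k, rm0.k, rtol=1e-9, atol=1e-12)


class TestExcitonStates:
    def test_two_by_two_closed_form(self):
        e, v = 15000.0, 120.0
        energies, coeffs = exciton_states(np.array([[e, v], [v, e]]))
        assert energies == pytest.approx([e - v, e + v])
        assert np.allclose(np.abs(coeffs), np.full((2, 2), 1 / math.sqrt(2)))

    def test_diagonal(self):
        energies, coeffs = exciton_states(np.diag([1.0, 2.0, 3.0]))
        assert energies == pytest.approx([1.0, 2.0, 3.0])
        assert np.allclose(coeffs, np.eye(3))

    def test_reconstruction(self):
        rng = np.random.default_rng(33)
        m = rng.normal(size=(8, 8))
        h = (m + m.T) / 2
        energies, coeffs = exciton_states(h)
        assert np.linalg.norm(coeffs @ np.diag(energies) @ coeffs.T - h) <= 1e-8
        assert np.allclose(coeffs.T @ coeffs, np.eye(8), atol=1e-10)

    def test_sign_convention(self):
        rng = np.random.default_rng(34)
        m = rng.normal(size=(5, 5))
        _, coeffs = exciton_states((m + m.T) / 2)
        for col in coeffs.T:
            assert col[np.argmax(np.abs(col))] > 0

    def test_ascending_order(self):
        rng = np.random.default_rng(35)
        m = rng.normal(size=(6, 6))
        energies, _ = exciton_states((m + m.T) / 2)
        assert np.all(np.diff(energies) >= 0)


class TestBoltzmann:
    def test_degenerate_pair(self):
        assert boltzmann_populations([100.0, 100.0], 300.0) == pytest.approx([0.5, 0.5])

    def test_single_kt_gap(self):
        kt = ORACLE_KB_CM * 300.0
        p = boltzmann_populations([0.0, kt], 300.0)
        assert p[0] == pytest.approx(1.0 / (1.0 + math.exp(-1)), rel=1e-9)
        assert p[0] == pytest.approx(0.731, abs=1e-3)

    def test_high_temperature_limit(self):
        p = boltzmann_populations([0.0, 50.0, 120.0], 1e9)
        assert p == pytest.approx([1 / 3] * 3, abs=1e-6)

    def test_normalization_random(self):
        rng = np.random.default_rng(55)
        for _ in range(25):
            e = rng.uniform(14000, 16000, size=rng.integers(1, 12))
            assert boltzmann_populations(e, rng.uniform(1, 600)).sum() == pytest.approx(1.0)

    def test_invalid_temperature(self):
        with pytest.raises(ParameterError):
            boltzmann_populations([0.0], 0.0)


def brute_force_gf(h, site_ids, classes, partition, params, donor, acceptor):
    """Fully independent generalized-Förster enumeration (test oracle)."""
    d_sites = sorted(s for s, l in partition.items() if l == donor)
    a_sites = sorted(s for s, l in partition.items() if l == acceptor)
    idx = {s: site_ids.index(s) for s in site_ids}
    hd = np.array([[h[idx[x], idx[y]] for y in d_sites] for x in d_sites])
    ha = np.array([[h[idx[x], idx[y]] for y in a_sites] for x in a_sites])
    vb = np.array([[h[idx[x], idx[y]] for y in a_sites] for x in d_sites])
    ed, cd = np.linalg.eigh(hd)
    ea, ca = np.linalg.eigh(ha)
    d_classes = [classes[s] for s in d_sites]
    a_classes = [classes[s] for s in a_sites]
    fwhm_d = np.mean([params.for_class(c).lineshape_fwhm for c in d_classes])
    fwhm_a = np.mean([params.for_class(c).lineshape_fwhm for c in a_classes])
    majority = max(sorted(set(d_classes)), key=d_classes.count)
    stokes = params.for_class(majority).stokes_shift
    sig = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    sd, sa = fwhm_d * sig, fwhm_a * sig
    w = np.exp(-(ed - ed.min()) / (ORACLE_KB_CM * params.temperature))
    w /= w.sum()
    total = 0.0
    for m in range(len(ed)):
        for n in range(len(ea)):
            v_mn = sum(
                cd[i, m] * ca[j, n] * vb[i, j]
                for i in range(len(d_sites))
                for j in range(len(a_sites))
            )
            delta = (ed[m] - stokes) - ea[n]
            var = sd**2 + sa**2
            j_ov = math.exp(-(delta**2) / (2 * var)) / math.sqrt(2 * math.pi * var)
            total += w[m] * ORACLE_RATE_CONST * v_mn**2 * j_ov
    return total


class TestGeneralizedForster:
    def test_singleton_reduction(self, params, templates):
        model, _, _ = make_two_domain_cluster(3, 3, 10.0, 30.0, seed=42)
        sites, _ = sites_of(model)
        h = build_hamiltonian(sites, params, "tresp", templates)
        rm = pairwise_rate_matrix(sites, h, params)
        singles = DomainPartition(mapping={s.site_id: s.site_id for s in sites})
        for i, donor in enumerate(rm.labels):
            for j, acceptor in enumerate(rm.labels):
                if i == j:
                    continue
                k_gf = gf_rate(donor, acceptor, h, singles, params, sites)
                assert k_gf == pytest.approx(rm.k[i, j], rel=1e-10)

    def test_zero_interdomain_block(self, params, templates):
        model, partition, _ = make_two_domain_cluster(2, 2, 10.0, 30.0, seed=1)
        sites, _ = sites_of(model)
        h = build_hamiltonian(sites, params, "tresp", templates)
        d_ids = partition.sites_in("domD")
        a_ids = partition.sites_in("domA")
        for x in d_ids:
            for y in a_ids:
                i, j = h.index(x), h.index(y)
                h.matrix[i, j] = h.matrix[j, i] = 0.0
        assert gf_rate("domD", "domA", h, partition, params, sites) == 0.0

    @pytest.mark.parametrize("n", [3, 5])
    def test_matches_brute_force_enumeration(self, n, params, templates):
        model, partition, _ = make_two_domain_cluster(n, n, 9.0, 25.0, seed=42)
        sites, _ = sites_of(model)
        h = build_hamiltonian(sites, params, "tresp", templates)
        classes = {s.site_id: s.cls for s in sites}
        for donor, acceptor in (("domD", "domA"), ("domA", "domD")):
            expected = brute_force_gf(h.matrix, h.site_ids, classes,
                                      partition.mapping, params, donor, acceptor)
            got = gf_rate(donor, acceptor, h, partition, params, sites)
            assert got == pytest.approx(expected, rel=1e-9)

    def test_overlapping_domains_error(self, params, templates):
        model, partition, _ = make_two_domain_cluster(2, 2, 10.0, 30.0, seed=3)
        sites, _ = sites_of(model)
        h = build_hamiltonian(sites, params, "tresp", templates)
        bad = DomainPartition(mapping=dict(partition.mapping))
        with pytest.raises(PartitionError):
            gf_rate("domD", "domD", h, bad, params, sites)

    def test_gf_matrix_covers_all_ordered_pairs(self, params, templates):
        model, partition, _ = make_two_domain_cluster(2, 3, 10.0, 30.0, seed=6)
        sites, _ = sites_of(model)
        h = build_hamiltonian(sites, params, "tresp", templates)
        rm = gf_rate_matrix(sites, h, partition, params)
        assert rm.level == "domain"
        assert sorted(rm.labels) == ["domA", "domD"]
        assert rm.k[rm.labels.index("domD"), rm.labels.index("domA")] > 0

    def test_partition_must_cover(self, params, templates):
        model, partition, _ = make_two_domain_cluster(2, 2, 10.0, 30.0, seed=6)
        sites, _ = sites_of(model)
        h = build_hamiltonian(sites, params, "tresp", templates)
        incomplete = DomainPartition(mapping={h.site_ids[0]: "domD"})
        with pytest.raises(PartitionError):
            gf_rate_matrix(sites, h, incomplete, params)

    def test_chain_tsv_loader(self, tmp_path, params):
        model, _, _ = make_two_domain_cluster(2, 2, 10.0, 30.0, seed=6)
        sites, _ = sites_of(model)
        tsv = tmp_path / "domains.tsv"
        tsv.write_text("D\tleft\nE\tright\n")
        partition = DomainPartition.from_chain_tsv(tsv, sites)
        assert set(partition.mapping.values()) == {"left", "right"}
        bad = tmp_path / "bad.tsv"
        bad.write_text("D\tleft\n")
        with pytest.raises(PartitionError):
            DomainPartition.from_chain_tsv(bad, sites)
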