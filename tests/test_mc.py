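import numpy as np
import pytest

from bnctmicro.geometry import MorphologyParams, build_lattice
from bnctmicro.mc import (
    CompartmentEmptyError,
    SimConfig,
    TallySet,
    TrackSample,
    compute_R,
    domain_spectrum,
    run_background_component,
    run_boron_component,
)

FAST = SimConfig(ds_um=0.1, domain_diameters=(), n_domain_samples=5000)


@pytest.fixture(scope="module")
def lattice():
    return build_lattice(MorphologyParams(36.0, 0.4, 2.0))


@pytest.fixture(scope="module")
def boron_tallies(lattice):
    return {c: run_boron_component(lattice, c, 4000, seed=100 + i, cfg=FAST)
            for i, c in enumerate(("nucleus", "cytoplasm", "extracellular"))}


class TestBoronComponent:
    def test_zero_gap_extracellular_is_error(self):
        lat = build_lattice(MorphologyParams(36.0, 0.4, 0.0))
        with pytest.raises(CompartmentEmptyError, match="zero volume"):
            run_boron_component(lat, "extracellular", 100, seed=1, cfg=FAST)

    def test_uniform_compartment_rejected(self, lattice):
        with pytest.raises(ValueError):
            run_boron_component(lattice, "uniform", 100, seed=1, cfg=FAST)

    def test_reproducible_given_seed(self, lattice):
        a = run_boron_component(lattice, "nucleus", 500, seed=5, cfg=FAST)
        b = run_boron_component(lattice, "nucleus", 500, seed=5, cfg=FAST)
        assert a.mean_nucleus_dose_per_reaction == b.mean_nucleus_dose_per_reaction
        assert np.array_equal(a.f_n1.counts, b.f_n1.counts)

    def test_full_containment_bound(self, lattice):
        # no single event can exceed the full pair energy over the nucleus mass
        t = run_boron_component(lattice, "nucleus", 2000, seed=9, cfg=FAST)
        z_max_possible = 2.792 * 1.602176634e-13 / lattice.nucleus_mass_kg
        occupied = np.nonzero(t.f_n1.counts)[0]
        assert t.f_n1.edges[occupied[-1] + 1] <= z_max_possible * 1.05

    def test_nucleus_source_dominates(self, boron_tallies):
        zn = boron_tallies["nucleus"].mean_nucleus_dose_per_reaction
        ze = boron_tallies["extracellular"].mean_nucleus_dose_per_reaction
        assert zn > ze

    def test_density_normalized(self, boron_tallies):
        h = boron_tallies["nucleus"].f_n1
        integral = np.sum(h.density() * np.diff(h.edges))
        assert integral == pytest.approx(1.0, abs=1e-6)

    def test_first_moment_consistency(self, boron_tallies):
        # mean of f_n1 times event frequency = mean nucleus dose per reaction
        t = boron_tallies["cytoplasm"]
        assert t.f_n1.m1 * t.events_per_history == pytest.approx(
            t.mean_nucleus_dose_per_reaction, rel=1e-9)

    def test_energy_bookkeeping(self, boron_tallies, lattice):
        # energy scored in nuclei cannot exceed energy emitted
        t = boron_tallies["nucleus"]
        scored = (t.mean_nucleus_dose_per_reaction * t.n_histories
                  * lattice.nucleus_mass_kg)
        emitted = t.mean_total_dose_per_reaction * t.n_histories \
            * lattice.pitch**3 * 1e-15
        assert scored <= emitted * (1 + 1e-9)

    def test_serialization_roundtrip(self, boron_tallies):
        t = boron_tallies["nucleus"]
        t2 = TallySet.from_json(t.to_json())
        assert t2.mean_nucleus_dose_per_reaction == t.mean_nucleus_dose_per_reaction
        assert np.array_equal(t2.f_n1.counts, t.f_n1.counts)


class TestBackgroundComponent:
    def test_gamma_softer_than_boron_in_domains(self, lattice):
        cfg = SimConfig(ds_um=0.1, domain_diameters=(0.5,),
                        n_domain_samples=4000)
        b = run_boron_component(lattice, "nucleus", 1500, seed=21, cfg=cfg)
        g = run_background_component(lattice, "gamma", 400, seed=22, cfg=cfg)
        zb = b.f_d1[0.5].m2 / b.f_d1[0.5].m1
        zg = g.f_d1[0.5].m2 / g.f_d1[0.5].m1
        assert zg < zb  # low-LET electrons give much softer domain spectra

    def test_density_normalized(self, lattice):
        t = run_background_component(lattice, "N", 2000, seed=23, cfg=FAST)
        h = t.f_n1
        assert np.sum(h.density() * np.diff(h.edges)) == pytest.approx(1.0,
                                                                       abs=1e-6)

    def test_variance_scales_with_histories(self, lattice):
        ses = []
        for n, seed in ((4000, 31), (8000, 31)):
            t = run_background_component(lattice, "N", n, seed=seed, cfg=FAST)
            ses.append(t.mean_nucleus_dose_se)
        # doubling histories roughly halves the variance of the mean
        assert 0.3 < (ses[1] / ses[0]) ** 2 < 0.7

    def test_uniform_source_sees_macroscopic_dose(self, lattice):
        # for a uniform source the nucleus dose equals the whole-period dose
        t = run_background_component(lattice, "gamma", 2000, seed=25, cfg=FAST)
        assert t.mean_nucleus_dose_per_reaction == pytest.approx(
            t.mean_total_dose_per_reaction, rel=0.05)


class TestDomainSpectrum:
    def test_mean_chord_is_two_thirds_diameter(self, lattice):
        d = 0.5
        tracks = TrackSample(let_kev_um=np.full(100, 100.0), step_um=0.1)
        h = domain_spectrum(lattice, tracks, d, 100_000, seed_or_rng=2)
        m_d = np.pi / 6.0 * d**3 * 1e-15
        mean_chord = h.m1 * m_d / (100.0 * 1.602176634e-16)
        assert mean_chord == pytest.approx(2.0 * d / 3.0, rel=0.01)

    def test_central_track_maximal_chord(self, lattice):
        # a domain centred on a constant-LET track sees at most LET * d
        tracks = TrackSample(let_kev_um=np.full(10, 50.0), step_um=0.1)
        h = domain_spectrum(lattice, tracks, 0.3, 20000, seed_or_rng=3)
        z_max = 50.0 * 0.3 * 1.602176634e-16 / (np.pi / 6.0 * 0.3**3 * 1e-15)
        occupied = np.nonzero(h.counts)[0]
        assert h.edges[occupied[-1]] <= z_max * 1.001

    def test_density_normalized(self, lattice):
        tracks = TrackSample(let_kev_um=np.full(10, 50.0), step_um=0.1)
        h = domain_spectrum(lattice, tracks, 0.3, 5000, seed_or_rng=4)
        assert np.sum(h.density() * np.diff(h.edges)) == pytest.approx(1.0,
                                                                       abs=1e-6)

    def test_oversized_domain_rejected(self, lattice):
        tracks = TrackSample(let_kev_um=np.full(10, 50.0), step_um=0.1)
        with pytest.raises(ValueError):
            domain_spectrum(lattice, tracks, lattice.a_n * 1.1, 100,
                            seed_or_rng=5)


class TestComputeR:
    def test_weighted_mean_identity(self, boron_tallies, lattice):
        r = compute_R(boron_tallies, lattice)
        f = (lattice.f_n, lattice.f_c, lattice.f_e)
        assert sum(fi * ri for fi, ri in zip(f, r)) == pytest.approx(1.0,
                                                                     rel=1e-12)

    def test_geometric_ordering(self, boron_tallies, lattice):
        r_n, r_c, r_e = compute_R(boron_tallies, lattice)
        assert r_n >= 1.0 >= r_e

    def test_missing_compartment_rejected(self, boron_tallies, lattice):
        partial = {k: v for k, v in boron_tallies.items() if k != "cytoplasm"}
        with pytest.raises(ValueError, match="cytoplasm"):
            compute_R(partial, lattice)
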