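import math

import numpy as np
import pytest
from scipy import stats

from tftgrad.core_models import ModelParams, make_model, default_params, LN2
from tftgrad.pde_engine import Grid
from tftgrad.age_analytics import mean_age
from tftgrad.stochastic_sim import (
    assign_maturation, binned_age, run_particles,
)

T_NC14 = 2.5 * 3600.0
K26 = LN2 / (26.0 * 60.0)


def pde_age_in_bins(spec, grid, t, bin_width=10.0):
    """Concentration-weighted PDE mean age per 10-um bin (minutes)."""
    prof = mean_age(spec, grid, t)
    n = int(round(grid.L / bin_width))
    idx = (prof.positions // bin_width).astype(int)
    m = np.bincount(idx, weights=prof.moment, minlength=n)
    c = np.bincount(idx, weights=prof.conc, minlength=n)
    out = np.full(n, np.nan)
    nz = c > 0
    out[nz] = m[nz] / c[nz] / 60.0
    return out


class TestRunParticles:
    def test_immobile_immortal_particles_stay_put(self):
        spec = make_model("SDD", ModelParams(D_protein=0.0,
                                             protein_half_life=1e9,
                                             synthesis_rate=2.0))
        ens = run_particles(spec, t_end=600.0, dt=1.0, seed=3)
        assert np.all(ens.position <= 2.0)  # source strip
        assert np.all(ens.alive)
        expected_mean_age = ens.clock - ens.birth_time.mean()
        assert ens.alive_ages().mean() == pytest.approx(expected_mean_age)

    def test_fixed_seed_bitwise_identical(self, sdd_spec):
        a = run_particles(sdd_spec, t_end=1200.0, dt=2.0, seed=11,
                          birth_rate=5.0)
        b = run_particles(sdd_spec, t_end=1200.0, dt=2.0, seed=11,
                          birth_rate=5.0)
        assert np.array_equal(a.position, b.position)
        assert np.array_equal(a.birth_time, b.birth_time)
        assert np.array_equal(a.alive, b.alive)

    def test_event_probability_bound_enforced(self, sdd_spec):
        with pytest.raises(ValueError, match="dt"):
            run_particles(sdd_spec, t_end=600.0, dt=300.0, seed=1,
                          birth_rate=5.0)

    def test_well_mixed_age_distribution_is_exponential(self):
        # k > 0 at steady state: ages ~ Exponential(k)
        spec = make_model("SDD", ModelParams(
            D_protein=0.0, protein_half_life=10.0, synthesis_rate=20.0))
        k = LN2 / (10.0 * 60.0)
        ens = run_particles(spec, t_end=15 * 10 * 60.0, dt=2.0, seed=5)
        ages = ens.alive_ages()
        assert ages.size > 2000
        ks = stats.kstest(ages, "expon", args=(0, 1.0 / k))
        assert ks.pvalue > 0.01

    def test_steady_state_particle_count_near_J_over_k(self):
        J, t_half = 8.0, 10.0
        spec = make_model("SDD", ModelParams(
            D_protein=1.0, protein_half_life=t_half, synthesis_rate=J))
        k = LN2 / (t_half * 60.0)
        ens = run_particles(spec, t_end=12 * t_half * 60.0, dt=2.0, seed=9)
        n_expected = J / k
        n_alive = ens.alive.sum()
        assert abs(n_alive - n_expected) < 3.0 * math.sqrt(n_expected)

    def test_positions_respect_reflecting_boundaries(self, sdd_spec):
        ens = run_particles(sdd_spec, t_end=1800.0, dt=2.0, seed=2,
                            birth_rate=20.0)
        assert np.all(ens.position >= 0.0)
        assert np.all(ens.position <= ens.L)

    def test_halving_dt_changes_binned_ages_within_se(self, sdd_spec):
        prof2, se2, n2 = binned_age(run_particles(
            sdd_spec, t_end=3600.0, dt=2.0, seed=21, birth_rate=20.0))
        prof1, se1, n1 = binned_age(run_particles(
            sdd_spec, t_end=3600.0, dt=1.0, seed=22, birth_rate=20.0))
        sel = (n1 >= 200) & (n2 >= 200)
        se = np.sqrt(se1[sel] ** 2 + se2[sel] ** 2)
        diff = np.abs(prof1.mean_age_min[sel] - prof2.mean_age_min[sel])
        # weak-order convergence: means agree within combined SE (3 sigma)
        assert np.all(diff < 3.0 * se)


class TestBinnedAge:
    def test_single_particle(self):
        from tftgrad.stochastic_sim import ParticleEnsemble
        ens = ParticleEnsemble(
            clock=600.0, L=500.0, seed=0,
            position=np.array([5.0]), birth_time=np.array([0.0]),
            alive=np.array([True]), green_mature=np.array([False]),
            red_state=np.array([0], dtype=np.int8))
        prof, se, counts = binned_age(ens, bin_width=10.0)
        assert prof.mean_age_min[0] == pytest.approx(10.0)
        assert math.isnan(se[0])
        assert counts[0] == 1
        assert not prof.defined[0]  # below the 20-particle floor

    def test_duplicated_ensemble_halves_se_variance(self, sdd_spec):
        from tftgrad.stochastic_sim import ParticleEnsemble
        base = run_particles(sdd_spec, t_end=1800.0, dt=2.0, seed=4,
                             birth_rate=20.0)
        doubled = ParticleEnsemble(
            clock=base.clock, L=base.L, seed=base.seed,
            position=np.concatenate([base.position, base.position]),
            birth_time=np.concatenate([base.birth_time, base.birth_time]),
            alive=np.concatenate([base.alive, base.alive]),
            green_mature=np.concatenate([base.green_mature,
                                         base.green_mature]),
            red_state=np.concatenate([base.red_state, base.red_state]))
        p1, se1, n1 = binned_age(base)
        p2, se2, n2 = binned_age(doubled)
        sel = n1 >= 50
        assert np.allclose(p2.mean_age_min[sel], p1.mean_age_min[sel])
        # SE scales as 1/sqrt(2) (up to the n-1 correction)
        expected = se1[sel] * np.sqrt((n1[sel] - 1) / (2 * n1[sel] - 1))
        assert np.allclose(se2[sel], expected, rtol=1e-6)

    def test_empty_ensemble_raises(self):
        from tftgrad.stochastic_sim import ParticleEnsemble
        ens = ParticleEnsemble(clock=0.0, L=500.0, seed=0,
                               position=np.empty(0), birth_time=np.empty(0),
                               alive=np.empty(0, dtype=bool),
                               green_mature=np.empty(0, dtype=bool),
                               red_state=np.empty(0, dtype=np.int8))
        with pytest.raises(ValueError):
            binned_age(ens)

    def test_sdd_binned_ages_increase_posteriorly(self, sdd_spec):
        ens = run_particles(sdd_spec, t_end=T_NC14, dt=2.0, seed=17,
                            birth_rate=20000 * K26)
        prof, se, counts = binned_age(ens)
        sel = (prof.positions >= 50) & (prof.positions <= 400) & (counts > 100)
        ages = prof.mean_age_min[sel]
        tau, p = stats.kendalltau(prof.positions[sel], ages)
        assert tau > 0.5 and p < 1e-6


class TestCrossModuleAgeAgreement:
    @pytest.mark.parametrize("name", ["SDD", "NucSh", "RNA-grad", "RNA-diff"])
    def test_mc_matches_moment_pde_within_3se(self, name, all_specs):
        grid = Grid(500.0, 250)
        spec = all_specs[name]
        kwargs = {}
        if name == "RNA-diff":
            import dataclasses
            params = dataclasses.replace(
                spec.params, translation_rate=20000 * K26 / 4000 * 1.2)
            spec = make_model(name, params)
            kwargs["n_initial"] = 4000
        else:
            kwargs["birth_rate"] = 2.0 if name == "NucSh" else 20000 * K26
        ens = run_particles(spec, t_end=T_NC14, dt=2.0, seed=12, **kwargs)
        prof_mc, se, counts = binned_age(ens)
        pde = pde_age_in_bins(spec, grid, T_NC14)
        sel = counts >= 200
        assert sel.sum() >= 10
        z = np.abs(prof_mc.mean_age_min[sel] - pde[sel]) / se[sel]
        assert np.nanmax(z) < 3.0


class TestMaturationAssignment:
    def test_green_fraction_matches_exponential_clock(self, sdd_spec,
                                                      maturation):
        ens = run_particles(sdd_spec, t_end=3600.0, dt=2.0, seed=8,
                            birth_rate=30.0)
        assign_maturation(ens, maturation)
        ages = ens.ages
        old = ages > 3 * 27.0 * 60.0
        if old.sum() > 100:
            assert ens.green_mature[old].mean() > 0.8
        # expected green fraction = 1 - exp(-m_g * age), checked in aggregate
        expected = 1.0 - np.exp(-maturation.m_g * ages)
        assert ens.green_mature.mean() == pytest.approx(expected.mean(),
                                                        abs=0.03)
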