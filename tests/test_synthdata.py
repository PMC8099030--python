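"""Synthetic ground-truth generators: determinism, statistical structure."""

import json

import numpy as np
import pytest

from scaledcm.renorm import (
    coarse_grain_step,
    decay_time,
    estimate_z_correlation,
    time_correlation,
    zscore_regions,
)
from scaledcm.synthdata import (
    SynthSpec,
    _ou,
    generate_scalable_series,
    generate_scalefree_lattice,
    write_fixture_set,
)


def lattice_spec(**kw):
    base = dict(kind="scalefree_lattice", L=16, T=2000, dt=0.05, z_true=0.5, seed=0)
    base.update(kw)
    return SynthSpec(**base)


class TestSpecValidation:
    def test_requires_power_of_two_lattice(self):
        with pytest.raises(ValueError):
            lattice_spec(L=12)

    def test_requires_exponent(self):
        with pytest.raises(ValueError):
            lattice_spec(z_true=None)
        with pytest.raises(ValueError):
            SynthSpec(kind="scalable_series", seed=0, alpha_true=None)

    def test_timescale_must_exceed_dt(self):
        with pytest.raises(ValueError):
            lattice_spec(base_timescale=0.01)

    def test_unmeasurable_coarse_timescale_signalled(self):
        with pytest.raises(ValueError, match="not measurable"):
            generate_scalefree_lattice(lattice_spec(T=200, z_true=3.0))


class TestDeterminism:
    def test_lattice_reproducible(self):
        a = generate_scalefree_lattice(lattice_spec(seed=5))
        b = generate_scalefree_lattice(lattice_spec(seed=5))
        c = generate_scalefree_lattice(lattice_spec(seed=6))
        for mv_a, mv_b in zip(a, b):
            assert (mv_a.values == mv_b.values).all()
        assert not (a[0].values == c[0].values).all()

    def test_series_reproducible(self):
        spec = SynthSpec(
            kind="scalable_series", seed=3, alpha_true=-1.0, T=200, dt=0.25,
            base_timescale=1.0, scales=(1.0, 2.0),
        )
        a = generate_scalable_series(spec)
        b = generate_scalable_series(spec)
        for (ba, ta, ma), (bb, tb, mb) in zip(a, b):
            assert ba == bb
            assert (ta.values == tb.values).all()
            assert (ma.A == mb.A).all()


class TestScalableSeries:
    def test_alpha_zero_shares_generator(self):
        spec = SynthSpec(
            kind="scalable_series", seed=1, alpha_true=0.0, T=100, dt=0.25,
            base_timescale=1.0, scales=(1.0, 1.5, 3.0),
        )
        fam = generate_scalable_series(spec)
        A0 = fam[0][2].A
        for _, _, model in fam[1:]:
            assert np.allclose(model.A, A0)

    def test_eigenvalue_scaling_doubles_decay_time(self):
        """alpha=-1, b=2, scalar, noiseless: decay time exactly doubles."""
        spec = SynthSpec(
            kind="scalable_series", seed=2, alpha_true=-1.0, T=400, dt=0.05,
            base_timescale=1.0, noise_sd=0.0, n_regions=1, scales=(1.0, 2.0),
        )
        (b1, ts1, m1), (b2, ts2, m2) = generate_scalable_series(spec)
        assert np.allclose(m2.A, 0.5 * m1.A)
        # e-folding read directly off the noiseless exponential decay
        x1, x2 = np.abs(ts1.values[0]), np.abs(ts2.values[0])
        t1 = ts1.times[np.argmax(x1 <= x1[0] / np.e)]
        t2 = ts2.times[np.argmax(x2 <= x2[0] / np.e)]
        assert t2 == pytest.approx(2 * t1, rel=0.1)

    def test_generating_models_stable(self):
        spec = SynthSpec(
            kind="scalable_series", seed=4, alpha_true=-1.5, T=100, dt=0.25,
            base_timescale=1.0,
        )
        for _, _, model in generate_scalable_series(spec):
            assert model.is_stable


class TestScaleFreeLattice:
    def test_levels_and_shapes(self):
        movies = generate_scalefree_lattice(lattice_spec())
        assert [mv.L for mv in movies] == [16, 8, 4, 2]
        assert [mv.level for mv in movies] == [0, 1, 2, 3]
        assert all(mv.zscored for mv in movies)

    def test_block_average_consistency(self):
        """Coarse-graining the finest movie reproduces the stored next level
        (up to z-scoring): the hierarchy is self-consistent.  Per-region
        standardisation at the finer level perturbs the exact block
        cancellation slightly, hence the 0.99 rather than exact match."""
        movies = generate_scalefree_lattice(lattice_spec(noise_sd=0.0))
        cg = zscore_regions(coarse_grain_step(movies[0]))
        corr = [
            np.corrcoef(cg.values[i, j], movies[1].values[i, j])[0, 1]
            for i in range(8)
            for j in range(8)
        ]
        assert min(corr) > 0.99

    def test_z_zero_has_equal_decay_times(self):
        movies = generate_scalefree_lattice(lattice_spec(z_true=0.0, seed=8))
        taus = [
            decay_time(time_correlation(mv, mv.n_samples // 2)) for mv in movies
        ]
        assert np.ptp(taus) / np.mean(taus) < 0.10

    def test_level_one_decay_doubles_at_z_one(self):
        taus0, taus1 = [], []
        for seed in range(5):
            movies = generate_scalefree_lattice(lattice_spec(z_true=1.0, seed=seed))
            taus0.append(decay_time(time_correlation(movies[0], 500)))
            taus1.append(decay_time(time_correlation(movies[1], 500)))
        ratio = np.mean(taus1) / np.mean(taus0)
        assert ratio == pytest.approx(2.0, rel=0.2)

    def test_ou_lag_autocorrelation_closed_form(self):
        """The OU building block follows exp(-lag/tau) (Lorentzian spectrum)."""
        tau, dt, T = 0.6, 0.05, 60000
        x = _ou(np.random.default_rng(9), (4,), T, dt, tau)
        x = (x - x.mean(axis=-1, keepdims=True)) / x.std(axis=-1, keepdims=True)
        for m in (1, 5, 10):
            rho = np.mean(np.sum(x[:, m:] * x[:, :-m], axis=1) / (T - m))
            assert rho == pytest.approx(np.exp(-m * dt / tau), abs=0.03)

    def test_recovery_across_z_range(self):
        """10-seed pooled recovery holds from shallow to steep exponents."""
        for z_true in (0.25, 1.5):
            zs = [
                estimate_z_correlation(
                    generate_scalefree_lattice(lattice_spec(z_true=z_true, seed=s))
                ).z
                for s in range(10)
            ]
            assert abs(np.mean(zs) - z_true) < 0.15


class TestFixtureSet:
    def test_empty_specs(self, tmp_path):
        manifest = write_fixture_set([], tmp_path)
        assert manifest == {"fixtures": []}

    def test_checksums_deterministic(self, tmp_path):
        spec = lattice_spec(L=4, T=100)
        m1 = write_fixture_set([spec], tmp_path / "a")
        m2 = write_fixture_set([spec], tmp_path / "b")
        assert m1["fixtures"][0]["checksums"] == m2["fixtures"][0]["checksums"]

    def test_manifest_round_trip_regenerates(self, tmp_path):
        specs = [
            lattice_spec(L=4, T=100),
            SynthSpec(
                kind="scalable_series", seed=1, alpha_true=-1.0, T=50, dt=0.25,
                base_timescale=1.0, scales=(1.0, 2.0),
            ),
        ]
        write_fixture_set(specs, tmp_path)
        with open(tmp_path / "manifest.json") as fh:
            manifest = json.load(fh)
        respecs = [SynthSpec.from_dict(e["spec"]) for e in manifest["fixtures"]]
        again = write_fixture_set(respecs, tmp_path / "again")
        for e1, e2 in zip(manifest["fixtures"], again["fixtures"]):
            assert e1["checksums"] == e2["checksums"]
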