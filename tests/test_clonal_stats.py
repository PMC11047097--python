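import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corrugo.clonal_stats import (
    UNOCCUPIED,
    SectorProfile,
    boundary_density,
    boundary_positions,
    census,
    founder_survival_density,
    heterozygosity,
    intensity_to_freqs,
    mean_sector_size,
    theory_clone_count,
    transect,
)
from corrugo.well_geometry import WellSpec


def profile_from_labels(labels, width=100.0):
    labels = np.asarray(labels)
    positions = np.linspace(0.0, width, labels.size)
    return SectorProfile(positions=positions, labels=labels, width=width)


class TestCensus:
    def test_single_clone(self, small_state):
        state = small_state.copy()
        state.genotype[:] = 7
        c = census(state)
        assert c.n_clones == 1
        assert float(c.fractions[7]) == 1.0

    def test_unique_genotypes_at_init(self, small_state):
        c = census(small_state)
        assert c.n_clones == small_state.n

    def test_fractions_sum_exactly_one(self, small_state):
        c = census(small_state)
        assert sum(c.fractions.values()) == 1  # exact rational arithmetic

    def test_empty_population_raises(self, small_state):
        state = small_state.copy()
        for name in ("ids", "founder", "genotype", "strain", "x", "y",
                     "angle", "length", "radius"):
            setattr(state, name, getattr(state, name)[:0])
        with pytest.raises(ValueError):
            census(state)


class TestTransect:
    def test_single_clone_constant_label(self, small_state):
        state = small_state.copy()
        state.genotype[:] = 3
        prof = transect(state, offset=2.0)
        occupied = prof.labels != UNOCCUPIED
        assert occupied.any()
        assert set(prof.labels[occupied]) == {3}

    def test_offset_must_exceed_radius(self, small_state):
        with pytest.raises(ValueError):
            transect(small_state, offset=0.4)

    def test_two_half_wells_one_boundary(self, small_state):
        # lay a row of horizontal cells along the transect line by hand
        state = small_state.copy()
        n = 10
        state.x = np.linspace(2.0, state.spec.width - 2.0, n)
        state.y = np.full(n, 2.0)
        state.angle = np.zeros(n)
        state.length = np.full(n, 4.0)
        state.radius = np.full(n, 0.5)
        state.ids = np.arange(n, dtype=np.int64)
        state.founder = np.arange(n, dtype=np.int64)
        state.strain = np.zeros(n, dtype=np.int8)
        state.genotype = np.where(state.x < state.spec.width / 2, 1, 2).astype(np.int64)
        prof = transect(state, offset=2.0)
        occ = prof.labels[prof.labels != UNOCCUPIED]
        changes = np.count_nonzero(occ[1:] != occ[:-1])
        assert changes == 1


class TestBoundaryDensity:
    def test_single_central_boundary(self):
        prof = profile_from_labels([0] * 100 + [1] * 100, width=100.0)
        edges, dens, n = boundary_density([prof], n_bins=50)
        assert n == 1
        peak_bin = np.argmax(dens)
        assert edges[peak_bin] <= 0.5 <= edges[peak_bin + 1] + 1e-9

    def test_integrates_to_one(self):
        rng = np.random.default_rng(0)
        profs = [profile_from_labels(rng.integers(0, 4, 200)) for _ in range(5)]
        edges, dens, n = boundary_density(profs, n_bins=40)
        assert n > 0
        integral = np.sum(dens * np.diff(edges))
        assert integral == pytest.approx(1.0, abs=1e-9)

    def test_no_boundaries_flagged_empty(self):
        prof = profile_from_labels([5] * 100)
        edges, dens, n = boundary_density([prof])
        assert n == 0
        assert np.all(dens == 0)

    def test_unoccupied_gaps_make_no_boundaries(self):
        labels = np.array([1] * 50 + [UNOCCUPIED] * 10 + [1] * 50)
        prof = profile_from_labels(labels)
        assert boundary_positions(prof).size == 0


class TestBoundaryRidgeClustering:
    def test_simulated_boundaries_cluster_near_ridges(self, neutral_ensemble):
        # endpoint sector boundaries of corrugated runs concentrate near the
        # ridges of the corrugation (T/8 window, against the uniform share)
        profs = []
        for snaps in neutral_ensemble["corrugated"]:
            profs.append(transect(snaps[-1], offset=2.0))
        pos = np.concatenate([boundary_positions(p) for p in profs])
        assert pos.size > 0
        spec = neutral_ensemble["corrugated"][0][0].spec
        T = spec.period_T
        ridges = np.arange(T / 2, spec.width, T)
        near = np.min(np.abs(pos[:, None] - ridges[None, :]), axis=1)
        frac_near = np.mean(near <= T / 8)
        uniform_share = 2 * (T / 8) * ridges.size / spec.width
        assert frac_near > 1.5 * uniform_share, (
            f"{frac_near:.2f} of boundary mass near ridges "
            f"(uniform {uniform_share:.2f})"
        )


class TestMeanSectorSize:
    def test_single_clone_full_width(self):
        prof = profile_from_labels([4] * 200)
        assert mean_sector_size(prof) == pytest.approx(1.0, rel=0.02)

    def test_eleven_equal_sectors(self):
        labels = np.repeat(np.arange(11), 20)
        prof = profile_from_labels(labels)
        assert mean_sector_size(prof) == pytest.approx(1 / 11, rel=0.06)

    def test_two_unequal_sectors(self):
        labels = np.array([0] * 60 + [1] * 140)
        prof = profile_from_labels(labels, width=100.0)
        assert mean_sector_size(prof) == pytest.approx(0.5, rel=0.02)

    def test_unoccupied_raises(self):
        prof = profile_from_labels([UNOCCUPIED] * 100)
        with pytest.raises(ValueError):
            mean_sector_size(prof)


class TestHeterozygosity:
    def test_balanced_mixture(self):
        n = 200
        prof = SectorProfile(positions=np.arange(n, dtype=float),
                             f1=np.full(n, 0.5), f2=np.full(n, 0.5))
        assert heterozygosity(prof) == pytest.approx(0.25)

    def test_single_strain(self):
        n = 200
        prof = SectorProfile(positions=np.arange(n, dtype=float),
                             f1=np.ones(n), f2=np.zeros(n))
        assert heterozygosity(prof) == 0.0

    def test_75_25(self):
        n = 50
        prof = SectorProfile(positions=np.arange(n, dtype=float),
                             f1=np.full(n, 0.75), f2=np.full(n, 0.25))
        assert heterozygosity(prof) == pytest.approx(0.1875)

    def test_all_unoccupied_raises(self):
        n = 10
        prof = SectorProfile(positions=np.arange(n, dtype=float),
                             f1=np.zeros(n), f2=np.zeros(n))
        with pytest.raises(ValueError):
            heterozygosity(prof)

    @given(st.lists(st.floats(0.0, 1.0), min_size=3, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_bounded_by_quarter(self, f1_values):
        f1 = np.array(f1_values)
        prof = SectorProfile(positions=np.arange(f1.size, dtype=float),
                             f1=f1, f2=1.0 - f1)
        h = heterozygosity(prof)
        assert 0.0 <= h <= 0.25 + 1e-12
        if np.allclose(f1, 0.5):
            assert h == pytest.approx(0.25)


class TestIntensityToFreqs:
    def test_equal_channels(self):
        f1, f2 = intensity_to_freqs([100.0], [100.0])
        assert f1[0] == pytest.approx(0.5) and f2[0] == pytest.approx(0.5)

    def test_three_to_one(self):
        f1, f2 = intensity_to_freqs([300.0], [100.0])
        assert f1[0] == pytest.approx(0.75)

    def test_dark_position_flagged_unoccupied(self):
        f1, f2 = intensity_to_freqs([0.0, 300.0], [0.0, 100.0])
        assert f1[0] == 0.0 and f2[0] == 0.0
        assert f1[1] == pytest.approx(0.75)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            intensity_to_freqs([-1.0], [1.0])


class TestTheoryCloneCount:
    @pytest.mark.parametrize("T,expected", [(10, 11), (100, 2), (50, 3)])
    def test_formula(self, T, expected):
        n, f = theory_clone_count(WellSpec.corrugated(T, 5))
        assert n == pytest.approx(expected)
        assert f == pytest.approx(1 / expected)

    def test_flat_raises(self):
        with pytest.raises(ValueError):
            theory_clone_count(WellSpec.flat_bottom())


class TestFounderSurvival:
    def _toy_snapshots(self, survive_low_only):
        """Two-snapshot toy run with a hand-written genealogy."""
        from corrugo.biofilm_sim import desk_profile, initialize

        spec = WellSpec.flat_bottom(40, 16)
        s0 = initialize(spec, desk_profile(), 10, seed=1)
        s0.time = 2.0
        s1 = s0.copy()
        s1.time = 72.0
        order = np.argsort(s0.y)
        if survive_low_only:
            keep = order[:5]  # only the 5 lowest founders leave descendants
        else:
            keep = order
        # descendants: fresh ids, parents = surviving founders
        parent_of = list(s0.parent_of)
        child_ids = []
        for j, k in enumerate(keep):
            child_ids.append(10 + j)
            parent_of.append(int(s0.ids[k]))
        s1.ids = np.array(child_ids, dtype=np.int64)
        s1.x = s0.x[keep]
        s1.y = s0.y[keep]
        s1.parent_of = parent_of
        s0.parent_of = parent_of
        return [s0, s1]

    def test_density_integrates_to_one(self):
        snaps = self._toy_snapshots(survive_low_only=True)
        edges, dens, d0, dsurv = founder_survival_density(snaps, 2.0, 72.0, n_bins=8)
        assert np.sum(dens * np.diff(edges)) == pytest.approx(1.0, abs=1e-9)

    def test_all_survivors_match_initial_distribution(self):
        snaps = self._toy_snapshots(survive_low_only=False)
        edges, dens, d0, dsurv = founder_survival_density(snaps, 2.0, 72.0, n_bins=6)
        ref, _ = np.histogram(d0, bins=edges, density=True)
        assert np.allclose(dens, ref)

    def test_low_founders_only(self):
        snaps = self._toy_snapshots(survive_low_only=True)
        edges, dens, d0, dsurv = founder_survival_density(snaps, 2.0, 72.0, n_bins=8)
        assert dsurv.max() <= np.median(d0) + 1e-9
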