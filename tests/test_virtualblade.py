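"""Fragmentation, interval assignment, trait profiles and light extinction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import flat_rectangle_leaf, single_leaf_architecture
from ricecanopy import datamodel, reconstruct, synthetic
from ricecanopy import virtualblade as vb
from ricecanopy.virtualblade import (
    BladeSectionSet,
    Fragment,
    SunConfig,
    area_profile_radial,
    area_profile_z,
    area_voxel,
    assign_cylindrical,
    assign_planar_z,
    azimuth_distribution,
    fragment_architecture,
    fragment_leaf,
    inclination_profile_radial,
    inclination_profile_z,
    light_profile_z,
    projection_factor,
)


def _frag(midpoint, area=1.0):
    return Fragment(
        leaf_id=(), index=0, l_lo=0.0, l_hi=1.0, area=area,
        midpoint=np.asarray(midpoint, float), azimuth=0.0, inclination=0.0,
        corners=np.zeros((4, 3)),
    )


class TestFragmentLeaf:
    def test_flat_rectangle(self):
        leaf, _ = flat_rectangle_leaf(length=10.0, halfwidth=1.0, z=15.0)
        frags = fragment_leaf(leaf, 10)
        assert len(frags) == 10
        np.testing.assert_allclose([f.area for f in frags], 2.0)
        np.testing.assert_allclose([f.inclination for f in frags], 0.0)
        np.testing.assert_allclose([f.midpoint[2] for f in frags], 15.0)

    def test_vertical_leaf_inclination(self):
        m = datamodel.MidribCurve2D(
            points=np.array([[0.0, 0.0], [0.0, 10.0]]),
            fit=np.array([0.0, 0.0, 0.0, 0.0, 1.0, 0.0]),
            length=10.0,
        )
        leaf, stem = flat_rectangle_leaf(z=5.0)
        leaf.midrib2d = m
        leaf.midrib3d = reconstruct.midrib_3d(m, 0.0, leaf.node3d, stem, 21)
        leaf.edges3d = reconstruct.leaf_edges_3d(leaf.midrib3d, leaf.shape)
        frags = fragment_leaf(leaf, 5)
        np.testing.assert_allclose([f.inclination for f in frags], np.pi / 2)

    @pytest.mark.parametrize(
        "step, expected",
        [((1, 1), np.pi / 4), ((-1, 1), 3 * np.pi / 4), ((1, -1), 7 * np.pi / 4)],
    )
    def test_azimuth_quadrants(self, step, expected):
        dx, dy = step
        az = float(np.arctan2(dy, dx)) % (2 * np.pi)
        leaf, _ = flat_rectangle_leaf(length=10.0, halfwidth=0.5, z=5.0, azimuth=az)
        frags = fragment_leaf(leaf, 4)
        np.testing.assert_allclose([f.azimuth for f in frags], expected, atol=1e-12)

    def test_fnum_below_one_raises(self):
        leaf, _ = flat_rectangle_leaf()
        with pytest.raises(ValueError):
            fragment_leaf(leaf, 0)

    def test_area_matches_width_trapezoid(self, small_arch):
        for _, _, leaf in list(small_arch.iter_leaves())[:5]:
            frags = fragment_leaf(leaf, 100)
            grid = np.linspace(0, leaf.midrib2d.length, 101)
            expect = np.trapezoid(2 * leaf.shape.halfwidth(grid), grid)
            assert sum(f.area for f in frags) == pytest.approx(expect, rel=1e-9)


class TestAssignment:
    @pytest.mark.parametrize(
        "z_pair, dns, expected",
        [((4.0, 6.0), 5.0, 2), ((0.0, 0.0), 5.0, 1), ((9.9, 10.1), 10.0, 2)],
    )
    def test_planar_examples(self, z_pair, dns, expected):
        f = _frag([0.0, 0.0, np.mean(z_pair)])
        assert assign_planar_z(f, dns) == expected

    @pytest.mark.parametrize(
        "midpoint, dns, expected",
        [((0, 0, 0), 5.0, 1), ((7.2, 0, 0), 5.0, 2), ((0, 5.0, 0), 5.0, 2)],
    )
    def test_cylindrical_examples(self, midpoint, dns, expected):
        assert assign_cylindrical(_frag(midpoint), dns) == expected

    @given(z=st.floats(0.0, 500.0), dns=st.floats(0.5, 50.0))
    @settings(deadline=None, max_examples=200)
    def test_planar_index_brackets_the_midpoint(self, z, dns):
        n = assign_planar_z(_frag([0, 0, z]), dns)
        assert (n - 1) * dns <= z
        assert z <= n * dns + 1e-9 * max(z, 1)

    def test_refinement_consistency_exact_at_fragment_level(self, small_arch):
        frags = fragment_architecture(small_arch, 50)
        dns = 4.0
        coarse = {}
        fine = {}
        for f in frags:
            coarse[assign_planar_z(f, dns)] = coarse.get(assign_planar_z(f, dns), 0.0) + f.area
            nf = assign_planar_z(f, dns / 2)
            fine[nf] = fine.get(nf, 0.0) + f.area
        for n, a in coarse.items():
            resummed = fine.get(2 * n - 1, 0.0) + fine.get(2 * n, 0.0)
            assert resummed == pytest.approx(a, rel=1e-12)

    def test_section_spacing_must_be_positive(self):
        with pytest.raises(ValueError):
            BladeSectionSet("planar-z", 0.0)
        with pytest.raises(ValueError):
            assign_planar_z(_frag([0, 0, 1]), -1.0)


class TestAreaProfiles:
    def test_one_leaf_lands_in_its_interval(self):
        leaf, stem = flat_rectangle_leaf(length=10.0, halfwidth=1.0, z=15.0)
        arch = single_leaf_architecture(leaf, stem)
        prof = area_profile_z(arch, fnum=10, dns=10.0)
        assert prof.area[1] == pytest.approx(20.0, rel=1e-9)
        assert prof.area.sum() == pytest.approx(20.0, rel=1e-9)

    @pytest.mark.parametrize("mode", ["z", "radial"])
    def test_conservation(self, small_arch, mode):
        frags = fragment_architecture(small_arch, 60)
        total = sum(f.area for f in frags)
        fn = area_profile_z if mode == "z" else area_profile_radial
        prof = fn(small_arch, fnum=60, dns=5.0)
        assert prof.total_area == pytest.approx(total, rel=1e-9)

    def test_probability_density_normalization(self, small_arch):
        ctx = small_arch.context
        prof = area_profile_z(small_arch, fnum=50, dns=5.0)
        s = (prof.area_pdensity * 5.0 * ctx.pm * ctx.spec.rs * ctx.spec.ps).sum()
        assert s == pytest.approx(1.0, rel=1e-9)

    def test_empty_canopy_gives_empty_profile(self):
        arch = datamodel.DigitalArchitecture(context=synthetic.default_context(), hills=[])
        prof = area_profile_z(arch)
        assert prof.total_area == 0.0

    def test_annulus_normalization_uniform_disc(self):
        # concentric flat ring-leaves whose areas scale with annulus area
        # produce a constant radial density
        ctx = synthetic.default_context(rows=1, cols=1)
        hills = [datamodel.Hill(datamodel.HillPosition(1, 1), (0.0, 0.0), [])]
        arch = datamodel.DigitalArchitecture(context=ctx, hills=hills)
        dns = 5.0
        frags = []
        for n in range(1, 5):
            annulus = np.pi * ((n * dns) ** 2 - ((n - 1) * dns) ** 2)
            r = (n - 0.5) * dns
            frags.append(_frag([r, 0.0, 0.0], area=annulus))
        # aggregate by hand through the same binning path
        idx = np.array([assign_cylindrical(f, dns) for f in frags])
        areas = np.array([f.area for f in frags])
        n_arr = np.arange(1, idx.max() + 1)
        binned = np.zeros(len(n_arr))
        np.add.at(binned, idx - 1, areas)
        dens = binned / (np.pi * ((n_arr * dns) ** 2 - ((n_arr - 1) * dns) ** 2)) / ctx.pm
        assert np.ptp(dens) / dens.mean() <= 0.05

    def test_monte_carlo_oracle_z(self, small_arch):
        rng = np.random.default_rng(99)
        prof = area_profile_z(small_arch, fnum=100, dns=5.0)
        zs = _surface_sample_z(small_arch, rng, 30000)
        _assert_mc_match(prof.area, zs, 5.0, 30000)


def _surface_sample_z(arch, rng, n_points):
    """Uniform sample of the canopy leaf surface; returns point heights."""
    leaves = [leaf for _, _, leaf in arch.iter_leaves()]
    weights = []
    for leaf in leaves:
        grid = np.linspace(0, leaf.midrib2d.length, 101)
        weights.append(np.trapezoid(2 * leaf.shape.halfwidth(grid), grid))
    weights = np.array(weights)
    counts = rng.multinomial(n_points, weights / weights.sum())
    zs = []
    for leaf, c in zip(leaves, counts):
        if c == 0:
            continue
        L = leaf.midrib2d.length
        wmax = 2.1 * leaf.shape.max_halfwidth
        got = []
        while sum(len(g) for g in got) < c:
            l = rng.uniform(0, L, 4 * c)
            keep = rng.uniform(0, wmax, 4 * c) < 2 * leaf.shape.halfwidth(l)
            got.append(l[keep])
        l = np.concatenate(got)[:c]
        # cross-width offset along the (horizontal) venation normal
        zmid = np.interp(l, leaf.midrib3d[:, 0], leaf.midrib3d[:, 3])
        z1 = np.interp(l, leaf.edges3d[0][:, 0], leaf.edges3d[0][:, 3])
        z2 = np.interp(l, leaf.edges3d[1][:, 0], leaf.edges3d[1][:, 3])
        t = rng.uniform(-1, 1, c)
        z = zmid + np.where(t >= 0, t * (z2 - zmid), -t * (z1 - zmid))
        zs.append(z)
    return np.concatenate(zs)


def _assert_mc_match(area, sample_vals, dns, n_points, sigmas=3.0):
    idx = np.floor(sample_vals / dns).astype(int) + 1
    nmax = max(int(idx.max()), len(area))
    hist = np.bincount(idx, minlength=nmax + 1)[1 : nmax + 1]
    frac = np.zeros(nmax)
    frac[: len(area)] = area / area.sum()
    mc = hist / n_points
    sigma = np.sqrt(np.maximum(frac * (1 - frac), 1e-12) / n_points)
    assert np.all(np.abs(mc - frac) <= sigmas * sigma + 3.0 / n_points)


class TestVoxel:
    def test_total_area_conserved(self, small_arch):
        vox = area_voxel(small_arch, fnum=40, spacing=(5.0, 5.0, 5.0))
        frags = fragment_architecture(small_arch, 40)
        assert vox.total_area == pytest.approx(sum(f.area for f in frags), rel=1e-9)

    def test_single_flat_leaf_in_one_box(self):
        leaf, stem = flat_rectangle_leaf(length=10.0, halfwidth=1.0, z=15.0, base_xy=(5.0, 5.0))
        ctx = synthetic.default_context(rows=1, cols=1)
        arch = single_leaf_architecture(leaf, stem, ctx)
        vox = area_voxel(arch, fnum=10, spacing=(20.0, 20.0, 20.0))
        occupied = {k: v for k, v in vox.area.items() if v > 1e-12}
        assert len(occupied) == 1
        assert next(iter(occupied.values())) == pytest.approx(20.0, rel=1e-9)

    def test_marginal_matches_planar_profile(self, small_arch):
        vox = area_voxel(small_arch, fnum=100, spacing=(5.0, 5.0, 5.0))
        prof = area_profile_z(small_arch, fnum=100, dns=5.0)
        mz = vox.marginal_z()
        for n, a in enumerate(prof.area, start=1):
            if a > 1e-9:
                assert mz.get(n, 0.0) == pytest.approx(a, rel=0.02)


class TestAzimuth:
    def test_fractions_sum_to_one(self, small_arch):
        prof = azimuth_distribution(small_arch, fnum=20, dn=12)
        assert prof.fraction.sum() == pytest.approx(1.0, rel=1e-12)

    def test_single_straight_leaf_in_one_sector(self):
        leaf, stem = flat_rectangle_leaf(length=10.0, halfwidth=0.5, z=5.0, azimuth=np.pi / 4)
        arch = single_leaf_architecture(leaf, stem)
        prof = azimuth_distribution(arch, fnum=10, dn=8)
        assert prof.fraction[1] == pytest.approx(1.0)  # sector 2 of 8

    def test_uniform_azimuths_pass_chi_square(self):
        from scipy import stats

        tpl = synthetic.PlantTemplate(seed=21, tillers_per_hill=7, leaves_per_tiller=4,
                                      midrib_droop_angle=(0.1, 0.2))
        arch = synthetic.generate_architecture(tpl, synthetic.default_context())
        prof = azimuth_distribution(arch, fnum=10, dn=12)
        nl = arch.n_leaves
        counts = prof.fraction * nl
        chi2 = ((counts - nl / 12) ** 2 / (nl / 12)).sum()
        p = stats.chi2.sf(chi2, 11)
        assert p > 0.01


class TestInclination:
    def test_all_horizontal_canopy_is_zero(self):
        leaf, stem = flat_rectangle_leaf(length=10.0, halfwidth=1.0, z=12.0)
        arch = single_leaf_architecture(leaf, stem)
        prof = inclination_profile_z(arch, fnum=10, dns=5.0)
        occ = prof.area > 0
        np.testing.assert_allclose(prof.mean_inclination[occ], 0.0, atol=1e-12)

    def test_weighted_mean_of_mixed_interval(self):
        f1 = _frag([0, 0, 2.0], area=2.0)
        f2 = _frag([0, 0, 3.0], area=6.0)
        f2.inclination = np.pi / 2
        from ricecanopy.virtualblade import _inclination_profile

        prof = _inclination_profile([f1, f2], np.array([1, 1]), BladeSectionSet("planar-z", 5.0))
        assert prof.mean_inclination[0] == pytest.approx(3 * np.pi / 8)

    def test_empty_interval_is_nan_not_zero(self):
        leaf, stem = flat_rectangle_leaf(length=10.0, halfwidth=1.0, z=22.0)
        arch = single_leaf_architecture(leaf, stem)
        prof = inclination_profile_z(arch, fnum=10, dns=5.0)
        assert np.isnan(prof.mean_inclination[0])  # empty bottom interval

    def test_radial_agrees_with_naive_groupby(self, small_arch):
        frags = fragment_architecture(small_arch, 30)
        prof = inclination_profile_radial(small_arch, fnum=30, dns=5.0)
        groups: dict[int, list] = {}
        for f in frags:
            groups.setdefault(assign_cylindrical(f, 5.0), []).append(f)
        for n, fs in groups.items():
            w = sum(f.area for f in fs)
            expect = sum(f.area * f.inclination for f in fs) / w
            assert prof.mean_inclination[n - 1] == pytest.approx(expect, rel=1e-9)
        assert prof.total_area == pytest.approx(sum(f.area for f in frags), rel=1e-9)


class TestLight:
    @pytest.mark.parametrize(
        "ts, tl, dphi, expected",
        [(0.3, 0.3, 0.0, 1.0), (0.7, 0.0, 1.0, np.cos(0.7)), (np.pi / 4, np.pi / 4, np.pi, 0.0)],
    )
    def test_projection_factor_closed_form(self, ts, tl, dphi, expected):
        sun = SunConfig(ts, 0.0)
        assert projection_factor(sun, tl, -dphi) == pytest.approx(expected, abs=1e-12)

    @given(
        ts=st.floats(0, np.pi / 2), tl=st.floats(0, np.pi / 2),
        ps=st.floats(0, 2 * np.pi), pl=st.floats(0, 2 * np.pi),
    )
    @settings(deadline=None, max_examples=300)
    def test_projection_equals_unit_vector_dot(self, ts, tl, ps, pl):
        def v(theta, phi):
            return np.array(
                [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
            )

        got = projection_factor(SunConfig(ts, ps), tl, pl)
        assert got == pytest.approx(float(v(ts, ps) @ v(tl, pl)), abs=1e-12)

    def test_empty_canopy_returns_par0_everywhere(self):
        arch = datamodel.DigitalArchitecture(context=synthetic.default_context(), hills=[])
        prof = light_profile_z(arch, sun=SunConfig(np.pi / 4, 0.0, par0=3.5), n_intervals=6)
        np.testing.assert_allclose(prof.lid, 3.5)

    def test_lid_non_increasing_top_down(self, small_arch):
        prof = light_profile_z(small_arch, fnum=50, dns=5.0, sun=SunConfig(np.pi / 3, 1.0))
        assert np.all(np.diff(prof.lid) >= -1e-12)  # grows with height index

    def test_single_opaque_layer_halves_the_light(self):
        # one horizontal layer whose projected area is half the ground area
        ctx = synthetic.default_context()  # ground area 3200 cm^2
        leaf, stem = flat_rectangle_leaf(length=40.0, halfwidth=20.0, z=15.0)
        arch = single_leaf_architecture(leaf, stem, ctx)
        sun = SunConfig(0.0, 0.0, par0=2.0)  # projection factor 1 for horizontal
        prof = light_profile_z(arch, fnum=100, dns=10.0, sun=sun, ctx=ctx)
        assert prof.lic[1] == pytest.approx(0.5, rel=1e-6)
        assert prof.lid[1] == pytest.approx(2.0)
        assert prof.lid[0] == pytest.approx(1.0, rel=1e-6)
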