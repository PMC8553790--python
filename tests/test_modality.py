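import numpy as np
import pytest

from viroproteome.modality import (
    InsufficientDataError,
    build_map,
    classify_modality,
    count_modes,
    kde_1d,
    silverman_bandwidth,
)
from viroproteome.physchem import profile
from viroproteome.synthetic import host_archetype, sample_proteome
from test_aggregate import make_profile


def brute_force_modes(density: np.ndarray, prominence_frac: float) -> int:
    """Independent oracle: exhaustive local-maxima + prominence scan.

    Topographic prominence of a peak is its height above the higher of
    the two deepest valleys separating it from taller terrain (the
    boundary counts as zero ground).
    """
    d = np.concatenate([[0.0], np.asarray(density, float), [0.0]])
    peaks = [i for i in range(1, len(d) - 1) if d[i] > d[i - 1] and d[i] >= d[i + 1]]
    threshold = prominence_frac * max(density)
    count = 0
    for i in peaks:
        # walk left/right to the nearest strictly-higher point; the
        # prominence base on each side is the minimum along the walk
        left_min = d[i]
        j = i - 1
        while j >= 0 and d[j] <= d[i]:
            left_min = min(left_min, d[j])
            j -= 1
        right_min = d[i]
        j = i + 1
        while j < len(d) and d[j] <= d[i]:
            right_min = min(right_min, d[j])
            j += 1
        prominence = d[i] - max(left_min, right_min)
        if prominence >= threshold:
            count += 1
    return count


def archetype_profiles(label, n=2000, seed=0):
    return [profile(r) for r in sample_proteome(host_archetype(label, n_proteins=n, seed=seed))]


class TestBuildMap:
    def test_point_mass_single_cell(self):
        profiles = [make_profile(pid=str(i), pi=5.0, mw_da=10000.0) for i in range(4)]
        m = build_map(profiles, 10, 10)
        assert m.counts.sum() == 4
        assert (m.counts > 0).sum() == 1
        assert int(m.counts.max()) == 4

    def test_counts_conserved(self, rng):
        profiles = [
            make_profile(pid=str(i), pi=float(p), mw_da=float(m))
            for i, (p, m) in enumerate(zip(rng.uniform(3, 12, 300), rng.uniform(5e3, 5e5, 300)))
        ]
        m = build_map(profiles)
        assert m.counts.sum() == 300

    def test_doubling_doubles_cells(self, rng):
        profiles = [
            make_profile(pid=str(i), pi=float(p), mw_da=float(m))
            for i, (p, m) in enumerate(zip(rng.uniform(3, 12, 100), rng.uniform(5e3, 5e5, 100)))
        ]
        single = build_map(profiles)
        double = build_map(profiles + profiles)
        assert np.array_equal(double.counts, 2 * single.counts)

    def test_out_of_range_clamped(self, caplog):
        profiles = [make_profile(pid="lo", pi=1.0, mw_da=1e4)] + [
            make_profile(pid=str(i), pi=6.0, mw_da=1e4 + i) for i in range(20)
        ]
        with caplog.at_level("WARNING"):
            m = build_map(profiles)
        assert m.counts.sum() == 21
        assert "clamped" in caplog.text

    def test_edges_strictly_increasing(self, rng):
        profiles = [make_profile(pid=str(i), pi=5.0 + i * 0.01, mw_da=1e4 * (i + 1)) for i in range(30)]
        m = build_map(profiles)
        assert np.all(np.diff(m.pi_edges) > 0)
        assert np.all(np.diff(m.mw_edges) > 0)

    def test_empty_and_small_bins_rejected(self):
        with pytest.raises(ValueError):
            build_map([])
        with pytest.raises(ValueError):
            build_map([make_profile()], pi_bins=5)

    def test_long_format_export(self):
        profiles = [make_profile(pid=str(i), pi=5.0, mw_da=1e4 + i) for i in range(10)]
        frame = build_map(profiles, 10, 10).to_frame()
        assert frame["count"].sum() == 10
        assert frame.shape[0] == 100


class TestKde1d:
    def test_single_gaussian_single_peak(self, rng):
        values = rng.normal(5.0, 1.0, size=1000)
        grid, density = kde_1d(values)
        count, locs = count_modes(density, 0.05, grid=grid)
        assert count == 1
        assert locs[0] == pytest.approx(5.0, abs=0.3)

    def test_density_non_negative_and_normalized(self, rng):
        values = rng.lognormal(1.0, 0.5, size=400)
        grid, density = kde_1d(values)
        assert np.all(density >= 0)
        assert np.trapezoid(density, grid) == pytest.approx(1.0, abs=0.01)

    def test_degenerate_values_rejected(self):
        with pytest.raises(ValueError):
            kde_1d(np.full(10, 3.0))
        with pytest.raises(ValueError):
            kde_1d([1.0])

    def test_bandwidth_factor_scales_silverman(self, rng):
        values = rng.normal(0, 1, 500)
        h = silverman_bandwidth(values)
        assert h == pytest.approx(values.std(ddof=1) * (4 / (3 * 500)) ** 0.2)
        # wider bandwidth flattens the density peak
        _, d1 = kde_1d(values, bandwidth_factor=1.0)
        _, d3 = kde_1d(values, bandwidth_factor=3.0)
        assert d3.max() < d1.max()


class TestCountModes:
    def test_unimodal_curve(self):
        x = np.linspace(-4, 4, 301)
        count, _ = count_modes(np.exp(-(x**2)), 0.05)
        assert count == 1

    def test_two_separated_bumps(self):
        x = np.linspace(-8, 8, 601)
        density = np.exp(-((x + 4) ** 2)) + np.exp(-((x - 4) ** 2))
        count, locs = count_modes(density, 0.05, grid=x)
        assert count == 2
        assert locs == sorted(locs)

    def test_tiny_ripple_not_counted(self):
        x = np.linspace(-4, 4, 801)
        # main bump plus a ripple of ~2% relative prominence on the flank
        density = np.exp(-(x**2) / 2) + 0.02 * np.exp(-((x - 2.0) ** 2) / 0.005)
        count, _ = count_modes(density, 0.05)
        assert count == 1
        assert brute_force_modes(density, 0.05) == 1

    def test_matches_brute_force_on_random_mixtures(self, rng):
        x = np.linspace(0, 14, 512)
        for _ in range(100):
            k = int(rng.integers(1, 5))
            means = rng.uniform(1, 13, k)
            sds = rng.uniform(0.2, 1.5, k)
            weights = rng.dirichlet(np.ones(k))
            density = np.zeros_like(x)
            for m, s, w in zip(means, sds, weights):
                density += w * np.exp(-((x - m) ** 2) / (2 * s**2)) / s
            count, _ = count_modes(density, 0.05)
            assert count == brute_force_modes(density, 0.05)

    def test_validation(self):
        with pytest.raises(ValueError):
            count_modes(np.array([]))
        with pytest.raises(ValueError):
            count_modes(np.array([1.0, 2.0]), prominence_frac=1.5)


class TestClassifyModality:
    @pytest.mark.parametrize("label,k", [("unimodal", 1), ("bimodal", 2), ("trimodal", 3)])
    def test_recovers_archetype(self, label, k):
        result = classify_modality(archetype_profiles(label, n=2000, seed=42))
        assert result.label == label
        assert result.pi_modes == k
        assert len(result.mode_locations) == k

    def test_bimodal_mode_locations(self):
        result = classify_modality(archetype_profiles("bimodal", n=2000, seed=7))
        lo, hi = result.mode_locations
        assert lo == pytest.approx(4.6, abs=0.5)
        assert hi == pytest.approx(10.1, abs=0.5)

    def test_refuses_small_input(self):
        profiles = [make_profile(pid=str(i), pi=5 + 0.01 * i) for i in range(49)]
        with pytest.raises(InsufficientDataError):
            classify_modality(profiles)

    def test_invariant_to_order_and_duplication(self):
        profiles = archetype_profiles("bimodal", n=400, seed=3)
        base = classify_modality(profiles)
        shuffled = classify_modality(profiles[::-1])
        doubled = classify_modality(profiles + profiles)
        assert base.label == shuffled.label == doubled.label
        assert base.pi_modes == shuffled.pi_modes == doubled.pi_modes

    def test_constant_values_one_mode(self):
        profiles = [make_profile(pid=str(i), pi=6.0, mw_da=5e4) for i in range(60)]
        result = classify_modality(profiles)
        assert result.pi_modes == 1
        assert result.label == "unimodal"
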