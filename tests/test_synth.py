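import numpy as np
import pytest
from shapely.geometry import box

import leriscape as L
from leriscape.raster import CLASS_CODES


class TestGenerateLandcover:
    def test_single_class_proportions_give_one_patch(self):
        cfg = L.SynthConfig(seed=0, proportions=(1, 0, 0, 0, 0, 0), clumping=0.4)
        lc = L.generate_landcover(cfg, (0, 0, 30, 30), 1.0)
        assert (lc.data == 1).all()
        assert L.label_patches(lc.data, 1) == 1

    def test_unclumped_proportions_match_request(self):
        """With clumping 0 pixels are i.i.d.; realized shares stay within 2 pp."""
        props = (0.30, 0.15, 0.30, 0.05, 0.10, 0.10)
        for seed in range(20):
            cfg = L.SynthConfig(seed=seed, proportions=props, clumping=0.0)
            lc = L.generate_landcover(cfg, (0, 0, 100, 100), 1.0)
            realized = np.array([(lc.data == c).mean() for c in CLASS_CODES])
            assert np.abs(realized - props).max() < 0.02

    def test_deterministic_under_seed(self, synth_config, square_extent):
        a = L.generate_landcover(synth_config, square_extent, 1.0)
        b = L.generate_landcover(synth_config, square_extent, 1.0)
        assert np.array_equal(a.data, b.data)

    @pytest.mark.parametrize(
        "proportions", [(0.5, 0.5, 0.5, 0, 0, 0), (-0.1, 1.1, 0, 0, 0, 0), (1, 0, 0)]
    )
    def test_invalid_proportions_rejected(self, proportions):
        with pytest.raises(ValueError):
            L.generate_landcover(
                L.SynthConfig(proportions=proportions), (0, 0, 10, 10), 1.0
            )

    def test_resolution_must_divide_extent(self, synth_config):
        with pytest.raises(ValueError, match="divide"):
            L.generate_landcover(synth_config, (0, 0, 10.5, 10), 1.0)

    def test_boundary_pixels_get_nodata(self, synth_config):
        boundary = box(0, 0, 5, 10)  # left half only
        lc = L.generate_landcover(synth_config, (0, 0, 10, 10), 1.0, boundary)
        assert (lc.data[:, :5] != lc.nodata).all()
        assert (lc.data[:, 5:] == lc.nodata).all()

    def test_clumping_reduces_patch_count(self):
        """Mean patch count (over seeds) falls monotonically with clumping."""
        clumpings = (0.0, 0.3, 0.6, 1.0)
        means = []
        for clump in clumpings:
            counts = []
            for seed in range(20):
                cfg = L.SynthConfig(seed=seed, clumping=clump)
                lc = L.generate_landcover(cfg, (0, 0, 50, 50), 1.0)
                counts.append(
                    sum(L.label_patches(lc.data, c) for c in CLASS_CODES)
                )
            means.append(np.mean(counts))
        assert all(a > b for a, b in zip(means, means[1:]))


class TestGenerateIndicators:
    def test_eight_named_surfaces(self, indicators):
        assert [s.name for s in indicators] == list(L.INDICATOR_NAMES)

    def test_deterministic_under_seed(self, synth_config, square_extent):
        a = L.generate_indicators(synth_config, square_extent, 1.0)
        b = L.generate_indicators(synth_config, square_extent, 1.0)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.data, sb.data)

    def test_heavy_smoothing_flattens_field(self):
        rough = L.SynthConfig(seed=1, correlation_length=1.0)
        smooth = L.SynthConfig(seed=1, correlation_length=200.0)
        v_rough = L.generate_indicators(rough, (0, 0, 50, 50), 1.0)[0].data.var()
        v_smooth = L.generate_indicators(smooth, (0, 0, 50, 50), 1.0)[0].data.var()
        assert v_smooth < 0.01 * v_rough

    def test_autocorrelation_grows_with_correlation_length(self):
        def lag1_corr(field):
            a, b = field[:, :-1].ravel(), field[:, 1:].ravel()
            return np.corrcoef(a, b)[0, 1]

        short = L.generate_indicators(L.SynthConfig(seed=2, correlation_length=1.0),
                                      (0, 0, 60, 60), 1.0)[0]
        long_ = L.generate_indicators(L.SynthConfig(seed=2, correlation_length=8.0),
                                      (0, 0, 60, 60), 1.0)[0]
        assert lag1_corr(long_.data) > lag1_corr(short.data)

    def test_nonpositive_correlation_length_rejected(self):
        with pytest.raises(ValueError):
            L.generate_indicators(L.SynthConfig(correlation_length=0.0), (0, 0, 10, 10), 1.0)


class TestEvolveLandcover:
    def test_zero_rate_is_identity(self, landcover):
        cfg = L.SynthConfig(seed=5, urban_rate=0.0)
        for step in L.evolve_landcover(landcover, cfg, 3):
            assert np.array_equal(step.data, landcover.data)

    def test_no_urban_nucleus_means_no_change(self):
        cfg = L.SynthConfig(seed=5, proportions=(1, 0, 0, 0, 0, 0), urban_rate=1.0)
        lc = L.generate_landcover(cfg, (0, 0, 20, 20), 1.0)
        assert not (lc.data == 5).any()
        for step in L.evolve_landcover(lc, cfg, 2):
            assert np.array_equal(step.data, lc.data)

    def test_rate_one_converts_whole_4_adjacent_frontier(self):
        """3×3 cropland with an urban center: exactly the 4 edge neighbours convert."""
        from conftest import toy_raster

        data = np.full((3, 3), 1, dtype=np.int16)
        data[1, 1] = 5
        lc = toy_raster(data)
        cfg = L.SynthConfig(seed=0, urban_rate=1.0)
        (after,) = L.evolve_landcover(lc, cfg, 1)
        expected = np.array([[1, 5, 1], [5, 5, 5], [1, 5, 1]], dtype=np.int16)
        assert np.array_equal(after.data, expected)

    def test_urban_area_monotone_nondecreasing(self, landcover, synth_config):
        seq = [landcover] + L.evolve_landcover(landcover, synth_config, 4)
        urban = [(s.data == 5).sum() for s in seq]
        assert all(a <= b for a, b in zip(urban, urban[1:]))

    def test_invalid_rate_rejected(self, landcover):
        with pytest.raises(ValueError):
            L.evolve_landcover(landcover, L.SynthConfig(urban_rate=1.5), 1)


def test_ascii_grid_roundtrip(tmp_path, landcover, indicators):
    p = L.write_ascii_grid(landcover, tmp_path / "lc.asc")
    back = L.read_ascii_grid(p, dtype=np.int16)
    assert np.array_equal(back.data, landcover.data)
    assert back.same_registry(landcover)
    q = L.write_ascii_grid(indicators[0], tmp_path / "gdp.asc")
    surf = L.read_ascii_grid(q, name="gdp")
    assert np.allclose(surf.data, indicators[0].data, atol=1e-5)
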