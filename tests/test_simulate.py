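"""Generator: determinism, renderers, noise model, zone sampling, truth quality."""

import warnings

import numpy as np
import pytest
from scipy import stats

from tolfish import coloc, logic, segment, simulate
from tolfish.logic import Condition, Genotype, Inducer

WT_MXYL = Condition(Genotype.WT_PWW0, Inducer.M_XYLENE)


# ---------------------------------------------------------------------------
# determinism


def test_same_seed_bit_identical():
    p = simulate.SimParams(n_cells=8)
    s1, t1 = simulate.generate_field(p, WT_MXYL, 42)
    s2, t2 = simulate.generate_field(p, WT_MXYL, 42)
    for ch in s1.channels:
        assert np.array_equal(s1.channels[ch], s2.channels[ch])
    assert t1.foci_df().equals(t2.foci_df())
    assert t1.cells_df().equals(t2.cells_df())
    assert np.array_equal(t1.labels, t2.labels)


def test_different_seed_differs():
    p = simulate.SimParams(n_cells=8)
    s1, _ = simulate.generate_field(p, WT_MXYL, 42)
    s2, _ = simulate.generate_field(p, WT_MXYL, 43)
    assert not np.array_equal(s1.channels["dapi"], s2.channels["dapi"])


# ---------------------------------------------------------------------------
# render_spot


def test_render_spot_integral():
    raster = np.zeros((64, 64))
    simulate.render_spot(raster, (32.0, 32.0), 100.0, 1.5)
    expected = 100.0 * 2 * np.pi * 1.5**2
    assert abs(raster.sum() - expected) / expected < 0.01


def test_render_spot_centroid():
    raster = np.zeros((64, 64))
    simulate.render_spot(raster, (30.3, 33.7), 50.0, 1.5)
    ys, xs = np.mgrid[0:64, 0:64]
    cx = (xs * raster).sum() / raster.sum()
    cy = (ys * raster).sum() / raster.sum()
    assert abs(cx - 30.3) < 0.05 and abs(cy - 33.7) < 0.05


def test_render_spot_zero_amplitude_noop():
    raster = np.zeros((16, 16))
    simulate.render_spot(raster, (8, 8), 0.0, 1.5)
    assert raster.sum() == 0.0


def test_render_spot_outside_raises():
    with pytest.raises(ValueError):
        simulate.render_spot(np.zeros((16, 16)), (20, 8), 1.0, 1.5)


# ---------------------------------------------------------------------------
# render_dispersed


def _disc_mask(n=40, r=12):
    ys, xs = np.mgrid[0:n, 0:n]
    return (xs - n / 2) ** 2 + (ys - n / 2) ** 2 <= r**2


def test_render_dispersed_uniform_at_zero_heterogeneity():
    mask = _disc_mask()
    raster = np.zeros(mask.shape)
    simulate.render_dispersed(raster, mask, 1000.0, 0.0, np.random.default_rng(0))
    vals = raster[mask]
    assert np.allclose(vals, vals[0])
    assert raster[~mask].sum() == 0.0


@pytest.mark.parametrize("het", [0.0, 0.5, 1.0])
def test_render_dispersed_conserves_total(het):
    mask = _disc_mask()
    raster = np.zeros(mask.shape)
    simulate.render_dispersed(raster, mask, 1000.0, het, np.random.default_rng(1))
    assert abs(raster[mask].sum() - 1000.0) / 1000.0 < 0.01


def test_render_dispersed_validates_heterogeneity():
    with pytest.raises(ValueError):
        simulate.render_dispersed(np.zeros((8, 8)), _disc_mask(8, 3), 1.0, 1.5, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# apply_noise


def test_apply_noise_noiseless_limit():
    arr = np.full((32, 32), 123.0)
    stack = simulate.ImageStack(channels={"a": arr})
    out = simulate.apply_noise(stack, np.inf, 0.0, np.random.default_rng(0))
    assert np.array_equal(out.channels["a"], np.full((32, 32), 123, dtype=np.uint16))


def test_apply_noise_monte_carlo_mean():
    arr = np.full((40, 40), 50.0)
    stack = simulate.ImageStack(channels={"a": arr})
    rng = np.random.default_rng(7)
    means = [
        simulate.apply_noise(stack, 1.0, 5.0, rng).channels["a"].mean() for _ in range(500)
    ]
    assert abs(np.mean(means) - 50.0) / 50.0 < 0.01


def test_apply_noise_clipped_to_depth():
    arr = np.full((16, 16), 70000.0)
    stack = simulate.ImageStack(channels={"a": arr})
    out = simulate.apply_noise(stack, 1.0, 10.0, np.random.default_rng(0), depth_max=65535)
    assert out.channels["a"].max() <= 65535
    assert out.channels["a"].min() >= 0


# ---------------------------------------------------------------------------
# ImageStack / SimParams validation


def test_imagestack_shape_mismatch():
    with pytest.raises(ValueError):
        simulate.ImageStack(channels={"a": np.zeros((4, 4)), "b": np.zeros((5, 5))})


def test_imagestack_negative_intensity():
    with pytest.raises(ValueError):
        simulate.ImageStack(channels={"a": np.full((4, 4), -1.0)})


def test_simparams_validation():
    with pytest.raises(ValueError):
        simulate.SimParams(zone_weights=(0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        simulate.SimParams(psf_sigma=0.0)
    with pytest.raises(ValueError):
        simulate.SimParams(pairing_mix=(1.0, 1.0, 1.0))


# ---------------------------------------------------------------------------
# sample_focus_position


def _one_geom(seed=3, **kw):
    p = simulate.SimParams(n_cells=1, **kw)
    _, truth = simulate.generate_field(p, WT_MXYL, seed)
    c = truth.cells[0]
    pose = (c.center[0], c.center[1], c.orientation, c.length_px, c.width_px)
    return simulate._CellGeom(1, pose, tuple(p.field_shape), p, np.random.default_rng(seed)), p


def test_sample_degenerate_weights_all_dense():
    geom, _ = _one_geom()
    rng = np.random.default_rng(0)
    for _ in range(50):
        _, zone = simulate.sample_focus_position(geom, (1.0, 0.0, 0.0), rng)
        assert zone == "DENSE"


def test_sample_zone_fractions_within_binomial_ci():
    geom, _ = _one_geom()
    rng = np.random.default_rng(1)
    n = 3000
    counts = {"DENSE": 0, "PERIPHERAL": 0, "FREE": 0}
    for _ in range(n):
        _, zone = simulate.sample_focus_position(geom, (1 / 3, 1 / 3, 1 / 3), rng)
        counts[zone] += 1
    lo, hi = stats.binom.interval(0.99, n, 1 / 3)
    for z, c in counts.items():
        assert lo <= c <= hi, f"{z}: {c} outside [{lo}, {hi}]"


def test_sample_position_inside_cell():
    geom, _ = _one_geom()
    rng = np.random.default_rng(2)
    for _ in range(200):
        (x, y), _ = simulate.sample_focus_position(geom, (0.01, 0.15, 0.84), rng)
        assert geom.mask[int(round(y)), int(round(x))]


def test_sample_respects_exclusion_predicate():
    geom, _ = _one_geom()
    rng = np.random.default_rng(3)
    cx = geom.pose[0]
    for _ in range(50):
        pos, _ = simulate.sample_focus_position(
            geom, (0.0, 0.0, 1.0), rng, exclude=lambda q: q[0] < cx
        )
        if pos is None:  # zone entirely on the excluded side of this cell
            continue
        assert pos[0] >= cx


def test_sample_label_matches_classifier():
    geom, _ = _one_geom()
    rng = np.random.default_rng(4)
    for _ in range(100):
        (x, y), zone = simulate.sample_focus_position(geom, (0.2, 0.3, 0.5), rng)
        assert geom.classify(x, y) == zone


def test_sample_invalid_weights():
    geom, _ = _one_geom()
    with pytest.raises(ValueError):
        simulate.sample_focus_position(geom, (0.5, 0.1, 0.1), np.random.default_rng(0))


# ---------------------------------------------------------------------------
# generate_field semantics


def test_uninduced_has_no_red_foci():
    p = simulate.SimParams(n_cells=10, plasmid_tagged=False)
    stack, truth = simulate.generate_field(p, Condition(Genotype.WT_PWW0, Inducer.NONE), 9)
    df = truth.foci_df()
    assert (df.channel == "red").sum() == 0
    # red channel is background + noise only: mean close to the background
    red = stack.channels["red"].astype(float)
    assert abs(red.mean() - p.background) < 5.0


def test_degenerate_free_mixture():
    p = simulate.SimParams(n_cells=20, zone_weights=(0.0, 0.0, 1.0), pairing_mix=(0.0, 0.0, 1.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, truth = simulate.generate_field(p, WT_MXYL, 13)
    red = truth.foci_df().query("channel == 'red'")
    assert len(red) > 0
    assert (red.zone == "FREE").all()


def test_placement_failure_names_budget():
    p = simulate.SimParams(field_shape=(96, 96), n_cells=60, max_place_retries=25)
    with pytest.raises(RuntimeError, match="25"):
        simulate.generate_field(p, WT_MXYL, 0)


def test_foci_inside_cells_and_plasmid_realism():
    p = simulate.SimParams(n_cells=25)
    totals, cells = 0, 0
    for stack, truth in simulate.generate_fields(p, WT_MXYL, 21, 4):
        df = truth.foci_df()
        for _, row in df.iterrows():
            assert truth.labels[int(round(row.y)), int(round(row.x))] == row.cell_id
        totals += (df.channel == "green").sum()
        cells += len(truth.cells)
    assert 1.0 <= totals / cells <= 2.0  # plasmid foci once or twice per cell


def test_truth_zone_labels_exact_in_noiseless_limit():
    """End-to-end truth-consistency: with noise off and no plasmid DAPI
    contribution, the analysis-side classifier reproduces every truth label."""
    p = simulate.SimParams(
        n_cells=15,
        read_sigma=0.0,
        photon_scale=np.inf,
        dapi_plasmid_frac=0.0,
        pairing_mix=(0.0, 0.0, 1.0),
    )
    stack, truth = simulate.generate_field(p, WT_MXYL, 31)
    cells = segment.segment_cells(stack.channels["phase"], truth_mask=truth.labels)
    by_id = {c.cell_id: c for c in cells}
    mapping = {"DENSE": "NUCLEOID_OVERLAP", "PERIPHERAL": "PERIPHERAL", "FREE": "NUCLEOID_FREE"}
    df = truth.foci_df().query("channel == 'red'")
    assert len(df) > 0
    for _, row in df.iterrows():
        cell = by_id[row.cell_id]
        norm = segment.normalize_channel(stack.channels["dapi"], cell)
        zones = segment.nucleoid_zones(norm, cell, p.l_dense, p.l_diffuse)
        got = coloc.classify_focus_zone(row, zones)
        assert got.value == mapping[row.zone], f"focus at ({row.x:.1f},{row.y:.1f})"


def test_rifampin_renders_dispersed_not_focal():
    cond = Condition(Genotype.PUXT7_IN_T7_HOST, Inducer.NONE, iptg=True, rifampin=True)
    p = simulate.SimParams(n_cells=10, plasmid_tagged=False)
    stack, truth = simulate.generate_field(p, cond, 17)
    assert (truth.foci_df().channel == "red").sum() == 0  # no discrete truth foci
    red = stack.channels["red"].astype(float)
    in_cell = red[truth.labels > 0].mean()
    out_cell = red[truth.labels == 0].mean()
    assert in_cell > out_cell + 5.0  # but the signal itself is present


def test_write_read_field_roundtrip(tmp_path):
    p = simulate.SimParams(n_cells=5)
    stack, truth = simulate.generate_field(p, WT_MXYL, 3)
    simulate.write_field(tmp_path, "f0", stack, truth, p)
    back = simulate.read_field(tmp_path / "f0.tif")
    for ch in stack.channels:
        assert np.array_equal(back.channels[ch], stack.channels[ch])
    assert back.pixel_size_um == stack.pixel_size_um
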