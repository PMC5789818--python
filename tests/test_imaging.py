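"""Imaging-leg tests: projection, segmentation, classification, measurement."""

import dataclasses
import math

import numpy as np
import pytest

from mitopla import (
    CellRecord,
    ClassifyParams,
    Detection,
    Ellipse,
    GroundTruthScene,
    LabeledMask,
    ProjectedImage,
    Punctum,
    SceneObject,
    SceneParams,
    SelectionError,
    analyze_field,
    analyze_stack,
    classify_cells,
    default_segmentation_params,
    evaluate_segmentation,
    generate_scene,
    max_intensity_projection,
    measure_pla,
    read_mask,
    render_acquisition,
    segment_category,
    segment_dapi,
    subtract_background,
    write_mask,
)
from mitopla.core import _measure_labels


def _image(dapi=None, fitc=None, tritc=None, shape=(96, 96)):
    z = np.zeros(shape)
    return ProjectedImage(
        channels={
            "DAPI": dapi if dapi is not None else z.copy(),
            "FITC": fitc if fitc is not None else z.copy(),
            "TRITC": tritc if tritc is not None else z.copy(),
        }
    )


def _disk(shape, cy, cx, r, value):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    out = np.zeros(shape)
    out[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = value
    return out


# ---- maximum intensity projection -----------------------------------------


def test_mip_equals_bruteforce_max():
    rng = np.random.default_rng(0)
    stack = rng.integers(0, 4096, size=(2, 4, 3, 4, 4)).astype(np.uint16)
    mip = max_intensity_projection(stack, 1)
    for ci, c in enumerate(("DAPI", "FITC", "TRITC")):
        expected = np.zeros((4, 4))
        for y in range(4):
            for x in range(4):
                expected[y, x] = max(stack[1, z, ci, y, x] for z in range(4))
        assert np.array_equal(mip.channel(c), expected)


def test_mip_zero_stack_and_errors():
    stack = np.zeros((1, 3, 3, 8, 8), dtype=np.uint16)
    assert np.all(max_intensity_projection(stack, 0).channel("DAPI") == 0)
    with pytest.raises(IndexError):
        max_intensity_projection(stack, 5)
    with pytest.raises(ValueError):
        max_intensity_projection(np.zeros((1, 0, 3, 8, 8), np.uint16), 0)


# ---- background subtraction ------------------------------------------------


def test_background_constant_zero_is_identity():
    img = _image(dapi=np.full((16, 16), 7.0))
    out = subtract_background(img, method="constant", value=0.0)
    assert np.array_equal(out.channel("DAPI"), img.channel("DAPI"))


def test_background_constant_removes_uniform_level():
    img = _image(dapi=np.full((16, 16), 40.0))
    out = subtract_background(img, method="constant", value=40.0)
    assert np.all(out.channel("DAPI") == 0)


def test_background_percentile_recovers_disk_amplitude():
    b, a = 100.0, 500.0
    plane = np.full((128, 128), b) + _disk((128, 128), 64, 64, 20, a)
    out = subtract_background(_image(dapi=plane, shape=(128, 128)), "percentile", q=50.0)
    recovered = out.channel("DAPI")[64, 64]
    assert abs(recovered - a) / a < 0.05


def test_background_unknown_method_errors():
    with pytest.raises(ValueError):
        subtract_background(_image(), method="wavelet")


def test_background_rolling_ball_nonnegative():
    rng = np.random.default_rng(1)
    plane = rng.uniform(50, 80, (64, 64)) + _disk((64, 64), 32, 32, 8, 300.0)
    out = subtract_background(_image(dapi=plane, shape=(64, 64)), "rolling_ball", radius=15)
    assert np.all(out.channel("DAPI") >= 0)


# ---- segmentation ----------------------------------------------------------


def test_segment_blank_image_yields_no_objects():
    seg = default_segmentation_params()
    mask = segment_category(_image(), seg, "interphase_nucleus")
    assert mask.n_objects == 0


def test_segment_disk_circularity_and_bar_rejection():
    shape = (128, 128)
    disk = _disk(shape, 40, 40, 20, 3000.0)
    # 5:1 bar with ~equal area (pi*400 ~ 1257 px ~ 79x16)
    bar = np.zeros(shape)
    bar[100:116, 20:99] = 3000.0
    seg = default_segmentation_params()
    params = dataclasses.replace(seg)
    params.categories["interphase_nucleus"] = dataclasses.replace(
        seg.categories["interphase_nucleus"],
        min_area_px=100,
        max_area_px=10_000,
        min_circularity=0.8,
    )
    mask = segment_category(_image(dapi=disk + bar, shape=shape), params, "interphase_nucleus")
    assert mask.n_objects == 1
    assert mask.props["circularity"].iloc[0] >= 0.9
    # measure both shapes without filters to check the bar's circularity
    loose = dataclasses.replace(
        seg.categories["interphase_nucleus"], min_area_px=1, min_circularity=0.0
    )
    params.categories["interphase_nucleus"] = loose
    both = segment_category(_image(dapi=disk + bar, shape=shape), params, "interphase_nucleus")
    assert both.n_objects == 2
    assert both.props["circularity"].min() < 0.6  # the bar
    assert both.props["circularity"].max() >= 0.9  # the disk


@pytest.mark.parametrize("radius", [10, 14, 20])
def test_rasterized_disk_circularity_bounds(radius):
    shape = (80, 80)
    disk = _disk(shape, 40, 40, radius, 3000.0)
    labels = (disk > 0).astype(np.uint8)
    props = _measure_labels(labels, disk)
    assert 0.9 <= props["circularity"].iloc[0] <= 1.0


def test_mask_roundtrip_reproduces_measurements(tmp_path, enriched_scene, imaging_params):
    _params, _scene, stack = enriched_scene
    records, dapi, spin, sub = analyze_field(stack, 0, imaging_params)
    write_mask(tmp_path / "dapi.tif", dapi)
    write_mask(tmp_path / "spin.tif", spin)
    dapi2 = read_mask(tmp_path / "dapi.tif", "dapi", sub.channel("DAPI"))
    spin2 = read_mask(tmp_path / "spin.tif", "spindle", sub.channel("FITC"))
    assert np.array_equal(dapi.labels, dapi2.labels)
    for r in records:
        sel = "union" if r.klass == "mitotic" else "nucleus"
        a = measure_pla(sub, r, sel, dapi, spin)
        b = measure_pla(sub, r, sel, dapi2, spin2)
        assert a == b


# ---- classification --------------------------------------------------------


def test_classify_round_moderate_nucleus_is_interphase():
    img = _image(dapi=_disk((96, 96), 48, 48, 16, 2800.0))
    seg = default_segmentation_params()
    dapi = segment_dapi(img, seg)
    spin = segment_category(img, seg, "spindle")
    records, unlinked = classify_cells(dapi, spin)
    assert len(records) == 1
    assert records[0].klass == "interphase"
    assert records[0].spindle_label is None
    assert unlinked == []


def test_classify_bright_irregular_object_is_mitotic_with_spindle():
    shape = (96, 96)
    dapi_arr = np.zeros(shape)
    dapi_arr[40:56, 20:70] = 8000.0  # bright elongated bar: low circularity
    fitc_arr = np.zeros(shape)
    fitc_arr[36:62, 24:66] = 6000.0  # adjacent bright spindle blob
    img = _image(dapi=dapi_arr, fitc=fitc_arr)
    seg = default_segmentation_params()
    dapi = segment_dapi(img, seg)
    spin = segment_category(img, seg, "spindle")
    records, _ = classify_cells(dapi, spin)
    assert len(records) == 1
    assert records[0].klass == "mitotic"
    assert records[0].spindle_label is not None


def test_classify_ph3_overlap_forces_mitotic():
    img = _image(dapi=_disk((96, 96), 48, 48, 16, 2800.0))
    seg = default_segmentation_params()
    dapi = segment_dapi(img, seg)
    spin = segment_category(img, seg, "spindle")
    ph3_labels = (_disk((96, 96), 48, 48, 10, 1.0) > 0).astype(np.int32)
    ph3 = LabeledMask("ph3", ph3_labels, _measure_labels(ph3_labels, img.channel("FITC")))
    records, _ = classify_cells(dapi, spin, ph3_masks=ph3)
    assert records[0].klass == "mitotic"


def test_classification_accuracy_on_synthetic_scene(imaging_params):
    """Class labels agree with ground truth for >= 95% of detected cells."""
    params = SceneParams(
        field_grid_count=25, cells_per_field=(8, 8), mitotic_fraction=0.5, rng_seed=13
    )
    scene, stack = generate_scene(params)
    analysis = analyze_stack(stack, imaging_params)
    agree = total = 0
    for r in analysis.records:
        truth_klass = None
        for o in scene.objects_in_field(r.field):
            if o.channel == "DAPI" and o.contains(*r.centroid):
                truth_klass = o.klass
                break
        if truth_klass is None:
            continue
        total += 1
        want = "mitotic" if truth_klass == "mitotic_chromosomes" else "interphase"
        agree += r.klass == want
    assert total >= 190
    assert agree / total >= 0.95


# ---- PLA measurement -------------------------------------------------------


def _single_cell_masks(shape=(96, 96)):
    dapi_labels = (_disk(shape, 48, 48, 20, 1.0) > 0).astype(np.int32)
    dapi = LabeledMask("dapi", dapi_labels, _measure_labels(dapi_labels, np.zeros(shape)))
    rec = CellRecord(0, 0, "interphase", 1, None, (48.0, 48.0))
    return dapi, rec


def test_measure_pla_zero_channel_and_selection_errors():
    dapi, rec = _single_cell_masks()
    img = _image()
    assert measure_pla(img, rec, "nucleus", dapi) == 0.0
    with pytest.raises(SelectionError):
        measure_pla(img, rec, "spindle", dapi)
    with pytest.raises(SelectionError):
        measure_pla(img, rec, "everything", dapi)


def test_measure_pla_monotone_under_mask_inclusion():
    shape = (96, 96)
    rng = np.random.default_rng(3)
    tritc = rng.uniform(0, 100, shape)
    small = (_disk(shape, 48, 48, 10, 1.0) > 0).astype(np.int32)
    big = (_disk(shape, 48, 48, 20, 1.0) > 0).astype(np.int32)
    m_small = LabeledMask("dapi", small, _measure_labels(small, tritc))
    m_big = LabeledMask("dapi", big, _measure_labels(big, tritc))
    rec = CellRecord(0, 0, "interphase", 1, None, (48.0, 48.0))
    assert measure_pla(tritc, rec, "nucleus", m_small) <= measure_pla(
        tritc, rec, "nucleus", m_big
    )


def test_measure_pla_flux_conservation(quiet_params):
    """Two rendered puncta fully inside the mask sum to ~their total flux."""
    scene = GroundTruthScene(
        params=quiet_params,
        condition="CTR",
        seed=0,
        field_focus=[2.0],
        objects=[],
        puncta=[
            Punctum(0, 0, 28.0, 28.0, 2, 500.0, "nucleus"),
            Punctum(0, 0, 36.0, 38.0, 2, 300.0, "nucleus"),
        ],
    )
    stack = render_acquisition(scene, quiet_params)
    mip = max_intensity_projection(stack, 0)
    labels = (_disk((64, 64), 32, 32, 22, 1.0) > 0).astype(np.int32)
    dapi = LabeledMask("dapi", labels, _measure_labels(labels, mip.channel("TRITC")))
    rec = CellRecord(0, 0, "interphase", 1, None, (32.0, 32.0))
    total = measure_pla(mip, rec, "nucleus", dapi)
    assert abs(total - 800.0) / 800.0 < 0.02


def test_measure_pla_additive_over_disjoint_masks():
    shape = (96, 96)
    rng = np.random.default_rng(4)
    tritc = rng.uniform(0, 50, shape)
    dapi_labels = (_disk(shape, 30, 30, 10, 1.0) > 0).astype(np.int32)
    spin_labels = (_disk(shape, 70, 70, 12, 1.0) > 0).astype(np.int32)
    dapi = LabeledMask("dapi", dapi_labels, _measure_labels(dapi_labels, tritc))
    spin = LabeledMask("spindle", spin_labels, _measure_labels(spin_labels, tritc))
    rec = CellRecord(0, 0, "mitotic", 1, 1, (30.0, 30.0))
    u = measure_pla(tritc, rec, "union", dapi, spin)
    a = measure_pla(tritc, rec, "chromosomes", dapi, spin)
    b = measure_pla(tritc, rec, "spindle", dapi, spin)
    assert math.isclose(u, a + b, rel_tol=1e-12)


# ---- evaluation ------------------------------------------------------------


def _toy_truth(n, params):
    objects = [
        SceneObject(i, i, 0, "interphase_nucleus", "DAPI",
                    (Ellipse(20.0 + 40.0 * (i % 5), 20.0 + 40.0 * (i // 5), 10.0, 10.0, 0.0),),
                    3000.0)
        for i in range(n)
    ]
    return GroundTruthScene(params=params, condition="CTR", seed=0,
                            field_focus=[0.0], objects=objects, puncta=[])


def test_evaluation_perfect_and_partial(quiet_params):
    truth = _toy_truth(10, quiet_params)
    perfect = [Detection(0, "interphase_nucleus", *o.centroid) for o in truth.objects]
    res = evaluate_segmentation(perfect, truth)
    assert res.coverage_pct == 100.0 and res.precision_pct == 100.0
    partial = perfect[:8] + [Detection(0, "interphase_nucleus", 1.0, 1.0)]
    res = evaluate_segmentation(partial, truth)
    assert res.coverage_pct == pytest.approx(80.0)
    assert res.precision_pct == pytest.approx(100.0 * 8 / 9)
    assert res.per_class["interphase_nucleus"] == {
        "matched": 8, "missed": 2, "spurious": 1,
    }


def test_field_processing_order_invariance(enriched_scene, imaging_params):
    _params, _scene, stack = enriched_scene
    forward = [analyze_field(stack, f, imaging_params)[0] for f in range(stack.shape[0])]
    backward = [analyze_field(stack, f, imaging_params)[0] for f in reversed(range(stack.shape[0]))]
    backward.reverse()
    for recs_f, recs_b in zip(forward, backward):
        assert [dataclasses.asdict(r) for r in recs_f] == [
            dataclasses.asdict(r) for r in recs_b
        ]
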