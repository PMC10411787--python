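"""Template structure, landmark-file round-trips and metadata validation."""

import numpy as np
import pytest

from phalanxgmm.io import (
    LandmarkConfiguration,
    Sex,
    build_dataset,
    load_metadata,
    load_study_metadata,
    read_landmark_table,
    read_tps_file,
    write_landmark_table,
    write_metadata,
    write_tps_file,
)
from phalanxgmm.templates import (
    PointRole,
    forelimb_template,
    hindlimb_template,
)


@pytest.mark.parametrize(
    "factory,n_points,n_curve",
    [(forelimb_template, 72, 43), (hindlimb_template, 74, 45)],
)
def test_template_point_counts(factory, n_points, n_curve):
    tpl = factory()
    assert tpl.n_points == n_points
    assert tpl.n_fixed == 4
    assert tpl.n_curve == n_curve
    assert tpl.n_surface == 25
    roles = tpl.roles
    assert (roles == PointRole.FIXED.value).sum() == 4
    assert (roles == PointRole.CURVE.value).sum() == n_curve
    assert (roles == PointRole.SURFACE.value).sum() == 25
    assert len(tpl.indices_of(PointRole.CURVE)) == n_curve


def test_template_curve_runs_disjoint_and_ordered():
    tpl = forelimb_template()
    seen = set()
    for run in tpl.curves:
        idx = set(run.indices.tolist())
        assert not idx & seen
        seen |= idx
    # exact 1-based ranges of the forelimb configuration
    assert [(r.start, r.stop) for r in tpl.curves] == [
        (5, 16), (17, 30), (31, 38), (39, 47)
    ]
    assert tpl.surface_patches == ((48, 57), (58, 72))
    hind = hindlimb_template()
    assert [(r.start, r.stop) for r in hind.curves] == [
        (5, 18), (19, 32), (33, 40), (41, 49)
    ]
    assert hind.surface_patches == ((50, 58), (59, 74))


def test_landmark_table_roundtrip_exact(tmp_path, rng):
    tpl = forelimb_template()
    cfgs = [
        LandmarkConfiguration(f"DPpha {i+1}", "fore", rng.normal(size=(72, 3)) * 30)
        for i in range(3)
    ]
    path = tmp_path / "landmarks.csv"
    write_landmark_table(cfgs, path)
    back = read_landmark_table(path, tpl)
    assert len(back) == 3
    for a, b in zip(cfgs, back):
        assert a.specimen_id == b.specimen_id
        np.testing.assert_array_equal(a.coords, b.coords)  # bit-exact


def test_landmark_table_point_count_mismatch(tmp_path, rng):
    cfg = LandmarkConfiguration("DPpha 9", "fore", rng.normal(size=(71, 3)))
    path = tmp_path / "short.csv"
    write_landmark_table([cfg], path)
    with pytest.raises(ValueError, match="DPpha 9"):
        read_landmark_table(path, forelimb_template())


def test_landmark_table_non_numeric(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("specimen_id,point_index,x,y,z\nA,1,1.0,oops,3.0\n")
    with pytest.raises(ValueError, match="line"):
        read_landmark_table(path, forelimb_template())


def test_tps_roundtrip(tmp_path, rng):
    cfgs = [
        LandmarkConfiguration("DPpha 1", "fore", rng.normal(size=(5, 3))),
        LandmarkConfiguration("DPpha 2", "fore", rng.normal(size=(5, 3))),
    ]
    path = tmp_path / "sample.tps"
    write_tps_file(cfgs, path)
    back = read_tps_file(path)
    assert [c.specimen_id for c in back] == ["DPpha 1", "DPpha 2"]
    for a, b in zip(cfgs, back):
        np.testing.assert_allclose(a.coords, b.coords, atol=1e-6)


def test_tps_minimal_block_and_empty(tmp_path):
    path = tmp_path / "one.tps"
    path.write_text("LM3=2\n0.0 0.0 0.0\n1.0 2.0 3.0\nID=DPpha1\n")
    cfgs = read_tps_file(path)
    assert len(cfgs) == 1 and cfgs[0].n_points == 2
    assert cfgs[0].specimen_id == "DPpha1"
    empty = tmp_path / "empty.tps"
    empty.write_text("")
    assert read_tps_file(empty) == []


def test_tps_missing_header(tmp_path):
    path = tmp_path / "noheader.tps"
    path.write_text("0.0 0.0 0.0\n")
    with pytest.raises(ValueError, match="LM3"):
        read_tps_file(path)


def test_study_metadata_counts():
    fore = load_study_metadata("fore")
    hind = load_study_metadata("hind")
    assert len(fore) == 34
    assert len(hind) == 44
    # mobility marginals of the forelimb sample
    mob = [r.mobility.value for r in fore]
    assert mob.count("altitudinal") == 6
    assert mob.count("planarly") == 16
    assert mob.count("sedentary") == 12
    # hindlimb sex margin: 26 of unknown sex
    assert sum(r.sex is Sex.UNKNOWN for r in hind) == 26
    # the single multi-habitat subspecies dominates the forelimb sample
    assert sum(r.subspecies.value == "caribou" for r in fore) == 24
    assert sum(r.subspecies.value == "caribou" for r in hind) == 36
    groups = {r.group for r in fore}
    assert len(groups) == 7


def test_metadata_invalid_enum(tmp_path):
    path = tmp_path / "meta.csv"
    path.write_text(
        "specimen_id,subspecies,habitat,mobility,sex,limb\n"
        "DPpha 1,caribou,Lake,sedentary,male,fore\n"
    )
    with pytest.raises(ValueError, match="Lake"):
        load_metadata(path)


def test_metadata_roundtrip_and_normalization(tmp_path):
    path = tmp_path / "meta.csv"
    path.write_text(
        "specimen_id,subspecies,habitat,mobility,sex,limb\n"
        "DPpha 1,Caribou,Boreal Forest,SEDENTARY,,fore\n"
    )
    rec = load_metadata(path)[0]
    assert rec.habitat.value == "boreal_forest"
    assert rec.sex is Sex.UNKNOWN
    assert rec.group == "Rtcaribou_BorealForest_Sedentary"
    out = tmp_path / "out.csv"
    write_metadata([rec], out)
    assert load_metadata(out)[0] == rec


def test_left_side_mirrored(rng):
    coords = rng.normal(size=(72, 3))
    cfg = LandmarkConfiguration("DPpha 1", "fore", coords)
    meta = load_study_metadata("fore")[0]
    rec = type(meta)(
        specimen_id="DPpha 1",
        subspecies=meta.subspecies,
        habitat=meta.habitat,
        mobility=meta.mobility,
        limb=meta.limb,
        side="left",
    )
    ds = build_dataset([cfg], [rec])
    np.testing.assert_array_equal(ds.configurations[0].coords[:, 0], -coords[:, 0])
    np.testing.assert_array_equal(ds.configurations[0].coords[:, 1:], coords[:, 1:])
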