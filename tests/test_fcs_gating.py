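"""FCS round-trips, compensation arithmetic and the three-step gate sequence."""

import numpy as np
import pandas as pd
import pytest

import damfretkit as dk
from damfretkit.gating import CHANNELS, PolyGate, RectGate, transform_channels


def test_fcs_roundtrip_small(tmp_path):
    table = pd.DataFrame(
        {"FS00.A": [1.0, 2.5, 3e6], "FL09.A": [0.5, -1.25, 1e7], "FL10.A": [0, 1, 2]}
    )
    path = tmp_path / "tiny.fcs"
    dk.write_fcs(table, path)
    back = dk.read_fcs(path)
    assert list(back.columns) == list(table.columns)
    np.testing.assert_array_equal(back.to_numpy(), table.to_numpy(np.float32))


def test_fcs_roundtrip_large(tmp_path):
    sample = dk.simulate_negative_control(n_cells=100_000, seed=3)
    path = tmp_path / "big.fcs"
    dk.write_fcs(sample.events, path)
    back = dk.read_fcs(path)
    orig = sample.events.to_numpy()
    rel = np.abs(back.to_numpy() - orig.astype(np.float32)) / np.maximum(np.abs(orig), 1.0)
    assert rel.max() <= 1e-6


def test_fcs_rejects_unsupported_mode(tmp_path):
    path = tmp_path / "c.fcs"
    dk.write_fcs(pd.DataFrame({"A": [1.0]}), path)
    raw = path.read_bytes().replace(b"$MODE/L/", b"$MODE/C/")
    bad = tmp_path / "bad.fcs"
    bad.write_bytes(raw)
    with pytest.raises(dk.FCSFormatError, match=r"\$MODE"):
        dk.read_fcs(bad)


def test_fcs_rejects_unsupported_datatype(tmp_path):
    path = tmp_path / "d.fcs"
    dk.write_fcs(pd.DataFrame({"A": [1.0]}), path)
    raw = path.read_bytes().replace(b"$DATATYPE/F/", b"$DATATYPE/A/")
    bad = tmp_path / "bad.fcs"
    bad.write_bytes(raw)
    with pytest.raises(dk.FCSFormatError, match=r"\$DATATYPE"):
        dk.read_fcs(bad)


# ---------------------------------------------------------------------------
# compensation


def test_compensation_arithmetic():
    table = pd.DataFrame(
        {CHANNELS["donor"]: [200.0], CHANNELS["acceptor"]: [100.0], CHANNELS["fret"]: [90.0]}
    )
    out = dk.compensate(table, dk.SpilloverModel(0.3, 0.1))
    assert out["FRET_comp"].iloc[0] == pytest.approx(20.0)
    identity = dk.compensate(table, dk.SpilloverModel(0.0, 0.0))
    assert identity["FRET_comp"].iloc[0] == pytest.approx(90.0)


def test_compensation_keeps_negative_values():
    table = pd.DataFrame(
        {CHANNELS["donor"]: [1000.0], CHANNELS["acceptor"]: [0.0], CHANNELS["fret"]: [10.0]}
    )
    out = dk.compensate(table, dk.SpilloverModel(0.5, 0.0))
    assert out["FRET_comp"].iloc[0] == pytest.approx(-490.0)


def test_compensation_missing_column():
    with pytest.raises(KeyError, match=CHANNELS["fret"].replace(".", r"\.")):
        dk.compensate(pd.DataFrame({CHANNELS["donor"]: [1.0], CHANNELS["acceptor"]: [1.0]}),
                      dk.SpilloverModel())


def test_fit_spillover_recovers_coefficients():
    rng = np.random.default_rng(0)
    donor = rng.uniform(1e3, 1e6, 1000)
    acceptor = rng.uniform(1e3, 1e6, 1000)
    dc = pd.DataFrame({CHANNELS["donor"]: donor, CHANNELS["acceptor"]: 0.0,
                       CHANNELS["fret"]: 0.07 * donor})
    ac = pd.DataFrame({CHANNELS["donor"]: 0.0, CHANNELS["acceptor"]: acceptor,
                       CHANNELS["fret"]: 0.12 * acceptor})
    s = dk.fit_spillover(dc, ac)
    assert s.s_donor == pytest.approx(0.07, rel=1e-9)
    assert s.s_acceptor == pytest.approx(0.12, rel=1e-9)


# ---------------------------------------------------------------------------
# gates


def _ray_cast_oracle(x, y, vertices):
    """Classic scalar even-odd point-in-polygon (boundary not handled)."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y) and x < (x2 - x1) * (y - y1) / (y2 - y1) + x1:
            inside = not inside
    return inside


def test_rectangle_membership_printed_bounds():
    gate = RectGate("a", "b", 2.7, 4.8, 2.7, 4.7)
    assert gate.contains(np.array([3.0]), np.array([3.0]))[0]
    assert not gate.contains(np.array([2.0]), np.array([3.0]))[0]
    # closed boundaries: every corner and edge value is inside
    for x in (2.7, 4.8):
        for y in (2.7, 4.7):
            assert gate.contains(np.array([x]), np.array([y]))[0]


def test_polygon_membership_against_oracle():
    verts = ((1.0, 0.1), (1.8, 2.0), (5.0, 2.0), (5.0, 0.1))
    gate = PolyGate("a", "b", verts)
    assert gate.contains(np.array([3.0]), np.array([1.0]))[0]
    assert not gate.contains(np.array([0.5]), np.array([1.0]))[0]
    rng = np.random.default_rng(1)
    xs = rng.uniform(0, 6, 500)
    ys = rng.uniform(-0.5, 2.5, 500)
    got = gate.contains(xs, ys)
    want = np.array([_ray_cast_oracle(x, y, verts) for x, y in zip(xs, ys)])
    assert np.array_equal(got, want)
    # vertices themselves are inside (closed gate)
    vx = np.array([v[0] for v in verts])
    vy = np.array([v[1] for v in verts])
    assert gate.contains(vx, vy).all()


def test_polygon_rejects_self_intersection():
    with pytest.raises(ValueError):
        PolyGate("a", "b", ((0, 0), (1, 1), (1, 0), (0, 1)))


def test_gate_sequence_idempotent_and_order_preserving(nucleated_sample):
    gated, report = dk.apply_gate_sequence(nucleated_sample.events)
    again, report2 = dk.apply_gate_sequence(gated)
    assert len(again) == len(gated)
    assert list(gated.index) == sorted(gated.index)
    assert report.stage_counts["expressing"] == len(gated)
    assert report2.stage_counts["expressing"] == len(gated)


def test_singlet_gate_removes_doublets(nucleated_sample):
    truth = nucleated_sample.truth
    gated, _ = dk.apply_gate_sequence(nucleated_sample.events)
    doublets_in = truth["is_doublet"].sum()
    doublets_out = truth.loc[gated.index, "is_doublet"].sum()
    assert doublets_in > 0
    assert doublets_out <= 0.1 * doublets_in


def test_expressing_gate_removes_nonexpressing(nucleated_sample):
    truth = nucleated_sample.truth
    gated, _ = dk.apply_gate_sequence(nucleated_sample.events)
    assert truth.loc[gated.index, "is_nonexpressing"].sum() == 0
    # and keeps the overwhelming majority of true expressing singlets
    good = (~truth["is_doublet"]) & (~truth["is_nonexpressing"])
    assert len(gated) >= 0.95 * good.sum()


def test_empty_stage_warns():
    events = dk.simulate_negative_control(n_cells=100, seed=0).events
    impossible = dk.GateSet(
        cells_gate=RectGate(CHANNELS["fsc_a"], CHANNELS["ssc_a"], 0.0, 0.01, 0.0, 0.01)
    )
    with pytest.warns(UserWarning, match="cells"):
        gated, report = dk.apply_gate_sequence(events, impossible)
    assert len(gated) == 0


def test_transform_missing_column():
    with pytest.raises(KeyError):
        transform_channels(pd.DataFrame({"A": [1.0]}), ["B"])
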