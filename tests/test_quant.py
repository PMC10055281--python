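"""AmFRET derivation, negative-gate construction, fgate and curve fits."""

import numpy as np
import pandas as pd
import pytest

import damfretkit as dk
from damfretkit.gating import CHANNELS
from damfretkit.kinetics import BinnedCurve
from damfretkit.quant import FitError


def make_table(amfret, acceptor, ssc=None, fret_comp=None):
    acceptor = np.asarray(acceptor, dtype=float)
    amfret = np.asarray(amfret, dtype=float)
    ssc = np.full_like(acceptor, 1.0) if ssc is None else np.asarray(ssc, float)
    return pd.DataFrame(
        {
            "AmFRET": amfret,
            "concentration": acceptor / ssc,
            CHANNELS["acceptor"]: acceptor,
            CHANNELS["ssc_a"]: ssc,
            "FRET_comp": amfret * acceptor if fret_comp is None else fret_comp,
        }
    )


# ---------------------------------------------------------------------------
# AmFRET / concentration derivation


def test_derive_arithmetic():
    table = pd.DataFrame(
        {
            "FRET_comp": [20.0, 0.0],
            CHANNELS["acceptor"]: [100.0, 50.0],
            CHANNELS["ssc_a"]: [50.0, 10.0],
        }
    )
    out, n_excluded = dk.derive_amfret_and_concentration(table)
    assert n_excluded == 0
    assert out["AmFRET"].tolist() == pytest.approx([0.2, 0.0])
    assert out["concentration"].tolist() == pytest.approx([2.0, 5.0])


def test_derive_excludes_nonpositive_acceptor():
    table = pd.DataFrame(
        {
            "FRET_comp": [1.0, 1.0],
            CHANNELS["acceptor"]: [0.0, 10.0],
            CHANNELS["ssc_a"]: [1.0, 1.0],
        }
    )
    out, n_excluded = dk.derive_amfret_and_concentration(table)
    assert n_excluded == 1 and len(out) == 1
    with pytest.raises(ValueError):
        dk.derive_amfret_and_concentration(table.iloc[:1])


# ---------------------------------------------------------------------------
# negative gate construction


def test_constant_control_gives_constant_gate():
    """Smoothing a constant is the constant; gate = value + shift."""
    rng = np.random.default_rng(0)
    acceptor = 10 ** rng.uniform(6.4, 7.6, 20_000)  # all above the 2e6 floor
    table = make_table(np.full(20_000, 0.1), acceptor)
    gate = dk.build_negative_gate(table)
    valid = gate.valid
    assert valid.sum() > 10
    np.testing.assert_allclose(gate.upper_gate[valid], 0.128, atol=1e-12)


def test_uniform_control_gate_is_99th_percentile():
    rng = np.random.default_rng(1)
    n = 200_000
    acceptor = 10 ** rng.uniform(6.4, 7.6, n)
    table = make_table(rng.uniform(0, 1, n), acceptor)
    gate = dk.build_negative_gate(table)
    assert np.allclose(gate.upper_gate_preshift[gate.valid], 0.99, atol=0.01)


def test_floor_bins_filled_from_nearest_valid():
    """Bins below the 2e6 intensity floor take the nearest valid bin's value:
    a pathological sub-floor population must leave no trace in the gate."""
    rng = np.random.default_rng(2)
    n = 50_000
    acceptor = 10 ** rng.uniform(5.0, 7.5, n)  # spans below and above the floor
    amfret = np.where(acceptor < 2e6, 5.0, 0.1)  # sub-floor bins would gate at 5
    table = make_table(amfret, acceptor)
    gate = dk.build_negative_gate(table)
    assert (~gate.valid).any() and gate.valid.any()
    # constant 0.1 in all valid bins -> fill, smooth and shift give 0.128 everywhere
    np.testing.assert_allclose(gate.upper_gate, 0.128, atol=1e-9)


def test_no_valid_bins_raises():
    table = make_table([0.0, 0.1], [1e5, 1e5])  # both below the floor
    with pytest.raises(ValueError, match="valid bins"):
        dk.build_negative_gate(table)


def test_gate_invariant_to_event_order(negative_table):
    shuffled = negative_table.sample(frac=1.0, random_state=0)
    g1 = dk.build_negative_gate(negative_table)
    g2 = dk.build_negative_gate(shuffled)
    np.testing.assert_array_equal(g1.upper_gate, g2.upper_gate)


# ---------------------------------------------------------------------------
# fraction positive / fgate


def test_fgate_extremes(negative_gate):
    rng = np.random.default_rng(3)
    acceptor = 10 ** rng.uniform(6.4, 7.6, 1000)
    low = make_table(np.full(1000, -0.1), acceptor)
    high = make_table(np.full(1000, 3.0), acceptor)
    assert dk.fraction_positive(low, negative_gate).fgate == 0.0
    assert dk.fraction_positive(high, negative_gate).fgate == 1.0


def test_fgate_identity_weighted_mean(nucleated_table, negative_gate):
    prof = dk.fraction_positive(nucleated_table, negative_gate)
    c = prof.curve
    ok = c.n > 0
    assert prof.fgate == pytest.approx(
        float(np.sum(c.n[ok] * c.fraction[ok]) / np.sum(c.n[ok])), abs=1e-12
    )
    assert 0.0 <= prof.fgate <= 1.0


def test_control_scores_around_one_percent_preshift(negative_table):
    """Against its own pre-shift gate the control sits at ~1% per bin."""
    gate = dk.build_negative_gate(negative_table)
    unshifted = dk.NegativeGateModel(
        params=gate.params,
        bin_edges=gate.bin_edges,
        upper_gate=gate.upper_gate_preshift,
        upper_gate_preshift=gate.upper_gate_preshift,
        raw_percentile=gate.raw_percentile,
        valid=gate.valid,
    )
    prof = dk.fraction_positive(negative_table, unshifted)
    frac = prof.curve.fraction[(prof.curve.n > 2000) & gate.valid]
    assert np.all(np.abs(frac - 0.01) < 0.01)


def test_control_fgate_below_one_percent_postshift(negative_table, negative_gate):
    prof = dk.fraction_positive(negative_table, negative_gate)
    assert prof.fgate <= 0.01


def test_out_of_range_events_counted(negative_gate):
    table = make_table([0.0, 0.0], [1e3, 1e7])  # first below binning range
    prof = dk.fraction_positive(table, negative_gate)
    assert prof.n_out_of_range == 1
    assert prof.curve.n.sum() == 1


# ---------------------------------------------------------------------------
# intermediate fraction


def test_intermediate_fraction_bimodal_is_near_zero(spillover, negative_gate):
    s = dk.simulate_population(
        nucleation=dk.NucleationParams(k=10.0), n_cells=20_000, seed=21,
        intermediate_fraction=0.0,
    )
    table, _, _ = dk.process_events(s.events, spillover)
    f = dk.intermediate_fraction(table, negative_gate)
    assert f is not None and f < 0.02


def test_intermediate_fraction_matches_configured(spillover, negative_gate):
    """Saturating kinetics: essentially every expressing cell nucleates, so
    the configured transitioning share is recovered."""
    frac_cfg, n = 0.10, 30_000
    s = dk.simulate_population(
        nucleation=dk.NucleationParams(k=10.0), n_cells=n, seed=22,
        intermediate_fraction=frac_cfg,
    )
    table, _, _ = dk.process_events(s.events, spillover)
    f = dk.intermediate_fraction(table, negative_gate)
    sd = np.sqrt(frac_cfg * (1 - frac_cfg) / len(table))
    assert f == pytest.approx(frac_cfg, abs=3 * sd + 0.01)


def test_intermediate_fraction_undefined_without_positives(negative_table, negative_gate):
    assert dk.intermediate_fraction(negative_table, negative_gate) is None


# ---------------------------------------------------------------------------
# EC50 fit and spline


def test_ec50_selfconsistent_on_exact_logistic():
    conc = np.logspace(0, 2, 64)
    frac = 1.0 / (1.0 + (10.0 / conc) ** 2)
    n = np.full(64, 10_000)
    curve = BinnedCurve(conc=conc, edges=np.r_[conc, conc[-1] * 1.1], n=n,
                        k=np.round(frac * n).astype(int), fraction=frac)
    ec50, hill, fmax = dk.fit_ec50(curve)
    assert ec50 == pytest.approx(10.0, rel=0.01)
    assert hill == pytest.approx(2.0, rel=0.05)


def test_ec50_flat_curve_raises():
    conc = np.logspace(0, 2, 10)
    curve = BinnedCurve(conc=conc, edges=np.r_[conc, 110.0], n=np.full(10, 100),
                        k=np.zeros(10, int), fraction=np.zeros(10))
    with pytest.raises(FitError):
        dk.fit_ec50(curve)


def test_ec50_on_simulated_population(nucleated_sample, nucleated_table, negative_gate):
    prof = dk.fraction_positive(nucleated_table, negative_gate)
    ec50, hill, fmax = dk.fit_ec50(prof)
    # oracle: truth half-saturation concentration of the analytic model
    params = nucleated_sample.config.nucleation
    c_half = (np.log(2.0) * (params.n + 1) / (params.k * params.pin_factor * 16.0)) ** (1 / params.n)
    conc_scale = dk.OpticsModel().acceptor_per_molecule
    assert ec50 == pytest.approx(c_half * conc_scale * 10**5.9, rel=0.5)


def test_spline_constant_data_gives_constant():
    rng = np.random.default_rng(5)
    table = make_table(np.full(500, 0.3), 10 ** rng.uniform(5, 7, 500))
    out = dk.spline_amfret(table)
    grid, fit = out["all"]
    np.testing.assert_allclose(fit, 0.3, atol=1e-3)


def test_spline_positive_population_lies_above_negative(nucleated_table, negative_gate):
    out = dk.spline_amfret(nucleated_table, gate=negative_gate, split_populations=True)
    gp, fp = out["positive"]
    gn, fn = out["negative"]
    # compare where both populations are well sampled: the interdecile range
    # of the positive population's concentrations (edge extrapolation of a
    # sparse tail is not a population statement)
    pos = negative_gate.is_positive(
        nucleated_table["AmFRET"].to_numpy(), nucleated_table[CHANNELS["acceptor"]].to_numpy()
    )
    x = np.log10(nucleated_table.loc[pos, "concentration"].to_numpy())
    lo, hi = np.quantile(x, [0.1, 0.9])
    grid = np.linspace(max(lo, gp[0], gn[0]), min(hi, gp[-1], gn[-1]), 50)
    assert np.all(np.interp(grid, gp, fp) > np.interp(grid, gn, fn))


def test_spline_stability_under_subsampling(negative_table):
    rng = np.random.default_rng(6)
    table = negative_table.copy()
    # smooth synthetic relationship on real concentration values
    x = np.log10(table["concentration"].to_numpy())
    table["AmFRET"] = 0.2 * np.sin(x) + 0.5 + rng.normal(0, 0.02, len(table))
    full = dk.spline_amfret(table)["all"]
    sub = dk.spline_amfret(table.sample(frac=0.9, random_state=1))["all"]
    grid = np.linspace(max(full[0][0], sub[0][0]), min(full[0][-1], sub[0][-1]), 100)
    diff = np.abs(np.interp(grid, *full) - np.interp(grid, *sub))
    scale = np.abs(np.interp(grid, *full)).max()
    assert diff.max() / scale < 0.05


def test_spline_degenerate_range_raises():
    table = make_table(np.zeros(100), np.full(100, 1e6))
    with pytest.raises(ValueError):
        dk.spline_amfret(table)
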