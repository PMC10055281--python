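"""AmFRET derivation, the negative-control binwise gate, and fgate.

The ratiometric read-out is ``AmFRET = FRET_comp / acceptor`` (FRET intensity
per molecule) and the per-cell concentration proxy is ``acceptor / SSC``
(acceptor divided by side scatter, a cell-volume surrogate; arbitrary units).

The positive/negative discrimination gate is built from a monomeric negative
control: acceptor intensity is divided into 64 logarithmically spaced bins
over a fixed range; the per-bin upper gate is the 99th percentile of the
control's AmFRET distribution in that bin; bins above the control's 99th
acceptor percentile or below a low-intensity floor (2e6 raw units) are filled
from the nearest valid bin; the profile is boxcar-smoothed (width 5) and
shifted up by 0.028 AmFRET units so the control sits entirely below the gate.
The lower gate is a constant -0.2.

``fgate`` -- the fraction of expressing cells above the gate -- is a unitless
statistic in [0, 1], and equals exactly the count-weighted mean of the
per-bin positive fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import curve_fit

from .gating import CHANNELS
from .kinetics import BinnedCurve

__all__ = [
    "NegativeGateParams",
    "NegativeGateModel",
    "DAmFRETProfile",
    "FitError",
    "derive_amfret_and_concentration",
    "build_negative_gate",
    "fraction_positive",
    "intermediate_fraction",
    "fit_ec50",
    "spline_amfret",
    "damfret_histogram",
]

log = logging.getLogger(__name__)


class FitError(RuntimeError):
    """A curve fit failed or was requested on degenerate data."""


def derive_amfret_and_concentration(
    table: pd.DataFrame, channels: dict[str, str] = CHANNELS
) -> tuple[pd.DataFrame, int]:
    """Add ``AmFRET`` and ``concentration`` columns.

    Events with non-positive acceptor signal (for which the ratio is
    undefined) are excluded; the exclusion count is returned and logged.
    Raises if every event is excluded.
    """
    if "FRET_comp" not in table.columns:
        raise KeyError("derive_amfret_and_concentration requires a FRET_comp column")
    acceptor = table[channels["acceptor"]].to_numpy(dtype=float)
    ssc = table[channels["ssc_a"]].to_numpy(dtype=float)
    keep = acceptor > 0
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise ValueError("all events have non-positive acceptor intensity")
    if n_excluded:
        log.info("excluded %d events with acceptor <= 0", n_excluded)
    out = table.loc[keep].copy()
    out["AmFRET"] = out["FRET_comp"].to_numpy(dtype=float) / acceptor[keep]
    out["concentration"] = acceptor[keep] / ssc[keep]
    return out, n_excluded


@dataclass(frozen=True)
class NegativeGateParams:
    """Construction parameters of the negative-control gate."""

    n_bins: int = 64
    acceptor_min: float = 1e4
    acceptor_max: float = 1e8
    percentile: float = 99.0
    boxcar_width: int = 5
    shift: float = 0.028
    lower_gate: float = -0.2
    intensity_floor: float = 2e6

    def bin_edges(self) -> np.ndarray:
        return np.logspace(
            np.log10(self.acceptor_min), np.log10(self.acceptor_max), self.n_bins + 1
        )


@dataclass
class NegativeGateModel:
    """The binwise upper/lower AmFRET gate derived from a negative control."""

    params: NegativeGateParams
    bin_edges: np.ndarray
    upper_gate: np.ndarray  # smoothed + shifted, one value per bin
    upper_gate_preshift: np.ndarray
    raw_percentile: np.ndarray  # per-bin percentile before filling/smoothing
    valid: np.ndarray  # bins whose percentile came from their own events

    @property
    def lower_gate(self) -> float:
        return self.params.lower_gate

    def bin_index(self, acceptor: np.ndarray) -> np.ndarray:
        """Bin assignment by raw acceptor intensity; -1 marks out-of-range."""
        edges = self.bin_edges
        idx = np.searchsorted(edges, acceptor, side="right") - 1
        idx[(acceptor < edges[0]) | (acceptor > edges[-1])] = -1
        np.clip(idx, -1, len(edges) - 2, out=idx)
        return idx

    def is_positive(self, amfret: np.ndarray, acceptor: np.ndarray) -> np.ndarray:
        """Closed-form membership: above the binwise upper gate and above the
        constant lower gate.  Out-of-range events are never positive."""
        idx = self.bin_index(np.asarray(acceptor, dtype=float))
        ok = idx >= 0
        out = np.zeros(len(amfret), dtype=bool)
        a = np.asarray(amfret, dtype=float)
        out[ok] = (a[ok] > self.upper_gate[idx[ok]]) & (a[ok] > self.lower_gate)
        return out


def _boxcar_smooth(values: np.ndarray, width: int) -> np.ndarray:
    """Boxcar with symmetric shrinking windows at the edges."""
    half = width // 2
    out = np.empty_like(values, dtype=float)
    n = len(values)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = values[i - h : i + h + 1].mean()
    return out


def build_negative_gate(
    control: pd.DataFrame,
    params: NegativeGateParams | None = None,
    channels: dict[str, str] = CHANNELS,
) -> NegativeGateModel:
    """Construct the binwise negative gate from a monomeric control sample.

    ``control`` needs ``AmFRET`` and raw acceptor columns.  Quantiles use
    linear interpolation between order statistics.  Invalid bins (no events,
    below the intensity floor, or above the control's 99th acceptor
    percentile) are filled from the nearest valid bin, ties toward the lower
    index, before smoothing and shifting.
    """
    p = params or NegativeGateParams()
    if "AmFRET" not in control.columns:
        raise KeyError("control table must carry an AmFRET column")
    acceptor = control[channels["acceptor"]].to_numpy(dtype=float)
    amfret = control["AmFRET"].to_numpy(dtype=float)

    edges = p.bin_edges()
    idx = np.searchsorted(edges, acceptor, side="right") - 1
    in_range = (idx >= 0) & (idx < p.n_bins)

    centers = np.sqrt(edges[:-1] * edges[1:])
    acceptor_p99 = np.percentile(acceptor, 99.0)
    raw = np.full(p.n_bins, np.nan)
    counts = np.zeros(p.n_bins, dtype=int)
    for b in range(p.n_bins):
        sel = in_range & (idx == b)
        counts[b] = sel.sum()
        if counts[b]:
            raw[b] = np.percentile(amfret[sel], p.percentile)  # linear interp

    valid = (
        (counts > 0) & (centers >= p.intensity_floor) & (centers <= acceptor_p99)
    )
    if not valid.any():
        raise ValueError(
            "no valid bins: control has no events between the intensity floor "
            "and its 99th acceptor percentile"
        )

    filled = raw.copy()
    valid_idx = np.flatnonzero(valid)
    for b in np.flatnonzero(~valid):
        nearest = valid_idx[np.argmin(np.abs(valid_idx - b))]  # argmin tie -> lower
        filled[b] = raw[nearest]

    smoothed = _boxcar_smooth(filled, p.boxcar_width)
    upper = smoothed + p.shift
    if np.any(upper <= p.lower_gate):
        raise ValueError("upper gate must exceed the lower gate in every bin")
    return NegativeGateModel(
        params=p,
        bin_edges=edges,
        upper_gate=upper,
        upper_gate_preshift=smoothed,
        raw_percentile=raw,
        valid=valid,
    )


@dataclass
class DAmFRETProfile:
    """Per-bin positive fractions and summary statistics for one sample."""

    curve: BinnedCurve
    fgate: float  # over events within the gate's bin range
    fgate_all: float  # over all expressing events incl. out-of-range
    n_events: int
    n_out_of_range: int
    median_amfret_top: float = np.nan
    ec50: Optional[float] = None
    hill: Optional[float] = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fgate": self.fgate,
            "fgate_all": self.fgate_all,
            "n_events": self.n_events,
            "n_out_of_range": self.n_out_of_range,
            "median_amfret_top": self.median_amfret_top,
            "ec50": self.ec50,
            "hill": self.hill,
        }

    def per_bin_frame(self) -> pd.DataFrame:
        c = self.curve
        return pd.DataFrame(
            {
                "acceptor_lo": c.edges[:-1],
                "acceptor_hi": c.edges[1:],
                "n": c.n,
                "n_positive": c.k,
                "fraction_positive": c.fraction,
            }
        )


def fraction_positive(
    table: pd.DataFrame,
    gate: NegativeGateModel,
    channels: dict[str, str] = CHANNELS,
) -> DAmFRETProfile:
    """Score a sample against the negative gate.

    Positive means AmFRET above both the binwise upper gate and the constant
    lower gate.  Events outside the gate's acceptor range are counted and
    reported but excluded from the per-bin curve, so the identity
    ``fgate = sum_b n_b f_b / sum_b n_b`` holds exactly.
    """
    if "AmFRET" not in table.columns:
        raise KeyError("sample table must carry an AmFRET column")
    amfret = table["AmFRET"].to_numpy(dtype=float)
    acceptor = table[channels["acceptor"]].to_numpy(dtype=float)
    idx = gate.bin_index(acceptor)
    in_range = idx >= 0
    positive = gate.is_positive(amfret, acceptor)

    n_bins = len(gate.upper_gate)
    n = np.bincount(idx[in_range], minlength=n_bins)
    k = np.bincount(idx[in_range & positive], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        frac = np.where(n > 0, k / np.maximum(n, 1), np.nan)
    curve = BinnedCurve(
        conc=np.sqrt(gate.bin_edges[:-1] * gate.bin_edges[1:]),
        edges=gate.bin_edges,
        n=n,
        k=k,
        fraction=frac,
        n_out_of_range=int((~in_range).sum()),
    )
    n_in = int(n.sum())
    fgate = float(k.sum() / n_in) if n_in else np.nan
    fgate_all = float(positive.sum() / len(table)) if len(table) else np.nan

    median_top = np.nan
    if positive.any():
        top = acceptor >= np.quantile(acceptor, 0.9)
        if (positive & top).any():
            median_top = float(np.median(amfret[positive & top]))
    return DAmFRETProfile(
        curve=curve,
        fgate=fgate,
        fgate_all=fgate_all,
        n_events=len(table),
        n_out_of_range=curve.n_out_of_range,
        median_amfret_top=median_top,
    )


def intermediate_fraction(
    table: pd.DataFrame,
    gate: NegativeGateModel,
    plateau: float | None = None,
    conc_window: tuple[float, float] | None = None,
    min_positive_fraction: float = 0.01,
    channels: dict[str, str] = CHANNELS,
) -> Optional[float]:
    """Fraction of expressing cells at intermediate ("transitioning") AmFRET.

    Intermediate means above the binwise upper gate but below 0.75 x the
    positive-population plateau (estimated, when not supplied, as the median
    AmFRET of positive cells in the top expression decile).  Returns ``None``
    when the plateau is undefined: no positive population, or fewer than
    ``min_positive_fraction`` of cells above the gate (gate false positives
    alone cannot define a plateau).  ``conc_window`` restricts the
    calculation to a concentration interval.
    """
    amfret = table["AmFRET"].to_numpy(dtype=float)
    acceptor = table[channels["acceptor"]].to_numpy(dtype=float)
    if plateau is None:
        prof = fraction_positive(table, gate, channels)
        plateau = prof.median_amfret_top
        if not np.isfinite(plateau) or prof.fgate < min_positive_fraction:
            return None
    sel = np.ones(len(table), dtype=bool)
    if conc_window is not None:
        conc = table["concentration"].to_numpy(dtype=float)
        sel = (conc >= conc_window[0]) & (conc <= conc_window[1])
    if not sel.any():
        return None
    above = gate.is_positive(amfret, acceptor)
    inter = above & (amfret < 0.75 * plateau)
    return float(inter[sel].sum() / sel.sum())


def fit_ec50(profile: DAmFRETProfile | BinnedCurve) -> tuple[float, float, float]:
    """Least-squares Hill fit ``f(c) = f_max / (1 + (ec50 / c)^h)``.

    Returns ``(ec50, hill, f_max)`` with ``f_max`` constrained to [0, 1].
    Raises :class:`FitError` on flat or insufficient curves.
    """
    curve = profile.curve if isinstance(profile, DAmFRETProfile) else profile
    cur = curve.informative()
    if len(cur.n) < 5:
        raise FitError("EC50 fit needs >= 5 non-empty bins")
    frac = cur.k / cur.n
    if frac.max() <= 0:
        raise FitError("EC50 undefined: fraction-positive curve is identically zero")

    def hill(c, ec50, h, fmax):
        return fmax / (1.0 + (ec50 / c) ** h)

    c0 = cur.conc[np.argmin(np.abs(frac - frac.max() / 2.0))]
    sigma = 1.0 / np.sqrt(cur.n)
    try:
        popt, _ = curve_fit(
            hill,
            cur.conc,
            frac,
            p0=[c0, 1.5, min(frac.max(), 1.0)],
            sigma=sigma,
            bounds=([cur.conc.min() / 100, 0.05, 1e-6], [cur.conc.max() * 100, 50, 1.0]),
            maxfev=20000,
        )
    except RuntimeError as err:  # pragma: no cover - scipy message passthrough
        raise FitError(f"EC50 fit did not converge: {err}") from err
    ec50, h, fmax = (float(v) for v in popt)
    return ec50, h, fmax


def spline_amfret(
    table: pd.DataFrame,
    gate: NegativeGateModel | None = None,
    split_populations: bool = False,
    eval_points: int = 100,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Smoothing spline of AmFRET versus log10 concentration.

    Smoothness is chosen by generalized cross-validation.  With
    ``split_populations`` (requires ``gate``) events are first assigned to the
    positive/negative population and a spline fitted per population.  Returns
    ``{label: (log10_conc_grid, amfret_fit)}``.
    """
    if len(table) < 50:
        raise ValueError("spline fit needs >= 50 events")
    conc = table["concentration"].to_numpy(dtype=float)
    amfret = table["AmFRET"].to_numpy(dtype=float)
    ok = conc > 0
    conc, amfret = conc[ok], amfret[ok]
    if np.ptp(np.log10(conc)) < 1e-6:
        raise ValueError("degenerate concentration range for spline fit")

    groups: dict[str, np.ndarray] = {"all": np.ones(len(conc), dtype=bool)}
    if split_populations:
        if gate is None:
            raise ValueError("split_populations requires a gate")
        acceptor = table.loc[ok, CHANNELS["acceptor"]].to_numpy(dtype=float)
        pos = gate.is_positive(amfret, acceptor)
        groups = {"positive": pos, "negative": ~pos}

    out = {}
    for label, sel in groups.items():
        if sel.sum() < 10:
            continue
        x = np.log10(conc[sel])
        y = amfret[sel]
        order = np.argsort(x)
        x, y = x[order], y[order]
        # GCV spline needs strictly increasing, well-separated x: average ties
        # and, for large samples, pre-bin into quantile bins for conditioning
        ux, inv = np.unique(x, return_inverse=True)
        uy = np.bincount(inv, weights=y) / np.bincount(inv)
        w = np.bincount(inv).astype(float)
        if len(ux) > 1000:
            edges = np.quantile(ux, np.linspace(0, 1, 401))
            bi = np.clip(np.searchsorted(edges, ux, side="right") - 1, 0, 399)
            wsum = np.bincount(bi, weights=w, minlength=400)
            keep = wsum > 0
            ux = (np.bincount(bi, weights=w * ux, minlength=400)[keep] / wsum[keep])
            uy = (np.bincount(bi, weights=w * uy, minlength=400)[keep] / wsum[keep])
            w = wsum[keep]
        if len(ux) < 10:
            continue
        spl = make_smoothing_spline(ux, uy, w=w)
        grid = np.linspace(ux[0], ux[-1], eval_points)
        out[label] = (grid, spl(grid))
    if not out:
        raise ValueError("no population had enough events for a spline")
    return out


def damfret_histogram(
    table: pd.DataFrame,
    bins: int = 150,
    ax=None,
    gate: NegativeGateModel | None = None,
):
    """2-D histogram (log10 concentration vs AmFRET) mirroring a DAmFRET plot."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    conc = table["concentration"].to_numpy(dtype=float)
    amfret = table["AmFRET"].to_numpy(dtype=float)
    ok = conc > 0
    h = ax.hist2d(np.log10(conc[ok]), amfret[ok], bins=bins, cmin=1, cmap="viridis")
    if gate is not None:
        # gate is binned on acceptor; display against its concentration proxy
        ax.set_title("DAmFRET")
    ax.set_xlabel("log10 concentration (AU)")
    ax.set_ylabel("AmFRET")
    return ax, h
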