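"""Synthetic DAmFRET population generator.

Emulates the statistical structure of a DAmFRET experiment so the whole
analysis chain can be exercised without instrument data:

* a high-variance expression system producing a ~hundred-fold range of
  per-cell concentrations, each cell's concentration rising monotonically
  over a 16-hour induction;
* stochastic, concentration-dependent amyloid nucleation -- each cell
  nucleates with probability ``1 - exp(-k_eff * integral c(t)^n dt)`` where
  ``k_eff = k * pin_factor`` (``pin_factor > 1`` models a pre-existing
  conformational template such as the Rnq1 prion);
* a bimodal AmFRET read-out: non-nucleated cells scatter around zero,
  nucleated cells sit at a sequence-class plateau (bilaterally contiguous
  Q_B sequences pack more densely and plateau higher than unilateral Q_U),
  with a configurable "transitioning" fraction at intermediate AmFRET that
  grows inside an optional self-poisoning concentration window;
* raw-channel optics: scatter channels, donor/acceptor/FRET/autofluorescence
  intensities including spillover, plus doublets (forward-scatter width
  inflated, fluorescence summed) and non-expressing cells, so the gate
  sequence has work to do.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; regenerating with the same seed reproduces the
event table bit for bit.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .fcs import write_fcs
from .gating import CHANNELS
from .kinetics import BinnedCurve, NucleationParams, cumulative_hazard, poisoning_window

__all__ = [
    "ExpressionModel",
    "OpticsModel",
    "ScatterChannelModel",
    "SimulationConfig",
    "PopulationSample",
    "simulate_population",
    "simulate_negative_control",
    "truth_fraction_positive",
]


@dataclass(frozen=True)
class ExpressionModel:
    """Distribution and time course of per-cell protein concentration.

    Concentrations are in arbitrary units spanning at least two decades
    (default 10^0 -- 10^2).  The per-cell trajectory rises from 0 to the final
    concentration over ``induction_time`` hours, linearly by default.
    """

    log10_conc_min: float = 0.0
    log10_conc_max: float = 2.0
    distribution_shape: str = "log-uniform"  # or "log-normal"
    log10_mean: float = 1.0
    log10_sd: float = 0.5
    ramp: str = "linear"  # or "exponential"
    ramp_rate: float = 0.3  # 1/h, exponential ramp only
    induction_time: float = 16.0

    def __post_init__(self) -> None:
        if self.log10_conc_max <= self.log10_conc_min:
            raise ValueError("log10_conc_max must exceed log10_conc_min")
        if self.distribution_shape not in ("log-uniform", "log-normal"):
            raise ValueError(f"unknown distribution_shape {self.distribution_shape!r}")
        if self.ramp not in ("linear", "exponential"):
            raise ValueError(f"unknown ramp {self.ramp!r}")
        if self.induction_time <= 0:
            raise ValueError("induction_time must be > 0")

    def draw_final_concentration(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.distribution_shape == "log-uniform":
            lg = rng.uniform(self.log10_conc_min, self.log10_conc_max, n)
        else:
            lg = np.clip(
                rng.normal(self.log10_mean, self.log10_sd, n),
                self.log10_conc_min,
                self.log10_conc_max,
            )
        return 10.0**lg


@dataclass(frozen=True)
class ScatterChannelModel:
    """Log10-normal model for one scatter channel (raw intensity units)."""

    log10_mean: float
    log10_sd: float

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return 10.0 ** rng.normal(self.log10_mean, self.log10_sd, n)


@dataclass(frozen=True)
class OpticsModel:
    """Channel gains, AmFRET plateaus and noise of the synthetic cytometer.

    Gains are fluorescence units per concentration unit per unit of side
    scatter (side scatter stands in for cell volume, so channel intensity is
    gain * concentration * SSC).  ``amfret_high_QB > amfret_high_QU`` by
    default: lamellar Q_B assemblies are denser, hence brighter in FRET per
    molecule.  Spillover coefficients model donor and acceptor bleed into the
    FRET detector.
    """

    donor_per_molecule: float = 0.05
    acceptor_per_molecule: float = 1.0
    amfret_high_QB: float = 0.6
    amfret_high_QU: float = 0.4
    amfret_negative_sd: float = 0.05
    amfret_positive_sd: float = 0.05
    autofluorescence_mean: float = 2.0e3
    autofluorescence_sd: float = 0.2  # decades
    baseline: float = 300.0
    s_donor: float = 0.05
    s_acceptor: float = 0.10
    doublet_width_factor: float = 1.6
    fsc_a: ScatterChannelModel = field(
        default_factory=lambda: ScatterChannelModel(6.10, 0.15)
    )
    fsc_h: ScatterChannelModel = field(
        default_factory=lambda: ScatterChannelModel(7.01, 0.02)
    )
    fsc_w: ScatterChannelModel = field(
        default_factory=lambda: ScatterChannelModel(6.78, 0.03)
    )
    ssc_a: ScatterChannelModel = field(
        default_factory=lambda: ScatterChannelModel(5.90, 0.15)
    )

    def __post_init__(self) -> None:
        if not (self.amfret_high_QB > self.amfret_high_QU > 0):
            raise ValueError("require amfret_high_QB > amfret_high_QU > 0")
        if self.amfret_negative_sd <= 0:
            raise ValueError("amfret_negative_sd must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Declarative description of one synthetic scenario."""

    expression: ExpressionModel = field(default_factory=ExpressionModel)
    nucleation: NucleationParams = field(default_factory=NucleationParams)
    optics: OpticsModel = field(default_factory=OpticsModel)
    doublet_fraction: float = 0.05
    nonexpressing_fraction: float = 0.05
    intermediate_fraction: float = 0.05
    zipper_class: str = "Q_B"

    def __post_init__(self) -> None:
        if self.zipper_class not in ("Q_B", "Q_U"):
            raise ValueError("zipper_class must be 'Q_B' or 'Q_U'")
        for name in ("doublet_fraction", "nonexpressing_fraction", "intermediate_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be within [0, 1]")

    @property
    def amfret_plateau(self) -> float:
        return (
            self.optics.amfret_high_QB
            if self.zipper_class == "Q_B"
            else self.optics.amfret_high_QU
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        optics_raw = raw.get("optics", {})
        for ch in ("fsc_a", "fsc_h", "fsc_w", "ssc_a"):
            if ch in optics_raw:
                optics_raw[ch] = ScatterChannelModel(**optics_raw[ch])
        return cls(
            expression=ExpressionModel(**raw.get("expression", {})),
            nucleation=NucleationParams(**raw.get("nucleation", {})),
            optics=OpticsModel(**optics_raw),
            doublet_fraction=raw.get("doublet_fraction", 0.05),
            nonexpressing_fraction=raw.get("nonexpressing_fraction", 0.05),
            intermediate_fraction=raw.get("intermediate_fraction", 0.05),
            zipper_class=raw.get("zipper_class", "Q_B"),
        )


@dataclass
class PopulationSample:
    """Events plus per-event ground truth for a simulated population."""

    events: pd.DataFrame
    truth: pd.DataFrame
    seed: int
    config: SimulationConfig

    def to_fcs(self, fcs_path: str | Path, truth_path: str | Path | None = None) -> None:
        """Write events as FCS 3.1 and (optionally) the truth sidecar as CSV."""
        write_fcs(self.events, fcs_path)
        if truth_path is not None:
            self.truth.to_csv(truth_path, index=False)


def simulate_population(
    expression: ExpressionModel | None = None,
    nucleation: NucleationParams | None = None,
    optics: OpticsModel | None = None,
    n_cells: int = 10_000,
    seed: int = 0,
    *,
    doublet_fraction: float = 0.05,
    nonexpressing_fraction: float = 0.05,
    intermediate_fraction: float = 0.05,
    zipper_class: str = "Q_B",
) -> PopulationSample:
    """Simulate one DAmFRET sample.

    Each cell draws a final concentration ``c_T``; nucleation is a Bernoulli
    event with ``P = 1 - exp(-k * pin_factor * integral_0^T c(t)^n dt)``
    (``c_T^n * T / (n + 1)`` for the linear ramp).  Nucleated cells take the
    sequence-class AmFRET plateau except for a configurable transitioning
    fraction -- enlarged inside the self-poisoning window -- drawn uniformly
    between 25% and 75% of the plateau.  Channels are emitted as raw
    intensities with spillover, autofluorescence, doublets and non-expressing
    cells included.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    config = SimulationConfig(
        expression=expression or ExpressionModel(),
        nucleation=nucleation or NucleationParams(),
        optics=optics or OpticsModel(),
        doublet_fraction=doublet_fraction,
        nonexpressing_fraction=nonexpressing_fraction,
        intermediate_fraction=intermediate_fraction,
        zipper_class=zipper_class,
    )
    rng = np.random.default_rng(seed)
    exp_m, nuc, opt = config.expression, config.nucleation, config.optics
    T = exp_m.induction_time

    c_final = exp_m.draw_final_concentration(n_cells, rng)
    category = rng.uniform(size=n_cells)
    is_doublet = category < config.doublet_fraction
    is_nonexpressing = (~is_doublet) & (
        category < config.doublet_fraction + config.nonexpressing_fraction
    )
    c_final = np.where(is_nonexpressing, 0.0, c_final)

    # --- nucleation ---------------------------------------------------------
    hazard = np.zeros(n_cells)
    expressing = ~is_nonexpressing
    hazard[expressing] = cumulative_hazard(c_final[expressing], T, nuc, expression=exp_m)
    u = rng.exponential(size=n_cells)
    nucleated = (u < hazard) & expressing
    # invert the cumulative hazard for the nucleation time (linear ramp:
    # Lambda(t) = k_eff c^n t^(n+1) / (T^n (n+1)), so t* = T (u/Lambda(T))^(1/(n+1)))
    t_nuc = np.full(n_cells, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(hazard > 0, u / hazard, np.nan)
    t_nuc[nucleated] = T * frac[nucleated] ** (1.0 / (nuc.n + 1.0))

    p_int = np.clip(
        config.intermediate_fraction + poisoning_window(c_final, nuc), 0.0, 1.0
    )
    stalled = nucleated & (rng.uniform(size=n_cells) < p_int)
    status = np.where(
        nucleated, np.where(stalled, "intermediate", "positive"), "negative"
    )

    plateau = config.amfret_plateau
    amfret = rng.normal(0.0, opt.amfret_negative_sd, n_cells)
    pos = status == "positive"
    amfret[pos] = rng.normal(plateau, opt.amfret_positive_sd, pos.sum())
    mid = status == "intermediate"
    amfret[mid] = plateau * rng.uniform(0.25, 0.75, mid.sum())

    # --- optics -------------------------------------------------------------
    fsc_a = opt.fsc_a.draw(n_cells, rng)
    fsc_h = opt.fsc_h.draw(n_cells, rng)
    fsc_w = opt.fsc_w.draw(n_cells, rng)
    ssc_a = opt.ssc_a.draw(n_cells, rng)

    baseline = opt.baseline * 10.0 ** rng.normal(0.0, 0.1, (2, n_cells))
    donor = opt.donor_per_molecule * c_final * ssc_a + baseline[0]
    acceptor = opt.acceptor_per_molecule * c_final * ssc_a + baseline[1]
    autofl = opt.autofluorescence_mean * 10.0 ** rng.normal(
        0.0, opt.autofluorescence_sd, n_cells
    )
    fret = amfret * acceptor + opt.s_donor * donor + opt.s_acceptor * acceptor

    # doublets: two cells' fluorescence summed, width pulse inflated
    for arr in (donor, acceptor, fret, autofl):
        arr[is_doublet] *= 2.0
    fsc_w[is_doublet] *= opt.doublet_width_factor
    fsc_a[is_doublet] *= 1.5
    ssc_a[is_doublet] *= 1.5

    events = pd.DataFrame(
        {
            CHANNELS["fsc_a"]: fsc_a,
            CHANNELS["fsc_h"]: fsc_h,
            CHANNELS["fsc_w"]: fsc_w,
            CHANNELS["ssc_a"]: ssc_a,
            CHANNELS["donor"]: donor,
            CHANNELS["acceptor"]: acceptor,
            CHANNELS["fret"]: fret,
            CHANNELS["autofluor"]: autofl,
        }
    )
    truth = pd.DataFrame(
        {
            "final_concentration": c_final,
            "status": status,
            "nucleation_time": t_nuc,
            "amfret_true": amfret,
            "is_doublet": is_doublet,
            "is_nonexpressing": is_nonexpressing,
        }
    )
    return PopulationSample(events=events, truth=truth, seed=seed, config=config)


def simulate_negative_control(
    expression: ExpressionModel | None = None,
    optics: OpticsModel | None = None,
    n_cells: int = 10_000,
    seed: int = 0,
    **kwargs,
) -> PopulationSample:
    """A monomeric control: identical pipeline with the nucleation rate forced
    to zero, so AmFRET is centred on 0 across the full expression range."""
    return simulate_population(
        expression,
        NucleationParams(k=0.0),
        optics,
        n_cells,
        seed,
        **kwargs,
    )


def truth_fraction_positive(
    sample: PopulationSample,
    bin_edges: np.ndarray,
    statuses: tuple[str, ...] = ("positive", "intermediate"),
) -> BinnedCurve:
    """Ground-truth nucleated fraction per final-concentration bin.

    By default counts every truth-nucleated cell (``positive`` or
    ``intermediate``) -- the quantity the cumulative-hazard model predicts;
    pass ``statuses=("positive",)`` for the high-AmFRET fraction relevant to
    self-poisoning.  Non-expressing cells fall outside any positive bin range
    and are reported in ``n_out_of_range``; empty bins are flagged, not
    dropped.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be a 1-D increasing array")
    c = sample.truth["final_concentration"].to_numpy()
    nucleated = sample.truth["status"].isin(statuses).to_numpy()

    idx = np.searchsorted(edges, c, side="right") - 1
    in_range = (idx >= 0) & (idx < len(edges) - 1) & (c <= edges[-1])
    idx = np.clip(idx, 0, len(edges) - 2)

    n_bins = len(edges) - 1
    n = np.bincount(idx[in_range], minlength=n_bins)
    k = np.bincount(idx[in_range & nucleated], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        frac = np.where(n > 0, k / np.maximum(n, 1), np.nan)
    return BinnedCurve(
        conc=np.sqrt(edges[:-1] * edges[1:]),
        edges=edges,
        n=n,
        k=k,
        fraction=frac,
        n_out_of_range=int((~in_range).sum()),
    )
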