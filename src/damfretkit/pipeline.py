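"""Convenience wrapper chaining gating, compensation and AmFRET derivation."""

from __future__ import annotations

import pandas as pd

from .gating import CHANNELS, GateSet, GatingReport, SpilloverModel, apply_gate_sequence, compensate
from .logicle import LogicleParams
from .quant import derive_amfret_and_concentration

__all__ = ["process_events"]


def process_events(
    events: pd.DataFrame,
    spillover: SpilloverModel,
    gates: GateSet | None = None,
    logicle_params: LogicleParams | None = None,
    channels: dict[str, str] = CHANNELS,
) -> tuple[pd.DataFrame, GatingReport, int]:
    """Gate raw events, compensate FRET, and derive AmFRET / concentration.

    Returns the expressing-singlet table (with ``AmFRET`` and
    ``concentration`` columns), the gating report, and the count of events
    dropped for non-positive acceptor signal.
    """
    gated, report = apply_gate_sequence(events, gates, logicle_params, channels)
    comp = compensate(gated, spillover, channels)
    table, n_excluded = derive_amfret_and_concentration(comp, channels)
    return table, report, n_excluded
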