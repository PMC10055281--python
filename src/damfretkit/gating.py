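"""Spillover compensation and the three-step DAmFRET gate sequence.

Events arrive as raw-intensity DataFrames (one column per channel).  The
pipeline logicle-transforms the scatter and reference-fluorescence channels,
then gates sequentially:

1. *cells* -- rectangle on transformed (FS00.A, SS02.A),
2. *singlets* -- rectangle on transformed (FS00.H, FS00.W),
3. *expressing* -- polygon on transformed (FL03.A donor, FL17.A
   autofluorescence).

All gates are closed: events exactly on an edge are kept.  The FRET channel is
compensated only in the direction of donor and acceptor signal spilling *into*
the FRET detector, since no pure-FRET control exists:
``FRET_comp = FRET - s_donor * donor - s_acceptor * acceptor``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .logicle import LogicleParams, LogicleTransform

__all__ = [
    "CHANNELS",
    "SpilloverModel",
    "RectGate",
    "PolyGate",
    "GateSet",
    "GatingReport",
    "compensate",
    "fit_spillover",
    "transform_channels",
    "apply_gate_sequence",
]

log = logging.getLogger(__name__)

#: default channel roles -> detector names (Bio-Rad ZE5 layout)
CHANNELS = {
    "fsc_a": "FS00.A",
    "fsc_h": "FS00.H",
    "fsc_w": "FS00.W",
    "ssc_a": "SS02.A",
    "donor": "FL03.A",
    "acceptor": "FL09.A",
    "fret": "FL10.A",
    "autofluor": "FL17.A",
}

TRANSFORM_SUFFIX = "_lgcl"


@dataclass(frozen=True)
class SpilloverModel:
    """Fractions of donor and acceptor signal appearing in the FRET channel."""

    s_donor: float = 0.0
    s_acceptor: float = 0.0

    def __post_init__(self) -> None:
        for name, s in (("s_donor", self.s_donor), ("s_acceptor", self.s_acceptor)):
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"{name} must be within [0, 1], got {s}")


@dataclass(frozen=True)
class RectGate:
    """Closed rectangular gate on two (transformed) channels."""

    x_channel: str
    y_channel: str
    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError("rectangle bounds must satisfy min < max")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (
            (x >= self.xmin) & (x <= self.xmax) & (y >= self.ymin) & (y <= self.ymax)
        )


@dataclass(frozen=True)
class PolyGate:
    """Closed simple-polygon gate on two (transformed) channels."""

    x_channel: str
    y_channel: str
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        if _self_intersects(self.vertices):
            raise ValueError("polygon gate must be simple (non-self-intersecting)")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return _points_in_polygon(x, y, np.asarray(self.vertices, dtype=float))


def _segments_cross(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1, d2 = orient(p3, p4, p1), orient(p3, p4, p2)
    d3, d4 = orient(p1, p2, p3), orient(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def _self_intersects(vertices) -> bool:
    n = len(vertices)
    edges = [(vertices[i], vertices[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 or (i == 0 and j == n - 1):
                continue  # adjacent edges share a vertex
            if _segments_cross(*edges[i], *edges[j]):
                return True
    return False


def _points_in_polygon(x: np.ndarray, y: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Even-odd rule with boundary points counted inside."""
    n = len(verts)
    inside = np.zeros(x.shape, dtype=bool)
    on_edge = np.zeros(x.shape, dtype=bool)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        # boundary test: collinear and within the bounding box of the edge
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        within = (
            (np.isclose(cross, 0.0, atol=1e-12))
            & (x >= min(x1, x2) - 1e-12)
            & (x <= max(x1, x2) + 1e-12)
            & (y >= min(y1, y2) - 1e-12)
            & (y <= max(y1, y2) + 1e-12)
        )
        on_edge |= within
        # ray casting (horizontal ray to +inf); horizontal edges never cross
        with np.errstate(divide="ignore", invalid="ignore"):
            crosses = ((y1 > y) != (y2 > y)) & (
                x < (x2 - x1) * (y - y1) / (y2 - y1) + x1
            )
        inside ^= crosses
    return inside | on_edge


def default_gate_set() -> "GateSet":
    """The standard three-gate DAmFRET sequence on logicle display coordinates."""
    return GateSet(
        cells_gate=RectGate(CHANNELS["fsc_a"], CHANNELS["ssc_a"], 2.7, 4.8, 2.7, 4.7),
        singlet_gate=RectGate(CHANNELS["fsc_h"], CHANNELS["fsc_w"], 4.45, 4.58, 2.5, 4.4),
        expressing_gate=PolyGate(
            CHANNELS["donor"],
            CHANNELS["autofluor"],
            ((1.0, 0.1), (1.8, 2.0), (5.0, 2.0), (5.0, 0.1)),
        ),
    )


@dataclass(frozen=True)
class GateSet:
    cells_gate: RectGate = field(default_factory=lambda: default_gate_set().cells_gate)
    singlet_gate: RectGate = field(default_factory=lambda: default_gate_set().singlet_gate)
    expressing_gate: PolyGate = field(
        default_factory=lambda: default_gate_set().expressing_gate
    )

    def stages(self):
        return (
            ("cells", self.cells_gate),
            ("singlets", self.singlet_gate),
            ("expressing", self.expressing_gate),
        )


@dataclass
class GatingReport:
    """Per-stage surviving event counts."""

    n_input: int
    stage_counts: dict[str, int]

    def to_dict(self) -> dict:
        return {"n_input": self.n_input, "stage_counts": dict(self.stage_counts)}


def compensate(
    table: pd.DataFrame,
    spillover: SpilloverModel,
    channels: dict[str, str] = CHANNELS,
) -> pd.DataFrame:
    """Add a ``FRET_comp`` column; negative values are retained, not clipped."""
    for role in ("donor", "acceptor", "fret"):
        col = channels[role]
        if col not in table.columns:
            raise KeyError(f"compensation requires column {col!r} ({role})")
    out = table.copy()
    out["FRET_comp"] = (
        table[channels["fret"]].to_numpy(dtype=float)
        - spillover.s_donor * table[channels["donor"]].to_numpy(dtype=float)
        - spillover.s_acceptor * table[channels["acceptor"]].to_numpy(dtype=float)
    )
    return out


def fit_spillover(
    donor_control: pd.DataFrame,
    acceptor_control: pd.DataFrame,
    channels: dict[str, str] = CHANNELS,
) -> SpilloverModel:
    """Least-squares spillover coefficients from single-color controls.

    Each control expresses only one fluorophore, so its FRET-channel signal is
    pure spillover: the slope of FRET on donor (resp. acceptor) through the
    origin estimates the coefficient.
    """

    def slope(tbl: pd.DataFrame, src: str) -> float:
        x = tbl[channels[src]].to_numpy(dtype=float)
        y = tbl[channels["fret"]].to_numpy(dtype=float)
        denom = float(np.dot(x, x))
        if denom == 0.0:
            return 0.0
        return float(np.clip(np.dot(x, y) / denom, 0.0, 1.0))

    return SpilloverModel(
        s_donor=slope(donor_control, "donor"),
        s_acceptor=slope(acceptor_control, "acceptor"),
    )


def transform_channels(
    table: pd.DataFrame,
    columns: list[str],
    params: LogicleParams | None = None,
) -> pd.DataFrame:
    """Append logicle display columns (``<name>_lgcl``) for ``columns``."""
    t = LogicleTransform(params)
    out = table.copy()
    for col in columns:
        if col not in table.columns:
            raise KeyError(f"cannot transform missing column {col!r}")
        out[col + TRANSFORM_SUFFIX] = t(table[col].to_numpy(dtype=float))
    return out


def apply_gate_sequence(
    table: pd.DataFrame,
    gates: GateSet | None = None,
    params: LogicleParams | None = None,
    channels: dict[str, str] = CHANNELS,
) -> tuple[pd.DataFrame, GatingReport]:
    """Run the cells -> singlets -> expressing gate sequence.

    Transformed columns are added if absent.  Surviving events keep their
    original order and index.  Returns the expressing singlet cells plus a
    per-stage count report; an empty stage emits a warning naming the stage.
    """
    gates = gates or GateSet()
    needed = sorted(
        {g.x_channel for _, g in gates.stages()} | {g.y_channel for _, g in gates.stages()}
    )
    missing = [c for c in needed if c + TRANSFORM_SUFFIX not in table.columns]
    current = transform_channels(table, missing, params) if missing else table

    counts: dict[str, int] = {}
    for stage_name, gate in gates.stages():
        x = current[gate.x_channel + TRANSFORM_SUFFIX].to_numpy(dtype=float)
        y = current[gate.y_channel + TRANSFORM_SUFFIX].to_numpy(dtype=float)
        keep = gate.contains(x, y)
        current = current.loc[keep]
        counts[stage_name] = int(keep.sum())
        log.info("gate %-10s kept %d events", stage_name, counts[stage_name])
        if counts[stage_name] == 0:
            warnings.warn(
                f"gate stage {stage_name!r} removed all events", stacklevel=2
            )
            break
    return current, GatingReport(n_input=len(table), stage_counts=counts)
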