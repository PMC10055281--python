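"""Glutamine-zipper sequence rules.

Polyglutamine amyloid nucleates through a steric "Q zipper": two antiparallel
beta-sheets whose glutamine side chains fully interdigitate.  Because side
chains alternate by 180 degrees along a beta-strand, a strand face is built
from residues at every *other* position (i, i+2, i+4, ...).  Two sequence
properties therefore control whether a sequence can nucleate a zipper de novo:

* **unilateral contiguity** (``uni``) -- the longest uninterrupted run of Q at
  alternating positions within one parity frame; a single long zipper needs at
  least five such glutamines (a strand of nine or ten residues).
* **bilateral contiguity** (``bi``) -- the longest literal run of consecutive
  Q; lamellar (multi-sheet) zippers need at least six.

Sequences meeting the bilateral threshold are classed ``Q_B``, those meeting
only the unilateral threshold ``Q_U``, the rest ``none``.  A minimal
*intramolecular* zipper comprises four six-residue strands joined by short
loops; ``min_tract_length`` and ``nucleus_scan`` implement that arithmetic and
the corresponding window search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Optional

__all__ = [
    "RuleParams",
    "SequenceReport",
    "contiguity",
    "classify",
    "min_tract_length",
    "strand_span",
    "nucleus_scan",
    "build_repeat",
]

#: residues considered flexible enough to form a shortened loop
FLEXIBLE_LOOP_RESIDUES = frozenset("GPS")


@dataclass(frozen=True)
class RuleParams:
    """Thresholds and geometry for the zipper competence rules.

    ``uni_threshold``/``bi_threshold`` are the minimal unilateral/bilateral
    contiguities for de novo nucleation.  ``strand_len``, ``n_strands`` and
    ``loop_len`` describe the minimal intramolecular zipper (four six-residue
    strands, ~four-residue loops; loops of only G/P/S may shrink to
    ``flexible_loop_len``).
    """

    uni_threshold: int = 5
    bi_threshold: int = 6
    strand_len: int = 6
    n_strands: int = 4
    loop_len: int = 4
    flexible_loop_len: int = 3

    def __post_init__(self) -> None:
        for name in ("uni_threshold", "bi_threshold", "strand_len",
                     "n_strands", "loop_len", "flexible_loop_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


@dataclass
class SequenceReport:
    """Contiguity metrics and zipper classification for one sequence.

    Coordinates are 1-based inclusive.  ``zipper_class`` is ``"Q_B"`` when the
    bilateral threshold is met, else ``"Q_U"`` when the unilateral threshold
    is met, else ``"none"``.  ``nucleus_layout`` holds the intramolecular
    four-strand layout found by :func:`nucleus_scan`, when feasible.
    """

    sequence: str
    length: int
    uni: int
    bi: int
    uni_run: Optional[tuple[int, int]]
    bi_run: Optional[tuple[int, int]]
    zipper_class: str
    de_novo_competent: bool
    nucleus_layout: Optional[list[tuple[int, int]]] = None
    params: RuleParams = field(default_factory=RuleParams)

    def to_dict(self) -> dict:
        return {
            "sequence": self.sequence,
            "length": self.length,
            "uni": self.uni,
            "bi": self.bi,
            "uni_run": list(self.uni_run) if self.uni_run else None,
            "bi_run": list(self.bi_run) if self.bi_run else None,
            "zipper_class": self.zipper_class,
            "de_novo_competent": self.de_novo_competent,
            "nucleus_layout": [list(w) for w in self.nucleus_layout]
            if self.nucleus_layout
            else None,
        }


def _longest_run(flags: list[bool]) -> tuple[int, int]:
    """Longest run of True; returns (length, start index) with ties -> first."""
    best = 0
    best_start = -1
    run = 0
    start = 0
    for i, f in enumerate(flags):
        if f:
            if run == 0:
                start = i
            run += 1
            if run > best:
                best = run
                best_start = start
        else:
            run = 0
    return best, best_start


def contiguity(sequence: str) -> tuple[int, int]:
    """Return ``(uni, bi)`` for a protein sequence.

    ``uni`` is the maximum over the two parity frames (1-based positions
    1,3,5,... and 2,4,6,...) of the longest uninterrupted stretch of Q within
    the frame; ``bi`` is the longest literal Q run.  The empty sequence gives
    (0, 0).
    """
    uni, _, bi, _ = _contiguity_runs(sequence)
    return uni, bi


def _contiguity_runs(
    sequence: str,
) -> tuple[int, Optional[tuple[int, int]], int, Optional[tuple[int, int]]]:
    seq = sequence.upper()
    is_q = [c == "Q" for c in seq]

    bi, bi_start = _longest_run(is_q)
    bi_run = (bi_start + 1, bi_start + bi) if bi else None

    uni = 0
    uni_run: Optional[tuple[int, int]] = None
    for frame in (0, 1):
        flags = is_q[frame::2]
        run, start = _longest_run(flags)
        if run > uni:
            uni = run
            first = frame + 2 * start  # 0-based position of first Q in run
            uni_run = (first + 1, first + 1 + 2 * (run - 1))
    return uni, uni_run, bi, bi_run


def classify(sequence: str, params: RuleParams | None = None) -> SequenceReport:
    """Classify a sequence as Q_B / Q_U / none and call de novo competence.

    A sequence is de novo amyloid-competent when it has at least
    ``uni_threshold`` unilaterally contiguous Qs or at least ``bi_threshold``
    bilaterally contiguous Qs.  The report carries the witnessing run
    coordinates and, when the default layout search succeeds, the
    intramolecular nucleus layout (reported alongside, not folded into the
    competence call).
    """
    p = params or RuleParams()
    seq = sequence.upper()
    uni, uni_run, bi, bi_run = _contiguity_runs(seq)

    if bi >= p.bi_threshold:
        zipper_class = "Q_B"
    elif uni >= p.uni_threshold:
        zipper_class = "Q_U"
    else:
        zipper_class = "none"
    competent = zipper_class != "none"

    layout = nucleus_scan(seq, p)
    return SequenceReport(
        sequence=seq,
        length=len(seq),
        uni=uni,
        bi=bi,
        uni_run=uni_run,
        bi_run=bi_run,
        zipper_class=zipper_class,
        de_novo_competent=competent,
        nucleus_layout=layout,
        params=p,
    )


def min_tract_length(strand_len: int, n_strands: int, loop_len: int) -> int:
    """Residues needed for ``n_strands`` strands of ``strand_len`` joined by
    ``n_strands - 1`` loops of ``loop_len``.

    With six-residue strands, four strands and four-residue loops this gives
    36 -- the clinical polyQ disease threshold; shrinking the loops to three
    glycines gives 33, the shortest sequence that can still encode the
    intramolecular zipper.
    """
    if strand_len < 1 or n_strands < 1 or loop_len < 1:
        raise ValueError("strand_len, n_strands and loop_len must be positive")
    return n_strands * strand_len + (n_strands - 1) * loop_len


def strand_span(n_face_q: int) -> int:
    """Minimal strand length placing ``n_face_q`` glutamines on one face.

    Face residues alternate, so the span is ``2 * n_face_q - 1`` (a strand of
    nine residues carries five alternating Qs).  Whether the physical strand
    is 2q-1 or 2q residues is ambiguous by one flanking residue; the lower
    bound is returned.
    """
    if n_face_q < 1:
        raise ValueError("n_face_q must be >= 1")
    return 2 * n_face_q - 1


def _window_ok(seq: str, start: int, strand_len: int) -> bool:
    """A window supports a zipper strand if one parity of its positions is all Q."""
    window = seq[start : start + strand_len]
    n_odd = ceil(strand_len / 2)
    n_even = strand_len // 2
    odd_ok = all(window[i] == "Q" for i in range(0, strand_len, 2)) and n_odd > 0
    even_ok = all(window[i] == "Q" for i in range(1, strand_len, 2)) and n_even > 0
    return odd_ok or even_ok


def _min_gap(seq: str, gap_start: int, gap_end: int, params: RuleParams) -> int:
    """Required loop length for the gap seq[gap_start:gap_end] (0-based, excl)."""
    gap = seq[gap_start:gap_end]
    if gap and all(c in FLEXIBLE_LOOP_RESIDUES for c in gap):
        return params.flexible_loop_len
    return params.loop_len


def nucleus_scan(
    sequence: str, params: RuleParams | None = None
) -> Optional[list[tuple[int, int]]]:
    """Search for an intramolecular multi-strand zipper layout.

    Looks for ``n_strands`` disjoint windows of ``strand_len`` residues, in
    order, each with glutamine at every position of at least one parity frame
    of the window, and with consecutive windows separated by at least
    ``loop_len`` residues (``flexible_loop_len`` when the gap contains only
    G/P/S).  Returns the lexicographically first feasible layout as 1-based
    inclusive windows, or ``None`` when infeasible.
    """
    p = params or RuleParams()
    seq = sequence.upper()
    n = len(seq)
    if n < min_tract_length(p.strand_len, p.n_strands, p.flexible_loop_len):
        return None

    ok_start = [
        _window_ok(seq, s, p.strand_len) for s in range(n - p.strand_len + 1)
    ]

    def search(next_start: int, chosen: list[int]) -> Optional[list[int]]:
        if len(chosen) == p.n_strands:
            return chosen
        remaining = p.n_strands - len(chosen)
        # loosest bound: remaining strands + flexible loops must still fit
        max_start = (
            n
            - remaining * p.strand_len
            - (remaining - 1) * p.flexible_loop_len
        )
        for s in range(next_start, max_start + 1):
            if not ok_start[s]:
                continue
            if chosen:
                prev_end = chosen[-1] + p.strand_len  # exclusive
                gap = s - prev_end
                if gap < _min_gap(seq, prev_end, s, p):
                    continue
            out = search(s + p.strand_len, chosen + [s])
            if out is not None:
                return out
        return None

    starts = search(0, [])
    if starts is None:
        return None
    return [(s + 1, s + p.strand_len) for s in starts]


def build_repeat(unit: str, total_length: int) -> str:
    """Tile ``unit`` and truncate to exactly ``total_length`` residues.

    ``build_repeat("QQQN", 60)`` gives the 60-mer with N at every fourth
    position -- the construction behind the Q_qN repeat series.
    """
    if not unit:
        raise ValueError("unit must be a non-empty string")
    if total_length < 1:
        raise ValueError("total_length must be >= 1")
    reps = -(-total_length // len(unit))
    return (unit.upper() * reps)[:total_length]
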