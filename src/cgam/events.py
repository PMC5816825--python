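"""Gait event detection from vertical ground reaction force.

Heel strike (HS) and toe off (TO) are found by debounced threshold crossings
of the baseline-corrected vertical force: a contact begins at the first sample
where the force rises above the threshold and stays above it for at least
``min_phase`` seconds, and ends at the first sample where it falls below and
stays below for the same duration.  Partial phases at the trial edges are
discarded.

A *step* runs from one side's heel strike to the next contralateral heel
strike and is labeled by the side of its terminal heel strike; consecutive
left/right steps are paired into stride pairs, which become the rows of the
downstream asymmetry matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .errors import IntegrityError, ParameterError

__all__ = ["SideEvents", "GaitEventTable", "detect_contacts", "build_step_sequence"]

log = logging.getLogger(__name__)


@dataclass
class SideEvents:
    """Ordered heel-strike / toe-off times (s) for one side.

    Events alternate HS, TO, HS, TO, ... with hs[i] < to[i]: equal-length
    arrays describe complete stances only.
    """

    hs: np.ndarray
    to: np.ndarray

    def __post_init__(self):
        self.hs = np.asarray(self.hs, dtype=float)
        self.to = np.asarray(self.to, dtype=float)
        if self.hs.shape != self.to.shape:
            raise IntegrityError("hs and to must have equal length (complete stances)")
        if self.hs.size:
            if np.any(np.diff(self.hs) <= 0) or np.any(np.diff(self.to) <= 0):
                raise IntegrityError("event times must strictly increase")
            if np.any(self.to <= self.hs):
                raise IntegrityError("every stance needs to > hs")
            if np.any(self.hs[1:] <= self.to[:-1]):
                raise IntegrityError("stances must not overlap")

    @property
    def n_stances(self) -> int:
        return int(self.hs.size)

    def stances(self) -> List[Tuple[float, float]]:
        return list(zip(self.hs, self.to))


@dataclass
class GaitEventTable:
    """Both sides' events plus the merged alternating heel-strike sequence."""

    left: SideEvents
    right: SideEvents
    #: merged, trimmed heel strikes: (time, side) with strictly alternating sides
    sequence: List[Tuple[float, str]] = field(default_factory=list)

    @property
    def n_step_pairs(self) -> int:
        """Complete left/right step pairs available for the asymmetry matrix.

        Steps are the intervals between consecutive merged heel strikes;
        the first merged heel strike only *starts* a step, and per-stride
        windows need one extra same-side heel strike at the end.
        """
        return max(0, (len(self.sequence) - 1) // 2)

    def steps(self) -> List[Tuple[float, float, str]]:
        """(start, end, side-of-terminal-HS) for each step in order."""
        out = []
        for (t0, _s0), (t1, s1) in zip(self.sequence[:-1], self.sequence[1:]):
            out.append((t0, t1, s1))
        return out

    def side(self, name: str) -> SideEvents:
        return self.left if name == "left" else self.right

    def to_frame(self):
        import pandas as pd

        rows = []
        for side in ("left", "right"):
            ev = self.side(side)
            for t in ev.hs:
                rows.append((side, "HS", t))
            for t in ev.to:
                rows.append((side, "TO", t))
        df = pd.DataFrame(rows, columns=["side", "type", "time_s"])
        return df.sort_values("time_s", ignore_index=True)


def detect_contacts(
    vertical_force: np.ndarray,
    rate: float,
    threshold: float = 20.0,
    min_phase: float = 0.05,
) -> SideEvents:
    """Detect complete stances in one side's baseline-corrected vertical force.

    Short excursions (above or below threshold) lasting less than ``min_phase``
    are absorbed into the surrounding state, which debounces noise spikes.
    Event times are the first sample of each sustained state change.
    """
    if threshold <= 0:
        raise ParameterError("threshold must be positive (newtons)")
    if min_phase <= 0:
        raise ParameterError("min_phase must be positive (seconds)")
    fz = np.asarray(vertical_force, dtype=float)
    above = fz > threshold
    if not above.any() or above.all():
        log.warning(
            "no threshold crossings found (threshold=%.3g N, max force=%.3g N)",
            threshold, fz.max(initial=np.nan),
        )
        return SideEvents(hs=np.empty(0), to=np.empty(0))

    min_samples = max(1, int(round(min_phase * rate)))
    # run-length encode, then absorb runs shorter than min_samples
    change = np.flatnonzero(np.diff(above.astype(np.int8))) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(above)]))
    states = above[starts]

    merged: List[Tuple[int, int, bool]] = []  # (start, end, state)
    for s, e, st in zip(starts, ends, states):
        if merged and (e - s) < min_samples:
            # too short to count as a new phase: extend the previous state
            ps, _pe, pst = merged[-1]
            merged[-1] = (ps, e, pst)
        elif merged and merged[-1][2] == bool(st):
            ps, _pe, pst = merged[-1]
            merged[-1] = (ps, e, pst)
        else:
            merged.append((s, e, bool(st)))
    # leading short run may have been kept verbatim; fold it forward
    if len(merged) >= 2 and (merged[0][1] - merged[0][0]) < min_samples:
        s0, _e0, _st0 = merged[0]
        s1, e1, st1 = merged[1]
        merged = [(s0, e1, st1)] + merged[2:]

    hs: List[int] = []
    to: List[int] = []
    for i, (s, e, st) in enumerate(merged):
        if st and i > 0:
            hs.append(s)  # sustained rise that does not start the trace
        if not st and i > 0:
            to.append(s)
    # keep only complete stances (hs matched with a following to)
    hs_arr, to_arr = [], []
    ti = 0
    for h in hs:
        while ti < len(to) and to[ti] <= h:
            ti += 1
        if ti < len(to):
            hs_arr.append(h)
            to_arr.append(to[ti])
            ti += 1
    return SideEvents(hs=np.asarray(hs_arr) / rate, to=np.asarray(to_arr) / rate)


def build_step_sequence(left: SideEvents, right: SideEvents) -> GaitEventTable:
    """Merge per-side events into an alternating step sequence.

    Leading/trailing heel strikes without a contralateral partner are trimmed;
    two consecutive same-side heel strikes *mid-trial* violate the step
    definition and raise :class:`IntegrityError` naming the time.
    """
    merged = sorted(
        [(t, "left") for t in left.hs] + [(t, "right") for t in right.hs]
    )
    # trim leading duplicates: keep only the last of an initial same-side run
    i = 0
    while i + 1 < len(merged) and merged[i][1] == merged[i + 1][1]:
        i += 1
    merged = merged[i:]
    # trim trailing duplicates symmetrically
    j = len(merged)
    while j - 2 >= 0 and merged[j - 1][1] == merged[j - 2][1]:
        j -= 1
    merged = merged[:j]

    for (t0, s0), (t1, s1) in zip(merged[:-1], merged[1:]):
        if s0 == s1:
            raise IntegrityError(
                f"two consecutive {s0} heel strikes at t={t0:.4f}s and t={t1:.4f}s; "
                "mid-trial step sequence is broken"
            )
    table = GaitEventTable(left=left, right=right, sequence=merged)
    log.info(
        "step sequence: %d left + %d right heel strikes -> %d complete step pairs",
        left.n_stances, right.n_stances, table.n_step_pairs,
    )
    return table
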