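"""Per-step gait parameters: spatiotemporal, kinematic and kinetic.

Eleven parameters are computed per step, one left and one right value per
stride pair (canonical order and short names):

====  =======================================  ==========
name  quantity                                 units
====  =======================================  ==========
SL    step length                              m
ST    step time                                s
GRF   peak vertical ground reaction force      body weight
PF    push-off (peak propulsive AP) force      body weight
BF    braking (peak retarding AP) force        body weight
KA    knee angle range of motion per stride    deg
AA    ankle angle range of motion per stride   deg
HA    hip angle range of motion per stride     deg
AM    ankle moment range per stride            N*m/kg
KM    knee moment range per stride             N*m/kg
HM    hip moment range per stride              N*m/kg
====  =======================================  ==========

Angles are sagittal-plane (Y–Z) segment angles: knee = thigh-shank angle
(0 at full extension, flexion positive), hip = thigh inclination from the
vertical (flexion positive), ankle = foot-shank angle minus 90 deg
(dorsiflexion positive).  Moments come from 2-D link-segment inverse dynamics
(foot/shank/thigh, Newton–Euler recursion distal-to-proximal) with
Winter-style anthropometric fractions, normalized by body mass.  The per-step
scalar for angles and moments is the range of motion over the stride — a
sign-convention-free summary that treats both sides identically; peak or
value-at-event summaries can be swapped in via ``summary``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError, ParameterError
from .events import GaitEventTable
from .io import GRAVITY, TrialRecording

__all__ = [
    "CANONICAL_PARAMS",
    "SPATIOTEMPORAL_SUBSET",
    "AnthropometricTable",
    "WINTER_ANTHROPOMETRY",
    "PairedStepTable",
    "step_times",
    "step_lengths",
    "grf_features",
    "joint_angles",
    "angle_summary",
    "inverse_dynamics_2d",
    "moment_summary",
    "assemble_parameter_table",
    "compute_parameters",
]

log = logging.getLogger(__name__)

CANONICAL_PARAMS = ("SL", "ST", "GRF", "PF", "BF", "KA", "AA", "HA", "AM", "KM", "HM")

#: The five-parameter spatiotemporal/kinetic subset (step length, step time,
#: vertical, push-off and braking forces) usable via ``active``.
SPATIOTEMPORAL_SUBSET = ("SL", "ST", "GRF", "PF", "BF")

_SIDES = ("left", "right")
_PREFIX = {"left": "L", "right": "R"}


@dataclass(frozen=True)
class SegmentFractions:
    mass: float  # fraction of body mass
    com: float  # CoM location, fraction of segment length from proximal end
    rog: float  # radius of gyration about CoM, fraction of segment length

    def __post_init__(self):
        for name in ("mass", "com", "rog"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ParameterError(f"anthropometric fraction {name}={v} not in (0, 1)")


@dataclass(frozen=True)
class AnthropometricTable:
    """Link-segment inertial fractions for foot, shank and thigh."""

    foot: SegmentFractions
    shank: SegmentFractions
    thigh: SegmentFractions
    source: str = "custom"

    def __getitem__(self, seg: str) -> SegmentFractions:
        return getattr(self, seg)


#: Standard adult link-segment fractions (Winter's tables).
WINTER_ANTHROPOMETRY = AnthropometricTable(
    foot=SegmentFractions(mass=0.0145, com=0.50, rog=0.475),
    shank=SegmentFractions(mass=0.0465, com=0.433, rog=0.302),
    thigh=SegmentFractions(mass=0.100, com=0.433, rog=0.323),
    source="winter",
)


@dataclass
class PairedStepTable:
    """One record per complete stride pair: <param>_L / <param>_R columns.

    ``data`` also carries ``stride_index``, the terminal heel-strike times
    ``t_hs_L``/``t_hs_R``, and a boolean ``complete`` flag; incomplete records
    (any non-finite value) are excluded downstream by default.
    """

    data: pd.DataFrame
    params: tuple

    def __post_init__(self):
        self.params = tuple(self.params)
        for p in self.params:
            for suf in ("_L", "_R"):
                if p + suf not in self.data.columns:
                    raise ParameterError(f"parameter table missing column {p + suf}")

    @property
    def n_pairs(self) -> int:
        return len(self.data)

    def complete(self) -> pd.DataFrame:
        return self.data[self.data["complete"]].reset_index(drop=True)

    def to_csv(self, path) -> None:
        from .io import _write_csv_with_comment
        from . import __version__

        cols = ["stride_index"] + [f"{p}_{s}" for p in self.params for s in ("L", "R")]
        cols += ["t_hs_L", "t_hs_R", "complete"]
        _write_csv_with_comment(
            path, self.data[cols], f"# cgam v{__version__} paired step table\n"
        )


# ---------------------------------------------------------------------------
# spatiotemporal
# ---------------------------------------------------------------------------

def step_times(events: GaitEventTable) -> pd.DataFrame:
    """Step time per merged step: contralateral HS to this side's HS.

    Returns columns (side, t_hs, value).
    """
    steps = events.steps()
    if not steps:
        raise IntegrityError("no complete steps in event table")
    rows = [(side, t1, t1 - t0) for (t0, t1, side) in steps]
    return pd.DataFrame(rows, columns=["side", "t_hs", "value"])


def step_lengths(trial: TrialRecording, events: GaitEventTable) -> pd.DataFrame:
    """Step length per merged step: anterior distance between the landing
    side's heel and the contralateral heel at the instant of heel strike."""
    trial.require_labels(("LHEE", "RHEE"))
    t = trial.marker_times()
    heel_y = {
        "left": trial.markers["LHEE"][:, 1],
        "right": trial.markers["RHEE"][:, 1],
    }
    rows = []
    for (_t0, t1, side) in events.steps():
        other = "right" if side == "left" else "left"
        if not (t[0] <= t1 <= t[-1]):
            rows.append((side, t1, np.nan))
            continue
        y_own = np.interp(t1, t, heel_y[side])
        y_other = np.interp(t1, t, heel_y[other])
        rows.append((side, t1, y_own - y_other))
    return pd.DataFrame(rows, columns=["side", "t_hs", "value"])


# ---------------------------------------------------------------------------
# GRF features
# ---------------------------------------------------------------------------

def grf_features(
    force: np.ndarray,
    rate: float,
    stances: Sequence[tuple],
    body_mass: float | None = None,
) -> pd.DataFrame:
    """Per-stance peak vertical, braking and push-off forces.

    braking = magnitude of the most negative anterior (Y) force in stance,
    push-off = the most positive.  Values are divided by body weight when
    ``body_mass`` is given (dimensionless), else reported in newtons.
    Returns columns (t_hs, GRF, BF, PF).
    """
    force = np.asarray(force, dtype=float)
    n = force.shape[0]
    scale = 1.0 / (body_mass * GRAVITY) if body_mass else 1.0
    rows = []
    for (hs, to) in stances:
        i0, i1 = int(round(hs * rate)), int(round(to * rate)) + 1
        if i0 < 0 or i1 > n or i1 <= i0:
            raise ParameterError(f"stance ({hs:.3f}, {to:.3f}) s outside force series")
        fz = force[i0:i1, 2]
        fy = force[i0:i1, 1]
        if fy.min() >= 0 or fy.max() <= 0:
            log.warning(
                "stance at t=%.3fs lacks a braking-then-propulsive AP pattern; "
                "extrema reported anyway", hs,
            )
        rows.append((hs, fz.max() * scale,
                     max(0.0, -fy.min()) * scale, max(0.0, fy.max()) * scale))
    return pd.DataFrame(rows, columns=["t_hs", "GRF", "BF", "PF"])


# ---------------------------------------------------------------------------
# joint angles
# ---------------------------------------------------------------------------

def _segment_angle_from_vertical(prox: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Sagittal angle (rad) of the prox->dist segment from the downward
    vertical; positive when the distal end lies anterior to the proximal."""
    d = dist - prox
    return np.arctan2(d[:, 1], -d[:, 2])


def _foot_pitch(heel: np.ndarray, toe: np.ndarray) -> np.ndarray:
    """Sagittal pitch (rad) of the heel->toe vector from the horizontal;
    positive toe-up."""
    d = toe - heel
    return np.arctan2(d[:, 2], d[:, 1])


def joint_angles(trial: TrialRecording) -> Dict[str, pd.DataFrame]:
    """Hip/knee/ankle sagittal angle time series (degrees) per side.

    hip  = thigh (ASI->knee) inclination from vertical, flexion positive;
    knee = thigh minus shank inclination, 0 at full extension;
    ankle = foot pitch plus shank inclination, 0 in neutral (foot horizontal
    under a vertical shank), dorsiflexion positive.
    """
    out = {}
    for side in _SIDES:
        p = _PREFIX[side]
        trial.require_labels((f"{p}ASI", f"{p}KNE", f"{p}ANK", f"{p}HEE", f"{p}TOE"))
        hip_pt = trial.markers[f"{p}ASI"]
        knee_pt = trial.markers[f"{p}KNE"]
        ankle_pt = trial.markers[f"{p}ANK"]
        heel = trial.markers[f"{p}HEE"]
        toe = trial.markers[f"{p}TOE"]
        phi_th = _segment_angle_from_vertical(hip_pt, knee_pt)
        phi_sh = _segment_angle_from_vertical(knee_pt, ankle_pt)
        phi_ft = _foot_pitch(heel, toe)
        out[side] = pd.DataFrame({
            "hip": np.degrees(phi_th),
            "knee": np.degrees(phi_th - phi_sh),
            "ankle": np.degrees(phi_ft + phi_sh),
        })
    return out


def angle_summary(series: np.ndarray, rate: float, window: tuple,
                  mode: str = "rom") -> float:
    """Scalar per-stride summary of an angle (or moment) series.

    ``rom`` (default) is max - min over the window; ``peak`` is the maximum.
    """
    i0 = int(np.ceil(window[0] * rate - 1e-9))
    i1 = int(np.floor(window[1] * rate + 1e-9)) + 1
    if i0 < 0 or i1 > len(series) or i1 <= i0:
        return np.nan
    seg = np.asarray(series[i0:i1], dtype=float)
    if mode == "rom":
        return float(seg.max() - seg.min())
    if mode == "peak":
        return float(seg.max())
    raise ParameterError(f"unknown summary mode {mode!r}")


#: Moments use the same windowed range summary as angles.
moment_summary = angle_summary


# ---------------------------------------------------------------------------
# inverse dynamics
# ---------------------------------------------------------------------------

def _cross2(r: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Scalar sagittal cross product r x f for (n,2) arrays in (y, z)."""
    return r[:, 0] * f[:, 1] - r[:, 1] * f[:, 0]


def _deriv(x: np.ndarray, dt: float, n: int = 1) -> np.ndarray:
    for _ in range(n):
        x = np.gradient(x, dt, axis=0)
    return x


def inverse_dynamics_2d(
    trial: TrialRecording,
    events: GaitEventTable,
    anthro: AnthropometricTable = WINTER_ANTHROPOMETRY,
) -> Dict[str, pd.DataFrame]:
    """Sagittal-plane internal joint moments (N*m/kg) per side at marker rate.

    Newton–Euler recursion distal to proximal over foot (ankle->toe), shank
    (knee->ankle) and thigh (hip->knee, hip joint taken at the ASI marker).
    During stance the measured GRF is applied at the CoP; during swing the
    external force is zero.  CoM accelerations and segment angular
    accelerations come from second-order central differences of the (already
    conditioned) marker trajectories.
    """
    mass = trial.subject.mass_kg
    dt = 1.0 / trial.marker_rate
    tm = trial.marker_times()
    tf = trial.force_times()
    g_vec = np.array([0.0, -GRAVITY])

    out = {}
    for side in _SIDES:
        p = _PREFIX[side]
        trial.require_labels((f"{p}ASI", f"{p}KNE", f"{p}ANK", f"{p}HEE", f"{p}TOE"))
        pts = {
            "hip": trial.markers[f"{p}ASI"][:, 1:],
            "knee": trial.markers[f"{p}KNE"][:, 1:],
            "ankle": trial.markers[f"{p}ANK"][:, 1:],
            "heel": trial.markers[f"{p}HEE"][:, 1:],
            "toe": trial.markers[f"{p}TOE"][:, 1:],
        }
        # (proximal joint point, geometry prox -> dist); the foot's inertial
        # geometry follows the heel->toe axis (the standard foot length) while
        # its proximal joint is the ankle
        segs = {
            "foot": ("ankle", "heel", "toe"),
            "shank": ("knee", "knee", "ankle"),
            "thigh": ("hip", "hip", "knee"),
        }

        # external load on the foot: GRF at CoP during stance, zero in swing
        fp = trial.forces[side]
        f_ext = np.column_stack([
            np.interp(tm, tf, fp.force[:, 1]),
            np.interp(tm, tf, fp.force[:, 2]),
        ])
        cop_raw = fp.cop[:, 1:]
        cop_ok = np.isfinite(cop_raw).all(axis=1)
        stance_mask = np.zeros(len(tm), dtype=bool)
        margin = 1.0 / trial.marker_rate
        for hs, to in events.side(side).stances():
            stance_mask |= (tm >= hs) & (tm <= to)
            inner = (tf >= hs + margin) & (tf <= to - margin)
            if np.any(inner & ~cop_ok):
                raise IntegrityError(f"CoP missing during stance on {side} side")
        cop_raw = np.where(cop_ok[:, None], cop_raw, 0.0)
        cop = np.column_stack([
            np.interp(tm, tf, cop_raw[:, 0]),
            np.interp(tm, tf, cop_raw[:, 1]),
        ])
        f_ext[~stance_mask] = 0.0

        moments = {}
        f_distal = -f_ext  # force the segment exerts on its distal neighbor
        m_distal = np.zeros(len(tm))
        p_distal = cop
        for seg_name, (joint_name, prox_name, dist_name) in segs.items():
            frac = anthro[seg_name]
            joint = pts[joint_name]
            prox, dist = pts[prox_name], pts[dist_name]
            seg_len = float(np.mean(np.linalg.norm(dist - prox, axis=1)))
            if seg_len <= 0:
                raise IntegrityError(f"degenerate zero-length {seg_name} segment")
            m_seg = frac.mass * mass
            inertia = m_seg * (frac.rog * seg_len) ** 2
            com = prox + frac.com * (dist - prox)
            acc = _deriv(com, dt, 2)
            d = dist - prox
            theta = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
            alpha = _deriv(theta, dt, 2)

            # forces on segment: gravity, distal load (-f_distal), proximal reaction
            f_prox = m_seg * (acc - g_vec) + f_distal
            m_prox = (
                inertia * alpha
                + m_distal
                - _cross2(p_distal - com, -f_distal)
                - _cross2(joint - com, f_prox)
            )
            moments[seg_name] = m_prox / mass
            f_distal, m_distal, p_distal = f_prox, m_prox, joint

        out[side] = pd.DataFrame({
            "ankle": moments["foot"],
            "knee": moments["shank"],
            "hip": moments["thigh"],
        })
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def compute_parameters(
    trial: TrialRecording,
    events: GaitEventTable,
    active: Sequence[str] = CANONICAL_PARAMS,
    anthro: AnthropometricTable = WINTER_ANTHROPOMETRY,
    summary: str = "rom",
    condition: bool = True,
) -> PairedStepTable:
    """Run every extractor the active set needs and assemble the step table.

    ``condition=True`` applies the default filtering (6 Hz markers, 15 Hz
    forces, baseline removal) before feature extraction; event times are taken
    as given (they should come from the raw baseline-corrected force).
    """
    active = tuple(active)
    if not active:
        raise ParameterError("active parameter set is empty")
    unknown = set(active) - set(CANONICAL_PARAMS)
    if unknown:
        raise ParameterError(f"unknown parameters {sorted(unknown)}; "
                             f"choose from {CANONICAL_PARAMS}")

    work = trial.filtered() if condition else trial

    steps = events.steps()
    st = step_times(events) if "ST" in active else None
    # step length is an instantaneous position difference: smoothing biases
    # the heel trajectory most right at contact, so use the raw markers
    sl = step_lengths(trial, events) if "SL" in active else None

    need_grf = {"GRF", "PF", "BF"} & set(active)
    grf = {}
    if need_grf:
        for side in _SIDES:
            grf[side] = grf_features(
                work.forces[side].force, work.force_rate,
                events.side(side).stances(), trial.subject.mass_kg,
            ).set_index(np.round(events.side(side).hs, 9))

    need_ang = {"KA", "AA", "HA"} & set(active)
    angles = joint_angles(work) if need_ang else None
    need_mom = {"AM", "KM", "HM"} & set(active)
    moments = inverse_dynamics_2d(work, events, anthro) if need_mom else None

    # stride window for the step ending at sequence index j: [t_j, t_{j+2}]
    seq = events.sequence
    angle_cols = {"KA": "knee", "AA": "ankle", "HA": "hip"}
    moment_cols = {"KM": "knee", "AM": "ankle", "HM": "hip"}

    records: List[dict] = []
    n_pairs = events.n_step_pairs
    for k in range(n_pairs):
        j_first, j_second = 2 * k + 1, 2 * k + 2
        rec: dict = {"stride_index": k}
        ok = True
        for j in (j_first, j_second):
            if j >= len(seq):
                ok = False
                continue
            t_hs, side = seq[j]
            suf = "_L" if side == "left" else "_R"
            rec[f"t_hs{suf}"] = t_hs
            if st is not None:
                rec["ST" + suf] = float(st["value"].iloc[j - 1])
            if sl is not None:
                rec["SL" + suf] = float(sl["value"].iloc[j - 1])
            if need_grf:
                row = _nearest_row(grf[side], t_hs)
                for name in ("GRF", "PF", "BF"):
                    if name in active:
                        rec[name + suf] = row[name] if row is not None else np.nan
            window = (t_hs, seq[j + 2][0]) if j + 2 < len(seq) else None
            if need_ang:
                for name, col in angle_cols.items():
                    if name in active:
                        rec[name + suf] = (
                            angle_summary(angles[side][col].to_numpy(),
                                          work.marker_rate, window, summary)
                            if window else np.nan
                        )
            if need_mom:
                for name, col in moment_cols.items():
                    if name in active:
                        rec[name + suf] = (
                            moment_summary(moments[side][col].to_numpy(),
                                           work.marker_rate, window, summary)
                            if window else np.nan
                        )
        if ok:
            records.append(rec)

    if not records:
        raise IntegrityError("no complete stride pairs could be assembled")
    df = pd.DataFrame.from_records(records)
    value_cols = [f"{pn}_{s}" for pn in active for s in ("L", "R")]
    for c in value_cols + ["t_hs_L", "t_hs_R"]:
        if c not in df.columns:
            df[c] = np.nan
    df["complete"] = np.isfinite(df[value_cols].to_numpy(dtype=float)).all(axis=1)
    n_bad = int((~df["complete"]).sum())
    if n_bad:
        log.info("%d of %d stride pairs flagged incomplete", n_bad, len(df))
    ordered = [p for p in CANONICAL_PARAMS if p in active]
    cols = (["stride_index"] + [f"{pn}_{s}" for pn in ordered for s in ("L", "R")]
            + ["t_hs_L", "t_hs_R", "complete"])
    return PairedStepTable(data=df[cols], params=ordered)


def _nearest_row(indexed: pd.DataFrame, t: float, tol: float = 2e-3):
    if len(indexed) == 0:
        return None
    idx = np.asarray(indexed.index, dtype=float)
    i = int(np.argmin(np.abs(idx - t)))
    if abs(idx[i] - t) > tol:
        return None
    return indexed.iloc[i]


def assemble_parameter_table(
    per_step_values: Dict[str, pd.DataFrame],
    active: Sequence[str] = CANONICAL_PARAMS,
) -> PairedStepTable:
    """Assemble a PairedStepTable from already-computed per-step value frames.

    Each frame must have columns (side, t_hs, value); steps are paired in
    time order.  Intended for callers that computed features themselves;
    :func:`compute_parameters` is the one-call pipeline version.
    """
    active = tuple(active)
    if not active:
        raise ParameterError("active parameter set is empty")
    missing = set(active) - set(per_step_values)
    if missing:
        raise ParameterError(f"values missing for parameters {sorted(missing)}")
    base = per_step_values[active[0]].sort_values("t_hs", ignore_index=True)
    records = []
    for k in range(len(base) // 2):
        rec = {"stride_index": k}
        for j in (2 * k, 2 * k + 1):
            side = base["side"].iloc[j]
            t_hs = base["t_hs"].iloc[j]
            suf = "_L" if side == "left" else "_R"
            rec[f"t_hs{suf}"] = t_hs
            for name in active:
                frame = per_step_values[name]
                match = frame[(frame["side"] == side)
                              & (np.abs(frame["t_hs"] - t_hs) < 1e-9)]
                rec[name + suf] = float(match["value"].iloc[0]) if len(match) else np.nan
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    value_cols = [f"{pn}_{s}" for pn in active for s in ("L", "R")]
    df["complete"] = np.isfinite(df[value_cols].to_numpy(dtype=float)).all(axis=1)
    ordered = [p for p in CANONICAL_PARAMS if p in active]
    cols = (["stride_index"] + [f"{pn}_{s}" for pn in ordered for s in ("L", "R")]
            + ["t_hs_L", "t_hs_R", "complete"])
    return PairedStepTable(data=df[cols], params=ordered)
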