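"""Trial recordings: containers, readers/writers, and signal conditioning.

A :class:`TrialRecording` bundles labeled 3-D marker trajectories, per-side
force-plate series (3-D force + center of pressure), and subject metadata for
one treadmill walking trial, all expressed in one canonical lab frame:

* X mediolateral (positive toward the subject's right),
* Y anterior (direction of progression),
* Z vertical up,

with positions in meters and forces in newtons.  Readers for the supported
dialects (``csv_wide``, ``csv_long``, ``c3d``) map file axes/units into this
frame via a :class:`Dialect` description.

Signal conditioning follows standard gait-lab practice: zero-phase Butterworth
low-pass filtering (default 6 Hz for markers, 15 Hz for forces) and removal of
the force-plate baseline offset estimated from the quietest vertical-force
samples.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from .errors import FormatError, MissingLabelError, ParameterError, UsageError

__all__ = [
    "LOWER_LIMB_LABELS",
    "Subject",
    "ForcePlate",
    "TrialRecording",
    "Dialect",
    "load_trial",
    "save_trial",
    "lowpass_filter",
    "remove_force_baseline",
]

#: Lower-limb marker subset used throughout the pipeline (pelvis, knees,
#: ankles, heels, toes).  The label map in a Dialect can alias other naming
#: schemes onto these canonical names.
LOWER_LIMB_LABELS = (
    "LASI", "RASI", "SACR",
    "LKNE", "RKNE",
    "LANK", "RANK",
    "LHEE", "RHEE",
    "LTOE", "RTOE",
)

SIDES = ("left", "right")

GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class Subject:
    """Subject metadata needed for normalization and simulation."""

    mass_kg: float
    leg_length_m: float
    belt_speed_mps: float

    def __post_init__(self):
        if self.mass_kg <= 0 or self.leg_length_m <= 0:
            raise ParameterError("subject mass and leg length must be positive")
        if self.belt_speed_mps < 0:
            raise ParameterError("belt speed must be non-negative")

    @property
    def weight_n(self) -> float:
        return self.mass_kg * GRAVITY


@dataclass
class ForcePlate:
    """One side's force-plate series: force (N) and CoP (m), shape (n, 3)."""

    force: np.ndarray
    cop: np.ndarray

    def __post_init__(self):
        self.force = np.asarray(self.force, dtype=float)
        self.cop = np.asarray(self.cop, dtype=float)
        if self.force.ndim != 2 or self.force.shape[1] != 3:
            raise FormatError("force series must have shape (n, 3)")
        if self.cop.shape != self.force.shape:
            raise FormatError("CoP series must match force series shape")

    def __len__(self) -> int:
        return self.force.shape[0]


@dataclass
class TrialRecording:
    """Synchronized markers + forces + metadata for one walking trial."""

    markers: Dict[str, np.ndarray]  # label -> (n_marker, 3) meters
    marker_rate: float  # Hz
    forces: Dict[str, ForcePlate]  # "left"/"right"
    force_rate: float  # Hz
    subject: Subject
    lab_frame: str = "X-mediolateral Y-anterior Z-up"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.marker_rate <= 0 or self.force_rate <= 0:
            raise ParameterError("sampling rates must be positive")
        if self.force_rate < self.marker_rate:
            raise FormatError("force_rate must be >= marker_rate")
        lengths = {arr.shape[0] for arr in self.markers.values()}
        if len(lengths) > 1:
            raise FormatError(
                f"marker series lengths differ across labels: {sorted(lengths)}"
            )
        for label, arr in self.markers.items():
            a = np.asarray(arr, dtype=float)
            if a.ndim != 2 or a.shape[1] != 3:
                raise FormatError(f"marker {label!r} must have shape (n, 3)")
            self.markers[label] = a
        flen = {len(fp) for fp in self.forces.values()}
        if len(flen) > 1:
            raise FormatError("left/right force series lengths differ")

    # -- basic views ------------------------------------------------------

    @property
    def n_marker_samples(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    @property
    def n_force_samples(self) -> int:
        return len(next(iter(self.forces.values())))

    def marker_times(self) -> np.ndarray:
        return np.arange(self.n_marker_samples) / self.marker_rate

    def force_times(self) -> np.ndarray:
        return np.arange(self.n_force_samples) / self.force_rate

    def require_labels(self, labels: Sequence[str]) -> None:
        for label in labels:
            if label not in self.markers:
                raise MissingLabelError(label)

    def filtered(self, marker_cutoff: float = 6.0, force_cutoff: float = 15.0,
                 order: int = 4) -> "TrialRecording":
        """Return a copy with low-pass-filtered markers and forces.

        Force baselines are removed before filtering.  Set a cutoff to None
        to leave that group untouched.
        """
        markers = dict(self.markers)
        if marker_cutoff is not None:
            markers = {
                k: lowpass_filter(v, marker_cutoff, self.marker_rate, order)
                for k, v in markers.items()
            }
        forces = {}
        for side, fp in self.forces.items():
            f = remove_force_baseline(fp.force)
            if force_cutoff is not None:
                f = lowpass_filter(f, force_cutoff, self.force_rate, order)
            forces[side] = ForcePlate(force=f, cop=fp.cop.copy())
        return replace(self, markers=markers, forces=forces)


# ---------------------------------------------------------------------------
# dialects
# ---------------------------------------------------------------------------

_AXIS_INDEX = {"X": 0, "Y": 1, "Z": 2}


def _parse_axis(spec: str) -> tuple[int, float]:
    spec = spec.strip()
    sign = 1.0
    if spec.startswith("-"):
        sign, spec = -1.0, spec[1:]
    elif spec.startswith("+"):
        spec = spec[1:]
    if spec.upper() not in _AXIS_INDEX:
        raise UsageError(f"unknown axis spec {spec!r}; use one of X/Y/Z with optional sign")
    return _AXIS_INDEX[spec.upper()], sign


@dataclass(frozen=True)
class Dialect:
    """How to interpret a source file.

    ``axes`` maps the canonical frame onto file axes: a triple of file-axis
    names (optionally signed) giving, in order, where canonical X (mediolateral),
    Y (anterior) and Z (up) live in the file.  ``units`` is 'm' or 'mm' for
    positions (forces are always newtons).  ``label_map`` renames file marker
    labels to the canonical lower-limb names.
    """

    kind: str = "csv_wide"  # csv_wide | csv_long | c3d
    units: str = "m"
    axes: tuple = ("X", "Y", "Z")
    label_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("csv_wide", "csv_long", "c3d"):
            raise UsageError(f"unknown dialect kind {self.kind!r}")
        if self.units not in ("m", "mm"):
            raise UsageError(f"unknown position units {self.units!r} (use 'm' or 'mm')")

    @property
    def scale(self) -> float:
        return 1.0 if self.units == "m" else 1e-3

    def to_canonical(self, xyz: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array from file axes/units into the canonical frame."""
        out = np.empty_like(xyz, dtype=float)
        for canon, spec in enumerate(self.axes):
            idx, sign = _parse_axis(spec)
            out[:, canon] = sign * xyz[:, idx]
        return out * self.scale

    def rename(self, label: str) -> str:
        return self.label_map.get(label, label)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_csv(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not parse CSV {path}: {exc}") from exc


def _markers_from_wide(df: pd.DataFrame, dialect: Dialect) -> Dict[str, np.ndarray]:
    markers: Dict[str, np.ndarray] = {}
    suffixes = ("_X", "_Y", "_Z")
    labels = sorted({c[:-2] for c in df.columns if c.endswith(suffixes)})
    for raw in labels:
        cols = [f"{raw}{s}" for s in suffixes]
        if not all(c in df.columns for c in cols):
            raise FormatError(f"marker {raw!r} is missing one of its _X/_Y/_Z columns")
        xyz = df[cols].to_numpy(dtype=float)
        markers[dialect.rename(raw)] = dialect.to_canonical(xyz)
    if not markers:
        raise FormatError("no LABEL_X/LABEL_Y/LABEL_Z marker columns found")
    return markers


def _markers_from_long(df: pd.DataFrame, dialect: Dialect) -> Dict[str, np.ndarray]:
    needed = {"frame", "label", "x", "y", "z"}
    cols = {c.lower(): c for c in df.columns}
    if not needed <= set(cols):
        raise FormatError(f"long CSV needs columns {sorted(needed)}, got {list(df.columns)}")
    markers: Dict[str, np.ndarray] = {}
    nframes = None
    for raw, grp in df.groupby(cols["label"], sort=False):
        grp = grp.sort_values(cols["frame"])
        xyz = grp[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=float)
        if nframes is None:
            nframes = len(xyz)
        elif len(xyz) != nframes:
            raise FormatError(
                f"marker {raw!r} has {len(xyz)} frames, expected {nframes}"
            )
        markers[dialect.rename(str(raw))] = dialect.to_canonical(xyz)
    return markers


def _forces_from_csv(path: Path, dialect: Dialect) -> ForcePlate:
    df = _read_csv(Path(path))
    fcols = ["FX", "FY", "FZ"]
    ccols = ["COPX", "COPY", "COPZ"]
    for c in fcols + ccols:
        if c not in df.columns:
            raise FormatError(f"force CSV {path} is missing column {c}")
    # Forces rotate with the frame but do not rescale; CoP does both.
    raw_f = df[fcols].to_numpy(dtype=float)
    force = dialect.to_canonical(raw_f) / dialect.scale
    cop = dialect.to_canonical(df[ccols].to_numpy(dtype=float))
    return ForcePlate(force=force, cop=cop)


def _load_c3d(path, dialect, subject):  # pragma: no cover - optional dependency
    try:
        import ezc3d  # noqa: F401
    except ImportError as exc:
        raise UsageError(
            "reading C3D requires the optional 'ezc3d' package "
            "(pip install cgam[c3d]); CSV dialects need no extra dependency"
        ) from exc
    raise UsageError("C3D reading is not wired up in this build; use a CSV dialect")


def load_trial(
    marker_source,
    force_sources,
    subject: Subject,
    dialect: Dialect | None = None,
    marker_rate: float | None = None,
    force_rate: float | None = None,
    required_labels: Sequence[str] = LOWER_LIMB_LABELS,
) -> TrialRecording:
    """Load one trial from files.

    Parameters
    ----------
    marker_source : path
        Marker file in the dialect's format.
    force_sources : mapping side -> path
        Per-side force CSV (columns FX, FY, FZ, COPX, COPY, COPZ).
    subject : Subject
        Body mass, leg length, belt speed.
    dialect : Dialect
        Axis/unit/label conventions of the source files.
    marker_rate, force_rate : float
        Sampling rates in Hz.  If omitted, read from a ``rate=`` token in the
        file's leading ``#`` comment line.
    required_labels : sequence of str
        Labels that must be present after renaming (checked; error names the
        first missing one).  Pass ``()`` to skip the check.
    """
    dialect = dialect or Dialect()
    marker_source = Path(marker_source)
    if dialect.kind == "c3d":
        return _load_c3d(marker_source, dialect, subject)

    if marker_rate is None:
        marker_rate = _rate_from_comment(marker_source)
    df = _read_csv(marker_source)
    if dialect.kind == "csv_wide":
        markers = _markers_from_wide(df, dialect)
    else:
        markers = _markers_from_long(df, dialect)

    forces = {}
    f_rate = force_rate
    for side in SIDES:
        if side not in force_sources:
            raise FormatError(f"force source for side {side!r} not provided")
        p = Path(force_sources[side])
        if f_rate is None:
            f_rate = _rate_from_comment(p)
        forces[side] = _forces_from_csv(p, dialect)

    trial = TrialRecording(
        markers=markers,
        marker_rate=float(marker_rate),
        forces=forces,
        force_rate=float(f_rate),
        subject=subject,
    )
    if required_labels:
        trial.require_labels(required_labels)
    return trial


def _rate_from_comment(path: Path) -> float:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first[1:].split():
            if token.startswith("rate="):
                return float(token.split("=", 1)[1])
    raise FormatError(
        f"sampling rate not given and no '# ... rate=<Hz>' comment in {path}"
    )


def _provenance_line(kind: str, rate: float) -> str:
    from . import __version__

    return f"# cgam v{__version__} {kind} rate={rate:g} units=m frame=X-ml,Y-ant,Z-up\n"


def save_trial(trial: TrialRecording, out_dir) -> Dict[str, Path]:
    """Write a trial as a directory of CSVs + meta.yaml (canonical frame, m/N).

    Layout: ``markers.csv`` (wide), ``forces_left.csv``, ``forces_right.csv``,
    ``meta.yaml``.  Round-trips through :func:`load_trial_dir`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    cols = {"frame": np.arange(trial.n_marker_samples)}
    for label in sorted(trial.markers):
        arr = trial.markers[label]
        for i, ax in enumerate("XYZ"):
            cols[f"{label}_{ax}"] = arr[:, i]
    mpath = out / "markers.csv"
    _write_csv_with_comment(mpath, pd.DataFrame(cols),
                            _provenance_line("markers", trial.marker_rate))
    paths["markers"] = mpath

    for side in SIDES:
        fp = trial.forces[side]
        df = pd.DataFrame({
            "frame": np.arange(len(fp)),
            "FX": fp.force[:, 0], "FY": fp.force[:, 1], "FZ": fp.force[:, 2],
            "COPX": fp.cop[:, 0], "COPY": fp.cop[:, 1], "COPZ": fp.cop[:, 2],
        })
        p = out / f"forces_{side}.csv"
        _write_csv_with_comment(p, df, _provenance_line("forces", trial.force_rate))
        paths[f"forces_{side}"] = p

    meta = {
        "marker_rate": trial.marker_rate,
        "force_rate": trial.force_rate,
        "subject": {
            "mass_kg": trial.subject.mass_kg,
            "leg_length_m": trial.subject.leg_length_m,
            "belt_speed_mps": trial.subject.belt_speed_mps,
        },
        "lab_frame": trial.lab_frame,
        "meta": _yaml_safe(trial.meta),
    }
    mp = out / "meta.yaml"
    mp.write_text(yaml.safe_dump(meta, sort_keys=True))
    paths["meta"] = mp
    return paths


def _yaml_safe(obj):
    if isinstance(obj, dict):
        return {k: _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _write_csv_with_comment(path: Path, df: pd.DataFrame, comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(comment)
        df.to_csv(fh, index=False, float_format="%.9g", lineterminator="\n")


def load_trial_dir(trial_dir, required_labels: Sequence[str] = LOWER_LIMB_LABELS
                   ) -> TrialRecording:
    """Load a trial directory written by :func:`save_trial`."""
    d = Path(trial_dir)
    meta = yaml.safe_load((d / "meta.yaml").read_text())
    subject = Subject(**meta["subject"])
    trial = load_trial(
        d / "markers.csv",
        {s: d / f"forces_{s}.csv" for s in SIDES},
        subject,
        dialect=Dialect(kind="csv_wide"),
        marker_rate=meta["marker_rate"],
        force_rate=meta["force_rate"],
        required_labels=required_labels,
    )
    trial.meta = meta.get("meta") or {}
    return trial


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# conditioning
# ---------------------------------------------------------------------------

def lowpass_filter(series: np.ndarray, cutoff: float, rate: float,
                   order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass along axis 0.

    ``filtfilt`` applies the filter forward and backward, doubling the
    effective order and canceling phase lag — the standard treatment for gait
    signals where timing must not shift.
    """
    series = np.asarray(series, dtype=float)
    nyq = rate / 2.0
    if cutoff <= 0 or cutoff >= nyq:
        raise ParameterError(
            f"cutoff must lie in (0, Nyquist={nyq:g}) Hz; got {cutoff:g}"
        )
    if series.shape[0] <= 3 * order:
        raise ParameterError(
            f"series too short ({series.shape[0]} samples) for order-{order} filtering"
        )
    sos = sps.butter(order, cutoff, btype="low", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, series, axis=0)


def remove_force_baseline(force: np.ndarray, fraction: float = 0.05) -> np.ndarray:
    """Subtract each channel's plate offset, estimated per channel as its value
    at the frames where vertical force is lowest (median over the lowest
    ``fraction`` of vertical-force samples).  Assumes nothing about swing
    phases existing; a constant-load plate simply keeps its load.
    """
    force = np.asarray(force, dtype=float)
    fz = force[:, 2]
    k = max(1, int(np.ceil(fraction * len(fz))))
    idx = np.argpartition(fz, k - 1)[:k]
    baseline = np.median(force[idx], axis=0)
    return force - baseline
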