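"""Synthetic asymmetric-gait generation with ground truth.

Two levels of generation make every stage of the pipeline testable without
recorded data:

* **Matrix level** — draw step-by-parameter symmetry-index rows directly from
  a multivariate normal with chosen mean offsets and covariance.  This gives
  exact statistical control for testing the metric itself.

* **Waveform level** — synthesize a full treadmill trial: per-side vertical
  GRF as a double-hump stance template, anterior-posterior force as a
  braking-then-propulsive biphasic wave, and lower-limb marker trajectories
  built from prescribed joint-angle waveforms (hip/knee chain) plus a
  stance/swing foot trajectory that realizes the programmed step lengths
  exactly.  Step-to-step variability is injected at the template-parameter
  level, and the generator emits its ground truth (event times, per-step
  parameter values per side) alongside the recording.

The heel/toe markers follow the foot-trajectory model (so programmed step
lengths and timings are exact) while knee/ankle markers follow the angle
chain (so programmed joint-angle ranges are exact); the two are therefore not
rigidly coupled, a deliberate simplification that leaves every *extracted*
quantity with a known truth value.  Joint moments are not independently
programmable at this level: they emerge from inverse dynamics of the
generated kinematics and forces.

Perturbation scenarios mirror a split-belt treadmill protocol in which leg
length increments (27/52 mm) and distal masses (2.3/4.6 kg) are worn on the
left leg and a stiffness/damping knee orthosis ("stroke simulator") on the
right.  Scenario effect maps are phenomenological mean-SI offsets per
parameter encoding each perturbation's qualitative signature (leg length
loads step-length asymmetry more than step-time; distal mass the reverse;
the orthosis adds large, variable step-length and hip-moment asymmetry).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np
import pandas as pd
import yaml

from .asymmetry import AsymmetryMatrix
from .errors import ParameterError
from .events import GaitEventTable, SideEvents, build_step_sequence
from .io import ForcePlate, Subject, TrialRecording

__all__ = [
    "SideTemplates",
    "NoiseSpec",
    "Perturbation",
    "SyntheticTrialConfig",
    "PerturbationScenario",
    "GroundTruth",
    "generate_asymmetry_matrix",
    "generate_waveform_trial",
    "apply_scenario",
    "scenario_catalog",
    "list_scenarios",
]

_SIDES = ("left", "right")


@dataclass(frozen=True)
class SideTemplates:
    """Per-side waveform template parameters."""

    step_length: float = 0.55  # m
    step_time: float = 0.6  # s (contralateral HS -> this side's HS)
    stance_fraction: float = 0.62  # of stride period
    vgrf_peak: float = 1.1  # body weight
    pushoff_bw: float = 0.2  # peak propulsive AP force, body weight
    braking_bw: float = 0.2  # peak braking AP force magnitude, body weight
    hip_rom: float = 40.0  # deg
    knee_rom: float = 60.0  # deg
    ankle_rom: float = 25.0  # deg
    ankle_moment_rom: float = 1.5  # N*m/kg (recorded; emergent at waveform level)
    knee_moment_rom: float = 1.0
    hip_moment_rom: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.stance_fraction < 1.0:
            raise ParameterError("stance fraction must lie in (0, 1)")
        for name in ("step_length", "step_time", "vgrf_peak", "pushoff_bw",
                     "braking_bw", "hip_rom", "knee_rom", "ankle_rom"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"template {name} must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Step-to-step standard deviations of the template parameters."""

    step_length: float = 0.012  # m
    step_time: float = 0.010  # s
    vgrf_peak: float = 0.03  # BW
    ap_amplitude: float = 0.01  # BW
    angle_rom: float = 1.5  # deg

    def __post_init__(self):
        for name in ("step_length", "step_time", "vgrf_peak", "ap_amplitude",
                     "angle_rom"):
            if getattr(self, name) < 0:
                raise ParameterError(f"noise SD {name} must be >= 0")

    def scaled(self, factor: float) -> "NoiseSpec":
        return NoiseSpec(**{k: getattr(self, k) * factor for k in
                            ("step_length", "step_time", "vgrf_peak",
                             "ap_amplitude", "angle_rom")})


@dataclass(frozen=True)
class Perturbation:
    """Physical perturbation metadata carried through to provenance."""

    leg_length_delta_mm: Dict[str, float] = field(
        default_factory=lambda: {"left": 0.0, "right": 0.0})
    distal_mass_kg: Dict[str, float] = field(
        default_factory=lambda: {"left": 0.0, "right": 0.0})
    knee_damping: bool = False
    knee_damper_gcms_per_deg: float = 0.0
    knee_spring_kg_per_mm: float = 0.0


@dataclass(frozen=True)
class SyntheticTrialConfig:
    """Complete recipe for one synthetic waveform trial."""

    n_strides: int = 20
    stride_period: float = 1.2  # s
    subject: Subject = field(
        default_factory=lambda: Subject(mass_kg=70.0, leg_length_m=0.94,
                                        belt_speed_mps=0.9))
    left: SideTemplates = field(default_factory=SideTemplates)
    right: SideTemplates = field(default_factory=SideTemplates)
    perturbation: Perturbation = field(default_factory=Perturbation)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    marker_rate: float = 100.0
    force_rate: float = 1000.0
    seed: int = 0
    scenario_name: str = "baseline"
    effect_map: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_strides < 1:
            raise ParameterError("n_strides must be >= 1")
        if self.stride_period <= 0:
            raise ParameterError("stride period must be positive")
        if abs(self.left.step_time + self.right.step_time
               - self.stride_period) > 1e-9:
            raise ParameterError(
                "left + right step times must add up to the stride period")

    def side(self, name: str) -> SideTemplates:
        return self.left if name == "left" else self.right


@dataclass(frozen=True)
class PerturbationScenario:
    """Named perturbation with its per-parameter mean SI offsets (percent)."""

    name: str
    effects: Dict[str, float]  # parameter -> mean SI offset, percent
    side: str = "left"
    noise_scale: float = 1.0
    perturbation: Perturbation = field(default_factory=Perturbation)
    description: str = ""


@dataclass
class GroundTruth:
    """What the generator knows: events and per-step parameter values."""

    events: GaitEventTable
    #: per complete stride pair: <param>_L/_R truth for SL, ST, GRF, PF, BF,
    #: KA, AA, HA (moments are emergent, see module docstring)
    steps: pd.DataFrame
    config: SyntheticTrialConfig


# ---------------------------------------------------------------------------
# matrix-level generation
# ---------------------------------------------------------------------------

def generate_asymmetry_matrix(
    mu: np.ndarray,
    Sigma_true: np.ndarray,
    m: int,
    seed: int | np.random.Generator = 0,
    params: Tuple[str, ...] = (),
) -> Tuple[AsymmetryMatrix, dict]:
    """Draw m symmetry-index rows from N(mu, Sigma_true).

    Returns the matrix plus a ground-truth dict ``{"mu", "Sigma"}`` for
    recovery tests.  Reproducible for a fixed seed.
    """
    mu = np.asarray(mu, dtype=float)
    Sigma_true = np.asarray(Sigma_true, dtype=float)
    n = mu.size
    if Sigma_true.shape != (n, n):
        raise ParameterError("Sigma_true shape must match mu length")
    if m < 1:
        raise ParameterError("m must be >= 1")
    try:
        chol = np.linalg.cholesky(Sigma_true)
    except np.linalg.LinAlgError as exc:
        raise ParameterError("Sigma_true must be symmetric positive definite") from exc
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal((m, n))
    values = mu + z @ chol.T
    names = tuple(params) if params else tuple(f"p{i}" for i in range(n))
    matrix = AsymmetryMatrix(values=values, params=names, step_index=np.arange(m))
    return matrix, {"mu": mu.copy(), "Sigma": Sigma_true.copy()}


# ---------------------------------------------------------------------------
# waveform-level generation
# ---------------------------------------------------------------------------

def _min_jerk(t: np.ndarray, t0: float, t1: float, p0: float, p1: float,
              v0: float = 0.0, v1: float = 0.0) -> np.ndarray:
    """Quintic interpolation with endpoint positions/velocities, zero accel."""
    T = t1 - t0
    s = np.clip((t - t0) / T, 0.0, 1.0)
    # quintic hermite basis (zero endpoint accelerations)
    h00 = 1 - 10 * s**3 + 15 * s**4 - 6 * s**5
    h10 = s - 6 * s**3 + 8 * s**4 - 3 * s**5
    h01 = 10 * s**3 - 15 * s**4 + 6 * s**5
    h11 = -4 * s**3 + 7 * s**4 - 3 * s**5
    return h00 * p0 + h10 * T * v0 + h01 * p1 + h11 * T * v1


def _stance_template(tau: np.ndarray) -> np.ndarray:
    """Double-hump vertical GRF shape on stance phase tau in [0, 1]."""
    g = (np.exp(-0.5 * ((tau - 0.3) / 0.13) ** 2)
         + np.exp(-0.5 * ((tau - 0.7) / 0.13) ** 2))
    return g


def generate_waveform_trial(config: SyntheticTrialConfig
                            ) -> Tuple[TrialRecording, GroundTruth]:
    """Synthesize one treadmill trial plus its ground truth.

    Deterministic for a fixed ``config.seed``; identical configs give
    byte-identical recordings.
    """
    rng = np.random.default_rng(config.seed)
    T = config.stride_period
    n = config.n_strides
    sub = config.subject
    bw = sub.weight_n

    # --- per-step jittered template draws (2 extra strides pad the edges so
    # the analysis pipeline can form n complete stride pairs) ---------------
    n_gen = n + 2
    jit: Dict[str, Dict[str, np.ndarray]] = {}
    for side in _SIDES:
        tpl = config.side(side)
        nz = config.noise
        jit[side] = {
            "step_time": tpl.step_time + rng.normal(0, nz.step_time, n_gen),
            "step_length": tpl.step_length + rng.normal(0, nz.step_length, n_gen),
            "vgrf_peak": tpl.vgrf_peak + rng.normal(0, nz.vgrf_peak, n_gen),
            "pushoff": np.abs(tpl.pushoff_bw + rng.normal(0, nz.ap_amplitude, n_gen)),
            "braking": np.abs(tpl.braking_bw + rng.normal(0, nz.ap_amplitude, n_gen)),
            "hip_rom": np.abs(tpl.hip_rom + rng.normal(0, nz.angle_rom, n_gen)),
            "knee_rom": np.abs(tpl.knee_rom + rng.normal(0, nz.angle_rom, n_gen)),
            "ankle_rom": np.abs(tpl.ankle_rom + rng.normal(0, nz.angle_rom, n_gen)),
        }
        if np.any(jit[side]["vgrf_peak"] <= 0) or np.any(jit[side]["step_time"] <= 0):
            raise ParameterError(
                "noise SDs too large: drew a non-positive force peak or step time")

    # --- heel-strike schedule: R, L, R, L, ... --------------------------------
    lead_in = 1.0
    hs = {"left": np.empty(n_gen), "right": np.empty(n_gen)}
    t = lead_in
    hs["right"][0] = t
    for k in range(n_gen):
        t = t + jit["left"]["step_time"][k]
        hs["left"][k] = t
        if k + 1 < n_gen:
            t = t + jit["right"]["step_time"][k + 1]
            hs["right"][k + 1] = t
    to = {
        side: hs[side] + config.side(side).stance_fraction * T
        for side in _SIDES
    }
    duration = max(to["left"][-1], to["right"][-1]) + lead_in

    # --- forces ---------------------------------------------------------------
    nf = int(round(duration * config.force_rate)) + 1
    tf = np.arange(nf) / config.force_rate
    forces = {}
    for side in _SIDES:
        fz = np.zeros(nf)
        fy = np.zeros(nf)
        copy = np.zeros(nf)
        in_stance = np.zeros(nf, dtype=bool)
        for k in range(n_gen):
            h, e = hs[side][k], to[side][k]
            i0 = int(np.ceil(h * config.force_rate - 1e-9))
            i1 = int(np.floor(e * config.force_rate + 1e-9)) + 1
            tau = (tf[i0:i1] - h) / (e - h)
            shape = _stance_template(tau)
            fz[i0:i1] = shape / shape.max() * jit[side]["vgrf_peak"][k] * bw
            ap = -np.sin(2 * np.pi * tau)
            neg, pos = ap < 0, ap > 0
            seg = np.zeros_like(ap)
            if neg.any():
                seg[neg] = ap[neg] / (-ap[neg].min()) * jit[side]["braking"][k] * bw
            if pos.any():
                seg[pos] = ap[pos] / ap[pos].max() * jit[side]["pushoff"][k] * bw
            fy[i0:i1] = seg
            in_stance[i0:i1] = True
        forces[side] = {"fz": fz, "fy": fy, "stance": in_stance}

    # --- heel trajectories (exact programmed step lengths) --------------------
    # backward foot speed in stance: the treadmill-consistent progression
    # speed for the programmed templates, so the gait is stationary on the
    # belt (no cumulative foot-pelvis drift)
    v = (config.left.step_length + config.right.step_length) / T
    land_y = {"left": np.empty(n_gen), "right": np.empty(n_gen)}
    land_y["right"][0] = 0.0
    for k in range(n_gen):
        # this side lands step_length ahead of where the other heel is now
        other_y = land_y["right"][k] - v * (hs["left"][k] - hs["right"][k])
        land_y["left"][k] = other_y + jit["left"]["step_length"][k]
        if k + 1 < n_gen:
            other_y = land_y["left"][k] - v * (hs["right"][k + 1] - hs["left"][k])
            land_y["right"][k + 1] = other_y + jit["right"]["step_length"][k + 1]

    nm = int(round(duration * config.marker_rate)) + 1
    tm = np.arange(nm) / config.marker_rate
    heel = {}
    for side in _SIDES:
        y = np.empty(nm)
        z = np.full(nm, 0.03)
        # before the first HS extend the stance line backwards (trace starts
        # mid-stance), keeping velocity continuous at the first contact
        pre = tm < hs[side][0]
        y[pre] = land_y[side][0] - v * (tm[pre] - hs[side][0])
        for k in range(n_gen):
            h, e = hs[side][k], to[side][k]
            m_st = (tm >= h) & (tm <= e)
            y[m_st] = land_y[side][k] - v * (tm[m_st] - h)
            if k + 1 < n_gen:
                h_next = hs[side][k + 1]
                m_sw = (tm > e) & (tm < h_next)
                y_to = land_y[side][k] - v * (e - h)
                y[m_sw] = _min_jerk(tm[m_sw], e, h_next, y_to,
                                    land_y[side][k + 1], v0=-v, v1=-v)
                z[m_sw] = 0.03 + 0.05 * np.sin(
                    np.pi * (tm[m_sw] - e) / (h_next - e)) ** 2
            else:
                m_end = tm > e
                y[m_end] = land_y[side][k] - v * (tm[m_end] - h)
        heel[side] = {"y": y, "z": z}

    # --- joint-angle chain -> pelvis/knee/ankle markers ------------------------
    leg = sub.leg_length_m
    d_thigh, d_shank, d_foot = 0.48 * leg, 0.45 * leg, 0.20
    hip_z = 0.10 + d_thigh + d_shank  # ankle height offset + leg
    phase = {}
    for side in _SIDES:
        ph = np.empty(nm)
        k_idx = np.searchsorted(hs[side], tm, side="right") - 1
        for i, ki in enumerate(k_idx):
            if ki < 0:
                ph[i] = (tm[i] - hs[side][0]) / T
            elif ki + 1 < n_gen:
                ph[i] = (tm[i] - hs[side][ki]) / (hs[side][ki + 1] - hs[side][ki])
            else:
                ph[i] = (tm[i] - hs[side][ki]) / T
            ph[i] += ki
        phase[side] = ph

    def _rom_at(side: str, key: str, ph: np.ndarray) -> np.ndarray:
        ks = np.clip(np.floor(ph).astype(int), 0, n_gen - 1)
        return jit[side][key][ks]

    markers: Dict[str, np.ndarray] = {}
    x_off = {"left": -0.10, "right": 0.10}
    markers["SACR"] = np.column_stack([np.zeros(nm), np.full(nm, -0.12),
                                       np.full(nm, hip_z + 0.05)])
    angles_deg: Dict[str, Dict[str, np.ndarray]] = {}
    for side in _SIDES:
        ph = phase[side]
        frac = ph - np.floor(ph)
        # waveforms are zero at every stride boundary, so per-stride amplitude
        # jitter never creates discontinuities and the within-stride range
        # equals the drawn ROM exactly
        hip = _rom_at(side, "hip_rom", ph) / 2.0 * np.sin(2 * np.pi * frac)
        knee = _rom_at(side, "knee_rom", ph) * 0.5 * (1 - np.cos(2 * np.pi * frac))
        ankle = _rom_at(side, "ankle_rom", ph) / 2.0 * np.sin(2 * np.pi * frac)
        angles_deg[side] = {"hip": hip, "knee": knee, "ankle": ankle}

        p = "L" if side == "left" else "R"
        x = np.full(nm, x_off[side])
        asi = np.column_stack([x, np.full(nm, 0.08), np.full(nm, hip_z)])
        h_r = np.radians(hip)
        sh_r = np.radians(hip - knee)  # shank inclination from vertical
        knee_pt = asi + d_thigh * np.column_stack(
            [np.zeros(nm), np.sin(h_r), -np.cos(h_r)])
        ankle_pt = knee_pt + d_shank * np.column_stack(
            [np.zeros(nm), np.sin(sh_r), -np.cos(sh_r)])
        # foot pitch chosen so extracted ankle angle reproduces the template
        pitch = np.radians(ankle) - sh_r
        heel_pt = np.column_stack([x, heel[side]["y"], heel[side]["z"]])
        toe_pt = heel_pt + d_foot * np.column_stack(
            [np.zeros(nm), np.cos(pitch), np.sin(pitch)])
        markers[f"{p}ASI"] = asi
        markers[f"{p}KNE"] = knee_pt
        markers[f"{p}ANK"] = ankle_pt
        markers[f"{p}HEE"] = heel_pt
        markers[f"{p}TOE"] = toe_pt

    # --- CoP: heel-to-toe progression during stance ----------------------------
    plates = {}
    for side in _SIDES:
        fz = forces[side]["fz"]
        fy = forces[side]["fy"]
        stance = forces[side]["stance"]
        heel_y_f = np.interp(tf, tm, heel[side]["y"])
        copy = np.zeros(nf)
        for k in range(n_gen):
            h, e = hs[side][k], to[side][k]
            i0 = int(np.ceil(h * config.force_rate - 1e-9))
            i1 = int(np.floor(e * config.force_rate + 1e-9)) + 1
            tau = (tf[i0:i1] - h) / (e - h)
            copy[i0:i1] = heel_y_f[i0:i1] + tau * d_foot
        # hold CoP continuous across swing (force is zero there anyway)
        if stance.any():
            copy = np.interp(tf, tf[stance], copy[stance])
        cop = np.column_stack([np.full(nf, x_off[side]), copy, np.zeros(nf)])
        force3 = np.column_stack([np.zeros(nf), fy, fz])
        plates[side] = ForcePlate(force=force3, cop=cop)

    trial = TrialRecording(
        markers=markers,
        marker_rate=config.marker_rate,
        forces=plates,
        force_rate=config.force_rate,
        subject=sub,
        meta={
            "synthetic": True,
            "scenario": config.scenario_name,
            "seed": int(config.seed),
            "effect_map": dict(config.effect_map),
            "perturbation": {
                "leg_length_delta_mm": dict(config.perturbation.leg_length_delta_mm),
                "distal_mass_kg": dict(config.perturbation.distal_mass_kg),
                "knee_damping": config.perturbation.knee_damping,
                "knee_damper_gcms_per_deg":
                    config.perturbation.knee_damper_gcms_per_deg,
                "knee_spring_kg_per_mm": config.perturbation.knee_spring_kg_per_mm,
            },
        },
    )

    truth = _ground_truth(config, hs, to, jit)
    return trial, truth


def _ground_truth(config, hs, to, jit) -> GroundTruth:
    """Assemble the event table and per-step truth records."""
    left = SideEvents(hs=hs["left"], to=to["left"])
    right = SideEvents(hs=hs["right"], to=to["right"])
    events = build_step_sequence(left, right)

    records = []
    seq = events.sequence
    idx_of = {side: {round(t, 9): k for k, t in enumerate(hs[side])}
              for side in _SIDES}
    for k in range((len(seq) - 1) // 2):
        rec = {"stride_index": k}
        for j in (2 * k + 1, 2 * k + 2):
            t_hs, side = seq[j]
            ki = idx_of[side][round(t_hs, 9)]
            suf = "_L" if side == "left" else "_R"
            rec["t_hs" + suf] = t_hs
            rec["ST" + suf] = t_hs - seq[j - 1][0]
            rec["SL" + suf] = jit[side]["step_length"][ki]
            rec["GRF" + suf] = jit[side]["vgrf_peak"][ki]
            rec["PF" + suf] = jit[side]["pushoff"][ki]
            rec["BF" + suf] = jit[side]["braking"][ki]
            # angle templates are zero at stride boundaries, so the range over
            # stride ki is exactly that stride's drawn ROM
            rec["HA" + suf] = jit[side]["hip_rom"][ki]
            rec["KA" + suf] = jit[side]["knee_rom"][ki]
            rec["AA" + suf] = jit[side]["ankle_rom"][ki]
        records.append(rec)
    return GroundTruth(events=events, steps=pd.DataFrame.from_records(records),
                       config=config)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def scenario_catalog() -> Dict[str, PerturbationScenario]:
    """Load the packaged scenario catalog."""
    text = (importlib.resources.files("cgam") / "data" / "scenarios.yaml").read_text()
    raw = yaml.safe_load(text)
    out = {}
    for name, spec in raw["scenarios"].items():
        pert = spec.get("perturbation", {})
        out[name] = PerturbationScenario(
            name=name,
            effects={k: float(v) for k, v in (spec.get("effects") or {}).items()},
            side=spec.get("side", "left"),
            noise_scale=float(spec.get("noise_scale", 1.0)),
            perturbation=Perturbation(
                leg_length_delta_mm={"left": 0.0, "right": 0.0,
                                     **pert.get("leg_length_delta_mm", {})},
                distal_mass_kg={"left": 0.0, "right": 0.0,
                                **pert.get("distal_mass_kg", {})},
                knee_damping=bool(pert.get("knee_damping", False)),
                knee_damper_gcms_per_deg=float(
                    pert.get("knee_damper_gcms_per_deg", 0.0)),
                knee_spring_kg_per_mm=float(
                    pert.get("knee_spring_kg_per_mm", 0.0)),
            ),
            description=spec.get("description", ""),
        )
    return out


def list_scenarios() -> list:
    return sorted(scenario_catalog())


#: parameters whose SI offsets the waveform generator can realize directly
_REALIZABLE = {
    "SL": "step_length", "ST": "step_time", "GRF": "vgrf_peak",
    "PF": "ap_amplitude", "BF": "ap_amplitude",
    "KA": "knee_rom", "AA": "ankle_rom", "HA": "hip_rom",
}


def apply_scenario(
    config: SyntheticTrialConfig,
    scenario: PerturbationScenario | str,
    effect_scale: float = 1.0,
) -> SyntheticTrialConfig:
    """Return a config whose per-side templates realize the scenario.

    A mean SI offset of s percent on parameter P is realized by multiplying
    the left template by (1 + s/200) and the right by (1 - s/200), which
    leaves the bilateral mean unchanged and the stride period intact.
    Moment offsets (AM/KM/HM) are recorded in provenance but emerge from
    dynamics rather than being imposed (see module docstring).
    ``effect_scale`` scales every offset, for dose-response sweeps.
    """
    if isinstance(scenario, str):
        catalog = scenario_catalog()
        if scenario not in catalog:
            raise ParameterError(
                f"unknown scenario {scenario!r}; available: {sorted(catalog)}")
        scenario = catalog[scenario]
    unknown = set(scenario.effects) - set(
        ("SL", "ST", "GRF", "PF", "BF", "KA", "AA", "HA", "AM", "KM", "HM"))
    if unknown:
        raise ParameterError(f"scenario effect map has unknown parameters {sorted(unknown)}")

    effects = {k: v * effect_scale for k, v in scenario.effects.items()}
    attr_off = {
        "step_length": effects.get("SL", 0.0),
        "step_time": effects.get("ST", 0.0),
        "vgrf_peak": effects.get("GRF", 0.0),
        "pushoff_bw": effects.get("PF", 0.0),
        "braking_bw": effects.get("BF", 0.0),
        "knee_rom": effects.get("KA", 0.0),
        "ankle_rom": effects.get("AA", 0.0),
        "hip_rom": effects.get("HA", 0.0),
    }
    new_sides = {}
    for side, sign in (("left", +1.0), ("right", -1.0)):
        tpl = config.side(side)
        updates = {attr: getattr(tpl, attr) * (1.0 + sign * off / 200.0)
                   for attr, off in attr_off.items()}
        new_sides[side] = replace(tpl, **updates)
    return replace(
        config,
        left=new_sides["left"],
        right=new_sides["right"],
        noise=config.noise.scaled(scenario.noise_scale),
        perturbation=scenario.perturbation,
        scenario_name=scenario.name,
        effect_map=effects,
    )
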