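"""High-level pipeline: recording -> events -> parameters -> SI matrix -> score."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .asymmetry import AsymmetryMatrix, build_asymmetry_matrix
from .core import CGAMResults, cgam_score
from .events import GaitEventTable, build_step_sequence, detect_contacts
from .io import TrialRecording, remove_force_baseline
from .parameters import CANONICAL_PARAMS, PairedStepTable, compute_parameters

__all__ = ["detect_events", "analyze_trial", "TrialAnalysis"]


def detect_events(trial: TrialRecording, threshold: float = 20.0,
                  min_phase: float = 0.05) -> GaitEventTable:
    """Detect both sides' gait events from baseline-corrected vertical force.

    Detection runs on the unfiltered force: zero-phase smoothing would blur
    the contact edges and bias the threshold crossings.
    """
    sides = {}
    for side in ("left", "right"):
        fz = remove_force_baseline(trial.forces[side].force)[:, 2]
        sides[side] = detect_contacts(fz, trial.force_rate, threshold, min_phase)
    return build_step_sequence(sides["left"], sides["right"])


@dataclass
class TrialAnalysis:
    """Everything one trial produces on its way to a score."""

    events: GaitEventTable
    table: PairedStepTable
    matrix: AsymmetryMatrix
    result: CGAMResults


def analyze_trial(
    trial: TrialRecording,
    active: Sequence[str] = CANONICAL_PARAMS,
    threshold: float = 20.0,
    min_phase: float = 0.05,
    side_convention: str = "left-minus-right",
    cov=None,
    ridge_policy="auto",
) -> TrialAnalysis:
    """Run the full per-trial pipeline and fit the metric.

    ``cov`` may supply an external (e.g. pooled) covariance model; by default
    the covariance is estimated from this trial's own asymmetry matrix.
    """
    events = detect_events(trial, threshold=threshold, min_phase=min_phase)
    table = compute_parameters(trial, events, active=active)
    matrix = build_asymmetry_matrix(table, side_convention=side_convention)
    result = cgam_score(matrix, cov=cov, ridge_policy=ridge_policy)
    return TrialAnalysis(events=events, table=table, matrix=matrix, result=result)
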