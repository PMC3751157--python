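"""End-to-end lane processing: raw trace → sized fragments → called profile.

The per-lane chain is: sliding-minimum baseline subtraction → provisional peak
finding → color-ratio matrix estimation → spectral separation → final peak
finding → artifact classification → ILS identification and calibration →
fragment sizing.  Sample lanes then pass through allele designation (against
the run's measured ladder when available), the iNTA and stutter filters, the
per-locus zygosity tests and profile assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .expert import (LocusCall, Profile, assemble_profile, call_locus,
                     designate_candidates, filter_inta, filter_stutter)
from .panel import Panel
from .signalproc import (ColorMatrices, RawTrace, SpectralError,
                         apply_color_correction, classify_artifacts,
                         estimate_color_matrix, find_peaks, subtract_baseline)
from .sizing import (ILSFailure, SizeCalibration, SizedFragment,
                     build_calibration, identify_ils, size_fragments)

__all__ = ["ProcessedLane", "process_lane", "measure_ladder", "call_sample"]

log = logging.getLogger("strexpert")


@dataclass
class ProcessedLane:
    """Everything extracted from one lane before allele calling."""

    trace: RawTrace               # baseline-subtracted, spectrally separated
    fragments: list[SizedFragment]
    calibration: SizeCalibration
    color: ColorMatrices


def process_lane(trace: RawTrace, panel: Panel) -> ProcessedLane:
    """Run the full signal-processing and sizing chain on one lane.

    Raises ILSFailure when the lane cannot be sized (no profile possible).
    A lane without enough spectral diversity to estimate the color matrix
    (for example an ILS-only lane, which lights a single dye) is processed
    uncorrected.
    """
    rules = panel.rules
    sub = subtract_baseline(trace, rules.baseline_window_scans)
    provisional = find_peaks(sub, rules)
    try:
        color = estimate_color_matrix(sub, provisional)
        separated = apply_color_correction(sub, color)
    except SpectralError as exc:
        log.info("lane %s: %s; proceeding without color correction",
                 trace.lane_id, exc)
        color = ColorMatrices(np.eye(4), np.eye(4))
        separated = sub
    peaks = find_peaks(separated, rules)
    ils_widths = [p.width_scans for p in peaks if p.channel == panel.ils.channel]
    nominal_width = float(np.median(ils_widths)) if ils_widths else max(
        rules.spike_max_scans + 1.0, 1.0)
    peaks = classify_artifacts(peaks, rules, nominal_width)
    assignment = identify_ils(peaks, panel.ils)
    cal = build_calibration(assignment, panel.ils)
    frags = size_fragments(peaks, cal)
    return ProcessedLane(separated, frags, cal, color)


def measure_ladder(lane: ProcessedLane, panel: Panel,
                   tol_bases: float = 1.0) -> dict[str, dict[str, float]]:
    """Measure per-locus ladder allele sizes from a processed ladder lane.

    For each locus, every ladder rung is matched to the nearest sized fragment
    on the locus channel within ``tol_bases`` of its nominal size.  A locus
    with any unmatched rung is treated as failed and omitted, so designation
    for that locus falls back to the panel's fixed bins.
    """
    usable = [f for f in lane.fragments if not f.flags]
    out: dict[str, dict[str, float]] = {}
    for locus in panel.loci:
        on_channel = [f for f in usable if f.channel == locus.channel]
        measured: dict[str, float] = {}
        for label, nominal in locus.ladder_alleles:
            best = None
            for f in on_channel:
                d = abs(f.size - nominal)
                if d <= tol_bases and (best is None or d < abs(best.size - nominal)):
                    best = f
            if best is None:
                measured = {}
                break
            measured[label] = best.size
        if measured:
            out[locus.name] = measured
        else:
            log.warning("ladder failed for locus %s; fixed bins will be used",
                        locus.name)
    return out


def call_sample(lane: ProcessedLane, panel: Panel,
                ladder: dict[str, dict[str, float]] | None,
                sample_id: str = "") -> Profile:
    """Designate, filter and call every panel locus for one sample lane."""
    sample_frags = [f for f in lane.fragments
                    if f.channel != panel.ils.channel]
    cands = designate_candidates(sample_frags, ladder, panel)
    cands = filter_inta(cands, panel.rules)
    cands = filter_stutter(cands, panel)
    calls: dict[str, LocusCall] = {}
    for locus in panel.loci:
        locus_cands = [c for c in cands if c.locus == locus.name]
        calls[locus.name] = call_locus(locus.name, locus_cands, panel.rules)
    return assemble_profile(calls, panel, sample_id)
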