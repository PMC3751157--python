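"""Synthetic electropherogram generator.

Produces raw four-channel lanes — sample, allelic ladder, and ILS-only — with
recorded ground truth, so every pipeline stage can be exercised without an
instrument.  A lane is built in "pure dye" space as a sum of Gaussian peaks
(alleles, their stutter and iNTA companions, ILS fragments), then passed
through a spectral bleed matrix, given a slow positive baseline drift, additive
Gaussian noise, and optional injected spikes and dye blobs.

Electrophoretic mobility is affine, scan = a·size + b (an optional quadratic
term is supported), and per-fragment sizing jitter emulates run-to-run
migration variability.  Defaults emulate a clean single-source buccal run on a
5 Hz, four-color detector: tall well-balanced heterozygote peaks (peak-height
ratios concentrated near 1), stutter around 6% of the parent, iNTA under 5%,
sub-resolution peak widths (FWHM 0.45 bases, so adjacent one-base pairs are
comfortably single-base resolved).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .panel import Panel
from .signalproc import N_CHANNELS, RawTrace

__all__ = [
    "SimParams",
    "GenotypeSpec",
    "GroundTruth",
    "TruthPeak",
    "default_bleed_matrix",
    "simulate_lane",
    "simulate_ladder_lane",
    "simulate_ils_lane",
    "random_genotype",
]


def default_bleed_matrix() -> np.ndarray:
    """Mild diagonal-dominant spectral crosstalk; columns normalized to sum 1."""
    m = np.array([
        [0.86, 0.07, 0.02, 0.01],
        [0.08, 0.84, 0.08, 0.03],
        [0.04, 0.07, 0.85, 0.08],
        [0.02, 0.02, 0.05, 0.88],
    ], dtype=float)
    return m / m.sum(axis=0, keepdims=True)


@dataclass
class SimParams:
    """Simulator configuration.

    mobility: scan = a·size + b (+ c·size²); with the default 5 Hz scan rate a
    30-minute separation covers roughly 9000 scans, so a = 12 scans/base places
    the 60-600 base window inside it.  ``peak_fwhm_bases`` is the full width at
    half maximum of every fragment peak.  Heights are rfu; heterozygote
    partner heights are drawn with small relative spread so simulated
    peak-height ratios concentrate well above the 0.37 calling floor.
    """

    mobility_a: float = 12.0          # scans per base
    mobility_b: float = 600.0         # scan offset
    mobility_c: float = 0.0           # optional quadratic term (scans/base^2)
    peak_fwhm_bases: float = 0.45
    allele_height_rfu: float = 1800.0
    height_cv: float = 0.08           # relative spread of per-allele heights
    hom_height_factor: float = 1.9    # homozygote single-peak boost
    ils_height_rfu: float = 900.0
    noise_sd_rfu: float = 6.0
    baseline_offset_rfu: float = 40.0
    baseline_drift_rfu: float = 25.0
    bleed_matrix: np.ndarray = field(default_factory=default_bleed_matrix)
    stutter_fraction: float = 0.06
    inta_fraction: float = 0.03
    spike_rate: float = 0.0           # expected spikes per lane
    dyeblob_rate: float = 0.0         # expected dye blobs per lane
    sizing_jitter_sd_bases: float = 0.05
    n_scans: int = 9000
    sample_hz: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.bleed_matrix = np.asarray(self.bleed_matrix, float)
        if self.mobility_a <= 0:
            raise ValueError("mobility_a must be positive")
        if abs(np.linalg.det(self.bleed_matrix)) < 1e-12:
            raise ValueError("bleed_matrix must be invertible")
        for name in ("stutter_fraction", "inta_fraction"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must be in [0, 1)")

    def scan_of(self, size: float) -> float:
        return self.mobility_a * size + self.mobility_b + self.mobility_c * size**2

    def fwhm_scans(self) -> float:
        return self.peak_fwhm_bases * self.mobility_a


@dataclass
class GenotypeSpec:
    """Per-locus genotype: 1-2 allele labels drawn from the ladder labels."""

    alleles: dict[str, tuple[str, ...]]

    def validate(self, panel: Panel) -> None:
        for locus, labels in self.alleles.items():
            loc = panel.locus(locus)
            known = {lab for lab, _ in loc.ladder_alleles}
            for lab in labels:
                if lab not in known:
                    raise ValueError(f"unknown allele {lab!r} at locus {locus}")
            if not 1 <= len(labels) <= 2:
                raise ValueError(f"locus {locus}: need 1-2 alleles")


@dataclass
class TruthPeak:
    """One injected feature, for comparing pipeline output with ground truth."""

    kind: str        # allele | stutter | inta | ils | ladder | spike | dye_blob
    channel: int
    size: Optional[float]
    scan: float
    height: float
    locus: str = ""
    label: str = ""


@dataclass
class GroundTruth:
    peaks: list[TruthPeak]

    def of_kind(self, *kinds: str) -> list[TruthPeak]:
        return [p for p in self.peaks if p.kind in kinds]


def _add_gaussian(pure: np.ndarray, channel: int, scan: float, height: float,
                  fwhm_scans: float) -> None:
    sigma = fwhm_scans / 2.354820045
    n = pure.shape[1]
    lo = max(0, int(scan - 6 * sigma))
    hi = min(n, int(scan + 6 * sigma) + 1)
    x = np.arange(lo, hi)
    pure[channel, lo:hi] += height * np.exp(-0.5 * ((x - scan) / sigma) ** 2)


def _nominal_size(panel: Panel, locus: str, label: str) -> float:
    for lab, size in panel.locus(locus).ladder_alleles:
        if lab == label:
            return size
    raise ValueError(f"unknown allele {label!r} at locus {locus}")


def _finish_lane(pure: np.ndarray, params: SimParams, rng: np.random.Generator,
                 truth: list[TruthPeak], lane_id: str) -> RawTrace:
    """Bleed, drift, noise and injected artifacts applied to a pure-dye lane."""
    n = pure.shape[1]
    fw = params.fwhm_scans()
    n_spikes = rng.poisson(params.spike_rate)
    for _ in range(n_spikes):
        ch = int(rng.integers(N_CHANNELS))
        scan = float(rng.uniform(0.1 * n, 0.95 * n))
        h = float(rng.uniform(300, 2500))
        _add_gaussian(pure, ch, scan, h, 1.2)  # 1-2 scans wide
        truth.append(TruthPeak("spike", ch, None, scan, h))
    n_blobs = rng.poisson(params.dyeblob_rate)
    for _ in range(n_blobs):
        ch = int(rng.integers(N_CHANNELS))
        scan = float(rng.uniform(0.1 * n, 0.95 * n))
        h = float(rng.uniform(200, 900))
        _add_gaussian(pure, ch, scan, h, 3.5 * fw)
        truth.append(TruthPeak("dye_blob", ch, None, scan, h))
    mixed = params.bleed_matrix @ pure
    t = np.arange(n)
    drift = (params.baseline_offset_rfu
             + params.baseline_drift_rfu * (1 + np.sin(2 * np.pi * t / n)) / 2)
    mixed = mixed + drift[None, :]
    if params.noise_sd_rfu > 0:
        mixed = mixed + rng.normal(0.0, params.noise_sd_rfu, mixed.shape)
    return RawTrace(mixed, params.sample_hz, lane_id)


def _add_ils(pure: np.ndarray, panel: Panel, params: SimParams,
             rng: np.random.Generator, truth: list[TruthPeak]) -> None:
    fw = params.fwhm_scans()
    for size in panel.ils.fragment_sizes:
        jitter = rng.normal(0.0, params.sizing_jitter_sd_bases)
        scan = params.scan_of(size + jitter)
        h = params.ils_height_rfu * float(rng.uniform(0.9, 1.1))
        _add_gaussian(pure, panel.ils.channel, scan, h, fw)
        truth.append(TruthPeak("ils", panel.ils.channel, size, scan, h))


def simulate_lane(genotype: GenotypeSpec, panel: Panel, params: SimParams,
                  lane_id: str = "sample") -> tuple[RawTrace, GroundTruth]:
    """Simulate a sample lane for one genotype, with ILS, returning ground truth.

    Each allele contributes a Gaussian peak at its nominal size (plus sizing
    jitter); tetra/pentanucleotide alleles get a stutter companion one repeat
    shorter at ``stutter_fraction`` of the parent height and an iNTA companion
    one base shorter at ``inta_fraction``.  Homozygous loci get a single boosted
    peak.  Alleles must lie within the ILS-anchored sizeable range.
    """
    genotype.validate(panel)
    rng = np.random.default_rng(params.seed)
    lo, hi = min(panel.ils.sizing_subset), max(panel.ils.sizing_subset)
    pure = np.zeros((N_CHANNELS, params.n_scans))
    truth: list[TruthPeak] = []
    for locus_name, labels in genotype.alleles.items():
        locus = panel.locus(locus_name)
        hom = len(set(labels)) == 1
        for label in sorted(set(labels)):
            size = _nominal_size(panel, locus_name, label)
            if not (lo <= size <= hi):
                raise ValueError(
                    f"allele {label} at {locus_name} ({size} bases) outside "
                    f"sizeable range {lo}-{hi}"
                )
            base = params.allele_height_rfu * (
                params.hom_height_factor if hom else 1.0)
            h = base * float(np.exp(rng.normal(0.0, params.height_cv)))
            jitter = rng.normal(0.0, params.sizing_jitter_sd_bases)
            scan = params.scan_of(size + jitter)
            _add_gaussian(pure, locus.channel, scan, h, params.fwhm_scans())
            truth.append(TruthPeak("allele", locus.channel, size, scan, h,
                                   locus_name, label))
            if params.stutter_fraction > 0 and locus.repeat_len > 0:
                ssize = size - locus.repeat_len
                sscan = params.scan_of(ssize + rng.normal(
                    0.0, params.sizing_jitter_sd_bases))
                sh = h * params.stutter_fraction
                _add_gaussian(pure, locus.channel, sscan, sh, params.fwhm_scans())
                truth.append(TruthPeak("stutter", locus.channel, ssize, sscan,
                                       sh, locus_name, label))
            if params.inta_fraction > 0:
                isize = size - 1.0
                iscan = params.scan_of(isize + rng.normal(
                    0.0, params.sizing_jitter_sd_bases))
                ih = h * params.inta_fraction
                _add_gaussian(pure, locus.channel, iscan, ih, params.fwhm_scans())
                truth.append(TruthPeak("inta", locus.channel, isize, iscan, ih,
                                       locus_name, label))
    _add_ils(pure, panel, params, rng, truth)
    trace = _finish_lane(pure, params, rng, truth, lane_id)
    return trace, GroundTruth(truth)


def simulate_ladder_lane(panel: Panel, params: SimParams,
                         lane_id: str = "ladder",
                         omit_loci: tuple[str, ...] = ()
                         ) -> tuple[RawTrace, GroundTruth]:
    """Simulate an allelic-ladder lane: one peak per ladder rung, plus ILS.

    ``omit_loci`` drops a locus's rungs to emulate a partial ladder failure
    (downstream designation then falls back to fixed bins).
    """
    rng = np.random.default_rng(params.seed)
    pure = np.zeros((N_CHANNELS, params.n_scans))
    truth: list[TruthPeak] = []
    for locus in panel.loci:
        if locus.name in omit_loci:
            continue
        for label, size in locus.ladder_alleles:
            jitter = rng.normal(0.0, params.sizing_jitter_sd_bases)
            scan = params.scan_of(size + jitter)
            h = params.ils_height_rfu * float(rng.uniform(0.85, 1.15))
            _add_gaussian(pure, locus.channel, scan, h, params.fwhm_scans())
            truth.append(TruthPeak("ladder", locus.channel, size, scan, h,
                                   locus.name, label))
    _add_ils(pure, panel, params, rng, truth)
    trace = _finish_lane(pure, params, rng, truth, lane_id)
    return trace, GroundTruth(truth)


def simulate_ils_lane(panel: Panel, params: SimParams,
                      lane_id: str = "ils") -> tuple[RawTrace, GroundTruth]:
    """Simulate a lane carrying only the internal lane standard."""
    rng = np.random.default_rng(params.seed)
    pure = np.zeros((N_CHANNELS, params.n_scans))
    truth: list[TruthPeak] = []
    _add_ils(pure, panel, params, rng, truth)
    trace = _finish_lane(pure, params, rng, truth, lane_id)
    return trace, GroundTruth(truth)


def random_genotype(panel: Panel, rng: np.random.Generator,
                    het_prob: float = 0.7) -> GenotypeSpec:
    """Draw a random single-source genotype from the panel's ladder alleles."""
    alleles: dict[str, tuple[str, ...]] = {}
    for locus in panel.loci:
        labels = [lab for lab, _ in locus.ladder_alleles]
        if locus.name == "AMEL":
            alleles[locus.name] = ("X", "Y") if rng.random() < 0.5 else ("X", "X")
            continue
        if rng.random() < het_prob and len(labels) >= 2:
            pick = rng.choice(len(labels), size=2, replace=False)
            alleles[locus.name] = (labels[pick[0]], labels[pick[1]])
        else:
            alleles[locus.name] = (labels[int(rng.integers(len(labels)))],) * 2
    return GenotypeSpec(alleles)
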