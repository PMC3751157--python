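"""Raw-trace signal processing: baseline subtraction, spectral separation,
peak detection, artifact classification, and lane finding.

The processing chain mirrors an on-instrument pipeline: a sliding-window
minimum baseline is subtracted per detector channel; peaks are found on the
baseline-subtracted signal; per-peak detector-response ratios are clustered
into a four-color ratio matrix whose inverse (the color correction matrix)
spectrally separates the channels; finally peaks are re-detected on the
separated trace and screened for spikes, dye blobs and pull-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal as sps

from .panel import CallingRules

__all__ = [
    "RawTrace",
    "Peak",
    "ColorMatrices",
    "SpectralError",
    "subtract_baseline",
    "estimate_noise_center",
    "find_peaks",
    "estimate_color_matrix",
    "apply_color_correction",
    "classify_artifacts",
    "find_lane_centers",
]

N_CHANNELS = 4


class SpectralError(RuntimeError):
    """Raised when the four dye ratio clusters cannot be resolved."""


@dataclass
class RawTrace:
    """A per-lane four-channel fluorescence signal sampled at fixed rate.

    ``channels`` is a (4, n_scans) float array in rfu.  The same container is
    used for raw, baseline-subtracted and spectrally separated traces.
    """

    channels: np.ndarray
    sample_hz: float = 5.0
    lane_id: str = ""

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[0] != N_CHANNELS:
            raise ValueError("channels must be a (4, n_scans) array")
        if self.sample_hz <= 0:
            raise ValueError("sample_hz must be positive")

    @property
    def n_scans(self) -> int:
        return self.channels.shape[1]


@dataclass
class Peak:
    """A detected apex on one detector channel.

    ``height`` is rfu above the channel's noise center; ``width_scans`` is the
    interpolated full width at half maximum, while ``span_scans`` counts the
    raw collection scans above half maximum (the quantity the spike rule is
    stated in).  ``flags`` collects artifact labels ({"spike", "dye_blob",
    "pull_up"}); a flagged peak never becomes an allele candidate.
    """

    channel: int
    apex_scan: int
    height: float
    width_scans: float
    span_scans: int = 0
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("peak height must be positive")
        self.width_scans = max(float(self.width_scans), 1.0)
        if self.span_scans <= 0:
            self.span_scans = int(round(self.width_scans))


@dataclass
class ColorMatrices:
    """Four-color ratio matrix and its inverse (the correction matrix).

    Column j of ``ratio_matrix`` is the normalized detector-response vector of
    dye j (columns sum to 1); multiplying a spectrally mixed trace by
    ``correction_matrix`` recovers the per-dye signals.
    """

    ratio_matrix: np.ndarray
    correction_matrix: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.ratio_matrix, float)
        c = np.asarray(self.correction_matrix, float)
        if r.shape != (4, 4) or c.shape != (4, 4):
            raise ValueError("matrices must be 4x4")
        if not np.allclose(r.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("ratio matrix columns must sum to 1")
        if not np.allclose(c @ r, np.eye(4), atol=1e-8):
            raise ValueError("correction_matrix must invert ratio_matrix")
        self.ratio_matrix, self.correction_matrix = r, c

    @classmethod
    def from_ratio(cls, ratio: np.ndarray) -> "ColorMatrices":
        ratio = np.asarray(ratio, float)
        try:
            inv = np.linalg.inv(ratio)
        except np.linalg.LinAlgError as exc:
            raise SpectralError("color ratio matrix is singular") from exc
        return cls(ratio, inv)


def subtract_baseline(trace: RawTrace, window_scans: int) -> RawTrace:
    """Subtract the sliding-window minimum baseline from each channel.

    At each scan the baseline is the minimum signal within a centered window
    of ``window_scans`` scans, truncated at the trace ends.  ``window_scans``
    must be odd, >= 1 and no longer than the trace.
    """
    if window_scans < 1 or window_scans % 2 == 0:
        raise ValueError("window_scans must be odd and >= 1")
    if window_scans > trace.n_scans:
        raise ValueError("window_scans exceeds trace length")
    # constant +inf padding makes the filter equivalent to truncating the
    # window at the edges
    baseline = ndimage.minimum_filter1d(
        trace.channels, size=window_scans, axis=1, mode="constant", cval=np.inf
    )
    return RawTrace(trace.channels - baseline, trace.sample_hz, trace.lane_id)


def estimate_noise_center(trace: RawTrace, channel: int,
                          peaks: list[Peak] | None = None,
                          exclude_halfwidth_scans: int = 12) -> float:
    """Robust center (median) of a channel's signal excluding peak regions.

    ``peaks`` are previously detected peaks on this channel; a window of
    ±``exclude_halfwidth_scans`` around each apex is masked out before taking
    the median.  Deterministic for fixed input.
    """
    y = trace.channels[channel]
    if y.size == 0:
        raise ValueError("empty trace")
    mask = np.ones(y.size, dtype=bool)
    for p in peaks or []:
        if p.channel != channel:
            continue
        lo = max(0, p.apex_scan - exclude_halfwidth_scans)
        hi = min(y.size, p.apex_scan + exclude_halfwidth_scans + 1)
        mask[lo:hi] = False
    if not mask.any():
        mask[:] = True
    return float(np.median(y[mask]))


def _fwhm(y: np.ndarray, apex: int) -> tuple[float, int]:
    """FWHM (interpolated) and raw-scan span above half maximum at an apex."""
    half = y[apex] / 2.0
    i = apex
    while i > 0 and y[i - 1] > half:
        i -= 1
    if i > 0 and y[i] != y[i - 1]:  # crossing between i-1 and i
        left = i - (y[i] - half) / (y[i] - y[i - 1])
    else:
        left = float(i)
    n = y.size
    j = apex
    while j < n - 1 and y[j + 1] > half:
        j += 1
    if j < n - 1 and y[j] != y[j + 1]:
        right = j + (y[j] - half) / (y[j] - y[j + 1])
    else:
        right = float(j)
    return max(right - left, 1.0), j - i + 1


def find_peaks(trace: RawTrace, rules: CallingRules,
               channels: list[int] | None = None) -> list[Peak]:
    """Detect candidate peaks strictly above the analytical threshold.

    A local maximum is retained only when its height is > ``rules.
    analytical_threshold_rfu`` above the channel's noise center.  Heights are
    reported relative to that center; widths are FWHM in scans.  Peaks are
    returned sorted by apex scan.
    """
    out: list[Peak] = []
    for ch in channels if channels is not None else range(N_CHANNELS):
        y = trace.channels[ch]
        # provisional detection to mask peaks out of the noise estimate
        apexes, _ = sps.find_peaks(y, height=rules.analytical_threshold_rfu / 2)
        provisional = [Peak(ch, int(a), max(float(y[a]), 1e-9), 1.0) for a in apexes]
        center = estimate_noise_center(trace, ch, provisional)
        apexes, _ = sps.find_peaks(y)
        for a in apexes:
            h = float(y[a]) - center
            if h > rules.analytical_threshold_rfu:
                w, span = _fwhm(y, int(a))
                out.append(Peak(ch, int(a), h, w, span))
    out.sort(key=lambda p: (p.apex_scan, p.channel))
    return out


def _cluster_ratios(vectors: np.ndarray, cos_threshold: float = 0.1) -> list[np.ndarray]:
    """Greedy clustering of normalized detector-ratio vectors by cosine distance."""
    centers: list[np.ndarray] = []
    members: list[list[np.ndarray]] = []
    for v in vectors:
        u = v / np.linalg.norm(v)
        best, best_d = -1, np.inf
        for k, c in enumerate(centers):
            d = 1.0 - float(u @ (c / np.linalg.norm(c)))
            if d < best_d:
                best, best_d = k, d
        if best >= 0 and best_d < cos_threshold:
            members[best].append(v)
            centers[best] = np.mean(members[best], axis=0)
        else:
            centers.append(v.copy())
            members.append([v])
    return [np.mean(m, axis=0) for m in members]


def estimate_color_matrix(trace: RawTrace, peaks: list[Peak]) -> ColorMatrices:
    """Build the four-color ratio matrix from per-peak detector ratios.

    For each detected peak the 4-vector of detector signals at the apex scan is
    normalized and the vectors are grouped into clusters; each dye must
    contribute at least one peak.  Cluster means, normalized to unit column
    sum and ordered by dominant detector, form the ratio matrix; the
    correction matrix is its inverse.
    """
    if not peaks:
        raise SpectralError("insufficient spectral diversity: no peaks")
    apexes = sorted({p.apex_scan for p in peaks})
    vecs = []
    for a in apexes:
        v = trace.channels[:, a].astype(float)
        v = np.clip(v, 0.0, None)
        s = v.sum()
        if s > 0:
            vecs.append(v / s)
    clusters = _cluster_ratios(np.array(vecs))
    if len(clusters) < 4:
        raise SpectralError(
            f"insufficient spectral diversity: {len(clusters)} ratio clusters < 4"
        )
    # keep the 4 most populated-dominant clusters: one per dominant detector
    by_dom: dict[int, np.ndarray] = {}
    for c in clusters:
        dom = int(np.argmax(c))
        if dom not in by_dom or c[dom] > by_dom[dom][dom]:
            by_dom[dom] = c
    if len(by_dom) < 4:
        raise SpectralError(
            "insufficient spectral diversity: fewer than 4 dominant detectors"
        )
    ratio = np.column_stack([by_dom[d] / by_dom[d].sum() for d in range(4)])
    return ColorMatrices.from_ratio(ratio)


def apply_color_correction(trace: RawTrace, m: ColorMatrices) -> RawTrace:
    """Spectrally separate a trace by applying the correction matrix per scan."""
    if trace.channels.shape[0] != 4:
        raise ValueError("trace must have 4 channels")
    return RawTrace(m.correction_matrix @ trace.channels,
                    trace.sample_hz, trace.lane_id)


def classify_artifacts(peaks: list[Peak], rules: CallingRules,
                       nominal_width_scans: float) -> list[Peak]:
    """Flag spikes, dye blobs and pull-up among detected peaks.

    A spike spans no more than ``rules.spike_max_scans`` raw collection scans
    above half maximum; a dye blob is wider (FWHM) than
    ``rules.dyeblob_width_multiple`` times the nominal fragment width (median
    ILS peak FWHM for the lane).  Pull-up is a peak
    coincident (within ±``rules.pullup_scan_tol`` scans) with a peak in another
    channel at least ``rules.pullup_height_multiple`` times taller.  Returns
    new Peak objects with flags set; flagged peaks are excluded from allele
    candidacy downstream.
    """
    if nominal_width_scans <= 0:
        raise ValueError("nominal_width_scans must be positive")
    out = []
    for p in peaks:
        flags = set(p.flags)
        if p.span_scans <= rules.spike_max_scans:
            flags.add("spike")
        if p.width_scans > rules.dyeblob_width_multiple * nominal_width_scans:
            flags.add("dye_blob")
        for q in peaks:
            if (q.channel != p.channel
                    and abs(q.apex_scan - p.apex_scan) <= rules.pullup_scan_tol
                    and q.height >= rules.pullup_height_multiple * p.height):
                flags.add("pull_up")
                break
        out.append(replace(p, flags=flags))
    return out


def find_lane_centers(waveform: np.ndarray, n_lanes: int,
                      smooth_sigma: float = 3.0) -> list[int]:
    """Locate separation-channel centers in a reflected-intensity waveform.

    The optical scanner sweeps laser light across the separation channels and
    records reflected intensity vs position; each channel produces a local
    feature whose apex marks the lane center.  The waveform is smoothed with a
    symmetric Gaussian kernel (``smooth_sigma`` samples) to suppress detector
    noise — a symmetric kernel leaves the apex of a symmetric feature in
    place.  Returns exactly ``n_lanes`` strictly increasing apex positions
    (the ``n_lanes`` most prominent local maxima).
    """
    if n_lanes < 1:
        raise ValueError("n_lanes must be >= 1")
    y = np.asarray(waveform, float)
    if smooth_sigma > 0:
        y = ndimage.gaussian_filter1d(y, smooth_sigma)
    apexes, props = sps.find_peaks(y, prominence=0.0)
    if apexes.size < n_lanes:
        raise ValueError(
            f"only {apexes.size} features detectable, need {n_lanes}"
        )
    order = np.argsort(props["prominences"])[::-1][:n_lanes]
    return sorted(int(a) for a in apexes[order])
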