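"""Internal-lane-standard identification, scan-to-base calibration, fragment
sizing and the separation-resolution metric R.

Every lane carries a co-electrophoresed internal lane standard (ILS) of
fragments of known size.  Detected ILS peaks are matched to the expected
fragment list by an order-preserving dynamic-programming alignment scored on
spacing consistency; the 20-fragment sizing subset (80-550 bases for the
default standard — the 60 and 600 base end fragments are excluded) anchors a
strictly monotone piecewise-linear scan→base mapping used to size every
sample fragment in the lane.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .panel import ILSDef
from .signalproc import Peak

__all__ = [
    "SizeCalibration",
    "SizedFragment",
    "ILSFailure",
    "identify_ils",
    "build_calibration",
    "size_fragments",
    "resolution_R",
]


class ILSFailure(RuntimeError):
    """Raised when the ILS cannot be identified: the lane is not sizeable."""


@dataclass
class SizeCalibration:
    """Monotone scan→base mapping anchored on identified ILS fragments."""

    anchor_scans: np.ndarray   # apex scans of the sizing-subset fragments
    anchor_sizes: np.ndarray   # their known sizes in bases
    method: str = "piecewise-linear"

    def __post_init__(self) -> None:
        s = np.asarray(self.anchor_scans, float)
        z = np.asarray(self.anchor_sizes, float)
        if s.size != z.size or s.size < 2:
            raise ValueError("calibration needs >= 2 matching anchors")
        if not (np.all(np.diff(s) > 0) and np.all(np.diff(z) > 0)):
            raise ValueError("anchors must be strictly increasing in scan and size")
        self.anchor_scans, self.anchor_sizes = s, z

    def in_range(self, scan: float) -> bool:
        return self.anchor_scans[0] <= scan <= self.anchor_scans[-1]

    def size_at(self, scan: float | np.ndarray) -> float | np.ndarray:
        """Interpolated size in bases (defined only within the anchored range)."""
        return np.interp(scan, self.anchor_scans, self.anchor_sizes)

    def local_slope(self, scan: float) -> float:
        """d(size)/d(scan) of the flanking anchor segment, for width conversion."""
        i = int(np.clip(np.searchsorted(self.anchor_scans, scan) - 1,
                        0, self.anchor_scans.size - 2))
        ds = self.anchor_scans[i + 1] - self.anchor_scans[i]
        dz = self.anchor_sizes[i + 1] - self.anchor_sizes[i]
        return float(dz / ds)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "anchors": [[float(s), float(z)] for s, z in
                        zip(self.anchor_scans, self.anchor_sizes)],
        }


@dataclass
class SizedFragment:
    """A detected peak with a calibrated size in bases."""

    peak: Peak
    size: float
    width_bases: float
    size_sd: float | None = None
    flags: set[str] = field(default_factory=set)

    @property
    def channel(self) -> int:
        return self.peak.channel

    @property
    def height(self) -> float:
        return self.peak.height


def _dp_align(scans: np.ndarray, sizes: np.ndarray, slope: float,
              skip_peak_cost: float, miss_frag_cost: float
              ) -> list[tuple[int, int]]:
    """Order-preserving assignment of detected peaks to expected fragments.

    Minimises the summed spacing-pattern mismatch |Δscan − slope·Δsize| between
    consecutive matched pairs, with fixed penalties for skipping a (spurious)
    peak or missing an expected fragment.  Returns (peak index, fragment index)
    pairs.
    """
    n, m = scans.size, sizes.size
    INF = np.inf
    cost = np.full((n, m), INF)
    back: dict[tuple[int, int], tuple[int, int] | None] = {}
    for i in range(n):
        for j in range(m):
            c = skip_peak_cost * i + miss_frag_cost * j  # start pair
            prev = None
            for i2 in range(i):
                for j2 in range(j):
                    if cost[i2, j2] == INF:
                        continue
                    mism = abs((scans[i] - scans[i2]) - slope * (sizes[j] - sizes[j2]))
                    cand = (cost[i2, j2] + mism
                            + skip_peak_cost * (i - i2 - 1)
                            + miss_frag_cost * (j - j2 - 1))
                    if cand < c:
                        c, prev = cand, (i2, j2)
            cost[i, j] = c
            back[(i, j)] = prev
    best, best_c = None, INF
    for i in range(n):
        for j in range(m):
            c = (cost[i, j] + skip_peak_cost * (n - 1 - i)
                 + miss_frag_cost * (m - 1 - j))
            if c < best_c:
                best, best_c = (i, j), c
    pairs = []
    node = best
    while node is not None:
        pairs.append(node)
        node = back[node]
    return pairs[::-1]


def identify_ils(peaks: list[Peak], ils: ILSDef) -> dict[float, Peak]:
    """Match detected ILS-channel peaks to the expected fragment sizes.

    Flagged peaks (spikes, dye blobs, pull-up) are excluded before matching.
    Returns a mapping {fragment size in bases → Peak} for every fragment that
    could be assigned; raises ILSFailure when fewer sizing-subset fragments are
    assignable than the subset requires.
    """
    clean = sorted((p for p in peaks if not p.flags and p.channel == ils.channel),
                   key=lambda p: p.apex_scan)
    sizes = np.asarray(ils.fragment_sizes, float)
    need = len(ils.sizing_subset)
    if len(clean) < need:
        raise ILSFailure(
            f"ILS failure: {len(clean)} usable ILS peaks < {need} required"
        )
    scans = np.array([p.apex_scan for p in clean], float)
    if len(clean) == sizes.size:
        # fast path: in-order assignment, accepted when the spacing pattern is
        # consistent with a single mobility fit
        coef = np.polyfit(sizes, scans, 1)
        resid = scans - np.polyval(coef, sizes)
        gap = float(np.median(np.diff(scans)))
        if np.abs(resid).max() < 0.35 * gap:
            return {float(z): p for z, p in zip(sizes, clean)}
    slope = (scans[-1] - scans[0]) / (sizes[-1] - sizes[0])
    pairs: list[tuple[int, int]] = []
    for _ in range(3):  # refine the mobility estimate against the assignment
        gap = float(np.median(np.diff(sizes))) * slope
        pairs = _dp_align(scans, sizes, slope,
                          skip_peak_cost=0.25 * gap, miss_frag_cost=0.5 * gap)
        if len(pairs) >= 2:
            i, j = np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs])
            slope = float(np.polyfit(sizes[j], scans[i], 1)[0])
    assignment = {float(sizes[j]): clean[i] for i, j in pairs}
    assigned_subset = [z for z in ils.sizing_subset if z in assignment]
    if len(assigned_subset) < need:
        raise ILSFailure(
            f"ILS failure: only {len(assigned_subset)} of {need} "
            "sizing-subset fragments assigned"
        )
    return assignment


def build_calibration(assignment: dict[float, Peak], ils: ILSDef) -> SizeCalibration:
    """Anchor the scan→base calibration on the sizing-subset fragments only."""
    missing = [z for z in ils.sizing_subset if z not in assignment]
    if missing:
        raise ILSFailure(f"sizing-subset fragments not assigned: {missing}")
    scans = np.array([assignment[z].apex_scan for z in ils.sizing_subset], float)
    sizes = np.array(ils.sizing_subset, float)
    if not np.all(np.diff(scans) > 0):
        raise ILSFailure("ILS apex order is not monotone in size")
    return SizeCalibration(scans, sizes)


def size_fragments(peaks: list[Peak], cal: SizeCalibration) -> list[SizedFragment]:
    """Assign a fractional size in bases to each unflagged peak.

    Sizes come from piecewise-linear interpolation between the flanking
    calibration anchors; peaks outside the anchored scan range are flagged
    ``out_of_range`` and given the clamped boundary size, never used for
    designation.  Flagged (artifact) peaks are passed through with their flags.
    """
    out: list[SizedFragment] = []
    for p in peaks:
        flags = set(p.flags)
        if not cal.in_range(p.apex_scan):
            flags.add("out_of_range")
        size = float(cal.size_at(p.apex_scan))
        width_bases = p.width_scans * cal.local_slope(p.apex_scan)
        out.append(SizedFragment(p, size, width_bases, flags=flags))
    return out


def resolution_R(f1: SizedFragment, f2: SizedFragment) -> float:
    """Separation resolution R = Δsize / (w1 + w2), widths as FWHM in bases.

    An adjacent pair is single-base resolved when its separation is about one
    base and R meets the single-base threshold (0.3 for the default rules).
    """
    if f1.channel != f2.channel:
        raise ValueError("resolution is defined within one channel")
    if f1.size > f2.size:
        f1, f2 = f2, f1
    wsum = f1.width_bases + f2.width_bases
    if wsum <= 0:
        raise ValueError("zero peak widths")
    return (f2.size - f1.size) / wsum
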