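"""File formats and run orchestration.

Mirrors the three operator-facing output files of the instrument: an annotated
electropherogram image (PNG here; call boxes gray for confident calls, red for
questionable), a .fsa container of the processed traces (a minimal big-endian
ABIF subset with DATA1-DATA4 tags), and a CMF-style XML profile for database
upload, written only when the profile passes the CODIS-loci export gate.

Traces also round-trip through a documented JSON format
``{"lane_id", "sample_hz", "channels": [[rfu, ...] x 4]}``.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np

from .expert import Profile
from .panel import Panel, default_panel, load_panel
from .pipeline import ProcessedLane, call_sample, measure_ladder, process_lane
from .sizing import ILSFailure

__all__ = [
    "read_trace_json", "write_trace_json", "read_fsa", "write_fsa",
    "write_cmf", "render_electropherogram", "RunManifest", "RunResult",
    "run_pipeline",
]

from .signalproc import RawTrace

log = logging.getLogger("strexpert")


# ---------------------------------------------------------------- JSON traces

def write_trace_json(trace: RawTrace, path: str | Path) -> None:
    doc = {
        "lane_id": trace.lane_id,
        "sample_hz": trace.sample_hz,
        "channels": [np.round(ch, 4).tolist() for ch in trace.channels],
    }
    Path(path).write_text(json.dumps(doc))


def read_trace_json(path: str | Path) -> RawTrace:
    doc = json.loads(Path(path).read_text())
    return RawTrace(np.array(doc["channels"], float),
                    float(doc.get("sample_hz", 5.0)),
                    str(doc.get("lane_id", "")))


# ------------------------------------------------------- minimal ABIF (.fsa)

_DIR_FMT = ">4sihhiiii"          # name, number, etype, esize, nelem, dsize, doff, handle
_SHORT = 4                        # ABIF element type code for int16


def write_fsa(trace: RawTrace, path: str | Path) -> None:
    """Write the four channels as DATA1-DATA4 int16 tags (big-endian ABIF).

    Signals are rounded and clipped to the int16 range.  Only the subset of
    ABIF needed to open the trace in fragment-analysis viewers is produced:
    the 128-byte header, a directory, and the four DATA tags.
    """
    entries = []
    blobs = []
    offset = 128
    for i in range(4):
        data = np.clip(np.round(trace.channels[i]), -32768, 32767).astype(">i2")
        blob = data.tobytes()
        entries.append((b"DATA", i + 1, _SHORT, 2, data.size, len(blob), offset))
        blobs.append(blob)
        offset += len(blob)
    dir_offset = offset
    with open(path, "wb") as fh:
        fh.write(b"ABIF")
        fh.write(struct.pack(">h", 101))
        fh.write(struct.pack(_DIR_FMT, b"tdir", 1, 1023, 28,
                             len(entries), 28 * len(entries), dir_offset, 0))
        fh.write(b"\x00" * (128 - fh.tell()))
        for blob in blobs:
            fh.write(blob)
        for name, number, etype, esize, nelem, dsize, doff in entries:
            fh.write(struct.pack(_DIR_FMT, name, number, etype, esize,
                                 nelem, dsize, doff, 0))


def read_fsa(path: str | Path) -> RawTrace:
    """Read DATA1-DATA4 channels from a minimal ABIF container."""
    raw = Path(path).read_bytes()
    if raw[:4] != b"ABIF":
        raise ValueError("not an ABIF file")
    (_, _, _, _, nelem, _, dir_off, _) = struct.unpack(_DIR_FMT, raw[6:6 + 28])
    channels: dict[int, np.ndarray] = {}
    for k in range(nelem):
        entry = raw[dir_off + 28 * k: dir_off + 28 * (k + 1)]
        name, number, etype, esize, n, dsize, doff, _ = struct.unpack(_DIR_FMT, entry)
        if name == b"DATA" and 1 <= number <= 4:
            if dsize <= 4:   # small data stored inline in the offset field
                buf = entry[20:20 + dsize]
            else:
                buf = raw[doff:doff + dsize]
            channels[number - 1] = np.frombuffer(buf, dtype=">i2").astype(float)
    if sorted(channels) != [0, 1, 2, 3]:
        raise ValueError("ABIF file lacks DATA1-DATA4 tags")
    return RawTrace(np.vstack([channels[i] for i in range(4)]),
                    lane_id=Path(path).stem)


# ------------------------------------------------------------------ CMF XML

def write_cmf(profile: Profile, panel: Panel, path: str | Path | None = None,
              metadata: dict | None = None) -> ET.Element:
    """Serialize a profile as a simplified CODIS-CMF-style XML document.

    One ``Specimen`` element carries one ``Locus`` element per *called* locus
    (no-call loci are never exported).  Refuses profiles that fail the
    ten-called-CODIS-loci export gate.
    """
    if not profile.cmf_eligible:
        raise ValueError(
            f"profile {profile.sample_id!r} is not CMF-eligible "
            f"({profile.called_codis_count} called CODIS loci)"
        )
    root = ET.Element("CODISImportFile")
    header = ET.SubElement(root, "Header")
    for key, val in (metadata or {}).items():
        ET.SubElement(header, key).text = str(val)
    specimen = ET.SubElement(root, "Specimen",
                             id=profile.sample_id or "unknown")
    for locus in panel.loci:
        call = profile.calls[locus.name]
        if not call.called:
            continue
        el = ET.SubElement(specimen, "Locus", name=locus.name,
                           zygosity=call.zygosity.value)
        for allele in call.genotype:
            ET.SubElement(el, "Allele").text = allele
    if path is not None:
        ET.ElementTree(root).write(path, xml_declaration=True,
                                   encoding="unicode")
    return root


# ---------------------------------------------------------------- rendering

def render_electropherogram(lane: ProcessedLane, panel: Panel,
                            path: str | Path,
                            profile: Profile | None = None) -> None:
    """Render one subplot per dye channel with gray/red allele call boxes.

    Deterministic for fixed input: fixed figure geometry and no timestamps.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    cal = lane.calibration
    colors = ["tab:blue", "tab:green", "black", "tab:red"]
    fig, axes = plt.subplots(4, 1, figsize=(11, 8), sharex=True)
    scan0, scan1 = cal.anchor_scans[0], cal.anchor_scans[-1]
    scans = np.arange(int(scan0), int(scan1))
    sizes = cal.size_at(scans)
    for ch, ax in enumerate(axes):
        ax.plot(sizes, lane.trace.channels[ch, scans[0]:scans[-1] + 1],
                lw=0.6, color=colors[ch])
        ax.set_ylabel(f"ch{ch} (rfu)")
    if profile is not None:
        by_locus = {l.name: l for l in panel.loci}
        for name, call in profile.calls.items():
            ch = by_locus[name].channel
            face = "lightgray" if call.display == "gray" else "lightcoral"
            for cand in call.candidates:
                axes[ch].annotate(
                    cand.label, (cand.size, cand.height),
                    textcoords="offset points", xytext=(0, 6), fontsize=6,
                    ha="center", bbox=dict(boxstyle="square,pad=0.15",
                                           fc=face, ec="black", lw=0.4))
    axes[-1].set_xlabel("size (bases)")
    fig.suptitle(f"lane {lane.trace.lane_id}")
    fig.savefig(path, dpi=110, metadata={"Software": None})
    plt.close(fig)


# ----------------------------------------------------------- run manifests

@dataclass
class LaneEntry:
    sample_id: str
    role: str                    # sample | ladder | ils
    trace: str                   # path to trace JSON or .fsa


@dataclass
class RunManifest:
    """One instrument run: up to five sample lanes plus one ladder lane."""

    lanes: list[LaneEntry]
    panel: str | None = None     # panel JSON path; None = bundled default
    out_dir: str = "."
    no_ladder: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        samples = [l for l in self.lanes if l.role == "sample"]
        ladders = [l for l in self.lanes if l.role == "ladder"]
        if not 1 <= len(samples) <= 5:
            raise ValueError("between one and five sample lanes required")
        if not self.no_ladder and len(ladders) != 1:
            raise ValueError("exactly one ladder lane required "
                             "(or set no_ladder)")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        doc = json.loads(Path(path).read_text())
        lanes = [LaneEntry(**l) for l in doc["lanes"]]
        return cls(lanes=lanes, panel=doc.get("panel"),
                   out_dir=doc.get("out_dir", "."),
                   no_ladder=bool(doc.get("no_ladder", False)),
                   seed=int(doc.get("seed", 0)))


@dataclass
class RunResult:
    profiles: dict[str, Profile]
    failed: dict[str, str]              # sample_id -> reason
    outputs: dict[str, list[str]] = field(default_factory=dict)


def _load_trace(path: str | Path) -> RawTrace:
    p = Path(path)
    if p.suffix.lower() == ".fsa":
        return read_fsa(p)
    return read_trace_json(p)


def run_pipeline(manifest: RunManifest) -> RunResult:
    """Process every lane of a run and write the per-sample output files.

    For each sample lane the chain produces (a) an annotated electropherogram
    PNG, (b) a .fsa of the processed traces, and (c) a CMF XML when the
    profile passes the export gate.  An ILS failure marks the sample failed
    with no profile; a detected mixture is rejected with no CMF.
    """
    panel = load_panel(manifest.panel) if manifest.panel else default_panel()
    out_dir = Path(manifest.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig()
    ladder = None
    if not manifest.no_ladder:
        entry = next(l for l in manifest.lanes if l.role == "ladder")
        try:
            lane = process_lane(_load_trace(entry.trace), panel)
            ladder = measure_ladder(lane, panel)
        except ILSFailure as exc:
            log.warning("ladder lane failed (%s); using fixed bins", exc)
            ladder = None
    result = RunResult({}, {})
    for entry in manifest.lanes:
        if entry.role != "sample":
            continue
        files: list[str] = []
        try:
            lane = process_lane(_load_trace(entry.trace), panel)
        except ILSFailure as exc:
            log.warning("sample %s failed: %s", entry.sample_id, exc)
            result.failed[entry.sample_id] = str(exc)
            continue
        profile = call_sample(lane, panel, ladder, entry.sample_id)
        result.profiles[entry.sample_id] = profile
        png = out_dir / f"{entry.sample_id}.png"
        render_electropherogram(lane, panel, png, profile)
        files.append(str(png))
        fsa = out_dir / f"{entry.sample_id}.fsa"
        write_fsa(lane.trace, fsa)
        files.append(str(fsa))
        if profile.status != "mixture_rejected" and profile.cmf_eligible:
            cmf = out_dir / f"{entry.sample_id}.cmf.xml"
            write_cmf(profile, panel, cmf)
            files.append(str(cmf))
        prof_json = out_dir / f"{entry.sample_id}.profile.json"
        prof_json.write_text(json.dumps(_profile_dict(profile), indent=1))
        files.append(str(prof_json))
        result.outputs[entry.sample_id] = files
    return result


def _profile_dict(profile: Profile) -> dict:
    return {
        "sample_id": profile.sample_id,
        "status": profile.status,
        "called_codis_count": profile.called_codis_count,
        "cmf_eligible": profile.cmf_eligible,
        "loci": {
            name: {
                "genotype": list(call.genotype),
                "zygosity": call.zygosity.value,
                "display": call.display,
            }
            for name, call in profile.calls.items()
        },
    }
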