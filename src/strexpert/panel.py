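"""Assay definition: dye channels, STR loci, internal lane standard, calling rules.

Every threshold used by the signal-processing and allele-calling stages lives
here, in one validated configuration object, so no rule constant is duplicated
elsewhere in the codebase.  The bundled default panel is a PowerPlex-16-style
16-locus assay (15 STRs + amelogenin) on three dye channels, with the 22-fragment
ILS600 size standard on the fourth channel.  Allele nominal sizes in the bundled
panel are plausible configuration values, not measured ground truth.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field, model_validator

__all__ = [
    "DyeChannel",
    "LocusDef",
    "ILSDef",
    "CallingRules",
    "Panel",
    "PanelError",
    "load_panel",
    "default_panel",
    "fixed_bin_lookup",
]


class PanelError(ValueError):
    """Raised when a panel configuration violates its invariants."""


class DyeChannel(BaseModel):
    """One of the four detector colors."""

    index: int = Field(ge=0, le=3)
    name: str


class LocusDef(BaseModel):
    """A single STR locus (or amelogenin, modelled as repeat_len 0).

    ``ladder_alleles`` are (label, nominal size in bases) pairs for the rungs of
    the allelic ladder; ``fixed_bins`` are the fallback designation bins used
    when the ladder lane fails in a run.
    """

    name: str
    channel: int = Field(ge=0, le=3)
    repeat_len: int = Field(ge=0, le=5)
    ladder_alleles: list[tuple[str, float]]
    fixed_bins: list[tuple[str, float]]
    is_codis: bool = False
    stutter_threshold: float = Field(gt=0.0, lt=1.0)

    @model_validator(mode="after")
    def _check(self) -> "LocusDef":
        sizes = [s for _, s in self.ladder_alleles]
        if sizes != sorted(sizes) or len(set(sizes)) != len(sizes):
            raise ValueError(
                f"locus {self.name}: ladder allele sizes must be strictly increasing"
            )
        if not self.fixed_bins:
            raise ValueError(f"locus {self.name}: fixed_bins must be nonempty")
        return self

    @property
    def size_range(self) -> tuple[float, float]:
        """(min, max) nominal size over ladder alleles and fixed bins."""
        sizes = [s for _, s in self.ladder_alleles] + [s for _, s in self.fixed_bins]
        return min(sizes), max(sizes)


class ILSDef(BaseModel):
    """Internal lane standard: co-electrophoresed fragments of known size.

    The default standard carries 22 fragments spanning 60-600 bases; the 20
    interior fragments from 80 to 550 bases form the sizing subset actually
    used as calibration anchors.
    """

    channel: int = Field(ge=0, le=3)
    fragment_sizes: list[float]
    sizing_subset: list[float]

    @model_validator(mode="after")
    def _check(self) -> "ILSDef":
        for label, seq in (("fragment_sizes", self.fragment_sizes),
                           ("sizing_subset", self.sizing_subset)):
            if list(seq) != sorted(seq) or len(set(seq)) != len(seq):
                raise ValueError(f"ils.{label} must be strictly increasing")
        if not set(self.sizing_subset) <= set(self.fragment_sizes):
            raise ValueError("ils.sizing_subset must be a subset of fragment_sizes")
        return self


class CallingRules(BaseModel):
    """All expert-system thresholds.

    Units: rfu for heights, bases for sizes, raw collection scans for widths.
    ``analytical_threshold_rfu``: peaks at or below this height above the noise
    center are never considered.  The heterozygote test requires both top peaks
    above ``het_min_rfu`` with peak-height ratio (low/high) above
    ``het_min_phr``; the homozygote test requires the higher peak above
    ``hom_min_rfu`` with ratio below ``hom_max_phr`` (0.00 when there is no
    second peak).  iNTA fragments are those under ``inta_max_fraction`` of a
    fragment ~1 base larger.
    """

    analytical_threshold_rfu: float = 150.0
    het_min_rfu: float = 250.0
    het_min_phr: float = 0.37
    hom_min_rfu: float = 600.0
    hom_max_phr: float = 0.20
    inta_max_fraction: float = 0.20
    inta_size_tol_bases: float = 0.5
    spike_max_scans: float = 2.0
    dyeblob_width_multiple: float = 2.0
    pullup_height_multiple: float = 10.0
    pullup_scan_tol: int = 1
    baseline_window_alleles: int = 5
    nominal_scans_per_base: float = 12.0
    mixture_min_loci: int = 2
    mixture_min_alleles: int = 3
    cmf_min_codis_loci: int = 10
    resolution_single_base_R: float = 0.3
    bin_halfwidth_bases: float = 0.5

    @model_validator(mode="after")
    def _check(self) -> "CallingRules":
        for name in ("analytical_threshold_rfu", "het_min_rfu", "het_min_phr",
                     "hom_min_rfu", "hom_max_phr", "inta_max_fraction",
                     "spike_max_scans", "dyeblob_width_multiple",
                     "baseline_window_alleles", "mixture_min_loci",
                     "mixture_min_alleles", "cmf_min_codis_loci",
                     "resolution_single_base_R", "bin_halfwidth_bases"):
            if getattr(self, name) <= 0:
                raise ValueError(f"rules.{name} must be positive")
        if self.het_min_phr <= self.hom_max_phr:
            raise ValueError("rules.het_min_phr must exceed rules.hom_max_phr")
        if self.het_min_rfu <= self.analytical_threshold_rfu:
            raise ValueError(
                "rules.het_min_rfu must exceed rules.analytical_threshold_rfu"
            )
        return self

    @property
    def baseline_window_scans(self) -> int:
        """Sliding-minimum window: five alleles wide, converted to scans.

        Five tetranucleotide alleles = 20 bases, mapped through the nominal
        electrophoretic mobility; forced odd so the window is centered.
        """
        w = int(round(self.baseline_window_alleles * 4 * self.nominal_scans_per_base))
        return w | 1


class Panel(BaseModel):
    """A complete validated assay configuration."""

    panel_name: str
    channels: list[DyeChannel]
    ils: ILSDef
    loci: list[LocusDef]
    rules: CallingRules = Field(default_factory=CallingRules)

    @model_validator(mode="after")
    def _check(self) -> "Panel":
        if len(self.channels) != 4:
            raise ValueError("channels: exactly 4 dye channels required")
        if sorted(c.index for c in self.channels) != [0, 1, 2, 3]:
            raise ValueError("channels: indices must be 0..3")
        for locus in self.loci:
            if locus.channel == self.ils.channel:
                raise ValueError(
                    f"locus {locus.name}: STR loci may not share the ILS channel"
                )
            half = self.rules.bin_halfwidth_bases
            centers = sorted(s for _, s in locus.fixed_bins)
            for lo, hi in zip(centers, centers[1:]):
                if hi - lo < 2 * half:
                    raise ValueError(
                        f"locus {locus.name}: fixed bins at {lo} and {hi} overlap "
                        f"for bin halfwidth {half}"
                    )
        return self

    def locus(self, name: str) -> LocusDef:
        for loc in self.loci:
            if loc.name == name:
                return loc
        raise KeyError(name)

    def loci_on_channel(self, channel: int) -> list[LocusDef]:
        return [l for l in self.loci if l.channel == channel]

    def locus_for_fragment(self, channel: int, size: float,
                           margin: float = 2.0) -> Optional[LocusDef]:
        """Locus whose size range (padded by ``margin`` bases) contains the fragment.

        Raises PanelError if the padded ranges of two loci both claim it.
        """
        hits = []
        for loc in self.loci_on_channel(channel):
            lo, hi = loc.size_range
            if lo - margin <= size <= hi + margin:
                hits.append(loc)
        if len(hits) > 1:
            raise PanelError(
                f"fragment at {size:.2f} bases on channel {channel} matches "
                f"multiple loci: {[l.name for l in hits]}"
            )
        return hits[0] if hits else None

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.model_dump(mode="json"), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def load_panel(source: str | Path | dict) -> Panel:
    """Load and validate a panel configuration from a JSON file or dict.

    Raises PanelError naming the offending field on any schema violation.
    """
    if isinstance(source, dict):
        raw = source
    else:
        path = Path(source)
        if not path.exists():
            raise PanelError(f"panel file not found: {path}")
        try:
            raw = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise PanelError(f"panel file is not valid JSON: {exc}") from exc
    try:
        return Panel.model_validate(raw)
    except Exception as exc:  # pydantic ValidationError carries field locations
        raise PanelError(f"invalid panel configuration: {exc}") from exc


def default_panel() -> Panel:
    """The bundled PowerPlex-16-style default panel."""
    text = (resources.files("strexpert") / "data"
            / "powerplex16_style_panel.json").read_text()
    return load_panel(json.loads(text))


def fixed_bin_lookup(panel: Panel, locus: str, size: float) -> Optional[str]:
    """Allele label of the unique fixed bin within half a bin-width of ``size``.

    The boundary is strict (|size - center| < halfwidth) so a fragment exactly
    on a bin edge is never double-assigned.  Returns None when no bin matches.
    """
    loc = panel.locus(locus)
    half = panel.rules.bin_halfwidth_bases
    for label, center in loc.fixed_bins:
        if abs(size - center) < half:
            return label
    return None
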