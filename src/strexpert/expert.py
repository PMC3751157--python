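"""The expert-system allele caller.

Implements the rule set an on-instrument expert system applies to sized
fragments: translation of fragment sizes into candidate allele designations
against a measured allelic ladder (or fixed bins when the ladder lane fails),
iNTA and stutter filtering, the heterozygote and homozygote peak-height-ratio
tests, no-call logic, whole-sample mixture rejection, and profile assembly
with the CODIS-export gate.

Rule order matters and is fixed: iNTA is considered first, then stutter, then
the two surviving candidates with the highest peak heights enter the zygosity
tests.  A locus whose top candidates fail both the heterozygote and the
homozygote test is a no-call: displayed red and excluded from database export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .panel import CallingRules, Panel, fixed_bin_lookup
from .sizing import SizedFragment

__all__ = [
    "CandidateStatus",
    "Zygosity",
    "CandidateAllele",
    "LocusCall",
    "Profile",
    "designate_candidates",
    "filter_inta",
    "filter_stutter",
    "call_locus",
    "detect_mixture",
    "assemble_profile",
]


class CandidateStatus(str, Enum):
    CANDIDATE = "candidate"
    INTA = "inta"
    STUTTER = "stutter"
    EXCLUDED_ARTIFACT = "excluded_artifact"
    CALLED = "called"
    SUSPECT = "suspect"


class Zygosity(str, Enum):
    HETEROZYGOTE = "heterozygote"
    HOMOZYGOTE = "homozygote"
    NO_CALL = "no_call"


@dataclass
class CandidateAllele:
    """A sized fragment assigned to a locus with a provisional designation."""

    locus: str
    label: str              # ladder/bin allele label, or "OL" (off-ladder)
    size: float             # bases
    height: float           # rfu above noise center
    status: CandidateStatus = CandidateStatus.CANDIDATE


@dataclass
class LocusCall:
    """The final genotype decision for one locus."""

    locus: str
    genotype: tuple[str, ...]            # 0-2 allele labels
    zygosity: Zygosity
    display: str = "gray"                # "gray" = confident, "red" = questionable
    candidates: list[CandidateAllele] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.zygosity is Zygosity.HETEROZYGOTE and len(self.genotype) != 2:
            raise ValueError("heterozygote requires exactly 2 allele labels")
        if self.zygosity is Zygosity.HOMOZYGOTE and len(self.genotype) != 1:
            raise ValueError("homozygote requires exactly 1 allele label")
        if self.zygosity is Zygosity.NO_CALL:
            self.display = "red"

    @property
    def called(self) -> bool:
        return self.zygosity is not Zygosity.NO_CALL


@dataclass
class Profile:
    """A sample-level result: per-locus calls plus export gating."""

    sample_id: str
    calls: dict[str, LocusCall]
    status: str                      # full | partial | mixture_rejected | failed
    called_codis_count: int
    cmf_eligible: bool


def designate_candidates(frags: list[SizedFragment],
                         ladder: dict[str, dict[str, float]] | None,
                         panel: Panel) -> list[CandidateAllele]:
    """Translate sized fragments into candidate allele designations.

    ``ladder`` maps locus name → {allele label → measured ladder size}; when it
    is None (ladder lane failed) the panel's fixed bins are used instead.  A
    fragment matching no bin within half a bin-width is designated "OL"
    (off-ladder) with suspect status: displayed red, never called.  Flagged
    fragments (artifacts, out-of-range) are skipped entirely.
    """
    half = panel.rules.bin_halfwidth_bases
    out: list[CandidateAllele] = []
    for f in frags:
        if f.flags:
            continue
        locus = panel.locus_for_fragment(f.channel, f.size)
        if locus is None:
            continue
        label = None
        if ladder is not None and locus.name in ladder:
            for allele, lad_size in ladder[locus.name].items():
                if abs(f.size - lad_size) < half:
                    label = allele
                    break
        else:
            label = fixed_bin_lookup(panel, locus.name, f.size)
        if label is None:
            out.append(CandidateAllele(locus.name, "OL", f.size, f.height,
                                       CandidateStatus.SUSPECT))
        else:
            out.append(CandidateAllele(locus.name, label, f.size, f.height))
    return out


def filter_inta(cands: list[CandidateAllele],
                rules: CallingRules) -> list[CandidateAllele]:
    """Flag incomplete-nontemplated-addition (iNTA) fragments.

    A candidate whose height is less than ``rules.inta_max_fraction`` of a
    same-locus fragment approximately one base larger (within
    ±``rules.inta_size_tol_bases``) is an iNTA fragment and not an allele.
    Applied before stutter filtering.
    """
    tol = rules.inta_size_tol_bases
    for c in cands:
        if c.status is not CandidateStatus.CANDIDATE:
            continue
        for other in cands:
            if (other is not c and other.locus == c.locus
                    and other.status in (CandidateStatus.CANDIDATE,
                                         CandidateStatus.SUSPECT)
                    and abs((other.size - c.size) - 1.0) <= tol
                    and c.height < rules.inta_max_fraction * other.height):
                c.status = CandidateStatus.INTA
                break
    return cands


def filter_stutter(cands: list[CandidateAllele],
                   panel: Panel) -> list[CandidateAllele]:
    """Flag stutter: one repeat unit shorter than a parent allele candidate.

    Stutter candidates are limited to fragments exactly one repeat length
    (within half a bin-width) below a surviving parent candidate, with height
    under the locus stutter threshold relative to the parent.  Fragments
    already flagged as iNTA or artifacts are not parents and not re-flagged.
    """
    half = panel.rules.bin_halfwidth_bases
    for c in cands:
        if c.status is not CandidateStatus.CANDIDATE:
            continue
        locus = panel.locus(c.locus)
        if locus.repeat_len <= 0:
            continue
        for parent in cands:
            if (parent is not c and parent.locus == c.locus
                    and parent.status is CandidateStatus.CANDIDATE
                    and abs((parent.size - c.size) - locus.repeat_len) <= half
                    and parent.height > 0
                    and c.height / parent.height < locus.stutter_threshold):
                c.status = CandidateStatus.STUTTER
                break
    return cands


def call_locus(locus: str, cands: list[CandidateAllele],
               rules: CallingRules) -> LocusCall:
    """Apply the heterozygote then homozygote peak-height-ratio tests.

    The two surviving candidates with the highest peak heights are tested:

    * heterozygote — two candidates, both above ``het_min_rfu``, with
      low/high peak-height ratio above ``het_min_phr``;
    * homozygote — higher peak above ``hom_min_rfu`` and ratio below
      ``hom_max_phr`` (taken as 0.00 when there is no second peak); the
      genotype is the higher peak's label.

    Failing both tests yields a no-call displayed in red.  Ties in height at
    the top-2 cut are broken toward the smaller-size candidate for
    determinism.
    """
    surviving = [c for c in cands if c.status is CandidateStatus.CANDIDATE]
    top2 = sorted(surviving, key=lambda c: (-c.height, c.size))[:2]
    if not top2:
        return LocusCall(locus, (), Zygosity.NO_CALL, candidates=cands)
    high = top2[0]
    low = top2[1] if len(top2) == 2 else None
    phr = (low.height / high.height) if low is not None else 0.0
    if (low is not None and high.height > rules.het_min_rfu
            and low.height > rules.het_min_rfu and phr > rules.het_min_phr):
        for c in top2:
            c.status = CandidateStatus.CALLED
        genotype = tuple(sorted((high.label, low.label),
                                key=lambda lab: _label_key(lab)))
        return LocusCall(locus, genotype, Zygosity.HETEROZYGOTE,
                         candidates=cands)
    if high.height > rules.hom_min_rfu and phr < rules.hom_max_phr:
        high.status = CandidateStatus.CALLED
        return LocusCall(locus, (high.label,), Zygosity.HOMOZYGOTE,
                         candidates=cands)
    return LocusCall(locus, (), Zygosity.NO_CALL, candidates=cands)


def _label_key(label: str):
    try:
        return (0, float(label))
    except ValueError:
        return (1, label)


def detect_mixture(calls_or_counts: dict[str, int] | dict[str, LocusCall],
                   rules: CallingRules) -> bool:
    """Whole-sample mixture test for sole-source (buccal) samples.

    True when at least ``rules.mixture_min_loci`` loci each retain at least
    ``rules.mixture_min_alleles`` surviving allele candidates — evidence of a
    mixed sample; the entire sample is then rejected.
    """
    n_loci = 0
    for v in calls_or_counts.values():
        if isinstance(v, LocusCall):
            count = sum(1 for c in v.candidates
                        if c.status in (CandidateStatus.CANDIDATE,
                                        CandidateStatus.CALLED))
        else:
            count = int(v)
        if count >= rules.mixture_min_alleles:
            n_loci += 1
    return n_loci >= rules.mixture_min_loci


def assemble_profile(calls: dict[str, LocusCall], panel: Panel,
                     sample_id: str = "") -> Profile:
    """Assemble per-locus calls into a sample profile with export gating.

    The profile is full when every panel locus is called, otherwise partial.
    Only CODIS core loci with a genotype count toward the CMF export gate of
    ``rules.cmf_min_codis_loci`` called loci (amelogenin is not a CODIS core
    STR and never counts).
    """
    missing = [l.name for l in panel.loci if l.name not in calls]
    if missing:
        raise ValueError(f"missing locus calls: {missing}")
    codis = sum(1 for l in panel.loci
                if l.is_codis and calls[l.name].called)
    full = all(calls[l.name].called for l in panel.loci)
    if detect_mixture(calls, panel.rules):
        return Profile(sample_id, calls, "mixture_rejected", codis, False)
    return Profile(
        sample_id, calls,
        "full" if full else "partial",
        codis,
        codis >= panel.rules.cmf_min_codis_loci,
    )
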