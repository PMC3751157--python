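# strexpert

Electropherogram signal processing and expert-system STR allele calling, as a
desk-scale Python library and CLI.

Rapid DNA analysis instruments separate fluorescently labeled short tandem
repeat (STR) amplicons by electrophoresis, detect them on four color channels,
and hand the raw traces to on-board software that must produce a database-ready
DNA profile with no human review. `strexpert` reimplements that software layer
for a PowerPlex-16-style assay (15 STR loci plus amelogenin over three dye
channels, with the 22-fragment ILS600 size standard on the fourth) and pairs it
with a synthetic electropherogram simulator, so the entire chain — raw trace to
CODIS-exportable profile — runs and is testable without hardware.

## What it computes

**Signal processing.** Per channel, a sliding-window minimum baseline (window
five alleles wide) is subtracted; peaks are detected and characterized by apex,
height above the noise center, and FWHM. Per-peak detector-response ratios are
clustered into a 4×4 color ratio matrix **M** (columns = normalized dye
response vectors); applying **M**⁻¹ per scan yields the spectrally separated
electropherogram. Spikes (≤ 2 raw scans), dye blobs (> 2× nominal fragment
width) and pull-up are flagged and excluded.

**Sizing.** The internal lane standard's 22 fragments (60–600 bases) are
matched to detected peaks by an order-preserving alignment; the 20 fragments
from 80–550 bases anchor a strictly monotone piecewise-linear scan→base map.
Separation resolution is summarized as R = Δsize / (w₁ + w₂) with FWHM widths
in bases; R ≥ 0.3 at one-base spacing is single-base resolution.

**Expert system.** Sized fragments become candidate allele designations against
the run's measured allelic ladder (fixed bins if the ladder fails), filtered in
fixed order: peaks < 150 rfu above the noise center are never considered; a
fragment < 20% the height of a fragment ~1 base larger is iNTA; a fragment one
repeat below a parent and under the locus stutter threshold is stutter. The two
surviving candidates with the highest peaks are then tested —

* heterozygote: both > 250 rfu and peak-height ratio (low/high) > 0.37;
* homozygote: higher peak > 600 rfu and ratio < 0.20 (0.00 if no second peak);

failing both is a no-call (shown red, excluded from export). Samples with two
or more loci each holding three or more surviving candidates are rejected as
mixtures. Profiles with at least ten called CODIS loci are exported as a
CMF-style XML; every sample also gets an annotated electropherogram PNG and a
minimal-ABIF `.fsa` of the processed traces.

## Worked example

```
$ strexpert simulate --kind ladder --seed 11 --out ladder.json
$ strexpert simulate --kind sample --seed 42 --out donor1.json
$ cat > run.json <<'JSON'
{"lanes": [
  {"sample_id": "donor1", "role": "sample", "trace": "donor1.json"},
  {"sample_id": "ladder", "role": "ladder", "trace": "ladder.json"}
 ],
 "out_dir": "out"}
JSON
$ strexpert call --manifest run.json
donor1: full (13 called CODIS loci)
```

The run writes `out/donor1.png` (electropherogram with gray/red call boxes),
`out/donor1.fsa`, `out/donor1.cmf.xml` and `out/donor1.profile.json`. The
profile holds one call per locus, e.g.

```
"D3S1358": {"genotype": ["17"],       "zygosity": "homozygote",   "display": "gray"}
"D21S11":  {"genotype": ["25", "26"], "zygosity": "heterozygote", "display": "gray"}
```

— a `full` profile: all 16 loci called, all 13 CODIS core loci present, so the
CMF export gate (≥ 10 called CODIS loci) passes. Genotypes match the simulated
donor's ground truth.

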