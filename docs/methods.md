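# Methods

## Scope and model

`strexpert` models the data-analysis layer of a four-color capillary/microchip
electrophoresis STR system: a lane is a four-channel fluorescence signal
sampled at a fixed scan rate (default 5 Hz), carrying amplified STR fragments
on three dye channels and an internal lane standard (ILS) on the fourth. The
package's job is deterministic: given the raw trace and the assay definition,
produce per-locus genotype calls with explicit confidence display and database
export gating. All thresholds live in one validated configuration object
(`CallingRules`) so no rule constant is duplicated in code.

## Signal processing

**Baseline.** The baseline at scan *i* is the minimum signal in a centered
window, truncated at trace ends, subtracted per channel. The window is five
alleles wide — 5 × 4 bases mapped through the nominal mobility
(`nominal_scans_per_base`, default 12 scans/base → 241 scans, forced odd).
Window minima via `scipy.ndimage.minimum_filter1d` with +∞ edge padding, which
is exactly the truncated-window definition. Subtraction is idempotent wherever
the window minimum of the output is zero.

**Noise center and peaks.** The noise center is the median of a channel after
masking ±12 scans around provisionally detected peaks; "height" is always rfu
above that center. Peaks are local maxima strictly above the 150 rfu analytical
threshold, with interpolated FWHM and, separately, the integer count of raw
scans above half maximum (`span_scans`) — the spike rule is stated in raw
collection scans, and an interpolated width of e.g. 2.04 scans must not let a
true two-scan spike escape.

**Spectral separation.** At each detected apex the 4-vector of detector
signals is normalized to unit sum; vectors are grouped by greedy cosine-distance
clustering (threshold 0.1), and the cluster means — one per dominant detector,
normalized, ordered by dominant detector index — form the color ratio matrix.
Its inverse is applied per scan. Fewer than four resolvable clusters (an
ILS-only lane lights one dye) raises a spectral-diversity error; the pipeline
then proceeds uncorrected, which is safe precisely because such lanes have no
cross-dye signal to unmix.

**Artifacts.** Spike: span ≤ 2 raw scans. Dye blob: FWHM > 2× the nominal
fragment width, taken as the lane's median ILS peak FWHM. Pull-up: apex
coincident within ±1 scan with a peak in another channel ≥ 10× taller. The
pull-up multiple is a design choice: on the *corrected* trace residual bleed is
far below 1/10, while genuinely co-migrating fragments (an ILS fragment
passing under a ~4500 rfu homozygote peak) can reach 1/5 — a 5× screen would
flag real ILS fragments and void lane sizing. Flagged peaks never become
allele candidates.

## Sizing

ILS identification aligns detected (unflagged) ILS-channel peaks to the
expected 22 fragment sizes. When counts match and a single linear mobility fit
explains the spacing, the in-order assignment is accepted; otherwise an
order-preserving dynamic program minimizes |Δscan − â·Δsize| over consecutive
matched pairs with fixed penalties for skipping a spurious peak (â·10 bases/2)
or missing a fragment (â·10 bases), iterating the mobility estimate â three
times. Fewer than 20 assignable sizing-subset fragments is an ILS failure: the
lane is not sizeable and yields no profile. A dye blob landing on an ILS
fragment merges with it, widens it past the blob threshold and removes it from
the usable set — such lanes correctly fail rather than mis-size.

Calibration anchors are exactly the 20 sizing-subset fragments (80–550 bases;
the 60 and 600 end fragments are excluded). Sizing is piecewise-linear
interpolation between flanking anchors; peaks outside the anchored range are
flagged, not sized. Local Southern sizing was considered and left as future
configuration — on affine simulated mobilities the two coincide.

Resolution: R = (size₂ − size₁)/(w₁ + w₂) with FWHM widths converted to bases
through the local calibration slope; a one-base pair with R ≥ 0.3 is
single-base resolved (boundary inclusive).

## Expert system

Designation: a fragment is assigned to the unique locus on its channel whose
nominal size range (±2 bases margin) contains it; its label is the measured
ladder allele within ±0.5 bases, or the fixed bin when that locus's ladder
failed, else "OL" (off-ladder, suspect — displayed red, never called, never in
top-2 selection). The bin boundary is strict (< 0.5) so no size can match two
bins. Rule order is fixed: iNTA (fragment < 20% of a fragment 1 ± 0.5 bases
larger) is considered first; stutter next (one repeat unit ± 0.5 bases below a
surviving parent, height ratio under the locus stutter threshold — 0.15
tetranucleotide, 0.10 pentanucleotide defaults, configurable per locus);
then the zygosity tests on the two tallest survivors, heterozygote before
homozygote, with the exact inequalities given in the README. Height ties at
the top-2 cut keep the smaller-size candidate, for determinism. Amelogenin
(repeat length 0) skips stutter logic and never counts toward the ten-CODIS
export gate. Mixture rejection (≥ 2 loci with ≥ 3 surviving candidates) is
evaluated at profile assembly and blocks CMF export.

## Simulator

The generator emulates a clean single-source buccal run. Fragments are
Gaussian peaks placed by affine mobility (scan = 12·size + 600 over 9000 scans
at 5 Hz; optional quadratic term), FWHM 0.45 bases — chosen so a one-base pair
gives R ≈ 1.1, comfortably in the single-base regime across 100–500 bases.
Heterozygote allele heights are 1800 rfu with 8% lognormal spread, so
simulated peak-height ratios concentrate above 0.8 and virtually always pass
the 0.37 floor; homozygotes get a single 1.9× peak. Companion artifacts:
stutter one repeat below each allele (default 6% of parent) and iNTA one base
below (default 3%), matching systems where iNTA stays below 5% of the major
peak; at default heights both sit below the 150 rfu threshold, which is
realistic — tests that exercise the filters raise the parent heights. Each
lane adds a positive offset plus slow sinusoidal drift (so baseline
subtraction is exercised nontrivially), Poisson-injected spikes (1–2 scans)
and dye blobs (3.5× width) at configurable rates, spectral mixing by a
diagonal-dominant bleed matrix with unit column sums, Gaussian detector noise
(6 rfu), and per-fragment sizing jitter (SD 0.05 bases) emulating run-to-run
migration variability. Everything is driven by one seeded generator:
identical seeds give identical traces.

What the simulator does not model: saturation and camera nonlinearity,
degraded or inhibited samples, true multi-contributor mixtures (mixture
fixtures are built by summing two simulated lanes), microvariant alleles off
the ladder, and physical electrokinetics (mobility is prescribed, not
derived). Passing tests therefore demonstrate the correctness of the decision
logic and the calibration/designation arithmetic under realistic noise — not
robustness to chemistry-level pathology.

## Problem sizes and verification

The test suite verifies the sliding-minimum baseline against a brute-force
O(n·w) oracle on random traces, the locus-calling decision against a verbatim
re-statement of the zygosity rules over a ~15,000-point height grid, spectral
estimation against a known bleed matrix to 1e-6, and sizing against the
closed-form affine inverse to 1e-9. Statistical mirrors run at desk scale: 20
simulated ladder lanes for inter-run sizing precision (per-allele SD ≤ 0.15
bases at default jitter), one-base pair resolution checks every 20 bases from
100–500, and 50 random genotypes end to end requiring 100% allele concordance
at called loci with ≥ 95% of loci called. Simulated lanes are 9000 scans ×
4 channels; the full suite completes in seconds.

## Known limitations

* The ILS alignment DP assumes a locally near-linear mobility; severe
  curvature between adjacent fragments would degrade the spacing score.
* Pull-up flagging is positional; it cannot distinguish residual bleed from a
  true co-migrating small fragment at ratios above 10×.
* The CMF dialect is a simplified, documented XML (specimen + called loci +
  alleles), not the full CODIS CMF 3.2 schema.
* Fixed bins in the bundled panel equal the nominal ladder sizes; real assays
  calibrate bins per instrument batch.
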