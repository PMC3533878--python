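# Methods

This note documents the models and procedures implemented in `gcmskit`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not establish.

## Raw data model

A run is a strictly time-ordered sequence of centroided scans; each scan is
a strictly m/z-ascending vector of (m/z, intensity) pairs of arbitrary
length, including zero (detector-threshold gaps). Retention times are
seconds everywhere inside the library; minute values appear only in I/O
literals (`"6.5m"`). Zero-intensity centroid points are retained on read —
dropping them is lossy and nothing downstream needs it.

ANDI-MS files are classic NetCDF with `scan_acquisition_time`,
`point_count` (or `scan_index`), `mass_values` and `intensity_values`; both
index conventions are accepted and validated (overlapping or out-of-range
scan index ranges are format errors). The accepted JCAMP-DX grammar is the
chromatography/MS dialect written by `gcmskit.simulate.write_jcamp`
(`##PAGE=T=`/`##DATA TABLE=` scan blocks or `##RETENTION_TIME=`/`##XYDATA=`
blocks, plain numeric pairs); SQZ/DIF compressed numeric forms are rejected
with the offending line number. `trim(run, begin, end)` keeps both
endpoints — the natural reading of "between scans a and b" — and maps time
literals to the nearest enclosed scan. The per-scan point-count median uses
the lower of the two middle values for even counts.

## Binning

Bin intervals are half-open, `[center − lower, center + upper)`, so they
tile the m/z axis: every point lands in exactly one bin and total intensity
is conserved to floating-point accuracy (verified against a per-point
re-binning oracle). Grid centers sit at integer multiples of `bin_size`,
so the default 1 Th grid with −0.3/+0.7 offsets is centered on integers —
the convention for nominal-mass quadrupole data, where typical fragment
accurate masses exceed the integer slightly. Oxygen/phosphorus-rich
fragments can fall below the integer; per-region offsets are not
implemented. All matrix operations (`null_mass`, `crop_mass`, the filter
maps) return new values rather than mutating, so pipelines are
referentially transparent.

The Leco CSV export dialect is pinned as: header
`"Scan","Time",<masses...>`, then per row the scan number, rt in seconds,
and intensities, comma-separated.

## Filters

- **Savitzky–Golay** (default window 7 points, degree 2): least-squares
  polynomial smoothing; a degree-d filter reproduces polynomial traces of
  degree ≤ d exactly on interior points (window-5/degree-2 interior weights
  are the classical (−3,12,17,12,−3)/35). Edge points are re-fitted over
  truncated windows rather than padded — padding fabricates signal at trace
  ends. Negative ringing is clipped to zero when the input is non-negative,
  since binned intensities are physical counts.
- **Moving mean/median** (default window 5): truncated windows at edges; the
  median kills singleton spikes, the mean trades sharpness for variance.
- **Top-hat** (default element 90 s): signal minus its morphological opening
  under a flat element; features narrower than the element survive, broader
  trends are removed; output is non-negative, pointwise ≤ input, and
  idempotent. Widths in seconds convert to the nearest odd point count.
  Erosion/dilation use clipped windows, so a linear ramp is removed exactly
  on points at least one element from the ends (edge cells see one-sided
  windows). The default suits 0.375 s scans with peak widths of a few
  seconds; it must exceed the widest genuine peak.

`map_columns`/`map_rows` apply a trace operation independently per ion
chromatogram or per spectrum; column/row independence is the designed
extension point for parallel execution, implemented sequentially here.

## Peak detection and deconvolution

Per-ion local maxima use a centered window (`window`, odd, default 5): a
point qualifies if strictly greater than every earlier window point, at
least as large as every later one, and strictly above at least one window
point — so plateaus report their leftmost point and flat traces report
nothing. Maxima whose apex scans differ by ≤ `scans` chain into one
composite peak (transitive single-linkage: the simplest reading of
combining "neighboring apexing ions"). The composite apex is the scan
maximizing the summed member-ion intensity (earliest on ties); the
composite spectrum holds each member ion's apex intensity.

Two named presets bundle the benchmark parameter sets for the two sample
types: `mix` (window 5, ions 3, scans 2, threshold 2000, r 2%) for a
low-complexity standard mixture, and `serum` (window 13, ions 3, scans 2,
threshold 6000, r 2%) for a complex biological matrix.

`threshold` is a peak-list filter: a peak survives if at least `ions`
member intensities are ≥ `threshold`. It is deliberately *not* applied
while finding per-ion maxima — that would strip every sub-threshold ion
from composite spectra and make the r% base-ion filter vacuous. A separate
`noise_floor` (default 0) gates maxima during deconvolution; on noisy data
set it to roughly 5–10× the detector-noise standard deviation, otherwise
surviving noise maxima chain unrelated apexes together under
single-linkage grouping.

**Integration.** Per-ion areas accumulate outward from the apex, each
direction independently (seeded with the apex intensity), until the
candidate point contributes less than `stop_fraction` (default 0.5%) of the
accumulated intensity, or its intensity exceeds the previously included
point (a neighbouring signal's rising edge; strict one-point comparison, no
look-ahead). Areas use the rectangle convention (sum × scan period). Note a
structural property of the candidate-versus-accumulated-sum rule: the
accumulated sum grows linearly with sampling density, so the stop point
moves *inward* in σ units as sampling gets finer. For a noiseless Gaussian
the relative area error is ≈0.9% at 4 points/σ, 1.5% at 8, 4.3% at 20 and
18% at 80. At the sampling this library targets (a few points per σ, e.g.
0.375 s scans on 2–3 s peaks) the rule loses ≲2%; it does not converge to
the analytic area as sampling increases, and no
candidate-relative-to-accumulated rule can.

**UIDs** follow the field convention
`<top ion>-<second ion>-<second/top % (1 dp)>-<rt s (1 dp)>` (single-ion
peaks: `<ion>-<rt>`); intensity ties rank the lower m/z first.

## Alignment

Peak-to-peak similarity is pinned as cosine spectral similarity modulated
by a Gaussian in retention-time difference,
`sim = cos(s_p, s_q) · exp(−Δrt²/(2D²))`; match cost `1 − sim`, flat gap
cost `G`. Defaults `D = 2.5 s`, `G = 0.30`, chosen so that peaks with equal
spectra drifted by ~D still match (`1 − e^{−1/2} < 2G`) while spectrally
unrelated coincidences do not. Pairwise alignment is global DP over the
rt-sorted lists; traceback prefers matches on cost ties, and between the
two gap moves consumes the earlier-eluting peak first, which makes the
matching symmetric in the input order. Correctness is checked against
exhaustive enumeration of all monotone matchings for small instances.

Multiple experiments align progressively along a guide tree:
average-linkage agglomeration of the pairwise optimal alignment costs, ties
by input index. A profile position scores against another as the mean
similarity over all defined member pairs (mean rather than max/consensus:
less sensitive to outlier members). Positions with fewer than `min_peaks`
members are dropped from the final table.

## Common-ion quantitation

Per aligned position, the top-N (default N = 5) ion sets of all member
peaks are intersected. If the intersection is empty the position is flagged
as probably misaligned and gets no areas. Otherwise the candidates are
ranked by summed intensity rank across members (most intense overall first,
ties to the lower m/z — a concrete pin of "the first found is used") and
the winner's per-ion area, already integrated over each member's own
bounds during peak quantitation, becomes the cell value. This uses the same
retention-time limits as the all-ions area, so no re-integration against
the intensity matrices is needed.

A caveat measured by the verification harness: across *different*
compounds, the common-ion area equals the all-ions area divided by the
compound's spectral intensity sum (≈2–7 for EI-like spectra), so the
Pearson correlation of raw areas across a heterogeneous peak set is
typically 0.95–0.98 — consistency is per compound (the dilution ratios are
exact to <1%), not across compounds.

## Synthetic runs and ground truth

The generator emulates: Gaussian elution (amplitude × relative intensity ×
dilution, width σ seconds), pseudo-EI spectra (8–14 fragments in 50–300 Th,
base ion 1.0, ≥3 ions ≥ 0.3 so peaks are always quantifiable), centroid m/z
jitter uniform within ±0.2 Th (exercises bin boundaries), zero-mean
Gaussian detector noise, a detector threshold that deletes weak points
(zero blocks), and linear/hump baselines carried on bleed channels
(73/147/207/281). Ground truth ships the drifted apex rt and the analytic
per-ion areas `amplitude · rel · dilution · σ√(2π)`.

The fixture library: **mix-like** (15 separated components over 60–660 s,
0.375 s scans, amplitudes log-uniform over 1e4–5e5 — metabolite panels span
orders of magnitude — light noise), **overlap** (three distinct compounds
at 600/605/610 s, σ = 2 s), **serum-like** (30 components, hump baseline,
strong noise), and a **dilution series** (4 replicates at 1, 1/2, 1/4, 1/8
with 0.8 s rt drift). Sizes are chosen so each full simulation runs in
well under a second.

Not emulated: peak tailing (EMG), saturation, spectral skew across a peak,
instrument-specific noise spectra, real fragmentation chemistry. Passing
tests on these fixtures validates the algorithms' contracts — conservation,
oracle agreement, ground-truth recovery — not robustness to every
instrument artifact.

## Pipelines and determinism

The YAML pipeline config chains `simulate → detect → align → quantify`
stages with validated parameter blocks; artifacts get stable names and a
SHA-256 manifest. All randomness flows from a single seed, so reruns
reproduce manifests bit-for-bit. Validation failures exit 2 before any
stage runs; stage failures exit 1 naming the stage.

## Known limitations

- Single-linkage apex grouping degenerates on dense noise without a
  `noise_floor`; a scan-partition or density-based grouping would be more
  robust but is a different algorithm.
- The integration stop rule's sampling dependence (above).
- JCAMP support covers the dialect the package writes, not compressed or
  vendor-idiosyncratic variants; profile-mode (non-centroided) data and
  mzML/mzXML are out of scope.
- Alignment is quadratic per pair and intended for tens, not thousands, of
  experiments per batch.
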