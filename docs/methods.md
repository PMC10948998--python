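# Methods

This note documents the measurement conventions, the synthetic-embryo
model, the defaults and the numerical choices made where the underlying
experimental procedure leaves the design open.

## Coordinates and timing

AP position is % egg length (%EL), measured from the anterior tip
(anterior = 0). The DV coordinate is µm from the embryo midline. Analysis
is restricted to a fixed 282 µm DV window (~17 nucleus rows) centred on
the midline, which standardizes the number of contributing nuclei across
embryos. NC14 — from the end of the 13th mitosis to the beginning of
gastrulation — is normalized onto a fixed grid of 100 time points on
[0, 1]; fluorescence is linearly interpolated from the 61 s acquisition
frames onto that grid, and grid points outside a nucleus's observed frames
are NaN. All per-embryo time axes quoted below (onsets, windows) are in
this normalized time.

## Per-nucleus quantities

- **Spot signal.** Per frame and nucleus, the MS2 signal is the mean of
  the two brightest pixels inside the nuclear mask. The search is
  restricted to the segmented mask, not a dilated neighbourhood — a
  convention choice; a punctum on the nuclear rim could in principle fall
  partly outside the mask.
- **Activity call.** A nucleus is active at a grid point when its signal
  strictly exceeds a per-embryo threshold (ties inactive). The default
  threshold is automatic: the 10 % dimmest nuclei (by time-mean raw frame
  signal) are treated as never-active background, and the threshold is
  their pooled mean + 5 SD. Five (not the more customary three) standard
  deviations because one embryo contributes ~10^5 background
  nucleus-frames: a 3 SD rule would produce hundreds of false activity
  calls, enough to bridge inter-stripe gaps during mature-stripe
  clustering, whereas 5 SD keeps the expected count below one while
  remaining several-fold below burst-level signal. The threshold is
  estimated from raw frame values, not grid-interpolated ones —
  interpolation averages adjacent frames and would bias the noise SD low.
  The threshold used is recorded in the run log.
- **Cumulative mRNA output.** Trapezoidal integral of the fluorescence
  trace over normalized time, over the observed support only; units are
  a.u. × NC14. The raw (unsubtracted) trace is integrated, so a constant
  imaging background adds a genotype-independent offset. Integration is
  performed on the normalized 100-point grid rather than raw frames,
  consistent with every other time axis in the pipeline; on linear
  signals the two are identical.
- **Amplitude.** Output divided by active duration, with duration
  expressed as the active-grid-point count / 100 (i.e. a fraction of
  NC14). Amplitude therefore has fluorescence units, and for an idealized
  on/off trace equals the burst loading amplitude. Never-active nuclei
  have undefined (NaN) amplitude even though their integrated output can
  be positive.
- **Spatial profiles.** 50 AP bins of 2 %EL, half-open [left, right) with
  the last bin closed; a bin's value is the arithmetic mean over the
  nuclei inside it.

## Stripe definition and tracking

Mature stripes are anchored at the last grid point before gastrulation:
active nuclei are sorted by %EL and split wherever the gap between
consecutive nuclei exceeds 2 internuclear spacings (2 %EL on the default
lattice); clusters of fewer than 3 nuclei are discarded. Both parameters
are configurable — the underlying experimental procedure names no
clustering rule. Stripe *domains* tile the AP axis from the first stripe's
anterior border to 100 %EL, each running to the next stripe's anterior
border (half-open intervals, last closed).

Boundary tracking splits the DV window into 5 equal sections. Per section
and time point, the stripe's anterior/posterior boundary is the min/max
%EL of its active member nuclei; the reported boundary is the mean over
the sections that contain any active member (empty sections are omitted
rather than propagating NaN). Width = posterior − anterior; *position* is
the midpoint of the averaged boundaries (the choice of midpoint over,
e.g., the anterior border is a convention; all genotype contrasts are
differences, so any consistent choice cancels). Widths convert to nuclei
via the internuclear spacing (1 %EL = 1 nucleus on the default lattice).
Late-NC14 summaries average time points 80–90 of 100. The transient
stripe-2 expansion is the maximum over mid-NC14 (window 0.40–0.70,
configurable) of the cohort-mean width difference (het − wt). Activation
onset is the first grid point at which ≥ 10 % of the domain's nuclei are
active; onset delays are converted to minutes via the NC14 duration.

Aligned output profiles re-origin each embryo's stripe at its
anteriormost member nucleus, integrate output over grid points 61–70
only, pool nuclei across embryos into 1 %EL bins and drop bins with fewer
than 10 pooled nuclei.

## Cohort statistics

Genotype is called from the posterior PP7 reporter channel: an embryo is
wild type when ≥ 20 % of the nuclei in the 72–92 %EL window ever exceed
the PP7 threshold. CV profiles are computed across embryos on per-bin
cumulative mRNA output (one value per embryo per bin; sample SD / mean) —
the summarized quantity behind published CV curves is not stated, and
cumulative output is the most integrative choice; it is selectable.
Genotype comparisons report mean ± s.e.m. across embryos (not nuclei) for
widths/positions, and a classical pooled-variance two-sample Student's
*t*-test (Welch optional) on per-nucleus cumulative output pooled over
each cohort's ever-active stripe nuclei. No multiple-testing correction
is applied across stripes. Before pooling, embryos whose detected stripe
count differs from the cohort mode are dropped (a merged or spurious
cluster would misalign stripe identities); with default settings no
embryo is dropped.

## FISH profiles

Fixed-embryo images are reduced to the middle 40 pixel rows, averaged
into 1 %EL bins (AP axis along image x, or remapped from a two-point
anterior/posterior annotation), and background-subtracted by the lowest
binned value whose center lies in 10–90 %EL, per embryo. Corrected values
may be negative outside that range; adding a constant to the image leaves
the corrected profile unchanged.

## The synthetic embryo generator

The generator exists so that every pipeline stage can be validated
against exact ground truth; its defaults define the test conditions.

**Geometry.** 500 µm AP length with 100 nucleus columns, so one nucleus =
1 %EL (clean bookkeeping for effects stated in nuclei); 282 µm DV window
with 17 rows; 61 s frames over a 3000 s (50 min) NC14 → 50 frames.

**Regulator fields.** Each gap-gene-like regulator (Kr, anterior/posterior
gt, kni, anterior/posterior hb) is a product-of-logistics bump in %EL with
a linear temporal ramp. The heterozygote presets halve Kr everywhere,
shift the posterior gt and kni domains anteriorly and reduce anterior hb —
the regulatory picture of a halved repressor dosage. A rate law maps
repressor concentrations to burst propensity
(`k_on = k_on_max · max(0, 1 − Σ wᵢcᵢ/floor)`).

**Transcription.** Two-state telegraph promoter: exponential ON/OFF
switching with `k_on = 0.02 s⁻¹` inside the stripe (graded by logistic
edges of scale 0.5 %EL, zero before the stripe's onset time) and
`k_off = 0.005 s⁻¹` (stationary occupancy 0.8, burst timescale minutes —
a standard minimal bursting parameterization with analytically checkable
occupancy). States are sampled with the exact two-state propagator on the
frame grid, rates piecewise-constant per frame. Emission is background
(40 a.u.) + loading amplitude (300 a.u.) while ON *and* inside the
stripe's current permissive window, + Gaussian noise (SD 15), clipped at
0. Tying the loading to the current window means a locus that drifts
outside a refining stripe edge goes dark even if its promoter state has
not yet decayed — this makes the planted edges the exact detectable truth
at every time point. The PP7 reporter channel is a constant posterior
domain (72–92 %EL) present only in wild types.

**Planted heterozygote effects** (the recovery targets; applied as direct
edge/onset/amplitude deltas, which give unambiguous ground truth —
deriving them from the regulator network is deliberately out of scope):
stripe 2 posterior edge transiently +1.6 %EL (trapezoidal time window
0.35/0.45–0.60/0.72, ending early enough that the k_off decay tail clears
before the late-NC14 summary window); stripes 3 and 4 each −0.9 %EL of
width with loading amplitude × 0.75; stripe 4 additionally shifted
anteriorly, onset +360 s and k_on × 0.6 (sporadic bursting); stripe 5
both edges −3 %EL. The 1.6 / 0.9 / 3-nuclei / 6-min values are the
planted study conditions; the amplitude and burst-rate factors have no
reported numeric value and were fixed once at plausible magnitudes.
Presets: `default` (above), `neutral` (all deltas off, for null
calibration) and `ideal` (deterministic, step-edged, always-on, noiseless
— for exact-recovery tests).

**Rendering.** Frames are generated as already-max-projected 2D images
(the z-projection step of the real pipeline is an explicit no-op here,
though `max_project` handles 3D stacks on the real-data path). The nuclei
channel holds Gaussian blobs at nucleus centers; the MS2 channel one
sub-nuclear punctum per emitting nucleus, snapped to the nearest pixel
center with its peak pre-compensated so the top-2-pixel mean equals the
planted trace value exactly. Nuclei are non-overlapping by construction
and rendering errors out if the requested radius would violate that.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: embryo-to-embryo parameter variability (all
embryos of a genotype share identical parameters, so across-embryo CV is
an order of magnitude below published curves — the generator's CV reflects
only burst sampling noise; the heterozygote still shows elevated CV via
stripe-4 sporadic bursting), nuclear movement/division, photobleaching,
z-attenuation, mitotic waves, uneven illumination and segmentation
failures from nuclear crowding. Lattice quantization also means
sub-nucleus planted shifts are recovered rounded toward the 1-nucleus
grid (e.g. the 0.9-nucleus width deficits measure as ~1.0, the 1.6-nucleus
transient expansion as ~2.0).

## Determinism and numerics

All randomness flows through `numpy.random.Generator` seeded per embryo
from a master seed (`SeedSequence.spawn`); identical config + seed gives
byte-identical trace tables and rendered stacks. Cohort sizes default to
10 + 10 embryos (the recovery tests and the acceptance script use this
size); the null-calibration test uses 500 pairs of 3 + 3 reduced embryos
(3 DV rows) — the pooled t-test operates on nuclei, so small cohorts
suffice there. Trapezoidal integration, linear interpolation and the
strict-inequality activity call are exact (1e-12-level) against
brute-force oracles in the test suite. Degenerate inputs (empty masks,
all-NaN windows, never-active nuclei, empty DV sections) return
documented NaN/empty markers rather than raising, except where the input
contract is violated (no active nuclei at the last frame, overlapping
domains, empty t-test pools).

## Known limitations

- The real-data imaging path (TIFF → traces) uses a deliberately simple
  segmenter (blur + Otsu + connected components + area filter) and greedy
  nearest-centroid tracking with no gap closing or mitosis handling; it is
  adequate for near-stationary blastoderm nuclei and for the synthetic
  renders, not for crowded or drifting preparations. Externally produced
  trace tables are accepted as an alternative entry point.
- Cumulative output integrates the raw trace including imaging
  background; comparisons between genotypes are unaffected (the offset
  cancels), but absolute outputs are background-inflated.
- Boundary positions are order statistics (min/max of active nuclei) and
  are biased inward/outward by occupancy; all reported genotype effects
  are differences, in which this bias cancels.
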