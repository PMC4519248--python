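# Methods

This note documents the models and conventions behind `fintrace`: what
each stage computes, the defaults and why, what the synthetic cohorts do
and do not emulate, and the design choices that were genuinely open.

## Trajectories and missing data

A recording is one fish in one plane of a rectangular tank: coordinates
in cm, origin at the bottom-left of the filmed cross-section, `y`
increasing upward. For vertical-plane recordings `tank_height_cm` is the
water-column height and the "upper quarter" is `y ≥ 0.75·H`. Frame rate
defaults to 25 fps and is stored, never hard-coded; all downstream
windowing requires an integer fps.

Tracking losses are explicit NaNs. `fill_gaps` linearly interpolates
interior runs of at most `max_gap_frames` missing frames (default 5,
i.e. 0.2 s at 25 fps) and leaves longer or edge runs missing; the gap
report partitions every missing frame into interpolated or excluded
spans. Excluded frames contribute to neither numerator nor denominator
of any time fraction, and every summary reports the effective observed
time. This conservative exclusion avoids biasing occupancy metrics when
tracking fails preferentially in one part of the tank.

## Kinematics

"Triangulation" of camera coordinates is read as the straight-line
Euclidean distance between consecutive frame positions — the only
construction available once per-frame coordinates exist. Instantaneous
velocity is per second: the sum of the `fps` inter-frame distances in
non-overlapping windows aligned to the first frame; a trailing partial
window is discarded rather than extrapolated. A window overlapping any
missing step is itself missing. The speed histogram uses half-open
1 cm/s bins `[i, i+1)` with one overflow bin at and above a configurable
ceiling (default 21 cm/s, covering the 1–21 cm/s range the assay
reports); a speed exactly on a boundary falls in the upper bin.

## Speed activity profiles

The three SAP bands are half-open in body lengths per second:
rest `[0, 0.5)`, moderate `[0.5, 3)`, fast `[3, ∞)`. The source
protocol's verbal band edges leave speeds exactly at 0.5 bl/s assigned
to neither class and 3 bl/s to two; a partition is required for the
fractions to sum to 100%, so boundaries go to the upper class. SAP is
classified per second because velocity is defined per second; spatial
zone membership is decided per frame because position is per frame.

## Zone occupancy

The center zone is the concentric rectangle with the tank's aspect
ratio, each side scaled by √0.5, so its area is exactly half the
footprint; the boundary counts as inside. Upper-quarter and center-zone
times accumulate 1/fps seconds per valid frame. Fractions are invariant
under uniform rescaling of tank and coordinates. Note the protocol this
mirrors scored the water column from accelerated video playback by eye;
the per-frame computation here is the exact version of that readout.
Trajectory diagrams subsample one frame every 150 (6 s at 25 fps).

## Synthetic cohorts

The generator produces data with the statistical structure the analysis
assumes, so parameter recovery is checkable end to end.

* **Behavioral states.** A stationary semi-Markov process over
  rest/moderate/fast with exponential dwell times. The next bout's state
  is drawn i.i.d. with probability `q_j ∝ occupancy_j / dwell_j`; by the
  renewal-reward theorem the long-run time fraction in state *j* is then
  exactly `occupancy_j`, and the initial state is drawn from the
  occupancy law so the process is stationary from frame 0. Default mean
  dwells are 8 s (rest), 6 s (moderate), 2.5 s (fast) — bout-scale
  dynamics for adult zebrafish; the occupancy targets, not the dwells,
  carry the genotype contrast.
* **Speeds.** Each 1 s window takes the state at its start time and
  draws a speed from that state's truncated normal, truncated to the
  state's band (fast capped at 6 bl/s), so the hidden state is exactly
  recoverable from the realised speed. Defaults: rest 0.15 ± 0.12,
  moderate 1.2 ± 0.6, fast 3.8 ± 0.7 bl/s.
* **Positions.** The window speed is realised as `fps` equal steps along
  a heading updated once per second by a von Mises increment
  (concentration 4). Walls reflect by flipping the offending step
  component, which preserves each inter-frame step length exactly —
  hence per-second path length equals the drawn speed to rounding, the
  property the sidecar oracle tests assert at 1e-9.
* **Vertical recordings.** Depth is a Gaussian-copula AR(1) (reversion
  time 5 s) whose stationary marginal is a truncated normal on the water
  column (spread 0.2·H) with its location solved by root-finding so that
  P(upper quarter) equals the configured preference exactly; targets of
  0 or 1 are rejected as unreachable. The commanded speed drives the
  horizontal coordinate only, so vertical-plane recordings are for
  occupancy metrics, not kinematics.
* **Respiration.** Poisson counts per minute around a per-fish rate with
  mean-preserving 10% lognormal between-fish scatter. Between-fish
  heterogeneity is otherwise absent — real cohorts are unlikely to be so
  exchangeable, and no published per-fish variance exists to constrain
  it, so the scatter knob is deliberately minimal.

Shipped presets are illustrative fixtures, not fitted estimates: 9-month
wild-type and heterozygote at 70/25/5 rest/moderate/fast, homozygote at
5/75/20; all 3-month genotypes share 15/70/15 (young fish swim mostly at
moderate speed); upper-quarter preferences 0.25/0.50/0.60 and
respiration 120/125/170 min⁻¹ for WT/HT/HM. Body lengths 2 cm (3 mpf)
and 4 cm (9 mpf); tanks 8.8×11.8 cm and 18×24 cm horizontal,
22.5×12.5 cm vertical.

What the generator does **not** emulate: burst-glide micro-structure
within a second, habituation or circadian drift, wall-following
(thigmotaxis) beyond what reflection induces, fish–fish interaction
(fish are recorded singly), or tracking noise. Passing recovery tests
therefore shows the analysis chain is correct on data satisfying its own
assumptions, not that those assumptions hold for any particular video
rig.

## Statistics

Mann–Whitney is two-sided, exact (full null distribution) when the
smaller group has ≤ 8 observations and the pooled sample is tie-free,
otherwise the normal approximation with tie and continuity corrections.
The per-fish scalars it compares (distance, max speed, class seconds,
zone seconds, respiration) are independent units, and the Monte-Carlo
harness confirms nominal type-I error (α = 0.05 → ≈ 0.045–0.05 at
n = 12/group).

The chi-square comparison of SAP distributions pools integer seconds per
class over the fish of each genotype into a 2×3 table (df = 2, Pearson,
no continuity correction; expected cells < 5 set a warning flag). This
is the only construction that yields df = 2 per pairwise comparison, but
it treats each second as an independent draw while seconds within a fish
are strongly serially dependent (behavioral bouts last seconds). For a
stationary state process sampled each second, the variance of pooled
class counts is inflated by roughly `(1+ρ)/(1−ρ)` with ρ the
second-to-second state autocorrelation — an order of magnitude for
bout-scale dwells — so the test is sharply anticonservative under the
null: with identical simulation parameters per group it rejects far more
than 5% of the time, and the acceptance suite records that shortfall
honestly rather than shortening dwells to unphysiological values to mask
it. This same pseudo-replication plausibly explains the extreme
chi-square p-values such pooled analyses report. The per-fish
Mann–Whitney comparisons are the calibrated alternative; every
chi-square output row carries a `pseudoreplicated` flag.

The Freeman–Halton exact test enumerates all tables with the observed
margins (guarded at a total of 500), computes hypergeometric
probabilities in log space with permutation-invariant summation so
symmetry-equivalent tables tie bit-exactly, and sums the probabilities
of tables no more probable than the observed one (probability-ordering
two-tail rule, relative tie tolerance 1e-12); the enumerated mass is
used as the normalizer, so degenerate margins give p = 1 exactly.
Alternative tail rules are not offered beyond the tolerance knob. No
multiple-testing correction is applied by default, matching the assay's
reporting convention; a Holm step-down adjuster is available.

Calibration and power studies default to 600 s speed series and use the
per-fish rest-SAP seconds as the Mann–Whitney metric (continuous, so
tie-free); chi-square studies use 3600 s per fish and 10 fish per group.
These sizes put each study in the seconds-to-half-minute range while
keeping Monte-Carlo error at or below the margins being asserted.

## Splice genotyping

Coordinates are 1-based inclusive with conversion helpers. Amplicon
length runs from the forward primer's 5′ start through the reverse
primer's 5′ start (its reverse complement on the template), with both
primers required to map uniquely. T7EI fragment sizes are pure
arithmetic on an amplicon and a cut position; the cut position is an
input (a helper approximates it as the indel-footprint midpoint), not a
thermodynamic prediction.

Indel calling aligns read to reference globally (match +2, mismatch −4,
gap open −10, extend −0.5), turns gap runs into events, merges
opposite-kind runs separated by fewer than 3 aligned nucleotides into a
single net-length event (a heuristic for aligner-split breakpoints;
balanced del+ins blocks stay separate, and a merged event's footprint is
approximated from its leftmost breakpoint), left-aligns every event to
its leftmost equivalent placement (the variant-calling normalization
convention; chosen because ambiguous placements in repeats otherwise
make positions aligner-dependent), and filters events shorter than
`min_indel_bp` — 2 in F0 mosaic screening, where 1 bp calls are
indistinguishable from amplification errors, 1 in F1 confirmation, where
a known 1 bp allele must be callable.

A splice donor is disrupted when an indel touches the first two
nucleotides of the downstream intron (the canonical GT); the window
width is configurable for donor-consensus variants. An insertion
disrupts when its insertion point separates the exon from the GT or
splits the GT itself. The transcript-outcome cascade is: donor hit →
skip of the preceding exon, in-frame iff the exon length is divisible by
3; otherwise a purely exonic indel shifts or preserves the frame by its
net length; otherwise no effect is predicted. Outcomes are explicitly
heuristic — a skipped transcript can be removed by nonsense-mediated
decay, so every prediction carries a caveat string and RT-PCR remains
the confirmation.

The bundled locus (`fintrace.locus.example_locus`) is synthetic: random
filler sequence (fixed seed) around planted primer sites, GT/AG intron
boundaries and a 54 bp fifth exon, dimensioned so that the genotyping
amplicon is 246 bp with the donor junction 136 bp from the forward
primer and the transcript product is 298/244 bp with/without the target
exon. Its six-mutation panel mirrors the footprint classes of a real
screen (five donor-overlapping deletions of 4–10 nt, one 1 nt exonic
deletion); real mutation sequences are not public, so footprints, not
base identities, are the modeled content.

## Numerical conventions

Seeds propagate through `numpy.random.SeedSequence.spawn`, so cohorts
are reproducible fish-by-fish and every pipeline output is byte-stable
under a fixed config. Trajectory CSVs are written at repr precision so
read(write(T)) is exact. Occupancy fractions on zero observed time are
NaN, not zero. The simulator validates that one frame's maximal step
fits inside half the tank, which keeps the reflection rule exact; the
shipped tanks and speed caps satisfy it with a wide margin.

## Known limitations

* The pooled chi-square construction is anticonservative by design of
  its inputs (see above); use the per-fish tests for inference.
* Vertical-plane simulations do not couple depth to swimming speed.
* The indel caller assumes a single dominant allele per read (Sanger of
  a clone or a homozygote); mixed traces are out of scope.
* Exact Mann–Whitney switches to the tie-corrected normal approximation
  whenever ties occur, even in tiny samples, where mid-p exact variants
  exist but are not implemented.
* The transcript-outcome rules ignore cryptic splice-site activation and
  intron retention; they classify, they do not predict splicing
  chemistry.
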