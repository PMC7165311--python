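# Methods

## Alignment model

Two uniformly sampled series are compared per axis: the *query* (the
reference, conventionally the real-world fall signal) and the *template*
(a re-enacted trial).  The local distance is the 1-D Euclidean distance
`d(i,j) = |q_i − t_j|`; a multivariate mode with the 3-D Euclidean local
distance exists in `dtw_align` (pass `(n, 3)` arrays) but the default
workflow is univariate per axis, since per-axis scores are what the
re-enactment loop inspects.

The step pattern is the Sakoe–Chiba asymmetric pattern with slope
constraint `P = 1` ("asymmetricP1").  Three rules end at cell `(i, j)`:

| rule | start        | weighted cells                  | slope |
|------|--------------|---------------------------------|-------|
| a    | `(i-1, j-2)` | `(i, j-1)` ×0.5, `(i, j)` ×0.5  | 1/2   |
| b    | `(i-1, j-1)` | `(i, j)` ×1                     | 1     |
| c    | `(i-2, j-1)` | `(i-1, j)` ×1, `(i, j)` ×1      | 2     |

Every rule advances the query, and its weights sum to its query advance,
so the weights along any path from start to finish sum to exactly `N`
(the query length).  The reported score is the *normalized distance*
`g*/N` — a weighted mean per-sample mismatch in g.  Slope constraints
alone bound the search region; no global window is applied.

**Open end** takes the minimum of the final query row over all template
columns (earliest column on ties).  **Open begin** lets a path start at
any cell `(0, j)` at cost `d(0, j)` — the template prefix is free — and
additionally admits entries through a multi-cell rule anchored in a
phantom zero-cost query row (e.g. entering via rule a at cost
`[d(0,j−1) + d(0,j)]/2`), the construction classically used to implement
open-begin alignment for normalizable asymmetric patterns.  The union of
the two start sets is used; both the exhaustive path-enumeration oracle
and the independent reference implementation in the test suite define
admissible starts identically, so the dual-route checks compare like with
like.  Every query sample is always matched; only template samples can go
unmatched.

**Determinism.**  DP ties prefer rules with smaller total advance (the
diagonal rule b), then earlier listed rules (a before c); direct
open-begin starts win ties against phantom entries.  Backtracking records
every weighted chain cell of every applied rule, which is what makes
`warp_template`'s "repeat each template element as many times as needed"
semantics exact.  Infeasible alignments (e.g. closed-end with
`M > 2(N−1)+1` or `M < (N−1)/2+1`) raise a typed error naming both
lengths rather than returning infinity.  Float comparisons in the tests
use absolute tolerance 1e-9 (deterministic double-precision DP).

## The re-enactment workflow

`compare_axes` aligns x, y, z with open begin/end on by default (closed
variants are exposed for testing).  `iteration_report` tracks the loop:
percent improvement between consecutive iterations is
`100·(previous − current)/previous` (positive = improvement, `null` when
the previous distance is zero), and `best_iteration` minimizes the
unweighted mean of the three axis distances — the per-axis table is
always reported alongside, since no combined score is canonical.
`transfer_phases` maps annotation boundaries through the warping path
(first matching pair for starts, last for ends); where a many-to-one warp
makes consecutive phases touch, the later phase is nudged forward one
sample so the output stays sorted and non-overlapping.

## Synthetic fall signals

The simulator stands in for real recordings, which are not distributable.
It emulates a lower-back (L5) sensor through a single-angle rigid-body
model: with trunk pitch θ (0° upright, 90° horizontal forward bend),
static gravity reads `(x, y, z) = (sin θ, 0, cos θ)` g, so noise-free
static magnitude is exactly 1 g.  Phase waveforms:

- **steps (label 1)** — upright gravity plus a vertical sinusoid at the
  step frequency, and a mediolateral sway at half that frequency with a
  quarter of the amplitude (steps alternate sides).
- **fall/impact (2)** — total magnitude decays linearly to 0 over the
  free-fall duration, then a half-sine burst of the impact peak on the
  vertical and sagittal axes, then the static reading at the end pitch.
- **rest (3, 5)** — static gravity at the phase pitch.
- **raise / stand (4, 6)** — cosine ramp of pitch from start to end,
  plus a 3 Hz oscillation whose amplitude decays linearly to zero by
  phase end (superimposed on z).

Default protocol (100 Hz, noise SD 0.02 g, no clipping): 5 s of steps
(2 Hz, 0.15 g), 1.5 s fall with 0.35 s free fall and a 3 g, 0.12 s impact
ending at 75° pitch, 1.5 s ground contact at 75° (within the 1–2 s
hands-on-ground instruction), 1.2 s raise to 10°, 4 s kneeling rest at
10°, 2.5 s stand-up to 0°.  The ground-contact and kneeling-rest
durations follow the written re-enactment instructions for this fall
paradigm; every other duration, pitch and amplitude is a package default
chosen as a plausible lower-back trace — no published amplitudes exist
for them.  The 3 g impact peak is explicitly synthetic: real impacts
depend on surface properties (and saturate 2 g sensors) that the
single-angle model does not represent.

Sample counts round half away from zero per phase; annotations tile the
concatenation exactly (zero-duration phases contribute no samples and no
annotation).  Noise is i.i.d. Gaussian per axis from per-phase substreams
spawned deterministically from the protocol seed, so a signal is bit-for-
bit reproducible and editing one phase does not change another's noise.
Optional symmetric clipping emulates a ±2 g sensor range.

`perturb_protocol` models protocol adaptation between iterations: per-
phase duration deltas (clamped at 0.1 s for originally positive phases,
never above the original so zero deltas are exact) and multiplicative
amplitude/frequency factors uniform in `[1−s, 1+s]`.  Pitches and the
free-fall/impact durations are left alone — they encode the fall
paradigm, not execution variability.

**What the simulator does not capture:** roll/yaw and multi-segment body
dynamics, realistic impact spectra, 1/f or quantization noise, soft-
tissue artifacts.  Tests passing on simulated data therefore validate the
alignment machinery and the bookkeeping, not the biomechanical fidelity
of any re-enactment.

## Problem sizes and verification

The exhaustive enumeration oracle covers all series up to length 8 (all
ternary value combinations at lengths 3×4, plus 500 random pairs across
all open-flag variants); an independently written rule-table reference DP
is compared on 50 random pairs of lengths 20–200 at 1e-9.  Convergence of
re-enactment quality is measured as the mean per-axis distance over 20
simulated re-enactments at perturbation scales 0.5 / 0.2 / 0.05 against a
fixed ~15.7 s reference (1570 samples at 100 Hz), which keeps a full run
of the suite and the acceptance script around a minute each.

## Known limitations

- Open-begin/open-end frees only the template; a query whose recording
  extends beyond the re-enacted interval will accumulate mismatch cost.
- The normalized distance has no absolute interpretation across signals
  of different dynamic range; compare only scores against the same query.
- Automatic phase segmentation from raw signal is out of scope; phase
  annotations come from the simulator or from manual labeling.
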