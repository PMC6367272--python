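# Methods

This note documents the models, conventions, parameter choices and
limitations of audiencemotion, in the order the pipeline runs.

## Conventions

8-bit grayscale frames; origin top-left; x rightward (columns), y
downward (rows); positions at pixel centers, 0-based. Native-rate motion
values are px/frame; 1 Hz values are px/s. Missing samples are NaN and
are never silently imputed: the causality stage refuses gapped windows.

## Synthetic scenes (the stated world)

The generator renders N persons, each inside a static polygonal
envelope, as a speckle-textured torso ellipse plus head disc with two
bright marker discs at the wrists. Texture exists because optical flow
is ill-posed on uniform regions; the background is a *static*
low-contrast speckle for the same reason — on a flat background,
temporal sensor noise alone produced a spurious mean flow of
~0.38 px/frame in early experiments, versus ~0.11 with texture, and real
venue footage is never textureless.

Two motion processes, per person:

* **Sway** — sinusoidal whole-body drift (x and y at 0.25 / 0.17 Hz,
  random phases), peak per-frame displacement = `sway_amplitude`
  (default 0.3 px/frame).
* **Fidget bursts** — each burst displaces one randomly chosen hand
  along a random direction with the rise-and-return kernel
  K(s) = (s/τ)·e^(1−s/τ), τ = 0.4 s, scaled so the peak per-frame
  displacement equals `fidget_amplitude` (default 2 px/frame). Bursts
  are a jittered-regular train: one burst per interval of
  60/`fidget_rate` s (default rate 12/min), uniformly placed within the
  interval. A homogeneous Poisson train was considered and rejected: at
  the durations tests can afford, Poisson count noise (CV ≈ N^−1/2)
  blurs the programmed amplitude ratios the generator exists to pin
  down, while adding no realism the pipeline is sensitive to.

Engagement modulates fidgeting as a whole — disengaged persons/parts get
larger burst amplitudes *and* larger sway. `true_engagement` is the
fixed monotone map exp(−rate·amp / 24) of the programmed fidget
intensity into (0, 1]. `true_person_speed` is recomputed from the stored
trajectories (mean per-frame displacement of the two wrists and the body
center), not from the nominal amplitudes.

Gray-level layout: background 10–36, body texture 40–120, markers 255,
truncated Gaussian pixel noise (default sd 3, clipped at ±3 sd so the
brightest non-marker pixel is bounded). Marker radius defaults to 3 px;
the paper-shaped world does not fix marker size or seat geometry, so
these are free parameters of the generator, not claims about any real
recording.

**What a green test does not establish**: the generator has no pose
changes, occlusions, illumination drift, camera shake, or compression
artifacts — the failure modes that force manual track correction on real
footage. Tracking metrics on synthetic scenes are therefore upper bounds
on real-world performance; the correction-table mechanism exists for the
real case.

## Optical flow and average speed

`estimate_flow` wraps scikit-image's iterative pyramidal Lucas–Kanade
(`optical_flow_ilk`, radius 7, 3 warps), clipped to a configurable
maximum displacement (default 8 px/frame). The algorithm is pluggable:
the contract is behavioral (rigid d-px translations of textured scenes
recovered within 0.2 px; direction invariance; approximate linearity),
not a named method. Average speed over a region is the flow-magnitude
sum divided by region area, so differently sized regions (hands vs
head+torso) are comparable.

## Wristband tracking

Detection: 8-connected components of pixels ≥ threshold, minimum size
9 px, unweighted centroid. The default threshold is the midpoint of the
frame's 90th brightness percentile and its maximum — a high percentile
alone sits inside the clothing-texture range whenever markers occupy
less than the percentile's complement, and equals the marker brightness
when they occupy more; the midpoint separates cleanly in both regimes.
Linking: blobs are routed to persons by envelope membership; within a
person, minimum-total-displacement matching (exhaustive over the ≤2×2
pairings) gated at `max_jump` = 12 px against the preceding detected
position; at track birth the leftmost blob is the left hand (analyses
aggregate both hands, so any fixed rule suffices). Gaps of ≤ 5 frames
are linearly interpolated and flagged; longer gaps stay missing. Hand
rectangles (default 40×40 px) are anchored by flooring (center − half
extent), so even sizes bias one pixel toward top-left — a deliberate
bit-reproducibility choice.

## Body-part series and resampling

Polygon rasterization uses the even-odd rule with pixel-center
inclusion, implemented directly (vectorized crossing test) because the
convention is load-bearing for mask identities and library rasterizers
leave boundary behavior unspecified. The pair-t hand mask is the one
anchored at frame t. head_torso = envelope ∖ (left ∪ right) per frame;
because rectangles may leave the envelope, upper_body − head_torso ≠
hands in general — the distinction is asserted in tests. 1 Hz
resampling averages native samples per [t, t+1) bin and multiplies by
the native rate; trailing partial bins are dropped; missing samples are
excluded from bin means and an all-missing bin stays missing.

## Granger causality

Series are first-differenced (the sole stationarity treatment; an ADF
diagnostic is logged but never gates). For a lag order L on aligned
differenced length T, both models are fitted by OLS on the T − L rows
with full lag history; F = ((RSS_r − RSS_u)/L)/(RSS_u/(T − 2L − 1)) with
df = (L, T − 2L − 1). The denominator counts T − 2L − 1 rather than the
fitted model's algebraic residual dof (T − 3L − 1): the former is the
convention this package standardizes on, chosen for consistency with the
field's published df accounting. Scans run both directions over lags
1..9 and are reported per lag without multiple-testing correction (a
Bonferroni column is included, clearly labeled, as an extra). The
mismatch control re-pairs audience and stage series across parts by a
seeded derangement; couplings that survive mismatching are not
performance-specific.

## Engagement statistics

Clip selection is greedy: k non-overlapping windows (default 10 s, k=3
per polarity — six clips, window length a design default since only
"short" is specified) maximizing, then minimizing, the window mean; ties
break earliest. The ratings model is a linear mixed model fitted by ML:
movement state and connection-to-dance fixed, participant and yearly
attendance (0–4) as random intercepts (crossed variance components; a
single random factor uses the native grouping route). The headline
statistic is the likelihood-ratio χ² for movement state from nested ML
fits. Optimizers: bfgs/lbfgs/cg are tried and the best likelihood kept;
a nested model that appears to beat the full model marks a failed
optimization and triggers structure reduction (participant-only, then
OLS) with a warning — zero-residual data lands on the OLS fallback and
still recovers noiseless effects exactly.

Exact Spearman: rho = 1 − 6Σd²/(n(n²−1)) on (mid)ranks; the p-value
doubles the one-sided exact tail over all n! permutations, capped at 1,
and is limited to n ≤ 8 (40320 permutations); ties warn that the exact
tail assumes distinct ranks.

## Numerical and degenerate-input choices

* Flow output is clipped to the max-displacement bound and NaN-scrubbed.
* Empty masks are errors for integration; missing-wrist frames yield
  empty hand masks and missing hands samples.
* GC refuses collinear designs (rank check) and zero unrestricted RSS.
* Derangements are rejection-sampled from the seeded generator; two
  parts use the unique swap.
* All generators are deterministic given their seed; the pipeline's
  outputs are byte-identical across reruns of the same configuration.

## Limitations

* The flow noise floor (~0.1 px/frame on textured synthetic scenes) is
  an additive pedestal on all series; comparisons across conditions with
  the same imaging parameters are unaffected, absolute speeds are
  slightly inflated.
* The facial-expression engine of the original setting is out of scope;
  expression series enter only as externally produced per-person CSVs
  analyzed with `state_model`.
* Real-footage concerns — multi-camera synchronization, fps conversion,
  codec artifacts — are out of scope; the pipeline consumes PNG stacks
  and resamples series in time rather than re-encoding frames.
* ML likelihood-ratio tests for fixed effects are mildly anticonservative
  in very small designs (few grouping levels); calibration was verified
  at the 13×24 design (null rejection 4–6% at α = 0.05).
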