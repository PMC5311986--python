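# Methods

## Signal model and scope

The package operates on ROI-averaged BOLD time series: short (140–220
samples), slow (TR = 2 s, so fs = 0.5 Hz and a Nyquist limit of 0.25 Hz),
non-stationary signals dominated by power below ~0.2 Hz. Upstream volume
corrections (slice timing, motion, spatial normalization, nuisance
regression) are out of scope and assumed done by standard neuroimaging
tools; the in-scope preprocessing is dummy-volume dropping, atlas-parcel
voxel averaging, linear detrending and temporal z-scoring, applied in that
fixed order. Detrending/normalization act on the ROI-averaged series; since
both operations are linear, applying them per voxel before averaging gives
essentially the same result, and whether the original acquisition pipeline
averaged before or after normalization is not recoverable — the ROI-level
order is the default and the cheaper of the two.

## Empirical mode decomposition

Sifting follows the classical scheme: find interior extrema, interpolate
cubic-spline envelopes through maxima and minima, subtract the envelope
mean, repeat. An extremum on a flat plateau is placed at the plateau's
midpoint index (deterministic tie-break). Boundary knots are obtained by
mirroring the two extrema nearest each end across the end sample; on
200-sample series this visibly suppresses the spline end-swings that
otherwise leak into the low-frequency modes.

Stopping is the genuinely open design choice: testing the IMF conditions
alone can cycle, so a candidate is accepted when EITHER

- the IMF conditions hold — extrema and zero-crossing counts differ by at
  most one, and the mean envelope magnitude stays below
  `envelope_tolerance` (default 0.05) times the candidate SD — OR
- the Cauchy-style criterion `SD = Σ(h_prev − h)² / Σ h_prev²` falls below
  `sd_threshold` (default 0.2, the conventional sifting value), OR
- `max_sift_iters` (default 100) is reached.

All three constants live in `SiftConfig`. Decomposition terminates when the
residue has fewer than two maxima or two minima (monotonic-or-near contract)
or at `max_imfs` (default 12, a safety bound never reached at n = 220).
Because each IMF is subtracted from the running residue, the reconstruction
identity `Σ IMFs + residue = input` holds to floating-point rounding by
construction; tests assert < 1e-8 relative error.

These stopping constants are conventions of standard EMD practice; a
different EMD implementation with different tolerances can split or merge
modes slightly differently, which is why the test suite cross-checks the
first IMF against an independently coded reference sifting on two-tone
fixtures (correlation > 0.9) rather than asserting equality.

## Hilbert weighted frequency

The analytic signal is computed in the frequency domain (negative bins
zeroed, positive doubled), the standard O(m log m) discretization of the
principal-value Hilbert integral. Instantaneous frequency is the central
difference of the unwrapped phase (one-sided at the ends), stored in
radians/second; the HWF divides by 2π so features are in Hz, the unit the
frequency bands are discussed in.

Short-window edge artifacts can produce isolated negative instantaneous-
frequency samples. They are retained — the a² weighting suppresses them in
the HWF — and their fraction per mode is available as a diagnostic
(`negative_frequency_fraction`). No edge trimming is applied by default
(`trim_edges=0` is exposed). In the rare degenerate case where the weighted
mean itself comes out negative, the feature is floored at 0 Hz so feature
vectors satisfy 0 ≤ HWF < fs/2.

IMFs are extracted highest-frequency first, but band labelling conventions
number bands from the lowest up; the five retained HWFs are therefore
reported sorted ascending. When a series yields fewer than five IMFs
(common for narrowband signals), the missing lowest positions are padded
with 0 Hz — an absent mode is a trend-like near-zero-frequency component —
and `n_imfs_found` records the true count.

## Clustering and model selection

Features are the five HWFs per ROI per subject, concatenated subject-major
into an ROI × (5·S) matrix. All columns are frequencies in Hz on one scale,
so no standardization is applied by default (a per-column z-scoring flag
exists). k-means uses k-means++ initialization with `n_restarts` (default
10) restarts and an explicit seed; empty-cluster handling is scikit-learn's
deterministic re-seeding. The WCSS-vs-k curve is the model-selection index;
`suggest_k` marks the knee (maximum perpendicular distance to the endpoint
chord after rescaling both axes to [0, 1]) but is advisory — the pipeline
k is user-set, default 20 for a 90-ROI atlas.

## Label alignment

`sort_labels` canonicalizes one run: scanning ROIs in atlas order, each
unseen raw label is assigned the next new label via a hash map, repeated
labels reuse their replacement. The output is invariant to any bijective
relabelling of the input, so runs that reach the same partition always get
identical label vectors.

`match_labels` aligns a target clustering to a reference: target clusters
take the reference label they overlap most (ROI counts by default; Jaccard
optional), assigned greedily in descending overlap with ties broken by
smaller reference label then smaller target label, each reference label
used at most once; leftover target clusters get fresh labels above the
reference maximum, in ascending target-label order. The exact matching
criterion for "similar spatial pattern" is underdetermined, so an exact
maximum-total-overlap assignment (Hungarian) is provided behind
`method="exact"` for comparison; on separable data the two agree. Matching
never alters the target partition, only its names.

## Synthetic data

The generator emulates BOLD at the spectrum level only: band-limited
Gaussian noise made by spectral masking (zeroing FFT bins outside the band),
summed with chosen relative powers and z-scored. Defaults are 220 samples at
fs = 0.5 Hz — a 225-volume acquisition minus five dummy volumes — with band
defaults straddling the low (0.01–0.03 Hz), mid (0.03–0.08 Hz) and high
(0.08–0.2 Hz) ranges where BOLD modes concentrate. Per-ROI-per-subject
random substreams derive from the master seed, so extending a dataset never
perturbs existing subjects.

What this does not emulate: hemodynamic response shape, 1/f background,
physiological confounds, spatial correlation between ROIs, or inter-subject
variability structure. Passing tests therefore demonstrate the correctness
and stability of the decomposition/feature/clustering machinery under known
spectral content — not that real data will form clusters this separable.

## Problem sizes and numerical tolerances

Ensemble statements (median IMF count, HWF band positions, dyadic filter-
bank ratios) use 200 white-noise series of 220 samples, the series length
of the larger acquisition protocol. Cluster-recovery and label-stability
suites use 10–12 ROIs, 2–5 subjects and 20 seeds with well-separated planted
bands. Reconstruction is asserted at 1e-8 relative; analytic-signal
identities at 1e-10; single-tone HWF recovery within 10% (edge effects on
220-sample windows dominate that budget). Degenerate inputs fail loudly:
constant series cannot be z-scored or assigned a frequency, all-zero
signals have undefined phase, and monotonic signals yield zero IMFs with
the residue equal to the input.

## Known limitations

- No ensemble EMD (EEMD/CEEMDAN): mode mixing on real, noisy BOLD is not
  mitigated beyond what plain sifting provides.
- Sifting constants are conventions; mode counts near the decision boundary
  (4 vs 5 IMFs at n = 220) are sensitive to them.
- The knee rule is a heuristic; on curves without a clear elbow it returns
  the smallest k with a warning.
- Greedy label-matching can be suboptimal when clusters merge or split
  heavily across datasets; inspect the overlap matrix (and the Hungarian
  option) in such cases.
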