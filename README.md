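# freqclust

Frequency clustering of resting-state fMRI ROI time series.

Slow BOLD fluctuations are not one undifferentiated "low-frequency" signal:
different brain regions carry different mixtures of oscillatory components.
`freqclust` groups atlas-defined regions of interest (ROIs) by the
time-frequency content of their resting-state BOLD signals, for researchers
who want a data-driven, frequency-based parcellation of functional networks
rather than one based on pairwise correlation.

## Method

For each ROI time series *x(t)* (sampled at `fs = 1/TR`, typically 0.5 Hz):

1. **Empirical mode decomposition (EMD).** The sifting algorithm splits the
   signal into intrinsic mode functions (IMFs) and a monotonic residue,

   ```
   x(t) = Σᵢ IMFᵢ(t) + r(t)
   ```

   Each IMF has balanced extrema/zero-crossing counts and a locally zero
   mean envelope; extraction order runs from the highest-frequency mode down.

2. **Hilbert weighted frequency (HWF).** The analytic signal
   *z(t) = x(t) + i y(t) = a(t) e^{iφ(t)}* of each IMF gives an instantaneous
   amplitude *a(t)* and frequency *ω(t) = dφ/dt*; the mode's HWF is the
   amplitude-squared-weighted mean

   ```
   HWF = [ Σᵢ ω(i) a²(i) / Σᵢ a²(i) ] / 2π     (Hz)
   ```

3. **Clustering.** The first five HWFs of every ROI, concatenated across
   subjects, form an ROI × (5·S) feature matrix clustered with k-means under
   squared Euclidean distance. The within-cluster sum of squares (WCSS) as a
   function of k supports choosing the cluster count (default k = 20 for a
   90-ROI atlas).

4. **Label alignment.** k-means labels are arbitrary, so the package
   canonicalizes them by first appearance along the atlas scan order
   (*label-sorting*) and aligns clusterings across runs or datasets by
   greedy maximum spatial overlap against a reference (*label-matching*).

A synthetic-data generator produces BOLD-length series with controlled band
content and planted cluster structure, so the whole pipeline is testable
without fMRI data.

## Worked example

```
$ freqclust simulate --n-subjects 3 --n-rois 10 --groups 2 --seed 1 --out fx
wrote 3 subjects to fx
$ freqclust run --k 2 --seed 0 --input fx/sub001.csv --input fx/sub002.csv \
      --input fx/sub003.csv --out out
wcss=0.00123755; outputs in out
```

The fixture plants two spectral groups (odd ROIs: 0.01–0.03 Hz band, even
ROIs: 0.08–0.18 Hz band). `out/hwf_sub001.csv` holds each ROI's five HWFs in
ascending order:

```
roi_id  hwf1   hwf2   hwf3   hwf4   hwf5  n_imfs_found
roi001   0.0 0.0000 0.0042 0.0113 0.0208             3
roi002   0.0 0.0084 0.0225 0.0574 0.1363             4
```

roi001 (low-band group) tops out near 0.02 Hz while roi002's dominant mode
sits near 0.14 Hz; narrowband series yield fewer than five IMFs, so the
missing low-frequency slots are padded with 0 and flagged. `out/labels.csv`
shows the recovered clusters with run-stable sorted labels:

```
roi_id,label,sorted_label
roi001,2,1
roi002,1,2
roi003,2,1
roi004,1,2
```

The planted two-group structure is recovered exactly (WCSS 0.0012 Hz², i.e.
tight clusters), and after label-sorting the group of roi001 is always
cluster 1 regardless of k-means initialization.

Library use mirrors the CLI: `gen_multisubject` → `run_pipeline(datasets,
PipelineConfig(k=2, seed=0))` returns the labels, feature matrix and
per-stage report.

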