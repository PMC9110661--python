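# pulsewave

Cardiac-frequency pulse-wave analysis of dynamic x-ray angiograms.

## The problem

A cerebral angiogram acquired at 6–7 frames/s samples faster than the human
cardiac rate (1–2 Hz), so the contrast signal in every pixel carries a
resolvable cardiac-frequency oscillation on top of the slow bolus passage.
`pulsewave` extracts that oscillation by cross-correlating each pixel's time
signal with a concurrently recorded pulse-oximeter trace in the Gabor-wavelet
domain. The result is a *wavelet angiogram*: the same frames and pixels as
the source run, but each pixel is a complex number whose magnitude is
cardiac-band magnitude and whose phase is cardiac phase relative to the
pulse trace.

From a single hand-placed region of interest (ROI) in a named artery and
vein, the package then classifies every intracranial pixel by phase
coherence — pixels within ±π/2 of the ROI mean phase are *relatively
coherent*, the rest *reciprocally coherent* — and binarizes the signed
coherent projection with Otsu's method to produce arterial, venous, and
parenchymal coherence masks. Applying the masks to the raw angiogram yields
time-signal curves whose mean arrival times

$$\bar t = \frac{\sum_i s_i t_i}{\sum_i s_i}$$

test the ordinal relation *arterial < parenchymal < venous*. With three
masks there are 3! = 6 possible orderings per projection; across eight
projections, 6⁸ = 1,679,616 joint combinations, of which exactly one is the
hypothesized ordering.

The package is aimed at researchers in cerebrovascular physiology and
biomedical image analysis who want to study arteriovenous pulse-wave
coupling from minimally invasive angiography, and it ships a fully
ground-truthed synthetic-angiogram generator (gamma-variate bolus envelopes
with envelope-gated cardiac modulation) to validate the entire chain.

## Worked example

```python
from pulsewave import run_pipeline

res = run_pipeline(seed=0)   # simulate -> transform -> masks -> curves
print(res.ref.freq_star)     # detected cardiac frequency
print(res.mats)              # mean arrival times per coherence mask
print(res.ordering.ordered)  # arterial < parenchymal < venous?
```

prints (seed 0, default 128×128 phantom, 256 frames at 6 Hz, cardiac
1.2 Hz, bolus SNR 3):

```
cardiac frequency (Hz): 1.190
mean arrival times (s): {'arterial': 10.24, 'parenchymal': 12.4, 'venous': 15.3}
ordered arterial < parenchymal < venous: True   (null probability 1/6)
phase separation (deg): 180.0
mask Jaccard: arterial 0.90, venous 0.64
```

The detected cardiac frequency matches the simulated 1.2 Hz rate to one
scale-grid step; the arterial and venous coherence masks — segmented from
nothing but two ~1-dozen-pixel seed ROIs and one analysis frame — recover
the assigned 180° arteriovenous phase reciprocity, overlap the true vessel
trees (Jaccard 0.90 / 0.64), and their bolus curves arrive in the
physiologic order.

The same stages are available from the shell for real or simulated data:

```
pulsewave simulate  --seed 0 --out-dir run/
pulsewave transform --angiogram run/angiogram.npz --trace run/trace.csv --out-dir run/
pulsewave masks     --angiogram run/angiogram.npz --wavelet run/wavelet.npz \
                    --arterial-roi run/roi_artery.json --venous-roi run/roi_vein.json \
                    --intracranial run/intracranial.png --out-dir run/
pulsewave curves    --angiogram run/angiogram.npz --masks-dir run/ --out-dir run/
pulsewave render    --wavelet run/wavelet.npz --out-dir run/png/
```

DICOM multiframe input is supported (`--polarity fluoro` inverts x-ray
brightness into contrast concentration); the portable `.npz` container, CSV
traces, PNG masks, and JSON ROIs are the interchange formats between stages.

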