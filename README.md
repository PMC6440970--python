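# cordfc — cross-modal functional connectivity of the spinal cord

`cordfc` analyses the intrinsic functional architecture of spinal-cord gray
matter from two complementary recording modalities and compares them:

* **Resting-state BOLD fMRI**: seed-based Pearson connectivity between the
  dorsal horns, intermediate gray matter (IGM) and ventral horns of the
  cervical cord, including the dorsal→ventral correlation *depth profile*
  whose U shape defines a functional IGM seed, and block-design
  (8 Hz vibrotactile, 30 s on/off) evoked responses.
* **Multi-shank electrophysiology**: stimulus-evoked local field potential
  (LFP) harmonic power and multi-unit spike responses, and resting-state
  LFP connectivity as broadband magnitude-squared coherence
  C(f) = |Sxy|² / (Sxx·Syy) between dorsal-horn and IGM channels within and
  across spinal segments.

The central quantities are the group means of three homologous pair
classes in both modalities — dorsal–dorsal within a segment, dorsal–IGM,
and dorsal–dorsal across segments — whose agreement
(Pearson r across pair classes) quantifies how faithfully resting-state
BOLD correlations reflect underlying neural coupling.

The package is exercised end to end on a **calibrated synthetic-data
module** (`cordfc.synth`) that emulates the study's spinal fMRI (cord
phantom with dorsal/IGM/ventral compartments, band-limited latent
connectivity structure, physiological noise, rigid motion, HRF-convolved
evoked responses) and its electrophysiology (4 shanks × 16 contacts at
150 µm, 500 Hz, coherent latents, line/respiration artifacts, 8-Hz evoked
harmonics, Poisson spikes).  See `docs/methods.md` for the model and its
calibration.

## Worked example

Generate a 5-minute resting electrophysiology recording, preprocess it
(60/120 Hz and respiration-harmonic notches, 1–150 Hz band-pass), and
compute band-mean coherence per pair class:

```python
from cordfc.synth.ephys import EphysGenConfig, simulate_lfp
from cordfc.ephys.signal import preprocess_lfp
from cordfc.ephys.connectivity import connectivity_summary
from cordfc.stats import modality_agreement

cfg = EphysGenConfig(seed=1, duration_s=300.0)   # 5-minute resting recording
rec = preprocess_lfp(simulate_lfp(cfg), resp_hz=cfg.resp_freq_hz)
table = connectivity_summary(rec, rec.meta["seed_channels"],
                             rec.meta["igm_channels"], subject="demo")
print(table.groupby("pair_class")["band_mean"].mean().round(3))

r = modality_agreement([0.49, 0.40, 0.26], [0.19, 0.12, 0.04])
print(f"cross-modal agreement r = {r:.4f}")
```

which prints

```
pair_class
DD_across              0.043
DD_within              0.194
D_IGM                  0.122
contralateral_depth    0.078
Name: band_mean, dtype: float64
cross-modal agreement r = 0.9963
```

The three pair classes order as within-segment dorsal–dorsal >
dorsal–IGM > across-segment dorsal–dorsal (the generator is calibrated so
a full 15-minute group study recovers 0.19 / 0.12 / 0.04), and the
correlation between the BOLD and LFP pair-class group means is ≈ 0.996 —
near-perfect cross-modal agreement of the connectivity structure.

A command-line interface wraps the same pipelines:

```bash
cordfc simulate fmri --seed 1 --out demo/          # NIfTI run + labels
cordfc preprocess --in demo/bold.nii.gz --labels demo/labels.nii.gz --out demo/pre
cordfc ephys-rest --lfp rec.h5 --band 1:100 --out demo/coh
cordfc report --fmri-table conn.csv --lfp-table coh.csv --out demo/report
```

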