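# bsnet — burst-suppression EEG source-network analysis

`bsnet` is a tested, reusable implementation of a source-level network
analysis for burst-suppression EEG: the alternating pattern of
high-amplitude slow-wave bursts (150–350 μV) and near-flat suppression
(< 25 μV) seen in deep coma, anesthesia and severe infantile
encephalopathies. The pipeline asks where the delta-band (1–4 Hz)
activity of each phase is generated, which brain regions are coherent
with the strongest source, and in which direction information flows
between them. It is aimed at neurophysiology researchers who want a
transparent, scriptable alternative to GUI toolboxes for this specific
analysis, with a ground-truth simulator in place of clinical recordings.

## What it computes

1. **Forward model** — analytic dipole potentials in a five-shell
   concentric-spheres head (white matter, grey matter, CSF, skull, scalp;
   infant-scaled defaults), a geometric 10–20 montage, and a lead field
   on a cubic source grid.
2. **Phase selection** — amplitude-based labeling of burst and
   suppression samples and concatenation into 60 s single-phase segments.
3. **Spectra** — multitaper (Slepian, NW=2, K=3) auto-/cross-spectral
   densities on 1 s epochs; pooled spectra; the dominant band; the
   burst/suppression relative SNR in dB.
4. **DICS beamforming** — spatial filters
   `A(r) = (LᴴC⁻¹L)⁻¹LᴴC⁻¹` from the 1–4 Hz band CSD; source power maps;
   automated reference selection (scalp-projected power maximum);
   iterative identification of sources coherent with the reference,
   with zero-gain constraints at already-found sources and a Monte-Carlo
   stopping rule; nulled-filter extraction of source time series.
5. **RPDC connectivity** — MVAR fits of the extracted signals at 32 Hz,
   renormalized partial directed coherence
   `λ_{ij}(f) = Z_{ij}ᵀV_{ij}⁻¹Z_{ij}` with its χ²(2) null, a per-channel
   block bootstrap threshold, and a time-reversal test that rejects
   zero-lag (volume-conducted) coupling. An edge is accepted only if all
   three tests pass at α = 0.01.
6. **Statistics** — within-subject Monte-Carlo surrogates (99th
   percentile of epoch-shuffled null maxima) for source significance and
   a Friedman rank test contrasting phases across subjects.
7. **Ground-truth generator** — a ten-node directed delta-band network
   (brainstem → thalamus → precuneus → somatosensory/prefrontal, silent
   deep nodes and symmetric cortical coupling in suppression) projected
   through the same forward model, with distributed background activity,
   calibrated to clinical burst/suppression amplitudes and SNR.

`docs/methods.md` documents every model, default and known limitation,
including an honest account of which parts of deep-source recovery are
and are not attainable with 19 electrodes.

## Worked example

```python
from bsnet import synth, pipeline

config = pipeline.PipelineConfig(n_surrogates=50, n_bootstrap=100, seed=7)
rec, truth = synth.assemble_burst_suppression(seed=0)
result = pipeline.run_subject(rec, config, subject="demo",
                              node_locations=truth.node_locations, seed=1)

print(f"relative SNR: {result.snr_db:.2f} dB")
print(f"dominant band: {result.band_peak_hz}")
for phase, pr in result.phases.items():
    print(phase, "sources:", pr.source_labels,
          "| edges:", pr.accepted_edges)
```

Output from this exact script:

```
relative SNR: 37.82 dB
dominant band: (1.0, 3.0)
burst sources: ['precuneus', 's2', 's3', 's4', 's5', 'somatosensory'] | edges: []
suppression sources: ['precuneus'] | edges: []
```

Reading it: the burst/suppression delta-band power ratio is 37.82 dB
(clinical recordings of this pattern show 36–39 dB); the pooled spectrum
peaks between 1 and 3 Hz; in both phases the strongest source is the
precuneus analogue of the simulation (labels come from the simulation's
ground-truth node positions; `s2`–`s5` are detections that fall outside
the labeled regions); the somatosensory source is recovered as coherent
with the reference; no directed edge passed all three significance
stages for this subject at these fast test settings.

The same pipeline runs from the shell:

```bash
bsnet simulate --n-subjects 2 --seed 0 --out sim/      # EDF + truth JSON
bsnet run --n-subjects 13 --seed 0 --out results/      # full cohort
```

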