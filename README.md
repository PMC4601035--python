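# p3net

Resting-state EEG coherence networks, P300 extraction, and their coupling
across subjects.

A recurring question in cognitive electrophysiology is whether the brain's
*resting* functional organization predicts how strongly it responds during a
task. `p3net` implements one concrete version of that analysis as a tested,
reusable pipeline:

1. **P3 extraction** — oddball-task EEG is average-referenced, band-pass
   filtered (0.5–6 Hz, zero-phase Butterworth), epoched around stimulus
   onset (−200…800 ms), baseline-corrected (−200…0 ms), screened at
   ±75 μV, and averaged per condition. On the target ERP, the P3 peak is
   the maximum in 300–500 ms post-stimulus; **latency** is the peak time
   and **amplitude** the mean over peak ± 50 ms (51 samples at 500 Hz),
   each averaged over the five centro-parietal electrodes
   CPz, CP1, CP2, Cz, Pz.
2. **Resting networks** — eyes-closed resting EEG is re-referenced,
   filtered to 1–30 Hz, cut into 10-s segments, amplitude-screened
   (±100 μV), and every channel pair gets the band-averaged
   magnitude-squared coherence

   Coh(f) = |P̂xy(f)|² / (P̂xx(f) · P̂yy(f)),

   estimated by Welch averaging (2-s Hann windows, 50% overlap → 9 windows
   per segment) and averaged over 1–30 Hz and over segments into a
   symmetric 21×21 weighted adjacency matrix W.
3. **Graph indexes** — on W with edge lengths l = 1/w: mean weighted
   clustering coefficient **C** (geometric-mean triangle intensity),
   global efficiency **Ge** = ⟨1/d_ij⟩, mean local efficiency **Le**
   (efficiency of each node's neighbour subgraph), characteristic path
   length **L** = ⟨d_ij⟩, and mean functional connectivity
   **MFC** = ⟨w_ij⟩.
4. **Cross-subject statistics** — Pearson correlations (exact-t p-values)
   between every index and P3 amplitude/latency, plus an edge-wise screen
   of all 210 connections (uncorrected p < 0.01 by default, with an
   optional Benjamini–Hochberg correction).

Because no public dataset accompanies this protocol, `p3net` ships a
first-class **synthetic cohort generator**: 21-channel, 500 Hz EEG with
shared alpha/theta oscillators mixed against channel-private pink noise,
an oddball task with planted centro-parietal P3 bumps, planted artifact
bursts, and — crucially — a programmable cross-subject correlation
(`coupling_rho`) between a subject's latent network efficiency and their
P3 amplitude. Every claim in the test suite is checked against this known
ground truth.

## Worked example

```python
from p3net import CohortSpec, analyze_cohort, correlate_cohort, simulate_cohort

spec = CohortSpec(n_subjects=19, coupling_rho=0.6, seed=1, dtype="float32")
subjects, truths = simulate_cohort(spec)
p3, metrics, adjacencies = analyze_cohort(subjects)
corr, edges = correlate_cohort(metrics, p3, adjacencies)
print(p3[["subject_id", "amplitude", "latency"]].head(3))
print(corr[corr.y == "amplitude"][["x", "r", "p"]])
```

Output (19 simulated subjects, seed 1):

```
  subject_id  amplitude  latency
0    sub-000   1.108803    404.4
1    sub-001   0.491662    423.6
2    sub-002   1.465916    354.8
     x         r         p
0  MFC  0.598852  0.006744
2    C  0.599347  0.006687
4   Ge  0.598852  0.006744
6   Le  0.598852  0.006744
8    L -0.553144  0.014027
```

Reading this: each subject's P3 amplitude (μV) and latency (ms) come from
their simulated task ERP; the correlation table shows that subjects with
more efficient resting networks (higher MFC/C/Ge/Le, lower L) produced
larger P3 amplitudes — the positive r's for the efficiency-type indexes and
the negative r for path length recover the programmed coupling of 0.6
after measurement attenuation. Amplitudes are on the post-average-reference
scale, which is smaller than the planted peak amplitudes by a fixed
spatial factor.

The same pipeline runs from the shell:

```bash
p3net run-all --config config.yaml --seed 1 --out out/
# stage-wise: p3net simulate | erp | network | correlate  (identical bytes)
```

writing the cohort, `p3.tsv`, per-subject adjacency TSVs, `metrics.tsv`,
`correlations.tsv`, `edges.tsv`, and a `report.json` whose hash is
reproducible given config + seed.

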