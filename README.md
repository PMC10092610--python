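# ctcgamma

Analysis of **late sensory-induced beta/gamma oscillations** (200–700 ms
post-stimulus) in four-site corticothalamic recordings — cortical EEG, layer 6
(L6), and the thalamic VPm and PoM nuclei — together with a seeded synthetic
session generator that emulates a saline vs. ketamine (NMDA-antagonist)
contrast, so the entire pipeline is testable without any recorded data.

The package is aimed at systems/computational neuroscientists studying how a
psychotomimetic dose of an NMDA-receptor antagonist disturbs stimulus-related
oscillations in the somatosensory cortico-thalamo-cortical loop: ongoing
("baseline") beta (17–29 Hz) and gamma (30–80 Hz) power goes **up**, the
stimulus-**induced** late beta/gamma response goes **down**, gamma-band signal
complexity (multiscale entropy) rises in L6 and VPm, and L6–VPm gamma
coherence collapses.

## What it computes

For trial *i* with baseline band power `P_b[i]` (the 500 ms before each
stimulus) and late-window band power `P_e[i]` (200–700 ms after it), spectra
are single-segment Hamming periodograms at 2 Hz resolution and band power is
the sum over in-band bins. The core statistics are:

- **Average normalised power** — the mean of per-trial ratios, not the ratio
  of means:

  `P_v = (1/N) Σ_{i=1..N} P_e[i] / P_b[i]`,  N = 40 trials (10 per rat, 4 rats).

- **Evoked/induced decomposition** — per trial,
  `induced[i] = total[i] − evoked − P_b[i]`, where `evoked` is the band power
  of the spectrum of the time-domain trial average of the same late epochs
  (random-phase activity cancels in the average; phase-locked activity does
  not). Reported as % change relative to baseline.

- **Band-limited multiscale entropy (MSE)** — the raw epoch is filtered into
  the band, coarse-grained at scale τ (`y_j = mean(x[(j−1)τ+1 .. jτ])`), and
  sample entropy `−ln(A/B)` (m = 2, r = 0.2 × SD, Chebyshev distance) is
  computed per scale 1–20, per trial, then averaged across the 40 trials.

- **Magnitude-squared coherence** — `C(f) = |S_xy|² / (S_xx S_yy)` via Welch
  cross-spectra (8 Hamming segments, 50 % overlap per 500 ms epoch), averaged
  over in-band bins, per trial, for L6–VPm, L6–PoM and VPm–PoM.

- **Statistics** — paired t (df = 39), Wilcoxon matched-pairs signed-rank,
  one-way ANOVA with Holm–Šidák post-hocs, and a balanced two-way ANOVA
  (time × condition) whose interaction term tests the induced-power contrast.

## Worked example

```python
from ctcgamma import synth, pipeline

cfg = synth.SessionConfig(sampling_rate=1000.0, seed=1)   # 40 trials, 4 channels
pair = synth.generate_condition_pair(cfg)                 # saline + ketamine sessions
bundle = pipeline.run_full_analysis(*pair)

print(bundle.power_tests.query("band == 'gamma'")[["channel", "baseline_ratio"]])
print(bundle.signature["signature_recovered"])
```

With seed 1 this prints baseline gamma power ratios (ketamine/saline) of
**1.88 (EEG), 3.07 (L6), 3.23 (VPm), 1.84 (PoM)** — ongoing gamma roughly
doubles or triples everywhere — and `signature_recovered: True`. The rest of
the bundle shows the full four-way signature: L6 normalised gamma power
`P_v` falls from **2.61** (saline) to **1.34** (ketamine); the induced gamma
%-change collapses from **+134 %** to **+20 %** (interaction F = 43.7);
gamma-band MSE rises in L6 (0.89 → 0.99, paired T(39) = 5.6) and VPm
(0.89 → 1.00, T(39) = 4.8) but not PoM (0.87 → 0.87); and L6–VPm gamma
coherence drops **61 %** (0.53 → 0.21, Wilcoxon significant) while the
PoM pairs are unchanged.

The same experiment from the shell:

```bash
ctcgamma simulate --seed 1 --sampling-rate 1000 --out sim/
ctcgamma analyze --saline sim/saline --ketamine sim/ketamine --out out/
ctcgamma report --bundle out/
```

`analyze` writes every per-trial value and test as TSV plus `summary.json`;
`report` renders bar charts, MSE-versus-scale curves and a text summary.

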