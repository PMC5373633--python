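# brduquant

Quantitative analysis of BrdU/EdU DNA-replication labelling experiments.

Cells in S phase incorporate thymidine analogues (BrdU, EdU) into nascent
DNA during a labelling pulse; immunofluorescence against the analogue then
marks replicating nuclei far above the non-specific background of
non-replicating cells. `brduquant` implements the full quantitative chain
used to score such experiments:

- **`synthgen`** — a ground-truth simulator: bimodal cell populations with a
  labelled fraction *F* (default 0.44), 2N–4N DNA content across G1/S/G2M,
  two-channel (DAPI + replication signal) microscopy rendering, flow-style
  event tables, and a first-order antibody wash-dissociation model with
  formaldehyde stabilisation.
- **`segment`** — DAPI nucleus segmentation (smoothed Otsu + watershed) and
  IoU-based matching against ground truth.
- **`quantify`** — per-nucleus mean signal and integrated DAPI (DNA proxy).
- **`replistat`** — the core statistic: the **R/non-R ratio**. With labelled
  fraction *F* and *n* nuclei ranked by signal, the mean of the
  (*F* − 0.1)·*n* most-labelled nuclei (R, certainly replicating) is divided
  by the mean of the (0.9 − *F*)·*n* least-labelled nuclei (non-R, certainly
  not). At *F* = 0.44 and *n* = 10,000 the R group holds **3,400** nuclei.
  Also: *F* estimation by exact Otsu thresholding of log signal (with a
  reliability flag keyed to the ratio-above-3 separation guideline) and
  normalisation to a 100% reference condition.
- **`kinetics`** — first-order dissociation of the BrdU–antibody complex
  during washing, retained = exp(−k_off·t), with k_off = ln(5)/5 ≈ 0.32/min
  (80% signal loss in a 5-minute wash), rate fitting from time courses, and
  the piecewise-linear formaldehyde stabilisation-efficiency curve.
- **`cytometry`** — bivariate cell-cycle gating (replication signal vs
  G1-peak-normalised DNA content) shared by the image and flow paths.

The package is organised as an analysis project: the numbered drivers in
`analysis/` run the study end to end and write their tables under
`results/`; every computation lives in the library under `src/brduquant/`.

## Worked example

```bash
python analysis/01_simulate_population.py
python analysis/02_segment_and_measure.py
python analysis/03_rnonr_statistic.py
python analysis/04_wash_kinetics.py
python analysis/05_cell_cycle_gating.py
```

prints (seed 0):

```
simulated 10000 cells; S fraction 0.441 (target 0.44); rendered 400 nuclei -> scratch/data
segmented 394 nuclei of 400; 96.0% matched at IoU>=0.5 (median IoU 0.872)
estimated F = 0.441 (reliable: True); truth path: R group n=3400, non-R n=4600, ratio 6.74; image path (394 nuclei): ratio 6.50
k_off = 0.3219/min (refit from time course: 0.3074); retained at 5/30 min: 0.200 / 6.40e-05
            unwashed: R/non-R   6.74, component ratio  5.997
           wash_5min: R/non-R   2.18, component ratio  1.999
          wash_30min: R/non-R   1.12, component ratio  1.000
   stabilised_0.2pct: R/non-R   6.87, component ratio  6.112
gated fractions: {'G1': 0.453, 'S': 0.44, 'G2M': 0.107} | truth: {'G1': 0.453, 'S': 0.441, 'G2M': 0.107} | max error 0.000
```

Reading the numbers: the simulated culture reproduces the ~44% replicating
fraction; segmentation recovers 96% of nuclei; the R/non-R ratio of ~6.7
reflects the generator's 6-fold component separation (the rank-based
statistic runs slightly above the true component ratio — see
`docs/methods.md`); an unstabilised 5-minute wash collapses the component
ratio to 1 + 0.2·(ρ−1) ≈ 2.0 and a 30-minute wash to 1.0 (complete loss of
specific signal), while 0.2% formaldehyde stabilisation preserves it; and
gating recovers the generator's phase fractions essentially exactly at
n = 10,000.

The same operations are available as a CLI (`brduquant simulate | segment |
measure | rnonr | kinetics | gate | run`); `brduquant run --out-dir <dir>`
executes the whole pipeline and writes a manifest with file hashes that is
bit-identical across reruns with the same seed.

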