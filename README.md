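# caspaseflow

Single-cell FRET imaging analysis for caspase cascades: from four-channel
fluorescence of two cleavable protease probes to per-cell kinetic response
indices and population-level correlation statistics — with a ground-truth
synthetic cascade generator so that every stage is testable without any
microscope data.

## Who this is for, and the problem it solves

Apoptosis is executed by a protease cascade: the initiator caspase-9
activates the executioner caspase-3, which digests key substrates.
Cleavable FRET probes report each protease in live cells — a
fluorescent-protein donor linked to a dye acceptor by a caspase-cleavable
peptide, so the donor/acceptor intensity ratio rises as the probe pool is
cleaved. The caspase-9 probe pairs GFP with Alexa Fluor 532, the caspase-3
probe RFP with Alexa Fluor 660, imaged together through four detection
bands (460–510 / 520–550 / 575–620 / 655–755 nm) every 20 s.

Turning those recordings into biology takes a chain of quantitative steps,
each easy to get subtly wrong: detection bands collect leakage from all
four fluorophores (linear spectral unmixing); ratios must be normalized to
initial values; response onsets detected against local baselines; and
per-cell indices correlated across a heterogeneous population.
`caspaseflow` implements that chain as a tested library for experimenters
analyzing such recordings and for methodologists studying what
single-cell kinetic statistics can and cannot recover.

## The model and statistics at its core

Each cell's normalized ratio per probe is a baseline of 1, a sigmoidal
rise from `t_init` to `t_sat`, and a plateau at `1 + scale`. From a
normalized trace R(t) the package extracts, per probe:

* response **initiation** t_i — first sustained excursion above
  mean + 3·SD of the 10 preceding frames (the onset rule);
* response **saturation** t_s — first sustained attainment of
  1 + 0.95·(max R − 1); **duration** = t_s − t_i;
* **response scale** max R − 1 and **maximum ratio** max R;
* **slope** — least-squares rise rate on [t_i, t_s] (1/s);
* **integration** ∫ max(R − 1, 0) dt over [t_i, t_s] — cumulative
  enzymatic output;
* **time at max**, reported separately from saturation;

and per cell the signed cross-intervals between the two probes:
promotion = t_i³ − t_i⁹, activation = t_i³ − t_s⁹, completion =
t_s³ − t_s⁹. Population analysis assembles the cells × indices table,
its Pearson correlation heatmap (R lower triangle, R² upper, positive
red / negative blue) and paired t-tests between the caspases.

The synthetic generator draws heterogeneous populations from truncated
normal marginals coupled by a Gaussian copula, so cross-index
correlations can be planted exactly (and infeasible, non-PSD requests are
rejected). Its default plants the cascade's headline structure — the
caspase-9 response scale and integration inversely coupled (r = −0.8) to
the completion interval: the more cumulative initiator activity, the
sooner executioner activity saturates. Rendering maps trajectories
through probe photophysics and a spectral cross-talk matrix into noisy
channel traces or labeled image stacks, with the exact index values of
every cell recorded as ground truth.

## Worked example

`examples/` holds one short script per capability. The population study
(`python examples/population_study.py`) runs the full path — simulate →
render 4 channels → unmix → ratios → indices → statistics — and prints:

```
accepted 200 of 200 cells
r(response_scale_c9, completion_interval) = -0.73
r(integration_c9,    completion_interval) = -0.69
  (strongly negative: the more total caspase-9 output, the faster
   caspase-3 execution completes)
paired t-test on time_at_max: c3 mean 2237.9 vs c9 mean 2017.9, p = 4.23e-14
paired t-test on response_scale: c3 mean 1.1 vs c9 mean 0.6, p = 3.68e-83
```

Read: the planted inverse coupling (−0.8) is recovered through the entire
measurement chain at −0.73/−0.69 (slight attenuation from detection
noise), and the executioner caspase-3 reaches its maximum later and
rises further than the initiator caspase-9 — the expected ordering of a
cascade. Stage outputs (population table, correlation matrix CSV, heatmap
PNG, t-test JSON, run manifest) land in `scratch/population_study/`.

Other examples: `simulate_cascades.py` (ground-truth generation),
`unmix_demo.py` (cross-talk inversion, noise-free error ~3e-16),
`extract_indices.py` (per-cell indices vs truth), `image_stack_roundtrip.py`
(image path ≡ trace path), `bulk_cleavage.py` (in-vitro first-order
cleavage, half-change at ln 2/k).

A thin CLI mirrors the pipeline for shell use:

```sh
caspaseflow run-all --seed 1 --out run/        # full synthetic study
caspaseflow simulate / unmix / quantify / indices / population   # stages
caspaseflow validate --mode traces_csv --traces-csv mydata.csv   # input checks
```

Real data enters as per-cell channel-trace CSVs (long format), or as a
T×C×Y×X TIFF stack plus 16-bit ROI label mask, with the mixing matrix as
JSON.

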