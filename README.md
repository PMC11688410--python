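# icage

Simulation and analysis pipeline for home-cage operant reaction-time
experiments (IntelliCage-style event streams).

A cohort of RFID-tagged mice lives in a four-corner operant cage for a
34-day protocol: adaptation shaping (free access → door → nose poke →
restricted 3-h water window), place preference and reversal, four
reaction-time task blocks of rising difficulty (pre-cue delays {2 s} or
{2, 4, 8 s}, cue durations 7/3/1 s), and a place-avoidance/extinction
block. The package provides:

- **`icage.events`** — the canonical event model (visits, nose pokes,
  lick bursts, roster), tab-delimited import/export, a single-file
  SQLite store, and 24-h day slicing (entry-time rule).
- **`icage.schedule`** — the 34-day phase calendar, water-access
  windows, least-visited-corner assignment balanced by count and
  genotype, diagonal reversal corners, and the 48-h lick-free
  rescue/removal rule.
- **`icage.engine`** — the corner-contingency state machine: door
  openings, air puffs, and adjudication of every reaction-time trial
  into premature / correct / abandoned (first poke initiates, first
  post-initiation poke before cue offset decides).
- **`icage.simulate`** — a generative cohort simulator (circadian
  Poisson visits, premature-poke hazard `h`, exponential cue-response
  rate `r`) with closed-form expected outcome fractions
  (`p_prem = 1 − e^{−hD}`, `p_corr = e^{−hD}(1 − e^{−rC})`) and packaged
  scenarios (`paper_like`: 14 + 10 animals with a genotype contrast;
  `null`: identical groups). Pre-cue delays come from a counter-based
  stream keyed by (seed, animal, trial index), so replaying simulated
  events through the engine reproduces the ground-truth trial table
  exactly.
- **`icage.metrics`** — every per-mouse per-day dependent variable
  (visits, licks, water-window visits, place-preference %Correct, trial
  counts and %abandoned/%premature/%correct overall and per pre-cue
  duration, puff-corner visit counts).
- **`icage.stats`** — two-way mixed repeated-measures ANOVA (genotype
  between × day within, classical univariate F), Bonferroni-corrected
  post hocs gated on a significant interaction, and pooled-variance
  two-sample t-tests (α = 0.05).

## CLI

```sh
icage simulate --seed 1 --scenario paper_like --out-dir runs/sim
icage analyze  --in-dir runs/sim --out-dir runs/analysis
icage stats    --metrics runs/analysis/metrics_wide.csv --out-dir runs/stats
icage report   --metrics runs/analysis/metrics_wide.csv --out-dir runs/report --plot
```

`simulate` writes `visits.tsv` / `pokes.tsv` / `licks.tsv` /
`roster.tsv` plus the ground-truth `trials_truth.csv` and a manifest
with the seed. `analyze` re-adjudicates the event stream (using the
manifest's seed for the pre-cue draws), applies the dropout rule, and
writes wide/long metric tables. `stats` produces an effects CSV (one
row per phase × DV × effect) and a gated post-hoc CSV.

## Reproducibility

Every stochastic path is driven by an explicit seed; the same
(config, seed) pair yields byte-identical event tables, trial logs, and
metric files.
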