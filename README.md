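# cytoval

Analytical-validation toolkit for rare-event mast-cell quantification by
flow cytometry. It covers the full validation study end to end:

- **`cytoval.io_formats`** — listmode event I/O (CSV and a minimal FCS 3.1
  list-mode/float dialect) and experiment-design configuration (TOML).
- **`cytoval.synthetic_cytometry`** — labeled synthetic cell suspensions for
  peripheral blood (PB), bone marrow (BM) and lymph node (LN), with
  CD117+/IgE+ mast-cell spike-ins at nominal fractions defined against the
  viable in-gate denominator, plus full dilution-series generation.
- **`cytoval.gating`** — the three-stage gating chain: FSC/SSC morphology
  polygon, 7-AAD viability threshold, IgE×CD117 quadrants; the readout is
  the double-positive percentage of viable in-gate events.
- **`cytoval.assay_stats`** — limit of blank (mean + 1.65 SD), detection
  limit (LOB + 1.65 SD), CV-rule quantification limit, precision profile,
  RMS overall precision, expanded-uncertainty (k = 2) reporting, and
  diagnostic nodal cut-off classification (> 0.3% metastatic, > 4% HN3).
- **`cytoval.passing_bablok`** — from-scratch Passing-Bablok regression:
  shifted median of pairwise slopes, rank-based confidence intervals,
  constant/proportional-bias verdicts.
- **`cytoval.pipeline_cli`** — simulate → gate → validate → report
  orchestration and the `cytoval` command line.

## CLI

```bash
# one spiked LN sample, 100k events, 0.3% mast cells
cytoval simulate --matrix LN --fraction 0.3 --events 100000 --seed 7 --out run.fcs

# gate it with the default gate set
cytoval gate --in run.fcs --min-events 100000 --json gated.json

# full validation study for one matrix (smaller min-events = faster)
cytoval run-all --matrix LN --seed 1 --min-events 100000 --out-dir out/

# statistics from externally gated measurements
cytoval validate --design design.toml --results measurements.csv --json report.json

# method-comparison regression on its own
cytoval pbfit --x expected.csv --y measured.csv --gamma 0.95 --json fit.json
```

`run-all` writes a JSON report, a human-readable summary of the detection
limits / precision / accuracy, and an expected-vs-measured regression plot.

## Python API sketch

```python
from cytoval import (ExperimentDesign, run_validation)

design = ExperimentDesign(matrix="LN", rng_seed=1, min_events=100_000)
report = run_validation(design)
print(report.limits.lob, report.limits.llod, report.limits.lloq)
print(report.overall_precision, report.regression.slope, report.emu)
```
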