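# bpref — blood-pressure reference values for 2-year-old children

`bpref` is a small, fully reproducible pipeline for constructing
height-adjusted blood-pressure (BP) reference tables in toddlers from
triplicate auscultation measurements. It covers every stage of such a
study:

1. **Synthetic cohort generation** — draws a realistic cohort of
   2-year-olds (height, weight, season, posture, triplicate SBP/DBP
   readings rounded to 2 mmHg) from a configurable truth surface, so the
   whole analysis can be exercised and validated end to end without any
   individual-level data.
2. **Measurement selection** — reduces each triplicate to one value per
   channel: the mean of the 2nd and 3rd readings when they differ by
   less than 5 mmHg, falling back to the (1st, 2nd) pair, and to the
   (1st, 3rd) pair only when the 2nd reading is missing.
3. **Exclusion cascade** — chronic disease, missing/zero readings,
   unstable condition (crying, moving), BP instability, missing
   covariates, implausible height, and age out of range, accounted per
   channel in a flowchart-style report with exact conservation.
4. **Height Z-scoring** — LMS-based height-for-age Z-scores against a
   pluggable growth standard (a synthetic standard ships with the
   package; it is *not* national reference data).
5. **Centile models** — the primary model is a penalized-likelihood LMS
   (BCCG) fit with smooth L(Zht), M(Zht), S(Zht) curves, effective
   degrees of freedom chosen by BIC; a quartic-polynomial
   normal-residual model is included for comparison.
6. **Reference tables** — BP percentiles (50/90/95/99th) tabulated at the
   5/10/25/50/75/90/95th height percentiles, rounded half-up to integer
   mmHg, with serialization and table-diff utilities.
7. **Diagnostics + CLI** — Q–Q and residual-density data, observed vs.
   fitted centile curves, and a `bpref` command-line pipeline that writes
   a provenance manifest (SHA-256 of every output).

## Why

Pediatric BP reference values below age 3 are scarce: oscillometric and
auscultation readings differ systematically, and toddlers' BP depends on
body size, so references must be height-adjusted. Building such tables
involves several error-prone steps (reading selection, exclusions,
skew-aware centile estimation). This package makes each step an
explicit, tested, seedable component.

## Worked example

Simulate a boys-only cohort, run the exclusion cascade, fit the LMS
model and build the SBP reference table:

```python
from bpref.simulate import SimulationConfig, generate_cohort, DEFAULT_SEED
from bpref.growth import synthetic_growth_standard
from bpref.cohort import apply_exclusions
from bpref.lms import LMSModel
from bpref.tables import build_reference_table

standard = synthetic_growth_standard()
cfg = SimulationConfig(n_children=3139, pct_boys=1.0, seed=DEFAULT_SEED)
df = generate_cohort(cfg, standard)

sbp_set, dbp_set, flow = apply_exclusions(df, standard)
print(flow.to_text())

res = LMSModel(sbp_set["zht"].to_numpy(), sbp_set["bp"].to_numpy(),
               sex="boy", outcome="sbp").fit()
print(res.summary())

tab = build_reference_table(res)
print(tab.grid.to_string())
print("cell(50, 95) =", tab.cell(50, 95))
```

Output (verbatim):

```text
records in: 3139
[SBP]
  excluded_chronic: 0
  excluded_missing_or_condition: 0
  excluded_unstable_bp: 6
  excluded_covariates_or_height_outlier: 0
  excluded_underage: 0
  analyzed: 3133
[DBP]
  excluded_chronic: 0
  excluded_missing_or_condition: 0
  excluded_unstable_bp: 14
  excluded_covariates_or_height_outlier: 0
  excluded_underage: 0
  analyzed: 3125

LMS (BCCG) centile model
  stratum      : boy / sbp
  n            : 3133
  edf (L, M, S): (1.0, 3.0, 1.0)
  loglik       : -11055.60
  BIC          : 22151.44
  Zht range    : [-4.54, 4.45]
  centiles at Zht = 0:
    p=0.05:    78.2 mmHg
    p=0.50:    91.0 mmHg
    p=0.95:   105.4 mmHg

height_percentile   5    10   25   50   75   90   95
bp_percentile
50                  90   90   90   91   92   93   93
90                 101  101  101  102  103  104  104
95                 104  104  105  105  107  107  107
99                 111  111  111  112  113  114  114

cell(50, 95) = 105
```

The same pipeline is available from the command line:

```bash
bpref simulate --n 3139 --seed 20150401 --out cohort.csv
bpref preprocess --cohort cohort.csv --out prep
bpref fit --analyzed prep/analyzed_sbp.csv --sex boy --outcome sbp --out fit
bpref table --model-json fit/lms_model_boy_sbp.json --out table.csv
bpref diagnose --model-json fit/lms_model_boy_sbp.json \
    --analyzed prep/analyzed_sbp.csv --sex boy --out diag
# or everything at once (all strata, both models, provenance manifest):
bpref run --seed 20150401 --out run
```

## Reproduction

The end-to-end reference-table computation is packaged as a script that
regenerates everything from scratch (cohort simulation → selection →
exclusions → LMS fit → rounded table) and reports the anchor table cells
as JSON:

```bash
python scripts/acceptance.py --seed 20150401 --out results/acceptance.json
```

This writes, for three strata (boys SBP, girls SBP, boys DBP), the
median-height 50th/95th/99th-percentile cells and per-stratum analyzed
counts, e.g. `{"t1": {"value": 91, "n": 3133}, ...}`. Identical seeds
reproduce identical output byte for byte; different seeds vary the cells
by about ±1 mmHg.

Run the test suite with:

```bash
python -m pytest -o addopts= -p no:cacheprovider -q tests/
```

`tests/test_acceptance.py` holds the end-to-end statistical checks
(selection oracle, BCCG identities, LMS recovery across 20 seeds,
LMS-vs-polynomial agreement, anchor-cell recovery, flowchart counts);
the remaining files are fast unit/property tests.

## Documentation

See [docs/methods.md](docs/methods.md) for the statistical model, the
penalized-likelihood fitting details, the synthetic-cohort design, all
default parameters, and known limitations.
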