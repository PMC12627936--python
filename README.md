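# asthma-adherence

A weekly-cycle Markov cohort model of difficult-to-control asthma in adults,
mapping population medication-adherence levels to long-term exacerbations,
life years, discounted QALYs and discounted NHS/PSS costs (2022 GBP), with a
seeded probabilistic sensitivity analysis (PSA).

## Model in brief

* Five states: controlled, partially controlled, uncontrolled, exacerbation,
  dead. The exacerbation state lasts one weekly cycle, with a 39%/61%
  admitted/non-admitted severity split entering as a cost and utility
  mixture. Asthma-specific death occurs only from the exacerbation state;
  background mortality from a life table applies from every alive state.
* Treatment effectiveness is a piecewise function of adherence `a`:
  `E = a` for `a <= 0.30`, `E = 1 - exp(-5 * (a - 0.2287))` for
  `0.30 < a < 1`, and `E = 1` at `a = 1`.
* Weekly transition rows at adherence `a` are the convex combination
  `E(a) * row_full + (1 - E(a)) * row_zero`, where the zero-adherence rows
  are derived from the full-adherence rows by applying odds ratios to the
  exacerbation-entry probabilities.
* Default horizon 20 years (1,040 weekly cycles); QALYs and costs
  discounted at 3.5%/yr; life years reported undiscounted.
* The PSA draws tagged parameters (beta / gamma / lognormal / dirichlet),
  shares each draw across all adherence levels (common random numbers) and
  reports means with percentile 95% intervals.

The package ships a documented stand-in parameter fixture
(`default_parameters()`) and a synthetic life table
(`default_life_table()`); values printed in the source publication
(initial state distribution, admitted fraction, discounting, horizon,
outpatient intervals) are used verbatim, everything else is a plausible
stand-in that can be replaced by transcribing the deposited supplementary
parameter list into the YAML schema (see `write_parameters` for the
format).

## CLI

```sh
# deterministic outcomes per adherence level
asthma-adherence run --grid 0.1,0.5,1.0 --out out/

# PSA with 95% intervals and Figure-style plots (seed is required)
asthma-adherence psa --iterations 1000 --seed 1 --out out/

# paired comparison of two adherence levels (common random numbers)
asthma-adherence compare --from 0.5 --to 0.7 --iterations 1000 --seed 1 --out out/
```

Common flags: `--params <file>` (YAML parameter file, defaults to the
built-in fixture), `--life-table <csv>` (`age,qx[,sex]`), `--grid`,
`--horizon`, `--discount`, `--config <yaml>` (file mirroring the flags;
flags win). Outputs are tab-separated tables with `#` audit headers
(package version, seed, input checksums); reruns with the same inputs are
byte-identical. Exit codes: 0 success, 2 usage error, 1 computation error.

## Package layout

| module | contents |
| --- | --- |
| `asthma_adherence.parameters` | parameter schema, validation, YAML/CSV I/O, default fixture, random plausible generator, life table |
| `asthma_adherence.adherence` | effectiveness curve, odds-ratio adjustment, transition-matrix construction |
| `asthma_adherence.engine` | cohort recursion, exacerbation/life-year/QALY/cost accumulation, trace export |
| `asthma_adherence.psa` | parameter sampling, PSA driver, summaries, paired comparisons |
| `asthma_adherence.cli` | `asthma-adherence` command group (`run`, `psa`, `compare`) |
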