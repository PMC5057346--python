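# nmasplit

Automated node-splitting assessment of inconsistency for Bayesian network
meta-analysis of continuous outcomes.

Node splitting contrasts the *direct* evidence on a treatment comparison with
the *indirect* evidence flowing through the rest of the network. Doing this
by hand is tedious: one must decide which comparisons admit a meaningful
split, handle multi-arm trials (whose evidence is internally consistent by
construction), and build a separate hierarchical model per comparison.
`nmasplit` automates the whole workflow:

- **Decision rule** — split `x:y` if and only if `x` and `y` remain connected
  after removing every study containing both. An exhaustive enumeration of
  potentially inconsistent loops is included as an independent oracle and is
  checked empirically against the rule in the test-suite.
- **Model generation** — spanning-forest basic parameters, automatic
  re-referencing, and virtual-study decomposition of multi-arm trials
  containing the split pair (the two split arms become a direct virtual
  study; the remaining arms a second virtual study, dropped when only one
  arm remains). Disconnected indirect components are retained by default to
  keep informing the shared heterogeneity parameter.
- **Estimation** — a self-contained MCMC sampler for the homogeneous-variance
  random-effects model with compound-symmetry multi-arm covariance
  (`sigma^2/2` off-diagonals), supporting arm-level normal likelihoods and
  contrast-level multivariate-normal likelihoods. The sampler collapses the
  linear-Gaussian location block analytically and runs an adaptive reflected
  random-walk Metropolis chain on the heterogeneity standard deviation, so
  draws are fast, exact in distribution, and bit-reproducible given a seed.
- **Reporting** — per-comparison direct/indirect/network posterior summaries,
  two-sided Bayesian inconsistency p-values, a heterogeneity table across all
  models, split-chain Gelman–Rubin diagnostics, and text/JSON/CSV export plus
  kernel-density export per comparison.

The seven-trial Parkinson mean off-time reduction dataset ships with the
package (`nmasplit.fixtures.parkinson_network()`), along with programmatic
topology fixtures and a generative simulator for parameter-recovery,
calibration and power studies.

## Command line

```sh
# which comparisons does the decision rule select?
nmasplit comparisons parkinson.csv
nmasplit comparisons parkinson.csv --loops     # add the loop oracle's output

# full analysis: consistency model + one split model per selected comparison
nmasplit run parkinson.csv --chains 4 --adapt 5000 --iter 20000 --seed 1 \
    --format json -o report.json

# simulate arm-based data for a named fixture topology with known truth
nmasplit simulate fig3c -d y=1.0 -d z=2.0 --sigma 0.1 --n 200 --seed 7 -o sim.csv
```

Input CSVs are long format (one arm per row). Arm style:
`study,treatment,mean,std.dev,sampleSize`; contrast style:
`study,treatment,diff,std.err,base.se` with an empty `diff`/`std.err` on each
study's reference row (`base.se` required there for studies with three or
more arms). `nmasplit run` exits non-zero when any model fails the PSRF
threshold unless `--allow-nonconverged` is given.

## Python API

```python
from nmasplit import (
    read_network, comparisons_to_split, run_nodesplit_analysis, Settings,
    export_report,
)

network = read_network("parkinson.csv", style="arm")
print(comparisons_to_split(network))           # [A:C, A:D, B:D, C:D]
report = run_nodesplit_analysis(network, Settings(seed=1))
print(export_report(report, "text"))
```

## Scope

Normal-identity likelihoods only (mean differences on a linear-additive
scale); extension to other likelihoods would slot into
`inference.assemble_model`. The split models use the unique parameterisation
that excludes both split treatments from the indirect network; the
alternative arm-inclusion mixtures are counted
(`count_parameterisations` = `2^k + 1`) but not estimated.
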