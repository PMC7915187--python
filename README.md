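# surgevol

Estimation of weekly general-anesthesia case volumes from a series of
4-option surgical-restriction polls.

The pipeline has four stages:

1. **Transition estimation** — each week's 4×4 transition matrix between
   restriction states (none / partial / extensive / no scheduled surgery) is
   estimated from consecutive aggregate poll proportions by constrained
   least squares, solved as a quadratic program with a banded (birth–death)
   zero pattern, row-sum equality constraints and [0, 1] bounds. The QP is
   solved by an exact primal active-set method written for this package.
2. **Restriction-rate model** — each state maps a hospital's reference
   weekly caseload to an actual caseload through a multiplicative rate drawn
   from a state-specific gamma distribution, parameterized by a target
   median (solved by root finding) and a shared variance. Three scenarios
   (baseline / optimistic / pessimistic) set the per-state medians.
3. **Monte Carlo volume simulation** — hospitals from a registry of annual
   caseloads are allocated to states from the first poll, evolved through
   the estimated chain, and assigned gamma rates per hospital-week; weekly
   totals are summarized as medians with 95% percentile confidence intervals
   over 1000 iterations and as percent of the pre-period baseline.
4. **Comparison** — the percent-of-baseline series is aligned to an external
   reference series by calendar-day linear interpolation and correlated
   (product-moment r with a t-approximation p-value).

A fully seeded synthetic-data module generates poll series (latent banded
Markov chain observed through multinomial polls), right-skewed hospital
registries and noisy reference series, retaining the latent truth for
recovery experiments.

## Command line

```sh
# write a complete synthetic input set (polls.csv, registry.csv,
# reference.csv, truth.yaml)
surgevol synth --out fixtures/ --seed 1

# weekly transition chain from a poll series
surgevol estimate --polls fixtures/polls.csv --out chain.json

# Monte Carlo volume estimates for one scenario
surgevol simulate --polls fixtures/polls.csv --registry fixtures/registry.csv \
    --scenario baseline --iterations 1000 --seed 1 --out estimates.csv

# correlate with an external reference series
surgevol compare --estimates estimates.csv --reference fixtures/reference.csv \
    --out comparison.json

# full pipeline from a YAML config
surgevol run --config config.yaml
```

A `run` config looks like:

```yaml
polls: fixtures/polls.csv
registry: fixtures/registry.csv
reference: fixtures/reference.csv   # optional
min_annual: 100
iterations: 1000
seed: 1
scenarios: [baseline, optimistic, pessimistic]
out_dir: results
```

Input formats: polls `date,n1,n2,n3,n4` (counts) or `date,p1,p2,p3,p4`
(proportions, rows re-normalized after parsing); registry
`hospital_id,annual_ga_count` filtered to at least `min_annual` (default
100) annual cases, with weekly reference = annual / 52; reference
`date,percent`.

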