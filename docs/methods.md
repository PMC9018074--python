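# Methods

This note documents the modelling semantics, parameter conventions and
numerical choices behind `ctboolsim`.

## 1. Stochastic semantics of Boolean models

A model is a set of nodes with one logical rule each (AND/OR/NOT over node
literals and the constants 0/1) plus strictly positive activation and
inhibition rates `k_up,i`, `k_down,i` (default 1.0, in model-time
units⁻¹). The dynamics are a continuous-time Markov chain on the state
transition graph: in state `s`, node `i` is *eligible* to flip up at rate
`k_up,i` iff `s_i = 0` and its rule evaluates to 1, and down at rate
`k_down,i` iff `s_i = 1` and the rule evaluates to 0. Trajectories are
generated with the Gillespie algorithm: waiting time exponential in the
total eligible rate, flipping node proportional to its rate. A state with
no eligible flip is a fixed point; the trajectory holds it until
`max_time`. Updates are asynchronous by construction — exactly one node
changes per event.

**Input nodes** model microenvironmental conditions (growth factors,
nutrients, hypoxia, ...). They carry a self rule, are never regulated, and
therefore never flip: their initial probability *is* their value for the
entire run. **Output nodes** are phenotype read-outs; they are excluded
from the default perturbable set of mutant screens.

### Ensemble statistics

`simulate_ensemble` samples `n_trajectories` (default 5000) initial states
— independent per-node Bernoulli draws, overridden by any declared joint
assignments — and reports, per time window of width `time_tick`, the
trajectory-averaged fraction of time spent in each joint state of the
tracked nodes. This *time-occupancy* statistic (rather than the
instantaneous end-of-window state) reduces variance and converges smoothly
to the stationary distribution. Marginals are sums of joint states, so the
normalisation (`Σ joint = 1` per window) and marginal-consistency
identities hold by construction. The **asymptotic phenotype score** is the
last window's marginal for each output node. `max_time` is model-specific;
if the last two windows differ by more than `convergence_tol` (default
0.01) beyond three Monte-Carlo standard errors, a `ConvergenceWarning`
asks for a longer horizon.

### Randomness

One root seed feeds a `SeedSequence`; each trajectory gets its own spawned
substream (initial-state sampling and dynamics), so results are
bit-reproducible and independent of execution order. Drug-mixture variant
assignment uses a separate dedicated stream (spawn key `2^31`), which makes
a 100%-inhibition run bit-identical to the corresponding knock-out mutant
run under the same seed.

### Exact oracles

For networks of ≤ 12 nodes, `oracles.master_equation_windows` integrates
the full master equation (matrix exponentials on a fine sub-grid, 64
sub-steps per window, trapezoid window averages). The one-node telegraph
process has the closed form `P(t) = p∞ + (p0 − p∞)e^{−(u+d)t}` with
`p∞ = u/(u+d)`; window averages are computed analytically. These oracles
are used only for testing and convergence checks, never to produce
results.

## 2. File formats

**BoolNet dialect** (`.bnet`): optional `targets, factors` header, one
`target, expression` line per node; `#` comments. Operators `&`, `|`, `!`
(or `AND`, `OR`, `NOT`), parentheses, constants 0/1. Node names are
case-sensitive identifiers starting with a letter or underscore; `/`, `-`
and `_` may appear inside. Nodes occurring only as factors are
auto-declared as inputs; a node whose rule is exactly itself is likewise
input-like. BoolNet text carries no rates, initial conditions or output
declarations; round-trips preserve node order and rules.

**MaBoSS dialect subset** (`.bnd` + `.cfg`):

```
node NAME {
  logic = <expression>;          // required
  rate_up = <float>;             // or: @logic ? <float> : 0
  rate_down = <float>;           // or: @logic ? 0 : <float>
}
```

The `.cfg` file supports `[NAME].istate = p [1], q [0];` (probabilities
must sum to 1 within 1e-9), joint istates `[A,B].istate = p [1,1], ...;`,
deterministic `NAME.istate = 0/1;`, `sample_count`, `max_time`,
`time_tick`, `seed` and `NAME.is_internal = TRUE/FALSE;`. When any
`is_internal` flag is present, the non-internal, non-input nodes become
the declared outputs. Any construct outside this subset (e.g. `$variable`
definitions, general rate expressions) raises an error — nothing is
silently ignored. Round-trips preserve rules, rates and initial
conditions.

## 3. Influence graph

The signed influence graph is semantic, not syntactic: an arc (r, t)
exists iff flipping r changes t's rule value in at least one context over
the rule's own literals (exhaustive enumeration, capped at 20 regulators).
Signs are `activator`, `inhibitor`, or `dual` when both a positive and a
negative context exist (e.g. XOR-like rules). One arc is counted per
(regulator, target) pair; a dual influence counts once. Syntactic literals
with no semantic effect (`B & !B`) produce no arc and log a warning. Input
self rules are bookkeeping for "held constant" and contribute no arc.
Published edge counts for curated models may follow different conventions
(e.g. counting dual influences twice or curation-tool edges), so such
totals should be treated as soft checks.

## 4. Personalisation

A `PersonalisationRecipe` assigns omics layers to roles. The default
mirrors a common tumour-cohort setting: mutations + copy number as
discrete layers, expression as the continuous layer acting on both initial
conditions and transition rates, amplification exponent `F = 1`, clamp
`ε = 0.01`.

**Discrete forcing.** Mutation effect classes come from a user-supplied
curation table (the tool does not predict variant effects):
gain-of-function → force 1, loss-of-function → force 0, unknown → ignored
with a warning; amplified → 1, deleted → 0. Mutations take precedence over
copy number on conflict; contradictory calls within one layer for the same
node are an error listing the genes. Forced nodes get the constant rule
*and* start at the forced value, so their activation probability equals the
forcing exactly from the first window.

**Continuous modulation.** Cohort normalisation is per gene:
`minmax` ((x−min)/(max−min)) or `sigmoid_z` (logistic of the robust
z-score, median/1.4826·MAD) — the latter is the default as it maps the
cohort median to 0.5 and resists outliers. All-constant genes map to 0.5
with a warning. Gene values are aggregated to nodes via the node–gene map
(mean/min/max per node, default mean; nodes with no available genes are
left untouched). The node value `x`, clamped to `[ε, 1−ε]`, sets the
initial ON probability and the rates through the odds-power map

    k_up = (x/(1−x))^{F/2},  k_down = ((1−x)/x)^{F/2},

which is neutral at `x = 0.5`, symmetric, and keeps `k_up·k_down = 1` so
only the up/down balance is personalised, never the overall timescale. For
a free (self-antagonistic) node this makes the stationary ON probability
exactly `x`. The map is isolated in `rates_from_value` so an alternative
(e.g. one relative to a reference sample) can be swapped in without
touching the rest of the pipeline. Forced nodes skip continuous modulation
(forcing dominates), and the skip is recorded in the provenance log.

**Precedence of experimental conditions.** Initial probabilities listed
explicitly in the run configuration are treated as experimental pins
(growth media, stimuli) and are *not* overridden by continuous
personalisation; discrete forcings still override everything. Rationale:
the growth condition is a property of the simulated experiment, not of the
sample, while a genomic alteration travels with the sample.

## 5. Perturbations and drugs

**Genetic.** Knock-out replaces the rule by constant 0, overexpression by
constant 1; rates are untouched. The exhaustive screen enumerates all
single (2n) and double (4·C(n,2)) perturbations — `2n²` in total — over
the perturbable set, which defaults to every node except the outputs
(inputs remain perturbable). With 127 perturbable nodes this yields 32,258
mutants.

**Drugs (gradual inhibition).** The default `mixture_ko_wt` semantics
simulates inhibition level `α` per target as a trajectory mixture: each
trajectory independently carries the knocked-out target with probability
`α` (per target, so two drugs at 50% give the exact 25/25/25/25 product
law over joint assignments). This makes 0% inhibition exactly wild type
and 100% exactly the knock-out. The alternative `frozen_on_off` semantics
freezes the target (self-identity rule) and starts it ON with probability
`1−α`. The mode is recorded in every output manifest. Dose grids default
to six levels (0, 0.2, 0.4, 0.6, 0.8, 1.0); a combination screen over `t`
targets and `L` levels runs `tL + C(t,2)L²` conditions (17 targets, 6
levels → 4,998 per phenotype). Phenotype scores of dosed models are
averages over the full ensemble, i.e. over the mixture.

**Condition presets** name complete input assignments (nutrient-rich base,
growth factor and/or androgen toggled) and must assign every input; they
pin the inputs' initial probabilities.

**Rule robustness.** The scan swaps each binary AND↔OR occurrence, one at
a time, re-simulates, and reports the largest absolute phenotype-score
shift against the unedited baseline.

## 6. Scoring

Drug efficiency for a phenotype with desired direction:
decrease `E = max(0, (P_ref − P)/P_ref)`; increase
`E = max(0, (P − P_ref)/(1 − P_ref))` — both in [0, 1], NaN when the
reference makes the denominator undefined. The Bliss Combination Index is
the standard form `CI = (E_a + E_b − E_a·E_b)/E_ab` (NaN when `E_ab = 0`);
CI < 1 flags synergy. The untreated reference is the level-0 row of the
screen, which under mixture semantics is identical to the wild-type run.

Fitness is `f = P_mutant/P_wt`, with NaN (never clamped values) when the
wild-type probability falls below the floor 1e-4 — clamping would
fabricate huge fitness values and spurious interactions. Epistasis is
`ε = f_AB − ψ(f_A, f_B)` with the four null models ADD (`x+y`), LOG
(`log2((2^x−1)(2^y−1)+1)`), MLT (`x·y`), MIN. Since fitness is wild-type
normalised, `ψ(1,1) = 1` for all kinds except ADD (which gives 2). The
null model for a screen is the one maximising the Pearson correlation
between predictions and observed double-mutant fitness; at least 3
complete pairs are required, zero observed variance is an error, and ties
break in the fixed order ADD < LOG < MLT < MIN.

Intervention ranking sorts perturbations by signed score change versus the
wild-type row in the requested direction, breaking ties lexicographically
on the perturbation label. The mutant map applies PCA to the
*wild-type-centred* phenotype matrix — the wild-type row, not column
means, is subtracted — so the reference maps exactly to the origin and
distances read as phenotype shifts away from it; axes are ordered by
descending explained variance (plain SVD, no re-centring).

## 7. Synthetic data

**Toys.** `telegraph` (closed-form two-state node), `cascade` (linear
activation chain; all-ON fixed point under an ON input) and `mini_tumour`:
GrowthFactor → {ERK, MYC} → Proliferation (`(ERK | MYC) & !Casp8`),
DeathSignal → Casp8 → Apoptosis. The two redundant branches are wired so
their joint inhibition is Bliss-synergistic on Proliferation — the
qualitative behaviour of complementary-pathway drug pairs — while each
input monotonically drives its output. Every toy ships with a
machine-readable oracle (closed form or master equation) so simulator
tests need no math in test code.

**Cohorts.** `SyntheticCohortSpec` draws a two-group cohort (default 488
samples, even mixing): group B carries a gain-of-function driver mutation
(default on the MYC-mapped gene) with probability 0.8 versus 0.05 in group
A, and a standardised expression shift `δ = 2` (in units of the noise
`σ = 1`) on driver-linked genes (EGF, MYC). Expression is independent
Gaussian per gene — deliberately simple: the generator exists to provide
controlled separation for recovery tests, not RNA-seq realism (no counts,
no gene–gene correlation, no batch structure). An optional background
copy-number rate exists for robustness experiments but defaults to 0, as
the group structure is defined by mutation frequency and expression shift
alone. Consequently, passing recovery tests demonstrates that the
personalisation pipeline transmits group signal from well-formed omics
tables to phenotype scores; it says nothing about normalisation choices on
real sequencing data.

## 8. Problem sizes and numerical choices

- Ensemble default 5000 trajectories; oracle-comparison tests use
  4000–5000 and a ±3 Monte-Carlo-standard-error band (binomial bound plus
  a 0.002 floor for near-degenerate probabilities).
- Cohort-recovery runs use 80 samples × 600 trajectories on the 7-node
  toy with `max_time = 8`, which keeps per-sample score noise near 0.02
  while the group effect is an order of magnitude larger.
- Null-model recovery uses 100 replicates × 30 pairs, noise σ = 0.01.
- Truth-table analysis (influence graph, rule compilation) is capped at 20
  regulators per rule; the master-equation oracle at 12 nodes.
- istate distributions must sum to 1 within 1e-9; joint-state rows are
  exact to accumulation error (≤ 1e-12 observed).
- Clamping for continuous personalisation: `ε = 0.01`, so rates stay
  within `[√(1/99), √99] ≈ [0.1, 9.95]` at `F = 1`.

## 9. Known limitations

- No exact attractor computation or model checking; asymptotics are
  estimated stochastically and depend on an adequate `max_time`.
- The master-equation oracle is dense (`2^n` states) and intended for
  toys, not production models.
- SBML-qual and GINsim formats are not parsed; models arrive as BoolNet
  or MaBoSS-subset text.
- Pharmacokinetics is out of scope: inhibition levels are abstract
  fractions, not concentrations.
- The odds-power rate map is one defensible choice among several; the
  `rates_from_value` hook is the supported place to change it.
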