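# Methods

## Model

`lgtratchet` simulates a haploid Wright–Fisher population of constant size
`N` with discrete, non-overlapping generations. An individual's genome is a
circular array of `g` loci; the state of individual `j` is the integer vector
`z(j) = (z_1, …, z_g)` of deleterious-mutation counts per locus (multiple
hits per locus are allowed; back-mutation and beneficial mutations are not
modelled). The population starts mutation-free.

Each generation applies, in the default order:

1. **Selection.** Offspring are drawn with replacement, each parent chosen
   with probability proportional to its fitness.
2. **Mutation.** Each offspring gains `n ~ Poisson(U)` new mutations placed
   at uniformly random loci, `U = μ g`. Drawing a genome-wide Poisson total
   with uniform placement is the literal implementation of "each locus
   mutates at rate μ"; it differs from per-locus Bernoulli draws only in
   allowing multi-hit loci within one generation, which is negligible at the
   rates used.
3. **Lateral gene transfer.** The parents die and their end-of-life genomes
   form the environmental DNA (eDNA) pool, which persists exactly one
   generation. Each offspring independently undergoes at most one LGT event
   with probability `λ` (a Bernoulli draw, not a Poisson event count): a
   donor genome is chosen uniformly from the pool, a start locus uniformly on
   the circle, and the donor's alleles replace the recipient's over `L`
   contiguous loci (homologous exchange at identical coordinates; the segment
   wraps from locus `g` to locus 1). Recipient load can rise or fall.

An alternative ordering (`event_order="figure1"`) runs LGT → mutation →
selection within each cycle, with eDNA still drawn from the previous
generation's end-of-life genomes; both orderings give the same qualitative
behaviour and the switch exists for sensitivity checks.

### Fitness

Two forms are available. The default **linear** form is
`w = max(0, 1 − Σ_i s_i m_i)` — for uniform `s` the classic no-epistasis
expression `w_m = 1 − s m`, clamped at zero. The **multiplicative** form is
`w = ∏_i (1 − s_i)^{m_i}`. For the coefficients of interest (`s ≤ 0.01`) the
two agree to first order in `s·m`; tests exercise both. Selection is either
uniform, or split into a core compartment (`g_c` loci at `s_core = 0.005`,
positions drawn uniformly without replacement once per replicate) and an
accessory compartment (`s_acc = 0.001`).

### Measures

Statistics are sampled once per generation, after recombination. The
least-loaded class (LLC) is the set of individuals with all-zero genomes. A
mutant **fixes** at locus `i` when the column minimum `min_j z_i(j)` becomes
≥ 1; because donors come from the previous generation and mutation only adds,
a fixation observed at this sampling point can never revert. `T_ext` is the
generation of the first fixation anywhere in the genome — the irreversible
loss of the mutation-free class. `Δm` counts fixed mutation *levels*
(`Σ_i min_j z_i(j)`; a locus that fixes twice contributes 2), with a
`count_fixed_loci_only` option for counting distinct fixed loci instead — the
two differ only in long, high-rate runs. `Δm/Δt` divides by run length; the
per-locus rate divides further by `g`, so `per-locus × g = genome-wide`
exactly. Runs with no fixation report `T_ext` censored at the run length with
an explicit flag; aggregated tables carry the censoring fraction, and
censored values enter replicate means at the run length (a lower bound).
Compartment rates normalise each compartment's fixed count by that
compartment's own locus count (toggle: by total `g`); an empty compartment
reports an undefined rate, not zero.

### Analytic anchor

At deterministic mutation–selection balance without recombination the
expected LLC size is `n₀ = N e^(−U/s)` (the classical Haigh equilibrium).
Under a constant per-locus rate `U = μ g`, `log n₀` falls linearly in `g`
with slope `−μ/s`: ratchet severity grows exponentially with genome size.
The `theory` module tabulates this and the simulator is validated against it
(time-averaged LLC between burn-in and the first click).

## Parameters and defaults

| symbol | meaning | default / typical |
|---|---|---|
| `N` | population size | 500 (desk), 5×10³–10⁴ (full scale) |
| `g` | genome size, loci | 50–2500 |
| `μ` | mutation rate / locus / generation | 10⁻³ (desk), 10⁻⁴ (full) |
| `U` | genome-wide rate, `μg` | derived, or held fixed in the constant-`U` regime |
| `s` | selection coefficient / mutation | 10⁻² (desk), 10⁻³ (full); core 5×10⁻³, accessory 10⁻³ |
| `λ` | LGT probability / individual / generation | 0, 0.01, 0.1 |
| `L` | recombination length, contiguous loci | 1, 5, or the fraction rule `0.2g` → `max(1, round(0.2 g))` |
| generations | run length | 10⁴ default; presets record their own |

Exactly one of `μ`, `U` is supplied; the other is derived through `U = μ g`
and an inconsistent pair is rejected at construction. `mutation_regime`
records which rate is held constant as `g` varies across a sweep.

## Desk-scale presets

The published-scale experiments (`full_preset`) use `N = 5×10³–10⁴`,
`μ = 10⁻⁴`, `s = 10⁻³`, 50 replicates and up to 10⁵ generations — cluster
workloads. The desk presets preserve each experiment's comparative structure
at interactive cost: `N = 500`, ~10 replicates, 5×10³–2×10⁴ generations, and
in the constant-per-locus-rate experiments **both** `μ` and `s` raised
tenfold (`μ = 10⁻³`, `s = 10⁻²`). Scaling the two rates together keeps `U/s`
— which sets the equilibrium LLC size `N e^(−U/s)` and with it the character
of the ratchet — at its published value while running the clock ten times
faster. Raising `μ` alone would drop `s/μ` from 10 to 1 and push the
population into a mutation-dominated regime in which LGT's reassortment
benefit disappears; the distinct LGT-benefit and genome-size orderings are
robust across seed batches under the ratio-preserving scaling. The
constant-`U` experiment keeps the published `s = 10⁻³` (there `U` is pinned
directly), and the core/accessory experiment keeps the published
coefficients 0.005/0.001, which already exceed the raised `μ`.

## Randomness and reproducibility

One base seed per experiment; replicate `i` runs from an independent
`numpy` `default_rng(base_seed + i)` stream, recorded in every output row.
The core/accessory locus assignment is drawn from the replicate's stream
before the simulation starts. Given a seed and a parameter set, trajectories
are reproducible bit-for-bit, and identical configurations produce
byte-identical output tables.

## Numerical choices and degenerate inputs

* Linear fitness is clamped at zero; a generation in which every individual
  has zero fitness raises an extinction error that sweeps surface as a
  flagged outcome rather than a crash.
* The multiplicative form is evaluated as `exp(Σ m_i log(1−s_i))`; `s_i = 1`
  loci are treated as lethal when mutated.
* `L` given as a fraction rule is rounded to the nearest integer with a floor
  of 1; a resolved `L > g` is a validation error, and infeasible sweep grid
  points are skipped with a warning rather than aborting the sweep.
* `U = 0` and `λ = 0` are legal and reduce the model to pure drift-selection;
  with `s = 0` as well, the long-run fixation rate equals `U` (the neutral
  substitution-rate identity, used as a validation oracle).
* `T_ext` of a censored run enters means at the run length; the censoring
  fraction is always reported alongside.

## What the experiments show — and what they do not

All experiments are self-generated simulations; there is no empirical data.
The desk-scale sweeps demonstrate the model's comparative structure — the
decline of extinction time with genome size, the benefit of LGT and its
erosion as `g` grows, the rescue by genome-proportional recombination length
under constant `U`, and the preferential accumulation of fixed mutations in
the weakly selected accessory compartment — at reduced `N`, shortened runs
and accelerated rates. They do not reproduce the published curves' absolute
values (those live at full scale), and the model itself abstracts away
plasmid/phage-mediated transfer, ectopic recombination, eDNA persistence
beyond one generation, epistasis, back-mutation, and any evolution of `λ`,
`L`, `N` or genome size itself.

## Known limitations

* The simulator is pure numpy; full-scale runs (`N = 10⁴`, `t = 10⁵`,
  `g = 2500`, 50 replicates) are cluster-sized jobs.
* `T_ext` means over replicates mix censored lower bounds with observed
  times when any replicate is censored; inspect the censoring fraction
  before interpreting them.
* The analytic equilibrium `n₀ = N e^(−U/s)` is deterministic; for small
  `n₀` (strong ratchet) it describes a mean of a highly skewed distribution
  and is used only as an order-of-magnitude anchor in that regime.
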