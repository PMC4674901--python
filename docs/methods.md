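# Methods

## The deletion process

The simulator (`fractionator.core`) models fractionation of a doubled genome
of `N` genes. The state is a boolean track (double vs single copy). One step:

1. draw a start gene uniformly among the *currently double-copy* genes
   (by rejection sampling, which is exactly uniform);
2. draw an event length `X` from a geometric law on `{1, 2, ...}` with mean
   `µ` (inversion sampling, so `µ = 1` is exactly degenerate at 1);
3. scan rightward from the start, converting double-copy genes to
   single-copy and skipping single-copy genes, until `X` genes have been
   converted.

The start law deserves a note: "a doubled gene chosen at random" could also
be read as uniform over all `N` positions with a skip-forward rule, but that
would make even the `µ = 1` process cluster deletions (a start inside a
single-copy run would convert the gene at its right edge), contradicting the
exact uniform-subset behaviour the gene-by-gene model must have. Uniform
over double-copy genes is the only reading under which `µ = 1` deletions are
an exchangeable random subset, and it is what the analytic overlap
probabilities assume (the start gene is length-biased into double runs with
weight `l·ρ_t(l)/ν_t`).

**Topology.** The analysis assumes `N` large enough to neglect end effects.
The default topology is a circle, which removes ends exactly rather than
approximately; `linear` is available (events then truncate at the right
chromosome end, and terminal runs are tallied like any other).

**Checkpoints.** A trajectory records run-length tallies when the deleted
count first reaches `round((1−θ)N)` for each requested deleted proportion
`1−θ`. The event that would overshoot a checkpoint is truncated so the
recorded state conditions on an exact deleted fraction — this is what makes
reference cumulatives indexed by `1−θ` well defined. A first-crossing mode
(`exact_checkpoints=False`) is kept for sensitivity checks. Checkpoints of
one trajectory are successive observations of the same genome, so tallies at
different `1−θ` are correlated — deliberately so, matching how a study
samples one evolving genome at stages.

**Event bookkeeping.** Each event records the positions it converted and
`overlapped_runs` (its `q`): the number of distinct pre-existing single-copy
runs the scan *skipped through*. An event that merely ends flush against an
existing run ("touching") merges with it but overlaps nothing; we count it
at `q = 0`. The test suite validates this accounting against an exact
prediction of the no-skip probability under geometric double-run lengths;
the observed no-skip fraction exceeds the strictly-interior probability
`p_0` by exactly the touching mass, which is large once runs are short.

**Determinism.** All randomness flows from a `numpy` `SeedSequence`; grid
builds spawn one child stream per (µ, N) cell and one grandchild per
replicate, so results are independent of iteration order and bit-identical
across runs with the same seed.

## Overlap probabilities (`fractionator.overlap`)

- `p0_discrete_sum` evaluates the defining triple sum for `p_0` with
  geometric event lengths (mean `µ`) and geometric double-run lengths (mean
  `ν_t`), reduced to a single incrementally-updated sum over the run length
  `l`. The outer sum truncates when the remaining length-biased mass
  `Σ_{k>l} k ρ_t(k)/ν_t` (closed form for a geometric tail) drops below
  `tail_tol` (default 1e−12, hard cap `l ≤ 10^7`).
- `p0_discrete_closed` is the closed form
  `(ν_t − 1)² / ((µ + ν_t − 1) ν_t)`. The printed source of this expression
  is typographically ambiguous; this reading is the unique one that agrees
  with the direct summation (to 1e−9 over
  `µ ∈ {1.0, 1.1, 1.5, 2.0, 2.4} × ν_t ∈ {2, ..., 1000}`) and approaches the
  large-`ν_t` form `ν_t/(µ+ν_t)·(1−1/ν_t)` (`p0_discrete_approx`).
- `zeta_mean` returns the mean `ζ` of the combined geometric law,
  `1 − 1/ζ = (1 − 1/µ)(1 − 1/ν_t)`, which is how the cross terms of the
  summation reduce to closed form.
- Continuous analogue (exponential event and segment lengths): the overlap
  count `q` is geometric, `p_q = (ν_t/(µ+ν_t))(µ/(µ+ν_t))^q`
  (`pq_continuous`). `pq_continuous_oracle` checks `q ∈ {0, 1}` by adaptive
  quadrature (scipy `quad` on the semi-infinite ranges, the innermost
  exponential integral taken as a CDF), default tolerance 1e−8.

Closed forms for the *discrete* `p_q`, `q ≥ 1`, are not provided: they exist
in principle but are unpublished, and we do not invent them. Empirical
`q`-counts come from the simulator's event log.

## Discrimination (`fractionator.discrimination`, `fractionator.model`)

Reference cumulatives `F` (single-copy runs) and `G` (double-copy runs) are
built per (µ, N, 1−θ) cell by pooling run counts over replicate trajectories
and normalising — run-weighted averaging, which is stable when individual
trials contribute few runs. Per-trial averaging of relative frequencies is
available (`pooling="per_trial"`); on the default grid the two differ by
less than Monte-Carlo noise. Cells pooling fewer than 30 runs log a warning.

Classification computes, for each candidate µ, the Kolmogorov–Smirnov
distance `D = max_l |F̂_sample(l) − F_ref(l)|` over integer run lengths up to
the larger observed maximum (both cumulatives are 1 beyond it), and returns
the argmin. Exact ties break to the smallest µ — conservative toward the
functional model. `RunLengthKS` wraps this as a model object: construct from
a tally, a genome state, or a copy-state TSV plus a reference library;
`fit()` returns results carrying `mu_hat`, the full distance profile, a tie
flag, diagnostics and a `summary()` table. There is no sampling-theory
standard error for a binning argmin; the distance profile across bins is the
honest uncertainty display.

## Study sizes and defaults

- µ grid `1.0 ... 2.4` step 0.1 (15 bins); deleted proportions
  `0.1 ... 0.9` step 0.1; genome sizes 100–900.
- Reference libraries default to 300 pooled replicates per (µ, N) and error
  assessments to 300 fresh samples per cell. These desk-scale sizes keep the
  full study in the low minutes while leaving per-cell binomial noise near
  ±0.03 on assignment frequencies; the upstream study they emulate used
  1000/1000, and both knobs are independent arguments.
- Assessments of single- vs double-copy classification reuse one seed, so
  the same trajectories are classified both ways and the comparison is
  paired.

## What the simulations do and do not show

The generator *is* the model: duplicate loss from one homeologue with
geometric event lengths and skipping. Passing tests show the estimator
discriminates the two mechanisms under that model, at these `N` and `1−θ`.
Real WGD descendants violate it in known ways — deletions from both
homeologues, genome rearrangements that break runs, double-copy losses, and
orthology-calling error — so error rates here are best-case. Applying the
classifier to a real genome additionally requires an accurate copy-state
track and an `N` matched to the analysed region.

Observed behaviour of the desk-scale study (all recomputed by the test
suite): the gene-by-gene model is recovered 70–85%+ of the time at `N = 900`
below half-deletion; `µ = 1.2` is misread as 1 roughly 10–25% of the time at
`N = 200` but only a few percent at `N = 900`; `µ ≥ 1.5` is essentially
never misread below half-deletion; accuracy degrades with smaller `N` and
larger `1−θ`. Early in fractionation the single-copy runs carry most of the
µ signal (double-run cumulatives are nearly µ-invariant geometrics there),
and the roles reverse late; consequently which run type better identifies
`µ = 1` depends on the deletion stage and on the true µ.

## Degenerate inputs and numerical edges

`N < 2`, all-single states, checkpoints outside (0, 1) or rounding to 0 or
`N` deleted genes, `µ < 1` (discrete), `ν_t ≤ 1` (discrete `p_0`), empty run
tallies, and missing library cells all raise explicit errors rather than
being silently patched. KS distances are exact maxima over the discrete
support, not supremum approximations.
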