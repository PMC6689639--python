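# Methods

## Model

The simulator evolves a fixed-size population of `n` research labs. Each
lab carries one heritable trait, its intrinsic false positive rate
`alpha` ∈ [0, 1], plus a funds balance (integer; one unit buys one
study), an age in iterations, and lifetime publication tallies. Every
iteration applies three stages in fixed order — Science, Evolution,
Grant-Seeking — then increments the ages of all survivors; the lab born
that iteration ends it at age 0.

**Science.** Each lab with funds ≥ 1 (funds are integers, so "funded"
means at least one whole study's worth) investigates one new hypothesis,
drawn true with base rate `b`. True hypotheses yield positive results
with power `W`; false ones with the lab's `alpha`. Communication applies
two independent filters: negative results are publishable with
probability `p`, and erroneous results (sign disagreeing with the
hypothesis's truth) are blocked by review with probability `r`. Because
the filters are independent, publication is realized as a single
Bernoulli draw with the product probability — fewer random draws,
identical distribution. One investigation per funded lab per iteration;
no carry-over of unfinished studies; hypothesis truth is redrawn
independently for every investigation.

**Evolution.** One death–birth event per iteration. Death: the oldest of
a uniform `d`-sample dies, ties uniform — age correlates coarsely, not
perfectly, with retirement. Birth: from a fresh `d`-sample of the `n−1`
survivors (the dying lab cannot reproduce), the most-published lab is
parent, ties uniform. A weaker `proportional` mode instead selects a
parent from all survivors with probability proportional to publication
count (uniform fallback when no lab has published — the natural limit of
the rule). The child gets a fresh identity: age 0, startup funds `G0`,
zero publications — it inherits methods, not track record — and
`alpha = clip(alpha_parent + N(0, epsilon), 0, 1)`.

**Grant-seeking.** A uniform `d`-pool applies regardless of current
funds; one grant of size `G` goes to the winner under PH, MI, RA, MS(X)
or ML(A) (see README). MS resolves its MI-versus-RA coin once per award
and the realized rule is logged. ML with no qualified applicant awards
nothing that iteration: the rule defines only the qualified pool, and
falling back to, say, the lowest-alpha applicant would smuggle MI
behaviour into a lottery. "Not greater than" is read inclusively,
alpha ≤ A, which makes A = 1 coincide exactly with RA.

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| n | population size | 100 | fixed by death–birth balance |
| b | base rate of true hypotheses | 0.1 | optimistic for most fields |
| W | statistical power | 0.8 | fixed for all labs |
| alpha0 | founding false positive rate | 0.05 | conventional nominal level |
| G0 | startup funds | 10 | studies a new lab can run unfunded |
| G | grant size | 10 | smallest of the tested {10, 35, 60, 85}; small grants are the realistic regime and the default here |
| d | sample size for death/birth/funding | 10 | one knob for all three lotteries |
| epsilon | mutation s.d. of alpha | 0.01 | slow trait diffusion |
| p | negative-result publication rate | 0 | 1 removes publication bias |
| r | peer-review efficacy | 0 | 1 blocks every erroneous result |
| X | MI share under MS | — | required for MS |
| A | qualification threshold under ML | — | required for ML |
| iterations | run length | 1e5 | see scale note below |
| record_interval | recording cadence | 100 | full resolution is wasteful |
| fdr_window | trailing window for windowed F | 1e4 | equilibrium comparisons |

Founding labs all start at age 0; early deaths are therefore decided by
the uniform tie-break, which is the least informative assumption when no
age structure is given.

## Metrics

`mean_alpha` is the arithmetic mean of alpha over all labs. The false
discovery rate `F` divides erroneous publications by all publications;
it is NaN (never 0) before the first publication so that early-time
summaries are not biased toward cleanliness. Alongside the cumulative
`F`, a windowed `F` over the trailing `fdr_window` iterations is
recorded: cumulative `F` is dominated by burn-in, so equilibrium
comparisons between conditions use the final-window estimate.

Convergence of the ᾱ series is operationalized as the first recorded
point whose trailing-window mean stays within a tolerance (default 0.05)
of the final-window mean for the rest of the run *and* is followed by at
least one further full window of stability — the extra-window condition
keeps a series that is still drifting at its end from "converging" at
its own endpoint.

## Randomness and reproducibility

One seeded PCG64 generator drives a run; draws occur in a fixed order
(science: funded-lab permutation, then truth/result/publication uniform
vectors; evolution: death sample, death tie-break, parent sample, parent
tie-break, mutation normal; funding: applicant sample, award draw). All
subset samples use the same partial Fisher–Yates protocol consuming one
uniform vector of length `d`, and tie-breaks always consume exactly one
integer draw whether or not a tie occurred, so the stream is
state-independent. Runs are bit-reproducible from `(seed, params)`.

The production loop is a numba kernel that replays exactly this stream;
the pure-Python stage functions remain the readable reference
implementation, and the suite asserts the two paths produce identical
trajectories (publication counts bitwise equal; recorded means equal up
to float summation order, ≈1e-16).

Sweeps derive each run's seed from the sweep seed, a canonical hash of
the condition's field values, and the replicate index. Seeds are
content-addressed, so results are independent of execution order and of
adding further conditions.

## Static oracle

With evolution and funding disabled and funds topped up every iteration
(the `disable_*`/`auto_refund` switches, used only for validation), every
investigation is an i.i.d. draw over four (truth, result) cells with
known occurrence and publication probabilities, giving closed forms for
the long-run `F` and the publication yield per investigation. The
simulator is checked against this oracle over a grid of (alpha, p, r).
What the oracle deliberately removes — funding constraints, selection,
mutation — is exactly what the dynamic model adds, so agreement validates
the science stage and the accounting, not the evolutionary dynamics,
which are exercised by the comparative experiments instead.

## Scale of the experiments

The default protocol runs 10⁵ iterations with 5 replicates per condition
and measures equilibria over the final 10⁴ iterations. The community
trait typically converges between 2×10⁴ and 8×10⁴ iterations under the
default parameters (the slowest case being MI funding), which the
convergence diagnostic confirms per run; longer runs and more replicates
sharpen the between-replicate dispersion but do not move the medians.
Full-scale protocols are available by configuration (`iterations`,
`replicates` in a sweep spec).

## What the simulation does and does not show

All data are generated by the model itself; there is no empirical input.
The model treats hypotheses as independent coin flips, publication as a
single binary event, labs as identical except for one scalar trait, and
funding as one fixed-size grant per iteration from a single agency.
Results therefore speak to the *logic* of selection under incentive
structures — e.g. that lotteries with a modest rigour threshold hold the
false discovery rate far below a pure lottery — not to quantitative
predictions for any real funding system. Effect sizes, p-hacking,
replication studies, correlated hypotheses, multi-grant portfolios and
rigour–productivity trade-offs are all outside the model.

## Numerical notes

- Probabilities are compared with `<` against uniforms in [0, 1), so
  degenerate parameters (0 or 1) behave exactly.
- `epsilon = 0` propagates parent alpha bit-exactly (the Gaussian draw is
  still consumed, keeping streams aligned across epsilon values).
- The proportional-parent CDF walk guards the `u == total` rounding edge
  by clamping to the last candidate.
- Windowed F uses the recorded cumulative counts at the two window
  endpoints; it is NaN when no paper was published inside the window.
- Recorded mean alpha is a sequential float64 sum over 100 labs; two
  mathematically equal paths can differ by ~1 ulp.
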