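# Methods

## The model

An **FpNHse-set** (fuzzy-parameterized neutrosophic hypersoft expert set)
organizes a multi-expert assessment problem along four axes:

* **Hypersoft structure.** Each clinical attribute (chest pain type, resting
  blood pressure, ...) is classified into a disjoint set of sub-attribute
  values. The parameter domain is the Cartesian product of these sets, so a
  single parameter is a *multi-argument tuple* — one sub-attribute value per
  attribute. `build_tuple_space` enumerates the product lexicographically in
  declared attribute order; the order is a library convention (the structure
  itself is order-free) chosen so fixtures and serialized cases are
  reproducible.
* **Expert dimension.** A panel of decision makers assesses every tuple, each
  with an agree/disagree opinion flag, giving assessment keys
  (tuple, expert, opinion).
* **Neutrosophic grades.** Each assessment is a single-valued neutrosophic
  triplet (t, i, f) ∈ [0,1]³: truth, indeterminacy and falsity memberships,
  mutually independent, so t+i+f may reach 3. The stricter dependent reading
  (t+i+f ≤ 1) is available in the generator as the `constrained` law.
* **Fuzzy parameterization.** Every tuple carries a degree χ ∈ [0,1]
  expressing how much weight the panel chair gives assessments on that tuple.

## Grades and degrees

A prescribed clinical value v is normalized to a fuzzy grade μ = v / v_max,
where v_max is the attribute's largest prescribed value (largest level for
discrete attributes, upper bound for ranges). The degree of a tuple whose
attribute spans normalized grades [μ_min, μ_max] is

    χ = (μ_max − μ_min) / 2,

so χ ∈ [0, 0.5] when derived this way; a user-supplied χ may use the full
[0, 1]. χ is computed from *full-precision* normalized grades and rounded
once at the end: deriving it from already-rounded grades shifts several
degrees by one unit in the second decimal (a slope minimum of level 1 of 3
gives χ = (1 − 1/3)/2 = 1/3 → 0.33, whereas starting from the 2-dp grade
0.33 gives 0.335 → 0.34).

A neutrosophic triplet is reduced to a single fuzzy value by

    m(t, i, f) = |t − i − f| / 3,   range [0, 2/3].

This is the reduction the method prescribes; note it is symmetric in i and f
and treats "indeterminate" exactly like "false". Alternative score functions
(e.g. (t + (1−i) + (1−f))/3) are deliberately not offered.

## The ranking pipeline

With p patients, q tuples and r experts:

1. reduce the neutrosophic patients×tuples matrix W1 and tuples×experts
   matrix W2 elementwise to fuzzy matrices F_pat (p×q) and F_exp (q×r);
2. weight F_pat column-wise and F_exp row-wise by χ:
   WF_pat[i,j] = χ_j·F_pat[i,j], WF_exp[j,k] = χ_j·F_exp[j,k];
3. compose D = WF_pat · WF_exp (ordinary sum-of-products matrix product —
   *not* the max–min composition of classic fuzzy-relation diagnosis);
4. score each patient by their row sum of D; rank descending (higher score =
   higher risk). Ties keep input order (stable sort).

Because χ_j enters both factors, every score scales with c² when all degrees
are scaled by c > 0, and the ranking is invariant under that rescaling — a
tested property. Scores are also equivariant under patient permutations and
invariant under consistent tuple relabeling.

The opinion axis is collapsed before the pipeline: `collapse_opinions` keeps
agree-side entries where present (falling back to all entries for keys with
no agree entry) and aggregates by componentwise arithmetic mean — over
experts for the patient matrix, over the universe for the expert matrix.
This reducer is deliberately simple; any monotone aggregator could be
substituted without touching the pipeline.

## Rounding

The published worked example tacitly rounds: reduced fuzzy values and χ to
2 decimals, weighted and composed values to 4. `RoundingPolicy("paper")`
reproduces this with decimal half-up rounding applied to the shortest
decimal representation of each float (so 0.375 → 0.38 and 0.275 → 0.28
regardless of binary representation); `RoundingPolicy("full")` keeps full
precision and is what the structural guarantees are tested against
(pipeline ≡ scalar brute-force oracle to 1e−12). Rounded 4-dp values can
tie where full-precision values differ, so rankings — including the
sensitivity rankings below — are always induced from unrounded quantities.

## The packaged worked example

The fixture (`fpnhse.paperdata`) carries a complete 6-patient / 8-tuple /
4-expert heart-disease case built on Cleveland-dataset attribute ranges:
both neutrosophic matrices (the patient matrix was published for 4 of the 8
tuples), the χ vector, the fuzzy, weighted and composed matrices, the final
scores, the ranking P303 > P24 > P25 > P75 > P2 > P1, and the sensitivity
table. All values are stored **as printed** and checksum-verified on load.

A recomputation sweep of every derivable cell found fourteen cells whose
printed value disagrees with the case's own formulas (single-cell arithmetic
slips, one value carried forward with a misplaced decimal point, and a
transposed pair in the sensitivity table). These are shipped as the
`ERRATA` list with both the printed and the recomputed value; tests and the
`verify-paper` command assert the formulas on clean cells and flag the known
slips, and the composed diagnosis matrix is reproduced from the weighted
matrices *as printed*, since that is what its published values are
consistent with.

One substantive consequence: recomputing the harmonic means of the printed
diagnosis rows swaps P2 and P75 relative to the score ranking (HM weights
P75's small first-expert entry heavily), so the rank-stability claim holds
for the arithmetic and geometric means but not, strictly, for the harmonic
mean. The published sensitivity table shows identical rankings for all
three means only because its P2/P75 harmonic-mean entries are transposed.

## Sensitivity analysis

`sensitivity_report` replaces the row-sum score by the arithmetic, geometric
and harmonic mean of each diagnosis row (scipy implementations), reports the
three induced rankings, and flags concordance with the score ranking
together with Kendall's τ. For strictly positive rows HM ≤ GM ≤ AM with
equality iff the row is constant (property-tested on 1000 random rows).
GM/HM require strictly positive rows; rows containing zeros raise a domain
error, and the CLI skips the sensitivity block for such cases.

## Synthetic generator

`generate_case` emulates the worked example's structure at configurable
dimensions (defaults 6×8×4, matching the case study): a χ degree per tuple,
neutrosophic assessments for every (tuple, expert, opinion) key, and a pair
of pipeline-ready assessment matrices. Triplets are drawn i.i.d. uniform on
[0,1]³ by default (`uniform-box`), or uniformly on the simplex t+i+f ≤ 1
(`constrained`); χ uniform on (0, 0.5] or via the degree formula applied to
random normalized ranges (`from-ranges`). All randomness flows through one
`numpy.random.default_rng(seed)`, so a config reproduces its case exactly.

What the generator does **not** emulate: the empirical distribution of real
Cleveland-dataset assessments (expert judgements are not uniform), expert
correlation, or any association between a tuple's χ and its assessments.
Passing tests on generated cases therefore demonstrate the pipeline's
algebraic correctness and robustness, not clinical validity.

## Problem sizes and numerics

All fixture computations are desk-scale (6×8×4) and run in milliseconds.
Property tests use 100 random instances with p, q, r ≤ 10 — comfortably
exercising every degenerate shape (1×1×1 upward) — and compare the full
pipeline against a hand-rolled scalar oracle at 1e−12 absolute tolerance.
Degenerate inputs: empty value sets, empty expert panels, label mismatches
and out-of-range grades raise immediately with the offending attribute or
cell named; validation of whole FpNHse-sets is reporting, not raising, so
one pass lists every violation.

## Known limitations

* The reduction |t−i−f|/3 discards the sign of t−i−f and conflates
  indeterminacy with falsity; it is implemented as specified, not endorsed.
* Set-theoretic operations on FpNHse-sets (union, intersection, complement)
  are out of scope.
* The opinion-collapsing reducer is a convention; published tables carry no
  opinion index, so no reference behaviour exists to validate it against.
* Ranking on 4-dp rounded scores can produce ties that full precision
  resolves; rankings are therefore computed at full precision.
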