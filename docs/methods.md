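# Methods

## Model

The package treats a molecule or crystal fragment as a simple undirected
graph and computes twelve irregularity indices, each an edge sum
`prefactor · Σ_{uv∈E} h(d_u, d_v)` of a symmetric, nonnegative per-edge
contribution with h(x, x) = 0 (module `molirreg.indices`; the table of
contributions is in the README). Consequences used throughout:

- every index is zero on every regular graph, and strictly positive as soon
  as one edge joins vertices of different degree;
- an index depends on the graph only through its degree-class edge
  partition `{(a, b) → count}`, which is therefore the package's central
  data structure;
- the reverse-degree variants (c = Δ − d + 1) preserve edge gaps
  |c_u − c_v| = |d_u − d_v|, so the gap-only indices coincide across
  flavors: CAL = AL, CIRF = IRF, CIRR_t = IRR_t.

The reverse-degree formula is not stated in the literature this follows; it
is pinned down uniquely by the published reverse class pairs of the InP
family ((1,4)→(4,1), (2,4)→(3,1), (4,4)→(1,1) with Δ = 4), which force
c = Δ − d + 1. Δ is computed per graph; for parametric partitions it is the
largest degree appearing in any class. Reverse degrees are undefined on an
edgeless graph (Δ = 0) and this is an error, not a silent 0.

## Closed-form derivation

For a family whose class counts are bilinear in size parameters (r, s) —
coefficient basis {rs, r, s, 1} — each index's closed form is obtained by
multiplying each class's contribution h(a, b) by its integer count
4-tuple and summing coefficient-wise (`molirreg.closedform`). The basis is
fixed: counts needing higher-degree terms are rejected at construction
(the `ParametricPartition` type only admits 4-tuples). Derivation is linear
in the partition, and evaluation of the derived form commutes with
class-wise summation — both are asserted by tests.

Two evaluation modes:

- **exact** — h evaluated exactly: `fractions.Fraction` arithmetic for the
  six rational indices (IRDIF, AL, IRLU, IRF, IRLA, IRR_t), IEEE doubles
  for the log/sqrt ones.
- **paper_rounded** — irrational contributions rounded to 4 decimal places
  (half away from zero) *before* multiplication by the counts; rational
  contributions stay exact. This is the convention under which the
  published coefficient tables for the InP family were produced (e.g. the
  IRB coefficient 4·0.3431 = 1.3724 rather than the exact 1.37258…), and it
  reproduces all 24 published coefficient tuples with zero deviation.
  All paper_rounded coefficients are exact rationals, so table cells carry
  no floating-point noise and can be compared at display precision.

The two modes differ only by the 4-decimal rounding of h, amplified by the
counts: on the InP family the worst coefficient gap is 3.4 × 10⁻⁴ (the
CIRGA r-coefficient, a sum of two rounded terms) and the worst cell gap on
the published 12 × 5 grid is 7.3 × 10⁻³ (CIRGA at (5,5)), both computed by
the test suite's sweep.

## The InP[r,s] family and its audit

`molirreg.inp` encodes the three-class parametric partition quoted in the
README. Two published statements about the family do not survive
recomputation, and the package reports rather than hides them:

1. **Edge count.** The published |E| = 16rs disagrees with the partition
   total 12rs + 4r + 4s − 4 whenever r > 1 and s > 1; the gap is exactly
   4(r−1)(s−1). `audit_consistency` returns both figures and the flag.
2. **Table cells.** The published degree-flavor IRLA row (42.6667 at (1,1),
   …) is not producible from any formula in the published account — the
   closed form 8/3·rs + 112/15·(r+s) − 24/5 gives 12.8 at (1,1) — and the
   published AL value at (4,4), 279, contradicts the closed form's 276
   (the reverse-flavor CAL row, an identical polynomial, prints 276).
   `build_table` flags these six cells `paper_discrepancy` and always shows
   the computed value. The flag is intrinsic to the cell (judged under the
   4-decimal rounding convention), so the same six cells are flagged in
   both evaluation modes.

The published vertex formula is typeset as "10rs + 3r + 3rs + 2"; the
package uses 10rs + 3r + 3s + 2, the reading that restores the family's
r↔s symmetry.

No atom-level adjacency for InP[r,s] is constructed: the published account
provides only the partition, and every index here is a function of the
partition alone.

## Numerical choices

- Class keys are canonicalized (a ≤ b); all contributions are symmetric so
  nothing is lost.
- IRLA's leading factor 2 is folded into h; IRR_t keeps its ½ as an
  external prefactor, matching the customary display.
- Display formatting: 4-decimal quantization (half away from zero) with
  trailing zeros trimmed and integers printed bare (12.8, 36) — the style
  of the published tables. Quantization is done in decimal arithmetic on
  exact rationals wherever possible.
- Degenerate inputs: the empty partition gives 0 for every index; isolated
  vertices are allowed and never contribute; self-loops and multi-edges are
  rejected at parse time.

## Test fixtures and the oracle

`molirreg.fixtures` generates paths, cycles, stars, complete bipartite
graphs, and seeded uniformly-sampled random simple graphs (n ≤ 15 in the
suite, 200 seeds, isolated vertices retained to exercise the degree-0
path). `brute_force_index` re-implements every index as a direct
edge-by-edge sum with inline formulas — an independent code path the suite
compares against the partition-based evaluation to 10⁻¹⁰ relative. These
fixtures exercise the combinatorics fully, but they are toy graphs: passing
says nothing about chemical semantics (bond orders, aromaticity, hydrogen
handling are out of scope by design).

## Known limitations

- The closed-form engine is restricted to the bilinear basis {rs, r, s, 1};
  families with quadratic-or-higher count polynomials are out of scope.
- Exact-mode values necessarily drift from the 4-decimal-rounded published
  tables as rs grows (see the sweep figures above); the package exposes
  both modes rather than privileging either.
- Reverse degrees depend on Δ of the *whole* graph, so they are not local:
  adding a single high-degree vertex changes every reverse degree. This is
  inherent to the definition, not an implementation artifact.
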