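# molirreg

Irregularity topological indices for molecular graphs — and closed-form
expressions of those indices for the InP[r,s] zinc-blende crystal lattice
family.

## The problem

A molecular graph (atoms = vertices, bonds = edges) is *regular* when every
vertex has the same degree. Irregularity indices quantify how far a graph is
from regular; in QSPR/QSAR work they serve as numeric descriptors that
correlate with physico-chemical properties. Almost all of them are edge sums
of the *imbalance* of an edge, `|d_u − d_v|`, or some function of the two
endpoint degrees:

| name | per-edge term h(d_u, d_v) |
|------|---------------------------|
| IRDIF | \|d_u/d_v − d_v/d_u\| |
| AL (Albertson) | \|d_u − d_v\| |
| IRL | \|ln d_u − ln d_v\| |
| IRLU | \|d_u − d_v\| / min(d_u, d_v) |
| IRLF | \|d_u − d_v\| / √(d_u d_v) |
| IRF | (d_u − d_v)² |
| IRLA | 2\|d_u − d_v\| / (d_u + d_v) |
| IRD1 | ln(1 + \|d_u − d_v\|) |
| IRA | (d_u^−½ − d_v^−½)² |
| IRGA | ln((d_u + d_v) / 2√(d_u d_v)) |
| IRB | (√d_u − √d_v)² |
| IRR_t | ½ Σ \|d_u − d_v\| (total irregularity) |

Each index also has a *reverse-degree* variant (names prefixed `C`: CAL,
CIRF, …) obtained by substituting the reverse degree `c_v = Δ − d_v + 1`
(Δ the maximum degree), which swaps the roles of hubs and leaves. Because
the substitution is an affine reflection, edge gaps are preserved, so
CAL = AL, CIRF = IRF and CIRR_t = IRR_t on every graph.

Since every index depends on the graph only through the multiset of
endpoint-degree pairs per edge, the package evaluates them on
**degree-class edge partitions**: counts of edges per canonical pair (a, b).
For a parametric graph family whose class counts are bilinear in two size
parameters r, s, each index then has a closed form
`c_rs·rs + c_r·r + c_s·s + c_0`. The bundled family is InP[r,s], an r × s
block of indium-phosphide zinc-blende unit cells, with classes

    (1,4): 4(r+s−1)     (2,4): 4(rs+r+s)     (4,4): 4(2rs−r−s)

and reverse classes (1,4), (1,3), (1,1) via c = 5 − d. The package derives
all 24 closed forms symbolically, rebuilds the published numeric tables,
and audits two internal contradictions in the published account of this
family (see `docs/methods.md`).

## Worked example

Carbon skeleton of isobutane — a 3-leaf star, degrees {1, 3}:

```sh
$ printf 'C1 C2\nC2 C3\nC2 C4\n' > isobutane.edges
$ molirreg indices isobutane.edges --reverse
index,flavor,value
IRDIF,degree,8
AL,degree,6
IRL,degree,3.2958
IRLU,degree,6
IRLF,degree,3.4641
IRF,degree,12
IRLA,degree,3
IRD1,degree,3.2958
IRA,degree,0.5359
IRGA,degree,0.4315
IRB,degree,1.6077
IRRt,degree,3
CIRDIF,reverse,8
CAL,reverse,6
...
```

Each of the three C–C bonds joins a degree-1 to the degree-3 centre, so
AL = 3·|1−3| = 6 and IRR_t is half that. With Δ = 3 the reverse degrees are
{3, 1} — the same pair mirrored — so here every reverse value equals its
degree-based counterpart.

Closed forms and tables for the lattice family:

```sh
$ molirreg derive --index IRB --mode paper
index,flavor,mode,c_rs,c_r,c_s,c_0
IRB,degree,paper_rounded,1.3724,5.3724,5.3724,-4
```

i.e. IRB(InP[r,s]) = 1.3724·rs + 5.3724·(r+s) − 4 under the 4-decimal
rounding convention the published tables use.

```sh
$ molirreg inp-table --flavor degree --mode paper
```

prints the full 12 × 5 table at (r,s) = (1,1)…(5,5) as CSV, e.g. AL = 36 at
[1,1] and IRF = 884 at [5,5]. Cells whose published values contradict the
closed forms (the IRLA row and AL at [4,4]) are shown as computed — e.g.
IRLA[1,1] = 12.8, AL[4,4] = 276 — with a parallel `*_flag` column marking
them `paper_discrepancy`. `molirreg inp-verify` additionally reports the
edge-count contradiction of the family: the class counts total
12rs + 4r + 4s − 4 while the published edge count is 16rs, equal only when
r = 1 or s = 1.

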