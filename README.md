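# chelstab

Prediction of stability constants (log *K*₁ and log *β*₂) of bivalent
first-row transition-metal chelates with aliphatic α-amino acids, from a
single topological descriptor: the third-order valence molecular
connectivity index ³χᵛ.

## The problem and the model

The Irving–Williams series (Mn²⁺ < Fe²⁺ < Co²⁺ < Ni²⁺ ≪ Cu²⁺ > Zn²⁺)
orders the stability of bivalent transition-metal complexes but is
rarely used quantitatively. This package encodes both the metal and the
ligand in one graph invariant. Each complex is represented as a simple
vertex-weighted graph of its aqua complex: the metal is tetracoordinate
in the mono-complex MB (amino N, one carboxylate O, two waters) and
hexacoordinate in the bis-complex MB₂ (two N,O-chelate rings, two
waters). Hydrogens are implicit. Each vertex *i* carries the Kier–Hall
valence delta

    δᵛ(i) = (Zᵛ(i) − H(i)) / (Z(i) − Zᵛ(i) − 1)

(Zᵛ = valence electrons of the neutral atom, H = attached hydrogens),
and the index is the sum over all simple 3-edge paths *i–j–k–l*:

    ³χᵛ = Σ [δᵛ(i) δᵛ(j) δᵛ(k) δᵛ(l)]^(−1/2)

For carbon, nitrogen and oxygen δᵛ is the familiar integer (primary…
quaternary C → 1…4, NH₂ → 3, OH → 5); for the metals the neutral-atom
d+s count over the core gives fractional deltas (Ni → 10/17) that fall
from Cu to Mn, so ³χᵛ rises along the reversed Irving–Williams order.

For the four metals Mn, Fe, Co, Ni the stability constants obey a
single quadratic model normalized on the Ni complex of the same ligand
(x = ³χᵛ(MB) − ³χᵛ(NiB); bis indices for log β₂):

    log K₁ = a₁x² + a₂x + a₃·³χᵛ(NiB) + b

fitted by ordinary least squares and validated leave-one-out. Cu²⁺
deviates strongly upward from the quadratic metal trend (it is the
strongest Lewis acid of the series) and is excluded from the
simultaneous fit, though all Cu indices and per-metal diagnostics are
supported.

## Worked example

```
$ chelstab compute-chi --metal Ni --ligand glycine --species mono --list-paths
C1-CA1-N1-M	0.266199
C1-O1-M-N1	0.153690
...
N1-CA1-C1-OX1	0.083333
1.90
```

The 11 lines are the canonical 3-edge paths of the Ni–glycine mono
graph with their individual contributions; their sum, ³χᵛ = 1.90, is
the descriptor value for this complex.

```
$ chelstab fit --response K1
log K1: N=12  a1=12.06(1.38)  a2=-12.04(0.54)  a3=-0.672(0.046)  intercept=7.48(0.12)  r=0.999  S.E.=0.05
```

The simultaneous model on the 12 measured non-Cu log *K*₁ values:
coefficients (standard errors in parentheses), Pearson correlation of
observed vs fitted, and standard error of estimate in log units.

```
$ chelstab loo --response K1 | tail -1
S.E._cv=0.08  max|resid|=0.13
```

Leave-one-out cross-validation: each record predicted from a model
refitted on the other 11; prediction errors stay near the experimental
reproducibility of the constants themselves.

```
$ chelstab predict --metal Ni --ligand valine --response K1
5.64
```

An estimate for a pair with no measured constant — the practical use of
the model.

## Layout

- `src/chelstab/fixtures.py` — metal/ligand specifications and the
  experimental stability-constant table (18 records)
- `src/chelstab/graphs.py` — mono/bis aqua-complex graph construction,
  validation, plain-text adjacency I/O
- `src/chelstab/chi.py` — valence deltas, exhaustive simple-path
  enumeration, ⁿχᵛ
- `src/chelstab/model.py` — simultaneous OLS models, LOO CV, per-metal
  linear and per-ligand quadratic diagnostics
- `src/chelstab/cli.py` — `chelstab` command-line tool
- `docs/methods.md` — modelling conventions and their rationale
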