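# fourfold

Mutation–selection Markov models of fourfold-degenerate (4FD) codon usage
under the standard genetic code and 23 alternative NCBI translation tables.

## The problem

Synonymous codon usage is shaped by directional mutation and by selection.
One under-appreciated contributor is *general selection at the amino-acid
level*: a synonymous codon is lost and regained through nonsynonymous
neighbors, and the acceptability of those neighboring substitutions depends
on which amino acids (or stop signals) the genetic code assigns around it.
Under the standard code, GGA (Gly) is one substitution away from the stop
codon TGA; GGC is not. Purifying selection against the GGA→TGA change alone
is enough to bias the relative usage of GGN codons — with no selection on
the synonymous site itself. Alternative genetic codes reassign exactly these
neighborhoods, so each code transmits amino-acid-level selection to
synonymous usage with a different strength.

This package is written for molecular evolutionists who want to quantify
that effect: it models mutation as a continuous-time nucleotide Markov
process, selection as Grantham-distance-based acceptance probabilities of
the implied amino-acid changes, and measures how far the equilibrium usage
of the five 4FD codon groups (Ala/GCN, Gly/GGN, Pro/CCN, Thr/ACN, Val/GTN)
departs from the pure-mutation expectation.

## The model

* **Mutational pressure.** An UNREST generator `Q` on {A,C,G,T} with a
  *prescribed* stationary distribution π, parameterized by flux
  decomposition: the flux matrix `F_ij = π_i q_ij` splits into 6 symmetric
  edge fluxes (the reversible part) and 3 cycle circulations (all the
  irreversibility), so πQ = 0 holds by construction. Uniformization
  `P = I + Q/λ`, `λ = max|q_ii|`, and the positional tensor product lift `P`
  to a 64×64 codon mutation matrix with stationary distribution
  π_{c1}π_{c2}π_{c3}.
* **Selection.** A 21×21 acceptance matrix over the 20 amino acids + stop:
  `a(x,y) = 1 − D(x,y)/D_max` from Grantham's distance matrix (D_max = 215,
  Cys–Trp), with stop-involving substitutions at the lowest possible
  acceptance (0 by default). Off-diagonal codon transitions are multiplied
  by the acceptance of their amino-acid change; rejected mass stays on the
  diagonal.
* **The statistic.** For each 4FD group *s* with stationary selection-chain
  usage π^sel,

      Fπ|s = Σ_{i∈{A,T,G,C}} |π_i − π^sel(s_i)/π^sel(s)| / π_i,
      Fπ = Σ_s Fπ|s,

  which is 0 iff selection leaves every group's relative third-position
  usage at the mutational equilibrium π. The sequence-level analogue `F`
  replaces π by the cross-group average relative usage `e_i` and π^sel by
  observed codon counts.
* **Optimization.** A stationary distribution pins down only part of the
  process, so an elitist (μ+λ) evolution strategy with log-normal
  self-adaptive steps searches the 9-dimensional flux space for the rate
  matrix maximizing (or minimizing) Fπ; grid sweeps summarize each code over
  the lattice of stationary compositions.

A structural fact the package exploits and tests: with a symmetric
acceptance matrix, every *reversible* pressure yields Fπ = 0 exactly, so all
selection-induced bias is carried by the circulation parameters and the
minimization direction converges to zero.

## Worked example

`examples/01_selection_strength.py` builds one A+T-rich pressure
(π = A .40, T .35, C .13, G .12), applies Grantham selection, and scores the
same rate matrix under two codes:

```
code  1 (Standard): Fpi = 0.5386   Ala=0.1118  Gly=0.2811  Pro=0.0443  Thr=0.0668  Val=0.0344
code 22 (Scenedesmus obliquus Mitochondrial): Fpi = 0.6739   Ala=0.1721  Gly=0.2585  Pro=0.0729  Thr=0.1229  Val=0.0476
```

Under code 22 the codon TCA is a stop signal, so the Ala codon GCA sits next
to a forbidden substitution that its synonyms escape — the Ala component
rises from 0.112 to 0.172, and the total Fπ rises accordingly. The other
examples cover ES optimization (`02`), the sequence-level F statistic with
parameter recovery on synthetic CDS (`03`), and a miniature grid sweep with
summary tables (`04`). A thin CLI mirrors these entry points
(`fourfold optimize|sweep|fstat|simulate|report --help`).

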