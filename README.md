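# neutroshell

Neutron-scattering analysis of osmolyte–water–protein systems: how a
compatible solute such as ectoine, at molar concentration, is arranged
around a soluble protein and a membrane, and what it does to water
structure and dynamics.

The package is written for neutron-scattering practitioners working on
preferential hydration.  It implements four quantitative stages that
together characterise such a system from corrected, absolute-scaled
data:

1. **SLD bookkeeping** — scattering length densities of
   H₂O/D₂O/osmolyte solvents (volume-additive mixing) and of H/D-labeled
   proteins with labile-hydrogen exchange; contrast-match points.
2. **SANS contrast variation** — Guinier fits
   (I(Q) ≈ I(0)·exp(−Q²R_g²/3)), Stuhrmann lines of signed √(I(0)/N)
   versus solvent SLD, and the decomposition of the scattering particle
   into protein plus a **dense hydration shell**.  The shell-to-protein
   volume ratio X is fitted from the amplitude ratio between two
   contrast conditions,

       R(X) = [(Δρ·V)_Prot,A + X·V_Prot·Δρ_Hyd,A] /
              [(Δρ·V)_Prot,B + X·V_Prot·Δρ_Hyd,B],

   and the protein and shell radii of gyration follow from the
   parallel-axes line R_g² = f₁·R_Prot² + (1−f₁)·R_Hyd², where f₁ is
   the fractional protein contribution to the amplitude at each
   condition.
3. **Elastic incoherent scattering** — mean-square displacements from
   ln I_el vs Q² in the Gaussian approximation
   (⟨u²⟩ = −d·slope, divisor d = 6 or 3 by convention) and the
   resilience ⟨k′⟩ = 2k_B/(d⟨u²⟩/dT).
4. **Liquids diffraction and membrane geometry** — S(Q) ↔ g(r)
   sine-Fourier transforms (optional Lorch window), solute
   intramolecular subtraction, peak extraction, water H-bond geometry
   by the law of cosines, and Bragg lamellar spacings d = nλ/(2 sin θ).

A seeded synthetic-data module generates inputs with the statistical
structure each stage assumes (core–shell SANS curves, contrast series
with known shell parameters, Gaussian elastic ramps, Gaussian-peak
structure factors, lamellar peak lists), so the entire pipeline is
testable offline, with ground truth carried alongside every dataset.

## Worked example

Fit the hydration shell from the packaged eight-condition
contrast-variation table (two protein labelings × four ectoine
solvents):

```python
from neutroshell.reproduce import hydration_shell_analysis

res = hydration_shell_analysis()
print(res.summary())
```

```
Hydration-shell decomposition
==================================
amplitude ratio D-MBP 3M ect H2O / D-MBP 3M ect D2O: 3.452 +/- 0.069
X = V_Hydration/V_Protein      0.283 +/- 0.016
R_Prot (f1 = 1)                25.32 +/- 0.19 A
R_Hyd  (f1 = 0)                37.62 +/- 1.07 A
sphere-equivalent radius       32.68 A
shell thickness                2.83 A
uniform-shell Rg               34.15 A
...
```

Read it as: the deuterated protein scatters 3.45× more strongly (in
amplitude) in the ectoine–H₂O solvent than in the ectoine–D₂O solvent;
the only shell volume consistent with that ratio is X ≈ 0.28 of the
protein volume — a single ~3 Å layer of ectoine-free water about 10 %
denser than bulk.  The radius-of-gyration line extrapolates to the bare
protein at f₁ = 1 (25.3 Å) and to the shell alone at f₁ = 0.

The same chain is available from the shell as
`neutroshell reproduce-paper`, and each stage separately as
`neutroshell sld | guinier | shell-fit | rg-fit | eins | gr | hbond |
bragg | simulate`.  For example:

```sh
$ neutroshell bragg --two-theta 5.0 --order 1
d = 54.45 +/- 0.00 A
$ neutroshell hbond --distances 0.98 1.51 2.80 1.93
...
  beta (O-D vs O-O)    22.36 deg
  theta (O-D...O)      146.5 deg
```

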