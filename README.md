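# proteogate

Allosteric gating kinetics and α-ring electrostatic mapping of the 20S
proteasome.

The 20S core particle interconverts between a "closed" (gate-shut) and an
"open" conformation; regulatory particles dock on the outer α-rings through
salt bridges and shift that equilibrium.  Tetra-cationic porphyrins can mimic
this anchoring: their four positive charges form a square whose side length
must match the spacing of the acidic (Asp/Glu) clusters edging the
inter-subunit grooves.  `proteogate` implements the full analysis chain that
connects this structural picture to kinetics, for structural biologists and
enzymologists working on allosteric proteasome modulators:

- **Interface mapping** — detect core-particle/regulator ionic contacts in
  PDB/mmCIF complexes (4.0 Å salt-bridge convention), transfer them to
  homologous sequences by global alignment, group them by groove, and score
  carboxylate-centroid quadruplets against a ligand's charge square.
- **Ligand charge geometry** — idealized planar D4h calculator for
  tetra-substituted porphyrins: adjacent spacing `r·√2` evaluates to ≈11 Å
  with no spacer ring per arm and ≈17 Å with one para-phenylene spacer.
- **Steady-state kinetics** — competitive / uncompetitive / mixed /
  non-competitive rate laws, global mechanism discrimination by AICc with an
  extra-sum-of-squares F-gate for the mixed elaboration, logistic IC50 fits,
  and Lineweaver–Burk diagnostics.
- **Stopped-flow analysis** — variable-projection fits of
  `A(t) = A∞ + Σ aᵢ·exp(−kᵢ·t)`, AICc phase-number selection with
  ill-conditioning pruning, hyper/hypochromic phase signing, and per-phase
  `k_obs(x)` collection.
- **Two-state gating model** — concerted (MWC-type) populations

  `f_open(x) = L(1+K_open·x)^n / [(1+K_closed·x)^n + L(1+K_open·x)^n]`

  and the observed-rate law
  `k_obs = (k_closed·f_closed + k_open·f_open)·x + k_off`, with fitting,
  bimolecular-vs-cooperative model comparison, site-number sweeps, population
  curves and detailed-balance reports.
- **Synthetic data** — every input above can be generated with known ground
  truth (reference parameter sets for human, yeast and the open-locked
  α-3ΔN mutant 20S), so the whole pipeline runs and is tested without any
  external download.

The fitting surfaces are scikit-learn style estimators
(`InhibitionKinetics`, `DoseResponseIC50`, `ExponentialRelaxation`,
`TwoStateBindingModel`) and compose with sklearn tooling; module-level
functions (`fit_inhibition`, `fit_ic50`, `fit_exponentials`, `fit_kobs`, …)
are thin wrappers.

## Worked example

Simulate the human-20S observed-rate series under its reference parameter
set (5 % relative noise) and analyse it:

```bash
$ proteogate simulate human-20s --out-dir .
$ proteogate fit-kobs --data human-20s.csv --mode auto --n 3
selected mode: cooperative (dAICc 60.15)
k_on_open = 2.79e+06 /M/s, k_off = 0.212 /s
k_on_closed = 0.01 /M/s, K_open = 1.46e+07 /M, K_closed = 1.31e+04 /M, L = 8.34e-06 (n = 3)
```

The cooperative law beats the straight bimolecular line by ~60 AICc units:
the series is sigmoidal, as expected for a ligand that shifts the
open/closed equilibrium.  The association slope (`k_on_open`, true 2.8×10⁶
M⁻¹s⁻¹) and the dissociation intercept (`k_off`, true 0.22 s⁻¹) are sharply
determined; `K_open` and `L` individually sit on a likelihood ridge (only
`L^{1/n}·K_open`, the transition midpoint, is well constrained — see
`docs/methods.md`) and their point values should be read together with the
reported confidence intervals.  The same parameter set places the 50/50
open/closed crossover at 3.53 µM:

```bash
$ proteogate populations --fixture human-20s | tail -1
50/50 crossover at 3.53 uM
```

A substrate×inhibitor rate grid simulated under pure non-competitive
inhibition (Ki = 2 µM) is classified correctly, with the interaction factor
of the mixed elaboration statistically indistinguishable from 1:

```bash
$ proteogate simulate suc-llvy-inhibition --out-dir .
$ proteogate fit-inhibition --data suc-llvy-inhibition.csv
selected mechanism: noncompetitive
  noncompetitive  AICc    -364.27
  mixed           AICc    -361.59
  uncompetitive   AICc    -273.98
  competitive     AICc    -271.55
Vmax=1.01, Km=50.44 uM, Ki=1.943 uM
```

Structural commands work the same way: `proteogate simulate toy-complex`,
`proteogate map-contacts --structure toy-complex.pdb --core-chains A
--rp-chains B`, `proteogate site-match --structure ring.pdb --side 17`,
`proteogate ligand-spacing --spacers 1`.

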