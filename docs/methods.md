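# Methods

## The two-state concerted gating model

The 20S core particle is treated as a two-conformation system — "closed"
(gate shut, proteolytically quiescent) and "open" — carrying one cluster of
`n` equivalent ligand sites on the α-ring.  Following the concerted
(Monod–Wyman–Changeux) assumption, all sites of a cluster switch
conformation together.  With

- `L` — conformational equilibrium ratio `[open]/[closed]` at zero ligand
  (dimensionless; the closed state dominates the apo enzyme when `L ≪ 1`),
- `K_open`, `K_closed` — per-site association constants of the two
  conformations (M⁻¹),

the open fraction at free ligand concentration `x` is

    f_open(x) = L·(1 + K_open·x)^n / [ (1 + K_closed·x)^n + L·(1 + K_open·x)^n ]

computed in log space (`log1p` + logistic) so it is exact for any `x`.
`L` multiplies the open-state term; with the reference human parameters
(`L = 4×10⁻⁶`, `K_open = 1.8×10⁷ M⁻¹`, `K_closed = 7×10³ M⁻¹`, `n = 3`)
this convention yields `f_open(0) ≈ 4×10⁻⁶` (closed-dominant apo enzyme)
and a 50/50 crossover at 3.53 µM, in the low-micromolar window where the
kinetics change character — the self-consistency checks that fixed the
convention.

The observed pseudo-first-order binding rate constant is the
population-weighted association rate plus a single dissociation term,

    k_obs(x) = ( k_on_closed·f_closed(x) + k_on_open·f_open(x) )·x + k_off

which collapses to the classical bimolecular line `k_on·x + k_off` when the
two states are kinetically identical or when only one conformation exists
(the open-locked α-3ΔN gate-deletion mutant).  Only the first (high-affinity)
site cluster is modelled quantitatively; the second cluster, whose occupancy
returns the particle to a closed-bound state, has no published constants and
is deliberately out of numerical scope (a time-domain simulation of the
two-cluster occupancies would additionally require the extinction
coefficients of the partially bound intermediates).

`n` is always a fixed small integer, never a continuous exponent; the
site-number sweep fits `n ∈ {1, 2, 3}` separately and compares AICc (equal
parameter counts, so this is a pure goodness-of-fit comparison).  Lower `n`
cannot reproduce the steepness of the cooperative transition: a one-site
law needs ~two decades of concentration for a 10–90% rise, the three-site
law ~0.6 decade.

### Fitting and identifiability

`TwoStateBindingModel` fits in natural-log parameter space (positivity by
construction) with ≥16 multistarts (one data-driven heuristic start plus
log-uniform draws from a seeded generator) and `scipy.optimize.least_squares`
(TRF, bounded).  Residuals are *relative* by default: `k_obs` spans three
decades on the standard 0.2–100 µM grid and rate-constant noise is
multiplicative, so unweighted SSR would see only the top of the curve (and,
in practice, mistakes cooperative data for a straight line).  Explicit
`sample_weight = 1/SE²` overrides the default when measured standard errors
exist.  Covariances come from `s²(JᵀJ)⁻¹` at the optimum with a
pseudo-inverse fallback; confidence intervals use Student-t quantiles at the
residual degrees of freedom and are reported on the natural scale.

On the standard study conditions (15 log-spaced points, 0.2–100 µM, 5%
relative noise) the likelihood sharply constrains `k_on_open` (saturating
slope), `k_off` (intercept) and the composite `L^{1/n}·K_open` (transition
midpoint), constrains `K_closed` weakly (approach to saturation), and is
almost flat along the ridge `L·K_open^n = const` and in `k_on_closed`
(whose contribution, ≈`k_c·x ≤ 0.013 s⁻¹`, is buried under the intercept).
A ±25% move in `L` at fixed midpoint shifts the curve by under a tenth of
the noise standard deviation at the most sensitive point, so `K_open` and
`L` are *not separately recoverable* at realistic noise, and their point
estimates should always be read with their (correctly enormous) confidence
intervals.  Noiseless data do resolve the ridge through the `x → 0` limit,
which is what the exact-recovery closure tests exercise.  The
detailed-balance report (`k_on/k_off` vs `K` per conformation, >3-fold
discrepancies flagged per branch) is the recommended external check; note
that the published closed-branch constants of the wild-type sets are
themselves ~12-fold inconsistent and are flagged honestly.

Model comparison (`compare_modes`) fits both rate laws and selects by AICc,
with an extra-sum-of-squares F-test of the straight-line model reported as
a linearity diagnostic.  Selection is refused (both fits still returned)
when either model lacks the degrees of freedom for a finite AICc.

## Steady-state inhibition

Rate laws (S, I in µM):

    competitive      v = Vmax·S / ( Km(1 + I/Ki) + S )
    uncompetitive    v = Vmax·S / ( Km + S(1 + I/Ki) )
    mixed            v = Vmax·S / ( Km(1 + I/Ki) + S(1 + I/(α·Ki)) )

with pure non-competitive = mixed at interaction factor α = 1.  Mechanism
discrimination fits all four globally across inhibitor levels on
*untransformed* rates (double-reciprocal transforms distort the error
structure; Lineweaver–Burk is kept as a diagnostic only, with its classical
intersection patterns — common 1/v intercept → competitive, common −1/S
intercept → pure non-competitive, parallel lines → uncompetitive).  AICc
picks among the three 3-parameter mechanisms; the 4-parameter mixed model is
adopted only when the extra-sum-of-squares F-test shows a significant
improvement (α = 0.01 by default) over the best restricted fit.  Plain AICc
would promote the extra parameter on ~15–25% of datasets generated under the
restricted law — the F-gate is the standard guard and brings the
correct-selection rate above 95%.  Parameters are fitted in log space with
multistart (`Km` seeded from the uninhibited curve, `Ki` log-spaced
0.1–100 µM, 8 starts).

Dose–response fits use `a(I) = 1/(1 + (I/IC50)^h)` with `h` fixed at 1
unless freed; data must span the 0.2–0.8 activity band (no-transition input
is an error, not a silent extrapolation).  Tight-binding corrections are out
of scope (inhibitor ≫ enzyme in the emulated experiments, nM enzyme vs µM
ligand).

## Stopped-flow decomposition

Progress curves at the porphyrin Soret band are modelled as
`A(t) = A∞ + Σ aᵢ·exp(−kᵢ·t)`.  Sign convention (documented because it is
the most error-prone choice in this analysis): a **negative** amplitude
relaxes upward and is labelled **hyperchromic**; positive relaxes downward,
**hypochromic**.  Phases are reported in temporal order, i.e. descending
`k_obs`.

Fitting uses variable projection — the nonlinear search runs over log rates
only, amplitudes and plateau solved exactly by linear least squares at each
step — with multistart over log-spaced rate ladders.  Rates are bounded to
the observable window `[0.2/record length, 2×sampling rate]`; anything
faster decays between samples and anything slower is indistinguishable from
the plateau.  Phase-number selection fits n = 1..max_n and compares AICc
after pruning ill-conditioned candidates: fits with nearly degenerate rates
(ratio < 1.05), an amplitude within 2 SE of zero, or a rate within 2 SE of
zero are excluded.  The pruning is what prevents a two-phase trace from
being "improved" by a third micro-phase, and a pure-noise trace selects one
phase with an explicit near-zero-amplitude flag.  Phases are matched across
concentrations by rate rank (rates vary smoothly with concentration;
amplitudes need not), and mismatched extra phases are excluded from the
collected `k_obs` tables with a warning.  Pseudo-first-order conditions are
assumed throughout (free ligand ≈ total ligand); instrument dead time and
photobleaching are not modelled.

## Interface mapping and ligand geometry

A salt bridge is an acidic side-chain oxygen (Glu OE1/OE2, Asp OD1/OD2,
optionally the C-terminal OXT) within 4.0 Å — the standard convention — of
a basic side-chain nitrogen (Lys NZ, Arg NE/NH1/NH2; His optional, off by
default).  Contacts are deduplicated at residue-pair level keeping the
closest atom pair (interfaces are described by residues, not atoms), the
acidic partner is always listed first, and the k-d-tree search is verified
against an all-pairs oracle in the tests.  Coordinates and author residue
numbering (insertion codes included) are used exactly as in the file;
altloc policy keeps the first conformer; hydrogens and waters are dropped.
No electrostatics beyond the distance criterion is computed (no
Poisson–Boltzmann, no pKa), and no docking.

Homolog transfer aligns template and target sequences globally (BLOSUM62,
gap open 10 / extend 0.5 — orthologous proteasome subunits are highly
similar, so alignment choice is uncritical) and re-indexes contacts;
contacts whose acidic residue lands on a gap or a non-Asp/Glu target are
dropped and counted per cause.  Groove labels come from caller-supplied
chain→groove annotations; no ring topology is hard-coded.

Site geometry takes the carboxylate-oxygen centroid per acidic residue and
the full pairwise distance matrix.  Quadruplet matching scores every
4-subset by the RMS deviation of its sorted six pairwise distances from the
ideal square multiset `(s, s, s, s, s√2, s√2)`; subsets containing any
distance outside `[s − 3·tol, s√2 + 3·tol]` are pruned first — lossless,
since such a distance alone already forces the RMS above `tol` — keeping
exhaustive semantics tractable.  The score is a rigid-motion invariant by
construction (distances only).

The porphyrin calculator chains standard aromatic fragment lengths along
each meso arm (center→meso 3.45 Å, biaryl bond 1.49 Å, para-phenylene span
2.78 Å, ring–ring bond 1.48 Å, pyridine ipso→para-N 2.79 Å) under an
idealized planar D4h geometry: radial distance
`r = 3.45 + 1.49 + k(2.78 + 1.48) + 2.79`, adjacent spacing `r√2`, diagonal
`2r`.  These are design distances (k = 0 → 10.93 ≈ 11 Å, k = 1 → 16.96 ≈
17 Å), not conformer ensembles; "adjacent" is taken as the spacing the
design argument refers to, consistent with both printed values.

## Synthetic data: what it emulates and what it does not

Generators produce Michaelis–Menten grids under a stated mechanism
(multiplicative Gaussian noise, CV-parameterized — rate data are
heteroscedastic), dose–response curves, multi-exponential traces (additive
Gaussian noise — detector noise is amplitude-independent), cooperative or
bimolecular `k_obs` series (mean-one lognormal relative noise), two-chain
complexes with planted ionic contacts at exact distances plus >8 Å decoys,
and a seven-subunit pseudo-ring with an exact planted carboxylate square.
All randomness flows through explicit integer seeds; identical arguments
and seed give byte-identical text output.

Default study conditions: substrate 10–200 µM × inhibitor 0 + 6–100 µM
(6×6 grid, 3% CV), dose–response 0.05–50 µM (3% CV), stopped-flow 5 s at
1 kHz with 0.002 AU detector noise and the two-phase reference
(a = −0.05 AU at 10 s⁻¹, +0.03 AU at 1 s⁻¹ on a 1.0 AU plateau),
`k_obs` series on 15 log-spaced points 0.2–100 µM at 5% CV (the
concentration grid of the source experiments is not published; log-spaced
coverage of the transition is the natural stand-in).  Reference parameter
sets hard-code the published human / yeast / α-3ΔN constants as simulation
truth so recovery tests have an unambiguous target.

Passing tests on these fixtures demonstrate correctness of the estimators
under their own model classes and realistic noise, **not** robustness to
everything real data add: baseline drift and dead-time loss in stopped-flow
traces, substrate depletion in steady-state assays, day-to-day enzyme
activity variation, partially occupied altlocs and missing side-chain atoms
in crystal structures.  The structural fixtures are labelled synthetic in
their headers and carry planted, not biological, geometry.

## Known limitations

- Single-cluster kinetics only; the second site cluster is narrative.
- `K_open` and `L` are jointly, not separately, identifiable from a single
  `k_obs` series at realistic noise (see above).
- Mechanism discrimination assumes a single inhibitor binding event per the
  classical laws; partial or substrate-inhibition models are out of scope.
- Interface mapping is purely geometric; protonation states and buried
  salt-bridge energetics are not assessed.
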