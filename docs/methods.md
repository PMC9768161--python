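# Methods

## Model representation

A metabolic model is a signed stoichiometric table over declared reactions
and metabolites, with reversibility flags and an internal/external
metabolite split. Coefficients are stored as exact rationals
(`fractions.Fraction`); decimal input like `1.5` is expanded exactly to
`3/2`. This matters because elementary-mode support minimality is a
combinatorial property: whether a restricted submatrix has a
one-dimensional nullspace must not depend on float round-off.

METATOOL text (`-ENZREV`, `-ENZIRREV`, `-METINT`, `-METEXT`, `-CAT`) is
the interchange format. The parser accepts a permissive superset of
observed dialects — sections in any order, `#` comments, both `2 A` and
`2A` coefficient spellings, decimal and rational coefficients — and the
writer emits one canonical form (`2 A`, unit coefficients omitted), so
parse∘write is the identity on valid models. Identifiers that begin with a
digit must use the spaced spelling, since `13BPG` would otherwise be
ambiguous. Substrate molecular weights, the exchange map and gene–reaction
links cannot be carried by METATOOL and ride in sidecar files (an
INI-style config and a two-column TSV). Gene–reaction association is a
flat many-to-many table; Boolean gene–protein–reaction logic is
deliberately out of scope.

## Elementary-mode enumeration

The EMs of a network whose reversible reactions have been split into
forward/reverse irreversible copies are exactly the extreme rays of the
pointed cone {v ≥ 0 : N_int·v = 0}. We enumerate them with the double
description method initialised on the nonnegative orthant: start from the
unit rays, impose one steady-state equality at a time, and at each step
combine adjacent (positive, negative) ray pairs. Adjacency uses the
combinatorial zero-set test — a pair is adjacent iff no third ray's zero
set contains the intersection of theirs. We chose the orthant-initialised
variant over the nullspace-initialised one because it is the simplest
formulation to verify line-by-line against the oracle below, and at the
network sizes this package targets the constant-factor difference is
irrelevant. All arithmetic is rational; every ray is normalised by its
smallest nonzero absolute coefficient, which also makes equality testing
exact.

Post-processing maps split-space rays back to signed original-space
vectors: the spurious forward+backward two-cycles of reversible splitting
are dropped, rays activating both directions of one reversible reaction
(decomposable, not original-space EMs) are rejected, and modes using only
reversible reactions — which appear in both orientations — are
canonicalised by making the first active reaction in declaration order
positive. Output order is deterministic (sorted by support signature, then
coefficients).

A configurable mode-count cap (default 10⁷) raises a hard error instead of
silently truncating: realistic organ models produce millions of modes and
users must opt into larger runs.

**Verification oracle.** `brute_force_modes` implements the algebraic
definition directly: a support S carries an EM iff the internal matrix
restricted to S has a one-dimensional nullspace whose basis vector is
nonzero on all of S and single-signed. (Strict sign-feasibility plus
rank deficiency one implies minimality: a feasible proper sub-support
would force a kernel vector with zeros inside S.) The oracle is limited to
14 reactions post-split and shares only the back-mapping code with the
main algorithm. Exact linear algebra (RREF/nullspace) is a small hand-
written routine over `Fraction` rows rather than a sympy dependency — the
inner loop needs plain lists, and the routine is ~40 lines exercised by
the oracle-equality property test on dozens of random networks.

## Structural fluxes

For mode *i*: yields e_i^k = c_i^k / Σ_s c_{s,i}·MW_s over the declared
substrate uptakes; efficiency ε_i = e_i^objective / Σ_k |e_i^k|; per-
reaction structural flux aSF_k = Σ_i ε_i·|e_i^k| / Σ_i ε_i; and
aStruF_k = aSF_k / aSF_TotalSub with aSF_TotalSub the sum over substrate
uptakes. Everything is degree-0 homogeneous in each mode's scaling (tested
to 1e-12 under random positive rescaling) and computed in rational
arithmetic; floats appear only at output boundaries.

Edge rules, chosen where the formulas are silent:

- a mode that takes up no substrate (internal futile cycle) is flagged
  `no-substrate` and gets ε = 0 — it stays in the mode set so the set is
  immutable across objectives;
- a substrate reaction running in reverse (substrate produced) contributes
  zero to the yield denominator;
- the objective yield is signed: modes producing the objective count,
  modes with zero or negative objective yield get ε = 0;
- if every ε is zero the objective is reported "unreachable" by name,
  never as an all-zero table.

The objective registry is configuration-driven. The default name list
covers the biological processes a kidney-type organ plausibly maximises
(ammonia excretion, growth, ATP maintenance, glucose production, urea
excretion, protein uptake and breakdown, lactate and free-fatty-acid
uptake, per-amino-acid transports) and is user-extensible, since the
appropriate reaction ids are model-specific.

## Expression-constrained scenarios

"Upregulated" means log2FC > 0 **and** adjusted P < α (default 0.05).
For each such gene separately, the active set is restricted to modes whose
support intersects the gene's reaction set — the ≥1-intersection reading
of "pathways containing the gene"; requiring the gene's reaction in every
mode would instead be a filter on single reactions and would empty most
scenarios. Restriction is idempotent and never enlarges the set; genes
mapped to identical reaction sets provably yield identical scenarios.
Gene symbol matching is case-insensitive (rat symbol capitalisation varies
across sources). Scenarios whose restricted set is empty or whose
objective becomes unreachable are flagged, not dropped. Relative flux
change against the unconstrained baseline is 100·(aStruF_c −
aStruF_b)/aStruF_b; 0/0 is 0% and a flux appearing only under the
constraint is flagged "new flux" (infinity) rather than given a number.

## Organ-balance fluxes

Exchange flux = (venous − arterial) · plasma flow · 100 / body weight, in
nmol (100 g bw)⁻¹ min⁻¹, release-positive, both kidneys. Renal plasma flow
comes from PAH infusion via Fick's principle: urinary PAH excretion rate
divided by the arteriovenous PAH difference (classical organ-balance
form). Plasma — not whole-blood — quantities are used throughout;
hematocrit is carried in the data model but enters no default formula, so
a whole-blood correction remains a caller-side opt-in. Total
ammoniagenesis is renal venous efflux plus urinary excretion; the urinary
percentage is undefined (not 0 or 100) when the total is non-positive.
Group summaries report both mean ± SEM and median (range), a two-sided
Mann-Whitney P per metabolite when exactly two groups are present, and a
direction-aware Stouffer-combined P across metabolites.

## Evaluation

Predicted aStruF values of mapped exchange reactions are oriented
release-positive using the reaction's net external stoichiometry and
paired with measured per-metabolite fluxes — by design the group means,
one value per metabolite per diet group. Pearson's r is invariant under
positive affine rescaling of either vector, which is exactly why
correlation is the right comparison between unitless aStruF and fluxes in
nmol (100 g bw)⁻¹ min⁻¹. At least three shared metabolites are required;
unmatched metabolites are listed as exclusions, never silently dropped.
Two-sided P values come from the t transform on n−2 degrees of freedom
(scipy); the two-tier significance flag ('*' for P < 0.05, '**' for
0.05 ≤ P < 0.1) is attached as metadata. Ranking is by descending r with
alphabetical tie-break for determinism. Stouffer's combined P converts
each one-sided P to a z score, applies the direction sign, and divides the
sum by √k; boundary P values are clamped at a configurable ε with a
warning.

## Synthetic study conditions

The generator produces the three input kinds the pipeline reads, in the
same file formats:

- **toy networks** with analytically known EM counts — chain (1), diamond
  / k-fan (k), double-diamond (4), cycle+chain (2, one mode substrate-
  free) — and seeded random-sparse networks capped at 12 reactions
  post-split so the brute-force oracle stays applicable. Random models are
  patched with export reactions so every internal metabolite touches ≥2
  reactions and the models validate cleanly. The toy substrate MW is
  100 g/mol so the worked-example arithmetic stays exact by hand.
- **measurements**: venous concentrations are constructed so the organ-
  balance formula returns a prescribed flux pattern exactly at zero noise
  (body weight 300 g, plasma flow 3 ml min⁻¹, arterial baseline
  500 nmol ml⁻¹ — representative rat-scale values); Gaussian noise is
  applied to the concentrations, i.e. upstream of the same arithmetic the
  real pipeline uses.
- **expression tables** whose upregulated subset is recovered exactly by
  the significance filter.

The recovery experiment — synthesize measurements from one objective's
predicted exchange pattern on a 4-fan (8 animals per replicate, noise SD
at 20% of the signal RMS, 100 replicates) and require the generating
objective to rank first — is the package's core parameter-recovery
guarantee. These conditions emulate the arithmetic structure of real
arteriovenous data, not its physiology: no inter-animal variation in body
weight or flow, no correlated analytical error across metabolites, no
hematocrit dynamics, and toy networks far smaller than a real organ model.
Passing tests therefore demonstrate correctness of the computational
chain, not predictive validity on any real kidney.

## Numerical choices and limitations

- Exact rational arithmetic end-to-end until the structural-flux output
  boundary; equality tests on modes are exact, float comparisons in tests
  use 1e-12.
- Enumeration cost grows steeply (the double description intermediate ray
  count can explode); the package targets medium-scale models and refuses,
  via the cap, to silently degrade. Problem sizes in the shipped tests and
  the acceptance script (≤ 12 reactions post-split, 50 random networks,
  100 recovery replicates) were chosen to keep the full verification suite
  in the minutes range on one CPU.
- Multi-gene simultaneous constraints, FBA/LP methods, thermodynamic
  weighting, SBML I/O and approximate EM sampling are out of scope.
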