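# Methods

## The μ-parametric ME formulation

A metabolism-and-expression (ME) model extends a stoichiometric network
with the machinery that produces it. Every constraint is a species balance
`S(μ)·v = 0` with bounds `vL ≤ v ≤ vU` and the biomass-dilution flux pinned
to the growth rate μ. Coupling constraints are encoded on the machinery
species itself: the formation reaction produces it and each enabled process
consumes a μ-dependent amount, so the balance row *is* the coupling
equation and no constraint leaves the single `S·v = 0` system. Where no
natural species exists for a row — mRNA degradation, and the explicit
coenzyme-formation row — a pseudo-species carries it.

Every coefficient is stored as `a + b·μ + c/μ + d·μ²`. The affine and 1/μ
parts cover the ribosome, RNA-polymerase, enzyme, tRNA, mRNA and coenzyme
terms; the μ² part carries the synthetase term, whose product form
`(1 + μ/k_t)(μ/k_c)` expands to `μ/k_c + μ²/(k_t k_c)` and is not
representable in a purely affine-plus-reciprocal scheme.

Consumption by a coupling term subsumes dilution of the machinery: an
enzyme used at flux v requires formation at `μ·v/k_eff`, which is exactly
the dilution loss of the steady-state enzyme pool `v/k_eff`. Machinery
protein mass is accounted where it is synthesised: each translation flux
adds the peptide's mass to the protein-biomass pool, which the
`protein_biomass_to_biomass` summary passes into the biomass pool drained
at rate μ.

### The μ = 0 limit

The mRNA-degradation coefficient diverges as 1/μ, so the LP cannot be
evaluated *at* μ = 0 naively. `evaluate_at_mu(model, 0)` raises a
singularity error; the solver instead evaluates in limit semantics: a
diverging coefficient forces its carrying flux to zero, which is the exact
μ→0⁺ limit. With all couplings vanishing (or forcing zeros) at μ = 0, the
zero flux vector is always feasible there, which anchors the bisection
bracket.

## Coenzyme-activity coupling

Recycled coenzymes (NAD, quinones, folates) are mass-balanced but their
*synthesis* is never forced by stoichiometry — traditionally a static
biomass demand fills that gap. Here the static demand is closed and each
qualifying coenzyme pair gets a pseudo-first-order activity coupling:
wherever the uncharged form is a reactant its coefficient is multiplied by
`(1 + μ/k_activity)`, leaking `μ/k_activity` of pool per unit charging flux
that biosynthesis must replace; an explicit formation row ties the
designated final synthesis reaction to the same sum. A species qualifies if
it functions exclusively as a coenzyme (outside its biosynthesis reaction,
every consumer also produces the charged partner; closed reactions are
ignored) and if it — or a user-declared close derivative via an alias map —
is a biomass-objective member.

`k_activity` defaults to 1e4 h⁻¹, a deliberately rough first-order scale:
with μ of order 1 h⁻¹ the multiplier is ~1.0001, so the coupling is
perturbative. The package verifies this design property directly: at
`k_activity = 1e8` the coupled optimum matches the uncoupled model to
better than 1e-4 relative. Per-(coenzyme, reaction) overrides exist for
sensitivity analyses. The multiplier is applied multiplicatively to
coefficients ≠ 1; the directional rewrite applies to forward-consuming
occurrences (reversible consumers should be split into irreversible pairs
before coupling).

An important structural consequence, exercised by the auxotroph analysis:
because the formation row *forces* flux through the designated synthesis
reaction, an auxotroph must be created upstream of it — the imported
precursor then feeds the still-active final step. Knocking out the
designated reaction itself makes external coenzyme supply useless.

## Solver

Feasibility at fixed μ is decided by scipy's HiGHS backend (double
precision, LP feasibility tolerance 1e-9) on the compiled parametric system
`S(μ) = A0 + μA1 + A2/μ + μ²A3`; compiling once makes re-evaluation cheap
and bit-reproducible. Growth is maximised by bisection maintaining a
(feasible, infeasible) bracket, defaulting to `mu_hi = 4 h⁻¹` and
tolerance 1e-6 h⁻¹ — double precision at toy scale, in place of the
quad-precision 1e-13 regime genome-scale systems need for conditioning.
Ties at the bracket boundary resolve toward feasibility; stored
biomass-dilution bounds act as an explicit cap on feasible μ. No solver
basis is reused between bisection steps (the backend exposes none);
warm-starting would be a speed optimisation only and may never change
feasibility verdicts. When HiGHS reports numerical ambiguity at the
feasibility boundary, the solve is retried without presolve and a
persistent ambiguity is classified infeasible — the conservative direction,
which can only round the reported optimum down by at most the bracket
resolution.

Because the LP at the optimal μ generally has alternate optima, reported
flux vectors are made deterministic by a parsimonious secondary objective:
minimise total absolute flux (reversible columns split into positive
parts). The choice of inner objective is a reporting convention; it does
not affect μ*.

## Biomass-demand accounting

* **Amino acids** — translation flux × peptide composition, summed over
  peptides.
* **Prosthetic groups** — complex-formation fluxes × engrafted
  stoichiometry, summed over complexes.
* **Coenzymes** — the flux of the one designated reaction of the coenzyme's
  biosynthetic pathway (participation throughout the network is too broad
  for a composition sum; each cofactor has one direct pathway).

Demands below 1e-12 mmol/gDW/h are clamped to zero to suppress LP noise.
Two normalizations: per growth (mmol/gDW — the biomass-objective
comparison convention) and per protein biomass (the cross-condition
convention, dividing by the protein-biomass summary flux). Protein
normalization is imperfect for coenzymes, whose usage is not strictly a
function of protein abundance; both modes are exposed and no third is
invented.

## Condition scans

Nutrient panels follow the sole-source protocol: the base source of one
element class (C/N/P/S) is closed and the candidate's exchange opened at
the class uptake limit (default 10 mmol/gDW/h for C/N, 5 for P/S);
a supplementation flag keeps the base source open instead. Aerobicity
toggles the O₂ exchange lower bound (−20 aerobic, 0 anaerobic).
Growth-supporting means μ* > 1e-3 h⁻¹. Scans never mutate the input model,
so output is order-independent and re-runs are bit-identical; per-condition
solver failures are logged and skipped.

## Composition statistics

* **PCA** — components are z-scored by default (demands span orders of
  magnitude); a flag reproduces covariance PCA. Signs are fixed
  deterministically, with PC1 oriented so aerobic conditions score
  negative. The PC2–growth-rate association is reported as Spearman rank
  correlation (with Pearson alongside).
* **Outliers** — per-component z-scores across conditions (sample sd);
  |z| > 3 is reported with log2 fold change against the component mean.
  With a constant background of n conditions the attainable |z| is capped
  at (n−1)/√n, which bounds how extreme a planted outlier can register.
* **Clustering** — outlier conditions removed, each component divided by
  its maximum, Ward-linkage agglomeration. The cluster count is selected by
  the gap statistic against B = 50 seeded uniform reference draws over the
  normalized bounding box, using the standard elbow rule (smallest k with
  Gap(k) ≥ Gap(k+1) − s(k+1)); a bare argmax is unstable on the near-flat
  plateau beyond the true k.
* **Cluster characterization** — two-sided Wilcoxon rank-sum per
  (cluster, component), in-cluster vs out-of-cluster, retained at
  p < 1e-5 and |log2 fold change| > 0.15. No multiple-testing correction is
  applied by default (the fixed stringent threshold plays that role); an
  option exists. For pooled sizes ≤ 40 without ties the exact null
  distribution of the rank-sum statistic is used — identical to a full
  permutation test, and necessary because the normal approximation cannot
  reach p < 1e-5 at group sizes around 10–15; larger or tied samples use
  the tie-corrected normal approximation.
* **Conditional essentiality** — a cofactor is flagged required in a
  condition iff its clamped demand is positive there.

The outlier-calling recipe operates on whatever table is passed in; the
aerobic-only analysis is obtained by subsetting the scan table to aerobic
growth-supporting conditions first.

## Limitation analysis

Auxotrophs are built by zeroing knockout-reaction bounds and opening an
uptake exchange for the essential metabolite; construction fails loudly if
the model still grows with the exchange closed. The limitation profile
takes the uptake at unconstrained maximum growth as 100% and caps uptake
magnitude at 20 fractions from 1.00 down to 0.05 (the cap is an upper bound
on uptake — the model may use less), re-optimising at each point. Protein
allocation assigns each complex the steady-state mass
`formation flux × MW / μ`, split across the subsystems of its catalysed
reactions proportionally to usage flux (annotation fallback for unused
machinery), normalized to sum to 1. Flux-response summaries report
growth-normalized, max-scaled series ranked by standard deviation, merging
series identical within 1e-6 ("perfectly correlated" — exact Pearson r = 1
is numerically fragile) into one row with a member count. The excess
analysis opens each auxotroph's uptake unbounded and reports subsystem
protein-mass log2 fold changes against the prototroph, filtered at
max |log2fc| > 0.2.

## The synthetic toy network

The generator emits a connected ME network (~25 enzymes' worth of species
and reactions at defaults) with: glucose-analog glycolysis feeding a
pyruvate hub; two fermentative branches (acetate-analog at 1 NADH and a
more-reduced ethanol-analog at 2 NADH per pyruvate, so redox closes
anaerobically while pyruvate drains to biomass); an aerobic branch
(pyruvate-dehydrogenase analog with thiamine-analog prosthetic group and a
1500 s⁻¹ turnover override, TCA-analog, NADH dehydrogenase charging the
quinone pair, terminal oxidase with heme-analog prosthetic group) yielding
9× the fermentative ATP per glucose; amino-acid synthesis from the pyruvate
hub (the sulfur amino acid via an assimilation enzyme carrying a
siroheme-analog group, bypassed by an organic sulfur source); a two-step
NAD-analog pathway via a niacin-analog precursor; per-enzyme expression
chains with ribosome/RNA-polymerase machinery and an optional
tRNA/synthetase layer; and a storage-polymer reaction that fills the
biomass mass balance beyond machinery protein — without it, the equality
closure `protein + storage = μ` would demand that modeled machinery protein
alone weigh a full gram per gDW, which the coupling equalities cannot
supply.

Planted structure for the statistics: a fatty-acid-analog carbon source
whose catabolism needs a flavin-analog prosthetic group and 3 NAD charges
per molecule (composition outlier), an ornithine-analog nitrogen source
needing a pyridoxal-analog enzyme, non-catabolizable decoy nutrients, and
four benign sugar alternates so the growth-supporting condition count
(~25) is large enough for |z| > 3 calls to be attainable.

Parameter defaults: the printed reference values where they exist
(k_eff default 65 s⁻¹ → 234000 h⁻¹, pyruvate-dehydrogenase 1500 s⁻¹,
k_activity 1e4 h⁻¹, unmodeled-protein fraction 0, κ_τ = 4.5 h⁻¹,
r₀ = 0.087); metabolic turnover numbers drawn per reaction from
U(30, 200) s⁻¹ to create proteome-cost heterogeneity; c_ribo = 5000
(effective elongation c_ribo·κ_τ ≈ 22500 aa/h per ribosome, ~6 aa/s),
c_mRNA = 10, c_tRNA = 500, k_deg = 12 h⁻¹ (~3.5 min mRNA half-life),
peptide lengths U{150..400} with seeded multinomial amino-acid
compositions, residue masses ≈ 0.105–0.115 g/mmol, 2 ATP per residue
translation cost. All randomness flows from the single config seed; the
same seed yields byte-identical model JSON. The generator self-checks by
solving once before returning.

What the toy does *not* emulate: element- and charge-balanced chemistry,
realistic proteome mass fractions (machinery protein is a small share of
toy biomass), metal-ion cofactors, thermodynamics, and regulatory
constraints (the toy will happily run its pyruvate-dehydrogenase analog
anaerobically if the LP favors it). Passing tests therefore demonstrate the
correctness of the constraint assembly, optimisation and statistics
machinery on networks with the right *structure*, not quantitative
agreement with any real organism.

## Problem sizes used in the shipped analyses

Toy models of ~130 species × ~160 reactions; 15-nutrient panels × 2
aerobicities (30 conditions, ~25 growth-supporting); 7 auxotrophs × 20
limitation fractions; statistics fixtures of 24–40 conditions × 6–10
components over 20 seeds with B = 50 gap-statistic references. These sizes
make every analysis exact and fast while preserving the structural
phenomena of interest; all of them are configuration, not code.

## Known limitations

* Double-precision LP with bisection tolerance 1e-6 h⁻¹; genome-scale
  ME systems are ill-scaled and need quad precision, which is out of scope.
* Coupling rows are strict equalities as formulated; a ≥-relaxation exists
  only as the biomass-dilution cap, not per row.
* The activity coupling uses one global first-order constant; estimating
  k_activity from data and sensitivity analysis around it are left to the
  override hooks.
* The M-model JSON importer produces metabolic-only specs; it does not
  reconstruct expression machinery.
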