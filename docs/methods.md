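# Methods

## The measurement model

`protstab` implements the computational pipeline of a pooled proteolysis
selection read out by deep sequencing.  Each library member is a small protein
domain (40–72 aa) covalently linked to its coding DNA; after a 5-minute
digestion at one of 24 protease conditions (two proteases × two replicate
dilution series of 11 threefold dilutions plus a no-protease control), intact
molecules are recovered and sequenced.  The raw observable is a count table:
reads per sequence per condition, matched exactly at the nucleotide level
against the ordered library.

Cleavage follows single-turnover kinetics (protease far in excess of each
substrate): `k_obs = k_max · E / (E + K50)`, with `K50` the protease
concentration at half-maximal cleavage rate, and survival after the digestion
time `t` is `exp(−k_obs · t)`.  `k_max · t` is treated as one calibration
constant (default `k_max = 1 min⁻¹`, `t = 5 min`); it is degenerate with an
overall concentration scale, which the inference absorbs.

Folding thermodynamics enter through a two-state model.  A folded molecule is
cleaved only in its constant tag regions, with a universal per-protease
`K50_F`; an unfolded molecule is cleaved at its sequence-specific sites, with
`K50_U` predicted from sequence.  Folding, unfolding and enzyme binding are
assumed in rapid equilibrium relative to cleavage, so binding is governed by
the population-weighted dissociation equilibrium and the observed `K50`
satisfies the harmonic mixing rule

    1 / K50 = f_U / K50_U + (1 − f_U) / K50_F,
    f_U = 1 / (1 + exp(ΔG / RT)).

This closed form is exact under joint rapid equilibrium (the bound fraction at
concentration `E` is `E / (E + K50_eff)`), and the test suite verifies it
against a brute-force equilibrium-population root finder.  Inverting it maps a
measured `K50` to an absolute unfolding free energy ΔG (kcal/mol, positive =
stable).  `RT` defaults to 0.593 kcal/mol (298 K).  ΔG estimates are reliable
only inside the assay's dynamic range and are clipped to [−1, 5] kcal/mol with
explicit censoring flags; values whose 95% interval lies fully outside the
range are reported as `<−1` / `>5`.

## K50 inference from counts

With pre-selection fraction `f_i` and survival `S_i(c)`, the expected
post-selection fraction at condition `c` is `f_i S_i(c) / Z_c`, where
`Z_c = Σ_j f_j S_j(c)` renormalizes the surviving pool.  Counts are multinomial
at the sequencing depth.  Under a Poisson approximation the nuisance `f_i`
profiles out in closed form, leaving a per-sequence profile log-likelihood
over a log10 K50 grid that is a single matrix product — see `k50.py`.  The
normalizer `Z_c` couples all sequences and is re-estimated from the current
fits in an EM-style alternation (it is only identifiable jointly; no extra
per-condition parameter is introduced, matching the multinomial's implicit
normalization).

Numerical choices:

* Prior/grid: uniform on log10 K50 over [log10(min conc) − 2,
  log10(max conc) + 2], 501 coarse points; the MAP is refined by local
  quadratic interpolation.
* Intervals: posterior quantiles on a per-sequence fine grid around the MAP
  (at high depth the posterior is narrower than the coarse step; quantiles on
  the coarse grid would misplace intervals).  Censoring is declared when the
  95% interval touches a prior bound.
* Multi-start: the joint (Z, K50) likelihood has near-degenerate optima
  related by a one-dilution-step ladder translation when the pool contains no
  fully resistant sequences; the alternation is started from step-shifted
  initializations and the highest-likelihood fixed point is kept.
* The default fit pools both replicate series; a per-replicate mode supports
  replicate QC and the effective-concentration calibration (a single
  multiplicative factor per condition set, recovered as
  `10^(−median Δlog10 K50)` over shared uncensored sequences).

Simulation calibration (see `scripts/acceptance.py`): at 10⁶ reads per
condition over 500 sequences, the median |log10 K̂50 − truth| is ≈ 0.004 and
95% intervals cover the truth for ≈ 93–95% of sequences.

## The unfolded-state model

`K50_U` is predicted by a cleavage-site position-specific scoring matrix:
every protease target residue (trypsin K/R; chymotrypsin F/Y/W/L/M — the
default target sets are configurable) contributes a rate
`10^(a0 + Σ_off w[off, aa])` over a −4..+3 window around the scissile bond
(out-of-range offsets use a dedicated boundary symbol), and site rates add:
`1/K50_U = Σ_sites rate`.  More cut sites therefore mean lower `K50_U`.  A
sequence with no target sites is flagged unfolded-state resistant and is
unusable for ΔG with that protease (the joint fit falls back to the other
protease).  Weights are fit by ridge-penalized least squares (λ = 1e−3) on
scrambled sequences — residue-shuffled, assumed fully unfolded, so their
measured K50 equals `K50_U` — using L-BFGS from zero initialization with an
analytic gradient.  The model form (log-additive weights, additive site rates)
is this package's concrete choice for a PSSM over cleavage sites; window,
targets and penalty are configurable.

## Joint ΔG fitting and quality filtering

The joint fit maximizes the product of the two proteases' count likelihoods
over a single shared ΔG, each protease's K50 tied to ΔG through its own
(`K50_U`, `K50_F`).  Per-protease ΔG estimates (used for consistency QC) come
from transforming the per-protease K50 posterior through the monotone
K50 → ΔG map.

Filtering has three stages.  (1) Measurement level: 95% interval width > 0.5
kcal/mol flags low confidence; out-of-range estimates are censored as above.
(2) Scan level: each wild-type background's full mutational scan is assigned
to exactly one group, first failing rule in the order G2 (poor expression,
median wild-type pre-selection counts < 20), G3 (wild type too unstable,
ΔG < 0.25), G4 (wild-type ΔG inconsistent between proteases, gap > 1.0), G5
(trypsin–chymotrypsin correlation r < 0.8 over reliable variants), G6 (OLS
slope outside [0.8, 1.25]), G9/G8 (> 1 Cys; G8 when whitelisted), G7 (> 10% of
variants with ΔΔG > +1), G10 (|intercept| > 0.75), G11 (folded-state cleavage
signature), then G1 if wild-type ΔG > 4.75 kcal/mol else G0.  Only the G1 cut
(4.75) and the 0.5 kcal/mol interval flag are canonical constants; the others
reproduce the decision structure and are exposed in `GroupThresholds`.  The
G11 heuristic looks for substitutions that remove a wild-type cut site of one
protease and gain apparent stability in that protease only; the jump is
measured on per-protease ΔΔG with threshold `0.5·RT·ln10 ≈ 0.68 kcal/mol`,
the ΔG-equivalent of half a log10 unit of K50 — removing a genuine cut site
also raises raw K50 in clean data (via `K50_U`), so raw K50 is the wrong
variable for this test.  (3) Mutant level, within G0/G1 scans: substitutions
that introduce a new cleavage site into a poorly structured region with
apparent destabilization in that protease, or a Cys into a poorly structured
region with apparent stabilization, are blanked in the `_ML` columns.
"Poorly structured" means the site's ΔG standard deviation across rule-exempt
substitutions is below 0.3 kcal/mol; computing the variance over the
rule-exempt set makes the filter idempotent.  Wild-type ΔG is the median over
synonymous wild-type codon variants.

Dataset assembly mirrors the deposited-table conventions: a dataset-2 analogue
(all G0+G1 variants with ΔG) and a dataset-3 analogue (G0 variants with ΔΔG,
the only scans where stabilizing mutations are resolvable), with filtered or
out-of-range entries replaced by `–` / `<-1` / `>5` in `_ML` columns.

## Downstream analyses

* **Site PCA** — site × 20 ΔG profiles are clipped, site-mean-centered, and
  decomposed with scikit-learn PCA (≤ 19 components; centering removes one
  degree of freedom).  The wild-type advantage statistic is the median over
  sites of the mean ΔΔG of the 19 alternatives; its rank-k reconstruction uses
  a truncated SVD of the site-centered matrix so that k = 0 gives exactly 0.
* **Thermodynamic couplings** — a 40-parameter two-way additive model per
  20×20 double-mutant grid, solved by least squares on clipped ΔG with
  censored/missing cells excluded; the coupling is observed − fitted (the
  classical interaction residual on complete tables).  Bootstrap cell
  uncertainties resample the observed cells with replacement (n = 1000,
  seeded); because each cell's own value stays fixed, the bootstrap sd
  measures the additive fit's uncertainty at the cell (σ·√(1/R + 1/C − 1/RC)
  under iid noise), which is what the uncertainty on a reported coupling
  should mean.  Triplet analyses fit each pair × background grid
  independently; the third-order signature is the wild-type cell's coupling
  difference between backgrounds.
* **Wild-type classifier** — `P(a|site) = softmax(ln2·(g(ΔG_a) + o_a))` over
  the 19 non-Cys amino acids; `g` is non-decreasing piecewise-linear with
  knots every 0.5 kcal/mol on [−1, 5] (nonnegative increments, small
  second-difference penalty to damp wiggles where data are sparse — the
  penalty vanishes on any constant slope), and offsets are anchored at
  Val = 0.  Recovery uses argmax with lexicographic tie-break; perplexity is
  base 2.  Two information limits matter for recovery studies: offsets are
  identified only up to an additive constant (the Val = 0 anchor is a
  reporting convention, and the anchor amino acid's own sampling error shifts
  every other offset), and the rarest amino acids occur only tens of times in
  5,000 sites.  Recovery is therefore summarized by the mean absolute offset
  error after aligning the gauge (removing the mean signed difference).
* **Functional sites** — per-site conservation scores (e.g. from an external
  evolutionary model) are averaged over the 19 non-Cys substitutions,
  standardized within each domain (mean 0, sd 1, population sd) and
  sign-flipped so positive = mutation-sensitive.  A site is functional when
  it is sensitive (z ≥ 1.0) yet unimportant for stability (mean ΔΔG ≥ −0.5);
  both thresholds are configurable, and a nonpolar-only mode restricts the
  ΔΔG average to substitutions into {A,V,L,I,M,F,W,Y} to expose buried
  functional sites.
* **Census and design evaluation** — stabilizing mutations are ΔΔG strictly
  > 1 kcal/mol (entries censored at a bound count only when the bound itself
  exceeds the threshold), broken down by substitution polarity class,
  insertion and deletion.  Design evaluation is the paired ΔG difference
  after redesign with mean, sd and fraction > 1.
* **Cone contacts** — the number of mode-specific atoms (Cα for burial, Cβ
  for side-chain contacts, CE2 of F/Y/W, OE1/OD1 of Glu/Asp, NZ/NE of
  Lys/Arg) within 9 Å of the focal residue's Cβ and within a 60° half-angle
  of its Cα→Cβ axis (cos ≥ 0.5; the half-angle is a package default — only
  the 9 Å cone is canonical).  Gly gets an ideal-geometry virtual Cβ from N,
  Cα, C.

## The synthetic-data generator

`protstab.simulate` defines the study conditions every test runs under.
Libraries: per domain, a site × 20 ΔG landscape from a rank-2 factor model
(hydropathy and helix-propensity loadings, factor scale 0.9 kcal/mol) plus
Gaussian profile noise (sd 0.15 kcal/mol); wild types sampled from a known
classifier model (slope 3.2 log2/kcal ≈ 9.2-fold per kcal; offsets spanning
Glu +1.5 to Trp −3.5 log2, Val = 0); wild-type ΔG uniform on [1.5, 4.0];
substitutions read off the landscape, deletions and Gly/Ala insertions mildly
destabilizing.  True `K50_U` comes from known generating PSSMs (a0 = 0.6,
weight sd 0.15, giving K50,U ~ 0.02–0.1 μM so the usable ΔG window covers the
clip range) and true K50 from the two-state model; unfolded-state-resistant
variants keep folded-state cleavability at `K50_F`.  Experiments: Dirichlet
pre-selection fractions (concentration 50), survival at the standard
concentration grids, multinomial reads at configurable depth, optional hidden
per-condition concentration errors (for calibration tests) and an optional
per-domain protease-specific folded-state cleavage floor (for the filtering
tests; a floor shared by every sequence of a pool is exactly absorbed by the
multinomial normalizer, so contaminated domains are simulated as a minority of
a pooled library, as in the real experiment).  Amino-acid sequences are
encoded with one fixed codon per amino acid, since counting is exact-match.
All randomness flows from a single seed; identical seeds give identical
outputs.

What the generator does **not** emulate: real PDB-derived sequence
composition, PCR amplification and sequencing error, cDNA-display chemistry
yields, partial unfolding, aggregation, or kinetic (non-equilibrium)
stability.  Passing tests therefore demonstrate that the inference machinery
recovers the truth when the two-state single-turnover model holds and flags
the simulated violations it is designed to catch — not that the model is
correct for any particular real protein.

## Problem sizes

The acceptance computations use desk-scale versions of the study design:
K50 recovery on 500 sequences at 10⁶ reads/condition; the unfolded-state
model on 5,000 scrambles (the generator handles the study-scale 64,238 as
well); classifier recovery on 5,000 sites; the filtering study on 40 pooled
domain scans (~33,000 variants, 300 reads/variant/condition).  The headline
statistics of the full-scale experiment (median ΔΔG, PC1 variance share,
stabilizing-mutation count) are properties of the deposited dataset and are
computed by `scripts/acceptance.py` only when that table is present locally.

## Known limitations

Intervals are profile-likelihood based and ignore uncertainty in `K50_U`,
`K50_F` and protease concentrations, matching the confidence statements of the
measurement model itself.  The PSSM functional form is one concrete choice; a
structure-aware or supplementary-exact parameterization can be swapped behind
`CleavagePSSM`.  Group thresholds other than G1's 4.75 are package defaults,
not canonical constants.  The additive-pair bootstrap conditions on the
observed cell values.
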