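# Methods

This note documents the models and procedures implemented in `minspec`,
the choices made where several defensible options existed, and what the
synthetic-data generators do and do not emulate.

## Substitution model

Amino-acid evolution is modeled as a reversible continuous-time Markov
chain on the 20 canonical states (fixed package-wide ordering
`ARNDCQEGHILKMFPSTWYV`). The generator is assembled from a symmetric
exchangeability matrix *s* and stationary frequencies *π* as
Q<sub>ij</sub> = s<sub>ij</sub> π<sub>j</sub> (i ≠ j), diagonal set so rows
sum to zero, then globally rescaled so the expected substitution rate at
stationarity is 1 — branch lengths are therefore in expected
substitutions per site. The packaged exchangeabilities and frequencies
are the published Jones–Taylor–Thornton (JTT) values
(`src/minspec/data/jtt.json`, identical to the canonical `jones.dat`
table distributed with the major phylogenetics packages). Empirical (+F)
frequencies computed from the input alignment are supported and are the
CLI default, since receptor alignments depart noticeably from the JTT
average composition; frequencies below 1e-6 are floored and renormalized
so the chain stays irreducible on small alignments. Whether the original
analyses used +F from the edited or the full alignment is not knowable
from the published description; both are a model-configuration switch
here.

Among-site rate variation uses the discrete-gamma approximation: K
equal-probability categories of a mean-1 gamma distribution with shape
α. Category rates are the conditional means of the bins (computed from
the incomplete-gamma identity), which makes the rates average exactly 1;
bin medians are available via `method="median"` for comparison with
tools that use them. K = 8 mirrors the usual free-eight-category setting
for ancestral reconstruction; K = 4 is a cheaper default for simulation
studies.

Transition probabilities P(t) = exp(Qt) are computed by
eigendecomposition of the π-symmetrized generator
diag(π)<sup>1/2</sup> Q diag(π)<sup>−1/2</sup>, which is symmetric for
any reversible model and hence stably diagonalizable; the decomposition
is cached on the model object. Rows are clipped at zero and renormalized
only when floating-point drift exceeds 1e-12.

## Likelihood and optimization

Site likelihoods use Felsenstein pruning over column-compressed site
patterns with per-pattern log scaling to prevent underflow; the mixture
likelihood is the equal-weight average of the per-category likelihoods.
Gaps and unrecognized residue codes are missing data (an all-ones tip
partial). Likelihoods are invariant to root placement (pulley
principle), which the tests exercise directly.

Parameter estimation is coordinate ascent: a bounded Brent line search
over each branch length (bounds 1e-8 to 20 substitutions/site) and over
α in [0.05, 50], sweeping until the total log-likelihood improves by
less than 1e-6 (at most 30 sweeps; non-convergence sets an explicit flag
and warning). This is slower than Newton-style branch optimization but
simple and robust at the problem sizes the package targets.

## Branch support (aLRT)

Support for an internal edge is the approximate likelihood-ratio
statistic: the best of the three resolutions of the edge — the input
topology and its two nearest-neighbour interchanges, each with the five
local branch lengths re-optimized — against the second best,
aLR = L₁/L₂. The root is handled by re-rooting the working copy at the
focal edge's parent (likelihood-neutral under reversibility); an edge
attached to a bifurcating root is canonicalized through the root
trifurcation. The confidence value is the χ²₁ CDF at 2·ln(aLR) by
default; the ½χ²₀ + ½χ²₁ mixture is available by flag. The original
study's support values do not state which null was used, so neither
option is asserted as "the" original — both are provided.

## Marginal ancestral reconstruction

The per-site posterior at an internal node is the empirical-Bayes
marginal: proportional to F(a)·G(a), where F is the pruning partial
below the node and G the outside partial computed root-to-tip (G at the
root is π). The gamma mixture is marginalized, not conditioned: each
category contributes its normalized within-category posterior weighted
by the posterior probability of the category given the site data. The
MAP ("ML") sequence is the per-site argmax with alphabetical
tie-breaking (ties are warned about; at double precision they
essentially only occur in constructed examples).

Indel handling follows the averaging convention of ancestral
resurrection studies: states are reconstructed at every column, but
columns containing a gap in any row are excluded from mean-PP summaries
and reported separately. Site subsets (e.g. ligand-contacting positions)
are user-supplied index lists; no automatic contact detection is done.
Full parsimony-style indel reconstruction is out of scope.

## Uncertainty propagation

`sample_alternates` draws whole sequences site-independently from the
posterior rows — the same scheme used to generate alternate-ancestor
"clouds" for resurrection studies — and records, per sample, the joint
log-PP (sum of log marginal PPs), the count of differences from the MAP
sequence, and the joint-PP ratio against it. `top_k_alternates` keeps
the k highest-joint-PP unique non-MAP sequences (both uniqueness and MAP
exclusion are enforced, since a sampled cloud otherwise concentrates on
the MAP sequence) and reports the pairwise difference matrix.
`enumerate_alternates` provides the exact ranking for small state
spaces and is the oracle the sampling path is tested against. The
desk-scale default for sampling is 1e5 sequences; the procedure is the
same at 1e6, only slower.

`plausible_alternates` lists, per site, every non-MAP state with PP
strictly above the cutoff (default 0.20) whose pairing with the MAP
state is not one of the biochemically conservative pairs K/R, D/E, S/T,
I/L. The exclusion applies only to the alternate-vs-MAP comparison; two
alternates at one site may themselves form an excluded pair and both be
listed. The output is ordered but has set semantics.

## Dose–response analysis

Reporter normalization divides each well's firefly reading by its
Renilla reading and scales by the mean vehicle-control ratio, giving
fold activation with vehicle = 1. Agonist curves are fitted with the
four-parameter logistic in log10-dose,

    response(d) = basal + (max − basal) / (1 + 10^((log10 EC50 − log10 d)·hill)),

by least squares on log responses — a multiplicative (log-normal) error
assumption appropriate for luciferase ratios. Hill slopes are bounded to
[0.3, 5] in magnitude to prevent degenerate fits on 8-point grids. The
95% CI on EC50 is Wald on log10 EC50 with a t critical value at n − 4
degrees of freedom (comparable to standard curve-fitting software; the
exact variant and weighting used in the original Prism analyses are not
published, so these defaults are declared rather than asserted as
identical). A fit whose signal is indistinguishable from flat
(extra-sum-of-squares F test, α = 0.05) is flagged `no_activation` with
EC50 "not determined"; an EC50 beyond the top tested dose is annotated
as a censored bound rather than trusted as a point estimate. Inhibition
(IC50) uses the same machinery with a negative Hill slope under a
recorded fixed agonist concentration.

Fold preference between two ligands differing by one moiety is
EC50_b/EC50_a with a CI from summed log10-EC50 variances; when one
ligand never activates, the fold is reported as a one-sided
orders-of-magnitude bound. Recognition rules classify each moiety from
its matched pairs: all folds above 1 with the weakest pair at or above
the strong threshold (default 10-fold, chosen below the weakest
"orders-of-magnitude" criterion observed in practice, 21-fold) gives
"required"; the symmetric case gives "excluded" (rendered `[not …]`);
mixed signs are flagged inconsistent rather than averaged away.

## Structural comparison

PDB files are read through gemmi; alternate locations resolve to the
highest-occupancy conformer (ties toward altloc 'A'); waters and
heteroatoms are flagged, not dropped. Superposition pairs residues by
global BLOSUM62 alignment of the chain sequences (gapped positions
excluded), then computes the least-squares Kabsch rotation with
reflection correction over the selected atoms (default backbone N, CA,
C, O). By default all residues present in both chains enter the
comparison and the atom count used is reported, since published RMSD
figures rarely state the exact residue range.

Cavity volume is a grid method in the VOIDOO tradition: a point is
probe-accessible if its distance to every atom center is at least that
atom's van der Waals radius (Bondi values, default 1.70 Å) plus the
probe radius; accessible points reachable from the bounding-box exterior
by 6-connected flood fill are bulk solvent; the rest are cavity, and the
volume is the point count times spacing³. Hydrogens are ignored by
default (medium-resolution crystal structures lack them). The
conventional "probe 1.4 Å" figure is ambiguous between radius and
diameter; the default here is probe radius 1.4 Å (the standard water
radius), with 0.7 Å available when the figure is read as a diameter, and
reports always state the radius used.

## Synthetic data

`simulate_evolution` draws a per-site rate category uniformly, the root
sequence from π, and evolves states down each branch with the exact
transition matrices — so the recorded internal states are true draws
from the model, and reconstruction accuracy/calibration can be measured
exactly. It emulates the statistical structure of the inference problem,
not receptor biology: sites are independent, there are no indels, no
alignment error, no among-lineage composition shifts, and no model
misspecification. Passing recovery/calibration tests therefore validate
the inference machinery under its own assumptions; they do not certify
accuracy on real alignments, where model violations dominate.

`simulate_assay` generates triplicate dual-luciferase wells on the
standard 8-point 10⁻¹²–10⁻⁵ M grid: firefly = base × 4PL(dose) ×
log-normal noise (median-1, σ = √log(1+cv²)), Renilla = base ×
independent log-normal noise, vehicle wells at basal. The default cv of
0.1 (10%) reflects typical well-to-well variability in transfected
reporter assays. Plate effects, edge effects, and dose-preparation error
are not modeled.

Randomness is numpy `default_rng` throughout; `derive_seed(master, purpose)`
gives stable sub-2³¹ substreams so multi-stage runs are reproducible
end to end.

## Problem sizes used in the validation runs

The bundled validation (`scripts/acceptance.py` and the test suite) uses
sizes chosen to make the statistical checks sharp while keeping a full
run interactive: exhaustive-oracle comparisons on trees of 2–5 leaves
(the largest space that brute force enumerates exactly); recovery and
calibration on 16-leaf balanced trees with 0.05 substitutions/site per
branch, 1000 sites × 10 replicates (pooled binomial SE ≈ 0.2%); sampling
checks at 1e5 draws; EC50 CI coverage over 200 simulated assays; cavity
accuracy on a 1500-atom shell with an ≈ 493 Å³ analytic void at 0.5 Å
spacing. At these conditions measured values are: root-state recovery
≈ 94.8–95.0% (the MAP estimator's ceiling at these branch lengths under
JTT+Γ — within 3 pooled binomial SEs of 95%), accuracy ≥ 99% among
sites with PP ≥ 0.9 (the posterior is conservative there), CI coverage
≈ 95–97%, cavity error < 1%.

## Known limitations

- Branch-length optimization recomputes the full likelihood per
  evaluation; fine for tens of taxa, not for hundreds.
- The aLRT re-optimizes only the five local branches, the standard
  approximation; strongly misspecified distant branches could bias it.
- Wald CIs on log10 EC50 undercover when the plateau is not reached
  within the dose range; such fits are flagged censored instead.
- Two reference comparisons (deposited-structure RMSD, published
  ancestral sequence difference count) require third-party files that
  are not redistributed here; see `data/external/README.md`.
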