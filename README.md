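# minspec

Computational pipeline for studying the evolution of ligand specificity in
steroid hormone receptors by ancestral protein resurrection: maximum
likelihood ancestral sequence reconstruction with explicit uncertainty
propagation, quantitative dose–response analysis of receptor–ligand
specificity, and structural comparison utilities.

## Who this is for

Molecular evolution groups that resurrect ancestral proteins need three
computational stages around the wet lab: (1) inferring the ancestral
sequence and how confident each site is, (2) turning reporter-assay
readouts into ligand-recognition statements (EC50s, fold preferences,
recognition rules), and (3) comparing the resulting structures. `minspec`
implements all three as a tested library with a thin CLI, plus
synthetic-data generators with known ground truth so every stage can be
validated end to end.

## The models

**Reconstruction.** Protein evolution follows a reversible Markov model
with JTT exchangeabilities, stationary frequencies π (model or empirical
+F), and discrete-gamma rate variation (K equal-probability categories of
a mean-1 Gamma(α) distribution). Site likelihoods come from Felsenstein
pruning; branch lengths and α are estimated by coordinate ascent on a
fixed topology; branch support is the aLRT statistic with a χ²-based
confidence value. The marginal posterior of state *a* at internal node
*u* is the empirical-Bayes quantity

> P(a | data) ∝ Σ_k P(k | data) · F_u^k(a) · G_u^k(a)

with F/G the partial likelihoods below/above the node and k the rate
category. The "ML ancestor" is the per-site argmax; its mean posterior
probability (mean PP) is averaged over indel-free sites, overall and over
named site subsets such as ligand-contacting positions.

**Uncertainty propagation.** Alternate ancestors are sampled from the
per-site posteriors, ranked by joint PP (product of per-site marginal
PPs), and compared to the ML sequence by joint-PP ratio and difference
count; a worklist of "plausible alternates" lists every non-ML state with
PP > 0.20 that is not a conservative K/R, D/E, S/T, or I/L exchange with
the ML state.

**Dose–response.** Dual-luciferase wells are normalized to fold
activation over vehicle; agonist and inhibition curves are fitted with
the four-parameter logistic in log10-dose (EC50/IC50, Hill slope,
plateaus, Wald 95% CI on log10 EC50); matched ligand pairs give fold
preferences (EC50 ratios with propagated CIs, censored bounds when one
ligand never activates), from which moiety-level recognition rules are
classified ("required", "excluded/not", weak, or inconsistent).

**Structures.** PDB reading (gemmi), Kabsch backbone superposition RMSD
over sequence-aligned residues, and probe-accessible internal cavity
volume on a grid with exterior flood fill.

See `docs/methods.md` for assumptions, defaults, and numerical choices.

## Worked example

Simulate sequence evolution on a balanced 8-taxon tree, then reconstruct
the root ancestor:

```sh
minspec simulate evolution --n-leaves 8 --n-sites 200 --seed 3 \
    --fasta-out a.fasta --tree-out t.nwk
minspec reconstruct --alignment a.fasta --tree t.nwk --node n1 \
    --gamma-categories 2 --no-optimize
```

```json
{
  "node": "n1",
  "mean_pp_all": 0.94682083426268,
  "mean_pp_subsets": {},
  "n_indel_sites": 0,
  "sequence": "ILSGALDPGG..."
}
```

`mean_pp_all` ≈ 0.95 says the root state is, on average, strongly
determined at these branch lengths (0.05 substitutions/site); the
per-site table (`--posterior-out`) shows which sites are ambiguous and
feeds the alternate-ancestor tools.

Simulate a triplicate luciferase assay (true EC50 = 1 nM, 5% noise) and
fit it:

```sh
minspec simulate assay --ec50 1e-9 --cv 0.05 --seed 2 --out assay.tsv
minspec doseresponse --assays assay.tsv
```

```json
{
  "receptor": "receptor",
  "ligand": "ligand",
  "ec50_M": 1.0834334813816897e-09,
  "ec50_ci_M": [8.305346961926978e-10, 1.4133402420872497e-09],
  "hill": 0.9682975859434187,
  "fold_activation_max": 9.957715010038982,
  "no_activation": false
}
```

The fitted EC50 (1.08 nM) sits on top of the true value with the 95% CI
spanning 0.83–1.41 nM — the kind of precision a triplicate 8-point dose
series supports at this noise level.

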