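# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `geneshop`.

## The winnowing procedure

A gene is characterized by three statistics.

**Concordance.** Both the rooted gene tree and the species tree are
restricted to their shared taxa (at least 4 required); each tree is then
reduced to its set of nontrivial unrooted bipartitions, canonicalized so a
split equals its complement. The reported proportion is
`|gene ∩ species| / |gene|` — the gene tree's splits found in the species
tree. Dividing by the gene tree's split count keeps the score well-defined
for genes with missing taxa; the species-tree denominator is available via
`concordance_proportion(..., denominator="species")`. A gene tree with no
nontrivial splits on the shared set (a star) scores 1.0: it contradicts
nothing. Polytomies are allowed in either tree; only resolved edges
generate splits.

**Root-to-tip variance.** The sample variance (n−1 denominator) of the
root-to-tip path lengths of the rooted phylogram. The estimator choice is
immaterial for ranking (it is a monotone transformation shared by all
genes) but is fixed and documented so absolute values are comparable
across runs. Variance 0 is equivalent to ultrametricity; the default
ultrametricity tolerance is a relative 1e-9 and is configurable.

**Tree length.** The sum of branch lengths, in expected substitutions per
site.

`compute_gene_stats` evaluates the three criteria in a fixed order: root
the gene tree on the outgroup (the root is placed at the midpoint of the
separating edge, conserving total tree length), score concordance on the
full rooted tree, then prune the outgroup and measure variance and tree
length on the ingroup. Concordance is computed before outgroup removal,
the clock statistics after, because only the clock statistics are defined
relative to the ingroup. Pruning keeps surviving root-to-tip paths intact
(suppressed degree-2 nodes have their branch lengths summed; a degree-1
root keeps its stem); the statistics then drop the root stem explicitly,
because its length depends on the arbitrary midpoint placement of the
root. The stem never affects the variance — it shifts every path by the
same constant — but it would contaminate tree length.

Ranking is a stable lexicographic sort, by default concordance
(descending), then variance (ascending), then tree length (descending),
with a final gene-id tie-break so output is bit-reproducible regardless of
input order. Hard thresholds are off by default: the package produces a
ranked list and the analyst chooses *n* by inspecting it. Whether the
reported tree length should include the outgroup subtree is a genuinely
open convention; this implementation excludes it (statistics are computed
post-pruning) and the choice is visible in this note and in the tests.

## Likelihood engine

The engine implements Felsenstein's pruning algorithm on a fixed rooted
topology under equal-exchangeability models: Jukes–Cantor for nucleotides
and its 20-state analog (Poisson, uniform frequencies and exchange rates)
for amino acids. With k states and the rate matrix normalized to one
expected substitution per unit branch length, the transition probabilities
have the closed form

    P_ij(t) = 1/k + (δ_ij − 1/k) e^(−βt),   β = k/(k−1),

so propagating a partial-likelihood matrix across a branch is O(sites × k)
and no matrix exponentials are needed. Gaps and ambiguity codes are
missing data (partial likelihood 1 in every state). Site patterns are
compressed up to state relabeling — for these fully symmetric models a
site's likelihood depends only on which taxa share states — which
typically shrinks a nucleotide alignment's pattern count severalfold.

These two models are deliberately the only ones provided. The winnowing
logic is model-agnostic, all validation experiments use matched
simulation/inference models, and restricting to the symmetric family keeps
the engine exactly testable against closed forms and state enumeration.
Empirical-matrix amino-acid models (WAG and relatives) and among-site rate
variation are noted as extension points; neither is used anywhere in the
package's experiments.

**Free branch lengths.** Monotone coordinate ascent: a depth-first sweep
visits every edge with inside/outside partials kept consistent with the
current lengths, and each edge is solved *exactly* — substituting
x = e^(−βt) makes the single-edge log-likelihood concave in x, and
safeguarded Newton on its derivative finds the optimum in a handful of
O(sites) operations. Because coordinate ascent on correlated adjacent
branches has a geometric convergence tail, each sweep is followed by an
extrapolation step along the sweep displacement (step doubling while the
likelihood improves). Convergence is declared when a sweep gains less than
`tol` (default 1e-6) log-likelihood units; branch lengths are bounded to
[1e-8, 20].

**Clock constraint.** The clock model is parameterized by the heights of
the internal nodes (tips at height 0), giving n−1 parameters for n taxa.
Coordinate ascent optimizes one height at a time by bounded Brent search
between the highest child and the parent — branch lengths can therefore
never go negative — with the same extrapolation acceleration, a minimum of
three full sweeps, and convergence at ΔlnL < tol. Initial heights are
taken from the input tree (each node at the top of its subtree). The root
height is capped at five times its initial value: once sequences approach
stationarity the likelihood becomes flat (and very slightly increasing) in
the root age, so on saturated data the unconstrained ML root diverges and
every normalized node age collapses toward zero. Bayesian daters prevent
this with the tree prior and penalized-likelihood daters with
calibrations; the cap is this ML engine's equivalent, generous enough to
be inactive whenever the root is actually identified by the data.

**Clock LRT.** With lnL from both optimizations, the statistic
2(lnL_free − lnL_clock) is referred to χ² with df = n − 2, from the
parameter counts 2n−3 (free, unrooted) versus n−1 (clock). The statistic
is clamped at 0 when optimizer noise makes it marginally negative (a
warning is raised beyond −0.05 lnL units). The default α is 0.05,
configurable. Outgroups are expected to be pruned before testing.

**Joint strict-clock dating.** For several genes on one fixed topology,
all genes share a single set of node heights while each gene g carries a
relative-rate multiplier r_g (r_0 ≡ 1); gene g's branch lengths are
r_g × (h_parent − h_child). The fit alternates exact 1-D rate updates with
joint height sweeps (each height optimized against the summed per-gene
likelihood), seeded by a single-clock fit to the concatenated matrix, and
the result is normalized to root height 1 — only relative ages are
identified without calibrations, so the normalization loses nothing.

## Simulators

**Yule chronograms.** Pure-birth simulation starting from two lineages:
with j extant lineages the waiting time to the next split is
Exp(j·λ) and the splitting lineage is uniform; the process stops at the
n-th birth and the root height excludes any origin stem. The expected
root height is Σ_{j=2}^{n−1} 1/(jλ) (≈ 2.0199 for n = 12, λ = 1), which
the tests verify by simulation. `rescale_height` multiplies all branches
to hit a target height exactly.

**Branch rates.** A `RateDecoration` maps a chronogram to a phylogram by
multiplying each branch by a rate: *strict* (one global rate), *noisy
clock* (global rate plus a zero-mean Gaussian per branch; negative draws
are redrawn until positive, since with noise_sd 0.75 around rate 1.0
negative rates are otherwise possible — the truncation policy is this
package's choice and slightly raises the realized mean rate), and *UCLN*
(i.i.d. lognormal per branch, parameters being the mean and standard
deviation of the log rate). Rates are drawn in a deterministic preorder so
a decoration seed fully determines the phylogram. In multi-gene pools
every gene gets fresh draws on the shared chronogram.

**Sequences.** The root sequence is drawn from the stationary (uniform)
frequencies and evolved down each branch with the closed-form transition
probabilities (a site keeps its state with probability p_same(t),
otherwise moves uniformly to one of the other k−1 states). Output is
substitution-only and gap-free; indels, rate heterogeneity across sites
and base-composition bias are deliberately not modeled, so the simulated
data are *easier* than real data — passing tests demonstrate correctness
of the machinery and the qualitative behavior of the winnowing criteria,
not robustness to alignment error or compositional effects.

## Validation experiments and problem sizes

All experiments are seed-deterministic and echo their full configuration.

* **Clock-test calibration**: an 11-taxon Yule tree rescaled to height
  0.5; 500 amino-acid genes of 500 residues simulated under a strict
  clock; clock LRT with the matched Poisson model at α = 0.05. The
  empirical false-rejection rate lands near the nominal level (slightly
  conservative; bounded-optimization tolerance pushes the statistic down,
  never up).
* **Heterogeneity landscape**: (tree length, root-to-tip variance) per
  gene for clock / noisy / UCLN pools; mean variance increases
  monotonically in noise_sd over {0, 0.25, 0.75} and in stdev_log over
  {0.5, 1.0}.
* **Shopped vs random**: 50 trials; per trial one 12-taxon Yule
  chronogram (λ = 1) and a pool of 200 genes of 1500 nt under JC, each
  gene with an overall rate drawn lognormal(0, 0.5) and a clock noise
  level drawn uniformly from {0, 0.1, 0.25, 0.5, 0.75} (noise scaled by
  the gene's rate so "degree of unclock-likeness" is comparable across
  slow and fast genes); per-gene phylograms re-estimated by ML on the true
  rooted topology; three shopped genes versus three random genes, each set
  dated by joint strict-clock ML; error is the cumulative absolute
  node-age difference from the truth after normalizing both trees to root
  height 1. The pool of 200 genes (rather than 1000) and the per-gene
  estimation tolerance (1e-2, eight sweeps) are throughput choices; both
  arms use the identical estimator, so the comparison is unbiased. The
  null configuration removes *all* heterogeneity (noise 0 and a common
  rate), making the pool exchangeable, and is run at 20 trials with a
  60-gene pool — ample to confirm indistinguishability at the p > 0.01
  level. Keeping rate heterogeneity while setting noise to 0 is *not* a
  null for this procedure: unrescaled Yule chronograms put the deepest
  divergences near saturation at JC rate ~1, the ML root age of a
  saturated gene set is pinned only by the regularization cap, and the
  variance criterion systematically steers selection away from such
  high-rate genes — so shopped sets date measurably better than random
  ones even with zero clock noise.

## Numerical choices and degenerate inputs

* Branch-length bounds [1e-8, 20] substitutions/site; height updates keep
  parent−child gaps ≥ 1e-9.
* Partial likelihoods are not rescaled per node; for the tree sizes this
  package targets (tens of taxa) double precision has ample headroom.
  Hundreds of taxa would require adding per-node scaling.
* A constant alignment drives all ML branch lengths to the lower bound
  (effectively 0) and the likelihood to L·log(1/k).
* Trees with < 4 taxa have no nontrivial splits (empty set, not an
  error); concordance requires ≥ 4 shared taxa and raises otherwise.
* Pruning to fewer than 3 tips, re-rooting on a non-separable outgroup,
  and taxon mismatches between tree and alignment raise typed errors that
  the pipeline reports per gene without aborting the run.
* Newick output uses `repr`-shortest float formatting, so
  parse → write → parse is byte-stable.

## Known limitations

* No Bayesian machinery: relaxed-clock posteriors and HPD intervals are
  out of scope; dating is ML point estimation under a strict clock, so
  only the point-estimate comparisons of the validation studies are
  reproduced.
* The likelihood engine covers only the symmetric model family (JC /
  Poisson); no GTR, empirical amino-acid matrices, or Γ rate variation.
* Gene-tree *topology* estimation is out of scope; experiments re-estimate
  branch lengths on the known topology, which isolates rate heterogeneity
  (the quantity the winnowing criteria act on) from topological error.
* The root is placed at the midpoint of the outgroup edge; other rooting
  conventions shift root-to-tip paths by a constant but leave the variance
  and ranking unchanged.
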