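# Methods

This note records the models, numerical choices and study conditions
behind `chronoscreen`, including the points where the design was
genuinely open and the package had to commit to one reading.

## Penalized-likelihood dating

**Model.** The phylogram's branch lengths are treated as expected
substitution counts x_j = b_j·L (L = alignment length), kept
real-valued rather than rounded: ML branch lengths are estimates, not
observed counts, and the Poisson term generalises smoothly via
x·log μ − μ. The objective maximised is

F(r, a) = Σ_j [x_j·log(r_j t_j) − r_j t_j] − λ·Φ(r),

where r_j is the count-scale rate of branch j (expected substitutions
across the alignment per MY), t_j its duration under node ages a, and
Φ the smoothness penalty: Σ over non-root branches of
(r_j − r_parent(j))² plus the variance of the root's immediate
descendant rates. Chronograms report per-site rates r_j/L.

**Identifiability and the root ceiling.** The likelihood depends on
rates and times only through their products, so a joint rescaling
(ages ×c, rates ÷c) leaves it unchanged while the penalty falls as
1/c²: with only a min/max constraint on one node, the objective is
monotone in a global stretch and the problem needs a ceiling. The
package therefore (a) refuses constraint sets without at least one
node carrying both a finite minimum and maximum, and (b) caps an
otherwise-unconstrained root at 10× the largest finite calibration
bound. The cap is the analogue of the root maximum every practical
dating run supplies; it binds exactly in the runs where the
calibrated node is too shallow to anchor the time scale, which is
also the class of run the downstream interquartile screen is designed
to flag.

**Optimisation.** Joint SLSQP over internal node ages and log rates:
ages are rescaled into units of the largest calibration bound and the
objective divided by the total expected count so both are O(1);
parent-older-than-child is a set of linear inequality constraints and
calibration bounds become per-node boxes after folding minima up and
maxima down the topology (infeasibility is detected there, before any
optimisation). Durations that graze zero are handled by a linear
extension of the log so trial points return finite values with
inward-pointing gradients. Defaults: λ = 1.0, ftol 1e-12, ≤2000
iterations, 5 restarts from jittered feasible initialisations
(deterministic per seed); solutions are projected exactly onto the
constraint set afterwards. The returned metadata records λ, seed,
objective, and convergence; non-convergence is flagged, never silent.

**Smoothing-weight cross-validation.** The smoothing value used in
the original analyses is not recorded anywhere, so the package makes
λ explicit and optionally data-driven: for each candidate λ, each
terminal branch's count is dropped from the likelihood and refit; the
penalty then pulls the orphaned branch's rate toward its neighbours,
so r̂·t̂ is the model's prediction for the held-out count, scored as
Σ (x − μ̂)²/μ̂. Score differences below ~1 sit under the Poisson noise
floor of this chi-square-style statistic and are treated as ties;
ties resolve to the larger (smoother) λ.

## The screening stage

One penalized-likelihood run per node-assigned fossil, constraining
the assigned node with the fossil's resolved minimum *and* maximum
(the two-sided constraint is what makes a single-fossil run
identifiable). Three reference divergences at distinct time frames
are monitored; quartiles (linear interpolation between order
statistics, the rule recorded in output metadata; Tukey hinges
available) are computed once per reference node over all successful
runs, and a fossil is excluded iff its run falls strictly outside
[Q1, Q3] at one or more reference nodes — boundary values survive,
reading "outside the interquartile region" literally. Culling is a
single pass; failed runs are excluded from quartile computation and
flagged, never counted as survivors. The node-support filter (drop
fossils at nodes with three or fewer survivors) runs *after* the IQR
cull, matching the stated order of the procedure. Selected
calibrations are per-node maxima over the survivors' minimum ages,
emitted as min-age constraints. Per-fossil seeds derive from the
record id, so permuting the input order changes nothing. Any
expected-age intervals attached to the reference nodes are echoed
into the report for context only; a test asserts they cannot affect
survivor flags.

## Bayesian node dating

A deliberately minimal Metropolis–Hastings sampler over node ages and
branch rates:

* **Likelihood** — the same generalized-Poisson branch-count model as
  the PL stage (an exact alignment likelihood is out of scope); this
  keeps the two dating stages internally consistent.
* **Rates** — i.i.d. lognormal per branch. The mean is fixed (default
  0.290696 substitutions/site per time unit); the log-scale spread
  defaults to 0.5 since no value is recorded for the original
  analysis. One internal time unit is 100 MY — the only reading under
  which a mean rate of ~0.29 coexists with node ages in the low
  hundreds of MYA — and all I/O is in MYA.
* **Age prior** — root uniform between its effective lower bound and
  the hard root maximum (default 334 MYA); every other internal node,
  visited root-down, uniform between its effective lower bound and
  its parent's age. Calibration minima and the root maximum are hard:
  proposals violating them are rejected, so no sampled state ever
  breaks a bound. A constructive sampler for this same prior provides
  the independent reference in prior-recovery tests.
* **Moves** — per-node age slides in the local feasibility window;
  per-branch log-rate slides; a whole-tree age scaling; and two
  likelihood-invariant moves that fix the slow directions: a global
  (ages ×c, rates ÷c) ridge move, and a local transform that slides
  one node's age while rescaling its three adjacent branch rates to
  hold every expected count fixed (Jacobian Π t_old/t_new). Step
  sizes adapt toward ~30% acceptance during burn-in only, so the
  post-burn-in kernel is fixed and chains are bit-reproducible given
  the seed. Acceptance rates outside [0.05, 0.8] are warned about in
  chain metadata.
* **Summaries** — burn-in removal, thinning, per-node mean/median/95%
  interval, ESS (via arviz; nodes under 100 flagged, not fatal), and
  per-node median deltas across replicate chains — the convergence
  criterion is agreement between independent seeds.

Defaults follow the reference protocol: 500,000 generations (one
generation = one full update sweep), sampling every 50, burn-in
50,000, two replicates.

## Synthetic data

The generator emulates the statistical structure the screen assumes:

* **Tree** — forward birth–death simulation (defaults 0.04 / 0.015
  per lineage per MY) conditioned on the tip count by rejection,
  pruned to extant lineages and rescaled to a 200 MYA root; default
  16 tips, a family-level tree at desk scale.
* **Branch data** — strict clock by default at 0.0029
  substitutions/site/MY (a slow mitochondrial-gene rate; an
  independent-lognormal clock with configurable log-sd is available);
  observed lengths are Poisson(r·t·L)/L at L = 1044 sites, or exact
  when L = ∞.
* **Fossils** — 100 records; each attaches to a family-level
  divergence, i.e. an internal node at ≥25% of root age (fossils
  classifiable to family pin deep splits; a coarse 5–15 MY age range
  carries no information about a cherry-age node, and no real
  registry would place one there). Informative records draw their
  minimum age uniformly on (0.5, 1.0)× the node's true age with a
  stage-level width of 5–15 MY; a planted 20% are misleading, with
  ages scaled 2×. Ground-truth labels (which records are misleading,
  true node ages) are written to a separate truth table, never into
  the registry.
* **Monitored references** — the internal nodes nearest 10%, 40% and
  100% of root age: divergences at distinct time frames whose ages
  the data can actually resolve. A node whose subtending branches
  expect less than a handful of substitutions has an unidentifiable
  age and would only add noise to the screen.

What passing tests on this generator do *not* show: robustness to
tree-topology error, to systematically biased (not just inflated)
fossil ages, to non-Poisson rate variation across sites, or to
registry taxonomy errors beyond the planted-age mechanism.

## Geologic time scale

Published conversions of stage names to MYA differ between time-scale
editions, and the edition behind any given registry is often
unstated. The package bundles one explicit table (standard
international chart values, stages through periods, version label
`chronoscreen-builtin-1`, echoed into load metadata) and accepts a
user-supplied replacement with the same columns. Unit matching is
case-insensitive with whitespace normalisation; hyphen and en-dash
both delimit spans, which resolve to the union of the named
intervals; explicit "X–Y MYA" strings pass through. Unresolvable ages
quarantine the record (flagged, excluded downstream, never silently
dropped) rather than failing the whole load.

## Biogeographic binning

Default bins: Neogene-to-recent (0–23.03), Paleogene (23.03–66), Late
Cretaceous (66–100) MYA; edges half-open [min, max) so a boundary age
belongs to the older bin it opens. A record contributes to every bin
its age interval overlaps (coarse fossil ranges frequently straddle
epoch boundaries; a midpoint single-assignment mode is available and
recorded in metadata). Filtering (age > 100 MYA, no family, suspect
ids) commutes with binning; per-cell record-id audit lists make every
count traceable.

## Problem sizes in tests and the acceptance script

Checks run at desk scale, sized to finish in minutes on one CPU: the
optimiser-vs-oracle battery uses 64 random 4-taxon problems (staged
30×30 grid over the two free ages, rates profiled out by exact
coordinate ascent); strict-clock recovery a 12-tip noiseless dataset;
screening power 20 replicate registries of 100 fossils on 12-tip
trees; MCMC checks 6–8-tip trees, with replicate-convergence at the
default 500,000 generations (the agreement criterion is a
Monte-Carlo-error statement, and shorter chains cannot pin wide
posterior medians to 2%) and interval coverage over 20 replicates of
25,000 generations. The replicate-convergence dataset includes one
two-sided calibration: convergence is checked on a well-identified
posterior, while the coverage check runs in the min-only setting the
pipeline itself produces.

## Known limitations

* The PL stage optimises a generalized-Poisson surrogate, not a full
  alignment likelihood; absolute objective values are not comparable
  across alignment lengths.
* The MCMC stage is a minimal sampler: no approximate-likelihood
  Hessian pipeline, no birth–death-with-fossils priors, no
  autocorrelated rates, no soft calibration bounds by default.
* Family→node assignment ships as an editable example mapping;
  stem-vs-crown placement per family is the user's call, and the
  bundled rules must be confirmed against the user's own tree.
* The 10× root ceiling in per-fossil runs is a pragmatic bound;
  screens whose fossils are all far too shallow to anchor the time
  scale will see it bind often and should supply an explicit root
  constraint instead.
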