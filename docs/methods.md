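# Methods

## The estimand and the estimators

The package targets *realized heritability*: the narrow-sense heritability
implied by the response an experiment actually achieved, estimated as the
slope of the cumulative response–differential regression.  Three
conventions, each recorded in every run manifest, pin the estimator down:

- **Progeny weighting.**  The differential `S = Σ (dᵢ − μ) pᵢ` weights each
  selected parent by its share of measured progeny.  Each measured progeny
  credits *both* of its parents, and `pᵢ` is normalized over the parent set
  so `Σpᵢ = 1`, as the weighted-sum form requires.  Raw counts are retained
  on the `SelectionRecord` for audit.  (Crediting half a progeny to each
  parent gives identical weights whenever all counts are scaled equally.)
- **Pairing.**  The response measured at generation g is paired with the
  cumulative |S| of the selection rounds applied before g (parent
  generations 0..g−1).  A four-generation experiment therefore yields four
  regression points per line × replicate.
- **Sign handling and intercept.**  Bottom-line responses are negative
  while cumulative |S| is positive, so they are negated by default
  (switchable) to put both directions on a positive-slope scale.  The
  regression includes a free intercept by default; a through-origin variant
  and an explicit (0, 0) point are one flag away.  With only four points
  the intercept costs precision but avoids forcing the fit through a point
  the experiment never observed.

Control adjustment always subtracts the same replicate's control-line mean
in the same generation, which removes environmental trends shared within a
replicate but adds the control mean's sampling noise to every response.

Plants measured more than once (e.g. two flowers) are collapsed to their
mean before any pooling.

## Relatedness and mate allocation

The additive relationship matrix is built by the tabular method with
founders assumed unrelated and non-inbred — the only defensible base
population when no deeper pedigree exists.  Any individual referenced as a
parent but absent as a row is inserted as a founder with a logged warning,
which tolerates hand-built cross sheets.  Accepted missing-parent tokens on
read are `0`, empty, and `NA`; `0` is written.

The cross designer searches for a simple k-regular graph on the selected
parents (complete graph when k equals parents−1) minimizing the *mean*
additive relationship over assigned pairs.  Mean rather than sum keeps the
objective comparable across plan sizes; sum and max are available.  The
search is pure seeded repeat-and-pick — construct a random feasible plan,
score it, keep the best — optionally refined by strictly-improving two-edge
exchanges (`swaps > 0`).  Feasibility edge cases: parents × k odd leaves
exactly one parent one cross short; k > parents−1 is an error naming the
maximum.  Pairs are unordered (pollen/ovule roles are not distinguished)
and duplicate pairs are disallowed by default, matching a design in which
each plant is crossed with up to k *other* plants.  The number of restarts
is an effort knob: on exhaustively searchable instances (≤ 6 parents,
k ≤ 2) the default 100 restarts reach the global optimum essentially
always; production-scale plans use more.

## The simulator

The generator implements the additive infinitesimal model — the minimal
model under which realized heritability is the estimand:

- founder breeding values `A ~ N(0, h²σ²_P)`; environment
  `E ~ N(0, (1−h²)σ²_P)`; phenotype `= mean + g·trend + A + E`;
- offspring breeding value = midparent + Mendelian deviation
  `~ N(0, ½h²σ²_P(1 − F̄))`, where `F̄` is the parents' mean inbreeding
  coefficient (toggleable off).  Kinship among each generation's selected
  parents is propagated recursively — exactly the quantity the numerator
  relationship matrix would give, computed on small matrices so thousands
  of Monte-Carlo experiments stay cheap;
- generation 0 is one founder pool per replicate from which the top,
  bottom and control 10% are drawn disjointly (the control from the
  remaining 80%), so no plant parents two lines; later generations select
  within line.  Ties at the truncation threshold break by seeded jitter;
- mates are assigned by the minimum-kinship designer; progeny per cross are
  multinomial with symmetric-Dirichlet weights whose concentration is
  `1/dispersion` (dispersion 0 degenerates to equal contributions) — the
  weighted differential exists precisely to correct such inequality, so the
  generator must produce it;
- replicates run on independent streams spawned from the master seed; two
  runs with the same seed are byte-identical.

Defaults mirror the emulated design: 500 plants per line per generation,
10% truncation, 10 crosses per parent, 4 generations, 2 replicates, trait
mean 11.5 mm.  The phenotypic SD of 1.9 mm follows from the design's
generation-0 standard error (0.06 mm over ~925 families).  The
environmental trend has no published magnitude; the default −0.1 mm per
generation produces the qualitative control-line decline without dominating
the selection signal.  Missingness ("plants that never flowered") defaults
to 0 because no rate is published.

The final-generation module draws four correlated floral size traits
(flower diameter, petal height, anther height, stigma height) per plant
from a group-specific multivariate normal centered on the group's simulated
diameter mean; the default covariance uses SDs 1.9/1.5/1.2/1.2 mm and a
common correlation of 0.6, with a helper to strengthen correlations in
chosen groups.

**What the simulator does not emulate:** genetic architecture beyond the
infinitesimal limit (no loci, no dominance or epistasis, hence no inbreeding
depression — the vigor decline such experiments show in bottom lines will
not appear), non-random flowering failure, measurement error distinct from
environmental deviation, and selection acting on the final-generation traits
other than diameter.  Passing recovery tests therefore show the estimator
chain is correct under the stated model, not that real data meet the model.

## Numerical and statistical choices

- **Recovery bias.**  Under four generations of 10% truncation the
  between-family additive variance shrinks (Bulmer effect) and inbreeding
  accumulates, so the realized slope sits a few points below the base-population
  h²: simulated experiments with true h² = 0.25 average ≈ 0.21–0.22.  This
  is a property of the estimand, not an estimator defect, and is inside the
  ±0.05 band the recovery checks use.
- **Box's M** uses the χ² approximation (`statistic = M·c`,
  `df = (k−1)p(p+1)/2`) with n−1 covariance denominators so the `(nⱼ−1)`
  weights are consistent; the F approximation is out of scope.  Singular
  group covariances and nⱼ ≤ p are rejected naming the group.  The test is
  exact in its degrees of freedom and approximate in its null: simulated
  type-I error at α = 0.05 with p = 4, k = 6, nⱼ = 50 lands near nominal.
- **Benjamini–Hochberg** delegates to statsmodels' step-up implementation.
  Note the adjustment is *not* idempotent in general: adjusted values are
  elementwise ≥ raw, so re-adjusting an adjusted family inflates any
  non-flat tail again.  Only the dominance, monotonicity and
  permutation-equivariance properties are stable.
- **OLS** fits use statsmodels; with two points the slope SE is reported as
  NaN (saturated fit) rather than a spurious number.
- Monte-Carlo problem sizes in the tests and acceptance script — 200
  experiments at 200 plants per line, 1000 homogeneity replicates at 50 per
  group — were chosen as the smallest sizes at which the Monte-Carlo error
  is comfortably inside each check's band.

## Known limitations

- Realized-heritability standard errors are per-regression only; no
  bootstrap across the experiment hierarchy.
- No BLUP/animal-model estimation and no marker-based relatedness; the
  pedigree is the only source of relationship information.
- The cross designer is a heuristic; it is exhaustively verified only on
  small instances, and makes no optimal-contribution trade-off between gain
  and inbreeding.
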