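# Methods

## Model and assumptions

The package operates on a normalized, log2-scale expression matrix (genes or
probes × samples) with no missing values; probe-level preprocessing (e.g.
RMA) is assumed done upstream. Samples are grouped into populations and each
population is mapped to exactly one class of an `is_a` ontology; several
populations may share one class (the same cell type sampled from different
anatomical sites, or distinguished by intermediate marker levels). The core
assumption is that class membership implies consistent expression: a gene
belongs to the signature of class x (relative to reference y) only if it
passes the differential-expression thresholds in *every* comparison between
a population under x and a population under y that is not under x. This
makes signatures deliberately conservative — a single discordant population
removes a gene from all ancestor signatures that include it (the behaviour
the spoiler test exercises), and adding populations can only shrink or
preserve a signature.

## Differential expression

Each ordered pair is a two-group contrast per gene. Residual variances
s²_g on d_g = nᵢ + nⱼ − 2 df are moderated toward a prior (d₀, s₀²) under
the hierarchical model s²_g ~ s₀²·F(d_g, d₀). The prior is estimated by
method of moments on z_g = log s²_g: with
e_g = z_g − ψ(d_g/2) + log(d_g/2),

- Var(e) − ψ′(d_g/2) = ψ′(d₀/2)  (solved for d₀ by Newton inversion of the
  trigamma function, mirroring the standard clamps for very large/small
  arguments),
- mean(e) = log s₀² − ψ(d₀/2) + log(d₀/2).

If the moment estimate of d₀ is non-finite or the excess variance is ≤ 0,
d₀ = ∞ (full pooling of the variance). Zero-variance genes are excluded from
the moment fit; when the moderated variance itself is zero (noiseless data),
t is reported as sign(log2FC)·∞ with p = 0 (p = 1 when the fold change is
also zero) and flagged. p-values are two-sided from t on d₀ + d_g df and
BH-adjusted within each comparison (not globally across comparisons). The
implementation agrees with limma's `lmFit`/`eBayes` on shared fixtures to
~1e-6 relative; that agreement is a cross-check in the test suite, not a
dependency.

Thresholds are strict everywhere: a gene is "up" iff its linear fold change
exceeds 1.5 (default) *and* adjusted p < 0.05. Both are configuration
values. Optional conveniences — probe→gene collapse keeping the
highest-mean row, and column quantile normalization — are provided but not
part of the default pipeline.

## Comparison ontology

n populations produce n·(n−1) comparison classes (both orders are kept,
since up and down sets are distinct objects). Ids are assigned
deterministically by sorted (up-population, down-population) order starting
at `GS:0000002`; `GS:0000001` is the comparisons hub under a second root
`GS:0000000` ("Gene-sets"). Each comparison class is `is_a` the hub and
nothing else, and carries exactly one `has_up_regulated_genes_for` and one
`has_down_regulated_genes_for` relation; the shorter relation spellings
(`has_up_regulated_genes`/`has_down_regulated_genes`) are accepted as read
aliases. Builds are byte-deterministic: identical inputs give identical OBO
and GMT output.

OBO has no payload tag for gene lists, so gene contents live in a GMT
sidecar (one up row and one down row per class; description
`up|down <up_class> vs <down_class>`; members are `gene|log2FC` tokens with
full-precision floats). The population pair is recorded in the comparison
term's `name` tag as `<up_pop> vs <down_pop>`, which is why population
labels may not contain the literal token `" vs "`; this keeps the sidecar
format exactly as specified while still allowing a complete reload of the
object from its two artifacts.

The OBO reader/writer supports the minimal tag set (id, name, is_a,
relationship, is_obsolete, xref, def); unknown tags inside `[Term]` stanzas
and non-Term stanzas are preserved verbatim, so parse→write round-trips are
lossless and the writer is deterministic (terms sorted by id, fixed tag
order). `is_a` acyclicity is enforced at load; cycles among non-`is_a`
relations are allowed since they carry no subsumption meaning. Closure
traverses only explicitly named relations (default `{is_a}`), so the
comparison relations can never leak into subsumption queries. Obsolete
terms contribute no outgoing edges to closure.

## Queries

For direction `up`, the three-constraint query keeps comparisons whose
up-side class is a reflexive descendant of the focus x, whose down-side
class is a reflexive descendant of the reference y, and whose down-side
class is not a reflexive descendant of x. Direction `down` swaps the roles
of the two relations; signature fold changes are always reported from the
focus class's perspective, so down signatures carry negative means. In
strict mode y must be a proper `is_a` ancestor of x; `ad_hoc` mode lifts
that for exploratory contrasts. Results are ordered by GS id.

Signatures intersect the gene memberships of all returned sets and report
per-gene mean and population standard deviation (ddof 0) of log2 fold
change, ranked by |mean| descending with lexicographic gene-id tie-break.
Ranking is on the log2 scale; the linear mean fold is also reported in the
TSV output. A query matching zero comparison classes yields an empty
signature flagged `no_gene_sets`, distinct from an empty intersection
(`ok`). Multi-parent classes get one signature per parent, never merged.

Profiles enumerate every class on the `is_a` paths from a class to a chosen
root (root excluded, having no reference parent), topologically ordered
starting at the focus, with the per-parent signature at each step.

The subtraction query intersects the focus populations' sets against every
population of each subtract class at a fold cutoff that may be stricter
than the build threshold (default 2-fold). Because sets are re-filtered
rather than recomputed, cutoffs below the build threshold are rejected with
a pointer to rebuild instead.

## Enrichment

Annotations are propagated to ancestors over `{is_a, part_of}` (when
declared) with set semantics, then each term is tested with the upper-tail
hypergeometric probability P(X ≥ k) for k query hits among K annotated
genes in a universe of N, query size n. The recommended universe is the
measured gene set of the expression matrix (signatures can only contain
measured genes); the default is the annotated genes. Correction is BH by
default (matching the differential-expression convention) or Bonferroni;
terms with no annotated genes are skipped; query genes outside the universe
are dropped with a logged count.

## Synthetic data

`simulate_ontology` builds a balanced `is_a` tree (`branching**levels`
leaves, one population per leaf). `plant_markers` assigns disjoint marker
genes to every non-root class; `simulate_expression` draws

value(g, sample of p) = baseline(g) + Σ_{a ∈ refl-ancestors(class(p))}
effect(a, g) + N(0, σ²),

with baseline(g) ~ N(μ₀, τ²) drawn once per gene, up effects added and down
effects subtracted along the ancestor chain so class-level and
subclass-level markers coexist. Defaults — μ₀ = 8, τ = 1, σ = 0.25, r = 3
replicates, effect δ = 2 (4-fold), 5 markers per class — reflect a small
but realistic RMA-like panel: log2 intensities centred in the usual
8-ish range, replicate noise a quarter of a log2 unit, and planted effects
comfortably above the 1.5-fold threshold. One `numpy` Generator seeded from
the truth's seed drives the whole simulation, so runs are exactly
reproducible.

What the generator does *not* emulate: probe-level artifacts, batch or
inter-center effects, correlated genes, heavy-tailed noise, or
inconsistent subtype expression (except when a test plants it
deliberately). Passing recovery tests therefore show the machinery is
correct under the model's own assumptions, not that real panels will yield
signatures of any particular size.

Recovery scoring reports precision and recall of a signature against a
class's planted set; an empty signature has undefined precision, reported
as 1 with a `precision_defined=False` flag.

## Problem sizes and numerical choices

The validation suite uses a 2-level, 3-branch panel (9 populations, 110
genes) for recovery checks — noiseless runs must recover planted sets
exactly, and ten noisy runs (σ = 0.25, r = 4) must average ≥ 0.95 precision
and recall — plus an 88-population, 1,000-gene panel for the comparison-
layer count and a 40-population lymphocyte-shaped panel for the
three-constraint query count. These sizes keep a full build in seconds
while preserving the combinatorial structure (7,656 and 256 respectively)
of a real mature-immune-cell panel. Query correctness is additionally
checked against brute-force predicate filtering on random multi-parent
DAGs.

Trigamma inversion uses Newton iteration with the standard asymptotic
clamps (x > 1e7 → 1/√x, x < 1e-6 → 1/x) and a 1e-10 relative stopping
criterion. BH adjustment delegates to statsmodels. Hypergeometric tails use
scipy's survival function.

## Known limitations

- The consistency requirement makes signatures sensitive to a single
  discordant population; no site-aware relaxation is implemented, and
  anatomical axes of differentia (e.g. UBERON integration) are out of
  scope.
- The OBO dialect is intentionally minimal: no OWL reasoning, logical
  definitions, imports, or relation property chains.
- Subtraction re-filters built sets, so it cannot loosen the build
  threshold.
- Enrichment is annotation-source-agnostic; evidence-code filtering is up
  to the caller.
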