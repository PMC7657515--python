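# Methods

## Storage model

A *genotyping protocol* is the unit of storage: one uploaded VCF's
"##" header lines (kept verbatim), reference genome and species names,
the observation-unit type sampled (`tissue_sample`, `plant`, `plot` or
`accession`), and the marker catalogue. The catalogue is persisted
three ways — an ordered name list, a name→record mapping, and an
ordered record array — deliberately redundant so that both "is marker
X in this protocol" and "walk markers in file order" are cheap. Each
marker record (the first nine VCF columns) keeps `qual`, `filter` and
`info` as raw strings: the model stores, it does not reinterpret.

A *callset* is one sample's calls for all markers of one protocol,
keyed by marker name — the transpose of the VCF layout. Loading
therefore transposes once; exporting to VCF transposes back. The
transpose works in marker-row chunks appended to per-sample
accumulators, and both writers are line generators, so export from
sample-first storage retains one marker row of state at a time.

### NT and DS derivation

For every call the loader adds two derived keys unless the file
already provides them (provided values are preserved verbatim, never
recomputed — imputation software legitimately uploads fractional DS):

- `NT`: one nucleotide per `GT` slot (0 → REF, i → ALT[i−1]),
  comma-joined in slot order, `.` per missing slot. Order is the GT
  order for both phased and unphased calls.
- `DS`: the count of reference (`0`) slots; `NA` the moment any slot
  is missing, at any ploidy. Counting *reference* alleles is the
  storage convention here; because most association and prediction
  tools count alternate alleles, `derive_dosage` takes a convention
  switch and the genetics layer converts internally, so the stored
  convention never leaks into results.

Exported VCFs append `NT` and `DS` after the original FORMAT keys
(original key order first, for diffability against the input); the
stored per-marker format string gains those keys at load time, which
makes a second export a byte-level fixpoint of the first.

### Storage-limit arithmetic

Engines that hold a whole callset in one field cap that field
(1 GB is the default here). `max_markers` is the integer quotient of
the field limit by the serialized bytes per marker;
`estimate_bytes_per_marker` measures the latter empirically from real
callsets rather than assuming a constant, since FORMAT richness and
ploidy change it. At 60 B/marker the cap is 16,666,666 markers (~17
million), i.e. under 2 SNPs per 100 bp on a 1-gigabase genome.

## Store and queries

The store is embedded SQLite with JSON1: property tables hold the
protocol and callset documents as JSON text, an `nd_experiment`-style
link table ties (project, protocol, stock, phenotype, genotype)
together, and a dedicated indexed `(protocol_id, marker_name)` table
stands in for a JSON GIN index. Protocols and callsets are immutable
after upload; every write bumps a store generation counter.

Cross-entity queries follow two patterns: marker-membership AND
trait-in-trial conjunction, and a per-call pattern matching `NT`/`GT`
*by exact string equality* (a phased `0|0` deliberately does not
satisfy a required `0/0`) combined with numeric phenotype thresholds.
Phenotype values are stored as strings and cast lazily; an uncastable
value is skipped with a logged warning instead of failing the query.
The DP/GQ thresholds of the conjunctive query read *protocol-level*
marker metadata, mirroring how such queries are written against the
marker catalogue even though depth and quality are per-call concepts.

Accession-name curation uses normalized Levenshtein similarity
(uppercase, non-alphanumerics stripped, edit distance via edlib,
similarity 1 − d/max(len)). Default flag threshold 0.85; matches are
flagged with candidates and scores, never merged automatically.

## Query cache

A query is canonicalized — list fields sorted, unset/empty fields
dropped, keys sorted, compact JSON — and MD5-hashed; the digest keys
the cache file (the output format is part of the query, hence of the
key). Results are computed straight from the store, streamed to a
temp file, atomically renamed, and marked complete by a JSON metadata
sidecar written afterwards; an entry is visible only with its sidecar,
so partial writes can never be served. Entries live under
`gen-<N>/` where N is the store generation, so any store write
invalidates the cache by namespace rather than by deletion. Cold and
warm serves of the same query are byte-identical by construction, and
the suite verifies cached payloads against a no-cache oracle path.

Position filtering is inclusive on both ends; chromosome matching is
exact string equality (`"2"` ≠ `"chr2"`).

## Genetics

All genetics converts dosages to alternate counts rescaled to the
diploid-equivalent range [0, 2] (a triploid count is multiplied by
2/3). This lets mixed-ploidy material and fractional mid-parent
dosages share one set of formulas; the cost is that a rescaled
trisomic count has variance 4/3·p(1−p) rather than 2p(1−p), so
triploid GRM diagonals sit near 2/3 rather than 1. Relationship
*contrasts* are unaffected, which is what the downstream models use.

**Filtering** (defaults MAF 0.01, marker missingness 0.6, sample
missingness 0.8) runs in a fixed order: drop samples over the
missingness bound, then recompute marker missingness and allele
frequencies on the survivors, drop markers over the missingness bound,
then drop markers under the MAF bound, with MAF = min(p, 1−p) from
mean dosage. The order matters (a bad sample can fake marker
missingness) and makes the operation idempotent. Emptying the matrix
raises an error naming the binding filter.

**EM imputation** models each marker row as a draw from an n-sample
multivariate normal: missing cells are replaced by their conditional
expectation given the observed cells of the same marker, then the
per-sample mean vector and sample covariance are re-estimated, until
the imputed values move less than the tolerance (default 1e-4, max
100 iterations; non-convergence warns and returns the last iterate).
The sample covariance is exactly what relatedness structure populates,
so related or duplicated samples inform each other's gaps; a small
ridge (1e-6 of the mean diagonal) keeps the observed-block solve
stable. Imputed values are clipped to [0, ploidy]. A complete matrix
is returned unchanged, exactly.

**GRM** is VanRaden method 1, G = W′W / Σ 2pₖ(1−pₖ), with W the
per-marker mean-centered rescaled dosages. The implementation is
checked against an element-by-element brute-force evaluation of the
formula at 1e-10, and against the invariance that duplicating every
marker leaves G unchanged.

**GWAS** fits, at the observation (plot) level,
y = Xβ + x_m·α_m + u + ε, u ~ N(0, σ²_g K) mapped through the
obs→sample incidence, ε ~ N(0, σ²_e I). X is intercept +
treatment-coded location, year and replicate factors; linearly
dependent columns are detected by pivoted QR and dropped with a
warning. The covariance ZKZ′ is eigendecomposed once per trait; the
variance ratio δ = σ²_e/σ²_g is estimated by profiled REML on a
61-point log grid over [1e−5, 1e5] refined by bounded scalar
minimization. Each marker is then tested by weighted (GLS) least
squares in the rotated basis with a t-test on α_m, df = n − p − 1
(P3D: δ is not re-estimated per marker; an exact per-marker REML flag
exists but is off by default). Scores are −log10 p. Passing
σ²_g = 0 with K = I bypasses REML and reduces the scan to ordinary
least squares — the suite checks this limit against statsmodels OLS at
1e-8. Repeated-measurements mode pools the listed traits' records as
replicate observations of one pooled trait; otherwise traits are
scanned independently.

**Compute-from-parents**: progeny dosage per marker is the mean of the
two parents' dosages, NA if either is NA; progeny with fewer than two
genotyped parents are reported and skipped. Fractional dosages have no
integer GT, so such callsets carry `GT="./."` with DS only, and VCF
renditions of them add a header note saying so.

Manhattan/QQ and GRM heatmap figures always ship with their underlying
TSVs (QQ expected quantiles: −log10((i−0.5)/k)), so nothing downstream
depends on rendered pixels.

## Synthetic data

The fixture generators are pure functions of their spec (seed
mandatory; same spec ⇒ identical bytes). They emulate the *shape* of
GBS breeding panels at hand-checkable scale — the presets sketch a
triploid banana-like panel, a diploid cassava-like panel, and a
diploid maize-like panel with hybrid pedigrees:

- allele frequencies ~ Beta(0.8, 0.8) truncated to [0.05, 0.95] (the
  U-shaped spread of GBS discovery panels), genotype slots drawn
  independently per allele; phasing, missingness, multi-allelic and
  indel sites at configurable rates; AD/DP/GQ from a Poisson
  read-depth model (default mean 20);
- phenotypes at plot level over a full location × year × replicate
  grid: y = 100 + location + year + replicate + Σ causal·effect +
  polygenic + noise, where the polygenic term is a genomic random
  effect (a random weighted sum over all markers) and the noise
  variance is set so the genetic variance fraction equals the spec's
  heritability;
- pedigrees pair each progeny with two distinct founders and inject
  case/punctuation variants of some parent names to exercise the
  fuzzy matcher.

What the generators do **not** emulate: linkage disequilibrium beyond
the weak correlation the polygenic construction induces, population
structure/families, genotyping error correlated with depth, or
missingness that depends on genotype. Passing tests therefore
demonstrate correctness of the machinery and calibration under
exchangeable samples; they do not certify GWAS behavior under strong
structure, which is exactly what the kinship term must absorb in real
panels.

## Problem sizes used in the checks

The round-trip and cache checks run on 50 samples × 500 markers; GRM
oracle checks on 5 × 8 matrices; GWAS calibration on 120 samples ×
400 markers (two seeded replicates pooled, 800 null tests) and power
on 20 seeded replicates of the same shape; the end-to-end scenario
suite uses the maize-like preset (60 samples, 500 markers, 10 draws of
25 accessions). These sizes make every expectation enumerable or
tightly simulated while exercising the same code paths as full-size
panels.

## Known limitations

- Single-writer cache coordination only (atomic rename; no locking
  across concurrent writers).
- No deletion/versioning: protocols and callsets are immutable, and
  cache invalidation is generational, so superseded cache files are
  orphaned rather than removed.
- The EM imputer estimates an n×n sample covariance; it is meant for
  panel-scale n (hundreds), not biobank-scale.
- P3D is an approximation: markers with large effects slightly shift
  the variance components they were estimated without; the exact
  per-marker flag exists for small panels.
- Ploidy is uniform within a dosage matrix; mixed-ploidy *within* one
  protocol is handled only through the diploid-equivalent rescaling.
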