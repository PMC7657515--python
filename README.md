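# callstore

Sample-first genotype storage and analysis for plant breeding data:
VCF-derived callset documents linked to phenotypes and pedigrees in an
embedded relational store, cached multi-format genotype queries, and
downstream genetics — genomic relationship matrices (GRM) and kinship
mixed-model GWAS — including progeny genotypes computed from genotyped
parents.

## Who this is for

Breeding informatics developers and quantitative geneticists who need
one queryable home for genotyping-by-sequencing (GBS) callsets *and*
the field-trial phenotypes measured on the same material, without
running a database server. A VCF is marker-first (rows are markers);
selection decisions are sample-first (one individual, all its markers).
`callstore` stores the transpose: one JSON document per sample per
genotyping protocol, keyed by marker name, next to the protocol's
marker catalogue, so cross-entity questions ("which accessions carry
the T allele on every chromosome *and* exceeded 5 cm plant height in
trial X?") are single queries.

## The model in brief

For every call the loader derives two keys from the VCF `GT` string:

- **NT** — the nucleotide rendering of `GT`, comma-joined in slot
  order (index 0 → REF, index *i* → ALT[*i*−1]), identical for `/` and
  `|` separators;
- **DS** — the dosage: the count of reference allele slots, so for a
  diploid `0/0 → 2`, `0/1` or `1/0 → 1`, `1/1 → 0`, and any missing
  slot gives `NA`. (Most association tools count alternate alleles
  instead; the convention is a switch, and the genetics layer converts
  internally.)

Downstream, with alternate dosages rescaled to the diploid range
[0, 2]:

- **GRM** (VanRaden method 1): G = W′W / Σₖ 2pₖ(1−pₖ), W the
  marker-centered dosage matrix, pₖ the alternate allele frequency;
- **GWAS**: y = Xβ + x_m·α_m + u + ε with u ~ N(0, σ²_g K), X encoding
  intercept + location + year + replicate; variance components are
  estimated once by spectral REML under the null and reused per marker
  (P3D), scores are −log10 p;
- **compute-from-parents**: an ungenotyped progeny's dosage at each
  marker is the mean of its two parents' dosages (NA if either is NA).

Query results (VCF, dosage-matrix TSV, or internal JSON) are cached in
files keyed by the MD5 of the canonicalized query and streamed
line-by-line; identical queries are served byte-identically from disk.

## Worked example

```python
import callstore as cs
from callstore.fixtures import preset, generate_vcf

vcf_text, truth = generate_vcf(preset("toy", seed=1))
header, block = cs.read_vcf(vcf_text)
protocol = cs.build_protocol(header, block, "p1", "demo_protocol")
callsets = cs.transpose_to_sample_first(block, protocol)
call = callsets[0].calls[protocol.marker_names[0]]
print(call.GT, call.NT, call.DS)
```

prints

```
1|0 A,T 1
```

— a phased heterozygote at a T→A marker: one reference slot, so the
reference-count dosage is 1, and `NT` spells the alleles in `GT` slot
order. Running `python examples/05_gwas.py` fits the mixed model on a
60-accession, 500-marker fixture with one planted causal marker
(effect 1.5 dosage units, h² ≈ 0.5) and prints

```
top hits (score = -log10 p):
   marker chrom    pos    score
 S3_66340     3  66340 3.378114
S1_234430     1 234430 2.244610
S4_836790     4 836790 2.201444

planted causal marker: S3_66340
```

— the planted marker leads the table. The `examples/` directory has
one short script per capability (loading/export, store queries, cached
search, GRM, GWAS, compute-from-parents); each prints what it computes
and what the numbers mean. A thin CLI mirrors the same surface:
`callstore make-fixture | load-protocol | load-phenotypes |
load-pedigree | search | grm | gwas`.

## Layout

- `src/callstore/datamodel.py` — domain types, NT/DS derivation,
  storage-limit arithmetic
- `src/callstore/vcf_io.py` — VCF read/write, marker-first ↔
  sample-first transposition, dosage-matrix export
- `src/callstore/store.py` — embedded relational store (SQLite +
  JSON1), fuzzy accession-name curation, cross-entity queries
- `src/callstore/search_cache.py` — parameterized search, MD5-keyed
  file cache, three output formats
- `src/callstore/popgen.py` — filtering, EM imputation, GRM, kinship
  mixed-model GWAS, compute-from-parents
- `src/callstore/fixtures.py` — deterministic synthetic VCF /
  phenotype / pedigree generators
- `src/callstore/pipelines.py`, `src/callstore/cli.py` — end-to-end
  conveniences and the thin CLI

See `docs/methods.md` for the statistical model, numerical choices and
known limitations.
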