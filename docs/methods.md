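# Methods

## Curation

The input is a multi-FASTA with RefSeq-style headers. Three filters run in
a fixed order — header keyword screen, sequence deduplication, accession
exclusion list — and every input record receives exactly one audit
decision (`kept`, `keyword_origin`, `keyword_cds`, `duplicate`,
`exclusion_list`), so kept + removed always partitions the input. The
keyword screen removes headers carrying a *single* `origin` or a single
`cds` token: such entries are almost always a deposited gene or
replication origin rather than a complete plasmid, while two or more `cds`
mentions indicate a multi-gene (plausibly plasmid) annotation. A `plasmid`
token overrides the screen. Matching is case-insensitive and token-based
(split on non-alphanumerics), so `cds` does not fire inside `cdsA`;
substring matching would over-remove. Whether `plasmid` rescues
single-`origin` headers as well as single-`cds` headers is configurable
(`plasmid_rescues_origin`, default true): the origin keyword is the more
aggressive of the two heuristics and a header naming both a plasmid and
its origin of replication is usually a plasmid. Deduplication keys on the
exact uppercased sequence string, not the accession, because the same
molecule is frequently deposited under several accessions. The filter
order only affects which reason a doubly-removable record is logged under.

## Sketching and distances

Canonical k-mers: each A/C/G/T-only window of length k is encoded 2
bits/base (A=0 < C=1 < G=2 < T=3, so integer order equals lexicographic
order) and the smaller of the forward and reverse-complement encodings is
kept; windows containing any other character are skipped rather than
coerced, which keeps canonicalization well defined. k is limited to 1–32
by the 64-bit packing; all defaults use k=21, for which the k-mer space
(4²¹ ≈ 4.4·10¹²) makes chance k-mer sharing between megabase-scale genomes
negligible.

Hashing is a seeded splitmix64 finalizer applied to the packed encoding
(default seed 42). It is a fixed, platform-independent 64-bit
non-cryptographic hash, so sketches are reproducible bit for bit and
serializable/reusable across runs. Compatibility with the Mash binary's
MurmurHash sketches is deliberately not a goal: sketches from different
tools are never mixed.

The bottom sketch keeps the s = 1000 smallest distinct hash values. For a
pair, the merged bottom sketch M is the s smallest values of the union of
both hash sets; x = |M ∩ A ∩ B| and j = x/|M|. The distance is
d = −(1/k)·ln(2j/(1+j)), with d = 1 when j = 0 (the formula diverges
there; a unit cap preserves ordering) and capped at 1 generally. When
s ≥ n₁ + n₂ the merged sketch is the whole union and j is exactly the true
Jaccard index — the test suite exploits this saturated regime.

The p-value for x shared hashes uses the chance-sharing null model: with
k-mer space Ω = 4^k and nᵢ distinct canonical k-mers per genome, the
probability that a random k-mer (hence a random sketch position) is shared
by chance is r = p₁p₂/(p₁+p₂−p₁p₂) with pᵢ = nᵢ/(nᵢ+Ω), and the reported
p is P(X ≥ x) for X ~ Binomial(s, r) (scipy's binomial survival function;
tests cross-check a term-by-term tail sum).

## Network

All unordered pairs of curated plasmids are evaluated; an edge is retained
iff p ≤ 0.05 and d < 0.1 (boundary semantics configurable). These defaults
keep only pairs whose distance corresponds to ANI ≳ 0.9, a regime in which
a link plausibly reflects shared plasmid backbone rather than a stray
mobile element. Clusters are connected components (networkx) over
degree ≥ 1 nodes, labelled 1..C in order of each component's
lexicographically smallest accession — deterministic per run, but not
stable across dataset versions. Degree-0 nodes are singletons. All-pairs
evaluation is the only code path; with s = 1000 sketches a pair costs a
~1000-element sorted-array merge, so collections into the tens of
thousands remain tractable without a prefilter.

Graph JSON export is fully ordered (sorted nodes, sorted links, sorted
keys) so identical inputs give identical bytes; links carry x, j, d, p and
the endpoint size ratio min(len)/max(len), and round-trip losslessly.

## Metadata and queries

Species and genus come from header tokens 2–3; the plasmid name is the
token after the word `plasmid` (trailing punctuation stripped); family and
order come from a genus → (family, order) mapping table supplied as TSV.
Annotations are ingested from ABRicate-style TSV (1-based inclusive
coordinates; strand recorded but unused; the ARO ontology accession kept
for card rows). Rows referencing unknown accessions or out-of-range
coordinates are rejected with warnings; by default no minimum
coverage/identity is imposed — annotation rows are stored as given, and
thresholds are the caller's policy. A plasmid's "family" is its set of
plasmidfinder replicon gene hits; no Inc-group ontology is modelled beyond
gene names. Selections (length range, taxa level, gene-in-database,
plasmid family) are plain accession sets with provenance strings and
combine by union/intersection, so the algebra is the set algebra.

## Hit scoring and redundancy removal

Imported sample documents carry one mode each: `mapping` (cov = coverage
breadth, the proportion of plasmid positions covered at least once; depth
is ignored), `screen` (ids = containment identity), or `dist`
(idd = 1 − mash distance, sh = shared-hash proportion, optional contig
label). Metrics must be proportions; values in (1, 100] are interpreted as
percentages and normalized with a warning. The per-hit weight is
metric × length (idd·sh·length in dist mode), and for every network edge
joining two hits the signed score S = w₁ − w₂ decides keep-first /
keep-second / keep-both.

Elimination is one-shot and order-independent: a hit is retained iff no
linked hit has strictly greater weight. An iterative variant (re-running
after removals) is explicitly not implemented — the one-shot rule matches
the per-comparison retain/drop semantics, needs no ordering convention,
and guarantees the maximum-weight hit of every linked clique survives.
Comparisons are restricted to pairs linked in the network (d < 0.1);
unlinked hits are never compared however similar their metrics, and
unknown accessions are flagged but retained. The full pre-removal sample
is preserved alongside the retained set. Multiple imported samples stay
independent (no cross-sample elimination); the heat-map matrix tabulates
samples × accessions with each sample's native metric (or weight, on
request) for cross-sample comparison.

## Synthetic data generator

The generator emulates the structure of a public plasmid collection at
desk scale: plasmid *families* (descendants of a random ancestor mutated
independently at a per-base substitution rate), unrelated random plasmids,
planted exact duplicates, gene-level decoy headers for the keyword screen,
an ABRicate-style annotation table over a small pool of real resistance /
virulence / replicon gene names, a genus taxonomy table, and sample-hit
documents with uniform metrics. Defaults are the network's study
conditions: 3 families of 3 descendants at rate 0.02 from 8 kb ancestors
(8 kb is a realistic small-plasmid size and keeps exact-Jaccard
bookkeeping cheap; at rate 0.02 the expected pairwise distance ≈ 2 × 0.02,
safely inside the d < 0.1 link threshold), 3 unrelated 6 kb plasmids, one
duplicate, three decoys, one exclusion.

Evolution is substitution-only, no indels, so the exact canonical-k-mer
Jaccard of every within-family pair is cheap to record in the manifest and
the distance ≈ rate relationship stays clean. The manifest also fixes the
expected filter decision per record, expected clusters/singletons, header
parses and annotation placements, so downstream modules are verified
without recomputation. Everything derives from a single integer seed and
regenerates byte-identically.

What the generator does *not* emulate — indels and rearrangements, shared
mobile elements between unrelated plasmids, uneven sequencing coverage,
chimeric assemblies, biased host metadata — bounds what passing tests
show: they validate the algorithms' contracts and statistics, not
robustness to the messiness of real collections.

## Numerical and testing choices

Distances and scores are IEEE doubles; ties in the scoring rule are exact
float equality (the tie case S = 0 arises from identical metric × length
products, which the equations produce exactly for identical inputs).
Sketch comparisons are integer set operations, so j is an exact rational
x/|M|. The mutation-rate recovery test treats the shared-hash count as
Binomial(s, j): the estimated d must fall inside the 99% binomial interval
of the generator's exact-Jaccard distance for ≥95% of pairs across 20
seeds (600 pairs; one 5-descendant family per rate 0.01/0.03/0.05 from
8 kb ancestors). Network oracle checks use a ~100-plasmid collection
(16 six-member families + 4 unrelated), the point at which all-pairs
brute-force verification still runs in seconds.

## Known limitations

- Sketch parameters must match exactly for comparison; there is no
  re-sketching or parameter negotiation.
- Cluster ids are deterministic per run only; adding one plasmid can
  relabel every cluster.
- No streaming sketching of reads and no containment estimation:
  screen-mode results are ingested from external pipelines, never
  computed here.
- The header heuristics cannot validate that a sequence is biologically a
  plasmid; curation quality is bounded by header quality.
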