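# Methods

## The analysis model

The experimental design this package analyzes pairs one *culture-independent*
16S sample per donor (direct fecal sequencing) with one *plate pool* per
culture condition — medium × incubation atmosphere — where each pool is all
colonies scraped from one plate, sequenced as a single sample. Both kinds of
samples are OTU count vectors over a shared OTU axis; the package consumes
post-clustering OTU tables and does no read processing.

**Cultured call.** An OTU is cultured for a donor iff its count reaches
`min_cultured_reads` (default 10) in at least one of that donor's plate
pools. The floor exists because plate-pool replicates are poorly
reproducible below ~10 reads; it applies to plates only. Detection in the
culture-independent sample is count ≥ 1 with no floor, since that sample is
the reference against which culture is judged. Control roles (no-growth and
DNA controls) are never consulted for calls. By default only fresh-storage
pools enter the call; frozen/aerobic-exposed pools are reserved for the
storage analysis.

**Recovery proportions.** For a threshold *t*, the proportion cultured is
computed over OTUs whose culture-independent relative abundance exceeds *t*
(t = 0 meaning "observed at all"). Because the call depends only on the
per-plate ≥ floor predicate, the proportion is invariant to common scaling
of plate counts. Across donors, means are unweighted.

**Detection partition.** Culture-only / both / independent-only sets over
the union of OTUs detected by either method, with percentages of the union
rounded half-up to integers (so a (1, 1, 1) split renders as 33/33/33).

**Rarefaction.** The depth-effect analysis subsamples the
culture-independent counts *without replacement* (multivariate
hypergeometric) and recomputes the threshold-0 proportion, keeping the
cultured calls fixed. Shallow culture-independent sequencing misses the rare
tail — where uncultured OTUs concentrate — so the apparent cultured
proportion is inflated at low depth and falls as depth grows.

**Minimal media sets.** Set cover: targets are culturable OTUs above the
abundance threshold (above-threshold OTUs cultured nowhere are excluded —
only culturable OTUs can be covered); each condition covers the targets it
recovered at the read floor. The greedy solver picks the condition covering
the most uncovered targets, ties broken lexicographically by (medium,
atmosphere). The exact solver runs depth-limited lexicographic
branch-and-bound with suffix-union and counting bounds, guarded to 30
conditions; the first solution found is minimum-cardinality and, among
equal-size covers, lexicographically smallest. Exact ≤ greedy by
construction, and both assert post-hoc that the returned selection actually
covers the target set. The cross-donor union of per-donor covers (optionally
restricted to one atmosphere) measures media redundancy across individuals.

**Community comparison.** Bray–Curtis dissimilarity, 1 − Σ min(pᵢ, qᵢ), is
always computed on relative abundances (scipy's implementation under the
hood) so unequal sequencing depth cannot masquerade as community change; no
rarefying is applied before BC. Storage effects pair same-condition plate
pools (fresh vs frozen, fresh vs aerobic-exposed) per donor — the
conservative pairing when no other scheme is recorded. Plate-versus-fecal
rankings sort conditions by ascending BC to the donor's fecal sample.

**Targeted isolation.** Media recommendation sums the relative abundance of
OTUs whose lineage matches the query taxon, per plate pool, and ranks
conditions (mean across donors when unrestricted). Lineages are
semicolon-delimited Greengenes-style strings; matching is case-insensitive
against whole rank fields after stripping `x__` prefixes, so "Clostridium"
does not match "Lachnoclostridium". The novelty screen aligns each isolate
globally to every reference (Needleman–Wunsch, match +1 / mismatch −1 /
gap −2, traceback ties broken diagonal → up → left); identity is matches
over alignment columns after trimming terminal-gap columns, appropriate for
near-fully-overlapping 16S fragments. IUPAC ambiguity codes match iff one
code's base set contains the other's. An isolate is flagged novel when its
best identity falls below `identity_threshold` (default 0.97, the
OTU-definition cutoff). This is a pure identity screen; it deliberately does
not reproduce classifier-confidence calls, which conflate identity with
assignment uncertainty.

## The simulator

The generator produces the statistical structure the analysis assumes, with
planted ground truth for parameter-recovery testing.

* **Community**: i.i.d. log-normal(μ = 0, σ = 2) masses, normalized — a few
  dominant OTUs and a long rare tail, the canonical gut rank-abundance
  shape. σ = 2 is the default because it yields >50 % of mass in the top
  decile. A deterministic power-law (Zipf) alternative is available. OTU ids
  are assigned in rank order.
* **Culturability**: exactly `round(frac_culturable · n)` OTUs are truly
  culturable (default 0.75 — roughly three-quarters of observed gut OTUs
  prove cultivable under extensive media panels). Membership is drawn with
  weights ∝ abundance^0.5, encoding the empirical pattern that the never-
  cultured OTUs sit in the rare tail; this bias is also what produces the
  rarefaction depth effect above. Each culturable OTU grows on a given
  condition with probability 1/selectivity (default ¼; at least one
  condition guaranteed), with log-normal(0, 1.5) growth factors — median 1,
  so roughly half the positive factors amplify an OTU above its fecal
  abundance, letting selective plates recover sub-1 % taxa at high plate
  abundance.
* **Sequencing**: multinomial draws; plate composition ∝ abundance × growth
  factor, renormalized. Default depths are ~2 × 10⁵ reads for the
  culture-independent sample and 10⁵ per plate pool, matching the scale of
  deep culture-enrichment studies. A configurable dead-DNA `background_rate`
  (default 0) mixes the fecal profile into plate compositions, emulating
  deposited-DNA controls; published control experiments put this under 2 %,
  hence the small-but-nonzero option.
* **Storage**: a seeded fraction `magnitude` of positive growth factors is
  hit — freezing zeroes them, aerobic exposure multiplies them by 0.1. BC
  between matched fresh/perturbed pools grows monotonically with magnitude.
* **Isolates**: substitution-only point mutants of reference sequences with
  exactly `round(divergence · length)` substitutions, so true identity is
  closed-form and the aligner can be checked exactly. No indels, chimeras,
  or PCR bias are modeled; dilution-plating bottlenecks are absorbed into
  the growth-factor draw (the bench protocol pools dilutions before
  sequencing anyway).

What passing tests on this simulator do *not* show: robustness to OTU-
clustering artifacts, primer bias, chimeras, compositional covariance
between taxa, or within-OTU strain structure — none of which the generator
emulates. The parameter-recovery results certify the analysis logic, not
the wet-lab protocol.

## Numerical and design choices

* Counts are integers everywhere; relative abundance is a computed view,
  never stored, preventing double-normalization.
* Orientation: tables are OTUs × samples on disk (classic layout, and dense
  BIOM-style JSON), samples × OTUs in memory.
* All ties (rank abundance, cover selection, condition rankings, alignment
  traceback, best-reference choice) break lexicographically/deterministically
  so reruns are byte-identical; every generator is a pure function of
  (parameters, seed).
* Percentages are rounded half-up to match common reporting style.
* Zero-read samples are excluded from dissimilarity matrices (BC is
  undefined on an empty profile); an all-zero growth row with zero
  background raises a "no growth" error rather than fabricating a sample.
* The minimal-set question is answered per-donor and then unioned across
  donors (the literal reading of "conditions required across samples");
  a joint multi-donor cover is a different, not-implemented objective.
* Test and demo problem sizes (hundreds of OTUs, 10–33 media, 10⁴–10⁵
  reads) are chosen so the full suite runs in seconds while remaining at
  the depth scale where the read-floor and rarefaction behaviors are
  realistic.

## Known limitations

* The exact cover solver is exponential in the worst case; beyond 30
  conditions only greedy (ln n-approximate) results are available.
* The aligner uses linear gap penalties; affine gaps would be preferable
  for sequences with long true indels, but 16S fragments of a shared
  region rarely need them.
* Taxon matching requires whole-field equality, so querying with a partial
  name (e.g. a genus prefix) finds nothing rather than risking false hits.
* `storage_effect` requires matched same-condition pools; designs that
  changed media between storage arms cannot be paired.
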