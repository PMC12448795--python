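# Methods

## Problem

Blood-group typing from sequencing data reduces to: given per-sample variant
calls over a panel of catalog-defining sites, which named pair of haplotypes
(diplotype) best explains them? The hard cases are (i) heterozygous sites
whose cis/trans configuration is unknown without phasing, (ii) missing calls
(dropout) at panel sites, and (iii) structural/paralogous events — RHD
deletion, RHCE hybrids — that small-variant callers do not emit at all.

## Catalog model

A catalog is two TSV tables. The variant table fixes each catalog site's
identity (`variant_id`) and VCF-comparable coordinates (1-based, anchored
indels). The haplotype table names alleles as variant-id sets plus the
antigens they express; the empty set is the system's reference allele, an
empty antigen set a null allele. Two alleles with identical variant sets are
legal (real ISBT tables contain alleles the panel cannot separate); they are
loaded with a warning and surface downstream as call ambiguity. The exact
column layout is this package's own: published descriptions of such
ISBT-style configuration files do not fix a schema, so ours is a documented,
versioned stand-in that is lossless for everything the matcher needs.

Antigen phenotype is the plain codominant union of the two alleles' antigen
sets. Dominance and suppressor epistasis (e.g. Bombay-type suppression) are
deliberately out of scope.

Allele *grouping* (e.g. merging indistinguishable GYPB*03N.xx null alleles
under one GYPB*03 reporting label) rewrites names at reporting time only;
score tensors are bitwise identical with and without grouping, which the
tests assert.

## Scoring

Encoding: per system with V variants, vectors live in {0,1}^(2V) — one REF
and one ALT dimension per variant. Design rationale:

- the reference allele is a nonzero vector, so its cosine is defined;
- dropout zeroes both dimensions of a site, so a missing call strictly
  lowers similarity to *every* allele — degradation under dropout is built
  into the geometry rather than special-cased.

Diplotype score = arithmetic mean of the two strand cosines, maximized over
pair order and per-block orientations. The mean (rather than a product) keeps
the score in [0, 1] and interpretable as "average per-strand agreement"; the
combination rule is a design choice of this package.

Orientation search: every observed strand has norm √O regardless of
orientation (each observed site contributes exactly one dimension per
strand), so the numerator decomposes additively over phase blocks and each
block's two orientations can be optimized independently. The per-block
choice is therefore *exact* for any block count B — no exhaustive/greedy
split is needed; a 2^B brute-force enumeration exists only in the test suite
as the independent oracle, which matches to 1e-12 with exact tie-set
equality.

Numerical choices: argmax ties use an absolute tolerance of 1e-12 (scores
are short sums of small integers over 2√(VO), so true gaps are orders of
magnitude larger); the all-missing observation scores 0 against everything
(zero-norm guard) and is reported NO_CALL; calls with best score below
`min_score` (default 0.5, configurable) are NO_CALL rather than a forced
guess. Homozygous pairs are legitimate candidates: the space is all
n(n+1)/2 unordered pairs.

## VCF projection

Catalog sites are matched by (chrom, pos, ref, alt) after splitting
multi-allelic records; symbolic alleles are skipped with a warning
(structural events belong to the coverage rules). Phased het genotypes carry
their PS tag as the phase block; phased GT without PS falls back to one
block per contig, mirroring common phaser output. Catalog sites absent from
the VCF resolve by policy: `ASSUME_REF` (default; right for whole-genome
single-sample VCFs) or `ASSUME_MISSING` (right for targeted panels, and the
semantics the dropout simulations model). Published behavior for this corner
is not specified, so both policies are implemented and exposed.

Coverage input is bedGraph text rather than BigWig: the two formats carry
the same per-base values, the environment provides no BigWig reader, and
text tracks suit a fully text-based test corpus. Bases absent from the track
count as depth 0; a contig absent from the file is a usage error.

## Copy-number rules

ratio = mean(target) / mean(control), control below 10× → LOW_CONTROL
NO_CALL for that rule only. Breakpoints 0.25/0.75 are the midpoints between
the expected ratios {0, 0.5, 1} for 0/1/2 copies — the standard depth-ratio
heuristic; no published thresholds exist for this application, so the
defaults are engineering choices and are config-overridable per rule. GC or
capture-bias normalization is not applied (documented limitation); choosing
a nearby 2-copy control region (e.g. shared RHCE exons for the RHD rule) is
the intended mitigation.

## Simulation world

The synthetic catalog generator emits, per system, a reference allele plus
alleles with random *distinct* variant subsets — so zero-noise calls are
provably unique and concordance at (d=0, b=0) is exactly 100%. Defaults (10
systems, 4–12 alleles and 4–12 variants per system) are the desk-scale
stand-in for a real ISBT catalog. Truth diplotypes are drawn uniformly over
alleles; published simulations of this kind do not state allele frequencies,
and uniform is the tested default (frequency weighting would be a
straightforward extension).

Noise operators:

- **dropout(d)** — every site independently goes MISSING with probability d,
  whole-site (a missing VCF record loses both strands).
- **phase_breaks(b)** — adjacent het pairs within a block split with
  probability b; each newly created block is flipped as a whole with
  probability ½ relative to its predecessor (a break destroys *between*-block
  linkage and nothing else). b=1 is provably identical to the unphased code
  path, which the tests assert call-for-call.

Phase breaks are applied before dropout, so breaks act on the full het
structure of the phaser's output and dropout then deletes sites; the two
operators commute in distribution for the quantities measured here.

Grid accounting: a (sample, system) unit is *concordant* only when the true
pair is the unique top-scoring diplotype — ambiguous-but-contains-truth
counts as not concordant, making concordance and ambiguity complementary
surfaces. The counting rule is stated here because published figures of this
kind do not print theirs. `concordance + discordance + no_call = 1`, with
ambiguous units inside discordance; the ambiguity rate is reported
separately. One master seed spawns per-condition substreams, so any grid
cell is independently reproducible.

What a green simulation does **not** establish: behavior on real ISBT
catalogs (allele-frequency structure, long shared haplotype backbones,
indistinguishable allele clusters), genotyping *errors* (wrong calls, not
missing calls — a documented extension point), read-level artifacts, or
reference-bias effects. Absolute concordance values at high dropout are
catalog-specific; only the qualitative structure (dropout dominates, phasing
breaks are minor) transfers.

## Report

The JSON report is versioned (`schema_version: "1.0"`) and modeled with
pydantic; a JSON Schema rendering ships in `hemotype/data/`. Under
ambiguity the reported antigen phenotype is the intersection over tied
candidates — only antigens certain to be present. Exit codes: 0 success,
1 internal error, 2 usage/input error, with machine-readable error JSON.

## Known limitations

- No novel-allele or hybrid-allele discovery beyond what the catalog encodes.
- No quality-score weighting of individual variant calls.
- Coverage heuristics assume roughly uniform depth; heavily biased capture
  data needs carefully chosen control regions.
- gVCF reference blocks are not interpreted; `ASSUME_REF` approximates them.
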