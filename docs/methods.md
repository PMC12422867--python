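# Methods

## The diagnostic model

The package implements the genomic battery used to classify a putative
hybrid between two divergent (here, intergeneric) bird species, together
with the occurrence-data accounting that frames how unusual the parental
contact is. The generative picture is simple: two parental lineages are
fixed for alternate alleles at a set of diagnostic sites and additionally
segregate low-frequency variation within themselves. An F1 inherits one
intact haplotype from each parent, so it is heterozygous at every fixed
difference; later-generation hybrids (F2, backcrosses) inherit recombined
gametes and lose that signature in a predictable, Mendelian way. Each
analysis module measures one projection of this structure.

### Triangle statistics

AIMs are biallelic sites with parental allele-frequency difference
≥ δ (closed comparison, so δ = 1.0 admits exactly fixed differences).
With a single diploid per parent, group frequencies take values
{0, 0.5, 1}; the API accepts arbitrarily many parental samples and
computes frequencies per group. Orientation: the parent-2 allele is the
majority allele in the parent-2 group. Sites missing in every sample of a
group, or with more than two alleles, are skipped and counted.

For a sample genotyped at n AIMs, h is the fraction of its 2n alleles
matching the parent-2 orientation and H the fraction of AIMs carrying one
allele from each class. Missing genotypes are excluded per sample with a
reported usable-AIM count (no imputation). Expectations: F1 → (0.5, 1.0)
exactly; BC1P1 → E = (0.25, 0.5); F2 → E = (0.5, 0.5). Alleles matching
neither parental orientation (e.g. genotyping error to a third base)
count toward the denominator but not the numerator of h, and break
interclass heterozygosity at that site; a per-allele error rate e
depresses F1 H to 1 − 2e(1 − e).

### Phase-block assignment

Blocks are runs of jointly phased heterozygous variants. Block length is
pinned as (last variant − first variant + 1): blocks are defined by their
phased variants, and the convention is fixed by test. Filtering retains
blocks with ≥ 10 variants and length ≥ 100 bp. Both haplotype consensus
sequences of every retained block are scored against each candidate
parent with a local affine-gap aligner whose parameters mimic default
nucleotide-BLAST ranking (+2 match, −3 mismatch, gap open 5, extend 2 —
implemented as open −7 / extend −2 in first-base-inclusive form). What is
promised is the decision semantics — rank by score, exact score ties form
a tie-set, identity = matches / alignment columns with gaps counting
against, hits under the identity gate (default 0.97) excluded *before*
ranking — not bit-score-level agreement with any external tool. `N` is
scored neutrally; queries more than 50% `N` are dropped and counted.
Candidate sequences longer than the block span are sliced to the
homologous coordinates (the simulator introduces no indels, so
coordinates are shared). The F1 expectation — equal top-hit counts for the
two parents — is tested with an exact two-sided binomial test against 0.5.

### Masked consensus

A read contributes to a position only if its base quality ≥ 20 AND its
mapping quality ≥ 20 (strict "below" semantics: exactly 20 passes). The
consensus is the majority base among contributing reads. Masking reasons:
`no_depth` (no reads), `low_bq` / `low_mq` (all reads fail; `low_bq`
takes precedence when any read failed the base-quality screen), and `tie`
(no unique majority — no tie-break rule is assumed, so ambiguity is not
resolved into a fabricated base; this adds a fifth reason beyond the four
obvious ones, chosen so that "N iff reason ≠ pass" stays exact). Raising
either threshold can only mask more positions (tested property). The
coverage fraction is the called share of the region.

How mixed pass/fail pileup columns are treated is an interpretation (the
protocol's depth-style screening does not pin it down): here failing
reads are simply excluded and any surviving read can call the base. The
choice is explicit and test-pinned.

### Window heterozygosity and synthetic hybrids

Per-site heterozygosity of a diploid window is (# sites where the two
haplotypes differ) / (# comparable sites), where a site is comparable
only if both haplotypes carry a called base — `N` and gap columns are
excluded from numerator *and* denominator (callable-sites denominator; a
whole-window denominator would conflate masking with homozygosity).
Synthetic hybrids pair one haplotype from each species, globally aligned
with free end gaps; alignments whose gapped-column fraction exceeds a
tolerance (default 10%) are rejected as non-homologous. The synthetic
diploid's expected heterozygosity equals the between-species per-site
divergence of the window, which is the F1 yardstick the natural hybrid is
compared against.

### Checklists and niche overlap

Co-occurrences are complete checklists listing both focal species.
Locality retention (vagrancy screen): keep a locality's observations of a
species iff it was reported there in ≥ 2 distinct years within the focal
window (default 2019-01-01 to 2023-05-31) OR detected on ≥ 50% of the
locality's *all-time* checklists — the all-time denominator follows the
rule's wording and keeps heavily surveyed contact-zone localities from
being over-penalized. Absence sets are localities with ≥ 1 checklist in
*every* focal year and zero detections in that period. Thinning keeps one
random point per 10-km cell in an equal-distance approximation
(longitude scaled by cos of the extent-center latitude; the projection
used by the original thinning is unstated, so the simplest
distance-faithful one is used); it is idempotent and seeded.

Suitability surfaces are regular lon/lat grids with values in [0, 1]. The
binarization threshold maximizes sensitivity + specificity over the
midpoints of consecutive distinct observed scores, breaking ties toward
the lowest threshold (deterministic). Overlap is the per-cell AND of two
binarized surfaces; area sums spherical-rectangle cell areas
(R = 6371.0088 km), the centroid is the area-weighted mean of overlap
cell centers, and polygons are the union of cell boxes (GeoJSON export).
The bundled suitability scorer is a Gaussian envelope over presence
coordinates — deliberately minimal, exercising thresholding and overlap
geometry; ecological realism (climate covariates, background sampling,
regularization) is the user's to plug in.

## The synthetic-data generator

The generator emulates: two lineages with per-site fixed-difference
probability (`divergence`) and within-lineage segregating sites
(`polymorphism`, minor-allele frequencies uniform on [0.05, 0.5]); a
short maternally inherited mitochondrial replicon without heteroplasmy;
pedigreed diploids (P1/P2/F1/F2/BC1) with Poisson-crossover
recombination (crossovers per gamete ~ Poisson(`recomb_rate`), positions
uniform — the simplest model that produces the partial-ancestry scenarios
of interest) and per-haplotype ancestry truth tracts; pileups with
Poisson depth, substitution errors and truncated-normal base/mapping
qualities (any spread straddling 20 exercises the masking rule); phase
blocks whose realized first-to-last-variant span follows a requested
(mean, sd) — each sampling window is widened by twice the mean inter-het
distance so realized spans match the request; at the default targets
(mean 340 bp, ~12.5 variants per block, i.e. heterozygous-site density
(12.5 − 2)/340 ≈ 0.031) realized means land within a few percent — with
optional switch errors that flip the haplotype assignment from a variant
onward; and checklist tables for two strictly allopatric species with
injected contact-zone co-occurrences and single-event vagrants, all
truth-labeled.

What it does not emulate: read-level sequencing (FASTQ, alignment,
reference bias — acknowledged for real data but not modeled), indels and
structural variation, linkage beyond a single uniform-recombination
chromosome, coalescent demography or selection, observer effort
covariates and detection heterogeneity within a locality. Passing tests
therefore demonstrate correctness of the statistics under the stated
generative model, not robustness to every artifact of real sequencing or
citizen-science data.

## Numerical and design choices

- Coordinates are 0-based half-open internally; VCF (1-based) and BED
  conversions happen at I/O.
- All randomness flows through `numpy.random.default_rng` seeds; pipeline
  stage seeds are spawned from one master seed via `SeedSequence`, kept
  below 2³¹.
- Sample SDs use the n−1 denominator; a single block has no SD (error).
- Degenerate inputs raise `ValueError` rather than returning sentinels:
  empty pileups/regions, all-N queries or windows, single-class or
  constant score sets for thresholding, zero genotyped AIMs.
- Problem sizes in tests and examples (tens to hundreds of kb, hundreds
  of blocks, hundreds of replicates) were chosen as the smallest scales
  at which the Monte-Carlo oracles are stable at 3-SE tolerances.
- The identity gate is applied before tie determination (gate first, then
  rank survivors); the alternative ordering is defensible but this one is
  pinned by test.

## Known limitations

- The alignment scorer reproduces BLAST's decision semantics, not its
  E-values or exact bit scores; seeding heuristics are irrelevant at
  block scale but matter genome-wide.
- Allele-frequency-based AIM discovery from single parental individuals
  (frequencies in {0, 0.5, 1}) cannot distinguish fixed differences from
  shared rare variation; larger parental panels sharpen δ.
- The equal-distance thinning approximation distorts cells far from the
  extent-center latitude; acceptable within a ~15° band, not globally.
- The bundled envelope scorer ignores environmental covariates entirely;
  overlap areas it produces are geometric exercises, not range forecasts.
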