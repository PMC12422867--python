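# hybriddiag

Tools for diagnosing a first-generation (F1) hybrid bird from low-coverage
whole-genome data and for quantifying how unusual the parental species'
co-occurrence is, built around the workflow used to confirm wild
intergeneric jay hybrids. Everything runs on simulated data with known
ground truth, so each step of the diagnosis can be validated end to end;
the same functions accept real inputs (FASTA/VCF/BED/TSV/CSV) at the
package boundary.

## Who this is for

Population geneticists and ornithologists who have a putative hybrid
genome (often sequenced at low depth), reference genomes for the candidate
parents, and citizen-science checklist data, and who want a reproducible,
tested implementation of the standard diagnostic battery rather than a
collection of one-off scripts.

## What it computes

**Triangle statistics.** Ancestry-informative markers (AIMs) are biallelic
sites with parental allele-frequency difference ≥ δ; at δ = 1.0 with one
diploid per parent these are exactly the sites fixed for alternate
alleles. For a sample genotyped at *n* AIMs,

- hybrid index  h = (# parent-2 alleles) / 2n
- interclass heterozygosity  H = (# AIMs with one allele from each parent) / n

(h, H) lives in the triangle with vertices P1 = (0,0), P2 = (1,0) and
F1 = (0.5, 1.0); H ≤ 2·min(h, 1−h). A true F1 sits exactly at the apex;
backcrosses average (0.25, 0.5) down the edges.

**Phase-block parental assignment.** Phased haplotype blocks (≥ 10
variants, ≥ 100 bp) contribute two haplotype consensus queries each,
scored against every candidate parent with a local aligner using
nucleotide-BLAST-like scoring (+2/−3, affine gaps 5/2), a ≥ 97% identity
gate, and explicit tie-sets on equal top scores. For an F1 the two parents
should split the top hits ~50/50 (exact binomial test against 0.5).

**Masked consensus.** Majority consensus from per-position read evidence
in which a read contributes only if base quality ≥ 20 AND mapping quality
≥ 20; positions with no surviving evidence (or a majority tie) become `N`,
and the callable share of the region is reported as the coverage fraction.

**Window heterozygosity and synthetic hybrids.** Per-site heterozygosity
of a phased diploid window (differing / comparable sites), and "synthetic"
hybrids built by pairing one haplotype from each species — the F1-level
heterozygosity yardstick for a conserved window such as ACTB.

**Checklist and niche accounting.** Co-occurrence counts from complete
checklists; vagrancy screening (retain a locality iff the species was
reported in ≥ 2 years of the focal window OR on ≥ 50% of its all-time
checklists); 10-km grid thinning; absence sets from localities surveyed in
every focal year without a detection; suitability binarization at the
maximum sensitivity+specificity (Youden) threshold; and the area (km²,
latitude-corrected) and centroid of the overlap between two binarized
suitability surfaces. The suitability model is pluggable (a Gaussian
climate-envelope scorer is bundled).

## Worked example

`examples/01_triangle_f1.py` simulates two lineages with ~1,000 fixed
differences, discovers AIMs at δ = 1.0, and places simulated pedigrees on
the triangle:

```
AIMs discovered at delta=1.0: 1001
          hybrid_index  interclass_het
pedigree
BC1P1            0.214           0.428
F1               0.500           1.000
F2               0.466           0.517
```

Every error-free F1 lands exactly at (0.5, 1.0) — heterozygous at every
AIM with equal ancestry from both parents — while 40-replicate backcross
and F2 means scatter around (0.25, 0.5) and (0.5, 0.5), the Mendelian
expectations. The other examples cover block assignment
(`02_block_ancestry.py`), masked consensus and coverage
(`03_masked_consensus.py`), synthetic-hybrid heterozygosity
(`04_synthetic_hybrid.py`) and checklist/niche overlap
(`05_niche_overlap.py`).

An end-to-end run with one config:

```bash
hybriddiag all --seed 1 --outdir out/
# or in Python:
# from hybriddiag.pipeline import RunConfig, run_pipeline
# report = run_pipeline(RunConfig(seed=1))
```

The JSON report carries every stage's statistics (coverage fraction, block
tally and balance p-value, h, H, window heterozygosities, niche counts and
overlap geometry) plus the fully resolved configuration.

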