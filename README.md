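# popgenkit

Population-genetic analysis of aligned locus samples: nucleotide diversity
and divergence, neutrality tests with coalescent-simulated nulls, linkage
disequilibrium and recombination, gene-conversion detection, haplotype
structure, and codon-based selection models — the toolkit needed to analyze
a resequenced gene region (e.g. a *Drosophila* locus sampled across natural
populations) end to end from a FASTA alignment to a reproducible results
bundle.

## What it computes

Given a multiple alignment with a region annotation (flank / exon / intron)
and optional population, species and haplotype-group labels:

- **Diversity & divergence** — π (average pairwise differences per site),
  Watterson's θ = S/(a₁·N), per-region masks (all / coding / synonymous /
  nonsynonymous / silent / intron / flank), Jukes–Cantor-corrected
  divergence *K* to an outgroup, GC content, sliding windows.
- **Site classification** — synonymous/nonsynonymous attribution of coding
  polymorphisms via minimal mutational pathways, Nei–Gojobori counting of
  synonymous and nonsynonymous site opportunities.
- **Neutrality tests** — Tajima's *D*, Kelly's Z<sub>nS</sub>, Wall's *B*
  and *Q*, each with an empirical p-value from a coalescent null simulated
  conditional on (n, S, L, ρ); the McDonald–Kreitman test (Fisher exact)
  and the multilocus HKA test.
- **LD & recombination** — pairwise D, D′, r²; the Hudson–Kaplan
  four-gamete minimum number of recombination events R<sub>m</sub>; a
  simulation-matched moment estimate of ρ = 4N₀r per site.
- **Gene conversion** — Sawyer's permutation scan over condensed silent
  polymorphic sites: SSCF/SSUF statistics, per-fragment significance
  against each sequence pair's own permutation null, mean significant
  tract length.
- **Haplotype structure** — Kimura two-parameter distances,
  neighbor-joining trees with bootstrap support, K<sub>st</sub>/F<sub>st</sub>
  group differentiation with label-permutation p-values, fixed/shared/private
  polymorphism contrasts, an exact Mann–Whitney test for mRNA folding-energy
  (ΔG) differences between groups.
- **Codon selection models** — GY94 codon models M0, M3, M7, M8, a dual
  synonymous×nonsynonymous rate-variation model, and a coding/noncoding ζ
  model, fit by maximum likelihood with likelihood-ratio tests and naive
  empirical Bayes site posteriors.
- **Coalescent simulation** — msprime-backed neutral samples with
  recombination, in θ mode or conditioned on a fixed number of segregating
  sites, streamed or written as ms-like text.
- **Synthetic data** — seeded generators with ground truth: neutral
  annotated loci, dimorphic samples with planted fixed differences,
  conversion tracts and indels, and codon alignments under dN/dS site
  mixtures.

## Worked example

Generate a synthetic two-haplogroup locus with known truth, then analyze it
with the CLI (output below is what the commands actually print):

```bash
$ popgenkit synth dimorphic --out demo --seed 42 --length 2000
$ cd demo

$ popgenkit diversity dimorphic.fasta --regions dimorphic.regions.tsv --mask silent
n       28
sites   1990
S       21
singletons      3
pi      0.00428
theta   0.00271
gc      0.5441

$ popgenkit neutrality dimorphic.fasta --regions dimorphic.regions.tsv --reps 1000 --seed 7
TajimaD 2.1315  p=0.0180
ZnS     0.5111  p=0.0280
WallB   0.3000  p=0.1149
WallQ   0.3226  p=0.1548

$ popgenkit haplo dimorphic.fasta --labels dimorphic.labels.tsv --bootstrap 200 --permutations 1000 --seed 7
Kst     0.859   p=0.0010
Fst(hsm)        0.922
fixed_differences       19
shared_polymorphisms    0
```

The strongly positive Tajima's *D*, elevated Z<sub>nS</sub>, and the
K<sub>st</sub> permutation test all pick up the planted dimorphic haplotype
structure, and the 19 planted fixed differences are recovered exactly
(`dimorphic.truth.json` records the ground truth).

## Reproducible pipelines

A whole analysis is driven by one YAML/JSON config:

```yaml
seed: 1
loci:
  - name: locusA
    fasta: locusA.fasta
    regions: locusA.regions.tsv
    labels: locusA.labels.tsv
    outgroup: sister_sp_1      # optional, enables divergence/MK/HKA
diversity: {masks: [all, silent]}
neutrality: {reps: 10000, rho_per_site: 0.006}
recombination: {estimate_rho: true}
geneconv: {permutations: 10000}
haplotypes: {permutations: 1000}
```

```bash
popgenkit pipeline run.yaml --out results/
```

The output bundle contains per-locus TSVs, `results.json`, and
`manifest.json` recording package and dependency versions, the master seed
and every derived per-analysis seed, SHA-256 hashes of all inputs and
outputs, and the estimator variants used. Re-running with the same config
and seed reproduces the bundle byte for byte.

`scripts/acceptance.py --seed 1 --out acceptance.json` computes the
package's headline quantities (simulator calibration, diversity and
neutrality statistics on seeded synthetic data, ρ recovery, planted-truth
passthrough, codon-model parameter recovery) into a single JSON report.
`scripts/fetch_accessions.py` downloads the deposited GenBank accession
sets used for the optional, network-dependent regression stage.

## Layout

| Module | Contents |
| --- | --- |
| `popgenkit.locus` | alignment/annotation I/O, site classification, indels |
| `popgenkit.diversity` | π, θ, divergence, GC, sliding windows |
| `popgenkit.neutrality` | Tajima's D, ZnS, Wall's B/Q, MK, HKA, haplotype test |
| `popgenkit.ld` | pairwise LD, Hudson–Kaplan R_m, ρ estimation |
| `popgenkit.geneconv` | Sawyer gene-conversion scan |
| `popgenkit.coalescent` | msprime-backed simulation, null distributions |
| `popgenkit.codon` | GY94 site models, LRTs, NEB posteriors |
| `popgenkit.haplotypes` | K2P/NJ trees, Kst/Fst, group contrasts, ΔG test |
| `popgenkit.synthetic` | seeded generators with ground truth |
| `popgenkit.pipeline`, `popgenkit.cli` | config-driven runs, command line |

See `docs/methods.md` for the statistical methods, parameter conventions
and numerical choices.
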