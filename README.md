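# allomap

Functional mapping of **allometric QTLs** from longitudinal leaf traits
measured under two planting densities.

When plants grow in dense stands they sense neighbor shading and respond
with the shade-avoidance syndrome: longer petioles, repositioned and
reshaped leaves. `allomap` asks *which loci control the scaling between
leaf traits* during that response, rather than which loci shift any single
trait. It is built for recombinant inbred line (RIL) populations — two
homozygous genotype classes per biallelic SNP — phenotyped weekly for
petiole length P (cm), leaf length L (cm) and leaf area A (cm²) under a
high- and a low-density treatment with possibly different numbers of
timepoints (7 and 8 weeks by default).

## Model

Two trait pairs carry the biology: L→A (leaf *shape*) and P→L (leaf
*position*). Within genotype class j and density d, the response
trajectory of progeny i follows the allometric power law evaluated at the
progeny's own predictor trajectory,

    mu_ijd(t) = alpha_jd * x_id(t) ^ beta_jd ,

and the stacked residual vector over (high weeks; low weeks) is
multivariate normal with a first-order structured antedependence (SAD(1))
covariance Sigma = Lambda Sigma_eps Lambda', parameterized by the
innovation-propagation coefficients (phi_h, phi_l) and one innovation
variance sigma². Each SNP is tested with the likelihood ratio

    LR = -2 (log L0 - log L1),     LOD = LR / (2 ln 10),

where H0 pools the two genotype classes and H1 gives each class its own
(alpha, beta) per density. Genome-wide thresholds come from progeny-level
permutations of the phenotype-to-genotype assignment (max-LR quantile).
A second nested test per significant SNP (alpha_jh = alpha_jl,
beta_jh = beta_jl) probes genotype-by-density interaction. Effects are
summarized as additive-effect curves a_d(x) = (mu_1d(x) - mu_0d(x))/2 and
as PVE = 4pq a² relative to the observed phenotypic variance.

Because no public dataset accompanies this design, `allomap.simulate`
generates study-scale data (84 progenies, 5 chromosomes, S-shaped growth,
power-law trait chains, SAD(1) residuals, causal loci with genotype- and
density-specific allometry) with a truth record for validation; see
`docs/methods.md` for every modeling choice and its rationale.

## Worked example

```python
import numpy as np
import allomap as am

# 84 RIL progenies, 150 SNPs, causal P-L locus at snp index 15
gm, traits, truth = am.make_paper_like_dataset(seed=11, snps_per_chrom=30)

cfg = am.ScanConfig(n_perm=99, level=0.05, n_starts=1)
records = am.genome_scan(gm, traits, am.PAIR_PL, cfg)
thr = am.permutation_threshold(gm, traits, am.PAIR_PL,
                               n_perm=99, level=0.05, seed=12, config=cfg)
idx = truth["qtls"][0]["snp_index"]
print(f"causal LOD  {records[idx].lod:.2f}")
print(f"LOD threshold (5%)  {thr.lod_threshold:.2f}")

table = am.significant_snps(records, thr.lr_threshold)
print(f"significant SNPs  {len(table)}")
```

prints

```
causal LOD  8.04
LOD threshold (5%)  3.76
significant SNPs  18
```

The causal locus clears the genome-wide 5% permutation threshold
(LOD 8.04 vs 3.76); the eighteen significant SNPs are the causal SNP and
its linked neighbors, all on the causal chromosome. `am.pve(...)` then converts the
fitted genotype curves into percent variance explained, and
`am.density_interaction_test(...)` asks whether the locus rescales the
allometry differently under the two densities.

The same pipeline is scriptable from the shell:

```bash
allomap simulate --seed 1 --out-dir out/sim
allomap scan --genotypes out/sim/genotypes.tsv \
             --phenotypes out/sim/phenotypes.csv --pair both --out-dir out
allomap permute --genotypes out/sim/genotypes.tsv \
                --phenotypes out/sim/phenotypes.csv \
                --pair PL --n-perm 1000 --level 0.01 --seed 1 --out out/thr_PL.json
allomap report --scan-table PL out/scan_PL.tsv --threshold PL out/thr_PL.json \
               --phenotypes out/sim/phenotypes.csv --out-dir out/report
```

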