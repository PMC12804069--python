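# snp-prior-gs

Genomic prediction with SNP prioritization for closed cattle populations:
maternal-effects GBLUP over plain, marker-subset and SNP-weighted genomic
relationship matrices, evaluated by replicated cross-validation.

## The problem

In small, closed beef-cattle herds (a highly inbred Hereford line with
effective population size near 8, and a closed composite herd), genomic
prediction of growth traits — birth (BW), weaning (WW) and yearling weight
(YW) — must work with one to a few thousand genotyped animals and ~65–70k
SNP after quality control. One route to squeezing more accuracy out of such
data is to *prioritize* markers: either keep only a promising subset in the
genomic relationship matrix, or keep all markers but weight them unequally.
This package implements and evaluates both routes:

* **temporal-cohort Fst** — per-SNP Weir & Cockerham (1984) fixation index
  between animals born up to 2010 and animals born after 2010, flagging
  loci moved by drift/selection in the closed herd;
* **backsolved SNP effects** — a GWAS-style scan obtained by backsolving
  per-SNP effects from GEBV, with iterative SNP reweighting of the
  relationship matrix (weighted GBLUP).

## The model

Phenotypes follow a maternal-effects animal model

```
y = Xb + Za + Wm + e,
[a; m] ~ N(0, G0 ⊗ G),   G0 = [[σa², σam], [σam, σm²]],   e ~ N(0, Iσe²)
```

where `b` holds sex and contemporary-group (birth year × dam age) effects,
`a` are direct and `m` maternal breeding values, and `W` links each record
to its dam. `G` is the VanRaden genomic relationship matrix
`G = M D M′ / Σⱼ 2pⱼqⱼ` over centered allele dosages `M`, with `D = I`
(plain), a marker subset, or per-SNP weights `dᵢ`. Variance components are
fixed inputs taken from the literature (e.g. Line 1 BW:
σa² = 100.24, σm² = 95.18, σam = −56.31, σe² = 150.32 kg²); solving
Henderson's mixed-model equations yields GEBV for every genotyped animal,
phenotyped or not. SNP effects are backsolved as
`ŝ = D M′ G⁻¹ â / Σ 2pq` and iterative weights use the per-SNP variance
`dᵢ = ŝᵢ² · 2pᵢqᵢ` (mean-normalized, 10 iterations by default).

Prediction quality is scored on a random 2/3 : 1/3 train/validation split,
replicated 5 times: accuracy = cor(GEBV, y − Xb̂) in validation, the
inflation slope of GEBV on corrected phenotypes, and their MSE.

Because the real herd data are restricted, the package ships a
closed-population simulator (`snp_prior_gs.simulate`) with two presets —
`inbred_line` and `composite` — that gene-drops linked genotypes through a
drift-only pedigree and builds phenotypes from direct + maternal QTL and
polygenic effects with known truth.

## Worked example

```python
import snp_prior_gs as sg
from snp_prior_gs.simulate import SimScenario, simulate_dataset

sc = SimScenario.preset("inbred_line", n_generations=6,
                        offspring_per_generation=60,
                        markers_per_chromosome=100, n_chromosomes=4,
                        n_qtl=40, seed=3)
ds = simulate_dataset(sc)                      # 380 animals, 400 markers
g, log = sg.apply_qc(ds.genotypes)             # MAF/call-rate/HWE filters
print(f"QC kept {log.n_retained}/{log.n_input} markers")
g = sg.impute_missing_mean(g, sg.compute_allele_frequencies(g))
for arm in ("all_snp", "preselect_effect", "weighted_effect"):
    rep = sg.run_scenario(g, ds.phenotypes, ds.pedigree, sc.varcomp, arm,
                          trait="BW", n_replicates=5, master_seed=1,
                          truth=ds.truth)
    row = rep.summary_row()
    print(f"{arm:>18}: nSNPs={row['nSNPs']:>4} accuracy={row['accuracy']} "
          f"cor(GEBV, true BV)={rep.mean_accuracy_true:.3f}")
```

prints

```
QC kept 343/400 markers
           all_snp: nSNPs= 343 accuracy=0.257 (0.063) cor(GEBV, true BV)=0.492
  preselect_effect: nSNPs=  34 accuracy=0.266 (0.035) cor(GEBV, true BV)=0.437
   weighted_effect: nSNPs= 343 accuracy=0.187 (0.056) cor(GEBV, true BV)=0.395
```

`accuracy` is the mean (SD) over the 5 replicates of the correlation
between validation GEBV and corrected phenotypes — modest here because the
corrected phenotype contains the full residual; the correlation with the
simulator's *true* breeding values shows the underlying prediction signal.
At this toy scale the 10%-subset scan (34 markers) already rivals the full
panel.

The same pipeline is available from the shell:

```
snp-prior-gs simulate --preset inbred_line --seed 5 --out sim
snp-prior-gs qc  --genotypes sim/genotypes --out qcd
snp-prior-gs fst --genotypes sim/genotypes --pedigree sim/pedigree.csv \
                 --phenotypes sim/phenotypes.csv --out fst.tsv
snp-prior-gs run --genotypes sim/genotypes --pedigree sim/pedigree.csv \
                 --phenotypes sim/phenotypes.csv --trait BW \
                 --scenario preselect_fst --replicates 5 --seed 1 --out run1
```

## Layout

```
src/snp_prior_gs/
  simulate.py      closed-population simulator (pedigree, gene drop, truth)
  io.py            PLINK .bed/.bim/.fam codec, tables, config
  qc.py            allele frequencies, MAF/call-rate/HWE filters, imputation
  relationship.py  plain / subset / weighted G, ridge conditioning
  fst.py           temporal cohorts, Weir–Cockerham Fst, selections, weights
  gblup.py         MaternalGBLUP model + results (Henderson MME)
  snp_effects.py   backsolved SNP effects, iterative weighting, GWAS export
  evaluation.py    CV splits, metrics, the five scenario arms
  cli.py           snp-prior-gs command-line interface
docs/methods.md    modelling and simulation notes
tests/             pytest suite with independent brute-force oracles
```
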