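# islescan

A desk-scale toolkit for case/control genome scans in small, structured
populations: genotype/site filtering, kinship and unrelated-set
selection, LD pruning and decay, sliding-window selection statistics
with outlier-peak intersection, runs of homozygosity, and PCA — plus a
synthetic two-island cohort simulator with known planted truth so the
whole pipeline is testable without external data.

## Modules

| module      | what it does |
|-------------|--------------|
| `simcohort` | Balding–Nichols two-island simulator: 3 cohorts (12 cases, 11 same-island controls, 9 second-island controls by default), planted differentiated loci with sweep-like footprints, planted autozygous tracts, depth/GQ/missingness model, truth table, gene/TFBS/neutral BED tracks |
| `variants`  | VCF 4.2 read/write (biallelic SNVs, GT:DP:GQ), per-call depth (60–250 % of individual mean) and GQ < 20 masking, call-rate ≥ 0.95 and MAF ≥ 0.01 site filters, Ts/Tv, polarization |
| `kinship`   | KING-robust pairwise kinship; exact maximum unrelated subset at the 0.0884 2nd-degree threshold |
| `linkage`   | genotypic r² (pairwise-complete dosages), 50/5/0.2 greedy LD pruning (0.90 strong-prune variant), LD-decay curve with the r² = 0.2 crossing distance |
| `winstats`  | windowed π, Weir–Cockerham Fst (weighted Σa/Σ(a+b+c)), Tajima's D, control−case deltas, genome-wide z-scores; 100 kb/10 kb and 50 kb/1 kb window specs |
| `outliers`  | top-1 % windows, peak merging, Fst ∩ Δπ ∩ ΔTajima's D candidate regions, per-SNV allelic Fst and |ΔAF| within ±150 kb, ΔAF > 0.45 selection, nearest-gene/TFBS annotation |
| `roh`       | 50-SNV sliding-window ROH calling (≤ 1 het, ≤ 2 missing per window; 0.05 window proportion; ≥ 2 SNVs, ≥ 100 kb, ≥ 1 SNV/50 kb, ≤ 100 kb gaps), FROH, per-SNV cohort sharing tracks, >75 %/<75 % candidate ROH regions |
| `structure` | PCA on variance-standardized dosages over neutral ∩ pruned sites |

## CLI

Every stage is exposed as a subcommand of `islescan`:

```sh
islescan simulate --config cfg.json --out study/ --seed 1
islescan filter   --vcf study/cohort.vcf --out filtered.vcf --report report.tsv
islescan kinship  --vcf filtered.vcf --out kinship.tsv --keep keep.txt
islescan prune    --vcf filtered.vcf --out pruned.tsv
islescan lddecay  --vcf filtered.vcf --out decay.tsv
islescan scan     --vcf filtered.vcf --design study/design.tsv \
                  --size 50000 --step 1000 --out scan.tsv
islescan outliers --scan scan.tsv --vcf filtered.vcf --design study/design.tsv \
                  --genes study/genes.bed --tfbs study/tfbs.bed \
                  --out-regions regions.tsv --out-snvs snvs.tsv
islescan roh      --vcf pruned.vcf --design study/design.tsv \
                  --out-runs runs.tsv --out-sharing sharing.tsv \
                  --out-candidates candidates.bed
islescan pca      --vcf filtered.vcf --neutral study/neutral.bed \
                  --pruned pruned.tsv -k 10 --out scores.tsv
```

Interval conventions: BED inputs/outputs are 0-based half-open; all TSV
outputs are 1-based inclusive.

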