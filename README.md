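# mosascan

Mosaic single-nucleotide-variant analysis for diagnostic exome cohorts:
allele-fraction-threshold mosaic calling, trio inheritance-origin
assignment with a UPD/AOH inconsistency flag, cohort summary statistics
over a bundled 120-record clinical variant table, and read-count-level
simulations that validate the threshold policy.

## What's inside

| Module | Purpose |
| --- | --- |
| `mosascan.cohort` | Domain types, the bundled cohort tables (80 proband + 40 parental/grandparental records), HGVS consequence classification, CpG-context annotation |
| `mosascan.caller` | AAF estimation with exact Clopper–Pearson CIs, fixed (0.36/0.64 diploid, 0.10 hemizygous) and depth-adaptive threshold classification, Spearman concordance, common-SNP filtering |
| `mosascan.trio` | Trio origin assignment (de novo / inherited / parental mosaic) and the AAF-inconsistency (suspected UPD/AOH) flag |
| `mosascan.stats` | Cohort aggregates: category/classification/consequence counts, group AAF means, recurrent genes, Ras/PI3K-AKT-mTOR pathway burden, Welch/Student group comparison, attribution rates |
| `mosascan.sim` | Binomial read-count sampling, operating characteristics of threshold policies, heterozygous-AAF distributions, synthetic trio cohorts with planted truth |
| `mosascan.vcfio`, `mosascan.cli` | VCF 4.2 (FORMAT AD/DP) + PED readers, call/report writers, umbrella CLI |

## CLI

```sh
# classify every per-sample observation of a VCF against the policy
mosascan call --vcf in.vcf --ped fam.ped --out calls.tsv \
    [--mode fixed|depth-adaptive --het-lower 0.36 --het-upper 0.64 \
     --hemi-min 0.10 --hemi-upper 0.90 --min-depth 20 --alpha 0.05]

# trio origin assignment with UPD-suspicion flagging
mosascan trio --vcf trio.vcf --ped fam.ped --out origins.tsv

# cohort summary report (bundled tables or your own TSV)
mosascan summarize --fixture builtin --out report.json

# heterozygote AAF interval for a given depth
mosascan thresholds --depth 48 --alpha 0.05 --method normal

# simulations
mosascan simulate oc --depths 20,40,130 --fractions 0.1,0.3,0.5 \
    --reps 10000 --seed 1 --out oc.tsv
mosascan simulate cohort --n-variants 50 --seed 1 --out-dir sim/
```

A TOML file passed as `mosascan --config config.toml <cmd>` supplies
per-subcommand option defaults (section names match subcommand names);
explicit flags override it.

## Notes

- Internally AAFs are fractions in [0, 1]; the bundled table stores the
  printed percentages. Display rounding is half-to-even at one decimal.
- Diploid thresholds are strict inequalities ("less than 36%, greater
  than 64%"); the hemizygous candidate band [0.10, 0.90] is inclusive.
- Coordinates are 1-based inclusive (VCF convention); GRCh37
  pseudoautosomal X regions are treated as diploid in both sexes.
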