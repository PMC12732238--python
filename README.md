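# pepscreen

Analysis pipeline for HLA class I immunopeptidome tables: FDR filtering,
%rank-based binder assignment, TCR recognition-motif construction and
motif-based screening for cross-reactive self-peptide candidates,
cross-peptidome set analytics, ERAP1 haplotype calling, and
hybridoma-assay readout normalization. A deterministic synthetic-data
generator stands in for deposited immunopeptidomes so every stage runs and
is validated offline.

## Modules

| module | purpose |
| --- | --- |
| `pepscreen.peptidome_io` | read/validate/write peptide tables, inclusive q-value (FDR) filtering, deduplication, exact peptide-to-proteome mapping |
| `pepscreen.binder_assignment` | strong/weak/non-binder calls at 0.5%/2% rank cutoffs, best-binder allele assignment, binder length distributions |
| `pepscreen.tcr_motif` | position-probability/log-odds motif from a stimulatory ligand panel, anchor + TCR-contact constraints, peptidome screening |
| `pepscreen.overlap_analytics` | upset-style exclusive intersection counts, pairwise overlap fractions |
| `pepscreen.erap1_haplotyping` | ERAP1 diplotype calls from phased 9-SNP genotypes via an editable JSON key (the bundled key is a placeholder, not authoritative) |
| `pepscreen.stimulation_normalization` | net and relative (positive-control-referenced) stimulation with replicate aggregation |
| `pepscreen.synthetic_data` | seeded peptidome suites with gold labels, ligand panels (alanine scan / anchor exchange / library), planted proteomes |

## CLI

All stages are exposed under a single `pepscreen` entry point:

```sh
pepscreen simulate --seed 17 --out fixtures/           # synthetic suite + gold labels
pepscreen filter --fdr 0.01 --per-category --in fixtures/SYN-A.tsv --out filtered.tsv
pepscreen assign --in filtered.tsv --out calls.tsv     # adds assigned_allele/category/rank
pepscreen motif-build --panel panel.tsv --out motif.json
pepscreen screen --motif motif.json --in filtered.tsv --threshold 0 --out candidates.tsv
pepscreen overlap --in a.tsv --in b.tsv --in c.tsv --in d.tsv --out upset.json
pepscreen erap1 --in genotypes.tsv --out diplotypes.tsv
pepscreen normalize --background FALK --positive ADAMTSL5 --in readings.tsv --out norm.tsv
```

Peptide tables are TSV (CSV accepted via `.csv` suffix) with `sequence`,
`q_value`, optional `category`, and one %rank column per allele named as
the allele (e.g. `HLA-C*06:02`). Genotypes are a 9-column rsID table with
`A|G`-style phased pairs, or a minimal VCF (GT extraction only).

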