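# gage

**Genome Analysis and Genome Editing (GAGE)** — an in-silico toolkit for
CRISPR/Cas12a-based plant species identification.

Authenticating high-value plant material (saffron stigmas vs dyed safflower,
lotus or corn) calls for a DNA test that is fast, sensitive and specific.
The GAGE workflow finds *target sequences* — 25-bp genome windows made of a
4-nt protospacer-adjacent motif (PAM, `TTTV` for LbCas12a) plus a 21-nt
protospacer — that occur in the subject species' genome and nowhere within
three mismatches in the genomes of its adulterants. A crRNA designed
against such a target arms Cas12a; in the presence of subject DNA the
enzyme's collateral ssDNA cleavage shreds a fluorophore–quencher reporter
and the sample lights up.

This package implements the computational half of that workflow:

| step | module | what it does |
| --- | --- | --- |
| target enumeration | `gage.target_library` | all PAM-bearing 25-mers of a genome, deduplicated with copy numbers and density (`L / total`) |
| annotation statistics | `gage.annotation_classify` | targets per class (unannotated / annotated / coding genes / CDS / ncRNA) and CDS gene coverage |
| region extraction | `gage.target_library` | targets inside a barcode region (e.g. ITS2), keeping genome-wide copy numbers |
| specificity screen | `gage.specificity` | Cas-OFFinder-style mismatch-tolerant search; verdict: no adulterant site within 3 mismatches |
| crRNA design | `gage.crrna_design` | direct repeat (5') + transcribed 21-nt spacer (3') |
| detection calling | `gage.assay_detection` | Welch t-test vs negative control at P < 0.01 with a direction guard; LOD of a dilution ladder |
| synthetic data | `gage.synth_data` | seeded genomes/annotations/adulterants/assays with exact planted ground truth |

## Worked example

```python
from gage import (PlantedSite, SyntheticGenomeSpec, generate_genome,
                  generate_adulterant, scan_targets, density,
                  select_final_targets, design_crrna)

# a subject genome carrying a 7-copy candidate target
site = PlantedSite(kmer="TTTA" + "ACGTT" * 4 + "G", copies=7)
genome, truth = generate_genome(
    SyntheticGenomeSpec(length=50_000, seed=7, planted=[site]))

lib = scan_targets(genome)
rec = lib.records[site.kmer]
print(lib.total_count, lib.dedup_count, round(density(lib), 1))
print(rec.copy_number, rec.pam, rec.protospacer)

adulterant = generate_adulterant(genome, divergence=0.35, seed=1)
result = select_final_targets([rec], genome, {"adulterant": adulterant})
print(len(result.selected), result.selected[0][1].passes)
print(design_crrna(rec).full)
```

prints

```
1233 1227 40.6
7 TTTA ACGTTACGTTACGTTACGTTG
1 True
UAAUUUCUACUAAGUGUAGAUACGUUACGUUACGUUACGUUG
```

— 1233 candidate windows in 50 kb (one per 40.6 bp), the planted target
recovered with all 7 genomic copies, its PAM/protospacer decomposition, a
passing specificity verdict against a 35%-diverged adulterant, and the
42-nt crRNA (21-nt LbCas12a direct repeat + 21-nt spacer, T→U).

The same workflow is scriptable from the shell:

```bash
gage build-library --genome genome.fa --out lib.tsv
gage region-targets --library lib.tsv --bed its2.bed --out region.tsv
gage classify --library lib.tsv --gff annotation.gff3 --out table.tsv
gage screen --library lib.tsv --subject genome.fa \
     --adulterant safflower=ct.fa --adulterant lotus=nn.fa --out screen.tsv
gage design-crrna --library lib.tsv --kmer TTTAACGTT... --out crrna.tsv
gage detect --tsv plate.tsv --control CK --lod --out calls.tsv
gage simulate genome --spec spec.json --out-prefix sim/
```

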