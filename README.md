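# peppr

Peptide-pattern subfamily discovery and CAZyme gene mining.

`peppr` finds and functionally annotates genes encoding glycoside hydrolases
(GH families 1–131) and lytic polysaccharide monooxygenases (LPMOs; CAZy
auxiliary-activity families AA9–AA11) directly in genome assemblies, without
alignment or gene models. It is aimed at researchers mining fungal (or other
microbial) genomes for plant-cell-wall-degrading enzymes and comparing
enzyme repertoires across species.

## The method

**Subfamily discovery (PPR — Peptide Pattern Recognition).** A CAZy protein
family is partitioned into subfamilies defined by shared short peptides. A
*conserved peptide* is a hexapeptide present in at least 20% of a group's
members; a *subfamily* is a group of ≥ 5 proteins that each contain at least
10 peptides from the group's list of at most 70 conserved hexapeptides.
Groups are peeled off greedily (largest first, then the largest among the
remaining proteins, …) until fewer than five proteins can be grouped. Each
group is a fixed point of the alternation

> profile ← conserved peptides of the members; members ← all proteins with
> ≥ 10 profile peptides,

seeded from the most widely shared peptides. Subfamilies containing
biochemically characterized members inherit those members' EC numbers; every
AA9/AA10/AA11 subfamily is labeled `LPMO`.

**Genome annotation (Hotpep — homology to peptide patterns).** Contigs
shorter than 500 bp are discarded; the rest are split into 2000-base
fragments with 100-base overlap and translated in all six reading frames.
Each frame is scored against every subfamily profile: for matched peptides
with within-subfamily frequencies f₁…fₙ the *frequency score* is Σfᵢ. A
frame is a significant hit when it

1. contains ≥ 3 conserved peptides of the subfamily,
2. has frequency score > 1.0 (strict), and
3. the peptides cover ≥ 10 residues (three hexapeptides can cover 8–18).

Within a family the frame is assigned to the subfamily with the highest
frequency score; scores are never compared *between* families, so one
sequence can hit several families (CAZymes are modular). Same-family hits
closer than 5800 bases on a contig are merged into one gene call, which
inherits the subfamily (and thus the predicted EC function) of its
best-scoring hit. Full-length proteins can be screened the same way
(`--protein-mode`), which rescues genes whose fragments fall below the
thresholds.

**Genome comparison.** Gene calls are aggregated into per-genome counts by
family and by predicted function, laid out as a count matrix, and clustered
with Ward's method on Euclidean distances; function counts can be collapsed
into cellulose / hemicellulose / other activity classes (cellulose =
EC 3.2.1.4, 3.2.1.21, 3.2.1.91, 3.2.1.176 plus AA9 LPMOs).

## Worked example

The package ships a planted-structure simulator, so the full pipeline runs
without any downloads:

```sh
peppr simulate  --out-dir sim --seed 3 --subfamilies 2 --members 8 \
                --vocab 20 --protein-length 150 --decoys 3 --genes 4
peppr ppr-build --proteins sim/family.faa --annotations sim/family.ec.tsv \
                --family-name GH5 --out-dir profiles
peppr annotate  --genome sim/genome.fna --profiles profiles --out out/toy
```

which logs

```
INFO peppr: simulated 19 proteins, 4 contigs, 4 planted genes
INFO peppr: family GH5: 2 subfamilies, 3 proteins ungrouped
INFO peppr: genome mode: 4/4 contigs kept, 4 hits, 4 gene calls
```

— the two planted subfamilies are recovered exactly (the 3 ungrouped
proteins are the random decoys), and each planted gene yields one gene call.
`out/toy.annotations.tsv` then contains one line per call, e.g.

```
contig      start  end  strand  family  subfamily  n_peptides  freq_sum  residues_covered  function
contig_000  1      906  +       GH5     1          32          24.3750   121               3.2.1.4
contig_001  1      906  +       GH5     2          24          21.0000   122               3.2.1.21
```

`n_peptides` is the number of distinct profile hexapeptides found in the
best frame (here more than the 20 planted ones, because junctions between
planted peptides are themselves conserved windows), `freq_sum` their summed
subfamily frequencies, and `function` the EC number transferred from the
subfamily's characterized members. `peppr profile` and `peppr cluster`
aggregate such tables into count matrices and a Newick dendrogram.

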