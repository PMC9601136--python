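# metamerge

Cross-site metagenome reconstruction and spatial covariation analysis of
microbial gene expression.

## The problem

Shotgun metagenome/metatranscriptome studies of the gut usually assemble
and annotate each sample separately, which makes it hard to say whether
*the same gene* changes activity between intestinal sites, and leaves
genes absent from COG/KEGG ("unknown" genes) without any functional
reading. `metamerge` is a desk-scale pipeline for communities sampled at
several **ordered** sites (cecum → transverse colon → feces) in two or
more individuals. It:

1. **Merges per-site scaffold sets into one common reference** by
   end-anchored overlap detection (k-mer seeding, gapless extension),
   greedy deterministic joining and containment removal — so every gene
   has one coordinate system across all sites, with per-base provenance.
2. **Quantifies gene expression at two levels**: whole-community TPM, and
   *per-cell* expression — mRNA reads-per-kilobase divided by the gene's
   mean DNA depth, which cancels species abundance and approximates
   activity per bacterium.
3. **Transfers function to unknown genes by spatial covariation**: gene
   clusters get an expression profile over the (individual × site)
   samples; pairs are scored with Lee's bivariate spatial association
   statistic

   L(x,y) = [n / Σᵢ(Σⱼ vᵢⱼ)²] · Σᵢ (Σⱼ vᵢⱼ(xⱼ−x̄))(Σⱼ vᵢⱼ(yⱼ−ȳ)) / (‖x−x̄‖‖y−ȳ‖)

   over site-adjacency weights V (block-diagonal across individuals,
   row-standardised). Known (COG) clusters sharing a KEGG-style reaction
   provide an ROC benchmark; the transfer threshold θ is chosen so the
   empirical false positive rate stays under a target (default 0.05), and
   unknown clusters linked at L ≥ θ inherit the known clusters' labels,
   with Fisher/Benjamini–Hochberg enrichment on top.
4. **Grades reconstructions** with N10–N100 contiguity curves, a chimera
   index, the nonchimeric rate, MAL/TAL and a composite score
   (N50_broken × (1−CI) × TAL/total).
5. **Simulates full synthetic studies** — genomes with ORF-valid genes,
   abundance gradients, designed covariant expression pairs, per-site
   fragmentations with cross-site overlaps, and paired-end DNA/mRNA reads
   with complete truth tables — so every stage is testable end to end.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

The demo simulates a community (6 genomes of 30–50 kb, 2 individuals ×
3 sites, error-free reads), runs merge → genes → quant → covary → eval in
memory, and prints a property summary:

```sh
metamerge demo --seed 0
```

prints (abridged):

```json
{
 "individuals": {
  "ind1": {
   "n_merged_scaffolds": 6,
   "n_exact_genome_reconstructions": 6,
   "nonchimeric_rate": 100.0,
   "nstat_dominance": true,
   "rna_mapping_rate_merged": 100.0,
   "rna_mapping_rate_sites": {"cecum": 86.2, "transverse_colon": 71.5, "feces": 73.8},
   "chimera_index": 0.0,
   "cpm": 38511.0
  }
 },
 "tpm_sum_max_rel_err": 2.2e-16,
 "covariation_community": {
  "auc": 0.937,
  "theta": 0.762,
  "achieved_fpr": 0.0497,
  "fpr_at_target_ok": true
 }
}
```

Reading it: all six genomes were reconstructed byte-exactly from the
three per-site fragmentations, so the nonchimeric rate is 100% and the
chimera index 0; the merged reference recovers 100% of mRNA reads while
the best single-site assembly maps only ~86%; TPM conserves its 10⁶ sum
to machine precision; and the covariation benchmark on known clusters
reaches AUC 0.94 with a threshold holding the false positive rate under
the 0.05 target.

The staged file pipeline (with manifest, checksums and resume) runs the
same analysis against a working directory:

```sh
metamerge run -o runs/demo          # simulate + all stages
metamerge merge --sites a.fasta b.fasta c.fasta --mL 1000 --c 95 --hco 100 -o merged.fasta
metamerge genes --ref merged.fasta -o genes.gff3 --proteins prot.fasta
metamerge eval --assembly merged.fasta --truth genomes.fasta -o eval.tsv
```

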