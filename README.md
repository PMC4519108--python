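# ssrforge

Cross-genotype microsatellite (SSR) marker discovery for non-model genomes.

Plant breeding programs that lack a reference genome still need co-dominant,
cheaply scorable markers. Given *de novo* assemblies of two genotypes (for
example the two parents of a mapping population), `ssrforge` predicts which
simple sequence repeats will be length-polymorphic between them *before any
wet-lab validation*: it enriches each assembly for long contigs, scans for
perfect tandem repeats, designs unique flanking primer pairs, matches
contigs reciprocally between the genotypes, and calls each shared repeat
polymorphic or monomorphic from its tract lengths. Companion modules screen
out organellar/repetitive contigs by homology keywords, hard-filter VCFs and
tally nucleotide substitution spectra, and produce the standard panel
summary tables. A synthetic-data module generates paired genomes with
planted, verified truth so the whole pipeline is testable offline.

## Method in brief

An SSR locus is a maximal perfect tandem repeat of a primitive motif with
period p ∈ {2,…,7} and tract length ℓ = p·c ≥ 20 bp (c = copy number).
For a locus shared by genotypes P1 and P2 (same rotation-canonical motif,
aligned positions within a 10 bp tolerance):

    verdict = polymorphic   if |ℓ₁ − ℓ₂| ≥ p
              monomorphic   if |ℓ₁ − ℓ₂| < p
              no_match      if no counterpart exists

Since perfect tracts differ by whole periods, one period is the smallest
observable length difference. The comparison is run in both directions
(P1 queried against P2 and vice versa, E ≤ 1e-9 for ingested alignment
tables) and the final panel keeps only loci polymorphic in *both*
directions. Contig enrichment keeps contigs strictly longer than the
assembly N50; panel rates use percent polymorphic = poly/(poly+mono) over
amplified markers and percent failure = failed/all-tested.

## Worked example

Simulate a small two-genotype pair with planted truth, then run the whole
pipeline (enrich → scan → primers → reciprocal compare → reconcile →
keyword filter → di/tri restriction):

```bash
cat > sim.toml <<'EOF'
[sim]
n_contigs = 120
n_planted_ssrs = 24
n_decoys = 3
EOF
ssrforge simulate --seed 11 --config sim.toml -o sim
ssrforge pipeline --p1 sim/p1.fasta --p2 sim/p2.fasta \
    --annotations sim/annotations.tsv -o run
```

The run logs its stage counts and writes the tables into `run/`:

```
INFO ssrforge: count ssrs_p1 = 27
INFO ssrforge: count primed_p1 = 27
INFO ssrforge: count primer_failed_p1 = 0
INFO ssrforge: count matches_1v2 = 25
INFO ssrforge: count reconciled_polymorphic = 11
INFO ssrforge: count keyword_excluded = 3
INFO ssrforge: count final_panel = 4
INFO ssrforge: final panel: 4 markers -> run
```

Reading the counts: the 27 P1 repeat loci all got unique primer pairs; 25
P1 contigs matched a P2 partner; 11 loci were length-polymorphic in both
directions; 3 of those sat on simulated organellar decoy contigs and were
excluded by the keyword screen; of the remainder, 4 were di- or
tri-nucleotide repeats — the motif classes kept for fragment-analysis
genotyping. `run/direction_counts.tsv` holds the per-direction verdict
table (here 14 monomorphic / 11 polymorphic / 2 no-match for P1 vs P2),
and `run/final_panel.tsv` the ready-to-order markers:

```
seq_id    start  end  period  motif  copies  fwd_primer                rev_primer              tm_fwd  tm_rev  product_len
ctg_0001  500    521  2       AG     11      AGTTTCGGTGTACCGTCCGACAAG  TCAGGTATGGCCTTCGCGCATT  58.96   58.96   260
ctg_0004  238    267  2       CT     15      TAGCCCAAAGAGCCCATGGCA     CACATGCCGCACGAACTGGTAA  58.12   58.12   366
```

Single-stage subcommands (`stats`, `enrich`, `scan`, `primers`, `compare`,
`annotate-filter`, `vcf-spectrum`, `report`) expose each step separately;
`ssrforge stats sim/p1.fasta` for instance prints contig count, total bp,
N50 and AT/GC composition. Externally computed 12-column tabular alignments
can replace the built-in matcher via `--blast1v2/--blast2v1`.

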