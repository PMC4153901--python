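# mitoreorg

Analysis of mitochondrial genome reorganization, built for the questions
that arise in anuran (frog) mitogenomics but applicable to any vertebrate
mitogenome set:

- **Gene orders.** Extract strand- and pseudogene-aware gene orders from
  annotated GenBank records, classify each genome against the vertebrate
  ancestral gene order (AGO) vs rearranged orders (RGO), and report
  diagnostic features (LTPF cluster, WANCY integrity, trnH translocation,
  trnM duplication, gene losses/duplications/pseudogenes).
- **TDRL inference.** Find all minimal tandem duplication–random loss
  scenarios — one tandem duplication of a gene tract followed by
  deletion/pseudogenization of redundant copies, with exactly one copy of
  each gene retained — that turn an ancestral segment into an observed
  one.
- **Codon usage.** Codon counts and RSCU under the vertebrate
  mitochondrial code (table 2), with leucine (CUN/UUR) and serine
  (UCN/AGY) each treated as two synonymous families, matching their two
  tRNAs; chi-square comparison of usage between genomes.
- **Adaptive-positioning test.** For each tRNA gene, the distance from
  the control region's 3' end to the tRNA's 5' end (circular, in
  transcription direction) is paired with the usage of the codons that
  tRNA decodes; Pearson and Spearman correlations with two-tailed
  p-values test whether heavily used tRNAs sit near the CR, where
  transcription initiates. RSCU_c = x_c / ((1/n_F) Σ_{c'∈F} x_{c'}).
- **Divergence.** Pairwise dS, dN and ω = dN/dS per protein-coding gene
  via Nei–Gojobori (1986) counting with pathway averaging and
  Jukes–Cantor correction, d = −(3/4)·ln(1 − (4/3)p), plus rank-based
  group comparisons.
- **Synthetic mitogenomes.** A generator producing annotated circular
  genomes (orders, pseudogene relics, duplications, TDRL events,
  distance-linked codon usage, congeneric pairs evolved to target dS/dN)
  with every true parameter recorded in a ledger, so the whole pipeline
  is testable without downloads.

See `docs/methods.md` for models, conventions and limitations.

## Worked example

```python
from mitoreorg import (SimSpec, generate_genome, evolve_pair,
                       assemble_dataset, correlate, genome_pair_divergence,
                       extract_gene_order, classify_order)

# 14 genomes with the ancestral order and a usage-position link (beta=0.5)
spec = SimSpec(seed=42, n_species=14, beta=0.5)
genomes = [generate_genome(spec, i)[0] for i in range(14)]

cls = classify_order(extract_gene_order(genomes[0]))
print(genomes[0].id, cls.label, sorted(cls.features))
# SYN000 AGO ['WANCY_intact']

res = correlate(assemble_dataset(genomes))
print(f"n={res.n} r={res.pearson_r:+.3f} rho={res.spearman_rho:+.3f}")
# n=308 r=-0.862 rho=-0.855
```

Each of the 14 genomes contributes its full 22-tRNA complement, hence
n = 14 × 22 = 308 data points; the strong negative correlation is the
generated distance–usage link (at `beta=0` it collapses to noise).

Divergence of a simulated congeneric pair at target dS = 0.10, dN = 0.02:

```python
partner, _ = evolve_pair(genomes[0], 0.10, 0.02, seed=7)
for r in genome_pair_divergence(genomes[0], partner)[:3]:
    print(f"{r.gene}  dS={r.dS:.4f}  dN={r.dN:.4f}  omega={r.omega:.3f}")
# atp6  dS=0.0785  dN=0.0190  omega=0.242
# atp8  dS=0.1240  dN=0.0234  omega=0.189
# cob   dS=0.0791  dN=0.0191  omega=0.242
```

Per-gene values scatter around the targets (short genes like atp8 are
noisiest); ω well below 1 reflects the simulated excess of synonymous
change, as expected under purifying selection.

The command line mirrors the library. Inferring the duplication scenario
behind an observed WANCY rearrangement (primes mark pseudogenes):

```console
$ mitoreorg tdrl "WANOLCY" "WA'N'OLANOL'CY"
scenario 1  cost=(3, 3)
tract : -trnA -trnN OL
copy1 : -trnA' -trnN' OL
copy2 : -trnA -trnN OL'
```

i.e. the tract trnA–trnN–O_L was duplicated; the first copies of trnA and
trnN and the second copy of O_L decayed into pseudogenes. Other
subcommands: `orders`, `codon-usage`, `correlate`, `dnds`, `simulate`,
and `run` (full pipeline from a YAML config; outputs `orders.tsv`,
`tdrl.json`, `codon_usage.tsv`, `rscu.tsv`, `correlations.tsv`,
`dnds.tsv` and a run log).

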