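# poolsel

Divergence analysis for a pair of sibling species sequenced as pooled
read sets. The pipeline classifies each coding site from two species'
pooled-read pileups as a fixed interspecific difference, a within-species
polymorphism, or invariant, under explicit read-count rules (allele
presence at max(5 reads, 5 % of depth); a fixed call needs a ≥95 %
majority base in one species that is absent from the other). Genes
carrying fixed differences are reduced to fixed-difference-only codon
alignments and analysed with:

- **pairwise dN/dS** under a 61-state codon substitution model
  (parameters *t*, κ, ω; F3x4 or equal codon frequencies), fitted by
  bounded maximum likelihood with a likelihood-ratio test against the
  neutral ω = 1 model, cross-checked by an NG86 counting estimator;
- **gene-set statistics**: Fisher's exact tests on fixed/polymorphic and
  nonsynonymous/synonymous contingency tables, Mann–Whitney U on
  per-gene rates, ω > 1 enrichment;
- **membrane-topology analysis**: a ≥2-of-3 per-residue consensus over
  multiple TM predictors, ligand-binding-domain transfer through global
  protein alignment, substitution-to-domain mapping, goodness-of-fit
  enrichment and spatial profiles.

A first-class synthetic-data module (`poolsel.synth`) emulates the study
design — 40 haploid individuals per pool, orthologous equal-length ORFs,
negative-binomial read depth with per-base error, noisy 7-TM topology
predictors — with complete ground truth, so every stage is testable
offline. ORF extraction, reciprocal-best-hit orthology and an iterative
homology-discovery loop over a pluggable search backend live in
`poolsel.orfkit`.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes property-based tests (hypothesis), independent
oracles (brute-force ORF scan, textbook NG86 reimplementation, grid
search over the codon-model likelihood) and `tests/test_acceptance.py`,
which reproduces the published statistics and runs the calibration /
parameter-recovery checks. The full run takes ~10–15 minutes on one CPU;
the LRT calibration (500 simulated alignments) dominates.

## CLI

```sh
poolsel run --config cfg.yaml            # simulate -> classify -> dnds -> stats -> domains
poolsel simulate --out run/              # synthetic dataset with ground truth
poolsel orfs --transcripts t.fasta --min-len 900 --out orfs.fasta
poolsel orthologs --set-a a.fasta --set-b b.fasta --out pairs.tsv
poolsel discover --transcripts t.fasta --queries seeds.fasta --out hits.fasta
poolsel classify --pileups pileups.tsv --orfs orfs.fasta --out run/
poolsel dnds --alignments run/alignments --out omega.tsv
poolsel stats --genes run/genes.tsv --omega run/omega.tsv --report stats.json
poolsel domains --topologies topo.tsv --substitutions subs.tsv --out domains.tsv
poolsel report run/
```

`poolsel run` writes every stage artifact (pileups, site calls, gene
tallies, fixed-difference alignments, dN/dS table, statistics, domain
reports, per-family summary tables) plus a machine-readable
`summary.json` into the run directory; reruns with the same config and
seed are byte-identical. A config YAML can be produced from the defaults
with `python -c "from poolsel.pipeline import RunConfig; RunConfig().to_yaml('cfg.yaml')"`.

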