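# genefamkit

A comparative gene-family evolution toolkit for small plant gene families:

- **Substitution rates** — pathway-counting estimation of synonymous (Ks) and
  nonsynonymous (Ka) substitution rates for in-frame aligned CDS pairs, with
  optional transition/transversion weighting of site counts and Jukes–Cantor
  multiple-hit correction (`genefamkit.substitution_rates`).
- **Molecular clock** — calibration of the synonymous rate `k = mean(Ks)/2T`
  from anchor pairs and conversion of Ks values into divergence/duplication
  times `T = Ks/2k`, with min–max ranges over cross-group pairs
  (`genefamkit.clock`).
- **Phylogeny** — Neighbor-Joining trees from JC or p-distances with
  column-resampling bootstrap supports and Newick output
  (`genefamkit.njtree`).
- **Promoters** — affine-gap global alignment with deterministic trace-back,
  indel calling (merged gap runs, 1-based reference coordinates), and IUPAC
  degenerate motif scanning on both strands (`genefamkit.promoters`).
- **qPCR expression** — 2^−ΔΔCt relative expression from Ct tables, one-way
  ANOVA with a Tukey HSD compact letter display, and exact two-sided
  Mann–Whitney U tests with tiered significance marks (`genefamkit.qpcr`).
- **Synthetic data** — generators with exact ground-truth manifests for all
  of the above: clock-evolved CDS pairs/families, promoters with planted
  motifs and a bundled 17-bp insertion, and replicated Ct tables with planted
  fold changes (`genefamkit.simulate`).

## Command line

```sh
genefamkit --help
genefamkit ks aligned_cds.fasta --out ks_pairs.tsv     # all-vs-all Ks/Ka
genefamkit date --ks 0.089                             # clock calibration + dating
genefamkit tree aligned.fasta --boot 1000 --seed 1378  # NJ + bootstrap -> Newick
genefamkit promoters promoters.fasta                   # motif hits + indel calls
genefamkit qpcr ct_table.tsv --calibrator uncoloured lemma
genefamkit simulate family|promoters|qpcr              # synthetic inputs + truth
genefamkit pipeline --outdir results                   # full end-to-end report
```

`genefamkit pipeline` chains every stage (Ks matrix → dating → tree →
promoter scan/indels → expression) and writes TSV/Newick reports whose
headers carry the tool version and a configuration hash; re-running with the
same configuration reproduces byte-identical outputs. Inputs not supplied on
the command line are generated by the synthetic module with the run seed.

All coordinates in outputs are 1-based inclusive; missing values are `.`.

## Notes

- Genetic code: standard nuclear code only. The site-count weighting defaults
  to `kappa = 1`, which reduces to the original unweighted counting method.
- Codon columns containing a gap, ambiguous base or stop in either sequence
  are dropped whole; dropped counts are recorded on each result.
- With 3-vs-3 samples the minimum exact two-sided U-test p-value is 0.10, so
  the strict `p ≤ 0.005` tier is unreachable at that design; the module
  warns when this happens.
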