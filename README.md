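# nucdis

Analysis toolkit for **transcription-coupled nucleosome disassembly** from
genome-wide occupancy data, built around chromatin-remodeller and
histone-chaperone mutants in fission yeast.

Elongating RNA polymerase II must pass through positioned gene-body
nucleosomes. At steady state the fraction of gene-body nucleosomes
disassembled by transcription, *D*, splits into nucleosomes that are lost
(*L*, not immediately reassembled, visible as reduced histone H3 occupancy)
and nucleosomes transiently disassembled but immediately restored behind
the polymerase (*R*, the FACT-dependent pathway):

```
D = L + R
```

Deleting a remodeller (Fun30-family Fft3, *fft3Δ*) that works on the
disassembly side reduces disassembly and loss proportionally, so the
observed gene-body H3 occupancy gain is `ΔH3_fft3Δ = x′·L_wt`, where
`x′ ∈ (0, 1]` is the remodeller's relative contribution to disassembly.
In the reassembly-null FACT mutant (*spt16-18*), `R ≈ 0` so
`D_spt16 = L_spt16` and `ΔH3_spt16 = L_wt − D_spt16`. Eliminating the
unobserved `L_wt`:

```
D_spt16(x′) = ΔH3_fft3Δ / x′ − ΔH3_spt16
```

Because disassembly is transcription-coupled, `x′` is estimated as the grid
point (step 0.01 over (0, 1]) maximizing the Pearson correlation between
`D_spt16(x′)` and RNAPII occupancy. The per-gene disassembly estimates are
proportional to `x′·D_wt` on an arbitrary scale. `x′` is identifiable only
because per-gene reassembly efficiency varies — if `L ∝ D` exactly, the
correlation curve is flat, which the estimator detects and flags.

Around this core the package provides, as plain Python modules:

- `nucdis.simulate` — synthetic cohorts with known ground truth
  (annotation, coverage tracks, gene tables, latent D/L/R per genotype);
- `nucdis.occupancy` — GFF3/BED/bedGraph I/O, fixed-step coverage
  rasterization, per-gene `log2(IP/control)` occupancy, `log2(mutant/WT)`
  changes, TSV gene tables;
- `nucdis.metagene` — scale-regions metagene matrices (flank / scaled
  body / flank, strand-aware) and mean profiles;
- `nucdis.genesets` — k-means gene classes, threshold gene sets,
  upper-tail hypergeometric overlap tests, Pearson summaries with the
  |r| ≥ 0.4 convention, Tukey HSD comparisons;
- `nucdis.model` — the reconstruction and the `x′` grid-search estimator;
- `nucdis.pipeline` / the `nucdis` CLI — the stages wired end to end with
  a manifest and byte-stable outputs.

## Worked example

`examples/estimate_contribution.py` generates a noise-free cohort of 5,000
genes with a true contribution of 0.84 and runs the estimator:

```
true x' = 0.84, estimated x' = 0.83 (r = 0.804 at the peak, 5000 genes)
curve flatness = 0.186 -> identifiable = True
estimated disassembly levels vs true x'*D_wt: r = 1.0000 (arbitrary scale, so only correlations are meaningful)
raw H3 loss vs RNAPII occupancy:          r = 0.60
estimated disassembly vs RNAPII occupancy: r = 0.80
the estimated disassembly tracks transcription much better than raw loss does - the signature of efficient reassembly masking disassembly.
constant reassembly fraction control: flatness = 8.88e-16 -> identifiable = False (loss proportional to disassembly makes x' unrecoverable)
```

The estimate lands one grid step from the truth (finite-sample scatter; see
`docs/methods.md`), the reconstructed per-gene disassembly is a perfect
correlate of the latent truth, and raw H3 loss correlates with
transcription far worse than reconstructed disassembly — the pattern that
motivates the decomposition: efficient reassembly hides most
transcription-coupled disassembly from plain H3 measurements. The
constant-rho control shows the identifiability flag working.

The other scripts in `examples/` each demonstrate one capability
(simulation, quantification, metagene profiles, gene-set statistics, the
full pipeline) and print a few numbers with a line on what they mean.

## Command line

```sh
nucdis all --seed 1 --outdir run/          # full synthetic run
nucdis simulate --config cfg.yaml          # single stages: simulate,
nucdis model --outdir run/                 # quantify, metagene, classify,
                                           # model, report
```

Outputs include the gene table, occupancy TSVs, metagene matrix/profile,
gene-set files, the r-vs-x′ curve (JSON + plot) and `report.json`; a
`manifest.json` carries the config hash and seed so reruns are
byte-identical.

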