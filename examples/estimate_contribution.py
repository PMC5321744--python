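"""The core analysis: estimate the remodeller's contribution x' to
transcription-coupled nucleosome disassembly.

Reconstructs per-gene disassembly in the reassembly-null genotype as
D(x') = dH3_fft3/x' - dH3_spt16 and scans x' over (0, 1] for the maximum
Pearson correlation with RNAPII occupancy; compares the estimate and the
resulting disassembly levels against the generator's ground truth.
"""

from nucdis import (
    DisassemblyObservables,
    GeneratorConfig,
    estimate_contribution,
    fun30_disassembly_levels,
    generate_cohort,
    pearson_r,
)

config = GeneratorConfig(n_genes=5000, seed=5, x_prime_true=0.84,
                         sigma_obs=0.0, sigma_P=0.0)
cohort = generate_cohort(config, tracks=False)
obs = DisassemblyObservables.from_table(cohort.gene_table)
est = estimate_contribution(obs)

print(f"true x' = {config.x_prime_true}, estimated x' = {est.x_hat:.2f} "
      f"(r = {est.r_max:.3f} at the peak, {est.n_genes_used} genes)")
print(f"curve flatness = {est.flatness:.3f} -> identifiable = {est.identifiable}")

levels = fun30_disassembly_levels(est)
truth = cohort.truth
r_truth = pearson_r(levels.to_numpy(), truth.x_prime_true * truth.d_wt).r
print(f"estimated disassembly levels vs true x'*D_wt: r = {r_truth:.4f} "
      f"(arbitrary scale, so only correlations are meaningful)")

r_loss = pearson_r(obs.dh3_fft3, obs.pol).r
r_dis = pearson_r(levels.to_numpy(), obs.pol).r
print(f"raw H3 loss vs RNAPII occupancy:          r = {r_loss:.2f}")
print(f"estimated disassembly vs RNAPII occupancy: r = {r_dis:.2f}")
print("the estimated disassembly tracks transcription much better than raw "
      "loss does - the signature of efficient reassembly masking disassembly.")

degenerate = generate_cohort(
    GeneratorConfig(n_genes=5000, seed=5, sigma_obs=0.0, sigma_P=0.0,
                    constant_rho=True),
    tracks=False,
)
est_flat = estimate_contribution(
    DisassemblyObservables.from_table(degenerate.gene_table)
)
print(f"constant reassembly fraction control: flatness = {est_flat.flatness:.2e} "
      f"-> identifiable = {est_flat.identifiable} (loss proportional to "
      f"disassembly makes x' unrecoverable)")
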