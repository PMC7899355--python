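"""Synthetic cohort: sample, raytrace, and refit the power models.

Draws a truncated-normal population from the published marginal statistics
(identity correlations), runs every eye through the full pipeline, fits the
population keratometer index per criterion and refits the multivariate
corneal-power model. A few hundred eyes suffice to see the structure; the
acceptance checks use 2,000.
"""

from corneatrace import PopulationSpec, analyze_batch, sample_population

eyes = sample_population(PopulationSpec(n=300, seed=42))
print(f"sampled {len(eyes)} eyes; mean R_f = {eyes.R_f.mean():.3f} mm, "
      f"mean PUP = {eyes.PUP.mean():.3f} mm")

batch = analyze_batch(eyes, n_rays=501)
print("\npopulation keratometer indices (least-squares):")
for c, nk in batch.keratometer_indices.items():
    print(f"  BFP-{c}: n_K = {nk:.5f}")

print("\nrefit power models (offset residual):")
for c, fit in batch.model_fits.items():
    print(f"  BFP-{c}: R^2 = {fit.r_squared:.3f}, RMS = {fit.rms_error:.3f} dpt")

print("\nfocus/power summary (per-eye distribution):")
print(batch.summaries["focus"].loc[["Mean", "SD", "Median"]].round(4).to_string())

print(
    "\nWith only the marginals published, covariates are sampled"
    "\nuncorrelated: keratometer indices land close to the published"
    "\n1.331-1.332, while dispersion statistics (model RMS) exceed the"
    "\ncohort values, which benefited from strongly correlated radii."
)
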