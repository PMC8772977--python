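"""Generate a sparse linear dataset with known ground truth.

The generator draws X with i.i.d. Gaussian rows (optional AR(1) column
correlation), plants a small true support with coefficients of random
sign and magnitude in [beta_low, beta_high], and adds Gaussian noise.
Because the true support is returned, selection quality can be scored
exactly with support_metrics.
"""

from splicega import SyntheticSpec, generate, support_metrics

spec = SyntheticSpec(n=100, p=200, s_star=4, rho=0.3, noise_sd=0.5, seed=42)
X, y, truth = generate(spec)

print(f"matrix: {X.n_samples} samples x {X.n_features} features")
print(f"phenotype: {y.name}, mean {y.values.mean():.3f}, sd {y.values.std():.3f}")
print(f"true support (column indices): {sorted(truth)}")

# a deliberately wrong guess, to show the scoring
guess = set(list(sorted(truth))[:2]) | {0, 1}
exact, tpr, fdr = support_metrics(guess, truth)
print(f"guess {sorted(guess)} -> exact={exact}, TPR={tpr:.2f}, FDR={fdr:.2f}")
# TPR is the fraction of true features found; FDR the fraction of the
# guess that is spurious.
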