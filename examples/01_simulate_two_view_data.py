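"""Generate a synthetic two-view dataset with planted modes of covariation.

The generator mimics the structure of a brain-connectivity x behaviour
study: two views share K latent modes, both carry additive scanner-site
and head-motion effects, and the behaviour view has missing entries and a
few near-constant questionnaire items.
"""

import numpy as np

from neurocca import SyntheticConfig, generate, population_canonical_correlation

config = SyntheticConfig(seed=1)  # defaults: n=306, p=150, q=60, K=2
bundle, truth = generate(config)

print(f"subjects: {bundle.n_subjects}")
print(f"brain view: {bundle.brain.n_variables} edges")
print(f"behaviour view: {bundle.behaviour.n_variables} items "
      f"({len(truth.near_constant_ids)} near-constant)")
missing = np.isnan(bundle.behaviour.values).mean()
print(f"missing behaviour entries: {missing:.1%}")
print(f"sites: {sorted(set(bundle.confounds.site))}")
print(f"mean FD range: {bundle.confounds.mean_fd.min():.3f}"
      f"-{bundle.confounds.mean_fd.max():.3f} mm")
for k in range(config.k_modes):
    rho = population_canonical_correlation(config, k + 1)
    print(f"mode {k + 1}: population canonical correlation rho = {rho:.2f}")

# The population correlations are what a perfectly estimated CCA would
# recover in the limit of infinitely many subjects; finite samples
# overestimate in-sample and underestimate out-of-sample.
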