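"""The statistical toolkit on its own: transforms, Fisher, circular ANOVA.

Small self-contained demonstrations of the procedures the pipeline uses,
with the numbers they print and what they mean.
"""

import numpy as np

from oculostim import (
    bonferroni_alpha, circ_descriptives, endpoint_ellipse, fisher_exact,
    hk_circ_anova, latency_test, reciprocal_transform,
)

# reciprocal (rate) transform: 200 ms -> 5/s, 250 ms -> 4/s
print("rates:", reciprocal_transform([200.0, 250.0]))

# two latency samples, 25 ms apart: the primary reciprocal-transformed t test
rng = np.random.default_rng(0)
ctrl = 150 + 20 * rng.standard_normal(200) + rng.exponential(40, 200)
stim = ctrl + 25.0
res = latency_test(stim, ctrl)
print(f"25 ms delay: mean diff {res.extras['mean_diff_ms']:+.1f} ms, "
      f"t = {res.statistic:.2f}, p = {res.p_value:.2g} ({res.method})")

# Fisher exact test on evocation counts at two currents
res = fisher_exact([[24, 16], [36, 4]])
print(f"Fisher: odds ratio {res.effect_estimate:.3f}, p = {res.p_value:.4f} "
      f"(evocation rises with current)")

# circular ANOVA: two electrodes with preferred directions 90 deg apart
ang = np.rad2deg(np.concatenate([
    rng.vonmises(0.0, 10.0, 40), rng.vonmises(np.pi / 2, 10.0, 40),
]))
electrode = np.repeat([0, 1], 40)
current = np.tile([100, 250], 40)
hk = hk_circ_anova(ang, electrode, current, n_perm=999, seed=0)
print(f"circular ANOVA electrode term: statistic = {hk.factor_a.statistic:.2f} "
      f"({hk.regime} regime, kappa = {hk.kappa_hat:.1f}), "
      f"df = {hk.factor_a.df}, p = {hk.factor_a.p_value:.2g}")

# circular mean of the pooled angles (low concentration across clusters)
cd = circ_descriptives(ang)
print(f"pooled mean direction {cd.mean_direction_deg:.1f} deg, "
      f"resultant length {cd.resultant_length:.2f}")

# 95% endpoint ellipse of a synthetic endpoint cloud
pts = rng.standard_normal((500, 2)) * [1.5, 0.6] + [5.0, 1.0]
center, axes, orient = endpoint_ellipse(pts)
print(f"endpoint ellipse: center ({center[0]:.2f}, {center[1]:.2f}), "
      f"semi-axes {axes[0]:.2f} x {axes[1]:.2f} deg, {orient:.0f} deg")

# Bonferroni levels used by the spatial (4 tests) and kinematics families
print("adjusted alphas:", bonferroni_alpha(0.05, 4), bonferroni_alpha(0.05, 8))
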