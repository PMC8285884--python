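"""Fusion-weight grid search against a planted miRNA-similarity reference.

Builds three random similarity networks, constructs a miRNA reference as
their weighted sum (weights 0.1 / 0.3 / 0.6) plus a little noise, and shows
that the 30-combination grid search recovers the planted weights.
"""

from mscfs import FusionWeights, SyntheticConfig, grid_search, make_planted_fusion

planted = FusionWeights(alpha=0.1, beta=0.3, gamma=0.6)
cdfs, gofs, sqfs, cms = make_planted_fusion(
    SyntheticConfig(n_circ=30, seed=11), planted, sigma=0.01)

best, table = grid_search(cdfs, gofs, sqfs, cms, step=0.1, alpha_max=0.2)
print(f"grid search evaluated {len(table)} weight combinations")
print(f"recovered weights: alpha={best.alpha:g}, beta={best.beta:g}, "
      f"gamma={best.gamma:g}  (planted 0.1, 0.3, 0.6)")

print("\ntop 5 combinations by correlation with the miRNA reference:")
for w, res in sorted(table, key=lambda t: -t[1].r)[:5]:
    print(f"  ({w.alpha:.1f}, {w.beta:.1f}, {w.gamma:.1f})  "
          f"r = {res.r:.4f}  p = {res.p:.2e}  pairs = {res.n_pairs}")
# The planted grid point wins clearly; neighbouring combinations trail it.
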