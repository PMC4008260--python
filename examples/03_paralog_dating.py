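"""Kimura 2-parameter paralog divergence dating with RBH confirmation.

Evolves nucleotide paralog pairs at a known K2P distance, re-estimates the
distance with pairwise deletion, converts it to divergence times at two
substitution rates, and confirms the pairs by reciprocal best match.
"""

import numpy as np

from pmekit import divergence_time, k2p_distance, reciprocal_best_match
from pmekit.synthetic import simulate_paralog_pairs

K_TRUE = 0.135  # substitutions per site
seqs, pairs = simulate_paralog_pairs(12, length=1000, K_true=K_TRUE, seed=42)

ks = [k2p_distance(seqs[a], seqs[b]).K for a, b in pairs]
mean_k = float(np.mean(ks))
times = divergence_time(mean_k)
print(f"true K = {K_TRUE}, mean estimated K = {mean_k:.4f} over {len(ks)} pairs")
for rate, t in times.items():
    print(f"  rate {rate:g} /site/year -> divergence {t:.1f} MYA")

rbh = reciprocal_best_match(seqs)
recovered = len(set(rbh.pairs) & {tuple(sorted(p)) for p in pairs})
print(f"reciprocal best match recovered {recovered}/{len(pairs)} planted pairs")
print()
print("t = K/(2r): the slower published rate gives times 1.852x older than "
      "the faster one; a family-mean K near 0.135 dates a duplication to "
      "roughly 4.5-8.3 million years ago.")
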