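"""Map many trajectory groups into a common low-dimensional space.

Simulates ten groups along an fBM-fraction gradient (two 'conditions' of
five replicate groups each), computes all pairwise squared MMDs with
subsampling-based uncertainties, and embeds the groups by MDS in which each
pairwise term is weighted by the inverse variance of its MMD estimate. The
replicate groups should land close together and the two conditions apart.

Run with:  python examples/04_group_embedding.py
"""

import numpy as np

from walkmmd import (
    classical_feature_table,
    generate_dataset,
    mds_with_uncertainty,
    mixture_pair,
    pairwise_group_mmd,
)

if __name__ == "__main__":
    mix_lo, mix_hi = mixture_pair(nu=0.35)
    rng = np.random.default_rng(11)
    sets = {}
    for rep in range(5):
        g = generate_dataset(mix_lo, 300, rng_seed=rng.integers(2**31))
        sets[f"low_fbm_{rep}"] = classical_feature_table(g)
        g = generate_dataset(mix_hi, 300, rng_seed=rng.integers(2**31))
        sets[f"high_fbm_{rep}"] = classical_feature_table(g)

    mat = pairwise_group_mmd(sets, min_trajectories=150, rng_seed=11)
    emb = mds_with_uncertainty(mat, embed_dim=3, rng_seed=11)

    print(f"MDS stress: {emb.stress:.4f}")
    for gid, xyz in zip(emb.group_ids, emb.coordinates):
        print(f"  {gid:<12} ({xyz[0]:+.3f}, {xyz[1]:+.3f}, {xyz[2]:+.3f})")

    lows = emb.coordinates[[g.startswith("low") for g in emb.group_ids]]
    highs = emb.coordinates[[g.startswith("high") for g in emb.group_ids]]
    gap = np.linalg.norm(lows.mean(0) - highs.mean(0))
    spread = max(lows.std(), highs.std())
    print(f"condition separation: {gap:.3f} vs within-condition spread {spread:.3f}")
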