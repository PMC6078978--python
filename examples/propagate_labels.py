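"""Score nodes by relevance to a seed set with random walk with restart.

On a noisy modular network, seeds from one planted community should pull
the rest of that community to the top of the ranking - and they do it more
cleanly on the enhanced network. Quantified by AUROC of the held-out
community members versus everyone else, plus a leave-one-out benchmark.
"""

from netenhance import (
    BlockNetworkSpec,
    auroc,
    enhance,
    generate_block_network,
    leave_one_out_auroc,
    rwr_propagate,
)

net, truth = generate_block_network(BlockNetworkSpec(n=120, n_blocks=4, seed=3))
enhanced = enhance(net)

block0 = [i for i, c in enumerate(truth.assignments) if c == 0]
seeds, held_out = block0[:5], block0[5:]

for name, g in [("raw", net), ("enhanced", enhanced)]:
    scores = rwr_propagate(g, seeds, restart_prob=0.5).scores
    negatives = [i for i in range(g.n_nodes) if i not in block0]
    print(f"{name:9s} AUROC of held-out community members: "
          f"{auroc(scores, held_out, negatives):.3f}")

loo = leave_one_out_auroc(enhanced, block0, restart_prob=0.5, seed=0)
print(f"leave-one-out AUROC on the enhanced network:  {loo:.3f}")
print()
print("AUROC is the probability a true community member outranks a random")
print("outsider; 0.5 is chance, 1.0 is a perfect ranking.")
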