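"""Denoise a noisy modular network and measure the downstream payoff.

Simulates a 200-node similarity network with four planted communities,
heavy edge noise and 20% missing within-community edges, then compares
Louvain community recovery (NMI) and top-20 same-label retrieval accuracy
before and after enhancement.
"""

from netenhance import (
    BlockNetworkSpec,
    detect_communities,
    enhance,
    generate_block_network,
    nmi,
    retrieval_accuracy,
)

net, truth = generate_block_network(BlockNetworkSpec(seed=7))
enhanced = enhance(net)

nmi_raw = nmi(detect_communities(net, seed=7), truth)
nmi_enh = nmi(detect_communities(enhanced, seed=7), truth)
acc_raw = retrieval_accuracy(net, truth, top_m=20)
acc_enh = retrieval_accuracy(enhanced, truth, top_m=20)

print(f"Louvain NMI            raw {nmi_raw:.3f} -> enhanced {nmi_enh:.3f}")
print(f"top-20 retrieval acc.  raw {acc_raw:.3f} -> enhanced {acc_enh:.3f}")
print()
print("NMI of 1 means the detected communities match the planted ones exactly;")
print("retrieval accuracy is the fraction of each node's 20 strongest neighbors")
print("that share its community - higher after enhancement means noisy edges were")
print("suppressed and within-community edges reinforced.")
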