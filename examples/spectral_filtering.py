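"""Watch the diffusion act as a spectral filter.

Builds the localized doubly stochastic operator of a mildly noisy 4-block
network, diffuses it in closed form, and reports how the eigenvalues move:
each passes through f(lam) = (1-a)*lam / (1 - a*lam^2), which fixes 0 and 1,
shrinks small eigenvalues hardest, and widens the gap below the community
eigenvalues.
"""

import numpy as np

from netenhance import BlockNetworkSpec, enhance, generate_block_network, map_eigenvalue
from netenhance.spectral import eigengap, spectral_report

net, _ = generate_block_network(BlockNetworkSpec(noise_sd=0.1, dropout=0.0, seed=42))
_, T, result = enhance(net, return_details=True)
report = spectral_report(T, result.denoised, alpha=0.9)

print("top 6 eigenvalues (operator -> diffused):")
for lb, la in zip(report.eigenvalues_before[:6], report.eigenvalues_after[:6]):
    print(f"  {lb:8.4f} -> {la:8.4f}   (map predicts {map_eigenvalue(min(lb, 1.0), 0.9):8.4f})")

print(f"\ngap below the 4 community eigenvalues: "
      f"{eigengap(T.operator, 4):.4f} -> {eigengap(result.denoised, 4):.4f}")
print(f"worst eigenvector drift: {report.max_eigenvector_drift:.2e}")
print()
print("The four near-1 eigenvalues (one per community) survive; everything below")
print("is crushed toward 0, so the gap separating community structure from noise")
print("grows while the eigenvectors - the structure itself - are untouched.")
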