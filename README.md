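# netenhance

Denoising for undirected, weighted networks — protein interaction maps,
chromatin contact matrices, image or cell similarity graphs — where
measurement noise inflates spurious edges and hides real ones, corrupting
everything downstream: community detection, label propagation, retrieval.

The method replaces the noisy weights with the fixed point of a regularized
diffusion over a *doubly stochastic* localized operator. From the input `W`
it builds a KNN-truncated transition matrix and symmetrizes it into an
operator `T` whose rows and columns all sum to 1, then solves

    W* = lim  W_{t+1} = α T W_t T + (1 − α) T .

Because `T` is a symmetric DSM, the limit has a closed form: `W*` keeps the
eigenvectors of `T` and maps each eigenvalue through

    f_α(λ) = (1 − α) λ / (1 − α λ²),

which fixes 0 and 1, shrinks small (noise-dominated) eigenvalues far more
aggressively than large (structure-carrying) ones, and widens the top
eigengap — without ever connecting disconnected components. The result is a
network with the same modules, cleaner boundaries, and provable spectral
guarantees, all verified by the test suite.

## Worked example

```python
from netenhance import (BlockNetworkSpec, generate_block_network, enhance,
                        detect_communities, nmi, retrieval_accuracy)

net, truth = generate_block_network(BlockNetworkSpec(seed=7))   # 200 nodes, 4 noisy blocks
enhanced = enhance(net)                                          # closed-form diffusion, α=0.9

print(nmi(detect_communities(net, seed=7), truth),
      nmi(detect_communities(enhanced, seed=7), truth))
print(retrieval_accuracy(net, truth, top_m=20),
      retrieval_accuracy(enhanced, truth, top_m=20))
```

Running `python examples/denoise_noisy_communities.py` (the same
computation) prints:

```
Louvain NMI            raw 1.000 -> enhanced 1.000
top-20 retrieval acc.  raw 0.708 -> enhanced 0.970
```

Louvain already recovers the four planted communities on this instance
(NMI 1 = exact match, and enhancement does not disturb that), but the edge
weights themselves are badly corrupted: only 71% of each node's 20 strongest
neighbors are true community mates in the raw network, versus 97% after
enhancement — weak spurious edges were suppressed and hidden within-block
edges reinforced.

The other scripts in `examples/` each exercise one capability: spectral
filtering and eigengap growth (`spectral_filtering.py`), random-walk label
propagation with leave-one-out AUROC (`propagate_labels.py`), and the three
on-disk formats (`file_formats_roundtrip.py`).

## Command line

A thin `ne` CLI wraps the library for shell pipelines:

```sh
ne simulate --n 200 --blocks 4 --seed 7 --output net.tsv --labels labels.tsv
ne enhance  --input net.tsv --alpha 0.9 --mode closed --output enhanced.tsv
ne spectra  --input net.tsv --top 10 --output report.tsv
ne propagate --input enhanced.tsv --seeds seeds.txt --restart 0.5 --output scores.tsv
ne eval retrieval --input enhanced.tsv --labels labels.tsv --top-m 40
ne eval nmi --labels-a detected.tsv --labels-b truth.tsv
```

Networks travel as TSV edge lists, dense labeled matrices, or MatrixMarket
coordinate files; a flat `key=value` config file mirrors the flags (CLI
wins). Exit codes: 0 ok, 2 validation error, 3 numerical failure, 4
non-convergence (best iterate still written).

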