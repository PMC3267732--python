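"""Independent brute-force oracles shared by the test modules."""

import numpy as np
from skbio import DistanceMatrix


def naive_average_linkage(D: np.ndarray) -> np.ndarray:
    """Brute-force UPGMA: at every step recompute every inter-cluster
    distance as the mean of the ORIGINAL pairwise distances, merge the
    closest pair, and record the merge height."""
    clusters = [[i] for i in range(len(D))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([D[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [
            clusters[i] + clusters[j]
        ]
    return np.array(heights)


def random_distance_matrix(rng: np.random.Generator, n: int) -> DistanceMatrix:
    """Euclidean distances between n random points on the 61-simplex."""
    F = rng.random((n, 61))
    F /= F.sum(axis=1, keepdims=True)
    from scipy.spatial.distance import pdist, squareform

    return DistanceMatrix(squareform(pdist(F)), ids=[f"L{i}" for i in range(n)])
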