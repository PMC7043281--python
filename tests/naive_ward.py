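"""Independent O(n^3) Ward-D2 oracle used by the clustering tests.

Instead of the Lance-Williams recurrence, every step recomputes each
candidate merge cost directly from the *initial* squared dissimilarities
via the pairwise-sum form of Ward's criterion,

    D(A, B) = 2|A||B|/(|A|+|B|) * ( g(A,B)/(|A||B|)
                                    - g(A,A)/(2|A|^2) - g(B,B)/(2|B|^2) )

where g(S, T) is the sum of squared input dissimilarities over ordered
pairs.  Reported heights are sqrt(D).  Tie-breaking matches the package
convention: smallest (left, right) cluster-id pair.
"""

import numpy as np
from scipy.spatial.distance import squareform


def naive_ward(condensed: np.ndarray) -> np.ndarray:
    d2 = squareform(np.asarray(condensed, dtype=float)) ** 2
    n = d2.shape[0]
    clusters = {i: [i] for i in range(n)}  # cluster id -> member leaves
    merges = np.empty((n - 1, 4))

    def g(a_members, b_members):
        return d2[np.ix_(a_members, b_members)].sum()

    for step in range(n - 1):
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                ma, mb = clusters[a], clusters[b]
                na, nb = len(ma), len(mb)
                cost = (2.0 * na * nb / (na + nb)) * (
                    g(ma, mb) / (na * nb)
                    - g(ma, ma) / (2.0 * na * na)
                    - g(mb, mb) / (2.0 * nb * nb)
                )
                tol = 1e-9 * max(1.0, abs(cost))
                if best is None or cost < best[0] - tol or (
                    abs(cost - best[0]) <= tol and (a, b) < best[1:3]
                ):
                    best = (cost, a, b)
        cost, a, b = best
        new_id = n + step
        merges[step] = (a, b, np.sqrt(max(cost, 0.0)), len(clusters[a]) + len(clusters[b]))
        clusters[new_id] = clusters.pop(a) + clusters.pop(b)
    return merges
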