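"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def brute_force_distance(nominal, perturbed, edges):
    """Element-by-element tabulation oracle for the histogram distance: walk
    every value through the bin edges (plus two overflow bins) and sum the
    absolute fraction differences."""

    def tabulate(sample):
        k = len(edges) - 1
        counts = np.zeros(k + 2)
        for v in sample:
            if v < edges[0]:
                counts[0] += 1
            elif v > edges[-1]:
                counts[-1] += 1
            else:
                j = k - 1  # last bin closed
                for b in range(k):
                    if edges[b] <= v < edges[b + 1]:
                        j = b
                        break
                counts[j + 1] += 1
        return counts / len(sample)

    return np.abs(tabulate(nominal) - tabulate(perturbed)).sum()
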