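"""Independent brute-force reference implementations used by the tests.

Deliberately written with plain Python loops and ``math`` only — no
numpy, no shared helpers from the package — so that agreement with the
library is evidence of correctness rather than of shared bugs.
"""

import math


def brute_force_consistency_survivors(tensor, sd_multiplier=4.0):
    """Indices of genes surviving the replicate-consistency filter.

    ``tensor`` is a nested list ``[gene][time][replicate]`` of positive
    intensities.  Implements, with explicit loops:

    * per-gene, per-timepoint replicate mean G,
    * percent relative error S^k = |G^k - G| / G * 100,
    * per-timepoint threshold r_thres = r_avg + m * r_std where r_avg and
      r_std (population SD) pool all genes and replicates,
    * removal of any gene whose worst replicate error strictly exceeds
      the threshold at any timepoint.
    """
    n_genes = len(tensor)
    n_time = len(tensor[0])
    n_rep = len(tensor[0][0])

    errors = []
    for i in range(n_genes):
        per_time = []
        for j in range(n_time):
            mean = sum(tensor[i][j][k] for k in range(n_rep)) / n_rep
            per_time.append(
                [abs(tensor[i][j][k] - mean) / mean * 100.0 for k in range(n_rep)]
            )
        errors.append(per_time)

    thresholds = []
    for j in range(n_time):
        pooled = [errors[i][j][k] for i in range(n_genes) for k in range(n_rep)]
        avg = sum(pooled) / len(pooled)
        var = sum((x - avg) ** 2 for x in pooled) / len(pooled)
        thresholds.append(avg + sd_multiplier * math.sqrt(var))

    survivors = []
    for i in range(n_genes):
        removed = False
        for j in range(n_time):
            worst = max(errors[i][j])
            if worst > thresholds[j]:
                removed = True
                break
        if not removed:
            survivors.append(i)
    return survivors
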