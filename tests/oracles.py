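"""Independent reference implementations used to cross-check the package.

These are deliberately written straight from first principles (rank
statistics, the two pruning rules as literal set operations) and share no
code with the implementation under test.
"""

import numpy as np
from scipy import stats


def mann_whitney_auc(labels, scores) -> float:
    """AUC as the Mann-Whitney U statistic U/(n1*n0); ties count 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(scores)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def brute_force_prune(names, corr, r_top, r_pairwise):
    """Literal transcription of the two-stage redundancy pruning rules.

    Rule 1: drop every feature with |r| > r_top against the first (most
    important) feature.  Rule 2: walk the surviving list from the second
    entry onward; each entry drops all later survivors with |r| >
    r_pairwise against it.
    """
    corr = np.asarray(corr)
    alive = [0] + [j for j in range(1, len(names))
                   if not abs(corr[0, j]) > r_top]
    i = 1
    while i < len(alive):
        anchor = alive[i]
        alive = alive[: i + 1] + [j for j in alive[i + 1:]
                                  if not abs(corr[anchor, j]) > r_pairwise]
        i += 1
    return [names[j] for j in alive]


def step_average_tpr(curves, grid):
    """Vertical ROC averaging recomputed point by point."""
    grid = np.asarray(grid, dtype=float)
    out = np.zeros_like(grid)
    for g_idx, g in enumerate(grid):
        vals = []
        for fpr, tpr in curves:
            best = 0.0
            for f, t in zip(fpr, tpr):
                if f <= g and t > best:
                    best = t
            vals.append(best)
        out[g_idx] = float(np.mean(vals))
    return out
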