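"""Brute-force oracles shared by the acceptance checks.

Kept independent of the library implementations they validate: AUC by
exhaustive pair counting, cutoff selection by exhaustive scan.
"""

import numpy as np


def brute_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_cutoff(scores, labels):
    """Returns (best Youden sum, lowest cutoff achieving it)."""
    uniq = np.unique(scores)
    cands = [uniq[0] - 1] + list((uniq[:-1] + uniq[1:]) / 2) + [uniq[-1] + 1]
    best = None
    for c in cands:
        pred = scores > c
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        if best is None or sens + spec > best[0] + 1e-12:
            best = (sens + spec, c)
    return best
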