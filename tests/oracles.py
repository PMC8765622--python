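"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately share no code with the package: TSS is maximized by
an explicit loop over every candidate threshold with hand-counted
confusion tables, and AUC is exhaustive pair counting.
"""

import numpy as np


def brute_force_tss(scores, y):
    """Max of sensitivity+specificity-1 over all midpoints of distinct
    sorted scores, via explicit confusion-table counting."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    uniq = sorted(set(scores.tolist()))
    if len(uniq) == 1:
        return 0.0, float(uniq[0])
    best_tss, best_t = -2.0, None
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        t = (lo + hi) / 2.0
        tp = fn = tn = fp = 0
        for s, label in zip(scores, y):
            if label == 1:
                if s >= t:
                    tp += 1
                else:
                    fn += 1
            else:
                if s < t:
                    tn += 1
                else:
                    fp += 1
        tss = tp / (tp + fn) + tn / (tn + fp) - 1.0
        if tss > best_tss:
            best_tss, best_t = tss, t
    return best_tss, best_t


def pair_counting_auc(scores, y):
    """P(presence outscores absence), ties counted half, by full enumeration."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pres = scores[y == 1]
    abs_ = scores[y == 0]
    wins = 0.0
    for p in pres:
        for a in abs_:
            if p > a:
                wins += 1.0
            elif p == a:
                wins += 0.5
    return wins / (len(pres) * len(abs_))


def one_way_anova_oracle(groups):
    """Classical one-way ANOVA (SSB, SSW, F) computed by hand."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    f = (ssb / df_b) / (ssw / df_w)
    return ssb, ssw, df_b, df_w, f
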