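"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths (and scipy's
hypergeometric machinery) so they can serve as cross-checks.
"""

from math import comb


def fisher_oracle(tp, fp, fn, tn, sided="two-sided"):
    """Fisher exact p-value by naive enumeration with exact rational
    binomial coefficients, collapsed to float at the end."""
    n = tp + fp + fn + tn
    row1, col1 = tp + fp, tp + fn
    denom = comb(n, col1)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    weights = {
        k: comb(row1, k) * comb(n - row1, col1 - k) for k in range(lo, hi + 1)
    }
    if sided == "greater":
        num = sum(w for k, w in weights.items() if k >= tp)
    elif sided == "less":
        num = sum(w for k, w in weights.items() if k <= tp)
    else:
        w_obs = weights[tp]
        num = sum(w for w in weights.values() if w <= w_obs)
    return num / denom


def kappa_oracle(pairs):
    """Cohen's kappa from first principles on a list of (a, b) label pairs."""
    n = len(pairs)
    po = sum(a == b for a, b in pairs) / n
    labels = {x for p in pairs for x in p}
    pe = sum(
        (sum(a == lab for a, _ in pairs) / n) * (sum(b == lab for _, b in pairs) / n)
        for lab in labels
    )
    return (po - pe) / (1 - pe)
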