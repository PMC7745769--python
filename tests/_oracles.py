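"""Brute-force reference implementations used to validate the fast engines.

These stay deliberately naive — enumerate every width, window and edit —
so they are independent of the vectorized implementations they check.
"""

from itertools import product

import numpy as np
from scipy.special import gammaln


def base_match(p: str, c: str) -> bool:
    return p == c or (c == "Y" and p in "CT") or (c == "R" and p in "AG")


def oracle_exact(probe: str, strand: str, cap: int = 50) -> int:
    for w in range(min(len(probe), cap), 0, -1):
        suf = probe[-w:]
        for s in range(len(strand) - w + 1):
            if all(base_match(a, b) for a, b in zip(suf, strand[s : s + w])):
                return w
    return 0


def oracle_inexact(probe: str, strand: str, clearance: int = 5, cap: int = 50) -> int:
    """Largest 3' suffix width matching with <= 1 admissible edit.

    Edit conventions mirrored from the engine contract: the 3'-terminal
    base has offset 1 and an edit needs offset > clearance; a substitution
    may sit anywhere in the window (subject to clearance) but never on a
    degenerate strand base; indels must be internal to the window.
    """
    for w in range(min(len(probe), cap), 0, -1):
        suf = probe[-w:]
        # exact
        for s in range(len(strand) - w + 1):
            if all(base_match(a, b) for a, b in zip(suf, strand[s : s + w])):
                return w
        # one substitution
        for s in range(len(strand) - w + 1):
            win = strand[s : s + w]
            mm = [i for i in range(w) if not base_match(suf[i], win[i])]
            if len(mm) == 1:
                i = mm[0]
                if w - i > clearance and win[i] not in "YR":
                    return w
        # one probe-base deletion at suffix index i (offset w - i)
        for i in range(1, w):
            if w - i <= clearance:
                continue
            s2 = suf[:i] + suf[i + 1 :]
            for s in range(len(strand) - (w - 1) + 1):
                if all(base_match(a, b) for a, b in zip(s2, strand[s : s + w - 1])):
                    return w
        # one strand-base insertion between suffix positions g-1 and g
        for g in range(1, w):
            if w - g <= clearance:
                continue
            for s in range(len(strand) - (w + 1) + 1):
                win = strand[s : s + w + 1]
                if all(base_match(a, b) for a, b in zip(suf, win[:g] + win[g + 1 :])):
                    return w
    return 0


def oracle_fisher_p(table) -> float:
    """Two-sided Fisher p by exhaustive enumeration over fixed margins."""
    (a, b), (c, d) = table
    n, m1, N = a + b, a + c, a + b + c + d
    m2 = N - m1
    lo, hi = max(0, n - m2), min(n, m1)

    def logpmf(k: int) -> float:
        return (
            gammaln(m1 + 1) - gammaln(k + 1) - gammaln(m1 - k + 1)
            + gammaln(m2 + 1) - gammaln(n - k + 1) - gammaln(m2 - n + k + 1)
            - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
        )

    probs = {k: np.exp(logpmf(k)) for k in range(lo, hi + 1)}
    cutoff = probs[a] * (1 + 1e-7)
    return float(sum(p for p in probs.values() if p <= cutoff))


def oracle_conditional_mle_or(table, grid=None) -> float:
    """Conditional MLE by maximizing the conditional log-likelihood on a
    dense grid of log-odds values (independent of any root-finder)."""
    (a, b), (c, d) = table
    n, m1, N = a + b, a + c, a + b + c + d
    m2 = N - m1
    lo, hi = max(0, n - m2), min(n, m1)
    if a == hi:
        return float("inf")
    if a == lo:
        return 0.0
    k = np.arange(lo, hi + 1)
    logw = (
        gammaln(m1 + 1) - gammaln(k + 1) - gammaln(m1 - k + 1)
        + gammaln(m2 + 1) - gammaln(n - k + 1) - gammaln(m2 - n + k + 1)
    )
    grid = np.linspace(-15, 15, 600001) if grid is None else grid
    # loglik(psi) = logw[a] + a*logpsi - logsumexp(logw + k*logpsi)
    t = logw[None, :] + np.outer(grid, k)
    tmax = t.max(axis=1, keepdims=True)
    lse = tmax[:, 0] + np.log(np.exp(t - tmax).sum(axis=1))
    ll = a * grid - lse
    return float(np.exp(grid[np.argmax(ll)]))
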