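"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the library's own code paths: the AUROC oracle
counts pairs exhaustively (optionally in exact rational arithmetic) and the
stepwise oracle replays the forward/backward path with statsmodels OLS
p-values.
"""

from fractions import Fraction

import numpy as np
import statsmodels.api as sm


def auroc_pairwise(dp, dn, exact=False):
    """(wins + half-ties) / (n m) by explicit enumeration of all pairs."""
    if exact:
        wins = sum(
            Fraction(1) if p < n else (Fraction(1, 2) if p == n else Fraction(0))
            for p in dp
            for n in dn
        )
        return wins / (len(dp) * len(dn))
    wins = sum(
        1.0 if p < n else (0.5 if p == n else 0.0) for p in dp for n in dn
    )
    return wins / (len(dp) * len(dn))


def stepwise_path(X, y, p_enter=0.1, p_remove=0.15):
    """Forward-entry / backward-removal path via statsmodels, returning the
    sorted retained column indices."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    active = []
    while True:
        changed = False
        best, best_p = None, np.inf
        for j in range(X.shape[1]):
            if j in active:
                continue
            design = sm.add_constant(X[:, active + [j]], has_constant="add")
            if np.linalg.matrix_rank(design) < design.shape[1]:
                continue
            res = sm.OLS(y, design).fit()
            p = res.pvalues[-1]
            if np.isfinite(p) and p < best_p:
                best_p, best = p, j
        if best is not None and best_p < p_enter:
            active.append(best)
            changed = True
        while active:
            design = sm.add_constant(X[:, active], has_constant="add")
            res = sm.OLS(y, design).fit()
            pv = np.asarray(res.pvalues)[1:]
            worst = int(np.nanargmax(pv))
            if np.isnan(pv[worst]) or pv[worst] > p_remove:
                active.pop(worst)
                changed = True
            else:
                break
        if not changed:
            return sorted(active)
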