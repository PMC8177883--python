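"""Shared independent oracles for the test suite."""

import numpy as np
import pandas as pd
import statsmodels.api as sm

def exhaustive_forward_path(y, X, p_enter=0.05, p_remove=0.10):
    """Oracle: stepwise path computed by brute-force OLS over all candidate
    additions/removals using statsmodels, for <= 5 predictors."""
    from scipy import stats as sps
    included = []
    cols = list(X.columns)
    yv = np.asarray(y, dtype=float)

    def rss(names):
        Xd = sm.add_constant(X[names]) if names else \
            pd.DataFrame({"const": np.ones(len(yv))})
        return float(sm.OLS(yv, Xd).fit().ssr)

    while True:
        base_rss = rss(included)
        dfb = len(yv) - len(included) - 1
        best = None
        for c in cols:
            if c in included:
                continue
            new_rss = rss(included + [c])
            if new_rss <= 0:
                f, p = np.inf, 0.0
            else:
                f = (base_rss - new_rss) / (new_rss / (dfb - 1))
                p = float(sps.f.sf(f, 1, dfb - 1))
            if best is None or p < best[0]:
                best = (p, c)
        if best is None or best[0] > p_enter:
            break
        included.append(best[1])
        # backward
        while len(included) > 1:
            full_rss = rss(included)
            dff = len(yv) - len(included) - 1
            worst = None
            for c in included:
                red = rss([v for v in included if v != c])
                f = (red - full_rss) / (full_rss / dff) if full_rss > 0 else np.inf
                p = float(sps.f.sf(f, 1, dff)) if np.isfinite(f) else 0.0
                if worst is None or p > worst[0]:
                    worst = (p, c)
            if worst[0] >= p_remove:
                included.remove(worst[1])
            else:
                break
        if best[0] > p_enter:
            break
    return included
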