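"""Independent brute-force oracles used by the test suite.

These deliberately use naive Python loops and dictionaries, not the
package's vectorized code paths.
"""

import math


def naive_normalize(depths, pools):
    """Four-step normalization with explicit loops.

    Parameters
    ----------
    depths : dict[(amplicon, sample)] -> number
    pools : dict[amplicon] -> pool id

    Returns
    -------
    (pool_means, rel, reference, norm) as plain dicts;
    undefined values are represented as None.
    """
    amplicons = sorted(pools)
    samples = sorted({s for (_, s) in depths})
    pool_ids = sorted(set(pools.values()))

    pool_means = {}
    for s in samples:
        for p in pool_ids:
            members = [a for a in amplicons if pools[a] == p]
            pool_means[(s, p)] = sum(depths[(a, s)] for a in members) / len(members)

    rel = {}
    for a in amplicons:
        for s in samples:
            pm = pool_means[(s, pools[a])]
            rel[(a, s)] = depths[(a, s)] / pm if pm != 0 else None

    reference = {}
    for a in amplicons:
        vals = [rel[(a, s)] for s in samples if rel[(a, s)] is not None]
        reference[a] = sum(vals) / len(vals) if vals else None

    norm = {}
    for a in amplicons:
        for s in samples:
            r, ref = rel[(a, s)], reference[a]
            if r is None or ref is None or ref == 0:
                norm[(a, s)] = None
            else:
                norm[(a, s)] = 2.0 * r / ref
    return pool_means, rel, reference, norm


def welch_t_p(x, y):
    """Textbook two-sided Welch t-test p-value via the t survival function."""
    from scipy.stats import t as tdist

    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        return 1.0 if mx == my else 0.0
    tstat = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return 2.0 * tdist.sf(abs(tstat), df)
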