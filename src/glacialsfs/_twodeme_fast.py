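"""JIT-compiled two-deme structured-coalescent kernel.

Used by the divergence-model fitter, where the expected joint spectrum
is re-simulated at every objective evaluation; the pure-Python
implementation in :mod:`glacialsfs.simdata` remains the reference (and
the generator used for data simulation).  Both implement the same
process: coalescence at rate ``k(k-1)/(4N)`` within demes, per-lineage
backward migration at rate ``Nm/(2N)``, demes merging ``tdiv``
generations ago, and an optional ancestral size change at ``tsep``.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def two_deme_branch_lengths(
    n1, n2, npop1, npop2, ncur, nanc, tdiv, tsep, has_anc,
    m_out1, m_out2, reps, seed, max_events,
):
    """Accumulated branch lengths by raw descendant configuration.

    Returns ``(lengths, ok)`` where ``lengths[i, j]`` sums, over ``reps``
    genealogies, the lengths of branches subtending ``i`` leaves from
    deme 1 and ``j`` from deme 2; ``ok`` is False when any genealogy
    exceeded the event budget (pathological migration corners).
    """
    n = n1 + n2
    lengths = np.zeros((n1 + 1, n2 + 1))
    np.random.seed(seed)
    deme = np.empty(n, np.int64)
    d1 = np.empty(n, np.int64)
    d2 = np.empty(n, np.int64)
    birth = np.empty(n, np.float64)
    for _ in range(reps):
        for i in range(n1):
            deme[i] = 0
            d1[i] = 1
            d2[i] = 0
            birth[i] = 0.0
        for i in range(n1, n):
            deme[i] = 1
            d1[i] = 0
            d2[i] = 1
            birth[i] = 0.0
        k = n
        t = 0.0
        events = 0
        # two-deme phase, looking back until the split time
        while k > 1 and t < tdiv:
            k1 = 0
            for i in range(k):
                if deme[i] == 0:
                    k1 += 1
            k2 = k - k1
            r_c1 = k1 * (k1 - 1) / (4.0 * npop1)
            r_c2 = k2 * (k2 - 1) / (4.0 * npop2)
            r_m1 = k1 * m_out1
            r_m2 = k2 * m_out2
            total = r_c1 + r_c2 + r_m1 + r_m2
            if total <= 0.0:
                break
            w = np.random.exponential(1.0 / total)
            if t + w >= tdiv:
                break
            t += w
            events += 1
            if events > max_events:
                return lengths, False
            u = np.random.random() * total
            if u < r_c1 + r_c2:
                which = 0
                kk = k1
                if u >= r_c1:
                    which = 1
                    kk = k2
                a = np.random.randint(kk)
                b = np.random.randint(kk - 1)
                if b >= a:
                    b += 1
                ia = -1
                ib = -1
                c = 0
                for i in range(k):
                    if deme[i] == which:
                        if c == a:
                            ia = i
                        if c == b:
                            ib = i
                        c += 1
                lengths[d1[ia], d2[ia]] += t - birth[ia]
                lengths[d1[ib], d2[ib]] += t - birth[ib]
                d1[ia] += d1[ib]
                d2[ia] += d2[ib]
                birth[ia] = t
                k -= 1
                deme[ib] = deme[k]
                d1[ib] = d1[k]
                d2[ib] = d2[k]
                birth[ib] = birth[k]
            elif u < r_c1 + r_c2 + r_m1:
                a = np.random.randint(k1)
                c = 0
                for i in range(k):
                    if deme[i] == 0:
                        if c == a:
                            deme[i] = 1
                            break
                        c += 1
            else:
                a = np.random.randint(k2)
                c = 0
                for i in range(k):
                    if deme[i] == 1:
                        if c == a:
                            deme[i] = 0
                            break
                        c += 1
        # ancestral phase(s)
        if k > 1 and t < tdiv:
            t = tdiv
        while k > 1:
            if has_anc and t >= tsep:
                ne = nanc
                t_end = 1e300
            elif has_anc:
                ne = ncur
                t_end = tsep
            else:
                ne = ncur
                t_end = 1e300
            rate = k * (k - 1) / (4.0 * ne)
            w = np.random.exponential(1.0 / rate)
            if t + w < t_end:
                t += w
                a = np.random.randint(k)
                b = np.random.randint(k - 1)
                if b >= a:
                    b += 1
                lengths[d1[a], d2[a]] += t - birth[a]
                lengths[d1[b], d2[b]] += t - birth[b]
                d1[a] += d1[b]
                d2[a] += d2[b]
                birth[a] = t
                k -= 1
                deme[b] = deme[k]
                d1[b] = d1[k]
                d2[b] = d2[k]
                birth[b] = birth[k]
            else:
                t = t_end
    return lengths, True
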