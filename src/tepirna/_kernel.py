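"""Numba kernels for the Wright-Fisher TE:piRNA forward simulation.

The population lives in flat, per-locus arrays grouped by individual:
``pos`` (0-based bp), ``sub`` (subtype id), ``pirna`` (1 = piRNA-generating
locus), ``homolog`` (0/1), with ``offsets`` (length Ne+1) delimiting each
individual's slice.  Both kernels are deterministic given the ``seed``
argument (numba's nopython np.random stream is seeded inside the kernel).
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_OVERFLOW = 1
STATUS_ZERO_FITNESS = 2


@njit(cache=True)
def fitness_rates(sub, pirna, offsets, R, s, a, b, p, u, per_subtype_excess):
    """Per-individual fitness w, effective load n, excess piRNA m, TE
    count, pooled transposition rate, and the per-locus transposition rate
    u/(1 + R*y_j/x_j) for TE loci.

    ``urate`` (per individual) equals the common per-element rate when the
    individual carries a single TE subtype; it is only consulted by the
    offspring kernel when no escape mutation has ever occurred (all loci
    share subtype 0), in which case it is exact.
    """
    Ne = offsets.shape[0] - 1
    nloci = sub.shape[0]
    w = np.empty(Ne, np.float64)
    neff = np.empty(Ne, np.float64)
    mex = np.empty(Ne, np.float64)
    xcnt = np.zeros(Ne, np.int64)
    urate = np.zeros(Ne, np.float64)
    rate = np.zeros(nloci, np.float64)
    maxseg = 0
    for k in range(Ne):
        c = offsets[k + 1] - offsets[k]
        if c > maxseg:
            maxseg = c
    subs = np.empty(maxseg, np.int64)
    xs = np.empty(maxseg, np.int64)
    ys = np.empty(maxseg, np.int64)
    for k in range(Ne):
        lo = offsets[k]
        hi = offsets[k + 1]
        nsub = 0
        for idx in range(lo, hi):
            sj = sub[idx]
            found = -1
            for t in range(nsub):
                if subs[t] == sj:
                    found = t
                    break
            if found < 0:
                subs[nsub] = sj
                xs[nsub] = 0
                ys[nsub] = 0
                found = nsub
                nsub += 1
            if pirna[idx]:
                ys[found] += 1
            else:
                xs[found] += 1
        n = 0.0
        xt = 0
        yt = 0
        m = 0.0
        for t in range(nsub):
            x = xs[t]
            y = ys[t]
            xt += x
            yt += y
            if x > 0:
                n += x / (1.0 + R * y / x)
            if per_subtype_excess:
                dm = y - x
                if dm > 0:
                    m += dm
        if not per_subtype_excess:
            m = float(yt - xt)
            if m < 0.0:
                m = 0.0
        w[k] = np.exp(-s * a * n - 0.5 * s * b * n * n
                      + p * (-s * a * m - 0.5 * s * b * m * m))
        neff[k] = n
        mex[k] = m
        xcnt[k] = xt
        if xt > 0:
            r_ = u / (1.0 + R * yt / xt)
            urate[k] = r_ if r_ < 1.0 else 1.0
        for idx in range(lo, hi):
            if not pirna[idx]:
                sj = sub[idx]
                for t in range(nsub):
                    if subs[t] == sj:
                        x = xs[t]
                        y = ys[t]
                        r_ = u / (1.0 + R * y / x)
                        if r_ > 1.0:
                            r_ = 1.0
                        rate[idx] = r_
                        break
    return w, neff, mex, rate, xcnt, urate


@njit(cache=True)
def make_offspring(pos, sub, pirna, homolog, offsets, w, rate, xcnt, urate,
                   L, d, i_rate, i_pi_rate, e_rate, f, rL,
                   next_subtype, seed, cap):
    """One Wright-Fisher generation: fitness-proportional parent sampling,
    transposition in each sampled parent, one gamete per parent
    (recombination then excision/escape/duplication), union of gametes.

    Returns (status, pos, sub, pirna, homolog, offsets, next_subtype).
    status=1 means the ``cap`` preallocation overflowed (caller retries
    with a larger cap); status=2 means total fitness is zero.
    """
    np.random.seed(seed)
    Ne = offsets.shape[0] - 1
    cumw = np.cumsum(w)
    tot = cumw[Ne - 1]
    empty64 = np.empty(0, np.int64)
    empty8 = np.empty(0, np.uint8)
    if tot <= 0.0:
        return (STATUS_ZERO_FITNESS, empty64, empty64, empty8, empty8,
                offsets, next_subtype)
    # single-subtype fast path: every locus is subtype 0 iff no escape ever
    uniform = next_subtype == 1
    out_pos = np.empty(cap, np.int64)
    out_sub = np.empty(cap, np.int64)
    out_pir = np.empty(cap, np.uint8)
    out_hom = np.empty(cap, np.uint8)
    out_off = np.zeros(Ne + 1, np.int64)
    ins_cap = 1024
    ins_pos = np.empty(ins_cap, np.int64)
    ins_sub = np.empty(ins_cap, np.int64)
    ins_pir = np.empty(ins_cap, np.uint8)
    ins_hom = np.empty(ins_cap, np.uint8)
    nbp_cap = 64 + int(8.0 * rL)
    bps = np.empty(nbp_cap, np.float64)
    keep_d = i_rate + (1.0 - i_rate) * d          # TE: survive & duplicate
    keep_d_pi = i_pi_rate + (1.0 - i_pi_rate) * d  # piRNA locus ditto
    nout = 0
    status = STATUS_OK
    for g in range(2 * Ne):
        # fitness-proportional parent draw
        rv = np.random.random() * tot
        par = np.searchsorted(cumw, rv)
        if par >= Ne:
            par = Ne - 1
        lo = offsets[par]
        hi = offsets[par + 1]
        # transposition in this parent (independently per use of the
        # parent); new insertions join the parental genome before meiosis
        nins = 0
        if uniform:
            k_ins = 0
            if xcnt[par] > 0 and urate[par] > 0.0:
                k_ins = np.random.binomial(xcnt[par], urate[par])
            for _ in range(k_ins):
                if nins >= ins_cap:
                    break
                q = np.random.randint(0, L)
                coll = True
                while coll:
                    coll = False
                    for t2 in range(nins):
                        if ins_pos[t2] == q:
                            q = np.random.randint(0, L)
                            coll = True
                            break
                ins_pos[nins] = q
                ins_sub[nins] = 0
                ins_pir[nins] = 1 if np.random.random() < f else 0
                ins_hom[nins] = 1 if np.random.random() < 0.5 else 0
                nins += 1
        else:
            for idx in range(lo, hi):
                if (not pirna[idx]) and rate[idx] > 0.0 \
                        and np.random.random() < rate[idx]:
                    if nins >= ins_cap:
                        break
                    q = np.random.randint(0, L)
                    coll = True
                    while coll:
                        coll = False
                        for t2 in range(nins):
                            if ins_pos[t2] == q:
                                q = np.random.randint(0, L)
                                coll = True
                                break
                    ins_pos[nins] = q
                    ins_sub[nins] = sub[idx]
                    ins_pir[nins] = 1 if np.random.random() < f else 0
                    ins_hom[nins] = 1 if np.random.random() < 0.5 else 0
                    nins += 1
        # meiosis: crossovers ~ Poisson(r*L), uniform breakpoints
        nbp = np.random.poisson(rL)
        if nbp > nbp_cap:
            nbp = nbp_cap
        for t2 in range(nbp):
            bps[t2] = np.random.random() * L
        for t2 in range(1, nbp):  # insertion sort (nbp is tiny)
            v = bps[t2]
            t3 = t2 - 1
            while t3 >= 0 and bps[t3] > v:
                bps[t3 + 1] = bps[t3]
                t3 -= 1
            bps[t3 + 1] = v
        h0 = 1 if np.random.random() < 0.5 else 0
        off_hom = np.uint8(g & 1)
        nsrc = (hi - lo) + nins
        for t2 in range(nsrc):
            if t2 < hi - lo:
                idx = lo + t2
                q = pos[idx]
                h = homolog[idx]
                sj = sub[idx]
                pi_ = pirna[idx]
            else:
                t4 = t2 - (hi - lo)
                q = ins_pos[t4]
                h = ins_hom[t4]
                sj = ins_sub[t4]
                pi_ = ins_pir[t4]
            cnt = 0
            for t3 in range(nbp):
                if bps[t3] <= q:
                    cnt += 1
            if ((h0 + cnt) & 1) != h:
                continue
            # excision / duplication decided by one partitioned draw;
            # escape (TE only) drawn separately when e > 0
            dup = False
            uvar = np.random.random()
            if pi_:
                if uvar < i_pi_rate:
                    continue
                dup = uvar < keep_d_pi
            else:
                if uvar < i_rate:
                    continue
                dup = uvar < keep_d
                if e_rate > 0.0 and np.random.random() < e_rate:
                    sj = next_subtype  # escape to a fresh subtype
                    next_subtype += 1
            if nout + 2 > cap:
                status = STATUS_OVERFLOW
                break
            out_pos[nout] = q
            out_sub[nout] = sj
            out_pir[nout] = pi_
            out_hom[nout] = off_hom
            nout += 1
            if dup:
                out_pos[nout] = np.random.randint(0, L)
                out_sub[nout] = sj
                out_pir[nout] = pi_
                out_hom[nout] = off_hom
                nout += 1
        if status != STATUS_OK:
            break
        if (g & 1) == 1:
            out_off[(g >> 1) + 1] = nout
    if status != STATUS_OK:
        return (status, empty64, empty64, empty8, empty8, out_off,
                next_subtype)
    return (STATUS_OK, out_pos[:nout].copy(), out_sub[:nout].copy(),
            out_pir[:nout].copy(), out_hom[:nout].copy(), out_off,
            next_subtype)
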