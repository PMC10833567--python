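"""Literal brute-force re-implementation of the tally/top/collapse/call
pipeline, used as an independent oracle. Enumerates every (shift, fragment)
pair and applies the published rules directly, with no shared code with the
package implementation."""

from collections import Counter


def brute_tally(downstreams, n, m):
    counts = Counter()
    for d in downstreams:
        for k in range(m + 1):
            if k + n <= len(d):
                counts[(k, d[k : k + n])] += 1
    n_tallied = sum(1 for d in downstreams if len(d) >= n)
    n_empty = sum(1 for d in downstreams if d == "")
    return counts, n_tallied, n_empty


def brute_top(counts, top_k):
    kept = {}
    for s in sorted({k for k, _ in counts}):
        group = sorted(
            ((f, c) for (k, f), c in counts.items() if k == s),
            key=lambda fc: (-fc[1], fc[0]),
        )
        for f, c in group[:top_k]:
            kept[(s, f)] = c
    return kept


def brute_pool(kept, ratio, max_jump):
    def children(s, f):
        return [(s2, f2) for (s2, f2) in kept if s2 == s + 1 and f2[:-1] == f[1:]]

    pool = {}
    for s, f in kept:
        has_parent = any(s0 + 1 == s and f0[1:] == f[:-1] for (s0, f0) in kept)
        if has_parent:
            continue
        cur = (s, f)
        while True:
            cs = children(*cur)
            if not cs:
                break
            best = sorted(cs, key=lambda sf: (-kept[sf], sf[1]))[0]
            if ratio < kept[best] / kept[cur] <= max_jump:
                cur = best
            else:
                break
        pool[cur] = kept[cur]
    return pool


def brute_call(pool, n_tallied, n_empty, n_matched,
               none_fraction, min_support, polyA_fraction, max_jump):
    if n_empty / n_matched >= none_fraction or not pool:
        return ("none", "", 0, 0, 0.0)
    (shift, frag), count = sorted(
        pool.items(), key=lambda it: (-it[1], it[0][0], it[0][1])
    )[0]
    seen = {frag}
    while True:
        ext = [
            (f2, c2) for (s2, f2), c2 in pool.items()
            if s2 == shift and f2 not in seen and f2[1:] == frag[:-1]
            and c2 >= count / max_jump
        ]
        if not ext:
            break
        frag, count = sorted(ext, key=lambda fc: (-fc[1], fc[0]))[0]
        seen.add(frag)
    support = count / max(n_tallied, 1)
    if support < min_support:
        return ("none", "", 0, 0, 0.0)
    klass = "polyA" if frag.count("A") / len(frag) >= polyA_fraction else "sequence"
    return (klass, frag, shift, count, support)


def brute_pipeline(downstreams, params, n_matched):
    counts, n_tallied, n_empty = brute_tally(downstreams, params.n_frag, params.m_shift)
    kept = brute_top(counts, params.top_k)
    pool = brute_pool(kept, params.ratio_cutoff, params.max_jump)
    call = brute_call(
        pool, n_tallied, n_empty, n_matched,
        params.none_fraction, params.min_support, params.polyA_fraction,
        params.max_jump,
    )
    return counts, kept, pool, call
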