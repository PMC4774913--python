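"""Brute-force reference implementations of the coreference metrics,
written independently of the library (explicit loops, exhaustive
alignment search) for dual-route checking on small partitions."""

from itertools import combinations, permutations


def _f1(p, r):
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def _universe(gold, pred):
    u = set()
    for c in list(gold) + list(pred):
        u |= set(c)
    return u


def _pad(chains, universe):
    covered = set()
    for c in chains:
        covered |= set(c)
    return [set(c) for c in chains] + [{m} for m in universe - covered]


def _components(chain, other_partition):
    """Number of pieces a chain is cut into by another partition (mentions
    absent from the other side are singleton pieces)."""
    pieces = 0
    remaining = set(chain)
    for other in other_partition:
        inter = remaining & set(other)
        if inter:
            pieces += 1
            remaining -= inter
    return pieces + len(remaining)


def muc_oracle(gold, pred):
    def side(keys, response):
        num = den = 0
        for k in keys:
            num += len(k) - _components(k, response)
            den += len(k) - 1
        return num / den if den else 0.0

    r = side(gold, pred)
    p = side(pred, gold)
    return p, r, _f1(p, r)


def bcubed_oracle(gold, pred):
    u = _universe(gold, pred)
    g = _pad(gold, u)
    p = _pad(pred, u)
    if not u:
        return 1.0, 1.0, 1.0
    prec = rec = 0.0
    for m in u:
        gc = next(c for c in g if m in c)
        pc = next(c for c in p if m in c)
        inter = len(gc & pc)
        prec += inter / len(pc)
        rec += inter / len(gc)
    prec /= len(u)
    rec /= len(u)
    return prec, rec, _f1(prec, rec)


def ceaf_oracle(gold, pred, variant="mention"):
    u = _universe(gold, pred)
    g = _pad(gold, u)
    p = _pad(pred, u)

    def phi(a, b):
        if variant == "mention":
            return len(a & b)
        return 2 * len(a & b) / (len(a) + len(b))

    small, large, swapped = (g, p, False) if len(g) <= len(p) else (p, g, True)
    best = 0.0
    for perm in permutations(range(len(large)), len(small)):
        score = sum(phi(small[i], large[j]) for i, j in enumerate(perm))
        best = max(best, score)
    if variant == "mention":
        den_r = sum(len(c) for c in g)
        den_p = sum(len(c) for c in p)
    else:
        den_r = len(g)
        den_p = len(p)
    prec = best / den_p if den_p else 0.0
    rec = best / den_r if den_r else 0.0
    return prec, rec, _f1(prec, rec)


def blanc_oracle(gold, pred):
    u = sorted(_universe(gold, pred), key=repr)
    if len(u) < 2:
        return 1.0, 1.0, 1.0

    def coref(chains, a, b):
        return any(a in c and b in c for c in chains)

    cg = cp = ng = np = both_c = both_n = 0
    for a, b in combinations(u, 2):
        in_g = coref(gold, a, b)
        in_p = coref(pred, a, b)
        cg += in_g
        cp += in_p
        ng += not in_g
        np += not in_p
        both_c += in_g and in_p
        both_n += (not in_g) and (not in_p)
    pc = both_c / cp if cp else (1.0 if not cg else 0.0)
    rc = both_c / cg if cg else (1.0 if not cp else 0.0)
    pn = both_n / np if np else (1.0 if not ng else 0.0)
    rn = both_n / ng if ng else (1.0 if not np else 0.0)
    return (pc + pn) / 2, (rc + rn) / 2, (_f1(pc, rc) + _f1(pn, rn)) / 2


def random_partition(rng, items):
    """Random set partition of the items (uniform over assignments)."""
    if not items:
        return []
    n_blocks = rng.randint(1, len(items))
    blocks = [set() for _ in range(n_blocks)]
    for x in items:
        blocks[rng.randrange(n_blocks)].add(x)
    return [frozenset(b) for b in blocks if b]
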