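"""Independent exhaustive BFS oracle over composite rearrangement moves.

Enumerates every tandem-duplication/loss outcome and every block
translocation directly on token tuples, breadth-first, without the
package's meet-in-the-middle search — a brute-force second route for
checking minimal op counts.
"""

import itertools


def canon(tokens):
    n = len(tokens)
    return min(tokens[k:] + tokens[:k] for k in range(n))


def oracle_moves(state, max_block):
    n = len(state)
    out = set()
    for s in range(n):
        for l in range(2, min(max_block, n - 1) + 1):
            blk = tuple(state[(s + k) % n] for k in range(l))
            rest = tuple(state[(s + l + k) % n] for k in range(n - l))
            for mask in itertools.product((1, 2), repeat=l):
                c1 = tuple(blk[i] for i in range(l) if mask[i] == 1)
                c2 = tuple(blk[i] for i in range(l) if mask[i] == 2)
                out.add(canon(c1 + c2 + rest))
        for l in range(1, min(max_block, n - 1) + 1):
            blk = tuple(state[(s + k) % n] for k in range(l))
            rest = tuple(state[(s + l + k) % n] for k in range(n - l))
            for j in range(n - l):
                out.add(canon(rest[:j] + blk + rest[j:]))
    return out


def oracle_min_ops(source, target, max_depth, max_block=4):
    """Minimal composite-op count by plain BFS, or None beyond max_depth."""
    src, tgt = canon(source.tokens), canon(target.tokens)
    if src == tgt:
        return 0
    frontier = {src}
    seen = {src}
    for depth in range(1, max_depth + 1):
        nxt = set()
        for st in frontier:
            nxt |= oracle_moves(st, max_block)
        if tgt in nxt:
            return depth
        frontier = nxt - seen
        seen |= nxt
    return None
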