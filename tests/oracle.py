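"""Independent brute-force oracle for secondary-structure optimization.

Enumerates every nested pairing of a short sequence by the unique
"first position unpaired or paired with k" decomposition, filters by the
minimum-helix rule, and scores with the same pair weights.  Exponential, so
only usable for n <= ~14; fully independent of the dynamic program it checks.
"""

from __future__ import annotations

def _enum(seq, i, j, params):
    """Yield all nested pair sets (1-based tuples) on seq[i..j] (0-based)."""
    if i >= j:
        yield frozenset()
        return
    for rest in _enum(seq, i + 1, j, params):
        yield rest
    for k in range(i + params.min_loop + 1, j + 1):
        if params.pair_weight(seq[i], seq[k]) > 0:
            for left in _enum(seq, i + 1, k - 1, params):
                for right in _enum(seq, k + 1, j, params):
                    yield left | right | {(i + 1, k + 1)}


def _helix_ok(pairs, min_helix):
    """Every maximal stacked run must have >= min_helix pairs."""
    ps = set(pairs)
    for i, j in ps:
        if (i - 1, j + 1) in ps:
            continue
        h = 1
        while (i + h, j - h) in ps:
            h += 1
        if h < min_helix:
            return False
    return True


def brute_best(seq: str, params) -> float:
    """Maximum total pair weight over all valid structures (0.0 if none)."""
    seq = seq.upper()
    best = 0.0
    for pairs in _enum(seq, 0, len(seq) - 1, params):
        if not _helix_ok(pairs, params.min_helix):
            continue
        score = sum(params.pair_weight(seq[i - 1], seq[j - 1]) for i, j in pairs)
        if score > best:
            best = score
    return best


def naive_find_sites(seq: str, ct: str):
    """Quadratic substring search: all 0-based start positions of ct."""
    return [
        i
        for i in range(len(seq) - len(ct) + 1)
        if all(seq[i + k] == ct[k] for k in range(len(ct)))
    ]
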