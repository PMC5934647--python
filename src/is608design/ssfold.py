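"""Single-stranded DNA secondary structure by weighted base-pair maximization.

IS200/IS605-family transposition runs entirely on top-strand ssDNA, so the
functional state of a transposon end is governed by its fold: the subterminal
imperfect palindrome (IP_L) must form a stem-loop for transposase binding,
while any *additional* hairpin over the 3' extension window buries the bases
needed for extended target pairing.  For these questions a qualitative,
deterministic fold is sufficient; this module implements a Nussinov-style
maximum-weight nested pairing with two stabilizing constraints:

* a minimum hairpin loop size (``min_loop``), and
* a minimum helix length (``min_helix``): pairs only count inside runs of at
  least ``min_helix`` stacked pairs.  Isolated 1-2 bp duplexes are not stable
  at assay temperature and would otherwise make every window look occluded.

The optimum is exact (dynamic programming over all nested structures obeying
the constraints) and the traceback is deterministic: when several structures
tie, the one that pairs the 5'-most position first is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
__all__ = [
    "FoldParams",
    "SecondaryStructure",
    "DEFAULT_FOLD_PARAMS",
    "fold",
    "find_hairpins",
    "accessibility",
    "dot_bracket",
    "write_ct",
]

_VALID = set("ACGTN")


class FoldError(ValueError):
    """Invalid sequence or window passed to the folding module."""


@dataclass(frozen=True)
class FoldParams:
    """Scoring parameters for the weighted pair-maximization fold.

    pair_weights
        Weight per closed pair, keyed "AT", "GC", "GT" (orientation-free).
    min_loop
        Minimum number of unpaired bases enclosed by a hairpin-closing pair:
        a pair (i, j) requires j - i > min_loop.
    allow_GT
        Whether G:T wobble pairs may form (off by default; the hairpins that
        matter here are drawn with canonical pairs).
    min_helix
        Minimum stacked-run length for pairs to count (see module docstring).
    """

    pair_weights: dict = field(
        default_factory=lambda: {"AT": 2.0, "GC": 3.0, "GT": 1.0}
    )
    min_loop: int = 3
    allow_GT: bool = False
    min_helix: int = 3

    def __post_init__(self):
        if self.min_loop < 3:
            raise FoldError("min_loop must be >= 3")
        if self.min_helix < 1:
            raise FoldError("min_helix must be >= 1")
        for key, w in self.pair_weights.items():
            if w < 0:
                raise FoldError(f"pair weight {key} must be >= 0")

    def pair_weight(self, a: str, b: str) -> float:
        """Weight of pairing bases a and b, 0.0 if they cannot pair."""
        key = "".join(sorted((a, b)))
        if key == "AT":
            return float(self.pair_weights.get("AT", 0.0))
        if key == "CG":
            return float(self.pair_weights.get("GC", 0.0))
        if key == "GT" and self.allow_GT:
            return float(self.pair_weights.get("GT", 0.0))
        return 0.0


DEFAULT_FOLD_PARAMS = FoldParams()


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested set of base pairs on an ssDNA sequence.

    ``pairs`` holds 1-based (i, j) tuples with i < j; nestedness and
    single-pairing are invariants of construction by :func:`fold`.
    """

    seq: str
    pairs: frozenset
    score: float

    @property
    def paired_positions(self) -> frozenset:
        return frozenset(p for ij in self.pairs for p in ij)

    def dot_bracket(self) -> str:
        return dot_bracket(self)


def _check_seq(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise FoldError(f"invalid characters in sequence: {sorted(bad)}")
    return seq


def fold(seq: str, params: FoldParams = DEFAULT_FOLD_PARAMS) -> SecondaryStructure:
    """Return the maximum-total-weight nested pairing of ``seq``.

    Exact dynamic programming; deterministic tie-breaking (the traceback
    prefers closing the 5'-most pair).  Sequences up to a few hundred nt fold
    in well under a second; the cubic DP handles up to 10 kb in principle.
    """
    seq = _check_seq(seq)
    n = len(seq)
    if n > 10_000:
        raise FoldError("sequence longer than 10000 nt")
    if n == 0:
        return SecondaryStructure(seq="", pairs=frozenset(), score=0.0)

    min_loop = params.min_loop
    min_helix = params.min_helix

    # w[i][j]: pair weight (0-based), 0.0 if unpairable.
    w = [[0.0] * n for _ in range(n)]
    for i in range(n):
        ai = seq[i]
        wi = w[i]
        for j in range(i + 1, n):
            wi[j] = params.pair_weight(ai, seq[j])

    # run[i][j]: length of the maximal inward stacked run starting at (i, j).
    run = [[0] * n for _ in range(n)]
    for i in range(n - 2, -1, -1):
        wi = w[i]
        runi = run[i]
        runi1 = run[i + 1]
        for j in range(n - 1, i, -1):
            if wi[j] > 0.0:
                runi[j] = 1 + (runi1[j - 1] if j - 1 > i + 1 else 0)

    # M[i][j]: best score over seq[i..j] inclusive (0-based).
    M = [[0.0] * n for _ in range(n)]

    def helix_candidates(i: int, j: int):
        """Yield (k, h, stack_weight) for helices whose outer pair is (i, k)."""
        runi = run[i]
        for k in range(i + min_loop + 1, j + 1):
            r = runi[k]
            if r < min_helix:
                continue
            # innermost pair (i+h-1, k-h+1) must still enclose min_loop bases
            h_cap = (k - i + 1 - min_loop) // 2
            if h_cap < min_helix:
                continue
            sw = 0.0
            for t in range(min_helix - 1):
                sw += w[i + t][k - t]
            for h in range(min_helix, min(r, h_cap) + 1):
                sw += w[i + h - 1][k - h + 1]
                yield k, h, sw

    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i + 1][j]
            for k, h, sw in helix_candidates(i, j):
                inner = M[i + h][k - h] if i + h <= k - h else 0.0
                right = M[k + 1][j] if k + 1 <= j else 0.0
                cand = sw + inner + right
                if cand > best:
                    best = cand
            M[i][j] = best

    # Deterministic traceback: at each interval, prefer a helix closing the
    # 5'-most position over leaving it unpaired; ties resolved by the fixed
    # candidate iteration order (ascending k, then ascending helix length).
    pairs = set()
    stack = [(0, n - 1)]
    eps = 1e-9
    while stack:
        i, j = stack.pop()
        while i < j:
            target = M[i][j]
            if target <= eps:
                break
            chosen = None
            for k, h, sw in helix_candidates(i, j):
                inner = M[i + h][k - h] if i + h <= k - h else 0.0
                right = M[k + 1][j] if k + 1 <= j else 0.0
                if abs(sw + inner + right - target) <= eps:
                    chosen = (k, h)
                    break
            if chosen is None:
                i += 1  # i unpaired in the optimum
                continue
            k, h = chosen
            for t in range(h):
                pairs.add((i + t + 1, k - t + 1))  # 1-based
            if k + 1 <= j:
                stack.append((k + 1, j))
            if i + h <= k - h:
                i, j = i + h, k - h
            else:
                break

    score = sum(w[i - 1][j - 1] for i, j in pairs)
    return SecondaryStructure(seq=seq, pairs=frozenset(pairs), score=score)


def find_hairpins(struct: SecondaryStructure, min_stem: int = 2):
    """Decompose a structure's pair set into maximal stacked helices.

    Returns ``(outer_start, outer_end, stem_len, loop_len)`` tuples (1-based,
    outermost pair coordinates) for every maximal run of >= ``min_stem``
    stacked pairs, sorted by outer_start.  ``loop_len`` counts the unpaired
    positions strictly inside the innermost pair of the helix (for a clean
    hairpin this is the terminal loop size; for a helix closing a multiloop
    it counts the unpaired bases of that interior region).
    """
    pairs = set(struct.pairs)
    paired = struct.paired_positions
    out = []
    for i, j in sorted(pairs):
        if (i - 1, j + 1) in pairs:
            continue  # not the outermost pair of its run
        h = 1
        while (i + h, j - h) in pairs:
            h += 1
        if h < min_stem:
            continue
        inner_i, inner_j = i + h - 1, j - h + 1
        loop_len = sum(
            1 for p in range(inner_i + 1, inner_j) if p not in paired
        )
        out.append((i, j, h, loop_len))
    out.sort()
    return out


def accessibility(struct: SecondaryStructure, window) -> float:
    """Unpaired fraction of a 1-based closed position interval.

    Quantifies how available a window (e.g. the +44..+51 extension) is for
    intermolecular pairing with a target: 1.0 means fully single-stranded.
    """
    start, end = window
    n = len(struct.seq)
    if not (1 <= start <= end <= n):
        raise FoldError(f"window {window} outside sequence of length {n}")
    paired = struct.paired_positions
    width = end - start + 1
    free = sum(1 for p in range(start, end + 1) if p not in paired)
    return free / width


def dot_bracket(struct: SecondaryStructure) -> str:
    chars = ["."] * len(struct.seq)
    for i, j in struct.pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


def write_ct(struct: SecondaryStructure, handle, title: str = "structure") -> None:
    """Write the structure in connectivity-table (.ct) format."""
    partner = {}
    for i, j in struct.pairs:
        partner[i] = j
        partner[j] = i
    n = len(struct.seq)
    handle.write(f"{n}\t{title}\n")
    for p in range(1, n + 1):
        handle.write(
            f"{p}\t{struct.seq[p - 1]}\t{p - 1}\t{(p + 1) if p < n else 0}"
            f"\t{partner.get(p, 0)}\t{p}\n"
        )
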