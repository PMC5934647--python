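"""Sequence and feature model for IS608 ends, junctions and target oligos.

Coordinate conventions
----------------------
* Transposon-end positions are 1-based on the top strand written 5'->3' and
  written with a ``+`` prefix in prose (+16..+19 is the G_L tetranucleotide).
  On a junction oligo the left-end coordinate system starts at the ``LE``
  feature; :meth:`TransposonEnd.le_base` translates.
* Target-oligo positions are cleavage-relative: the core tetranucleotide C_T
  occupies -4..-1 and cleavage falls between -1 and +1 (immediately 3' of
  C_T).  The base at +1 is the one the transposase covalently attacks.
* Genome coordinates in BED output are 0-based half-open.

Fixture generators
------------------
The wild-type IS608 end sequences live in supplementary material only, so
tests and demonstrations run on synthetic ends that pin the functionally
characterized anchors: G_L = AAAG at +16..+19, a perfect-palindrome IP_L
stem-loop over +20..+41, the triplet-forming A+42/T+43, an extension window
opening at +44, and (optionally) a second hairpin over +46..+60 whose 3' arm
(+55..+60) occludes the extension.  Random filler is drawn deterministically
from the seed and redrawn until the fold (``ssfold``) exhibits exactly the
intended architecture, so every fixture is a genuine, verifiable instance of
the element layout rather than a hard-coded string.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from typing import Optional

from .ssfold import accessibility, find_hairpins, fold

__all__ = [
    "CL",
    "CR",
    "GL",
    "GR",
    "CT_DEFAULT",
    "TransposonEnd",
    "TargetSite",
    "Oligo",
    "OligoPool",
    "revcomp",
    "make_synthetic_le",
    "make_canonical_junction",
    "make_target_fixtures",
    "make_locus_fixture",
    "longest_match_run",
]

# Field-standard motifs (top strand, 5'->3')
CL = "TTAC"  # left cleavage site, retained in the donor's left flank
CR = "TCAA"  # right cleavage site, 3' terminus of the element
CT_DEFAULT = "TTAC"  # integration target core
GL = "AAAG"  # left guide, pairs with C_T
GR = "GAAT"  # right guide

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_ALPHABET = "ACGT"

# Anchored left-end layout (1-based, top strand)
GL_SPAN = (16, 19)
IPL_SPAN = (20, 41)
EXT_START = 44
HP2_SPAN = (46, 60)
HP2_ARM3 = (55, 60)  # 3' arm of the second hairpin / opening-mutation window
LE_LEN = 70
JUNCTION_5P_LEN = 50  # 5' (RE-derived) segment of the canonical junction


class ParameterError(ValueError):
    """A generator or design parameter is out of its supported range."""


class GenerationError(RuntimeError):
    """A constrained fixture could not be generated within the retry budget."""


class ParseError(ValueError):
    """A sequence contains characters outside the supported alphabet."""


def revcomp(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet (N maps to N)."""
    bad = set(seq.upper()) - set("ACGTN")
    if bad:
        raise ParseError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq.translate(_COMP)[::-1]


def longest_match_run(ext: str, window: str) -> int:
    """Longest run of consecutive register-correct WC pairs.

    ``ext`` is the LE extension read 5'->3' from +44; ``window`` is the target
    window read 5'->3'.  In the antiparallel register +44 pairs the window's
    3'-most base, so position k of ``ext`` matches iff it equals
    ``revcomp(window)[k]``.
    """
    if len(ext) != len(window):
        raise ParameterError("extension and window lengths differ")
    rc = revcomp(window)
    best = cur = 0
    for a, b in zip(ext, rc):
        cur = cur + 1 if a == b else 0
        best = max(best, cur)
    return best


@dataclass(frozen=True)
class TransposonEnd:
    """An annotated single-stranded top-strand oligo (LE, RE or junction).

    ``features`` maps feature names to closed 1-based intervals on ``seq``.
    A junction carries an ``LE`` feature marking where left-end coordinates
    begin; ``circular`` marks a junction represented linearly but closed at
    the RE-LE joint.
    """

    seq: str
    role: str  # "LE" | "RE" | "junction"
    features: dict
    label_5prime: bool = False
    circular: bool = False

    def __post_init__(self):
        if self.role not in ("LE", "RE", "junction"):
            raise ParameterError(f"unknown role {self.role!r}")
        n = len(self.seq)
        for name, (a, b) in self.features.items():
            if not (1 <= a <= b <= n):
                raise ParameterError(
                    f"feature {name} interval ({a},{b}) outside [1,{n}]"
                )
        if self.role == "LE":
            for required in ("GL", "IPL"):
                if required not in self.features:
                    raise ParameterError(f"LE requires feature {required}")
            gl, ipl = self.features["GL"], self.features["IPL"]
            if gl[1] - gl[0] != 3:
                raise ParameterError("GL must span 4 nt")
            if ipl[1] - ipl[0] + 1 < 10:
                raise ParameterError("IPL must span >= 10 nt")
            if not gl[1] < ipl[0]:
                raise ParameterError("GL must end before IPL begins")
            if "EXT" in self.features:
                ext = self.features["EXT"]
                if not ipl[1] < ext[0]:
                    raise ParameterError("EXT must begin after IPL ends")
                if ext[1] - ext[0] + 1 > 13:
                    raise ParameterError("EXT longer than 13 nt")

    # -- coordinate helpers -------------------------------------------------

    @property
    def le_offset(self) -> int:
        """0-based offset of left-end position +1 within ``seq``."""
        if self.role == "junction" and "LE" in self.features:
            return self.features["LE"][0] - 1
        return 0

    def le_base(self, pos: int) -> str:
        """Base at left-end position ``pos`` (+1-based)."""
        return self.seq[self.le_offset + pos - 1]

    def with_le_base(self, pos: int, base: str) -> "TransposonEnd":
        idx = self.le_offset + pos - 1
        seq = self.seq[:idx] + base + self.seq[idx + 1 :]
        return replace(self, seq=seq)

    def feature_seq(self, name: str) -> str:
        a, b = self.features[name]
        return self.seq[a - 1 : b]

    def le_interval(self, le_a: int, le_b: int):
        """Translate a left-end interval into this oligo's coordinates."""
        off = self.le_offset
        return (le_a + off, le_b + off)


@dataclass(frozen=True)
class TargetSite:
    """A candidate integration site: C_T window, +1 base, upstream context."""

    source_id: str
    ct_start: int  # 0-based coordinate of the first C_T base
    strand: str  # "+" | "-"
    ct_seq: str
    plus1: str
    upstream: str  # bases immediately 5' of C_T, 5'->3'

    def __post_init__(self):
        if len(self.ct_seq) != 4:
            raise ParameterError("ct_seq must be a 4-mer")
        if len(self.plus1) != 1:
            raise ParameterError("plus1 must be a single base")
        if self.strand not in "+-":
            raise ParameterError("strand must be + or -")


@dataclass(frozen=True)
class Oligo:
    seq: str
    id: str
    rel_conc: float = 1.0


@dataclass(frozen=True)
class OligoPool:
    """A pool of target oligos with relative molar concentrations."""

    members: tuple

    def __post_init__(self):
        if not any(m.rel_conc > 0 for m in self.members):
            raise ParameterError("pool needs at least one member with rel_conc > 0")
        for m in self.members:
            if not (m.rel_conc >= 0 and m.rel_conc == m.rel_conc):
                raise ParameterError(f"rel_conc of {m.id} must be finite and >= 0")

    def __iter__(self):
        return iter(self.members)

    def __len__(self):
        return len(self.members)


# ---------------------------------------------------------------------------
# fixture generation
# ---------------------------------------------------------------------------

_MAX_ATTEMPTS = 1000


def _rand_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_ALPHABET) for _ in range(n))


def _transversion(base: str) -> str:
    # first transversion in the deterministic candidate order used throughout
    return {"A": "T", "T": "A", "G": "C", "C": "G"}[base]


def _le_candidate(
    rng: random.Random, ext_len: int, with_second_hairpin: bool, ext_seq: Optional[str]
) -> str:
    """One random draw of the anchored left-end layout (validity unchecked)."""
    stem = _rand_seq(rng, 9)
    parts = [
        _rand_seq(rng, 15),  # +1..+15 filler
        GL,  # +16..+19
        stem + _rand_seq(rng, 4) + revcomp(stem),  # IP_L +20..+41
        "AT",  # A+42, T+43
    ]
    tail = list(_rand_seq(rng, LE_LEN - 43))  # +44..+70
    if ext_len:
        ext = ext_seq if ext_seq is not None else _rand_seq(rng, ext_len)
        tail[: ext_len] = list(ext)
    if with_second_hairpin:
        arm5 = "".join(tail[2:8])  # +46..+51
        tail[11:17] = list(revcomp(arm5))  # +55..+60 pairs +46..+51
    parts.append("".join(tail))
    return "".join(parts)


def _has_hairpin_covering(struct, span, min_stem=3, slack=None) -> bool:
    """A helix whose outer pair covers ``span``; with ``slack`` the helix must
    also be local (outer pair within ``slack`` nt of the span)."""
    a, b = span
    for oa, ob, _stem, _loop in find_hairpins(struct, min_stem):
        if oa <= a and ob >= b:
            if slack is None or (oa >= a - slack and ob <= b + slack):
                return True
    return False


def _le_fold_ok(seq: str, ext_len: int, with_second_hairpin: bool, offset: int = 0) -> bool:
    """Check that a (possibly junction-embedded) LE folds as architected.

    ``offset`` is the 0-based position of LE +1 within ``seq``.  Requires the
    IP_L hairpin; if a second hairpin was planted, requires a hairpin spanning
    +46..+60 and that the extension window is paired only by that planted
    stem, and that replacing the +55..+60 arm by transversions frees the
    extension completely (so structural unlocking is guaranteed to work).
    Without a second hairpin the extension must be fully unpaired.
    """
    struct = fold(seq)
    ip_span = (IPL_SPAN[0] + offset, IPL_SPAN[1] + offset)
    if not _has_hairpin_covering(struct, ip_span):
        return False
    if ext_len:
        ext_span = range(EXT_START + offset, EXT_START + ext_len + offset)
        paired = struct.paired_positions
    if with_second_hairpin:
        hp_span = (HP2_SPAN[0] + offset, HP2_SPAN[1] + offset)
        if not _has_hairpin_covering(struct, hp_span, slack=2):
            return False
        if ext_len:
            allowed = set(range(HP2_SPAN[0] + offset, 51 + offset + 1))
            if any(p in paired and p not in allowed for p in ext_span):
                return False
            # opening the planted arm must free the extension entirely
            a, b = HP2_ARM3[0] + offset, HP2_ARM3[1] + offset
            opened = (
                seq[: a - 1]
                + "".join(_transversion(c) for c in seq[a - 1 : b])
                + seq[b:]
            )
            ostruct = fold(opened)
            opaired = ostruct.paired_positions
            ofree = sum(1 for p in ext_span if p not in opaired)
            if ofree / ext_len < 0.9:
                return False
    elif ext_len:
        free = sum(1 for p in ext_span if p not in paired)
        if free / ext_len < 0.9:
            return False
    return True


def make_synthetic_le(
    seed: int,
    ext_len: int = 8,
    with_second_hairpin: bool = False,
    ext_seq: Optional[str] = None,
) -> TransposonEnd:
    """Generate a synthetic left end with the anchored IS608 architecture.

    Deterministic for a given seed.  ``ext_seq`` (optional) fixes the
    extension content (used when embedding a design); otherwise the extension
    is random.  ``with_second_hairpin`` plants a stem-loop over +46..+60 whose
    3' arm (+55..+60) base-pairs the +46..+51 portion of the extension window,
    emulating the occluding wild-type hairpin.
    """
    if not (0 <= ext_len <= 13):
        raise ParameterError(f"ext_len {ext_len} outside 0..13")
    if with_second_hairpin and ext_len > 8:
        raise ParameterError(
            "with_second_hairpin supports ext_len <= 8: the planted arm at "
            "+55..+60 would overwrite a longer extension"
        )
    if ext_seq is not None and len(ext_seq) != ext_len:
        raise ParameterError("ext_seq length must equal ext_len")
    rng = random.Random(f"LE-{seed}")
    for _ in range(_MAX_ATTEMPTS):
        seq = _le_candidate(rng, ext_len, with_second_hairpin, ext_seq)
        if _le_fold_ok(seq, ext_len, with_second_hairpin):
            features = {"GL": GL_SPAN, "IPL": IPL_SPAN}
            if ext_len:
                features["EXT"] = (EXT_START, EXT_START + ext_len - 1)
            if with_second_hairpin:
                features["HP2"] = HP2_SPAN
            return TransposonEnd(seq=seq, role="LE", features=features)
    raise GenerationError("could not generate a fold-conforming LE fixture")


def _selfcomp_clean(seq: str, ext_span, min_match: int = 6) -> bool:
    """True when no >= min_match-nt reverse-complement of the extension
    occurs elsewhere in the oligo (would nucleate an occluding hairpin)."""
    ea, eb = ext_span
    ext = seq[ea - 1 : eb]
    for i in range(0, len(ext) - min_match + 1):
        probe = revcomp(ext[i : i + min_match])
        start = 0
        while True:
            j = seq.find(probe, start)
            if j < 0:
                break
            s, e = j + 1, j + min_match
            if e < ea or s > eb:
                return False
            start = j + 1
    return True


def make_canonical_junction(
    seed: int,
    design=None,
    ext_len: int = 8,
    with_second_hairpin: bool = False,
    ext_seq: Optional[str] = None,
    label_5prime: bool = True,
    avoid_ct: str = CT_DEFAULT,
) -> TransposonEnd:
    """Generate the canonical junction oligo (RE-LE joint layout).

    The segment from the 5' terminus to the cleavage position is exactly
    50 nt: 46 nt of RE-derived filler followed by the joint motif C_R (TCAA,
    feature ``CJ``), cleaved immediately 3' of the motif.  The LE portion
    follows with all left-end features shifted by 50.  When a design is
    supplied (or ``ext_seq`` is given) that extension is substituted into
    the LE portion.

    Filler is redrawn (deterministically from the seed) until the oligo is
    architecturally clean *in the unlocked state* (+42 read as T, as the
    design pipeline will set it): the IP_L hairpin folds, the extension
    window is >= 90% single-stranded (or, with a planted second hairpin,
    paired only by that hairpin and freeable by opening mutations), no >= 6-nt
    reverse complement of the extension occurs elsewhere, and the extension
    neighbourhood does not contain ``avoid_ct``.  With a caller-fixed
    extension a fully clean scaffold may not exist (the window can pair with
    itself); the best candidate found is then returned and downstream
    validation reports the residual structure honestly.
    """
    if design is not None:
        ext_seq = design.extension
        ext_len = design.ext_len
    if ext_seq is not None:
        ext_seq = ext_seq.upper()
        ext_len = len(ext_seq)
    if not (0 <= ext_len <= 13):
        raise ParameterError(f"ext_len {ext_len} outside 0..13")
    if with_second_hairpin and ext_len > 8:
        raise ParameterError("with_second_hairpin supports ext_len <= 8")
    rng = random.Random(f"junction-{seed}")
    off = JUNCTION_5P_LEN
    fixed_ext = ext_seq is not None
    attempts = 150 if fixed_ext else 300
    best = None  # (accessibility, seq)

    def build(seq: str) -> TransposonEnd:
        features = {
            "CJ": (off - 3, off),
            "LE": (off + 1, off + LE_LEN),
            "GL": (GL_SPAN[0] + off, GL_SPAN[1] + off),
            "IPL": (IPL_SPAN[0] + off, IPL_SPAN[1] + off),
        }
        if ext_len:
            features["EXT"] = (EXT_START + off, EXT_START + ext_len - 1 + off)
        if with_second_hairpin:
            features["HP2"] = (HP2_SPAN[0] + off, HP2_SPAN[1] + off)
        return TransposonEnd(
            seq=seq, role="junction", features=features,
            label_5prime=label_5prime,
        )

    for _ in range(attempts):
        re_seg = _rand_seq(rng, off - 4) + CR
        le_seq = _le_candidate(rng, ext_len, with_second_hairpin, ext_seq)
        seq = re_seg + le_seq
        if seq.count(CR) != 1:
            continue  # cleavage-site motif must be locatable unambiguously
        if ext_len:
            ea, eb = EXT_START + off, EXT_START + ext_len - 1 + off
            # the planted second hairpin is itself a self-complement of the
            # extension window, so the guard only applies without it
            if not with_second_hairpin and not _selfcomp_clean(seq, (ea, eb)):
                continue
            if avoid_ct and avoid_ct in seq[max(0, ea - 4) : eb + 3]:
                continue
        # evaluate fold cleanliness in the unlocked state (+42 -> T)
        idx42 = off + 42 - 1
        unlocked = seq[:idx42] + "T" + seq[idx42 + 1 :]
        if _le_fold_ok(unlocked, ext_len, with_second_hairpin, offset=off):
            return build(seq)
        if fixed_ext and ext_len and not with_second_hairpin:
            struct = fold(unlocked)
            if _has_hairpin_covering(
                struct, (IPL_SPAN[0] + off, IPL_SPAN[1] + off)
            ):
                acc = accessibility(struct, (ea, eb))
                if best is None or acc > best[0]:
                    best = (acc, seq)
    if fixed_ext and best is not None:
        return build(best[1])
    raise GenerationError("could not generate a fold-conforming junction fixture")


def _target_oligo(
    rng: random.Random,
    window: str,
    linker_len: int,
    ct: str,
    downstream_len: int,
    pad: int = 5,
) -> str:
    """Assemble upstream-pad + window + linker + C_T + C(+1) + downstream."""
    down = "C" + _rand_seq(rng, downstream_len - 1)
    return _rand_seq(rng, pad) + window + _rand_seq(rng, linker_len) + ct + down


def make_target_fixtures(seed: int, design, n_scrambled: int = 4) -> OligoPool:
    """Build the competition-assay target pool for a design.

    * ``Tic``: fully complementary window, 38-nt 3' segment.
    * ``Tr``: random window (< 5 contiguous register matches), 30-nt 3'
      segment so its integration product is distinguishable.
    * ``Ts1..Tsn``: scrambled windows (< 5 contiguous register matches),
      38-nt 3' segments.

    All members share the design's C_T with a C at +1, contain exactly one
    C_T occurrence, and are regenerated on constraint failure (deterministic
    draws from the seed).
    """
    rng = random.Random(f"targets-{seed}")
    ext = design.extension
    ct = design.site.ct_seq
    linker = design.linker_len
    window_c = revcomp(ext)

    def draw(window, downstream_len, require_scrambled):
        for _ in range(_MAX_ATTEMPTS):
            w = window
            if w is None:
                if require_scrambled == "shuffle":
                    letters = list(window_c)
                    rng.shuffle(letters)
                    w = "".join(letters)
                else:
                    w = _rand_seq(rng, len(ext))
                if longest_match_run(ext, w) >= 5:
                    continue
            oligo = _target_oligo(rng, w, linker, ct, downstream_len)
            if oligo.count(ct) == 1:
                return oligo
        raise GenerationError("could not satisfy target-oligo constraints")

    members = [
        Oligo(draw(window_c, 38, None), "Tic"),
        Oligo(draw(None, 30, "random"), "Tr"),
    ]
    for i in range(n_scrambled):
        members.append(Oligo(draw(None, 38, "shuffle"), f"Ts{i + 1}"))
    return OligoPool(members=tuple(members))


def make_locus_fixture(
    seed: int,
    length: int = 400,
    ct: str = CT_DEFAULT,
    site_pos: Optional[int] = None,
) -> tuple:
    """Random locus with a single planted C_T site (C at +1) for design demos.

    Returns ``(sequence, ct_start)``; the site is planted far enough from the
    5' end to supply any supported extension window, and the rest of the
    locus contains no other occurrence of ``ct`` on the top strand.
    """
    rng = random.Random(f"locus-{seed}")
    if site_pos is None:
        site_pos = length // 2
    if site_pos < 20 or site_pos + 5 > length:
        raise ParameterError("site_pos leaves too little flanking sequence")
    for _ in range(_MAX_ATTEMPTS):
        up = _rand_seq(rng, site_pos)
        down = "C" + _rand_seq(rng, length - site_pos - 5)
        seq = up + ct + down
        if seq.count(ct) != 1 or revcomp(seq).count(ct) != 0:
            continue
        # screen the design window (up to the 13-nt extension, default
        # 3-nt linker) so the demo site is a *good* target: extensions
        # complementary to G_L (AAAG reads TTT/CTT runs) or that fold on
        # themselves make poor designs, as a user's site screen would show
        ext13 = revcomp(seq[site_pos - 16 : site_pos - 3])
        if "TTT" in ext13 or "CTT" in ext13:
            continue
        if fold(ext13).pairs:
            continue
        return seq, site_pos
    raise GenerationError("could not plant a unique target site")
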