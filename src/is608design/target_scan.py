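"""Target-site scanning, +1 preference, and the cooperative competition model.

IS608 integrates 3' of a 4-nt core site (C_T, TTAC by default) and strongly
prefers a cytosine at the first downstream position (+1): the +1 pocket is
tight and disfavors purines.  An engineered junction additionally pairs its
extension with the window a short linker upstream of C_T; selectivity in
competition assays is all-or-nothing in match length — 8 contiguous matches
win even against a 20-fold excess of zero-match competitors, while 5 matches
confer essentially no advantage.  A per-base multiplicative bonus cannot
reproduce that switch, so match length is converted to an integration weight
through a cooperative (Hill-type) curve:

    coop(m) = floor + (amp - floor) * m^h / (m^h + K^h)

with shipped defaults floor=1, amp=60, K=6.8, h=12, which satisfy the two
calibration constraints encoded from the competition outcomes:
coop(8)/coop(0) >= 40 and coop(5)/coop(0) <= 3.  The constraints are
re-checked whenever parameters are constructed, including from user configs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

from .transposon_model import (
    CT_DEFAULT,
    Oligo,
    OligoPool,
    ParameterError,
    ParseError,
    TargetSite,
    longest_match_run,
    revcomp,
)

__all__ = [
    "CoopParams",
    "SiteScore",
    "DEFAULT_PLUS1_WEIGHTS",
    "CalibrationError",
    "DegeneratePoolError",
    "plus1_weight",
    "coop",
    "scan",
    "match_len",
    "competition",
    "offtarget_summary",
    "offtarget_table",
    "sites_to_bed",
]

# Ordinal encoding of the covalent-complex gel classes: C is the clear
# winner, T intermediate, purines equally poor.
DEFAULT_PLUS1_WEIGHTS = {"C": 1.0, "T": 0.5, "A": 0.15, "G": 0.15}

DEFAULT_UPSTREAM = 20


class CalibrationError(ValueError):
    """Cooperativity parameters violate the calibration constraints."""


class DegeneratePoolError(ValueError):
    """All pool members carry zero integration weight."""


@dataclass(frozen=True)
class CoopParams:
    """Hill-type match-length -> weight curve (see module docstring).

    floor: weight at zero matches; amp: weight at saturation; K: midpoint in
    matched bases; h: steepness.  Must be nondecreasing and satisfy
    coop(8)/coop(0) >= 40 and coop(5)/coop(0) <= 3.
    """

    floor: float = 1.0
    amp: float = 60.0
    K: float = 6.8
    h: float = 12.0

    def __post_init__(self):
        if self.floor <= 0 or self.amp < self.floor or self.K <= 0 or self.h <= 0:
            raise CalibrationError(
                "need 0 < floor <= amp, K > 0, h > 0 for a nondecreasing curve"
            )
        r8 = self(8) / self(0)
        r5 = self(5) / self(0)
        if r8 < 40:
            raise CalibrationError(
                f"coop(8)/coop(0) = {r8:.2f} < 40: an 8-match target would not "
                "dominate a 20-fold excess of zero-match competitors"
            )
        if r5 > 3:
            raise CalibrationError(
                f"coop(5)/coop(0) = {r5:.2f} > 3: 5 matches must confer at most "
                "a 3-fold advantage (no efficient selection)"
            )

    def __call__(self, m: int) -> float:
        if m < 0:
            raise ParameterError("match length must be >= 0")
        if m == 0:
            return self.floor
        mh = float(m) ** self.h
        return self.floor + (self.amp - self.floor) * mh / (mh + self.K ** self.h)


DEFAULT_COOP = CoopParams()


def coop(m: int, params: CoopParams = DEFAULT_COOP) -> float:
    """Cooperative weight of ``m`` contiguous register-correct matches."""
    return params(m)


def plus1_weight(base: str, weights: Optional[dict] = None) -> float:
    """Relative cleavage/integration weight of the +1 base (C is best)."""
    w = DEFAULT_PLUS1_WEIGHTS if weights is None else weights
    base = base.upper()
    if base not in "ACGT" or len(base) != 1:
        raise ParseError(f"+1 base must be one of ACGT, got {base!r}")
    return float(w[base])


@dataclass(frozen=True)
class SiteScore:
    """Scored candidate site; ``fraction`` is populated by :func:`competition`."""

    site: TargetSite
    match_len: int
    plus1_weight: float
    weight: float  # plus1_weight * coop(match_len), concentration-free
    fraction: float = float("nan")


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


def _iter_sequences(seqs) -> Iterable:
    """Yield (id, sequence) from a FASTA path, a mapping, or (id, seq) pairs."""
    if isinstance(seqs, (str, Path)):
        try:
            for rec in SeqIO.parse(str(seqs), "fasta"):
                yield rec.id, str(rec.seq).upper()
        except FileNotFoundError:
            raise
        except Exception as exc:  # malformed FASTA
            raise ParseError(f"could not parse FASTA {seqs}: {exc}") from exc
    elif isinstance(seqs, dict):
        for k, v in seqs.items():
            yield k, v.upper()
    else:
        for k, v in seqs:
            yield k, v.upper()


def _find_all(hay: str, needle: str):
    start = 0
    while True:
        i = hay.find(needle, start)
        if i < 0:
            return
        yield i
        start = i + 1


def scan(
    seqs,
    ct: str = CT_DEFAULT,
    both_strands: bool = False,
    upstream: int = DEFAULT_UPSTREAM,
) -> list:
    """All occurrences of the core site on the requested strand(s).

    Each hit becomes a :class:`TargetSite` with its +1 base and up to
    ``upstream`` nt of context 5' of C_T (on the site's own strand).
    ``ct_start`` is the 0-based top-strand coordinate of the first C_T base
    (BED-compatible).  Occurrences whose +1 base falls outside the sequence
    are omitted (they cannot be scored or integrated into).  Output order is
    deterministic: by source id, coordinate, then strand.
    """
    ct = ct.upper()
    if len(ct) != 4 or set(ct) - set("ACGT"):
        raise ParameterError("ct must be a 4-mer over ACGT")
    sites = []
    for sid, seq in _iter_sequences(seqs):
        n = len(seq)
        for i in _find_all(seq, ct):
            if i + 4 >= n:
                continue
            sites.append(TargetSite(
                source_id=sid, ct_start=i, strand="+", ct_seq=ct,
                plus1=seq[i + 4], upstream=seq[max(0, i - upstream):i],
            ))
        if both_strands:
            rc = revcomp(seq)
            for q in _find_all(rc, ct):
                if q + 4 >= n:
                    continue
                sites.append(TargetSite(
                    source_id=sid, ct_start=n - q - 4, strand="-", ct_seq=ct,
                    plus1=rc[q + 4], upstream=rc[max(0, q - upstream):q],
                ))
    sites.sort(key=lambda s: (s.source_id, s.ct_start, s.strand))
    return sites


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def match_len(site: TargetSite, design) -> int:
    """Longest run of consecutive WC pairs between the design extension and
    the site's upstream window, evaluated in the design's register.

    The window occupies target positions -(linker+4+L)..-(linker+5), i.e. the
    slice of ``site.upstream`` ending ``linker`` bases before its 3' end.
    """
    ext = design.extension
    a = design.ext_len + design.linker_len
    b = design.linker_len
    if len(site.upstream) < a:
        raise ParameterError(
            f"site upstream context ({len(site.upstream)} nt) does not cover "
            f"the design register window ({a} nt)"
        )
    window = site.upstream[-a:-b] if b else site.upstream[-a:]
    return longest_match_run(ext, window)


def site_from_oligo(oligo: Oligo, ct: str) -> TargetSite:
    """Locate the unique core site in a target oligo and wrap it."""
    hits = list(_find_all(oligo.seq.upper(), ct))
    if len(hits) != 1:
        raise ParameterError(
            f"oligo {oligo.id} contains {len(hits)} occurrences of {ct} "
            "(need exactly 1)"
        )
    i = hits[0]
    seq = oligo.seq.upper()
    if i + 4 >= len(seq):
        raise ParameterError(f"oligo {oligo.id} has no +1 base after {ct}")
    return TargetSite(
        source_id=oligo.id, ct_start=i, strand="+", ct_seq=ct,
        plus1=seq[i + 4], upstream=seq[:i],
    )


def competition(
    pool: OligoPool,
    design,
    params: CoopParams = DEFAULT_COOP,
    plus1_weights: Optional[dict] = None,
) -> list:
    """Predicted integration fractions over a pool of competing targets.

    weight_i = rel_conc_i * plus1_weight(+1_i) * coop(match_len_i);
    fraction_i = weight_i / sum(weights).  Deterministic; fractions sum to 1
    and are invariant under uniform scaling of the concentrations.
    """
    ct = design.site.ct_seq
    scored = []
    weights = []
    for member in pool:
        site = site_from_oligo(member, ct)
        m = match_len(site, design)
        p1 = plus1_weight(site.plus1, plus1_weights)
        unit = p1 * params(m)
        scored.append((site, m, p1, unit))
        weights.append(member.rel_conc * unit)
    total = sum(weights)
    if total <= 0:
        raise DegeneratePoolError("all pool members have zero weight")
    return [
        SiteScore(site=s, match_len=m, plus1_weight=p1, weight=unit,
                  fraction=w / total)
        for (s, m, p1, unit), w in zip(scored, weights)
    ]


# ---------------------------------------------------------------------------
# off-target reporting
# ---------------------------------------------------------------------------

HIGH_RISK_MATCH = 8  # demonstrated selective length


def offtarget_table(genome, design, both_strands: bool = True) -> pd.DataFrame:
    """Per-site off-target table for a genome scan.

    Sites too close to a sequence end to evaluate the register window get
    ``match_len = -1`` (unscored).  ``high_risk`` flags full-length register
    matches with the preferred C at +1.
    """
    need = design.ext_len + design.linker_len
    rows = []
    for site in scan(genome, ct=design.site.ct_seq, both_strands=both_strands,
                     upstream=max(DEFAULT_UPSTREAM, need)):
        try:
            m = match_len(site, design)
        except ParameterError:
            m = -1
        rows.append({
            "source": site.source_id,
            "ct_start": site.ct_start,
            "strand": site.strand,
            "plus1": site.plus1,
            "match_len": m,
            "high_risk": m >= HIGH_RISK_MATCH and site.plus1 == "C",
        })
    return pd.DataFrame(
        rows,
        columns=["source", "ct_start", "strand", "plus1", "match_len",
                 "high_risk"],
    )


def offtarget_summary(genome, design, both_strands: bool = True) -> dict:
    """Binned off-target summary; ``pass`` means no high-risk site other than
    the design's own intended site."""
    table = offtarget_table(genome, design, both_strands)
    risky = table[table.high_risk]
    own = design.site
    extra = risky[
        ~((risky.source == own.source_id)
          & (risky.ct_start == own.ct_start)
          & (risky.strand == own.strand))
    ]
    bins = table[table.match_len >= 0].match_len.value_counts().sort_index()
    return {
        "pass": len(extra) == 0,
        "n_sites": int(len(table)),
        "by_match_len": {int(k): int(v) for k, v in bins.items()},
        "n_high_risk": int(len(risky)),
        "n_high_risk_offtarget": int(len(extra)),
    }


def sites_to_bed(scores: Iterable, handle) -> None:
    """Write scored sites as BED6 (name = match_len:plus1, score = 1000 x
    fraction, clamped)."""
    for sc in scores:
        s = sc.site
        frac = 0.0 if sc.fraction != sc.fraction else sc.fraction
        score = max(0, min(1000, round(1000 * frac)))
        handle.write(
            f"{s.source_id}\t{s.ct_start}\t{s.ct_start + 4}\t"
            f"{sc.match_len}:{s.plus1}\t{score}\t{s.strand}\n"
        )


def competition_summary(scores: Iterable) -> dict:
    """JSON-ready competition result keyed by oligo id."""
    return {
        sc.site.source_id: {
            "match_len": sc.match_len,
            "plus1": sc.site.plus1,
            "weight": sc.weight,
            "fraction": sc.fraction,
        }
        for sc in scores
    }
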