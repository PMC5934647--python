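"""Rational retargeting of IS608 integration by extended LE/target pairing.

The engineering recipe implemented here:

1. **Extension design** — place an 8-13 nt sequence at LE positions
   +44..+(43+L) that is the reverse complement of the target window lying a
   short linker (default 3 nt) upstream of the 4-nt core site C_T.  Together
   with the native G_L/C_T pairing this makes the recognized site 4 + L nt
   long (12 nt for the default 8-nt extension, 17 nt for 13).
2. **Structural unlocking** — mutate the bulky triplet-forming A+42 to T, and
   if the fold of the engineered junction still occludes the extension
   window (second hairpin over +46..+60), introduce up to ``max_mut`` point
   substitutions confined to +55..+60 until the extension is >= 90%%
   single-stranded.
3. **C_T resetting** — redirect the core site itself by rewriting the guide
   bases that read it: by default target -4 is read by G_L +17 and -3 by
   +16 (the structure-characterized pairs); other positions are exposed via
   :class:`GlCtMap` but not rewritten silently.
4. **Validation** — accessibility, self-complementarity, unintended-C_T and
   (optionally) genome off-target checks, all recorded in a report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

from .ssfold import FoldParams, DEFAULT_FOLD_PARAMS, accessibility, fold
from .transposon_model import (
    EXT_START,
    HP2_ARM3,
    ParameterError,
    TargetSite,
    TransposonEnd,
    make_canonical_junction,
    revcomp,
)

__all__ = [
    "Design",
    "PairingRegister",
    "GlCtMap",
    "DesignWarning",
    "design_extension",
    "apply_structural_unlocking",
    "reset_ct",
    "validate_design",
    "with_extension",
]

DEFAULT_ACCESSIBILITY = 0.9
UNLOCK_WINDOW = HP2_ARM3  # opening mutations allowed at +55..+60 only
_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


class DesignWarning(UserWarning):
    """Design parameters outside the demonstrated-optimal range."""


@dataclass(frozen=True)
class PairingRegister:
    """Antiparallel pairing register between LE/junction and target.

    Each entry is ``(le_pos, target_pos, kind)`` with ``le_pos`` on the
    left-end + scale, ``target_pos`` on the cleavage-relative - scale, and
    ``kind`` one of "WC", "noncanonical", "triplet".  LE positions ascend
    while target positions descend.  The two structure-characterized base
    triplets are recorded as (+42, -4) and (+43, -3).
    """

    pairs: tuple

    def __post_init__(self):
        wc = [(l, t) for l, t, k in self.pairs if k != "triplet"]
        les = [l for l, _ in wc]
        tgts = [t for _, t in wc]
        if les != sorted(les) or tgts != sorted(tgts, reverse=True):
            raise ParameterError("register must be antiparallel")

    def kind_at(self, le_pos: int, target_pos: int) -> Optional[str]:
        for l, t, k in self.pairs:
            if (l, t) == (le_pos, target_pos):
                return k
        return None

    def with_kind(self, le_pos: int, target_pos: int, kind: str) -> "PairingRegister":
        pairs = tuple(
            (l, t, kind if (l, t) == (le_pos, target_pos) else k)
            for l, t, k in self.pairs
        )
        return PairingRegister(pairs=pairs)


@dataclass(frozen=True)
class GlCtMap:
    """Which G_L position reads each resettable C_T position.

    The crystal structure names only the -4 -> +17 and -3 -> +16 pairs; -2
    and -1 are not resettable unless the user extends the map explicitly.
    """

    entries: dict = field(default_factory=lambda: {-4: 17, -3: 16})

    def __post_init__(self):
        vals = list(self.entries.values())
        if len(vals) != len(set(vals)):
            raise ParameterError("GlCtMap values must be distinct")
        for p in self.entries:
            if p not in (-4, -3, -2, -1):
                raise ParameterError(f"C_T position {p} outside -4..-1")


@dataclass(frozen=True)
class Design:
    """An engineered junction, its intended site, and the pairing register."""

    junction: TransposonEnd
    target_source: str
    site: TargetSite
    ext_len: int
    linker_len: int
    register: PairingRegister
    locus: str  # full top-strand sequence the site was designed on
    validation: dict = field(default_factory=dict)

    @property
    def extension(self) -> str:
        return self.junction.feature_seq("EXT")

    @property
    def recognized_site_len(self) -> int:
        """Total specifically recognized target length: 4-nt C_T + extension."""
        return 4 + self.ext_len

    @property
    def target_window(self) -> str:
        """The extension-addressed target window, 5'->3'."""
        return revcomp(self.extension)

    def overall_pass(self) -> bool:
        checks = self.validation.get("checks", {})
        return bool(checks) and all(c["pass"] for c in checks.values())


def _target_window(locus: str, site: TargetSite, ext_len: int, linker_len: int) -> str:
    """Extract the window at target positions -(linker+4+L)..-(linker+5)."""
    cleave = site.ct_start + 4  # 0-based index just 3' of C_T
    hi = cleave - (linker_len + 4)  # exclusive, -(linker+5) is index hi-1
    lo = hi - ext_len
    if lo < 0:
        raise ParameterError(
            "site too close to locus 5' end for the requested extension"
        )
    return locus[lo:hi]


def _build_register(ext_len: int, linker_len: int) -> PairingRegister:
    pairs = [(16, -3, "WC"), (17, -4, "WC")]
    first_target = -(linker_len + 5)
    for k in range(ext_len):
        pairs.append((EXT_START + k, first_target - k, "WC"))
    pairs.append((42, -4, "triplet"))
    pairs.append((43, -3, "triplet"))
    return PairingRegister(pairs=tuple(pairs))


def design_extension(
    locus: str,
    site: TargetSite,
    ext_len: int = 8,
    linker_len: int = 3,
    seed: int = 0,
) -> Design:
    """Design an extended-complementarity junction for one target site.

    The extension placed at +44..+(43+ext_len) is the reverse complement of
    the locus window ending ``linker_len + 4`` bases upstream of the cleavage
    position, so that +44 pairs target -(linker_len+5) and the duplex runs
    antiparallel from there.  ``seed`` fixes the synthetic RE/LE scaffold the
    extension is embedded in.
    """
    if ext_len > 13:
        raise ParameterError(
            "extensions longer than 13 nt are unsupported (13 is the longest "
            "demonstrated selective extension)"
        )
    if ext_len < 5:
        raise ParameterError("ext_len must be >= 5")
    if 5 <= ext_len <= 7:
        warnings.warn(
            f"ext_len={ext_len}: 5 bp of extra complementarity does not give "
            "efficient target selection; 8-13 recommended",
            DesignWarning,
            stacklevel=2,
        )
    if not (2 <= linker_len <= 5):
        raise ParameterError("linker_len must be in 2..5")
    if linker_len != 3:
        warnings.warn(
            f"linker_len={linker_len}: 3 nt best supports cleavage",
            DesignWarning,
            stacklevel=2,
        )
    locus = locus.upper()
    window = _target_window(locus, site, ext_len, linker_len)
    ext_seq = revcomp(window)
    junction = make_canonical_junction(seed=seed, ext_seq=ext_seq)
    return Design(
        junction=junction,
        target_source=site.source_id,
        site=site,
        ext_len=ext_len,
        linker_len=linker_len,
        register=_build_register(ext_len, linker_len),
        locus=locus,
        validation={"params": {"ext_len": ext_len, "linker_len": linker_len,
                               "seed": seed}},
    )


def with_extension(design: Design, ext_len: int, linker_len: Optional[int] = None,
                   seed: int = 0) -> Design:
    """Recompute the extension of an existing design from its stored locus.

    Preserves edits outside the extension window (G_L resets, unlocking) by
    reapplying them to the fresh scaffold.
    """
    linker = design.linker_len if linker_len is None else linker_len
    fresh = design_extension(design.locus, design.site, ext_len, linker, seed=seed)
    junction = fresh.junction
    # carry over LE edits recorded on the old design (outside EXT)
    for pos, base in design.validation.get("le_edits", []):
        junction = junction.with_le_base(pos, base)
    register = fresh.register
    for l, t, k in design.register.pairs:
        if register.kind_at(l, t) is not None and k != register.kind_at(l, t):
            register = register.with_kind(l, t, k)
    validation = dict(fresh.validation)
    if "le_edits" in design.validation:
        validation["le_edits"] = list(design.validation["le_edits"])
    return replace(
        fresh,
        junction=junction,
        register=register,
        site=design.site,
        validation=validation,
    )


def _record_edit(validation: dict, pos: int, base: str) -> dict:
    v = dict(validation)
    v.setdefault("le_edits", [])
    v["le_edits"] = [e for e in v["le_edits"] if e[0] != pos] + [(pos, base)]
    return v


def _ext_accessibility(junction: TransposonEnd,
                       params: FoldParams = DEFAULT_FOLD_PARAMS) -> float:
    struct = fold(junction.seq, params)
    return accessibility(struct, junction.features["EXT"])


def apply_structural_unlocking(
    design: Design,
    max_mut: int = 6,
    threshold: float = DEFAULT_ACCESSIBILITY,
    fold_params: FoldParams = DEFAULT_FOLD_PARAMS,
) -> Design:
    """Open the occluding fold around the extension window.

    Sets the triplet-forming +42 base to T, then, while the extension window
    is less than ``threshold`` single-stranded, greedily substitutes one base
    at a time within +55..+60 (5'->3', transversions tried before the
    transition, keeping the substitution that maximizes accessibility) until
    the threshold is reached or ``max_mut`` edits have been spent.  Never
    touches G_L, IP_L, +43, or the extension.  Idempotent: re-running on its
    own output applies no further edits.

    On failure the best design found is returned with the ``unlocking`` check
    marked failed (no exception).
    """
    junction = design.junction
    validation = dict(design.validation)
    edits = []
    if junction.le_base(42) != "T":
        junction = junction.with_le_base(42, "T")
        validation = _record_edit(validation, 42, "T")
        edits.append((42, "T"))

    acc = _ext_accessibility(junction, fold_params)
    lo, hi = UNLOCK_WINDOW
    ext_lo, ext_hi = EXT_START, EXT_START + design.ext_len - 1
    if acc < threshold:
        n_mut = 0
        for pos in range(lo, hi + 1):
            if acc >= threshold or n_mut >= max_mut:
                break
            if ext_lo <= pos <= ext_hi:
                continue  # the extension itself is never edited
            current = junction.le_base(pos)
            order = {
                "A": ["T", "C", "G"], "G": ["C", "T", "A"],
                "C": ["G", "A", "T"], "T": ["A", "G", "C"],
            }[current]
            best_base, best_acc = None, acc
            for cand in order:
                trial = junction.with_le_base(pos, cand)
                a = _ext_accessibility(trial, fold_params)
                if a > best_acc:
                    best_base, best_acc = cand, a
            if best_base is None and acc < threshold:
                # no single substitution helps yet; take the first
                # transversion to keep dismantling the arm deterministically
                best_base = order[0]
                best_acc = _ext_accessibility(
                    junction.with_le_base(pos, best_base), fold_params
                )
            if best_base is not None:
                junction = junction.with_le_base(pos, best_base)
                validation = _record_edit(validation, pos, best_base)
                edits.append((pos, best_base))
                n_mut += 1
                acc = best_acc
        acc = _ext_accessibility(junction, fold_params)

    validation["checks"] = dict(validation.get("checks", {}))
    validation["checks"]["unlocking"] = {
        "pass": acc >= threshold,
        "accessibility": acc,
        "threshold": threshold,
        "edits": edits,
    }
    return replace(design, junction=junction, validation=validation)


def reset_ct(design: Design, new_ct: str, gl_map: Optional[GlCtMap] = None) -> Design:
    """Redirect the core C_T by rewriting the guide bases that read it.

    For every target position p in -4..-1 where ``new_ct`` differs from the
    current C_T, the LE base at ``gl_map[p]`` is set to the Watson-Crick
    complement of the new base; positions with no map entry cannot be reset
    and raise, naming them.  Register kinds at reset positions become WC.
    """
    if gl_map is None:
        gl_map = GlCtMap()
    new_ct = new_ct.upper()
    if len(new_ct) != 4 or set(new_ct) - set("ACGT"):
        raise ParameterError("new_ct must be a 4-mer over ACGT")
    old_ct = design.site.ct_seq
    changed = [p for p, (a, b) in zip((-4, -3, -2, -1), zip(old_ct, new_ct)) if a != b]
    unmapped = [p for p in changed if p not in gl_map.entries]
    if unmapped:
        raise ParameterError(
            f"C_T change at unmappable position(s) {unmapped}: only guide-read "
            f"positions {sorted(gl_map.entries)} can be reset"
        )
    junction = design.junction
    validation = dict(design.validation)
    register = design.register
    for p in changed:
        le_pos = gl_map.entries[p]
        base = _WC[new_ct[p + 4]]
        junction = junction.with_le_base(le_pos, base)
        validation = _record_edit(validation, le_pos, base)
        if register.kind_at(le_pos, p) is not None:
            register = register.with_kind(le_pos, p, "WC")
    site = replace(design.site, ct_seq=new_ct)
    # the intended target now carries the new core site
    s = design.site.ct_start
    locus = design.locus[:s] + new_ct + design.locus[s + 4 :]
    return replace(
        design, junction=junction, site=site, register=register,
        locus=locus, validation=validation,
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _self_complementarity_check(design: Design, min_match: int = 6) -> dict:
    """No >= min_match reverse-complement match between the extension and any
    other window of the junction (such a match nucleates an intramolecular
    hairpin that sequesters the extension)."""
    junction = design.junction
    ext = design.extension
    ea, eb = junction.features["EXT"]
    hits = []
    for i in range(0, len(ext) - min_match + 1):
        probe = revcomp(ext[i : i + min_match])
        start = 0
        while True:
            j = junction.seq.find(probe, start)
            if j < 0:
                break
            s, e = j + 1, j + min_match  # 1-based
            if e < ea or s > eb:  # outside the extension itself
                hits.append({"ext_offset": i, "at": [s, e], "match": probe})
            start = j + 1
    return {"pass": not hits, "hits": hits, "min_match": min_match}


def _unintended_ct_check(design: Design) -> dict:
    """Extension edits must not create a new C_T occurrence in the junction.

    Scans the extension window padded by 3 nt on each side for occurrences of
    the design's C_T motif.
    """
    junction = design.junction
    ct = design.site.ct_seq
    ea, eb = junction.features["EXT"]
    lo = max(0, ea - 1 - 3)
    hi = min(len(junction.seq), eb + 3)
    region = junction.seq[lo:hi]
    hits = []
    start = 0
    while True:
        j = region.find(ct, start)
        if j < 0:
            break
        hits.append(lo + j + 1)
        start = j + 1
    return {"pass": not hits, "hits": hits, "motif": ct}


def _register_check(design: Design) -> dict:
    """Pairing the junction against the intended target in the declared
    register must give 100% WC pairs over the extension and mapped C_T
    positions."""
    cleave = design.site.ct_start + 4
    mismatches = []
    for le_pos, t_pos, kind in design.register.pairs:
        if kind == "triplet":
            continue
        le_base = design.junction.le_base(le_pos)
        t_idx = cleave + t_pos  # t_pos is negative
        if not (0 <= t_idx < len(design.locus)):
            mismatches.append({"le_pos": le_pos, "target_pos": t_pos,
                               "reason": "target out of range"})
            continue
        t_base = design.locus[t_idx]
        if _WC.get(le_base) != t_base:
            mismatches.append({
                "le_pos": le_pos, "target_pos": t_pos,
                "le_base": le_base, "target_base": t_base,
            })
    return {"pass": not mismatches, "mismatches": mismatches}


def validate_design(
    design: Design,
    genome=None,
    threshold: float = DEFAULT_ACCESSIBILITY,
    fold_params: FoldParams = DEFAULT_FOLD_PARAMS,
) -> Design:
    """Run all design checks and record them; never raises on check failure.

    ``genome`` may be a FASTA path or a mapping of id -> sequence; when given,
    an off-target summary (sites binned by register match length) is attached.
    """
    from . import target_scan  # deferred: target_scan imports this module's types

    validation = dict(design.validation)
    checks = dict(validation.get("checks", {}))

    acc = _ext_accessibility(design.junction, fold_params)
    checks["accessibility"] = {
        "pass": acc >= threshold, "accessibility": acc, "threshold": threshold,
    }
    checks["triplet_bases"] = {
        "pass": design.junction.le_base(42) == "T"
        and design.junction.le_base(43) == "T",
        "plus42": design.junction.le_base(42),
        "plus43": design.junction.le_base(43),
    }
    checks["self_complementarity"] = _self_complementarity_check(design)
    checks["unintended_ct"] = _unintended_ct_check(design)
    checks["register"] = _register_check(design)
    if genome is not None:
        summary = target_scan.offtarget_summary(genome, design)
        checks["offtarget"] = summary

    validation["checks"] = checks
    validation["overall_pass"] = all(c["pass"] for c in checks.values())
    return replace(design, validation=validation)


# ---------------------------------------------------------------------------
# JSON design report
# ---------------------------------------------------------------------------


def design_to_report(design: Design) -> dict:
    """JSON-ready report: sequences, features, register, edits, checks."""
    j = design.junction
    return {
        "junction": {
            "seq": j.seq,
            "role": j.role,
            "features": {k: list(v) for k, v in j.features.items()},
            "label_5prime": j.label_5prime,
            "circular": j.circular,
        },
        "target_source": design.target_source,
        "site": {
            "source_id": design.site.source_id,
            "ct_start": design.site.ct_start,
            "strand": design.site.strand,
            "ct_seq": design.site.ct_seq,
            "plus1": design.site.plus1,
            "upstream": design.site.upstream,
        },
        "ext_len": design.ext_len,
        "linker_len": design.linker_len,
        "recognized_site_len": design.recognized_site_len,
        "extension": design.extension,
        "target_window": design.target_window,
        "register": [list(p) for p in design.register.pairs],
        "locus": design.locus,
        "validation": design.validation,
    }


def design_from_report(report: dict) -> Design:
    """Inverse of :func:`design_to_report` (feature intervals round-trip)."""
    j = report["junction"]
    junction = TransposonEnd(
        seq=j["seq"],
        role=j["role"],
        features={k: tuple(v) for k, v in j["features"].items()},
        label_5prime=j["label_5prime"],
        circular=j.get("circular", False),
    )
    s = report["site"]
    site = TargetSite(
        source_id=s["source_id"], ct_start=s["ct_start"], strand=s["strand"],
        ct_seq=s["ct_seq"], plus1=s["plus1"], upstream=s["upstream"],
    )
    validation = dict(report.get("validation", {}))
    if "le_edits" in validation:
        validation["le_edits"] = [tuple(e) for e in validation["le_edits"]]
    return Design(
        junction=junction,
        target_source=report["target_source"],
        site=site,
        ext_len=report["ext_len"],
        linker_len=report["linker_len"],
        register=PairingRegister(
            pairs=tuple(tuple(p) for p in report["register"])
        ),
        locus=report["locus"],
        validation=validation,
    )
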