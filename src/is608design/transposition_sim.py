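"""Sequence bookkeeping for the peel-and-paste transposition cycle.

Single-strand chemistry only (the mechanism runs on top-strand ssDNA):

* **Target cleavage** — the transposase cuts immediately 3' of the core site;
  the downstream segment becomes covalently attached to the enzyme through a
  5'-phosphotyrosine, the upstream segment ends 3'-OH.
* **Excision** — the element is cut out between the left cleavage site
  (TTAC, which stays in the donor's left flank) and the element's 3'
  terminus; the donor backbone is sealed and the element circularizes into
  the RE-LE junction.
* **Integration** — the junction is opened at its cleavage site and joined
  to a cleaved target: for a linear junction oligo the observable (labeled)
  product is junction-5'-segment + target-3'-segment, exactly the species
  resolved on a denaturing gel; for a circular junction the whole element is
  inserted 3' of the target's core site (scarless donor reconstitution).
* **Virtual gel** — labeled species sorted by length, optionally weighted by
  competition fractions, emulating the sequencing-PAGE readout.

Cleavage positions are always located by sequence/feature analysis at run
time (motif verified in the sequence), never read from stored lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .transposon_model import CL, Oligo, ParameterError, TransposonEnd

__all__ = [
    "CleavageEvent",
    "TransferProduct",
    "AmbiguityError",
    "cleave_target",
    "locate_end_cleavage",
    "excise",
    "integrate",
    "virtual_gel",
]


class AmbiguityError(ValueError):
    """The cleavage motif occurs zero or multiple times in a substrate."""


@dataclass(frozen=True)
class CleavageEvent:
    """One strand scission 3' of a cleavage-site motif."""

    substrate_id: str
    cut_after: int  # 0-based index of the last base 5' of the cut
    upstream_len: int
    downstream_len: int
    covalent_attachment: str  # "none" | "enzyme_5prime_phosphotyrosine"


@dataclass(frozen=True)
class TransferProduct:
    """A joined strand-transfer product with segment provenance."""

    id: str
    length: int
    composition: tuple  # ((source_id, (start, end)), ...) 1-based closed
    labeled: bool
    seq: str = ""

    def __post_init__(self):
        total = sum(b - a + 1 for _src, (a, b) in self.composition)
        if total != self.length:
            raise ParameterError("product length must equal sum of segments")


def _seq_of(substrate) -> str:
    return (substrate.seq if hasattr(substrate, "seq") else substrate).upper()


def _id_of(substrate, default: str) -> str:
    return getattr(substrate, "id", default)


def cleave_target(target, ct: str = "TTAC") -> CleavageEvent:
    """Cut a target oligo immediately 3' of its unique core site.

    The downstream segment is flagged as enzyme-attached (5'-phosphotyrosine
    intermediate); the upstream segment ends 3'-OH.  Zero or multiple motif
    occurrences raise :class:`AmbiguityError`.
    """
    seq = _seq_of(target)
    ct = ct.upper()
    hits = []
    start = 0
    while True:
        i = seq.find(ct, start)
        if i < 0:
            break
        hits.append(i)
        start = i + 1
    if len(hits) != 1:
        raise AmbiguityError(
            f"substrate contains {len(hits)} occurrences of {ct} (need 1)"
        )
    cut_after = hits[0] + 3
    return CleavageEvent(
        substrate_id=_id_of(target, "target"),
        cut_after=cut_after,
        upstream_len=cut_after + 1,
        downstream_len=len(seq) - cut_after - 1,
        covalent_attachment="enzyme_5prime_phosphotyrosine",
    )


def locate_end_cleavage(end: TransposonEnd) -> int:
    """0-based cut index (last base 5' of the cut) of a junction/end oligo.

    Looks up the cleavage-site feature ("CJ", falling back to "CL"/"CR"),
    verifies that the annotated motif is really present at that interval in
    the sequence, and returns the index of the motif's last base.
    """
    for name in ("CJ", "CL", "CR"):
        if name in end.features:
            a, b = end.features[name]
            if b - a + 1 != 4:
                raise ParameterError(f"feature {name} does not hold a 4-nt motif")
            motif = end.seq[a - 1 : b]
            if end.seq.count(motif) != 1:
                raise AmbiguityError(
                    f"cleavage motif {motif} occurs {end.seq.count(motif)} "
                    "times in the oligo (need 1)"
                )
            return end.seq.find(motif) + 3
    raise ParameterError("no cleavage-site feature (CJ/CL/CR) on this oligo")


def excise(donor: str, le_start: int, re_end: int):
    """Excise the element from a donor strand and seal the backbone.

    ``le_start``/``re_end`` are 0-based inclusive element boundaries on the
    donor top strand.  Requires the left cleavage site TTAC immediately 5' of
    the element (it is retained in the sealed donor's left flank).  Returns
    ``(sealed_donor, junction)`` where the junction is the excised element
    circularized at the RE-LE joint, represented linearly opened at the
    joint (element sequence as-is, ``circular=True``).  Length is conserved:
    len(sealed) + len(junction) = len(donor).
    """
    donor = donor.upper()
    if not (0 <= le_start <= re_end < len(donor)):
        raise ParameterError("element boundaries outside donor")
    if le_start < 4 or donor[le_start - 4 : le_start] != CL:
        raise ParameterError(
            f"left cleavage site {CL} must lie immediately 5' of the element"
        )
    sealed = donor[:le_start] + donor[re_end + 1 :]
    element = donor[le_start : re_end + 1]
    junction = TransposonEnd(
        seq=element,
        role="junction",
        features={"JOINT": (1, 1)},
        circular=True,
    )
    return sealed, junction


def integrate(junction: TransposonEnd, target, ct: str = "TTAC") -> TransferProduct:
    """Join a cleaved junction to a cleaved target.

    Linear junction oligo: the observable strand-transfer product is the
    junction's 5' segment (up to its cleavage site, located from the feature
    map) joined to the target's 3' segment; it is labeled iff the junction
    carries the 5' radiolabel.

    Circular junction (from :func:`excise`): the full element is inserted
    immediately 3' of the target's core site, reconstituting
    upstream + element + downstream; labeling follows the target's 5' end.
    """
    tseq = _seq_of(target)
    tid = _id_of(target, "target")
    event = cleave_target(tseq, ct)
    cut = event.cut_after  # 0-based last base 5' of the cut

    if junction.circular:
        seq = tseq[: cut + 1] + junction.seq + tseq[cut + 1 :]
        composition = [
            (tid, (1, cut + 1)),
            ("element", (1, len(junction.seq))),
        ]
        if cut + 1 < len(tseq):
            composition.append((tid, (cut + 2, len(tseq))))
        return TransferProduct(
            id=f"{tid}::insertion",
            length=len(seq),
            composition=tuple(composition),
            labeled=getattr(target, "label_5prime", False),
            seq=seq,
        )

    jcut = locate_end_cleavage(junction)
    jid = _id_of(junction, "junction")
    seq = junction.seq[: jcut + 1] + tseq[cut + 1 :]
    composition = [(jid, (1, jcut + 1))]
    if cut + 1 < len(tseq):
        composition.append((tid, (cut + 2, len(tseq))))
    return TransferProduct(
        id=f"{jid}+{tid}",
        length=len(seq),
        composition=tuple(composition),
        labeled=junction.label_5prime,
        seq=seq,
    )


def junction_cleavage_product(junction: TransposonEnd) -> TransferProduct:
    """The labeled 5' cleavage segment of a linear junction oligo (the
    species running below the substrate on a gel)."""
    jcut = locate_end_cleavage(junction)
    jid = _id_of(junction, "junction")
    return TransferProduct(
        id=f"{jid}::cleaved",
        length=jcut + 1,
        composition=((jid, (1, jcut + 1)),),
        labeled=junction.label_5prime,
        seq=junction.seq[: jcut + 1],
    )


def virtual_gel(
    products: Iterable[TransferProduct],
    substrates: Iterable = (),
    fractions: Optional[dict] = None,
) -> list:
    """Ordered band table of labeled species (descending length).

    ``substrates`` may include labeled :class:`TransposonEnd`/:class:`Oligo`
    inputs, rendered as bands alongside the products.  When ``fractions``
    maps product ids to predicted competition fractions, those appear as
    relative band intensities.  Returns a list of dicts (one per band).
    """
    bands = []
    for sub in substrates:
        if getattr(sub, "label_5prime", False):
            sid = _id_of(sub, "substrate")
            bands.append({
                "id": sid,
                "length": len(_seq_of(sub)),
                "kind": "substrate",
                "composition": [[sid, [1, len(_seq_of(sub))]]],
                "intensity": None,
            })
    for prod in products:
        if not prod.labeled:
            continue
        bands.append({
            "id": prod.id,
            "length": prod.length,
            "kind": "product",
            "composition": [[src, list(iv)] for src, iv in prod.composition],
            "intensity": None if fractions is None else fractions.get(prod.id),
        })
    bands.sort(key=lambda b: (-b["length"], b["id"]))
    return bands
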