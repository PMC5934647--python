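"""Geometry checks against a deposited target-capture-complex structure.

Given a PDB/mmCIF coordinate file of the transposase/LE/target ternary
complex, this module resolves named atom selections and recomputes the two
distances that certify a cleavage-competent design geometry:

* the target 5'-terminus O5' to the phosphorus of the first extension
  position (+44) — the gap the engineered linker must bridge; and
* the catalytic tyrosine hydroxyl to the scissile phosphorus at the target
  +1 nucleotide — close only in the active complex copy.

The asymmetric unit typically holds several complex copies with the +1 base
in different orientations; :func:`find_active_complex` selects the copy by
the tyrosine-to-scissile-phosphate distance itself.  Parsing is delegated to
gemmi; this module is optional at run time and all bundled tests use small
synthetic coordinate fixtures (no download required).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import gemmi

__all__ = [
    "AtomSelection",
    "SelectionError",
    "read_structure",
    "write_structure",
    "atom_distance",
    "find_active_complex",
]


class SelectionError(ValueError):
    """An atom selection resolved to zero or multiple atoms."""


@dataclass(frozen=True)
class AtomSelection:
    """One atom, addressed by chain / residue number / atom name.

    ``residue_name`` is checked when given (guards against numbering shifts
    between depositions); set it to None to match any residue name.
    """

    chain: str
    residue_number: int
    atom_name: str
    residue_name: Optional[str] = None


def read_structure(path: str) -> gemmi.Structure:
    """Parse a PDB or mmCIF file (format auto-detected)."""
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:
        raise SelectionError(f"could not parse structure {path}: {exc}") from exc
    if len(st) == 0 or sum(len(ch) for ch in st[0]) == 0:
        raise SelectionError(f"structure {path} contains no atoms")
    st.setup_entities()
    return st


def write_structure(st: gemmi.Structure, path: str) -> None:
    path = str(path)
    if path.endswith(".cif") or path.endswith(".mmcif"):
        st.make_mmcif_document().write_file(path)
    else:
        st.write_pdb(path)


def _resolve(st: gemmi.Structure, sel: AtomSelection) -> gemmi.Atom:
    model = st[0]
    matches = []
    for chain in model:
        if chain.name != sel.chain:
            continue
        for residue in chain:
            if residue.seqid.num != sel.residue_number:
                continue
            if sel.residue_name is not None and residue.name.strip() != sel.residue_name:
                continue
            for atom in residue:
                if atom.name == sel.atom_name:
                    matches.append(atom)
    if len(matches) != 1:
        raise SelectionError(
            f"selection {sel} resolved to {len(matches)} atoms (need exactly 1)"
        )
    return matches[0]


def atom_distance(st: gemmi.Structure, a: AtomSelection, b: AtomSelection) -> float:
    """Euclidean distance in angstroms, reported to 0.1 A."""
    pa = _resolve(st, a).pos
    pb = _resolve(st, b).pos
    return round(pa.dist(pb), 1)


def find_active_complex(
    st: gemmi.Structure,
    tyr_selections,
    scissile_selections,
) -> dict:
    """Pick the complex copy poised for cleavage.

    ``tyr_selections`` and ``scissile_selections`` are equal-length lists of
    :class:`AtomSelection` (one per complex copy: catalytic-tyrosine hydroxyl
    and target scissile phosphorus).  The copy with the smallest
    tyrosine-to-phosphorus distance is the active one; returns its index and
    the per-copy distances.
    """
    if len(tyr_selections) != len(scissile_selections) or not tyr_selections:
        raise SelectionError("need matching, non-empty selection lists")
    dists = [
        atom_distance(st, ty, sc)
        for ty, sc in zip(tyr_selections, scissile_selections)
    ]
    active = min(range(len(dists)), key=lambda i: dists[i])
    return {"active_index": active, "distances": dists,
            "active_distance": dists[active]}
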