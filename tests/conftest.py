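"""Shared fixtures: one validated default design and its target pool.

The expensive objects (designs involve repeated 120-nt folds) are session
scoped so every test file reuses the same computation.
"""

from __future__ import annotations

from dataclasses import replace

import pytest

from is608design import target_scan as ts
from is608design.retarget_design import (
    apply_structural_unlocking,
    design_extension,
    validate_design,
)
from is608design.transposon_model import (
    make_canonical_junction,
    make_locus_fixture,
    make_target_fixtures,
)

SEED = 1


@pytest.fixture(scope="session")
def locus_and_site():
    locus, pos = make_locus_fixture(SEED)
    sites = ts.scan({"locus": locus})
    (site,) = [s for s in sites if s.ct_start == pos]
    return locus, site


@pytest.fixture(scope="session")
def design8(locus_and_site):
    """Default 8-nt-extension design: designed, unlocked, validated."""
    locus, site = locus_and_site
    d = design_extension(locus, site, ext_len=8, linker_len=3, seed=SEED)
    d = apply_structural_unlocking(d)
    return validate_design(d, genome={"locus": locus})


@pytest.fixture(scope="session")
def pool8(design8):
    return make_target_fixtures(SEED, design8, n_scrambled=4)


@pytest.fixture(scope="session")
def hairpin_design(design8):
    """The same design embedded in a junction with the occluding second
    hairpin planted over +46..+60 (not yet unlocked)."""
    junction = make_canonical_junction(
        SEED, ext_seq=design8.extension, with_second_hairpin=True
    )
    return replace(design8, junction=junction, validation={})
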