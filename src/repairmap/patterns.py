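"""Repair-outcome pattern vocabulary.

Cas9-induced double-strand-break repair outcomes are grouped into seven
mechanistic indel patterns defined by indel type (insertion/deletion),
length, and microhomology (MH) usage, plus an Unedited class:

* ``1bp Ins`` — single 1-bp insertion, the canonical fast-NHEJ product,
  frequently templated from the flanking base.
* ``Large Ins`` — insertion of >= 2 bp.
* ``MH Small Del`` / ``NonMH Small Del`` — deletions of 1-5 bp with or
  without >= ``mh_min`` bp of junction microhomology.
* ``MH Large Del`` / ``NonMH Large Del`` — deletions of > 5 bp, split the
  same way; the MH classes are the MMEJ signature.
* ``Mut`` — substitution-only alleles localized near the cleavage site.
"""

from __future__ import annotations

# Edited patterns, in canonical display order.
EDITED_PATTERNS: tuple[str, ...] = (
    "1bp Ins",
    "Large Ins",
    "MH Small Del",
    "NonMH Small Del",
    "MH Large Del",
    "NonMH Large Del",
    "Mut",
)

UNEDITED = "Unedited"

ALL_PATTERNS: tuple[str, ...] = EDITED_PATTERNS + (UNEDITED,)

#: Deletions of length <= SMALL_DEL_MAX are "small"; longer are "large".
SMALL_DEL_MAX = 5

#: Minimum junction microhomology (bp) for the MH deletion classes.
DEFAULT_MH_MIN = 2

#: Half-width (bp) of the cut-site window used to call repair events.
DEFAULT_WINDOW_BP = 5
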