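"""Approximate primer-binding-site search with 3'-anchored mismatch profiles.

A binding site is an ungapped alignment of a primer against a template
window, on either strand, with at most ``max_mismatches`` incompatible
positions under the IUPAC set-intersection rule.  Mismatch positions are
indexed from the primer's 3' end (the 3'-terminal base is position 1)
because polymerase extension — and hence the amplifiability criterion — is
3'-anchored; the 5'-indexed view is ``length - p + 1``.

Coordinates are 0-based half-open on the template PLUS strand regardless of
which strand the primer matches, so all downstream product arithmetic uses
one convention.

The scan is vectorised: each residue becomes a 4-bit base-set mask
(A=1, C=2, G=4, T=8); two codes are compatible iff their masks AND to a
non-zero value, so mismatch counts per offset are a windowed sum of
zero-tests.  Primer/template indels are out of scope (substitutions only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .seqio import IUPAC_MASK, Primer, SequenceRecord

__all__ = [
    "PLUS",
    "MINUS",
    "BindingSite",
    "find_binding_sites",
    "terminal_mismatch_count",
    "best_site",
]

PLUS = "plus"
MINUS = "minus"

# complement of a 4-bit mask: swap A(1)<->T(8) and C(2)<->G(4)
_COMP_MASK = np.array(
    [
        ((m & 1) and 8) | ((m & 8) and 1) | ((m & 2) and 4) | ((m & 4) and 2)
        for m in range(16)
    ],
    dtype=np.uint8,
)

_ENCODE = np.zeros(128, dtype=np.uint8)
for _code, _mask in IUPAC_MASK.items():
    _ENCODE[ord(_code)] = _mask


def _encode(residues: str) -> np.ndarray:
    """Residue string -> array of 4-bit base-set masks."""
    return _ENCODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class BindingSite:
    """One approximate match of a primer on a template strand.

    ``strand`` names the template strand whose 5'→3' reading the primer
    matches; ``start``/``end`` are always plus-strand coordinates.  On the
    plus strand the primer's 3' end sits at ``end - 1``; on the minus strand
    it sits at ``start``.
    """

    template_id: str
    primer_name: str
    strand: str  # PLUS or MINUS
    start: int
    end: int
    mismatch_positions: tuple[int, ...]  # indexed from the 3' end, 1-based, ascending
    total_mismatches: int
    terminal_window_mismatches: int
    has_ambiguity: bool = False  # site overlaps a template ambiguity code

    def __post_init__(self) -> None:
        assert self.strand in (PLUS, MINUS)
        assert self.total_mismatches == len(self.mismatch_positions)
        assert self.terminal_window_mismatches <= self.total_mismatches
        assert all(a < b for a, b in zip(self.mismatch_positions, self.mismatch_positions[1:]))


def find_binding_sites(
    primer: Primer,
    template: SequenceRecord,
    max_mismatches: int,
    window: int = 5,
) -> list[BindingSite]:
    """Every ungapped alignment of ``primer`` on either strand of ``template``
    with at most ``max_mismatches`` incompatible positions.

    ``window`` sets the 3'-terminal span used to pre-compute each site's
    ``terminal_window_mismatches``.  Sites are sorted by (start, strand) with
    plus before minus; templates shorter than the primer yield an empty list.
    Raising ``max_mismatches`` only ever adds sites (monotone superset).
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    plen = primer.length
    tlen = len(template)
    if tlen < plen:
        return []

    tmask = _encode(template.residues)
    pmask = _encode(primer.residues)
    windows = np.lib.stride_tricks.sliding_window_view(tmask, plen)
    # a template window overlapping any ambiguity code (mask not a power of 2)
    ambiguous = np.array([m not in (1, 2, 4, 8) for m in range(16)], dtype=bool)
    win_ambig = ambiguous[windows].any(axis=1)

    sites: list[BindingSite] = []
    for strand in (PLUS, MINUS):
        if strand == PLUS:
            # primer[j] vs template[start + j]; 3'-position p = plen - j
            probe = pmask
            pos_from_3prime = plen - np.arange(plen)
        else:
            # primer matches revcomp(window): primer[i] vs comp(template[end-1-i]).
            # Equivalently comp(primer) reversed, compared along the window:
            # offset j pairs primer index i = plen-1-j, so p = j + 1.
            probe = _COMP_MASK[pmask][::-1]
            pos_from_3prime = np.arange(plen) + 1
        mism = (windows & probe) == 0  # (n_offsets, plen)
        totals = mism.sum(axis=1)
        for start in np.flatnonzero(totals <= max_mismatches):
            js = np.flatnonzero(mism[start])
            positions = tuple(sorted(int(pos_from_3prime[j]) for j in js))
            sites.append(
                BindingSite(
                    template_id=template.id,
                    primer_name=primer.name,
                    strand=strand,
                    start=int(start),
                    end=int(start) + plen,
                    mismatch_positions=positions,
                    total_mismatches=len(positions),
                    terminal_window_mismatches=sum(1 for p in positions if p <= window),
                    has_ambiguity=bool(win_ambig[start]),
                )
            )
    sites.sort(key=lambda s: (s.start, 0 if s.strand == PLUS else 1))
    return sites


def terminal_mismatch_count(site: BindingSite, window: int) -> int:
    """Number of mismatches within ``window`` bases of the primer's 3' end."""
    if window < 1:
        raise ValueError("window must be >= 1")
    return sum(1 for p in site.mismatch_positions if p <= window)


def best_site(
    sites: Sequence[BindingSite],
    terminal_threshold: int = 2,
    total_threshold: int = 3,
) -> Optional[BindingSite]:
    """The single site a bench scientist would inspect for a primer/template
    pair: the one closest to supporting amplification.

    Sites are ranked first by their *excess* over the amplifiability
    thresholds — mismatches beyond ``terminal_threshold - 1`` in the 3'
    window plus mismatches beyond ``total_threshold`` overall — so a
    near-viable orthologous locus is preferred over a heavily mismatched
    chance match even when the latter happens to be clean at its 3' end.
    Ties break on fewest 3'-window mismatches (they dominate the criterion),
    then fewest total mismatches, then leftmost start, plus strand before
    minus.  ``None`` for an empty list.
    """
    if not sites:
        return None

    def excess(s: BindingSite) -> int:
        return max(0, s.terminal_window_mismatches - (terminal_threshold - 1)) + max(
            0, s.total_mismatches - total_threshold
        )

    return min(
        sites,
        key=lambda s: (
            excess(s),
            s.terminal_window_mismatches,
            s.total_mismatches,
            s.start,
            0 if s.strand == PLUS else 1,
        ),
    )
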