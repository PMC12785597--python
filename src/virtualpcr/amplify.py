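"""Pair converging binding sites into amplicons and predict the product.

Product length follows the standard PCR convention: it spans both primer
footprints inclusively, so for a plus-strand forward site ``f`` and a
minus-strand reverse site ``r`` the product is ``r.end - f.start`` bases.
This is the convention under which the assay's 526 bp COI product is
reproducible from genomic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .binding import MINUS, PLUS, BindingSite
from .seqio import SequenceRecord, reverse_complement

__all__ = ["AmpliconPrediction", "predict_amplicons", "extract_product"]


class CoordinateError(ValueError):
    """An amplicon span falls outside its template."""


@dataclass(frozen=True)
class AmpliconPrediction:
    """An orientation-consistent forward/reverse site pair and its product.

    ``forward_site`` and ``reverse_site`` lie on opposite strands with their
    3' ends pointing toward each other.  ``product_sequence`` is filled by
    :func:`extract_product` (or by passing a template to
    :func:`predict_amplicons`) and is oriented to begin with the forward
    primer's footprint.
    """

    template_id: str
    forward_site: BindingSite
    reverse_site: BindingSite
    product_length: int
    product_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        assert self.forward_site.strand != self.reverse_site.strand
        if self.product_sequence is not None:
            assert len(self.product_sequence) == self.product_length

    @property
    def span(self) -> tuple[int, int]:
        """Plus-strand half-open coordinates of the whole product."""
        lo = min(self.forward_site.start, self.reverse_site.start)
        hi = max(self.forward_site.end, self.reverse_site.end)
        return lo, hi


def predict_amplicons(
    fwd_sites: Sequence[BindingSite],
    rev_sites: Sequence[BindingSite],
    min_len: int,
    max_len: int,
    template: Optional[SequenceRecord] = None,
) -> list[AmpliconPrediction]:
    """All converging forward/reverse site pairs whose product length falls in
    ``[min_len, max_len]`` (closed interval).

    Both primer-role/strand assignments are considered, so a template
    deposited in either orientation is handled: the pair is valid when the
    plus-strand member lies upstream of the minus-strand member and the
    footprints do not overlap.  Duplicate spans (from overlapping site lists)
    are deduplicated; results are sorted by product length ascending, and the
    shortest is the "primary" product for reporting.  If ``template`` is
    given the product sequence is extracted as well.
    """
    if not (0 < min_len <= max_len):
        raise ValueError("require 0 < min_len <= max_len")
    out: list[AmpliconPrediction] = []
    seen: set[tuple[int, int, int, int]] = set()
    for f in fwd_sites:
        for r in rev_sites:
            if f.strand == PLUS and r.strand == MINUS:
                plus, minus = f, r
            elif f.strand == MINUS and r.strand == PLUS:
                plus, minus = r, f
            else:
                continue  # same strand: primers would extend in parallel
            if minus.start < plus.end:
                continue  # diverging or overlapping footprints
            length = minus.end - plus.start
            if not (min_len <= length <= max_len):
                continue
            key = (f.start, f.end, r.start, r.end)
            if key in seen:
                continue
            seen.add(key)
            amp = AmpliconPrediction(
                template_id=f.template_id,
                forward_site=f,
                reverse_site=r,
                product_length=length,
            )
            if template is not None:
                amp = replace(amp, product_sequence=extract_product(template, amp))
            out.append(amp)
    out.sort(key=lambda a: (a.product_length, a.span))
    return out


def extract_product(template: SequenceRecord, amplicon: AmpliconPrediction) -> str:
    """Template residues over the amplicon span, oriented so the string begins
    with the forward primer's footprint (reverse-complemented when the forward
    site is on the minus strand)."""
    lo, hi = amplicon.span
    if lo < 0 or hi > len(template):
        raise CoordinateError(
            f"amplicon span [{lo},{hi}) outside template {template.id!r} "
            f"of length {len(template)}"
        )
    product = template.residues[lo:hi]
    if amplicon.forward_site.strand == MINUS:
        product = reverse_complement(product)
    return product
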