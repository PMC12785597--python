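"""The amplifiability criterion and per-template specificity verdicts.

A template is considered unlikely to amplify when, for either primer's best
binding site, two or more mismatches fall within the 3'-terminal five bases,
or more than three mismatches occur across the whole primer; mismatches at
the extension end disproportionately block the polymerase, which is why the
rule is 3'-anchored.  The thresholds live in :class:`SpecificityParams`
(defaults window=5, terminal_threshold=2, total_threshold=3) rather than in
constants.  The total-mismatch clause is applied per primer, not summed over
the pair.

A verdict of "amplifiable" additionally requires an orientation-valid
amplicon within the configured length bounds — two converging sites 50 kb
apart should not count as amplification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .amplify import predict_amplicons
from .binding import BindingSite, best_site, find_binding_sites
from .seqio import Primer, SequenceRecord

__all__ = [
    "SpecificityParams",
    "PrimerSiteSummary",
    "SpecificityVerdict",
    "classify_primer_site",
    "classify_template",
    "OK",
    "NO_SITE",
    "TERMINAL_MM",
    "TOTAL_MM",
]

# reason codes
OK = "OK"
NO_SITE = "NO_SITE"
TERMINAL_MM = "TERMINAL_MM"
TOTAL_MM = "TOTAL_MM"
NO_VALID_PAIR = "NO_VALID_PAIR"


@dataclass(frozen=True)
class SpecificityParams:
    """Tunable rule parameters.

    window
        3'-terminal span inspected per primer, in bases (default 5).
    terminal_threshold
        mismatches inside the window that block amplification (default 2,
        i.e. "two or more").
    total_threshold
        maximum tolerated mismatches across a whole primer (default 3,
        i.e. "more than three" fails).
    max_mismatches
        search budget for the binding-site scan.  The rule saturates above
        3 total mismatches, so any budget >= 4 yields identical verdicts;
        the default 7 leaves margin for informative reporting.
    min_len, max_len
        accepted product-length bounds, generous around the 526 bp target.
    """

    window: int = 5
    terminal_threshold: int = 2
    total_threshold: int = 3
    max_mismatches: int = 7
    min_len: int = 50
    max_len: int = 2000

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.terminal_threshold < 1:
            raise ValueError("terminal_threshold must be >= 1")
        if self.total_threshold < 0:
            raise ValueError("total_threshold must be >= 0")
        if self.terminal_threshold > self.max_mismatches:
            raise ValueError("terminal_threshold cannot exceed max_mismatches")
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("require 0 < min_len <= max_len")


@dataclass(frozen=True)
class PrimerSiteSummary:
    """Best-site mismatch summary for one primer on one template."""

    primer_name: str
    found: bool
    strand: Optional[str] = None
    start: Optional[int] = None
    total_mismatches: Optional[int] = None
    terminal_window_mismatches: Optional[int] = None
    mismatch_positions: tuple[int, ...] = ()
    has_ambiguity: bool = False


@dataclass(frozen=True)
class SpecificityVerdict:
    """Per-template amplifiable/non-amplifiable call with reason codes.

    ``amplifiable`` is true iff ``reasons == ["OK"]``; every failed condition
    contributes its own code, so a congener failing both clauses on both
    primers lists all four.
    """

    template_id: str
    species_label: str
    amplifiable: bool
    reasons: tuple[str, ...]
    primary_product_length: Optional[int]
    fwd: PrimerSiteSummary
    rev: PrimerSiteSummary

    def __post_init__(self) -> None:
        assert self.amplifiable == (self.reasons == (OK,))
        if self.amplifiable:
            assert self.primary_product_length is not None


def classify_primer_site(
    site: Optional[BindingSite], params: SpecificityParams
) -> tuple[bool, list[str]]:
    """Apply the per-primer clauses of the rule to one (best) binding site.

    Fails when the site is absent, when >= ``terminal_threshold`` mismatches
    fall inside the 3'-terminal window, or when total mismatches exceed
    ``total_threshold``.  Returns (passed, reason codes); codes enumerate
    every triggered condition.
    """
    if site is None:
        return False, [NO_SITE]
    reasons: list[str] = []
    terminal = sum(1 for p in site.mismatch_positions if p <= params.window)
    if terminal >= params.terminal_threshold:
        reasons.append(TERMINAL_MM)
    if site.total_mismatches > params.total_threshold:
        reasons.append(TOTAL_MM)
    return (not reasons), reasons


def classify_template(
    fwd: Primer,
    rev: Primer,
    template: SequenceRecord,
    params: SpecificityParams = SpecificityParams(),
    species_label: Optional[str] = None,
) -> SpecificityVerdict:
    """Full virtual-PCR verdict for one template.

    Scans both strands for each primer, takes the best site per primer,
    applies the per-primer criterion, and requires at least one converging
    amplicon within the length bounds.  Deterministic: identical inputs give
    identical verdicts.
    """
    if species_label is None:
        species_label = _species_from_description(template)

    fwd_sites = find_binding_sites(fwd, template, params.max_mismatches, window=params.window)
    rev_sites = find_binding_sites(rev, template, params.max_mismatches, window=params.window)
    fwd_best = best_site(fwd_sites, params.terminal_threshold, params.total_threshold)
    rev_best = best_site(rev_sites, params.terminal_threshold, params.total_threshold)

    reasons: list[str] = []
    fwd_pass, fwd_reasons = _classify_candidates(fwd_sites, fwd_best, params)
    rev_pass, rev_reasons = _classify_candidates(rev_sites, rev_best, params)
    reasons += [_suffix(r, "FWD") for r in fwd_reasons]
    reasons += [_suffix(r, "REV") for r in rev_reasons]

    # Only criterion-passing sites can prime, so only they are paired into
    # products; the wide search budget still feeds the per-primer report.
    # Overlapping same-strand registers of one primer are a single physical
    # locus, and the register with fewer mismatches outcompetes the others
    # for binding, so dominated registers are dropped before pairing.
    fwd_viable = _suppress_dominated(
        [s for s in fwd_sites if classify_primer_site(s, params)[0]]
    )
    rev_viable = _suppress_dominated(
        [s for s in rev_sites if classify_primer_site(s, params)[0]]
    )

    primary_length: Optional[int] = None
    if fwd_viable and rev_viable:
        amplicons = predict_amplicons(
            fwd_viable, rev_viable, params.min_len, params.max_len, template=template
        )
        if amplicons:
            primary_length = amplicons[0].product_length
        elif fwd_pass and rev_pass:
            reasons.append(NO_VALID_PAIR)

    amplifiable = not reasons and primary_length is not None
    return SpecificityVerdict(
        template_id=template.id,
        species_label=species_label,
        amplifiable=amplifiable,
        reasons=(OK,) if amplifiable else tuple(reasons),
        primary_product_length=primary_length,
        fwd=_summarize(fwd, fwd_best),
        rev=_summarize(rev, rev_best),
    )


def _suppress_dominated(sites: list[BindingSite]) -> list[BindingSite]:
    """Drop sites that overlap a same-strand site with strictly fewer total
    mismatches — shifted registers of a self-similar primer over one locus
    collapse to the register that actually wins the binding competition."""
    return [
        s
        for s in sites
        if not any(
            t is not s
            and t.strand == s.strand
            and t.start < s.end
            and s.start < t.end
            and t.total_mismatches < s.total_mismatches
            for t in sites
        )
    ]


def _classify_candidates(
    sites: list[BindingSite],
    best: Optional[BindingSite],
    params: SpecificityParams,
) -> tuple[bool, list[str]]:
    """Per-primer pass/fail with reasons drawn from every candidate locus.

    Self-similar primers can bind their own footprint region in several
    shifted registers that tie on how far they are from amplification
    competence; when the primer fails, the codes therefore enumerate the
    blocking conditions across all sites tied at minimal criterion excess,
    not just the single reported best site.  Pass/fail itself is unchanged:
    the primer passes iff its best site satisfies the rule.
    """
    passed, _ = classify_primer_site(best, params)
    if passed:
        return True, []
    if best is None:
        return False, [NO_SITE]

    def excess(s: BindingSite) -> int:
        return max(0, s.terminal_window_mismatches - (params.terminal_threshold - 1)) + max(
            0, s.total_mismatches - params.total_threshold
        )

    min_excess = min(excess(s) for s in sites)
    codes: list[str] = []
    for s in sites:
        if excess(s) != min_excess:
            continue
        for code in classify_primer_site(s, params)[1]:
            if code not in codes:
                codes.append(code)
    codes.sort(key=[TERMINAL_MM, TOTAL_MM].index)
    return False, codes


def _suffix(reason: str, role: str) -> str:
    if reason == NO_SITE:
        return f"NO_{role}_SITE"
    return f"{reason}_{role}"


def _summarize(primer: Primer, site: Optional[BindingSite]) -> PrimerSiteSummary:
    if site is None:
        return PrimerSiteSummary(primer_name=primer.name, found=False)
    return PrimerSiteSummary(
        primer_name=primer.name,
        found=True,
        strand=site.strand,
        start=site.start,
        total_mismatches=site.total_mismatches,
        terminal_window_mismatches=site.terminal_window_mismatches,
        mismatch_positions=site.mismatch_positions,
        has_ambiguity=site.has_ambiguity,
    )


def _species_from_description(template: SequenceRecord) -> str:
    """Species label = first whitespace token after the id, else the id."""
    parts = template.description.split()
    if parts and parts[0] == template.id:
        parts = parts[1:]
    return parts[0] if parts else template.id
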