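"""Shared fixtures and the independent brute-force binding oracle.

The oracle here re-derives approximate binding sites from first principles
(per-offset character scan over explicit IUPAC base sets) and deliberately
shares no code with ``virtualpcr.binding``'s vectorised bitmask scan.
"""

from __future__ import annotations

import random

import pytest

from virtualpcr import COI_FORWARD_PRIMER, COI_REVERSE_PRIMER

# independent IUPAC table (sets, not bitmasks)
ORACLE_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}
ORACLE_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def oracle_sites(primer_seq: str, template_seq: str, max_mm: int) -> list[tuple]:
    """All-offsets, both-strands brute-force scan.

    Returns tuples (strand, start, mismatch_positions_from_3prime) sorted by
    (start, plus-first), exactly the content find_binding_sites must report.
    Early-exits an offset once the budget is exceeded — that cannot change
    which offsets qualify.
    """
    plen, tlen = len(primer_seq), len(template_seq)
    out = []
    for start in range(tlen - plen + 1):
        # plus strand: primer read along the template
        mm = []
        for i, p in enumerate(primer_seq):
            if not (ORACLE_SETS[p] & ORACLE_SETS[template_seq[start + i]]):
                mm.append(plen - i)
                if len(mm) > max_mm:
                    break
        if len(mm) <= max_mm:
            out.append(("plus", start, tuple(sorted(mm))))
        # minus strand: primer read along the reverse complement of the window
        mm = []
        for i, p in enumerate(primer_seq):
            t = ORACLE_COMPLEMENT[template_seq[start + plen - 1 - i]]
            if not (ORACLE_SETS[p] & ORACLE_SETS[t]):
                mm.append(plen - i)
                if len(mm) > max_mm:
                    break
        if len(mm) <= max_mm:
            out.append(("minus", start, tuple(sorted(mm))))
    out.sort(key=lambda s: (s[1], 0 if s[0] == "plus" else 1))
    return out


def random_seq(rng: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


@pytest.fixture(scope="session")
def fwd_primer():
    return COI_FORWARD_PRIMER


@pytest.fixture(scope="session")
def rev_primer():
    return COI_REVERSE_PRIMER
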