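"""Synthetic templates and panels with planted, independently-scored truth.

Real reference sequences for the target species and its congeners are not
bundled; instead this module builds templates in which the ground truth is
known by construction: a random background, the forward primer's footprint
planted at a chosen position, the reverse primer's reverse complement ending
exactly ``product_length`` bases later, and mismatches mutated in at chosen
3'-indexed primer positions.  Every mutation breaks IUPAC compatibility
outright (never to an ambiguity code), so planted mismatch counts are
unambiguous.

The expected verdict attached to each template is computed by
:func:`expected_amplifiable_from_specs`, a deliberately separate
re-statement of the amplifiability rule that shares no code with the
specificity module — it is the anti-circular oracle the pipeline is tested
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .seqio import IUPAC_SETS, Primer, SequenceRecord, write_fasta

__all__ = [
    "MismatchSpec",
    "PlantedTruth",
    "random_template",
    "plant_amplicon",
    "make_congener_panel",
    "default_congener_specs",
    "expected_amplifiable_from_specs",
    "write_truth_tsv",
]

FORWARD = "forward"
REVERSE = "reverse"

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class MismatchSpec:
    """Mismatches to plant into one primer's footprint, positions indexed
    from the primer's 3' end (3'-terminal base = 1)."""

    primer_role: str  # FORWARD or REVERSE
    positions_from_3prime: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.primer_role not in (FORWARD, REVERSE):
            raise ValueError(f"primer_role must be {FORWARD!r} or {REVERSE!r}")
        pos = self.positions_from_3prime
        if len(set(pos)) != len(pos) or any(p < 1 for p in pos):
            raise ValueError("mismatch positions must be unique integers >= 1")


@dataclass(frozen=True)
class PlantedTruth:
    """Generator ground truth for one template: where the product sits, what
    was mutated, and the verdict the pipeline is expected to reach."""

    template_id: str
    fwd_start: int
    product_length: int
    mismatch_specs: tuple[MismatchSpec, ...]
    expected_amplifiable: bool
    seed: int


def expected_amplifiable_from_specs(
    specs: Sequence[MismatchSpec],
    window: int = 5,
    terminal_threshold: int = 2,
    total_threshold: int = 3,
) -> bool:
    """Score planted mismatches with a free-standing statement of the rule:
    amplifiable iff, for each primer, fewer than ``terminal_threshold``
    mismatches sit within ``window`` of the 3' end and the primer's total
    does not exceed ``total_threshold``.  Kept independent of the
    specificity module on purpose.
    """
    for role in (FORWARD, REVERSE):
        positions = [
            p for s in specs if s.primer_role == role for p in s.positions_from_3prime
        ]
        in_window = sum(1 for p in positions if p <= window)
        if in_window >= terminal_threshold or len(positions) > total_threshold:
            return False
    return True


def random_template(
    length: int,
    gc_fraction: float = 0.45,
    seed: int = 0,
    id: str = "template",
    description: str = "",
) -> SequenceRecord:
    """Reproducible random A/C/G/T template with the requested GC content.

    Same (length, gc_fraction, seed) always yields the identical string.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 <= gc_fraction <= 1.0):
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    residues = "".join(rng.choice(list("ACGT"), size=length, p=probs))
    return SequenceRecord(id=id, residues=residues, description=description)


def _incompatible_base(primer_code: str, facing: str, rng: np.random.Generator) -> str:
    """A concrete template base (as it faces the primer) incompatible with
    ``primer_code``; N-like primer codes admit none and are rejected."""
    candidates = [b for b in "ACGT" if b not in IUPAC_SETS[primer_code]]
    if not candidates:
        raise ValueError(
            f"cannot plant a mismatch against primer code {primer_code!r}: "
            "it matches every base"
        )
    return candidates[int(rng.integers(len(candidates)))]


def plant_amplicon(
    background: SequenceRecord,
    fwd: Primer,
    rev: Primer,
    fwd_start: int,
    product_length: int,
    specs: Sequence[MismatchSpec] = (),
    seed: int = 0,
) -> tuple[SequenceRecord, PlantedTruth]:
    """Overwrite ``background`` so a virtual product of exactly
    ``product_length`` bp starts at ``fwd_start``, then mutate in the
    requested mismatches.

    The forward primer footprint occupies ``[fwd_start, fwd_start+|fwd|)``
    on the plus strand; the reverse primer's reverse complement ends at
    ``fwd_start + product_length``.  Each planted position is mutated, on
    the strand the primer reads, to a base incompatible with the primer's
    code there (choice seeded).
    """
    flen, rlen = fwd.length, rev.length
    if product_length < flen + rlen:
        raise ValueError("product_length must cover both primer footprints")
    end = fwd_start + product_length
    if fwd_start < 0 or end > len(background):
        raise ValueError("planted product falls outside the background template")
    for s in specs:
        plen = flen if s.primer_role == FORWARD else rlen
        if any(p > plen for p in s.positions_from_3prime):
            raise ValueError(
                f"mismatch position beyond {s.primer_role} primer length {plen}"
            )

    rng = np.random.default_rng(seed)
    seq = list(background.residues)

    # perfect footprints first
    seq[fwd_start : fwd_start + flen] = list(fwd.residues)
    rev_rc = "".join(_COMPLEMENT[b] for b in reversed(rev.residues))
    seq[end - rlen : end] = list(rev_rc)

    # then break compatibility at the planted positions
    for s in specs:
        for p in s.positions_from_3prime:
            if s.primer_role == FORWARD:
                # primer index i = flen - p (0-based from 5'); template faces it directly
                t_index = fwd_start + flen - p
                code = fwd.residues[flen - p]
                seq[t_index] = _incompatible_base(code, seq[t_index], rng)
            else:
                # reverse primer's 3' base pairs with plus-strand position end - rlen;
                # position p from the 3' end sits p-1 further right
                t_index = end - rlen + (p - 1)
                code = rev.residues[rlen - p]
                facing = _incompatible_base(code, seq[t_index], rng)
                seq[t_index] = _COMPLEMENT[facing]

    template = SequenceRecord(
        id=background.id, residues="".join(seq), description=background.description
    )
    truth = PlantedTruth(
        template_id=background.id,
        fwd_start=fwd_start,
        product_length=product_length,
        mismatch_specs=tuple(specs),
        expected_amplifiable=expected_amplifiable_from_specs(specs),
        seed=seed,
    )
    return template, truth


def default_congener_specs(
    fwd: Primer, rev: Primer, rng: np.random.Generator
) -> list[MismatchSpec]:
    """A congener-like mismatch pattern: for each primer, two mismatches
    inside the 3'-terminal five-base window plus one or two further out —
    multiple mismatches concentrated at the extension ends, the pattern that
    distinguishes non-target relatives at an otherwise conserved locus."""
    specs = []
    for role, primer in ((FORWARD, fwd), (REVERSE, rev)):
        window_positions = rng.choice(np.arange(1, 6), size=2, replace=False)
        n_outer = int(rng.integers(1, 3))
        outer_positions = rng.choice(
            np.arange(6, primer.length + 1), size=n_outer, replace=False
        )
        positions = tuple(sorted(int(p) for p in (*window_positions, *outer_positions)))
        specs.append(MismatchSpec(primer_role=role, positions_from_3prime=positions))
    return specs


def make_congener_panel(
    fwd: Primer,
    rev: Primer,
    n_decoys: int = 9,
    config: Optional[Sequence[Sequence[MismatchSpec]]] = None,
    seed: int = 0,
    product_length: int = 526,
    template_length: int = 1200,
    gc_fraction: float = 0.45,
    mode: str = "independent",
) -> tuple[list[SequenceRecord], list[PlantedTruth]]:
    """One perfectly matched target template plus ``n_decoys`` mismatched
    decoys, all with planted truth.

    ``config`` gives the per-decoy mismatch specs (length must equal
    ``n_decoys``); when omitted each decoy gets :func:`default_congener_specs`.
    ``mode='independent'`` builds each decoy on its own random background;
    ``mode='mutant'`` copies the target's sequence and only mutates the
    primer footprints, emulating congeners that differ from the target just
    at the binding sites.  Fully seeded: the same arguments always return
    byte-identical panels.
    """
    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")
    if config is not None and len(config) != n_decoys:
        raise ValueError(f"config has {len(config)} entries but n_decoys={n_decoys}")
    if mode not in ("independent", "mutant"):
        raise ValueError("mode must be 'independent' or 'mutant'")

    rng = np.random.default_rng(seed)
    max_start = template_length - product_length
    if max_start < 0:
        raise ValueError("template_length must be >= product_length")

    templates: list[SequenceRecord] = []
    truths: list[PlantedTruth] = []

    def _build(index: int, label: str, specs: Sequence[MismatchSpec]) -> None:
        sub_seed = int(rng.integers(2**31))
        fwd_start = int(rng.integers(max_start + 1))
        if mode == "mutant" and index > 0:
            background = SequenceRecord(
                id=f"synthetic_{label}",
                residues=templates[0].residues,
                description=f"synthetic_{label} {label}",
            )
            fwd_start = truths[0].fwd_start
        else:
            background = random_template(
                template_length,
                gc_fraction,
                seed=sub_seed,
                id=f"synthetic_{label}",
                description=f"synthetic_{label} {label}",
            )
        template, truth = plant_amplicon(
            background, fwd, rev, fwd_start, product_length, specs, seed=sub_seed
        )
        templates.append(template)
        truths.append(truth)

    _build(0, "target", specs=())
    for i in range(1, n_decoys + 1):
        specs = config[i - 1] if config is not None else default_congener_specs(fwd, rev, rng)
        _build(i, f"decoy_{i}", specs)
    return templates, truths


def write_truth_tsv(truths: Sequence[PlantedTruth], path: str | Path) -> None:
    """Fixture contract for tests: one row per template with coordinates,
    per-primer planted positions and the expected verdict."""
    rows = []
    for t in truths:
        by_role = {FORWARD: [], REVERSE: []}
        for s in t.mismatch_specs:
            by_role[s.primer_role].extend(s.positions_from_3prime)
        rows.append(
            {
                "template_id": t.template_id,
                "fwd_start": t.fwd_start,
                "product_length": t.product_length,
                "fwd_mismatch_positions": ",".join(map(str, sorted(by_role[FORWARD]))),
                "rev_mismatch_positions": ",".join(map(str, sorted(by_role[REVERSE]))),
                "expected_amplifiable": t.expected_amplifiable,
                "seed": t.seed,
            }
        )
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)
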