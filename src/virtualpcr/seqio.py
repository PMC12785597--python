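"""Sequence and primer I/O plus the IUPAC nucleotide-alphabet primitives.

Everything downstream (binding-site search, mismatch profiling, amplicon
prediction) is defined in terms of the two primitives here:

* :func:`reverse_complement` under the full IUPAC complement table, and
* :func:`iupac_compatible`, the set-intersection match rule: two codes are
  compatible iff the base sets they denote intersect.  A primer/template
  position is a *mismatch* iff its codes are incompatible.  A consequence
  of this convention is that an ``N`` in a template can never count as a
  mismatch; reports flag binding sites that overlap ambiguity codes.

Sequences are normalised on construction: lowercase is uppercased and RNA
``U`` becomes ``T`` (GenBank downloads vary in case).  Gap characters are
rejected rather than stripped — the pipeline consumes unaligned sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "IUPAC_SETS",
    "AlphabetError",
    "FastaParseError",
    "SequenceRecord",
    "Primer",
    "read_fasta",
    "write_fasta",
    "read_primers",
    "reverse_complement",
    "iupac_compatible",
    "normalize_residues",
]

#: base sets denoted by each IUPAC nucleotide code
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# 4-bit mask per code (A=1, C=2, G=4, T=8); shared with the binding module.
_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
IUPAC_MASK: dict[str, int] = {
    code: sum(_BASE_BITS[b] for b in bases) for code, bases in IUPAC_SETS.items()
}


class AlphabetError(ValueError):
    """A residue string contains a character outside the IUPAC nucleotide set."""


class FastaParseError(ValueError):
    """A FASTA or primer file is malformed (bad header, empty or invalid sequence,
    duplicate identifier)."""


def normalize_residues(raw: str, *, context: str = "sequence") -> str:
    """Uppercase, convert U to T and validate against the IUPAC alphabet.

    Gap characters (``-``, ``.``) are rejected: inputs must be unaligned.
    """
    residues = raw.upper().replace("U", "T")
    bad = set(residues) - IUPAC_SETS.keys()
    if bad:
        raise AlphabetError(
            f"{context} contains non-IUPAC character(s): {sorted(bad)!r}"
        )
    return residues


@dataclass(frozen=True)
class SequenceRecord:
    """A named template sequence over the IUPAC nucleotide alphabet.

    ``description`` is free text and may carry a species label (the panel
    module reads the first whitespace-delimited token of it).
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise FastaParseError(f"sequence id {self.id!r} is empty or has whitespace")
        if not self.residues:
            raise FastaParseError(f"record {self.id!r} has an empty sequence")
        object.__setattr__(
            self, "residues", normalize_residues(self.residues, context=f"record {self.id!r}")
        )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Primer:
    """A named oligonucleotide, written 5'→3'.

    The 3'-terminal bases drive the amplifiability criterion, so orientation
    matters: ``residues[-1]`` is the extension end.  Strings shorter than 10
    bases are rejected as implausible primers.
    """

    name: str
    residues: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("primer name must be non-empty")
        object.__setattr__(
            self, "residues", normalize_residues(self.residues, context=f"primer {self.name!r}")
        )
        if len(self.residues) < 10:
            raise ValueError(
                f"primer {self.name!r} is only {len(self.residues)} nt long; "
                "strings shorter than 10 nt are rejected as implausible primers"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


def reverse_complement(residues: str) -> str:
    """Reverse complement under full IUPAC complementation (R↔Y, K↔M, B↔V, D↔H,
    S/W/N self-complementary)."""
    residues = normalize_residues(residues)
    return str(Seq(residues).reverse_complement())


def iupac_compatible(a: str, b: str) -> bool:
    """True iff the base sets denoted by codes ``a`` and ``b`` intersect.

    A primer/template position is a mismatch iff this returns ``False``.
    Symmetric by construction.
    """
    try:
        return bool(IUPAC_MASK[a.upper()] & IUPAC_MASK[b.upper()])
    except KeyError as exc:
        raise AlphabetError(f"invalid IUPAC code: {exc.args[0]!r}") from None


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into :class:`SequenceRecord` objects.

    Order is preserved; residues are normalised (U→T, uppercased); duplicate
    ids raise :class:`FastaParseError` naming the offending record.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for index, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if not rec.id:
            raise FastaParseError(f"{path}: record #{index} has a malformed/empty header")
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate sequence id {rec.id!r} (record #{index})")
        seen.add(rec.id)
        try:
            records.append(
                SequenceRecord(id=rec.id, residues=str(rec.seq), description=rec.description)
            )
        except (FastaParseError, AlphabetError) as exc:
            raise FastaParseError(f"{path}: record #{index}: {exc}") from exc
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA; round-trips byte-identically for normalised input."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description or "")
        for r in records
    ]
    SeqIO.write(bio, str(Path(path)), "fasta")


def read_primers(path: str | Path) -> tuple[Primer, Primer]:
    """Read a forward/reverse primer pair from a 2-record FASTA or a 2-row TSV.

    TSV format: columns ``name`` and ``sequence`` (header optional).  The
    first entry is taken as the forward primer, the second as the reverse.
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        recs = read_fasta(path)
        if len(recs) != 2:
            raise FastaParseError(f"{path}: expected exactly 2 primer records, got {len(recs)}")
        return Primer(recs[0].id, recs[0].residues), Primer(recs[1].id, recs[1].residues)
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FastaParseError(f"{path}:{lineno}: expected 'name<TAB>sequence'")
        if parts[0].lower() == "name" and parts[1].lower() == "sequence":
            continue  # header row
        rows.append((parts[0], parts[1]))
    if len(rows) != 2:
        raise FastaParseError(f"{path}: expected exactly 2 primer rows, got {len(rows)}")
    return Primer(rows[0][0], rows[0][1]), Primer(rows[1][0], rows[1][1])
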