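"""Cross-species panel evaluation and specificity reports.

This is the computational twin of a wet-lab specificity gel: one primer
pair run against templates from the target species plus candidate
adulterants and congeners, with one amplifiable/non-amplifiable verdict per
lane.  When an expected-label table is supplied (species → should-amplify),
a confusion matrix is computed against it; a perfectly specific assay on a
1-target/9-decoy panel reads (TP, FP, TN, FN) = (1, 0, 9, 0).

Multiple sequence alignment is deliberately absent: per-template ungapped
approximate matching at the orthologous locus yields the same per-primer
mismatch counts as reading them off an MSA column-by-column, without the
alignment dependency.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .seqio import Primer, SequenceRecord
from .specificity import (
    PrimerSiteSummary,
    SpecificityParams,
    SpecificityVerdict,
    classify_template,
)

__all__ = [
    "PanelReport",
    "ConfigError",
    "evaluate_panel",
    "write_report",
    "read_report_json",
    "read_expected_tsv",
]

_TSV_COLUMNS = [
    "species",
    "template_id",
    "amplifiable",
    "reasons",
    "product_length",
    "fwd_terminal_mm",
    "fwd_total_mm",
    "rev_terminal_mm",
    "rev_total_mm",
]


class ConfigError(ValueError):
    """An expectations table references a species absent from the panel."""


@dataclass(frozen=True)
class PanelReport:
    """Ordered per-template verdicts with summary and optional confusion counts.

    ``confusion`` is ``(tp, fp, tn, fn)`` over the templates whose species
    appear in the expectations map; ``None`` when no expectations were given.
    """

    rows: tuple[tuple[str, str, SpecificityVerdict], ...]
    summary: dict[str, int]
    confusion: Optional[tuple[int, int, int, int]] = None

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for species, template_id, v in self.rows:
            records.append(
                {
                    "species": species,
                    "template_id": template_id,
                    "amplifiable": v.amplifiable,
                    "reasons": ";".join(v.reasons),
                    "product_length": v.primary_product_length,
                    "fwd_terminal_mm": v.fwd.terminal_window_mismatches,
                    "fwd_total_mm": v.fwd.total_mismatches,
                    "rev_terminal_mm": v.rev.terminal_window_mismatches,
                    "rev_total_mm": v.rev.total_mismatches,
                }
            )
        return pd.DataFrame.from_records(records, columns=_TSV_COLUMNS)

    def to_dict(self) -> dict:
        d: dict = {
            "rows": [
                {"species": s, "template_id": t, "verdict": asdict(v)}
                for s, t, v in self.rows
            ],
            "summary": dict(self.summary),
        }
        if self.confusion is not None:
            tp, fp, tn, fn = self.confusion
            d["confusion"] = {
                "true_positive": tp,
                "false_positive": fp,
                "true_negative": tn,
                "false_negative": fn,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PanelReport":
        rows = []
        for row in d["rows"]:
            vd = dict(row["verdict"])
            vd["reasons"] = tuple(vd["reasons"])
            for role in ("fwd", "rev"):
                pd_ = dict(vd[role])
                pd_["mismatch_positions"] = tuple(pd_["mismatch_positions"])
                vd[role] = PrimerSiteSummary(**pd_)
            rows.append((row["species"], row["template_id"], SpecificityVerdict(**vd)))
        confusion = None
        if "confusion" in d:
            c = d["confusion"]
            confusion = (
                c["true_positive"],
                c["false_positive"],
                c["true_negative"],
                c["false_negative"],
            )
        return cls(rows=tuple(rows), summary=dict(d["summary"]), confusion=confusion)


def evaluate_panel(
    fwd: Primer,
    rev: Primer,
    templates: Sequence[SequenceRecord],
    params: SpecificityParams = SpecificityParams(),
    expected: Optional[Mapping[str, bool]] = None,
    species_map: Optional[Mapping[str, str]] = None,
) -> PanelReport:
    """One verdict per template, in input order.

    Species labels come from ``species_map`` (template id → species) when
    given, otherwise from the first whitespace token of the FASTA description.
    ``expected`` maps species labels to the expected amplifiability; every
    species it names must occur in the panel, and the confusion matrix covers
    the templates whose species it names.
    """
    if not templates:
        raise ValueError("panel requires at least one template")

    rows: list[tuple[str, str, SpecificityVerdict]] = []
    for t in templates:
        label = species_map.get(t.id) if species_map else None
        verdict = classify_template(fwd, rev, t, params, species_label=label)
        rows.append((verdict.species_label, t.id, verdict))

    if expected is not None:
        panel_species = {s for s, _, _ in rows}
        unknown = sorted(set(expected) - panel_species)
        if unknown:
            raise ConfigError(f"expected-label table names species not in the panel: {unknown}")

    n_pos = sum(1 for _, _, v in rows if v.amplifiable)
    summary = {"amplifiable": n_pos, "non_amplifiable": len(rows) - n_pos}

    confusion = None
    if expected is not None:
        tp = fp = tn = fn = 0
        for species, _, v in rows:
            if species not in expected:
                continue
            want = expected[species]
            if v.amplifiable and want:
                tp += 1
            elif v.amplifiable and not want:
                fp += 1
            elif not v.amplifiable and not want:
                tn += 1
            else:
                fn += 1
        confusion = (tp, fp, tn, fn)

    return PanelReport(rows=tuple(rows), summary=summary, confusion=confusion)


def write_report(report: PanelReport, path: str | Path, format: str = "tsv") -> None:
    """Serialise a report to TSV (fixed column order) or JSON (full schema)."""
    path = Path(path)
    if format == "tsv":
        df = report.to_dataframe()
        df.to_csv(path, sep="\t", index=False)
    elif format == "json":
        path.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r} (expected 'tsv' or 'json')")


def read_report_json(path: str | Path) -> PanelReport:
    """Inverse of ``write_report(..., format='json')``."""
    return PanelReport.from_dict(json.loads(Path(path).read_text()))


def read_expected_tsv(path: str | Path) -> dict[str, bool]:
    """Expectations table: TSV with columns ``species`` and
    ``expected_amplifiable`` (true/false, yes/no, 1/0; header optional)."""
    truthy = {"true", "yes", "1", "t", "y"}
    falsy = {"false", "no", "0", "f", "n"}
    out: dict[str, bool] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ConfigError(f"{path}:{lineno}: expected 'species<TAB>expected_amplifiable'")
        if parts[0].lower() == "species":
            continue
        flag = parts[1].strip().lower()
        if flag in truthy:
            out[parts[0]] = True
        elif flag in falsy:
            out[parts[0]] = False
        else:
            raise ConfigError(f"{path}:{lineno}: unrecognised boolean {parts[1]!r}")
    return out
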