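"""Synthetic template generation: determinism, planted truth, recovery."""

import numpy as np
import pytest

from virtualpcr import classify_template, write_fasta
from virtualpcr.seqio import Primer
from virtualpcr.synthetic import (
    MismatchSpec,
    expected_amplifiable_from_specs,
    make_congener_panel,
    plant_amplicon,
    random_template,
    write_truth_tsv,
)


class TestRandomTemplate:
    def test_same_seed_is_identical(self):
        a = random_template(100, 0.5, seed=1)
        b = random_template(100, 0.5, seed=1)
        assert a.residues == b.residues

    def test_zero_gc_uses_only_at(self):
        t = random_template(10000, gc_fraction=0.0, seed=3)
        assert set(t.residues) <= {"A", "T"}

    def test_empirical_gc_tracks_requested_fraction(self):
        t = random_template(100_000, gc_fraction=0.4, seed=4)
        gc = sum(1 for b in t.residues if b in "GC") / len(t)
        assert abs(gc - 0.4) < 0.01

    @pytest.mark.parametrize("kwargs", [{"length": 0}, {"length": 10, "gc_fraction": 1.5}])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            random_template(**{"gc_fraction": 0.5, **kwargs})


class TestIndependentTruthPredicate:
    @pytest.mark.parametrize(
        "specs,expected",
        [
            ([], True),
            ([MismatchSpec("reverse", (1, 3))], False),  # 2 in the 3'-terminal window
            ([MismatchSpec("forward", (7, 10, 14, 18))], False),  # >3 total
            ([MismatchSpec("forward", (1, 8, 12))], True),  # 1 terminal, 3 total
            ([MismatchSpec("forward", (1,)), MismatchSpec("reverse", (2, 9))], True),
            ([MismatchSpec("forward", (6, 7)), MismatchSpec("forward", (8, 9))], False),
        ],
    )
    def test_rule_restatement(self, specs, expected):
        assert expected_amplifiable_from_specs(specs) is expected

    def test_totals_are_per_primer_not_summed(self):
        """Three mismatches on each primer (six in total) still amplify: the
        total-mismatch clause applies to each primer separately."""
        specs = [
            MismatchSpec("forward", (6, 9, 12)),
            MismatchSpec("reverse", (7, 10, 13)),
        ]
        assert expected_amplifiable_from_specs(specs) is True


class TestPlantAmplicon:
    def test_perfect_plant_verdict_and_length(self, fwd_primer, rev_primer):
        bg = random_template(800, seed=21, id="t")
        template, truth = plant_amplicon(bg, fwd_primer, rev_primer, 37, 526)
        assert truth.expected_amplifiable is True
        v = classify_template(fwd_primer, rev_primer, template)
        assert v.amplifiable and v.primary_product_length == 526

    def test_planted_mismatch_counts_are_unambiguous(self, fwd_primer, rev_primer):
        """Every planted position breaks IUPAC compatibility, so the search
        recovers exactly the planted 3'-indexed positions at the locus."""
        from virtualpcr.binding import MINUS, PLUS, find_binding_sites

        bg = random_template(800, seed=22, id="t")
        specs = [MismatchSpec("forward", (2, 11)), MismatchSpec("reverse", (1, 5, 9))]
        template, _ = plant_amplicon(bg, fwd_primer, rev_primer, 37, 526, specs, seed=5)
        fsite = [
            s for s in find_binding_sites(fwd_primer, template, 7)
            if (s.start, s.strand) == (37, PLUS)
        ]
        rsite = [
            s for s in find_binding_sites(rev_primer, template, 7)
            if (s.start, s.strand) == (37 + 526 - rev_primer.length, MINUS)
        ]
        assert fsite[0].mismatch_positions == (2, 11)
        assert rsite[0].mismatch_positions == (1, 5, 9)

    @pytest.mark.parametrize(
        "kwargs,match",
        [
            ({"fwd_start": 0, "product_length": 20}, "footprint"),
            ({"fwd_start": 750, "product_length": 100}, "outside"),
            (
                {"fwd_start": 0, "product_length": 526,
                 "specs": [MismatchSpec("forward", (25,))]},
                "beyond",
            ),
        ],
    )
    def test_invalid_plants_rejected(self, fwd_primer, rev_primer, kwargs, match):
        bg = random_template(800, seed=23, id="t")
        with pytest.raises(ValueError, match=match):
            plant_amplicon(bg, fwd_primer, rev_primer, **kwargs)

    def test_mismatch_against_all_matching_code_rejected(self, rev_primer):
        degenerate = Primer("deg", "NNNNNNNNNN")
        bg = random_template(800, seed=24, id="t")
        with pytest.raises(ValueError, match="every base"):
            plant_amplicon(bg, degenerate, rev_primer, 0, 200, [MismatchSpec("forward", (1,))])


class TestCongenerPanel:
    def test_same_seed_gives_byte_identical_fasta(self, fwd_primer, rev_primer, tmp_path):
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        for p in (p1, p2):
            templates, _ = make_congener_panel(fwd_primer, rev_primer, n_decoys=5, seed=31)
            write_fasta(templates, p)
        assert p1.read_bytes() == p2.read_bytes()

    def test_zero_decoys_is_single_target(self, fwd_primer, rev_primer):
        templates, truths = make_congener_panel(fwd_primer, rev_primer, n_decoys=0, seed=1)
        assert len(templates) == len(truths) == 1
        assert truths[0].expected_amplifiable is True

    def test_config_length_must_match_decoy_count(self, fwd_primer, rev_primer):
        with pytest.raises(ValueError, match="n_decoys"):
            make_congener_panel(
                fwd_primer, rev_primer, n_decoys=2,
                config=[[MismatchSpec("forward", (1, 2))]], seed=1,
            )

    def test_mutant_mode_decoys_differ_only_at_footprints(self, fwd_primer, rev_primer):
        templates, truths = make_congener_panel(
            fwd_primer, rev_primer, n_decoys=2, seed=33, mode="mutant"
        )
        target, decoy = templates[0], templates[1]
        start = truths[0].fwd_start
        end = start + truths[0].product_length
        flen, rlen = fwd_primer.length, rev_primer.length
        diffs = {i for i, (a, b) in enumerate(zip(target.residues, decoy.residues)) if a != b}
        footprints = set(range(start, start + flen)) | set(range(end - rlen, end))
        assert diffs and diffs <= footprints

    def test_truth_tsv_round_trips_expected_columns(self, fwd_primer, rev_primer, tmp_path):
        import pandas as pd

        _, truths = make_congener_panel(fwd_primer, rev_primer, n_decoys=3, seed=34)
        out = tmp_path / "truth.tsv"
        write_truth_tsv(truths, out)
        df = pd.read_csv(out, sep="\t")
        assert list(df["template_id"]) == [t.template_id for t in truths]
        assert list(df["expected_amplifiable"]) == [t.expected_amplifiable for t in truths]
        assert (df["product_length"] == 526).all()

    def test_pipeline_recovers_planted_truth(self, fwd_primer, rev_primer):
        """Across seeded panels with mixed amplifiable/non-amplifiable decoy
        configurations, verdicts match the independent truth predicate and
        recovered product lengths match the plants."""
        rng = np.random.default_rng(55)
        for _ in range(8):
            config = []
            for _ in range(4):
                role = "forward" if rng.integers(2) else "reverse"
                k = int(rng.integers(1, 5))
                positions = tuple(
                    sorted(int(p) for p in rng.choice(np.arange(1, 19), size=k, replace=False))
                )
                config.append([MismatchSpec(role, positions)])
            templates, truths = make_congener_panel(
                fwd_primer, rev_primer, n_decoys=4, config=config,
                seed=int(rng.integers(2**31)),
            )
            for template, truth in zip(templates, truths):
                v = classify_template(fwd_primer, rev_primer, template)
                assert v.amplifiable == truth.expected_amplifiable, truth
                if truth.expected_amplifiable:
                    assert v.primary_product_length == truth.product_length
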