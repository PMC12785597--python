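# virtualpcr

In-silico PCR specificity screening for species-authentication assays.

Food-authentication PCR assays hinge on a single question: given a primer
pair designed against one species' barcode locus (here the mitochondrial
cytochrome C oxidase subunit I, *COI*), which candidate templates — the
target species, common adulterant species, close congeners — would actually
yield a product?  `virtualpcr` answers it computationally:

1. **Binding-site search** — every ungapped alignment of each primer on each
   template, both strands, under IUPAC set-intersection matching (two codes
   match iff their base sets intersect), up to a configurable mismatch
   budget.  Mismatch positions are indexed from the primer's 3′ end, because
   that is the end the polymerase extends.
2. **Amplicon prediction** — converging forward/reverse site pairs on
   opposite strands, with product length spanning both primer footprints
   inclusively (for a plus-strand forward site *f* and minus-strand reverse
   site *r*: `len = r.end − f.start`).
3. **Amplifiability criterion** — a template is called non-amplifiable if,
   for either primer, **≥ 2 mismatches fall within the 3′-terminal 5 bases**
   or **> 3 mismatches occur across the whole primer**; otherwise, if a
   valid amplicon exists within the length bounds, it is called amplifiable.
4. **Panel reports** — per-species verdicts with reason codes, summary
   counts and, when an expected-label table is given, a confusion matrix.

The built-in example assay is a sika-deer (*Cervus nippon*) *COI* primer
pair — forward `5′-ACACCCTAATCAACTGGC-3′`, reverse
`5′-AAGAAAGAAGGAGGGAGG-3′` — with an expected 526 bp product on the target.
A synthetic-data module generates templates and whole panels with planted
binding sites, controlled mismatch placement and independently scored
ground truth, so the entire pipeline is testable offline.

## Worked example

Generate a synthetic 10-template panel (one perfect-match target plus nine
congener-like decoys carrying mismatches concentrated at the primers'
3′ ends), then scan it:

```bash
$ virtualpcr synth --out panel --seed 7
wrote 10 templates (1 target + 9 decoys, seed 7) to panel/panel.fasta with truth table panel/truth.tsv

$ virtualpcr scan --primers primers.fasta --templates panel/panel.fasta --out results
criterion: window=5 terminal_threshold=2 total_threshold=3 | search budget 7 mm, product 50-2000 bp
primers: COI-F 5'-ACACCCTAATCAACTGGC-3' / COI-R 5'-AAGAAAGAAGGAGGGAGG-3'
templates: 10 from panel/panel.fasta
  target           synthetic_target     AMPLIFIABLE (526 bp)
  decoy_1          synthetic_decoy_1    no amplification [TERMINAL_MM_FWD;TOTAL_MM_FWD;TERMINAL_MM_REV;TOTAL_MM_REV]
  decoy_2          synthetic_decoy_2    no amplification [TERMINAL_MM_FWD;TERMINAL_MM_REV;TOTAL_MM_REV]
  ...
summary: 1 amplifiable, 9 non-amplifiable
report written to results/report.tsv
```

Reading the output: the target template carries perfectly complementary
binding sites 526 bp apart, so a single primary amplicon of 526 bp is
predicted — the assay's diagnostic band.  Each decoy fails the criterion;
the reason codes name every blocking condition per primer
(`TERMINAL_MM_*` = two or more mismatches in that primer's 3′-terminal
five bases, `TOTAL_MM_*` = more than three mismatches overall,
`NO_*_SITE` = no binding site within the search budget).  The report TSV
carries the per-primer terminal and total mismatch counts behind each call.

The same workflow runs on real sequences: put the templates
(e.g. mitochondrial genomes fetched from GenBank) in a FASTA, one record
per candidate species, and pass an optional expectations TSV
(`species<TAB>expected_amplifiable`) to get a confusion matrix.

Library use mirrors the CLI:

```python
from virtualpcr import COI_FORWARD_PRIMER, COI_REVERSE_PRIMER, classify_template, read_fasta

template = read_fasta("cervus_nippon_mito.fasta")[0]
verdict = classify_template(COI_FORWARD_PRIMER, COI_REVERSE_PRIMER, template)
print(verdict.amplifiable, verdict.primary_product_length)
```

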