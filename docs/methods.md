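# Methods

## The virtual-PCR model

`virtualpcr` predicts PCR outcomes from sequence alone, for one primer pair
against a panel of candidate templates.  The model has three stages.

**Approximate binding.**  A binding site is an ungapped alignment of the
primer against a template window, on either strand, scored by counting
positions whose IUPAC base sets do not intersect.  Set-intersection
semantics means a template `N` (or any ambiguity code overlapping the
primer base) never counts as a mismatch; sites overlapping ambiguity codes
are flagged (`has_ambiguity`) so reports can mark calls that rest on
uncertain template bases.  Indels between primer and template are not
modelled: primer-template heteroduplexes with bulges are rare at typical
annealing stringency, and the amplifiability rule below counts
substitutions only.  The search is exhaustive over all offsets and both
strands up to a mismatch budget (`max_mismatches`, default 7), implemented
with 4-bit base-set masks and a windowed AND so it is vectorised yet
exactly equivalent to the per-offset character scan (property-tested
against an independently coded brute-force oracle).

Mismatch positions are recorded from the primer's 3′ end (terminal base =
position 1).  This is the chemically meaningful coordinate: mismatches at
or near the extension end block the polymerase far more effectively than
internal ones, which mostly lower duplex stability.

**Amplicon prediction.**  Two sites form a candidate product when they lie
on opposite strands with their 3′ ends pointing toward each other and
non-overlapping footprints.  Product length spans both primer footprints
inclusively — the standard convention under which the example assay's
526 bp *COI* product is reproduced from genomic coordinates.  Both
primer-role/strand assignments are tried, so templates deposited in either
orientation are handled; duplicate spans are deduplicated and the shortest
passing product is designated primary (shorter products dominate PCR).
Accepted lengths default to 50–2000 bp: wide enough for any realistic
assay around the 526 bp target, tight enough that two chance sites tens of
kilobases apart are not called a product.

**Amplifiability criterion.**  A template is called unlikely to amplify
when, for either primer's best binding site, two or more mismatches fall
within the 3′-terminal five bases, or more than three mismatches occur
across the whole primer.  The defaults (`window=5`,
`terminal_threshold=2`, `total_threshold=3`) encode that rule; they are
parameters, not constants, so sensitivity to the rule can be explored.
The total-mismatch clause is applied per primer, not summed over the pair:
the rule's subject is "either primer", and a joint-sum reading would let
one badly mismatched primer be rescued by a perfect partner.  An
"amplifiable" verdict additionally requires at least one orientation-valid
product within the length bounds.  The criterion is deterministic — there
is no randomness anywhere in the classification path.

### Site selection and reporting

Two design choices here were genuinely open:

*Which site represents a primer on a template?*  The reported best site is
the one closest to amplification competence: sites are ranked first by
their excess over the criterion thresholds (mismatches beyond
`terminal_threshold − 1` inside the window, plus mismatches beyond
`total_threshold` overall), then by fewest 3′-window mismatches, fewest
total mismatches, leftmost start, plus strand first.  Ranking by raw
3′-window count alone would let a chance match with seven scattered
mismatches but a clean 3′ end outrank a congener's orthologous locus
carrying the diagnostic two terminal mismatches — precisely the locus a
bench scientist would inspect.  Because self-similar primers can bind one
locus in several shifted registers that tie on this ranking, the reason
codes for a failing primer are unioned over all tied minimal-excess sites;
pass/fail itself depends only on the best site.

*Which sites may pair into products?*  Only criterion-passing sites: a
site that itself cannot prime cannot found a product.  Without this
filter, high-mismatch chance sites inside the generous search budget pair
into spurious short "primary" products on random backgrounds.  Among
passing sites, overlapping same-strand registers of one primer are
collapsed to the register(s) not overlapped by a strictly-fewer-mismatch
register, since overlapping registers compete for one physical locus and
the better-matched register wins the annealing competition.

The mismatch budget of 7 deliberately exceeds anything that can change a
verdict (any site with more than 3 total mismatches already fails): the
margin exists purely so reports can show *how* mismatched a congener locus
is rather than reporting "no site".

### Relationship to alignment-based workflows

Manual workflows often build a multiple sequence alignment of the target
and related species and read primer mismatches off the alignment columns.
Direct per-template approximate matching gives the same per-primer
mismatch counts whenever the orthologous locus aligns to the primer
without indels (the case for conserved barcode loci within a genus), while
requiring no alignment step and treating each template independently.
Gapped orthologs would need an aligner and are out of scope.

## Synthetic data

The generator builds templates whose truth is known by construction:

- **Backgrounds** are i.i.d. random nucleotides, default 1,200 bp at GC
  0.45 — roughly the base composition of cervid mitochondrial DNA and long
  enough to hold the 526 bp product at a random offset.
- **Planting** overwrites the forward primer's footprint at a chosen
  start and the reverse primer's reverse complement so the product is
  exactly the requested length (default 526 bp).  Requested mismatches are
  then mutated in at chosen 3′-indexed primer positions, always to a base
  whose IUPAC set is disjoint from the primer code (never to an ambiguity
  code), so planted mismatch counts are exact.
- **Default congener panels** pair one perfect target with decoys carrying
  two mismatches inside each primer's 3′-terminal five bases plus one or
  two further out — multiple mismatches concentrated at the extension
  ends, the pattern that distinguishes congeners at an otherwise conserved
  locus.  Decoys are built on independent backgrounds by default; a
  `mutant` mode instead copies the target and mutates only the footprints,
  emulating congeners that differ from the target solely at the binding
  sites.
- **Expected verdicts** are scored by a free-standing restatement of the
  amplifiability rule that shares no code with the classification path —
  the anti-circular oracle all recovery tests compare against.

Everything is seeded; identical arguments give byte-identical panels.

What the generator does *not* emulate: real mitochondrial genome
structure, phylogenetic correlation among decoys, sequencing error,
indels, and heteroplasmy.  Passing the recovery tests therefore
demonstrates that the search, pairing and criterion are implemented
exactly — not that the criterion itself predicts wet-lab outcomes for
real congeners, which depends on the biology the thresholds summarise.

One interaction is worth knowing about: the example assay's reverse primer
is internally repetitive, so a shifted-by-4 register over its own planted
footprint differs from the planted register by only a few bases.  When
planted mismatches leave a template amplifiable but make the shifted
register the better match, the register competition moves the primary
product by one repeat unit (522 vs 526 bp).  The generator's truth does
not model this, so planted-truth recovery over unrestricted random
mismatch configurations sits at ≈99.5–100% rather than exactly 100%; the
verdicts themselves are unaffected.

## Numerical and edge-case behaviour

- Coordinates are 0-based half-open on the template plus strand for all
  site and product arithmetic, whatever the strand of the match.
- Templates shorter than the primer yield an empty site list, not an
  error; an empty panel is an error.
- Length bounds are a closed interval; `min_len = max_len = L` accepts
  exactly length-`L` products.
- Ties in site ranking break deterministically (start, then plus strand),
  and panel evaluation preserves input order, so identical inputs always
  produce identical reports.
- Gap characters in input sequences are rejected rather than stripped —
  the pipeline consumes unaligned sequences, and silently degapping an
  alignment would corrupt coordinates.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` exercise: the full
39-configuration criterion truth table; 1,000 random primer/template pairs
(primers 10–25 nt, templates up to 2 kb, budgets 0–7) against the
brute-force oracle; 50 seeded panels with 0–6 decoys of random mismatch
configuration for truth recovery; and the default 10-template panel for
the confusion matrix and the 526 bp product reconstruction.  These sizes
make the whole suite run in seconds while covering every code path at
full fidelity.
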