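# Methods

## The census model

`topomotif` implements a topology-aware census of short linear motifs
(SLiMs) in the cytoplasmic C-terminal regions of membrane proteins. The
motivating biology is endosomal recycling: short cytoplasmic sequences —
the bileucine LxxL core, the Retromer consensus [F/Y/W]x[L/M/V], the
Retriever-recognized NxxY, Φx[F/Y/V]x[F/Y], and the C-terminal
PDZ-binding [D/E][S/T]xΦ — route endocytosed membrane proteins back to
the cell surface. A sequence match is only biologically plausible if the
motif faces the cytoplasm, sits near the C terminus where the recycling
machinery engages its cargo, and (for Retromer-type engagement) lies far
enough from the membrane for the complex to reach it. The census encodes
those constraints explicitly:

1. **Cytoplasmic tail filter.** A protein enters the census only if its
   final residue lies inside a topological domain (UniProt TOPO_DOM)
   whose note begins, case-insensitively, with "Cytoplasmic". Prefix
   matching tolerates qualifier text such as "Cytoplasmic; in dimer".
   Tails covered by "Extracellular", another note ("Lumenal", …), or no
   TOPO_DOM at all are classified and counted, but excluded.
2. **C-terminal window.** Patterns are scanned in the last `window_len`
   residues (default 100; the whole sequence if shorter). A match counts
   only if it lies *entirely* inside the window — a motif half outside
   the region is not "in" it. The PDZ pattern is instead anchored: it
   must end at the final residue, which makes it independent of the
   window size (an explicitly tested equivalence).
3. **Topology of the match.** Every occurrence is annotated with the
   TOPO_DOM that fully contains it. With
   `require_cytoplasmic_match` (default on), matches in extracellular
   loops, or straddling a transmembrane boundary, are marked failing
   with the reason `not cytoplasmic`. Matches in cytoplasmic *loops* of
   multi-pass proteins pass: the filter excludes non-cytoplasmic
   context, it does not restrict to the final domain.
4. **Membrane distance.** For each match the scanner reports the number
   of residues strictly between the motif and the nearest flanking
   TRANSMEM/INTRAMEM boundary, minimized over both flanks (relevant in
   cytoplasmic loops). The convention is a strict gap: a motif starting
   immediately after a membrane segment has distance 0, as does one
   overlapping a segment. A protein with no membrane segment has
   *undefined* distance — such matches pass any distance floor but carry
   an explicit flag, because silently dropping peripheral or
   lipid-anchored proteins would hide data. Where the off-by-one of
   "at least 15 residues from the membrane" is concerned, this
   strict-gap-to-the-nearest-motif-residue reading is a package
   convention, fixed here and pinned by boundary tests at 14 vs 15.
5. **Deduplication.** Summary counts are per unique protein per
   pattern; the per-protein table keeps each protein's most C-terminal
   passing match. All matches — passing and failing, with reasons — are
   retained in the match table for audit.

### Hard filters vs. the distance sub-parse

The bileucine literature applies the ≥15-residue Retromer-engagement
floor as a *sub-parse* of an already-computed motif list, not as part of
the census itself. The configuration mirrors that: a pattern's own
`min_membrane_distance` (15 for LxxL in the packaged pattern file) does
not remove matches; it produces the separate
`n_unique_proteins_distance_filtered` tally and drives
`apply_membrane_filter`. Only the census-wide
`SearchConfig.min_membrane_distance` acts as a hard filter that flips
`passes_filters`. This keeps the two headline numbers of a bileucine
census — proteins with a cytoplasmic LxxL, and the subset clearing the
distance floor — both visible in one run.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| `window_len` | 100 | residues | the C-terminal region where recycling machinery engages cargo |
| `require_cytoplasmic_match` | on | – | a recycling motif must face the cytoplasm |
| per-pattern `min_membrane_distance` | 15 (LxxL only) | residues | reported minimum reach for Retromer engagement |
| `SearchConfig.min_membrane_distance` | none | residues | optional census-wide hard floor |
| PDZ anchoring | on (PDZ pattern) | – | the motif must terminate the protein |

Coordinates are 1-based inclusive everywhere (UniProt convention), so a
match prints as `500-LEYL` exactly as positions are reported in the
field.

## Pattern grammar

`@` matches any residue (including nonstandard letters such as X or U);
a literal or bracket class matches only its listed standard residues, so
an ambiguous residue never satisfies a specific class. There is no
repetition, alternation or negation — the five shipped consensi need
none, and a smaller grammar is easier to hold to the oracle-equivalence
standard below. Overlapping occurrences are all reported; since final
counts are per protein, overlap handling cannot change the census, but
match-level output is complete.

## Synthetic proteome generator

`topomotif.synth` generates records that emulate the *annotation
structure* the census consumes: alternating Cytoplasmic/Extracellular
TOPO_DOMs separated by 21-residue TRANSMEM segments, single- and
multi-pass architectures, cytoplasmic or extracellular C termini,
membrane-less proteins, and motifs planted at exact distances from the
membrane boundary. Background residues are i.i.d. draws with leucine
and the aromatic/PDZ-class residues (L, F, Y, W, M, V, N) down-weighted
to 0.3 relative frequency — accidental motif hits stay rare but nonzero,
and library ground truth is therefore *recomputed* by an independent
naive scanner rather than assumed accident-free.

What the generator does **not** emulate: realistic amino-acid
composition or correlation structure, signal peptides, isoform
annotation, UniProt note vocabulary beyond
Cytoplasmic/Extracellular/Helical, or the size distribution of real
membrane-protein families. Passing tests therefore certify the
*filtering logic and coordinate arithmetic* of the census on annotated
input, not performance on any particular UniProt release — the paper
peptides embedded at their native coordinates (GLUT4 `TELEYLGP` at 498,
DMT1-II `QPELYLL` at 551, MOR `QLENLE` at 406, and the three screen
hits) sit in synthetic GAS-repeat scaffolds whose filler contains none
of the motif-critical residues, so those fixtures certify coordinates,
not native sequence context.

Problem sizes used by the shipped suites: the oracle-equivalence
acceptance check runs 50 libraries of 40 proteins (seeds 100–149);
property tests use libraries of 20–80 proteins. These sizes give full
coverage of the archetype mix while keeping the default test run fast.

## Trafficking metrics

The metric functions are the standard assay arithmetic:
internalization = (1 − GM_int/GM_total)·100; recycling =
(GM_rec − GM_int)/(GM_total − GM_int)·100; percent remaining =
treated/untreated·100; cAMP inhibition = (1 − L_iso+op/L_iso)·100;
neuron internalization and recycling as differences of per-cell
surface/total ratios (post-agonist − baseline, post-antagonist −
post-agonist; the pre-antagonist timepoint *is* the post-agonist one);
surface expression as a fold over a non-expressing or uninduced
control. Degenerate denominators (no measurable internalization,
non-positive control) raise `AssayPreconditionError` — the assay, not
the arithmetic, failed. Out-of-range values (negative internalization,
recycling > 100 %) are returned with an `out_of_range` flag, never
clamped. A helper computes geometric means from per-event vectors,
dropping non-positive events with a reported count.

## Numerical and design choices

- Deterministic everywhere: matches sort by (accession, pattern, start);
  the generator uses a seeded `numpy` Generator with per-record child
  seeds drawn below 2³¹; two runs with the same inputs/seed produce
  byte-identical output files.
- Overlapping same-kind features are an ingest error (loud corruption);
  different-kind overlaps produce a warning only, since rare real
  entries contain them.
- Three match routes exist: the element-wise scanner (the
  implementation), a regex translation used when recomputing library
  ground truth, and a loop-based oracle inside the test suite that
  shares no code with either. Equivalence of all three is
  property-tested over random grammar-valid patterns and sequences.
- Live UniProt retrieval (`uniprot_live.py`) emits the same TSV dialect
  the readers consume but is never touched by tests; the counts such a
  download yields are release-dependent, so provenance (retrieval date,
  query) should be recorded with any live run.

## Known limitations

- Topology is taken from annotation; no prediction is attempted for
  unannotated proteins, and matches in annotation gaps are flagged
  rather than guessed.
- The membrane-distance convention is one literal reading of "residues
  away from the membrane"; alternative off-by-one conventions would
  shift individual distances by ±1 and the threshold boundary with them.
- The metrics module takes summary statistics (geometric means,
  normalized luminescence) as inputs; FCS parsing, gating and curve
  fitting are out of scope.
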