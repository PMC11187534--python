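# Methods

## Accounting model

The unit of account is the MS2 acquisition event. The denominator of every
rate is the number of well-formed `BEGIN IONS`/`END IONS` blocks in the
deposited peak lists — acquisition events, not usable spectra, so a block
with zero peak lines still counts. The numerator is the number of distinct
spectra with at least one rank-1 identification passing the engine's
threshold (`passThreshold` in mzIdentML; membership in `msms.txt` /
the `MS/MS Identified` tally for MaxQuant). Restricting to rank 1 prevents
co-ranked items from double-counting a spectrum.

Rates aggregate two ways and the report carries both:

- **pooled** (headline): 100 · Σ assigned / Σ submitted — spectrum-weighted,
  so large runs dominate, matching how corpus totals are quoted;
- **mean**: the unweighted mean of per-run (or per-dataset) rates.

Which convention underlies a given repository-wide "average" rate is often
unstated, which is exactly why both are printed.

Rounding is 2 decimals, half away from zero, applied only at the reporting
layer; all internal arithmetic is unrounded.

### Denominator conventions

Real deposits are ambiguous about whether published per-dataset denominators
come from MGF block counts or from MaxQuant's own `MS/MS` column. Both are
implemented behind the `denominator` config switch (`mgf`, the default, or
`maxquant`); the convention actually applied is recorded in the report's
provenance block. On the synthetic corpora the two agree by construction.

### Target-decoy competition

Concatenated-search TDC over rank-1 PSMs. PSMs are sorted by descending
score (ties: decoys before targets, then run and spectrum key — the
within-tie order is cosmetic because FDR estimates are computed per score
value, so tied PSMs always share a q-value). At each score *s* the estimate
is FDR̂(s) = D(s)/max(T(s), 1) over PSMs at or above *s*; q-values are the
running minimum from the permissive end upward, clipped to [0, 1]. The
conservative (D+1)/max(T, 1) estimator is available (`plus_one=True`,
default off). Engines' scores are normalised higher-is-better on input;
expectation values become their negated natural logs. Mixing incomparable
score types in one competition is the caller's responsibility; the pipeline
pools PSMs only within a dataset, which is also one search.

Threshold convention for counting assigned spectra in mzIdentML is
passThreshold-only (no additional score cut); the convention is stamped into
report provenance.

### Peptides, protein groups, contaminants

Distinct peptides are counted among target, pass-threshold PSMs with
bracketed modification tags stripped by default (`PEPT[+15.99]IDE` and
`PEPTIDE` are one peptide). Protein groups: map each accession to its set of
stripped peptides, merge accessions with identical sets, remove groups whose
set is a strict subset of another's, count the remainder — deterministic and
permutation-invariant, with no razor-peptide or probabilistic inference
(deliberately out of scope). A spectrum is contaminant only if *every*
accession of its rank-1 passing match is a contaminant by rule (prefix list,
default `CON__`, plus an explicit accession list) or engine flag; shared
peptides therefore stay non-contaminant, a conservative choice. Contaminant
spectra remain inside the assigned count — the identification rate is about
assignment, not sample origin — and the contaminant tally is a separate
field, never a replacement rate.

## Synthetic corpus generator

The generator emulates the statistical shape of deposited ancient-sample
corpora at desk scale: Orbitrap-style DDA acquisitions (precursor m/z
300–1600, charge 2–4, 5–12 random peaks per spectrum), a small configured
fraction of spectra carrying passing identifications, decoy matches drawn
from a lower-scoring Gaussian, and a configured contaminant fraction among
assignments. Defaults: 15 datasets × 1 run × 1000 spectra, identification
rate 5.88% (floor → 58 assigned per run), contaminant fraction 10%, one
decoy match per assigned spectrum, target scores ~ N(60, 8²) vs decoy
~ N(20, 8²) (a 5σ separation, so essentially all planted targets survive
q ≤ 0.01), peptides of 7–20 residues over the 20 canonical amino acids.

Design choices that make testing sharp:

- assigned counts are planted as exact integers (`floor(n · rate)`), so rate
  recovery is exact and only FDR-derived quantities are stochastic;
- every generated peptide is globally unique and belongs to exactly one
  accession (proteins take blocks of 5 pool peptides; contaminant peptides
  map onto a fixed set of `CON__` accessions), so peptide sets are disjoint
  and the planted protein-group count is simply the number of accessions
  observed — no merging or subsumption can fire, which keeps the ground
  truth closed-form;
- decoy matches carry `passThreshold="false"` (mzIdentML) / `Reverse="+"`
  (msms.txt), so they never perturb the assigned-spectrum count but fully
  exercise the TDC machinery;
- a fixed seed yields byte-identical files and manifest (all paths in the
  manifest are relative).

The generated mzIdentML is the minimal valid subset the reader consumes:
`SequenceCollection` (DBSequence with `isDecoy`, Peptide, PeptideEvidence)
and one `SpectrumIdentificationResult` per matched spectrum with one rank-1
item, a Mascot-score cvParam and a spectrum-title cvParam.

What the generator does *not* emulate: fragment-ion physics (peaks are
random, not peptide-derived), retention-time structure, chimeric spectra,
modified peptides, shared peptides between proteins, or engine-specific
score distributions. Passing tests therefore demonstrate that the
*accounting* is correct on files with the deposited formats' structure, not
that any search engine's identifications are reproduced.

### The worked corpus

The corpus-level analysis is reproduced on a deterministic 1:1000-scale
corpus: 15 datasets totalling exactly 14,970 submitted and 880 assigned
spectra (pooled rate 5.88%, dark fraction 94.12%), per-dataset rates from
0.47% to 12.61%, 11 datasets MaxQuant-flavoured and 4 deposited as
mzIdentML. Only the totals, the rate extremes and the engine split are
meaningful; the individual dataset sizes in `WORKED_DATASETS` are fixed
arbitrary values consistent with those constraints, since per-dataset sizes
of the real corpora are not part of the emulation target.

## mzIdentML subset reader

The reader is built on `lxml.etree.iterparse` (two passes: reference tables,
then results), accepts mzIdentML 1.1/1.2 namespaces by local-name matching,
and is insensitive to element order within a result. Decoy precedence:
explicit `isDecoy` attributes win; otherwise configured accession prefixes
(`REV__`, `DECOY_`, `rev_`, `XXX_` by default); otherwise target. Items
without a resolvable peptide reference or accession are collected in a
per-file parse report (surfaced in report provenance), not fatal. The file's
searched-spectrum count is reported only when present; the subset does not
carry it, so it is null and the MGF count is authoritative.

## Numerical and degenerate-input conventions

- rate with 0 submitted spectra: an error, never NaN or 0;
- assigned > submitted: an inconsistency error at construction time;
- empty PSM list: empty q-value table, 0 PSMs at any FDR;
- all-target tables: every q-value is 0 (D = 0 throughout);
- deposited MaxQuant percentages are cross-checked against the counts and
  flagged (warning, tolerance 0.05 for deposited rounding), with the counts
  authoritative;
- report metrics that cannot be computed are nulls with reason codes
  (`no_psms_file`, `no_decoys_present`, `not_computed`).

## Problem sizes

The shipped analyses and tests run on desk-scale corpora: the worked corpus
holds 14,970 spectra across 15 datasets (~1–2 s to generate and account),
property suites use ≤ 12-PSM instances against a brute-force
threshold-enumeration oracle (200 seeded instances) and corpora of tens to
hundreds of spectra. Reproducing the full-scale corpus numbers would require
downloading all 15 public accessions (millions of spectra) and is explicitly
out of scope; the worked corpus preserves the corpus arithmetic at 1:1000
scale instead.

## Known limitations

- No mzML/raw peak-list input (MGF only), no pepXML/idXML/Percolator
  results, no mzIdentML writing beyond the generator's subset.
- Protein grouping ignores razor-peptide assignment and protein-level FDR.
- The contaminant rule is accession-based; it cannot recognise contaminant
  peptides assigned to non-contaminant database entries.
- Scores are compared within one dataset only; no cross-engine calibration.
- No assessment of whether assigned spectra are endogenous/ancient versus
  modern contamination — the rate deliberately counts assignments only.
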