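# Methods

## Model and guarantee

`progsearch` maintains tandem-MS database search results under database
updates. Its correctness contract is *exact equivalence*: for the same
spectra and parameters, the progressive update of a stored run against
`D_old` produces, for `D_new`, the same bytes a from-scratch search writes —
peptides, protein lists, Xcorr, deltaCn, E-values and per-scan histograms.
Equivalence is a structural property of the design, not a numerical
accident; the pieces that make it hold exactly are listed below.

### Protein identity and partitions

Databases are compared by exact amino-acid sequence, not accession: the
sequence alone determines candidate peptides and scores, so a renamed entry
with an unchanged sequence is "shared" and costs nothing to update.
Within-database duplicate sequences are collapsed into one searchable
protein carrying all accessions. The shared partition carries the *new*
database's accessions, so pruned protein lists match what a scratch search
of `D_new` reports. Sequence changes inside a protein are one deletion plus
one insertion; no isoform or fuzzy matching is attempted.

### Scoring core

A deterministic SEQUEST-lineage fast Xcorr:

- **Digestion.** Cleavage after K/R not followed by P; protein termini
  count as enzymatic termini. `ntt` (0/1/2) is the minimum number of
  enzymatic termini, `mc` the maximum internal missed cleavages. Length
  bounds 6–50 by default. Peptides are deduplicated by sequence with merged
  protein sets; the *occurrence* multiplicity of a peptide is the number of
  distinct protein sequences containing it.
- **Preprocessing.** Fragment bin `floor(mz / 1.0005079 + 0.4)`,
  square-root intensities with max-per-bin, ten equal m/z windows each
  normalized to 50, then background subtraction of the mean over ±75
  neighbouring bins.
- **Score.** 0.005 × the sum of the preprocessed intensities at the
  singly charged b- and y-ion bins (each ion contributes its bin's value;
  coinciding bins count once per ion), plus the doubly charged series for
  precursor charge ≥ 3. Precursor matching is on neutral mass within
  `precursor_tol` (Da or ppm); the spectrum's declared charge is trusted.

Two numerical decisions make scores well-defined *values* rather than
artifacts of evaluation order:

1. **Canonical quantization.** Every Xcorr is rounded (half-to-even) to
   `xcorr_out_decimals` (7) places immediately after scoring, and the
   quantized value is used for ranking, ties, deltaCn, histogram binning and
   E-values. A 7-decimal fixed-point value survives the text round-trip
   through the results file exactly, so a later progressive run computes
   with the very numbers the original run used. This realizes the intent of
   7-decimal Xcorr output (output-derived deltaCn equals internal deltaCn)
   and upgrades it to a guarantee.
2. **Batch-independent summation.** Fragment masses are accumulated
   per-peptide (row-wise cumulative sums) and ion contributions are reduced
   over a parameter-fixed width, so a peptide's score never depends on which
   database partition or batch it was scored in.

Ranking uses the canonical total order (Xcorr descending, peptide text
ascending); since stored peptides are unique per scan, no two stored PSMs
compare equal, and merge results are independent of database record order.

### Deletion

Stored PSMs are probed against the shared partition's peptide index: a
peptide found there gets the shared support as its new protein list; a
peptide found only in the deleted partition marks its scan for re-search; a
peptide found in neither is a hard consistency error (the results were not
produced from the stated old database). A scan is re-searched if *any*
stored PSM — not just rank 1 — loses all support: the stored top-(n+1) list
must remain exactly the top of the shared candidate set for the merge step
to be exact, and this is the simplest rule that guarantees it. Candidate
totals are maintained exactly by subtracting the deleted partition's
in-tolerance occurrence count (a count, not a scoring pass).

### Insertion and the merge

The inserted partition is searched for every spectrum (one pass whose score
multisets also feed the histograms). Per scan the shared and inserted
top-(n+1) lists are merged: same-peptide entries coalesce with unioned
protein sets (their scores are equal by determinism), and the top n+1 of
the merge is kept. Any peptide in the true top n+1 of `D_new` is in the top
n+1 of each partition containing it, so merging truncated lists is exact.

### deltaCn

`deltaCn(i) = 1 − Xcorr(i+1)/Xcorr(i)` for ranks 1..n, computed from the
canonical scores. The results file stores n+1 rows: the extra row exists so
`deltaCn(n)` is computable, and so the *next* progressive run has the full
stored list. Conventions applied identically on both paths: the helper row's
own deltaCn is left unset (its successor was never stored); a scan whose
last stored row has rank ≤ n (the candidate list was exhausted) gets 1.0
there; a rank with Xcorr ≤ 0 gets 0.0.

### Histograms and E-values

Per-scan histograms bin the per-occurrence candidate score multiset at
width 0.1 (`floor(xcorr / 0.1)`, negative bins allowed), stored sparsely.
Because multisets count (peptide, protein) occurrences, histograms are
additive over partitions and `His(new) = His(old) − His(del) + His(ins)`
holds bin-for-bin in exact integers; a negative intermediate bin is a hard
error flagging inconsistent inputs.

E-values: scans with fewer than `min_hist_entries` (3000) target entries
are padded with decoy peptides — random residue strings of length 7–20 from
a PRNG seeded by `(decoy_seed, scan_id)`. The decoys are deliberately a
function of the spectrum and parameters only, never of the database:
otherwise the sub-3000 padding would differ between the progressive and
scratch paths and the E-value equality could not hold. Histogram files store
target counts only; decoys are added transiently at fit time. The tail fit
is ordinary least squares of log10 survival counts against bin-center
score, over bins from one past the histogram mode through the last occupied
bin, extended left toward the mode if fewer than four points remain; fewer
than four survival bins overall or a positive slope yields a degenerate
flag. Then `E = 10^(intercept + slope·Xcorr)`, clamped to (0, total]; a
degenerate fit reports the total count (maximally conservative). Any
deterministic fit preserves the progressive/scratch equality; this one was
chosen for simplicity and testable closed-form recovery.

### Run manifests

Results and histogram files carry `#`-header manifests with parameter and
database content digests. A progressive run refuses mismatched inputs,
because the equivalence guarantee is conditional on identical parameters
and exactly the stored old database. Manifests contain no wall-clock
timestamp by default so that identical inputs yield byte-identical outputs.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `precursor_tol`, `precursor_tol_unit` | 3.0 Da | neutral-mass window for candidate selection |
| `fragment_bin_width`, `fragment_bin_offset` | 1.0005079, 0.4 | fragment binning |
| `ntt`, `mc` | 2, 2 | minimum enzymatic termini / max missed cleavages |
| `min_pep_len`, `max_pep_len` | 6, 50 | candidate length bounds (residues) |
| `num_output_lines` (n) | 5 | ranks reported; n+1 rows stored |
| `hist_bin_width` | 0.1 | Xcorr histogram bin width |
| `min_hist_entries` | 3000 | minimum null-distribution size before decoy padding |
| `xcorr_out_decimals`, `deltacn_out_decimals` | 7, 4 | output (= canonical) precisions |
| `decoy_seed` | 1 | decoy PRNG seed (part of the parameter digest) |

## Synthetic data

The generators emulate a monthly update of a tryptic protein database:

- `gen_database`: uniform-random sequences (default 60–180 residues) with
  K/R placed at per-residue probability 1/11, giving expected tryptic
  peptide length ≈ 11.
- `gen_update`: deletes/inserts a rounded fraction of proteins (defaults in
  the standard scenario: 2% + 2%, the upper end of typical monthly change).
- `gen_spectra`: charge-2 spectra containing the source peptide's complete
  singly charged b/y ladder (intensities 30–100) plus uniform noise peaks
  (default 10, intensities 1–15). Sources are drawn uniformly from the
  database's (peptide, protein) occurrence pool — the "identifications are
  random database picks" premise under which the deleted-spectra fraction
  tracks the deleted candidate-mass fraction.
- `standard_fixture` (500 proteins / 200 spectra / ntt=1 / mc=2) plants one
  instance of each update branch by construction: a peptide shared between
  a deleted and a surviving protein (pruning without re-search), a
  deleted-only scan (full re-search), a deleted peptide re-introduced by an
  inserted protein (replacement), and a peptide shared between a surviving
  and an inserted protein (equal-Xcorr protein append). Sub-3000 decoy
  padding occurs on every scan at these sizes.

What the generator does *not* model: realistic fragment intensity patterns,
isotope envelopes, chimeric spectra, charge errors, modifications, retention
time. Passing tests therefore demonstrate the *update algebra* — exact
equivalence, composability, complexity bounds — on spectra with idealized
signal; they do not certify identification accuracy on real data, where the
scoring core (deliberately minimal: no PTMs, no charge enumeration, no
isotope error handling) would be the limiting factor.

## Problem sizes used in the test suite

Unit and property tests run on a reduced scenario (120 proteins / 40
spectra); the equivalence acceptance suite runs ten seeds at the standard
500-protein / 200-spectrum scale and the composability suite chains three
2% updates at the same scale. These sizes exercise every code path
(including decoy padding and all planted branches) while keeping the whole
suite at a few minutes on one CPU.

## Known limitations

- Equivalence is guaranteed only for identical parameters between runs
  (enforced via manifests); parameter changes require a fresh search.
- The scoring engine is intentionally small: no modifications, no
  semi-supervised rescoring, no FDR estimation, MGF/FASTA only.
- The E-value model (log-linear survival tail) is a simple, deterministic
  choice; absolute E-value calibration is not a goal — only cross-path
  equality and monotonicity are relied on.
- I/L are distinct peptides; mass-equal peptides are distinct candidates.
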