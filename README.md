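# progsearch

Progressive tandem mass-spectrometry database search: keep peptide-spectrum
matches (PSMs), deltaCn scores and E-values up to date when the protein
database changes, at a cost proportional to the database *difference* — with
output identical, field for field, to a search of the new database from
scratch.

## Who this is for

Proteomics groups that re-search large spectrum collections every time their
protein database is updated (monthly releases typically change 0.5–2% of
entries). A from-scratch search costs O(|S|·|D|) for |S| spectra and |D|
candidate peptides; yet almost all of that work reproduces the previous
run. `progsearch` updates the previous run instead, in O(|S|·|ΔD|) time on
average, without changing a single output value.

## The method

Let `D_old`, `D_new` be the two databases and `R_old` the stored results.

1. **Database separation.** Compare the databases by exact sequence into
   shared (`D_srd`), deleted-only (`D_del`) and inserted-only (`D_ins`)
   partitions.
2. **Deletion.** Remove deleted proteins from stored PSM protein lists. A
   scan in which any stored PSM loses all protein support (set `S_del`) is
   re-searched against `D_srd` only; every other scan keeps its stored
   top-(n+1) list, which is provably still the top of the shared candidate
   set.
3. **Insertion.** Search `D_ins` for *all* spectra and merge the two ranked
   lists under a canonical total order (Xcorr descending, peptide text
   ascending); identical peptides coalesce with unioned protein lists.
4. **Score calculation.** Recompute `deltaCn(i) = 1 − Xcorr(i+1)/Xcorr(i)`
   (ranks are stored through n+1 so that `deltaCn(n)` is computable).
5. **E-value calculation.** Per-spectrum Xcorr histograms obey the exact
   per-bin identity `His(new) = His(old) − His(del) + His(ins)`, so E-values
   (a log-linear fit to the histogram survival function, padded to at least
   3000 entries with database-independent seeded decoys) are refit per scan
   without rescoring any candidate — O(|S|) regardless of the update size.

The scoring core is a deterministic SEQUEST-lineage fast cross-correlation
(Xcorr) engine: tryptic digestion with configurable enzymatic termini (ntt)
and missed cleavages (mc), sqrt/window-normalized spectrum preprocessing
with ±75-bin background subtraction, and b/y fragment-ion scoring. Every
Xcorr is quantized to its 7-decimal output precision and that value is
canonical — which is what makes the progressive and scratch paths *exactly*
equal rather than merely close (see `docs/methods.md`).

## Worked example

```sh
# a synthetic monthly update: 500 proteins, 2% deleted, 2% inserted, 200 scans
progsearch simulate --n-proteins 500 --n-spectra 200 --seed 3 --out fix

# search the old database once (also writes per-scan score histograms)
progsearch search fix/spectra.mgf fix/old.fasta --params fix/params.txt --out old

# progressive update to the new database
progsearch progressive fix/spectra.mgf fix/old.fasta fix/new.fasta \
    --old-results old.results.tsv --old-hist old.hist.tsv \
    --params fix/params.txt --out prog

# from-scratch baseline and field-exact comparison
progsearch search fix/spectra.mgf fix/new.fasta --params fix/params.txt --out new
progsearch compare prog.results.tsv new.results.tsv   # prints: identical
progsearch compare prog.hist.tsv new.hist.tsv         # prints: identical
```

The results table holds one row per (scan, rank):

```
scan  rank  peptide         xcorr      deltacn  evalue       proteins   candidates
1     1     MLCAAGGAAFPPPR  5.5644520  0.7648   2.19523e-01  SYN000012  480
1     2     MMRYMKELTR      1.3089596  0.1243   1.04883e+01  SYN000437  480
```

Xcorr is printed at 7 decimals so that a deltaCn recomputed from the file
equals the internally computed one: from the internal pair
(0.0324375, 0.0171654) the rank-1 deltaCn is 0.4708162 (printed 0.4708),
whereas 4-decimal-rounded Xcorr values (0.0324, 0.0172) would give 0.4691.
E-values are the expected number of candidates reaching a PSM's Xcorr by
chance under the fitted per-scan null; `candidates` is the scan's
per-occurrence candidate total (the histogram mass).

Every results/histogram file carries a `#`-header manifest (parameter and
database digests); `progressive` refuses inputs whose manifest does not
match, because the equivalence guarantee holds only for identical
parameters and the exact old database.

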