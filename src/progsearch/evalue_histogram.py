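"""Per-spectrum Xcorr histograms and tail-fit E-values.

The per-scan histogram of candidate Xcorr values is the null model for the
E-value.  Because the score multiset is additive over database partitions
(one entry per peptide-protein occurrence), the histogram of the new
database is an exact per-bin identity::

    His(new) = His(old) - His(deleted) + His(inserted)

so a progressive run never has to rescore the shared partition to update
E-values.  Spectra with fewer than ``min_hist_entries`` candidate scores are
padded with seeded decoy peptides; the decoys are a function of the spectrum
and the parameters only — never of the database — so the padded histogram,
the tail fit, and every E-value are identical between the progressive and
the from-scratch path.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Union

import numpy as np

from .errors import ConsistencyError
from .model import ResultSet, SearchParams, Spectrum, SpectrumSet, XcorrHistogram
from .search_engine import (
    CandidateIndex,
    Counters,
    ScoreMultiset,
    preprocess,
    score_encoded,
)

DECOY_MIN_LEN = 7
DECOY_MAX_LEN = 20
_MIN_FIT_POINTS = 4


def score_bin(x, hist_bin_width: float):
    """Histogram bin index: floor(xcorr / bin width); may be negative."""
    return np.floor(np.asarray(x) / hist_bin_width).astype(np.int64)


def build_histogram(
    scores: Union[ScoreMultiset, Iterable[float]],
    scan_id: int,
    params: SearchParams,
) -> XcorrHistogram:
    """Bin a score multiset; an empty multiset gives an empty histogram."""
    if isinstance(scores, ScoreMultiset):
        vals, occ = scores.scores, scores.occ
    else:
        vals = np.asarray(list(scores), dtype=float)
        occ = np.ones(len(vals), dtype=np.int64)
    hist = XcorrHistogram(scan_id)
    if len(vals) == 0:
        return hist
    bins = score_bin(vals, params.hist_bin_width)
    uniq, inv = np.unique(bins, return_inverse=True)
    sums = np.zeros(len(uniq), dtype=np.int64)
    np.add.at(sums, inv, occ)
    hist.counts = {int(b): int(c) for b, c in zip(uniq, sums) if c > 0}
    return hist


def histogram_arithmetic(
    his_old: XcorrHistogram, his_del: XcorrHistogram, his_ins: XcorrHistogram
) -> XcorrHistogram:
    """Per-bin integer arithmetic His(old) - His(del) + His(ins).

    Absent bins count as zero; zero-result bins are dropped.  A negative
    result bin means the inputs were not produced from the same old database
    and parameters, and is a hard error.
    """
    out: Dict[int, int] = dict(his_old.counts)
    for b, c in his_del.counts.items():
        out[b] = out.get(b, 0) - c
    for b, c in his_ins.counts.items():
        out[b] = out.get(b, 0) + c
    for b, c in out.items():
        if c < 0:
            raise ConsistencyError(
                f"scan {his_old.scan_id}: negative histogram bin {b} after "
                "subtraction; the deleted-partition histogram was not derived "
                "from the stored run"
            )
    return XcorrHistogram(his_old.scan_id, {b: c for b, c in out.items() if c > 0})


def histogram_search(
    spectra: SpectrumSet,
    db_part,
    params: SearchParams,
    counters: Optional[Counters] = None,
    counter_key: str = "histogram_scorings",
    index: Optional[CandidateIndex] = None,
) -> Dict[int, XcorrHistogram]:
    """Score every spectrum's candidates from one database partition and
    histogram the per-occurrence scores (no ranking)."""
    if index is None:
        index = CandidateIndex.build(db_part, params)
    out: Dict[int, XcorrHistogram] = {}
    for spectrum in spectra:
        lo, hi = index.window(spectrum)
        if hi == lo:
            out[spectrum.scan_id] = XcorrHistogram(spectrum.scan_id)
            continue
        if counters is not None:
            counters.add(counter_key, hi - lo)
        yprime = preprocess(spectrum, params)
        off = index.offsets[lo : hi + 1]
        scores = score_encoded(
            yprime, index.codes[off[0] : off[-1]], off - off[0], spectrum.charge, params
        )
        out[spectrum.scan_id] = build_histogram(
            ScoreMultiset(scores, index.occ[lo:hi].copy()), spectrum.scan_id, params
        )
    return out


# ---------------------------------------------------------------------------
# decoy augmentation

def augment_with_decoys(
    spectrum: Spectrum,
    current_total: int,
    params: SearchParams,
    yprime: Optional[np.ndarray] = None,
    counters: Optional[Counters] = None,
) -> np.ndarray:
    """Quantized Xcorr scores of seeded decoy peptides padding a sparse null.

    Generates ``min_hist_entries - current_total`` random residue strings of
    length 7-20 from a PRNG seeded by (decoy_seed, scan_id) and scores them
    against the spectrum.  A deliberate property: the decoys depend only on
    the spectrum and parameters, never on any database, so both search paths
    add the identical multiset.
    """
    n = params.min_hist_entries - current_total
    if n <= 0:
        return np.zeros(0)
    rng = np.random.default_rng(
        np.random.SeedSequence([abs(int(params.decoy_seed)), int(spectrum.scan_id)])
    )
    lengths = rng.integers(DECOY_MIN_LEN, DECOY_MAX_LEN + 1, size=n)
    codes = rng.integers(0, 20, size=int(lengths.sum())).astype(np.int16)
    offsets = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(lengths, out=offsets[1:])
    if yprime is None:
        yprime = preprocess(spectrum, params)
    if counters is not None:
        counters.add("decoy_scorings", n)
    return score_encoded(yprime, codes, offsets, spectrum.charge, params)


# ---------------------------------------------------------------------------
# tail fit

@dataclass
class TailFit:
    """Log10-linear fit of the histogram survival function."""

    slope: float
    intercept: float
    degenerate: bool = False


def fit_tail(
    his: Union[XcorrHistogram, Mapping[int, int]], params: SearchParams
) -> TailFit:
    """Ordinary least squares of log10 survival counts against bin-center score.

    Survival s(k) counts entries in bin k or above.  The fitted window runs
    from one past the histogram mode through the last occupied bin, extended
    left toward the mode when fewer than 4 points remain.  Fewer than 4
    survival bins overall, or a positive fitted slope, yields the degenerate
    flag (the caller then falls back to the most conservative E-value).
    """
    counts = his.counts if isinstance(his, XcorrHistogram) else dict(his)
    counts = {b: c for b, c in counts.items() if c > 0}
    if not counts:
        return TailFit(0.0, 0.0, True)
    kmin, kmax = min(counts), max(counts)
    ks = np.arange(kmin, kmax + 1)
    dense = np.array([counts.get(int(k), 0) for k in ks], dtype=np.int64)
    survival = np.cumsum(dense[::-1])[::-1]
    if len(ks) < _MIN_FIT_POINTS:
        return TailFit(0.0, 0.0, True)
    mode = int(ks[int(np.argmax(dense))])  # lowest bin on ties
    start = mode + 1
    if kmax - start + 1 < _MIN_FIT_POINTS:
        start = kmax - (_MIN_FIT_POINTS - 1)
    start = max(start, kmin)
    sel = ks >= start
    x = (ks[sel] + 0.5) * params.hist_bin_width
    yv = np.log10(survival[sel].astype(float))
    slope, intercept = np.polyfit(x, yv, 1)
    if slope > 0:
        return TailFit(float(slope), float(intercept), True)
    return TailFit(float(slope), float(intercept), False)


def compute_evalue(xcorr: float, fit: TailFit, total: int) -> float:
    """E = 10^(intercept + slope * xcorr), clamped to (0, total].

    On a degenerate fit the most conservative value, the total count, is
    returned (every candidate scored at least this low by chance).
    """
    if fit.degenerate:
        return float(total)
    e = 10.0 ** (fit.intercept + fit.slope * xcorr)
    e = min(e, float(total))
    return max(e, 1e-300)


def recalc_evalues(
    r_new: ResultSet,
    his_new: Dict[int, XcorrHistogram],
    spectra: SpectrumSet,
    params: SearchParams,
    counters: Optional[Counters] = None,
) -> ResultSet:
    """Assign E-values to every stored PSM from per-scan histograms.

    Touches each scan once and never scores a database candidate: the only
    scoring performed is the database-independent decoy padding.
    """
    for scan in sorted(r_new.psms):
        psms = r_new.psms[scan]
        if not psms:
            continue
        if scan not in his_new:
            raise ConsistencyError(f"scan {scan} has PSMs but no histogram")
        hist = his_new[scan]
        total = hist.total
        combined = dict(hist.counts)
        if total < params.min_hist_entries:
            spectrum = spectra[scan]
            decoys = augment_with_decoys(spectrum, total, params, counters=counters)
            for b in score_bin(decoys, params.hist_bin_width):
                combined[int(b)] = combined.get(int(b), 0) + 1
            total = params.min_hist_entries
        fit = fit_tail(combined, params)
        for psm in psms:
            psm.evalue = compute_evalue(psm.xcorr, fit, total)
    return r_new
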