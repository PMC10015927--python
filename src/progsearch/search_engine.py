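"""Deterministic SEQUEST-lineage scoring core.

Tryptic digestion with ntt/mc control, fast cross-correlation (Xcorr)
scoring against a preprocessed spectrum, per-spectrum candidate ranking and
from-scratch database search.

Determinism contract
--------------------
Every Xcorr is quantized to ``params.xcorr_out_decimals`` decimal places
immediately after scoring; the quantized value is the engine's canonical
score, used for ranking, tie-breaking, deltaCn, histogram binning and
E-values.  Because the quantized value survives a text round-trip exactly,
a progressive run that re-reads an earlier results file works with the very
same numbers a from-scratch search computes, which is what makes the two
paths field-identical rather than merely close.

Per peptide, theoretical singly charged b- and y-ion bins are visited in a
fixed order (b1+y(L-1), b2+y(L-2), ..., plus the doubly charged series when
the precursor charge is >= 3), so the floating-point summation order never
depends on which database partition a peptide came from.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterator, List, Optional, Sequence, Tuple

import numpy as np
from pyteomics import mass as _pt_mass

from .errors import ProgsearchError
from .io_formats import quantize
from .model import (
    PSM,
    STANDARD_RESIDUES,
    ProteinDB,
    ProteinRecord,
    ResultSet,
    SearchParams,
    Spectrum,
    SpectrumSet,
)

WATER = _pt_mass.calculate_mass(formula="H2O")
PROTON = _pt_mass.nist_mass["H+"][0][0]

#: residue -> code; codes index MASS_TABLE
RESIDUE_CODE: Dict[str, int] = {aa: i for i, aa in enumerate(STANDARD_RESIDUES)}
MASS_TABLE = np.array([_pt_mass.std_aa_mass[aa] for aa in STANDARD_RESIDUES])


class Counters:
    """Instrumentation: how many (spectrum, candidate) scorings each phase did."""

    def __init__(self):
        self.counts = defaultdict(int)

    def add(self, key: str, n: int = 1) -> None:
        self.counts[key] += n

    def __getitem__(self, key: str) -> int:
        return self.counts.get(key, 0)


@dataclass(frozen=True)
class PeptideCandidate:
    sequence: str
    mono_mass: float
    ntt_count: int
    mc_count: int
    proteins: FrozenSet[str]


def peptide_mass(sequence: str) -> float:
    """Neutral monoisotopic mass, accumulated left-to-right (canonical order).

    The same sequential accumulation is used when indexes are built in bulk,
    so a peptide's mass is one well-defined double everywhere.
    """
    try:
        codes = [RESIDUE_CODE[aa] for aa in sequence]
    except KeyError as exc:
        raise ProgsearchError(f"no mass entry for residue {exc.args[0]!r}") from None
    return float(np.cumsum(MASS_TABLE[codes])[-1]) + WATER


# ---------------------------------------------------------------------------
# digestion

def _cut_positions(seq: str) -> List[int]:
    """Positions p where trypsin cuts between seq[p-1] and seq[p] (K/R not before P)."""
    return [p for p in range(1, len(seq)) if seq[p - 1] in "KR" and seq[p] != "P"]


def _digest_spans(seq: str, params: SearchParams) -> Iterator[Tuple[int, int, int, int]]:
    """Yield (start, end, ntt_count, mc_count) for every peptide span.

    Protein N- and C-termini count as tryptic termini.  Spans are generated
    per enzymatic class: fully tryptic cores for ntt=2, plus one-free-end
    spans for ntt=1, plus arbitrary spans for ntt=0; missed cleavages are
    the cut positions strictly inside the span.
    """
    L = len(seq)
    cuts = _cut_positions(seq)
    boundary = [0] + cuts + [L]
    bset = set(boundary)
    # cumulative count of cuts <= p, for O(1) internal-cut counting
    ncut = np.zeros(L + 1, dtype=np.int64)
    for p in cuts:
        ncut[p:] += 1
    lo, hi, mc = params.min_pep_len, params.max_pep_len, params.mc

    def internal(s: int, e: int) -> int:
        # cuts p with s < p < e
        return int(ncut[e - 1] - ncut[s])

    if params.ntt == 2:
        for i, s in enumerate(boundary[:-1]):
            for k in range(1, min(mc + 2, len(boundary) - i)):
                e = boundary[i + k]
                if e - s > hi:
                    break
                if e - s >= lo:
                    yield s, e, 2, k - 1
        return

    # ntt <= 1: spans with a tryptic start and any end
    for s in boundary[:-1]:
        e = s + lo
        while e <= min(L, s + hi):
            m = internal(s, e)
            if m > mc:
                break
            yield s, e, 1 + (e in bset), m
            e += 1
    # spans with a tryptic end and a non-tryptic start
    for e in boundary[1:]:
        s = e - lo
        while s >= max(0, e - hi):
            if s not in bset:
                m = internal(s, e)
                if m > mc:
                    break
                yield s, e, 1, m
            s -= 1
    if params.ntt == 0:
        # fully non-specific spans
        for s in range(1, L):
            if s in bset:
                continue
            e = s + lo
            while e <= min(L, s + hi):
                if e in bset:
                    e += 1
                    continue
                m = internal(s, e)
                if m > mc:
                    break
                yield s, e, 0, m
                e += 1


def digest(
    protein: ProteinRecord,
    params: SearchParams,
    diagnostics: Optional[Dict[str, int]] = None,
) -> List[PeptideCandidate]:
    """Enumerate peptide candidates of one protein under ntt/mc/length rules.

    Spans containing a residue without a mass entry are skipped and counted
    in ``diagnostics['skipped_unknown_residue']``.
    """
    seq = protein.sequence
    unknown = {i for i, aa in enumerate(seq) if aa not in RESIDUE_CODE}
    out = []
    skipped = 0
    proteins = frozenset([protein.accession])
    for s, e, ntt_c, mc_c in _digest_spans(seq, params):
        if unknown and any(s <= i < e for i in unknown):
            skipped += 1
            continue
        pep = seq[s:e]
        out.append(PeptideCandidate(pep, peptide_mass(pep), ntt_c, mc_c, proteins))
    if diagnostics is not None and skipped:
        diagnostics["skipped_unknown_residue"] = (
            diagnostics.get("skipped_unknown_residue", 0) + skipped
        )
    return out


# ---------------------------------------------------------------------------
# candidate index

class CandidateIndex:
    """Mass-sorted deduplicated peptide index over a database.

    Peptides are deduplicated by sequence with merged protein-accession sets;
    ``occ[i]`` counts the number of distinct protein sequences containing
    peptide ``i`` — the per-occurrence multiplicity used for histogramming
    (a peptide found in k proteins contributes its score k times).
    Order is (mono_mass ascending, peptide text ascending).
    """

    def __init__(self, seqs, masses, occ, proteins, params: SearchParams):
        self.seqs: List[str] = seqs
        self.masses: np.ndarray = masses
        self.occ: np.ndarray = occ
        self.proteins: List[Tuple[str, ...]] = proteins
        self.params = params
        codes = [np.frombuffer(s.encode("ascii"), dtype=np.uint8) for s in seqs]
        lut = np.full(128, -1, dtype=np.int16)
        for aa, c in RESIDUE_CODE.items():
            lut[ord(aa)] = c
        self.offsets = np.zeros(len(seqs) + 1, dtype=np.int64)
        np.cumsum([len(s) for s in seqs], out=self.offsets[1:])
        flat = np.concatenate(codes) if codes else np.zeros(0, dtype=np.uint8)
        self.codes = lut[flat]
        self.position: Dict[str, int] = {s: i for i, s in enumerate(seqs)}

    def __len__(self) -> int:
        return len(self.seqs)

    @property
    def total_occurrences(self) -> int:
        return int(self.occ.sum())

    @classmethod
    def build(
        cls,
        db: ProteinDB,
        params: SearchParams,
        diagnostics: Optional[Dict[str, int]] = None,
    ) -> "CandidateIndex":
        table: Dict[str, set] = {}
        occ: Dict[str, int] = {}
        skipped = 0
        for seq in db.unique_sequences:
            accs = db.by_sequence[seq]
            unknown = [i for i, aa in enumerate(seq) if aa not in RESIDUE_CODE]
            peps = set()
            for s, e, _ntt, _mc in _digest_spans(seq, params):
                if unknown and any(s <= i < e for i in unknown):
                    skipped += 1
                    continue
                peps.add(seq[s:e])
            for pep in peps:
                if pep in table:
                    table[pep].update(accs)
                    occ[pep] += 1
                else:
                    table[pep] = set(accs)
                    occ[pep] = 1
        if diagnostics is not None and skipped:
            diagnostics["skipped_unknown_residue"] = (
                diagnostics.get("skipped_unknown_residue", 0) + skipped
            )
        items = sorted(
            ((peptide_mass(p), p) for p in table), key=lambda t: (t[0], t[1])
        )
        seqs = [p for _, p in items]
        masses = np.array([m for m, _ in items]) if items else np.zeros(0)
        occs = np.array([occ[p] for p in seqs], dtype=np.int64)
        prots = [tuple(sorted(table[p])) for p in seqs]
        return cls(seqs, masses, occs, prots, params)

    def window(self, spectrum: Spectrum) -> Tuple[int, int]:
        """Index slice [lo, hi) of candidates within precursor tolerance."""
        mobs = spectrum.neutral_mass(PROTON)
        p = self.params
        tol = p.precursor_tol if p.precursor_tol_unit == "Da" else p.precursor_tol * 1e-6 * mobs
        lo = int(np.searchsorted(self.masses, mobs - tol, side="left"))
        hi = int(np.searchsorted(self.masses, mobs + tol, side="right"))
        return lo, hi

    def match_count(self, spectrum: Spectrum) -> int:
        """Per-occurrence candidate total within tolerance (no scoring)."""
        lo, hi = self.window(spectrum)
        return int(self.occ[lo:hi].sum())


def candidates_for(
    spectrum: Spectrum, index: CandidateIndex, params: SearchParams
) -> List[PeptideCandidate]:
    """Candidates whose neutral mass lies within precursor tolerance,
    ordered by (mass, sequence)."""
    lo, hi = index.window(spectrum)
    out = []
    for i in range(lo, hi):
        pep = index.seqs[i]
        out.append(
            PeptideCandidate(
                pep, float(index.masses[i]), 2, 0, frozenset(index.proteins[i])
            )
        )
    return out


# ---------------------------------------------------------------------------
# spectrum preprocessing and scoring

_BG_HALF = 75  # background window: mean over offsets tau in [-75, 75], tau != 0
_N_WINDOWS = 10
_WINDOW_NORM = 50.0
_XCORR_SCALE = 0.005


def fragment_bin(mz, params: SearchParams):
    """Fragment bin index: floor(mz / bin_width + bin_offset)."""
    return np.floor(
        np.asarray(mz) / params.fragment_bin_width + params.fragment_bin_offset
    ).astype(np.int64)


def preprocess(spectrum: Spectrum, params: SearchParams) -> np.ndarray:
    """Binned, sqrt-scaled, window-normalized, background-corrected intensities.

    Intensities are square-rooted and binned (max per bin); the vector is
    split into 10 equal m/z windows, each max-normalized to 50; the fast-
    Xcorr background correction subtracts from each bin the mean of its
    neighbours within +/-75 bins.
    """
    if len(spectrum.peaks) == 0:
        return np.zeros(2 * _BG_HALF + 1)
    bins = fragment_bin(spectrum.peaks[:, 0], params)
    n = int(bins.max()) + _BG_HALF + 1
    y = np.zeros(n)
    np.maximum.at(y, bins, np.sqrt(spectrum.peaks[:, 1]))
    wlen = -(-n // _N_WINDOWS)  # ceil
    for w in range(0, n, wlen):
        seg = y[w : w + wlen]
        m = seg.max()
        if m > 0:
            seg *= _WINDOW_NORM / m
    window_sum = np.convolve(y, np.ones(2 * _BG_HALF + 1), mode="same")
    return y - (window_sum - y) / (2 * _BG_HALF)


def _padded_prefix(
    codes: np.ndarray, offsets: np.ndarray, width: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-per-peptide residue-mass prefix sums, zero-padded to ``width``.

    Each row's cumulative sum is computed independently (sequentially within
    the row), so a peptide's fragment masses never depend on which batch it
    was scored in.
    """
    starts = offsets[:-1]
    ends = offsets[1:]
    lens = (ends - starts).astype(np.int64)
    cols = np.arange(width)
    idx = np.minimum(starts[:, None] + cols[None, :], len(codes) - 1)
    mask = cols[None, :] < lens[:, None]
    res = np.where(mask, MASS_TABLE[codes[idx]], 0.0)
    return np.cumsum(res, axis=1), lens, mask


def score_encoded(
    yprime: np.ndarray,
    codes: np.ndarray,
    offsets: np.ndarray,
    charge: int,
    params: SearchParams,
) -> np.ndarray:
    """Quantized Xcorr for each encoded peptide segment against ``yprime``.

    ``codes`` is a flat residue-code array, ``offsets`` the segment bounds
    (len m+1).  Returns an array of m scores.  The reduction width is fixed
    by the parameters (max peptide length), so the floating-point summation
    tree — and therefore every score — is batch-independent.
    """
    m = len(offsets) - 1
    if m == 0:
        return np.zeros(0)
    offsets = np.asarray(offsets, dtype=np.int64)
    lens = offsets[1:] - offsets[:-1]
    width = int(max(params.max_pep_len, 20, lens.max()))
    cum, lens, _mask = _padded_prefix(codes, offsets, width)
    rows = np.arange(m)
    total = cum[rows, np.maximum(lens - 1, 0)]
    # interior prefix columns k = 0..width-2 correspond to b_{k+1} / y_{L-k-1}
    ion_cols = np.arange(width - 1)
    ion_mask = ion_cols[None, :] < (lens - 1)[:, None]
    prefix = cum[:, :-1]
    b_mz = prefix + PROTON
    y_mz = total[:, None] - prefix + WATER + PROTON

    nbins = len(yprime)

    def contrib(mz):
        b = fragment_bin(mz, params)
        ok = ion_mask & (b >= 0) & (b < nbins)
        return np.where(ok, yprime[np.clip(b, 0, nbins - 1)], 0.0)

    per_ion = contrib(b_mz) + contrib(y_mz)
    if charge >= 3:
        per_ion = per_ion + contrib((b_mz + PROTON) / 2.0) + contrib((y_mz + PROTON) / 2.0)
    raw = _XCORR_SCALE * per_ion.sum(axis=1)
    return np.round(raw, params.xcorr_out_decimals)


def encode_peptides(seqs: Sequence[str]) -> Tuple[np.ndarray, np.ndarray]:
    """Flat residue-code encoding of peptide strings (for ad-hoc scoring)."""
    lut = np.full(128, -1, dtype=np.int16)
    for aa, c in RESIDUE_CODE.items():
        lut[ord(aa)] = c
    offsets = np.zeros(len(seqs) + 1, dtype=np.int64)
    np.cumsum([len(s) for s in seqs], out=offsets[1:])
    if seqs:
        flat = lut[np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)]
        if np.any(flat < 0):
            raise ProgsearchError("peptide contains a residue with no mass entry")
    else:
        flat = np.zeros(0, dtype=np.int16)
    return flat, offsets


def xcorr(
    preprocessed: np.ndarray,
    peptide: PeptideCandidate,
    charge: int,
    params: SearchParams,
) -> float:
    """Quantized Xcorr of one peptide against a preprocessed spectrum."""
    seq = peptide.sequence if isinstance(peptide, PeptideCandidate) else str(peptide)
    flat, off = encode_peptides([seq])
    return float(score_encoded(preprocessed, flat, off, charge, params)[0])


# ---------------------------------------------------------------------------
# per-spectrum search

@dataclass
class ScoreMultiset:
    """Per-occurrence candidate score multiset of one scan.

    ``scores[i]`` is the quantized Xcorr of the i-th distinct matched
    peptide, contributing ``occ[i]`` occurrences (one per source protein).
    """

    scores: np.ndarray = field(default_factory=lambda: np.zeros(0))
    occ: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    @property
    def total(self) -> int:
        return int(self.occ.sum())


def search_spectrum(
    spectrum: Spectrum,
    index: CandidateIndex,
    params: SearchParams,
    counters: Optional[Counters] = None,
    counter_key: str = "candidate_scorings",
    yprime: Optional[np.ndarray] = None,
) -> Tuple[List[PSM], ScoreMultiset]:
    """Score every in-tolerance candidate and keep the top n+1 PSMs.

    Canonical total order: Xcorr descending, peptide text ascending.  The
    returned multiset holds one score per (peptide, source protein)
    occurrence for histogramming.
    """
    lo, hi = index.window(spectrum)
    m = hi - lo
    if m == 0:
        return [], ScoreMultiset()
    if yprime is None:
        yprime = preprocess(spectrum, params)
    if counters is not None:
        counters.add(counter_key, m)
    off = index.offsets[lo : hi + 1]
    scores = score_encoded(
        yprime, index.codes[off[0] : off[-1]], off - off[0], spectrum.charge, params
    )
    keep = min(m, params.num_output_lines + 1)
    order = sorted(range(m), key=lambda i: (-scores[i], index.seqs[lo + i]))[:keep]
    psms = [
        PSM(
            scan_id=spectrum.scan_id,
            rank=r + 1,
            peptide=index.seqs[lo + i],
            xcorr=float(scores[i]),
            proteins=index.proteins[lo + i],
        )
        for r, i in enumerate(order)
    ]
    return psms, ScoreMultiset(scores, index.occ[lo:hi].copy())


def scratch_search(
    spectra: SpectrumSet,
    db: ProteinDB,
    params: SearchParams,
    counters: Optional[Counters] = None,
    index: Optional[CandidateIndex] = None,
):
    """From-scratch search of every spectrum against ``db``.

    Returns (ResultSet, per-scan XcorrHistogram dict).  Scans with zero
    in-tolerance candidates appear with an empty PSM list and an empty
    histogram.
    """
    from .evalue_histogram import build_histogram  # local: avoids import cycle

    if index is None:
        index = CandidateIndex.build(db, params)
    results = ResultSet()
    histograms = {}
    for spectrum in spectra:
        psms, multiset = search_spectrum(spectrum, index, params, counters)
        results.psms[spectrum.scan_id] = psms
        results.candidate_count[spectrum.scan_id] = multiset.total
        histograms[spectrum.scan_id] = build_histogram(
            multiset, spectrum.scan_id, params
        )
    return results, histograms
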