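"""Core domain containers shared by every module.

The containers mirror the objects a SEQUEST-lineage search engine works
with: protein databases, MS/MS spectra, search parameters, peptide-spectrum
matches (PSMs) and per-spectrum Xcorr histograms.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .errors import FormatError

# The 20 standard amino acids; B, J, O, U, X, Z are not accepted as residues.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_RESIDUES)


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry: accession (first header token), description, sequence."""

    accession: str
    description: str
    sequence: str


class ProteinDB:
    """Ordered protein collection with a sequence -> accessions mapping.

    Duplicate sequences are collapsed for search purposes: ``by_sequence``
    maps each distinct sequence to the sorted tuple of all accessions that
    carry it, and ``unique_sequences`` lists distinct sequences in first-
    occurrence order.  ``records`` keeps every parsed entry so FASTA output
    round-trips exactly.
    """

    def __init__(self, records: Sequence[ProteinRecord]):
        self.records: List[ProteinRecord] = list(records)
        seen = set()
        by_seq: Dict[str, List[str]] = {}
        order: List[str] = []
        for rec in self.records:
            if rec.accession in seen:
                raise FormatError(f"duplicate accession {rec.accession!r}")
            seen.add(rec.accession)
            if not rec.sequence:
                raise FormatError(f"empty sequence for accession {rec.accession!r}")
            if rec.sequence not in by_seq:
                by_seq[rec.sequence] = []
                order.append(rec.sequence)
            by_seq[rec.sequence].append(rec.accession)
        self.by_sequence: Dict[str, Tuple[str, ...]] = {
            s: tuple(sorted(a)) for s, a in by_seq.items()
        }
        self.unique_sequences: List[str] = order

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    @property
    def accessions(self) -> List[str]:
        return [r.accession for r in self.records]

    def n_residues(self) -> int:
        """Total amino-acid count over distinct sequences."""
        return sum(len(s) for s in self.unique_sequences)

    def digest_id(self) -> str:
        """Content digest (order-independent) used in run manifests."""
        h = hashlib.sha256()
        for acc, seq in sorted((r.accession, r.sequence) for r in self.records):
            h.update(acc.encode())
            h.update(b"\t")
            h.update(seq.encode())
            h.update(b"\n")
        return h.hexdigest()[:16]


@dataclass(eq=False)
class Spectrum:
    """A single MS/MS scan: precursor and an m/z-sorted peak list."""

    scan_id: int
    title: str
    precursor_mz: float
    charge: int
    peaks: np.ndarray  # shape (n, 2): m/z, intensity

    def __post_init__(self):
        self.peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if np.any(self.peaks[:, 1] < 0):
            raise FormatError(f"scan {self.scan_id}: negative peak intensity")
        order = np.argsort(self.peaks[:, 0], kind="stable")
        self.peaks = self.peaks[order]

    def neutral_mass(self, proton: float) -> float:
        return (self.precursor_mz - proton) * self.charge


class SpectrumSet:
    """Spectra keyed by unique scan_id, in file order."""

    def __init__(self, spectra: Sequence[Spectrum]):
        self.spectra: List[Spectrum] = list(spectra)
        self.by_scan: Dict[int, Spectrum] = {}
        for s in self.spectra:
            if s.scan_id in self.by_scan:
                raise FormatError(f"duplicate scan_id {s.scan_id}")
            self.by_scan[s.scan_id] = s

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, scan_id: int) -> Spectrum:
        return self.by_scan[scan_id]


@dataclass
class SearchParams:
    """Every search tunable; a progressive run requires these to be identical
    to the run that produced its inputs (enforced via :meth:`digest_id`)."""

    precursor_tol: float = 3.0
    precursor_tol_unit: str = "Da"  # "Da" or "ppm"
    fragment_bin_width: float = 1.0005079
    fragment_bin_offset: float = 0.4
    ntt: int = 2
    mc: int = 2
    min_pep_len: int = 6
    max_pep_len: int = 50
    num_output_lines: int = 5
    compute_evalue: bool = False
    hist_bin_width: float = 0.1
    min_hist_entries: int = 3000
    xcorr_out_decimals: int = 7
    deltacn_out_decimals: int = 4
    decoy_seed: int = 1

    def __post_init__(self):
        if self.precursor_tol_unit not in ("Da", "ppm"):
            raise FormatError(f"bad precursor_tol_unit {self.precursor_tol_unit!r}")
        if self.ntt not in (0, 1, 2):
            raise FormatError("ntt must be 0, 1 or 2")
        if self.mc < 0:
            raise FormatError("mc must be >= 0")
        if self.num_output_lines < 1:
            raise FormatError("num_output_lines must be >= 1")
        for name in ("precursor_tol", "fragment_bin_width", "hist_bin_width"):
            if getattr(self, name) <= 0:
                raise FormatError(f"{name} must be positive")
        if not (0 < self.min_pep_len <= self.max_pep_len):
            raise FormatError("require 0 < min_pep_len <= max_pep_len")

    def canonical_text(self) -> str:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, bool):
                v = int(v)
            if isinstance(v, float):
                v = repr(v)
            lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    def digest_id(self) -> str:
        return hashlib.sha256(self.canonical_text().encode()).hexdigest()[:16]


@dataclass
class PSM:
    """A ranked peptide-spectrum match.

    ``xcorr`` is the engine's canonical score: the cross-correlation value
    quantized to ``xcorr_out_decimals`` decimals, so that the value written
    to the results file IS the internal value (lossless round-trip).
    """

    scan_id: int
    rank: int
    peptide: str
    xcorr: float
    proteins: Tuple[str, ...]
    deltacn: Optional[float] = None
    evalue: Optional[float] = None


@dataclass
class ResultSet:
    """Per-scan ranked PSM lists plus per-scan candidate-occurrence totals."""

    psms: Dict[int, List[PSM]] = field(default_factory=dict)
    candidate_count: Dict[int, int] = field(default_factory=dict)

    def scans(self) -> List[int]:
        return sorted(self.psms)


@dataclass
class XcorrHistogram:
    """Sparse per-scan histogram of candidate Xcorr values.

    ``counts`` maps bin index (``floor(xcorr / hist_bin_width)``, may be
    negative) to a positive integer count; zero-count bins are never stored.
    """

    scan_id: int
    counts: Dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        for b, c in list(self.counts.items()):
            if c < 0:
                raise FormatError(
                    f"scan {self.scan_id}: negative histogram count in bin {b}"
                )
            if c == 0:
                del self.counts[b]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def is_empty(self) -> bool:
        return not self.counts
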