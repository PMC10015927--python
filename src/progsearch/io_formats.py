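"""Readers and writers for every external representation.

Formats handled: protein FASTA (via pyteomics), MGF spectra (via pyteomics),
the flat ``key = value`` parameter file, the results TSV and the per-spectrum
histogram TSV.  The two TSV dialects are this tool's own: their byte-exact
numeric formatting is what lets a later progressive run consume an earlier
run's output losslessly.

Numeric formatting is fixed-point with round-half-to-even (IEEE-754 double
formatting), so formatting the same value twice is byte-identical and
``float(formatted)`` returns exactly the quantized value that was written.
"""
from __future__ import annotations

import os
import re
from dataclasses import fields
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
from pyteomics import fasta as _fasta
from pyteomics import mgf as _mgf

from . import __version__
from .errors import ConsistencyError, FormatError
from .model import (
    PSM,
    ProteinDB,
    ProteinRecord,
    ResultSet,
    SearchParams,
    Spectrum,
    SpectrumSet,
    XcorrHistogram,
    _STANDARD_SET,
)

PathLike = Union[str, os.PathLike]

# ---------------------------------------------------------------------------
# numeric formatting


def quantize(x: float, decimals: int) -> float:
    """Round ``x`` to ``decimals`` decimal places (half-to-even).

    The result is the double nearest to the rounded decimal value, so
    ``float(format_fixed(quantize(x, d), d)) == quantize(x, d)`` exactly.
    """
    return float(np.round(x, decimals))


def format_fixed(x: float, decimals: int) -> str:
    return f"{x:.{decimals}f}"


def format_evalue(e: float) -> str:
    """Scientific notation with 6 significant digits (round-trip stable)."""
    return f"{e:.5e}"


def _format_opt(x: Optional[float], decimals: int) -> str:
    return "-" if x is None else format_fixed(x, decimals)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike, permissive: bool = False) -> ProteinDB:
    """Parse a protein FASTA file into a :class:`ProteinDB`.

    Sequences are uppercased and trailing ``*`` stop characters stripped.
    Residues outside the 20 standard amino acids raise unless ``permissive``
    (non-standard letters are then rejected at digestion instead).
    """
    with open(path) as fh:
        lines = fh.readlines()
    # structural pre-scan for precise line-numbered errors
    header_line = None
    has_seq = False
    for i, line in enumerate(lines, start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith(">"):
            if header_line is not None and not has_seq:
                raise FormatError(f"{path}: line {header_line}: empty sequence")
            header_line, has_seq = i, False
        else:
            if header_line is None:
                raise FormatError(f"{path}: line {i}: expected FASTA header '>'")
            has_seq = True
    if header_line is not None and not has_seq:
        raise FormatError(f"{path}: line {header_line}: empty sequence")
    records: List[ProteinRecord] = []
    with open(path) as fh:
        for header, seq in _fasta.FASTA(fh):
            parts = header.split(None, 1)
            if not parts:
                raise FormatError(f"{path}: empty FASTA header")
            accession = parts[0]
            description = parts[1] if len(parts) > 1 else ""
            seq = seq.upper().rstrip("*")
            if not seq:
                raise FormatError(f"{path}: empty sequence for {accession!r}")
            bad = set(seq) - _STANDARD_SET
            if bad:
                if not all(c.isalpha() for c in bad):
                    raise FormatError(
                        f"{path}: non-residue characters {sorted(bad)} in {accession!r}"
                    )
                if not permissive:
                    raise FormatError(
                        f"{path}: non-standard residues {sorted(bad)} in {accession!r}"
                        " (use permissive mode to defer to digestion)"
                    )
            records.append(ProteinRecord(accession, description, seq))
    return ProteinDB(records)


def write_fasta(db: ProteinDB, path: PathLike) -> None:
    entries = []
    for rec in db.records:
        header = rec.accession if not rec.description else f"{rec.accession} {rec.description}"
        entries.append((header, rec.sequence))
    with open(path, "w") as fh:
        _fasta.write(entries, fh)


# ---------------------------------------------------------------------------
# MGF


def read_mgf(path: PathLike) -> SpectrumSet:
    """Read an MGF file; blocks without SCANS are numbered sequentially from 1."""
    spectra: List[Spectrum] = []
    with open(path) as fh:
        for i, block in enumerate(_mgf.MGF(fh), start=1):
            params = block["params"]
            if "pepmass" not in params or params["pepmass"] is None:
                raise FormatError(f"{path}: spectrum block {i} lacks PEPMASS")
            pepmass = params["pepmass"][0]
            charge_field = params.get("charge")
            if not charge_field:
                raise FormatError(f"{path}: spectrum block {i} lacks CHARGE")
            charge = int(charge_field[0])
            if charge < 1:
                raise FormatError(f"{path}: spectrum block {i}: charge must be >= 1")
            scan_id = int(params["scans"]) if "scans" in params else i
            title = str(params.get("title", ""))
            peaks = np.column_stack(
                [np.asarray(block["m/z array"], float), np.asarray(block["intensity array"], float)]
            ) if len(block["m/z array"]) else np.empty((0, 2))
            spectra.append(Spectrum(scan_id, title, float(pepmass), charge, peaks))
    return SpectrumSet(spectra)


def write_mgf(spectra: SpectrumSet, path: PathLike) -> None:
    blocks = []
    for s in spectra:
        blocks.append(
            {
                "params": {
                    "title": s.title,
                    "pepmass": (s.precursor_mz, None),
                    "charge": s.charge,
                    "scans": s.scan_id,
                },
                "m/z array": s.peaks[:, 0],
                "intensity array": s.peaks[:, 1],
            }
        )
    with open(path, "w") as fh:
        _mgf.write(blocks, fh)


# ---------------------------------------------------------------------------
# parameter file


def read_params(path: PathLike) -> SearchParams:
    """Read a flat ``key = value`` parameter file mirroring SearchParams."""
    field_types = {f.name: f.type for f in fields(SearchParams)}
    defaults = SearchParams()
    kwargs = {}
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}: line {i}: expected 'key = value'")
            key, val = (t.strip() for t in line.split("=", 1))
            if key not in field_types:
                raise FormatError(f"{path}: line {i}: unknown parameter {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                kwargs[key] = int(val)
            elif isinstance(current, float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
    return SearchParams(**kwargs)


def write_params(params: SearchParams, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(params.canonical_text())


# ---------------------------------------------------------------------------
# run manifests ('#'-prefixed header lines on results / histogram files)

_MANIFEST_KEYS = ("kind", "params_digest", "db_digest", "version", "timestamp")


def _write_manifest(fh, kind: str, params_digest: str, db_digest: str, timestamp: str) -> None:
    fh.write(f"# kind={kind}\n")
    fh.write(f"# params_digest={params_digest}\n")
    fh.write(f"# db_digest={db_digest}\n")
    fh.write(f"# version={__version__}\n")
    fh.write(f"# timestamp={timestamp}\n")


_MANIFEST_RE = re.compile(r"^#\s*(\w+)=(.*)$")


def _read_header(lines: List[str]) -> Tuple[Dict[str, str], int]:
    manifest: Dict[str, str] = {}
    i = 0
    while i < len(lines) and lines[i].startswith("#"):
        m = _MANIFEST_RE.match(lines[i].rstrip("\n"))
        if m:
            manifest[m.group(1)] = m.group(2)
        i += 1
    return manifest, i


def verify_manifest(manifest: Dict[str, str], params: SearchParams, d_old: ProteinDB, what: str) -> None:
    """Refuse progressive inputs whose provenance does not match.

    The equivalence guarantee only holds if the stored run used identical
    search parameters and exactly the old database now supplied.
    """
    pd = manifest.get("params_digest")
    if pd is not None and pd != "-" and pd != params.digest_id():
        raise ConsistencyError(
            f"{what}: parameter digest mismatch (stored {pd}, current {params.digest_id()});"
            " progressive search requires identical parameters"
        )
    dd = manifest.get("db_digest")
    if dd is not None and dd != "-" and dd != d_old.digest_id():
        raise ConsistencyError(
            f"{what}: old-database digest mismatch (stored {dd}, current {d_old.digest_id()})"
        )


# ---------------------------------------------------------------------------
# results TSV

_RESULTS_COLUMNS = ("scan", "rank", "peptide", "xcorr", "deltacn", "evalue", "proteins", "candidates")


def write_results(
    results: ResultSet,
    path: PathLike,
    params: SearchParams,
    db_digest: str = "-",
    timestamp: str = "-",
) -> None:
    """Write one TSV row per (scan, rank).

    Xcorr is formatted to ``xcorr_out_decimals`` decimals (it is already
    quantized to that precision), deltaCn to ``deltacn_out_decimals``,
    E-values in 6-significant-digit scientific notation or ``-``.
    The trailing column carries the scan's candidate-occurrence total.
    """
    with open(path, "w") as fh:
        _write_manifest(fh, "results", params.digest_id(), db_digest, timestamp)
        fh.write("\t".join(_RESULTS_COLUMNS) + "\n")
        for scan in sorted(results.psms):
            count = results.candidate_count.get(scan, 0)
            for psm in results.psms[scan]:
                ev = "-" if psm.evalue is None else format_evalue(psm.evalue)
                fh.write(
                    "\t".join(
                        (
                            str(scan),
                            str(psm.rank),
                            psm.peptide,
                            format_fixed(psm.xcorr, params.xcorr_out_decimals),
                            _format_opt(psm.deltacn, params.deltacn_out_decimals),
                            ev,
                            ";".join(sorted(psm.proteins)),
                            str(count),
                        )
                    )
                    + "\n"
                )


def read_results(path: PathLike) -> Tuple[ResultSet, Dict[str, str]]:
    with open(path) as fh:
        lines = fh.readlines()
    manifest, start = _read_header(lines)
    if start >= len(lines) or lines[start].rstrip("\n").split("\t") != list(_RESULTS_COLUMNS):
        raise FormatError(f"{path}: line {start + 1}: bad or missing results header")
    results = ResultSet()
    for i, raw in enumerate(lines[start + 1:], start=start + 2):
        if not raw.strip():
            continue
        tok = raw.rstrip("\n").split("\t")
        if len(tok) != len(_RESULTS_COLUMNS):
            raise FormatError(f"{path}: line {i}: expected {len(_RESULTS_COLUMNS)} fields")
        try:
            scan = int(tok[0])
            rank = int(tok[1])
            xcorr = float(tok[3])
            deltacn = None if tok[4] == "-" else float(tok[4])
            evalue = None if tok[5] == "-" else float(tok[5])
            count = int(tok[7])
        except ValueError as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from None
        proteins = tuple(tok[6].split(";")) if tok[6] else ()
        psm = PSM(scan, rank, tok[2], xcorr, proteins, deltacn, evalue)
        results.psms.setdefault(scan, []).append(psm)
        results.candidate_count[scan] = count
    for scan, psms in results.psms.items():
        if [p.rank for p in psms] != list(range(1, len(psms) + 1)):
            raise FormatError(f"{path}: scan {scan}: ranks are not 1..k in order")
    return results, manifest


# ---------------------------------------------------------------------------
# histogram TSV

_HIST_COLUMNS = ("scan", "bin", "count")


def write_histograms(
    histograms: Dict[int, XcorrHistogram],
    path: PathLike,
    params: SearchParams,
    db_digest: str = "-",
    timestamp: str = "-",
) -> None:
    """Sparse histogram table: only count > 0 rows are written."""
    with open(path, "w") as fh:
        _write_manifest(fh, "histograms", params.digest_id(), db_digest, timestamp)
        fh.write("\t".join(_HIST_COLUMNS) + "\n")
        for scan in sorted(histograms):
            counts = histograms[scan].counts
            for b in sorted(counts):
                if counts[b] > 0:
                    fh.write(f"{scan}\t{b}\t{counts[b]}\n")


def read_histograms(path: PathLike) -> Tuple[Dict[int, XcorrHistogram], Dict[str, str]]:
    """Reconstruct sparse histograms; absent bins read as zero."""
    with open(path) as fh:
        lines = fh.readlines()
    manifest, start = _read_header(lines)
    if start >= len(lines) or lines[start].rstrip("\n").split("\t") != list(_HIST_COLUMNS):
        raise FormatError(f"{path}: line {start + 1}: bad or missing histogram header")
    out: Dict[int, XcorrHistogram] = {}
    for i, raw in enumerate(lines[start + 1:], start=start + 2):
        if not raw.strip():
            continue
        tok = raw.rstrip("\n").split("\t")
        if len(tok) != 3:
            raise FormatError(f"{path}: line {i}: expected 3 fields")
        try:
            scan, b, count = int(tok[0]), int(tok[1]), int(tok[2])
        except ValueError as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from None
        if count < 0:
            raise FormatError(f"{path}: line {i}: negative count (corrupt histogram)")
        if count > 0:
            out.setdefault(scan, XcorrHistogram(scan)).counts[b] = count
    return out, manifest
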