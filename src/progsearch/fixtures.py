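"""Seeded synthetic data: protein databases, database updates, MS/MS spectra.

The generators emulate a monthly database-update scenario: random tryptic
proteins, a small deleted/inserted fraction, and charge-2 spectra whose
peaks are the b/y ladder of a known source peptide plus uniform noise.
Spectrum sources are drawn uniformly from the (peptide, protein) occurrence
pool of the database, i.e. identifications are "randomly selected from the
database" — the average-case premise of the progressive deletion bound.

``standard_fixture`` additionally plants, by construction, one instance of
each update branch: a peptide shared between a deleted and a surviving
protein (protein-list pruning without re-search), a deleted-only scan
(full re-search), an inserted protein that beats the shared partition on
one scan (PSM replacement), and a peptide shared between a surviving and an
inserted protein (equal-Xcorr protein append).
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ProgsearchError
from .model import (
    ProteinDB,
    ProteinRecord,
    SearchParams,
    Spectrum,
    SpectrumSet,
)
from .search_engine import PROTON, WATER, MASS_TABLE, RESIDUE_CODE, _cut_positions, _digest_spans

# residue alphabet split for K/R placement: expected tryptic segment ~11
_NON_KR = "ACDEFGHILMNPQSTVWY"
_KR_PROB = 1.0 / 11.0


@dataclass(frozen=True)
class UpdateSpec:
    """A database update: fractions of proteins deleted and inserted."""

    frac_del: float
    frac_ins: float
    seed: int


@dataclass(frozen=True)
class SpectrumTruth:
    scan_id: int
    source_peptide: str
    source_proteins: Tuple[str, ...]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    is_kr = rng.random(length) < _KR_PROB
    kr = rng.integers(0, 2, length)
    other = rng.integers(0, len(_NON_KR), length)
    return "".join(
        ("KR"[kr[i]] if is_kr[i] else _NON_KR[other[i]]) for i in range(length)
    )


def gen_database(
    n_proteins: int,
    len_range: Tuple[int, int] = (60, 180),
    seed: int = 0,
    accession_prefix: str = "SYN",
) -> ProteinDB:
    """Random protein database; deterministic per seed.

    K/R residues are placed with per-residue probability 1/11 so the expected
    fully tryptic peptide length is ~11.
    """
    if n_proteins < 1:
        raise ProgsearchError("n_proteins must be >= 1")
    lo, hi = len_range
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        records.append(
            ProteinRecord(
                f"{accession_prefix}{i + 1:06d}",
                "synthetic protein",
                _random_sequence(rng, length),
            )
        )
    return ProteinDB(records)


def gen_update(
    db: ProteinDB,
    spec: UpdateSpec,
    len_range: Tuple[int, int] = (60, 180),
) -> Tuple[ProteinDB, ProteinDB, Dict[str, frozenset]]:
    """Apply a random update to ``db``: returns (d_old, d_new, expected sets).

    Deletes round(frac_del * n) proteins (seeded sample without replacement)
    and inserts round(frac_ins * n) newly generated ones.
    """
    n = len(db)
    n_del = int(round(spec.frac_del * n))
    n_ins = int(round(spec.frac_ins * n))
    if n_del >= n:
        raise ProgsearchError("update would leave no shared proteins")
    rng = np.random.default_rng(spec.seed)
    del_idx = set(rng.choice(n, size=n_del, replace=False).tolist()) if n_del else set()
    survivors = [r for i, r in enumerate(db.records) if i not in del_idx]
    inserted = []
    for j in range(n_ins):
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        inserted.append(
            ProteinRecord(
                f"INS{spec.seed}_{j + 1:05d}", "inserted protein",
                _random_sequence(rng, length),
            )
        )
    d_new = ProteinDB(survivors + inserted)
    expected = {
        "deleted_accessions": frozenset(
            db.records[i].accession for i in sorted(del_idx)
        ),
        "inserted_accessions": frozenset(r.accession for r in inserted),
    }
    return db, d_new, expected


# ---------------------------------------------------------------------------
# spectra

def _tryptic_pool(db: ProteinDB, params: SearchParams) -> List[Tuple[str, str]]:
    """All fully tryptic (peptide, first-accession) occurrences of the database."""
    tryptic = replace(params, ntt=2)
    pool = []
    for seq in db.unique_sequences:
        accs = db.by_sequence[seq]
        for s, e, _ntt, _mc in _digest_spans(seq, tryptic):
            pep = seq[s:e]
            if all(aa in RESIDUE_CODE for aa in pep):
                pool.append((pep, accs))
    return pool


def _by_ion_mzs(peptide: str) -> np.ndarray:
    masses = np.array([MASS_TABLE[RESIDUE_CODE[aa]] for aa in peptide])
    prefix = np.cumsum(masses)[:-1]
    b = prefix + PROTON
    y = masses.sum() - prefix + WATER + PROTON
    return np.concatenate([b, y])


def _make_spectrum(
    scan_id: int,
    peptide: str,
    noise_peaks: int,
    rng: np.random.Generator,
    charge: int = 2,
) -> Spectrum:
    ions = _by_ion_mzs(peptide)
    intens = rng.uniform(30.0, 100.0, len(ions))
    mz = ions
    if noise_peaks:
        noise_mz = rng.uniform(150.0, float(ions.max()) + 100.0, noise_peaks)
        noise_int = rng.uniform(1.0, 15.0, noise_peaks)
        mz = np.concatenate([mz, noise_mz])
        intens = np.concatenate([intens, noise_int])
    total_mass = float(np.sum([MASS_TABLE[RESIDUE_CODE[aa]] for aa in peptide])) + WATER
    precursor = (total_mass + charge * PROTON) / charge
    return Spectrum(
        scan_id,
        f"synthetic scan {scan_id}",
        precursor,
        charge,
        np.column_stack([mz, intens]),
    )


def gen_spectra(
    db: ProteinDB,
    n_spectra: int,
    noise_peaks: int,
    seed: int,
    params: SearchParams,
    forced_truths: Optional[Sequence[Tuple[str, Tuple[str, ...]]]] = None,
) -> Tuple[SpectrumSet, List[SpectrumTruth]]:
    """Synthesize charge-2 spectra from uniformly sampled peptide occurrences.

    ``forced_truths`` (peptide, accessions) pairs occupy the first scans —
    used by ``standard_fixture`` to guarantee branch coverage.
    """
    pool = _tryptic_pool(db, params)
    if not pool:
        raise ProgsearchError("database yields no tryptic peptides under these params")
    rng = np.random.default_rng(seed)
    spectra: List[Spectrum] = []
    truths: List[SpectrumTruth] = []
    forced = list(forced_truths or [])
    if len(forced) > n_spectra:
        raise ProgsearchError("more forced truths than spectra")
    for scan in range(1, n_spectra + 1):
        if scan <= len(forced):
            pep, accs = forced[scan - 1]
        else:
            pep, accs = pool[int(rng.integers(0, len(pool)))]
        spectra.append(_make_spectrum(scan, pep, noise_peaks, rng))
        truths.append(SpectrumTruth(scan, pep, tuple(accs)))
    return SpectrumSet(spectra), truths


def write_truth(truths: Sequence[SpectrumTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("scan\tpeptide\tproteins\n")
        for t in truths:
            fh.write(f"{t.scan_id}\t{t.source_peptide}\t{';'.join(sorted(t.source_proteins))}\n")


# ---------------------------------------------------------------------------
# standard fixture with guaranteed branch coverage

@dataclass
class FixtureBundle:
    d_old: ProteinDB
    d_new: ProteinDB
    spectra: SpectrumSet
    truths: List[SpectrumTruth]
    params: SearchParams
    deleted_accessions: frozenset
    inserted_accessions: frozenset
    #: scan ids of the planted branch cases
    scan_shared_del: int  # peptide in a deleted AND a surviving protein
    scan_replaced: int  # deleted-only truth re-found in an inserted protein
    scan_appended: int  # peptide in a surviving AND an inserted protein


def _tryptic_segment(seq: str, lo: int = 8, hi: int = 15) -> Optional[str]:
    """A fully tryptic segment of length lo..hi not starting with P (so it
    stays tryptic when grafted after a K/R)."""
    cuts = _cut_positions(seq)
    bounds = [0] + cuts + [len(seq)]
    for s, e in zip(bounds[:-1], bounds[1:]):
        if lo <= e - s <= hi and seq[s] != "P":
            return seq[s:e]
    return None


def _graft(record: ProteinRecord, peptide: str) -> ProteinRecord:
    seq = record.sequence
    if seq[-1] not in "KR":
        seq += "K"
    return ProteinRecord(record.accession, record.description, seq + peptide)


def standard_fixture(
    seed: int,
    n_proteins: int = 500,
    n_spectra: int = 200,
    frac_del: float = 0.02,
    frac_ins: float = 0.02,
    noise_peaks: int = 10,
    params: Optional[SearchParams] = None,
) -> FixtureBundle:
    """The reference test scenario: a 2% / 2% monthly-style update.

    Deterministic per seed; every progressive-update branch occurs at least
    once by construction, asserted before returning.
    """
    if params is None:
        params = SearchParams(ntt=1, mc=2, compute_evalue=True, decoy_seed=seed)
    base = gen_database(n_proteins, seed=seed)
    rng = np.random.default_rng([seed, 7])
    n_del = int(round(frac_del * n_proteins))
    n_ins = int(round(frac_ins * n_proteins))
    if n_del < 2 or n_ins < 2:
        raise ProgsearchError("standard fixture needs >= 2 deletions and insertions")
    del_idx = sorted(rng.choice(n_proteins, size=n_del, replace=False).tolist())
    del_set = set(del_idx)

    # pick deleted donors with a usable tryptic segment
    donors = [i for i in del_idx if _tryptic_segment(base.records[i].sequence)]
    if len(donors) < 2:
        raise ProgsearchError("deleted sample lacks tryptic segments; change seed")
    a0, a1 = donors[0], donors[1]
    pep_shared = _tryptic_segment(base.records[a0].sequence)
    pep_replace = _tryptic_segment(base.records[a1].sequence)

    survivor_idx = [i for i in range(n_proteins) if i not in del_set]
    # survivor C carries a copy of the deleted protein A0's peptide
    c_idx = survivor_idx[int(rng.integers(0, len(survivor_idx)))]
    records = list(base.records)
    records[c_idx] = _graft(records[c_idx], pep_shared)
    # survivor B donates a peptide to an inserted protein
    b_candidates = [
        i for i in survivor_idx if i != c_idx and _tryptic_segment(records[i].sequence)
    ]
    b_idx = b_candidates[int(rng.integers(0, len(b_candidates)))]
    pep_append = _tryptic_segment(records[b_idx].sequence)

    d_old = ProteinDB(records)
    inserted = []
    for j in range(n_ins):
        length = int(rng.integers(60, 181))
        inserted.append(
            ProteinRecord(f"INS{seed}_{j + 1:05d}", "inserted protein",
                          _random_sequence(rng, length))
        )
    inserted[0] = _graft(inserted[0], pep_append)
    inserted[1] = _graft(inserted[1], pep_replace)
    d_new = ProteinDB(
        [r for i, r in enumerate(records) if i not in del_set] + inserted
    )

    forced = [
        (pep_shared, (records[a0].accession, records[c_idx].accession)),
        (pep_replace, (records[a1].accession,)),
        (pep_append, (records[b_idx].accession,)),
    ]
    spectra, truths = gen_spectra(
        d_old, n_spectra, noise_peaks, seed, params, forced_truths=forced
    )

    # branch indicators, by construction
    def _products(seq: str) -> set:
        return {seq[s:e] for s, e, _n, _m in _digest_spans(seq, replace(params, ntt=2))}

    assert pep_shared in _products(records[a0].sequence)
    assert pep_shared in _products(records[c_idx].sequence)
    assert pep_replace in _products(inserted[1].sequence)
    assert pep_append in _products(records[b_idx].sequence)
    assert pep_append in _products(inserted[0].sequence)

    return FixtureBundle(
        d_old=d_old,
        d_new=d_new,
        spectra=spectra,
        truths=truths,
        params=params,
        deleted_accessions=frozenset(records[i].accession for i in del_idx),
        inserted_accessions=frozenset(r.accession for r in inserted),
        scan_shared_del=1,
        scan_replaced=2,
        scan_appended=3,
    )
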