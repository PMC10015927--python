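"""The progressive update: deletion, insertion, deltaCn, E-value recalculation.

Converts the stored results of a search against an old database into the
results for a new database in four steps:

1. *Deletion* — prune deleted proteins from stored PSM protein lists; scans
   in which any stored PSM loses all protein support are re-searched against
   the shared partition only.
2. *Insertion* — search the inserted partition for every spectrum and merge
   the two top-(n+1) lists under the canonical order.
3. *Score calculation* — recompute deltaCn(i) = 1 - Xcorr(i+1)/Xcorr(i).
4. *E-value calculation* — per-bin histogram arithmetic plus decoy-padded
   tail refit (no candidate rescoring).

The output is field-identical to a from-scratch search of the new database;
the only searched partitions are the deleted and inserted ones (plus the
shared partition for the re-searched scans), so the cost is proportional to
the database difference.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

from .database_diff import DBDiff, diff_databases
from .errors import ConsistencyError
from .evalue_histogram import (
    build_histogram,
    histogram_arithmetic,
    histogram_search,
    recalc_evalues,
)
from .model import PSM, ProteinDB, ResultSet, SearchParams, SpectrumSet, XcorrHistogram
from .search_engine import (
    CandidateIndex,
    Counters,
    ScoreMultiset,
    scratch_search,
    search_spectrum,
)


@dataclass
class DeletionPartition:
    """Scans needing a shared-partition re-search, plus the pruned survivors."""

    s_del: Set[int]
    pruned: ResultSet


def partition_deletion(
    r_old: ResultSet,
    diff: DBDiff,
    params: SearchParams,
    srd_index: Optional[CandidateIndex] = None,
    del_index: Optional[CandidateIndex] = None,
) -> DeletionPartition:
    """Split stored scans by whether deletion invalidates any stored PSM.

    For every stored PSM the protein list is replaced by the shared
    partition's support for its peptide (probed in the shared peptide index).
    If any stored PSM of a scan has no shared support left, the whole scan
    is re-searched later: its stored list is no longer guaranteed to be the
    top of the shared candidate set.  A peptide with support in neither
    partition means the inputs were not produced from this old database.
    """
    if srd_index is None:
        srd_index = CandidateIndex.build(diff.srd, params)
    if del_index is None:
        del_index = CandidateIndex.build(diff.del_, params)
    s_del: Set[int] = set()
    pruned = ResultSet()
    for scan, psms in r_old.psms.items():
        new_list: List[PSM] = []
        dead = False
        for psm in psms:
            i = srd_index.position.get(psm.peptide)
            if i is None:
                if psm.peptide not in del_index.position:
                    raise ConsistencyError(
                        f"scan {scan}: stored peptide {psm.peptide!r} is a digest "
                        "product of neither partition; results were not produced "
                        "from the given old database / parameters"
                    )
                dead = True
                break
            new_list.append(
                PSM(scan, psm.rank, psm.peptide, psm.xcorr, srd_index.proteins[i])
            )
        if dead:
            s_del.add(scan)
        else:
            pruned.psms[scan] = new_list
            pruned.candidate_count[scan] = r_old.candidate_count.get(scan, 0)
    return DeletionPartition(s_del, pruned)


def deletion_step(
    r_old: ResultSet,
    diff: DBDiff,
    spectra: SpectrumSet,
    params: SearchParams,
    counters: Optional[Counters] = None,
    srd_index: Optional[CandidateIndex] = None,
    del_index: Optional[CandidateIndex] = None,
    partition: Optional[DeletionPartition] = None,
) -> ResultSet:
    """Produce the shared-partition result set R_srd from R_old.

    Scans outside S_del keep their pruned stored lists (still exactly the
    top of the shared candidate set); scans in S_del are re-searched against
    the shared partition only.  Candidate totals are maintained exactly by
    subtracting the deleted partition's in-tolerance occurrence count.
    """
    if srd_index is None:
        srd_index = CandidateIndex.build(diff.srd, params)
    if del_index is None:
        del_index = CandidateIndex.build(diff.del_, params)
    if partition is None:
        partition = partition_deletion(r_old, diff, params, srd_index, del_index)
    for scan in r_old.psms:
        if scan not in spectra.by_scan:
            raise ConsistencyError(f"scan {scan} in stored results missing from spectra")
    r_srd = ResultSet()
    for spectrum in spectra:
        scan = spectrum.scan_id
        if scan in partition.s_del:
            psms, multiset = search_spectrum(
                spectrum, srd_index, params, counters, "deletion_rescore"
            )
            r_srd.psms[scan] = psms
            r_srd.candidate_count[scan] = multiset.total
        else:
            r_srd.psms[scan] = partition.pruned.psms.get(scan, [])
            old_count = partition.pruned.candidate_count.get(scan, 0)
            r_srd.candidate_count[scan] = old_count - del_index.match_count(spectrum)
    return r_srd


def insertion_step(
    r_srd: ResultSet,
    spectra: SpectrumSet,
    diff: DBDiff,
    params: SearchParams,
    counters: Optional[Counters] = None,
    ins_index: Optional[CandidateIndex] = None,
) -> Tuple[ResultSet, ResultSet, Dict[int, ScoreMultiset]]:
    """Search the inserted partition for all spectra and merge into R_new.

    Entries with identical peptide text are coalesced (union of protein
    sets; their Xcorr is necessarily equal).  Returns (R_new, R_ins, and the
    per-scan inserted-partition score multisets, reused for histogramming so
    the inserted partition is scored exactly once).
    """
    if ins_index is None:
        ins_index = CandidateIndex.build(diff.ins, params)
    keep = params.num_output_lines + 1
    r_new = ResultSet()
    r_ins = ResultSet()
    ins_multisets: Dict[int, ScoreMultiset] = {}
    for spectrum in spectra:
        scan = spectrum.scan_id
        ins_psms, multiset = search_spectrum(
            spectrum, ins_index, params, counters, "insertion_scorings"
        )
        r_ins.psms[scan] = ins_psms
        r_ins.candidate_count[scan] = multiset.total
        ins_multisets[scan] = multiset
        merged: Dict[str, PSM] = {}
        for psm in r_srd.psms.get(scan, []) + ins_psms:
            prev = merged.get(psm.peptide)
            if prev is None:
                merged[psm.peptide] = PSM(scan, 0, psm.peptide, psm.xcorr, psm.proteins)
            else:
                prev.proteins = tuple(sorted(set(prev.proteins) | set(psm.proteins)))
        ordered = sorted(merged.values(), key=lambda p: (-p.xcorr, p.peptide))[:keep]
        for rank, psm in enumerate(ordered, start=1):
            psm.rank = rank
        r_new.psms[scan] = ordered
        r_new.candidate_count[scan] = (
            r_srd.candidate_count.get(scan, 0) + multiset.total
        )
    return r_new, r_ins, ins_multisets


def compute_deltacn(r: ResultSet, params: SearchParams) -> ResultSet:
    """deltaCn(i) = 1 - Xcorr(i+1)/Xcorr(i) for ranks 1..n.

    Conventions (identical on the scratch and progressive paths): the rank
    n+1 helper row keeps deltaCn unset (its successor was never stored); a
    scan whose last stored PSM is rank <= n gets deltaCn 1.0 there (no
    further candidate exists); any rank with Xcorr <= 0 gets 0.0.
    """
    helper_rank = params.num_output_lines + 1
    for psms in r.psms.values():
        m = len(psms)
        for i, psm in enumerate(psms):
            if psm.rank == helper_rank:
                psm.deltacn = None
            elif psm.xcorr <= 0:
                psm.deltacn = 0.0
            elif i + 1 < m:
                psm.deltacn = 1.0 - psms[i + 1].xcorr / psm.xcorr
            else:
                psm.deltacn = 1.0
    return r


def run_scratch(
    spectra: SpectrumSet,
    db: ProteinDB,
    params: SearchParams,
    counters: Optional[Counters] = None,
):
    """From-scratch search with finalized deltaCn (and E-values if enabled)."""
    results, histograms = scratch_search(spectra, db, params, counters)
    compute_deltacn(results, params)
    if params.compute_evalue:
        recalc_evalues(results, histograms, spectra, params, counters)
    return results, histograms


def run_progressive(
    spectra: SpectrumSet,
    d_old: ProteinDB,
    d_new: ProteinDB,
    r_old: ResultSet,
    his_old: Optional[Dict[int, XcorrHistogram]],
    params: SearchParams,
    counters: Optional[Counters] = None,
) -> Tuple[ResultSet, Optional[Dict[int, XcorrHistogram]]]:
    """Full progressive update: R_old -> R_new (+ His_new when E-values are on).

    ``r_old`` and ``his_old`` must come from a run of this tool over
    (spectra, d_old) with identical parameters; the CLI verifies this via
    the stored run manifest before calling here.
    """
    diff = diff_databases(d_old, d_new)
    srd_index = CandidateIndex.build(diff.srd, params)
    del_index = CandidateIndex.build(diff.del_, params)
    ins_index = CandidateIndex.build(diff.ins, params)
    r_srd = deletion_step(
        r_old, diff, spectra, params, counters, srd_index, del_index
    )
    r_new, _r_ins, ins_multisets = insertion_step(
        r_srd, spectra, diff, params, counters, ins_index
    )
    compute_deltacn(r_new, params)
    his_new = None
    if params.compute_evalue:
        if his_old is None:
            raise ConsistencyError(
                "E-value recalculation requires the stored run's histograms"
            )
        his_del = histogram_search(
            spectra, diff.del_, params, counters, "del_histogram_scorings", del_index
        )
        his_new = {}
        for spectrum in spectra:
            scan = spectrum.scan_id
            his_new[scan] = histogram_arithmetic(
                his_old.get(scan, XcorrHistogram(scan)),
                his_del.get(scan, XcorrHistogram(scan)),
                build_histogram(ins_multisets[scan], scan, params),
            )
        recalc_evalues(r_new, his_new, spectra, params, counters)
    return r_new, his_new
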