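import math

import numpy as np
import pytest

from progsearch.database_diff import diff_databases
from progsearch.fixtures import gen_database, gen_spectra
from progsearch.io_formats import write_histograms, write_results
from progsearch.model import ProteinDB, ProteinRecord, SearchParams, Spectrum, SpectrumSet
from progsearch.search_engine import (
    MASS_TABLE,
    PROTON,
    RESIDUE_CODE,
    WATER,
    CandidateIndex,
    candidates_for,
    digest,
    peptide_mass,
    preprocess,
    scratch_search,
    search_spectrum,
    xcorr,
)

# ---------------------------------------------------------------------------
# digestion


def brute_force_digest(seq, params):
    """Independent oracle: test every substring against the ntt/mc/length
    predicate directly."""
    cuts = [p for p in range(1, len(seq)) if seq[p - 1] in "KR" and seq[p] != "P"]
    bset = {0, len(seq)} | set(cuts)
    out = []
    for s in range(len(seq)):
        for e in range(s + 1, len(seq) + 1):
            if not (params.min_pep_len <= e - s <= params.max_pep_len):
                continue
            ntt = (s in bset) + (e in bset)
            mc = sum(1 for p in cuts if s < p < e)
            if ntt >= params.ntt and mc <= params.mc:
                out.append((seq[s:e], ntt, mc))
    return sorted(out)


def test_digest_tryptic_products():
    params = SearchParams(ntt=2, mc=0, min_pep_len=1)
    rec = ProteinRecord("P", "", "MKAR")
    assert sorted(c.sequence for c in digest(rec, params)) == ["AR", "MK"]


def test_digest_kp_suppression():
    """K followed by P does not cleave: MKPAR digests to a single peptide."""
    params = SearchParams(ntt=2, mc=0, min_pep_len=1)
    rec = ProteinRecord("P", "", "MKPAR")
    assert [c.sequence for c in digest(rec, params)] == ["MKPAR"]


@pytest.mark.parametrize("ntt", [0, 1, 2])
@pytest.mark.parametrize("mc", [0, 2])
@pytest.mark.parametrize("seed", range(12))
def test_digest_matches_brute_force(ntt, mc, seed):
    params = SearchParams(ntt=ntt, mc=mc, min_pep_len=4, max_pep_len=30)
    db = gen_database(1, (40, 70), seed=seed)
    rec = db.records[0]
    got = sorted((c.sequence, c.ntt_count, c.mc_count) for c in digest(rec, params))
    assert got == brute_force_digest(rec.sequence, params)


def test_digest_skips_unknown_residues_with_tally():
    params = SearchParams(ntt=2, mc=0, min_pep_len=1)
    rec = ProteinRecord("P", "", "MBKAR")  # B has no mass entry
    diag = {}
    got = digest(rec, params, diagnostics=diag)
    assert sorted(c.sequence for c in got) == ["AR"]
    assert diag["skipped_unknown_residue"] == 1


def test_digest_mono_mass_is_residues_plus_water():
    assert peptide_mass("GK") == pytest.approx(
        MASS_TABLE[RESIDUE_CODE["G"]] + MASS_TABLE[RESIDUE_CODE["K"]] + WATER
    )


# ---------------------------------------------------------------------------
# candidate selection


def _spectrum_for_mass(mass, scan=1, charge=2, peaks=((300.0, 10.0),)):
    return Spectrum(scan, "t", (mass + charge * PROTON) / charge, charge, np.array(peaks))


def test_candidates_for_empty_database():
    params = SearchParams()
    idx = CandidateIndex.build(ProteinDB([]), params)
    assert candidates_for(_spectrum_for_mass(800.0), idx, params) == []


def test_candidates_for_degenerate_tolerance_exact_match():
    params = SearchParams(precursor_tol=1e-9, min_pep_len=2)
    db = ProteinDB([ProteinRecord("P", "", "AAKGGKCCK")])
    idx = CandidateIndex.build(db, params)
    target = idx.seqs[0]
    got = candidates_for(_spectrum_for_mass(peptide_mass(target)), idx, params)
    assert [c.sequence for c in got] == [target]


@pytest.mark.parametrize("seed", range(10))
def test_candidates_for_agrees_with_linear_scan(seed):
    params = SearchParams(precursor_tol=2.0, ntt=1)
    db = gen_database(5, (40, 80), seed=seed)
    idx = CandidateIndex.build(db, params)
    rng = np.random.default_rng(seed)
    mass = float(rng.uniform(700, 1500))
    got = {c.sequence for c in candidates_for(_spectrum_for_mass(mass), idx, params)}
    expected = {
        s for s, m in zip(idx.seqs, idx.masses) if abs(m - mass) <= params.precursor_tol
    }
    assert got == expected


# ---------------------------------------------------------------------------
# preprocessing


def brute_preprocess(spectrum, params):
    """Literal reimplementation: bin/sqrt, 10-window normalize, double-loop
    offset-mean background subtraction."""
    if len(spectrum.peaks) == 0:
        return np.zeros(151)
    bins = [
        math.floor(mz / params.fragment_bin_width + params.fragment_bin_offset)
        for mz in spectrum.peaks[:, 0]
    ]
    n = max(bins) + 76
    y = [0.0] * n
    for b, inten in zip(bins, spectrum.peaks[:, 1]):
        y[b] = max(y[b], math.sqrt(inten))
    wlen = math.ceil(n / 10)
    for w0 in range(0, n, wlen):
        seg_max = max(y[w0 : w0 + wlen])
        if seg_max > 0:
            for i in range(w0, min(w0 + wlen, n)):
                y[i] = y[i] * (50.0 / seg_max)
    out = []
    for b in range(n):
        acc = 0.0
        for tau in range(-75, 76):
            if tau != 0 and 0 <= b + tau < n:
                acc += y[b + tau]
        out.append(y[b] - acc / 150.0)
    return np.array(out)


def test_preprocess_empty_peak_list_is_zero_vector():
    s = Spectrum(1, "t", 500.0, 2, np.empty((0, 2)))
    assert not np.any(preprocess(s, SearchParams()))


def test_preprocess_single_peak_structure():
    params = SearchParams()
    s = Spectrum(1, "t", 500.0, 2, np.array([[500.0, 100.0]]))
    y = preprocess(s, params)
    b = int(np.floor(500.0 / params.fragment_bin_width + params.fragment_bin_offset))
    assert y[b] > 0
    neighbours = np.concatenate([y[max(b - 75, 0) : b], y[b + 1 : b + 76]])
    assert np.all(neighbours <= 0) and neighbours.sum() < 0


@pytest.mark.parametrize("seed", range(10))
def test_preprocess_matches_double_loop(seed):
    params = SearchParams()
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 60))
    peaks = np.column_stack([rng.uniform(150, 1500, n), rng.uniform(1, 100, n)])
    s = Spectrum(1, "t", 800.0, 2, peaks)
    got = preprocess(s, params)
    expected = brute_preprocess(s, params)
    m = min(len(got), len(expected))
    np.testing.assert_allclose(got[:m], expected[:m], atol=1e-9)
    assert not np.any(got[m:]) and not np.any(expected[m:])


# ---------------------------------------------------------------------------
# Xcorr


def brute_xcorr(yprime, pep, charge, params):
    """Direct re-summation over theoretical ion bins."""
    masses = [float(MASS_TABLE[RESIDUE_CODE[aa]]) for aa in pep]
    total = 0.0
    for m in masses:
        total += m

    def val(mz):
        b = math.floor(mz / params.fragment_bin_width + params.fragment_bin_offset)
        return float(yprime[b]) if 0 <= b < len(yprime) else 0.0

    score = 0.0
    pref = 0.0
    for m in masses[:-1]:
        pref += m
        b_mz = pref + PROTON
        y_mz = total - pref + WATER + PROTON
        score += val(b_mz) + val(y_mz)
        if charge >= 3:
            score += val((b_mz + PROTON) / 2.0) + val((y_mz + PROTON) / 2.0)
    return 0.005 * score


def test_xcorr_zero_vector_scores_zero():
    params = SearchParams()
    cands = digest(ProteinRecord("P", "", "AAAGGGKCCCDDDK"), params)
    for c in cands:
        assert xcorr(np.zeros(2000), c, 2, params) == 0.0


@pytest.mark.parametrize("charge", [2, 3])
@pytest.mark.parametrize("seed", range(10))
def test_xcorr_matches_brute_force_sum(seed, charge):
    params = SearchParams()
    rng = np.random.default_rng(seed)
    yprime = rng.normal(0, 5, 2500)
    pep = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), rng.integers(6, 30)))
    got = xcorr(np.asarray(yprime), pep, charge, params)
    assert got == pytest.approx(brute_xcorr(yprime, pep, charge, params), abs=1.1e-7)


def test_xcorr_own_spectrum_beats_low_overlap_candidates():
    """A spectrum built from a peptide's b/y ladder scores that peptide above
    every candidate sharing < 50% of its ion bins."""
    params = SearchParams(ntt=1)
    db = gen_database(30, (40, 80), seed=3)
    spectra, truths = gen_spectra(db, 5, noise_peaks=0, seed=3, params=params)
    idx = CandidateIndex.build(db, params)

    def ion_bins(pep):
        masses = [float(MASS_TABLE[RESIDUE_CODE[aa]]) for aa in pep]
        pref = np.cumsum(masses)[:-1]
        mzs = np.concatenate([pref + PROTON, sum(masses) - pref + WATER + PROTON])
        return set(
            int(b)
            for b in np.floor(mzs / params.fragment_bin_width + params.fragment_bin_offset)
        )

    for spectrum, truth in zip(spectra, truths):
        yprime = preprocess(spectrum, params)
        truth_bins = ion_bins(truth.source_peptide)
        truth_score = xcorr(yprime, truth.source_peptide, 2, params)
        for c in candidates_for(spectrum, idx, params):
            if c.sequence == truth.source_peptide:
                continue
            overlap = len(ion_bins(c.sequence) & truth_bins) / len(truth_bins)
            if overlap < 0.5:
                assert xcorr(yprime, c.sequence, 2, params) < truth_score


# ---------------------------------------------------------------------------
# per-spectrum search and scratch search


def test_search_spectrum_single_candidate():
    params = SearchParams(precursor_tol=0.5, min_pep_len=2)
    db = ProteinDB([ProteinRecord("P", "", "AAKGGK")])
    idx = CandidateIndex.build(db, params)
    s = _spectrum_for_mass(peptide_mass("AAK"))
    psms, multiset = search_spectrum(s, idx, params)
    assert len(psms) == 1 and psms[0].rank == 1 and psms[0].peptide == "AAK"
    assert multiset.total == 1


def test_search_spectrum_tie_breaks_lexicographically():
    """Equal Xcorr (here: zero against a far-away peak) ranks the
    lexicographically smaller peptide first."""
    params = SearchParams(precursor_tol=1.0, min_pep_len=2)
    db = ProteinDB(
        [ProteinRecord("P1", "", "CADEFK"), ProteinRecord("P2", "", "ACDEFK")]
    )
    idx = CandidateIndex.build(db, params)
    s = _spectrum_for_mass(peptide_mass("ACDEFK"), peaks=((3000.0, 5.0),))
    psms, _ = search_spectrum(s, idx, params)
    assert [p.xcorr for p in psms] == [0.0, 0.0]
    assert [p.peptide for p in psms] == ["ACDEFK", "CADEFK"]


def test_search_spectrum_top_list_matches_full_sort(small_bundle):
    b = small_bundle
    idx = CandidateIndex.build(b.d_old, b.params)
    spectrum = b.spectra.spectra[4]
    psms, _ = search_spectrum(spectrum, idx, b.params)
    yprime = preprocess(spectrum, b.params)
    scored = [
        (c.sequence, xcorr(yprime, c.sequence, spectrum.charge, b.params))
        for c in candidates_for(spectrum, idx, b.params)
    ]
    expected = sorted(scored, key=lambda t: (-t[1], t[0]))
    keep = b.params.num_output_lines + 1
    assert [(p.peptide, p.xcorr) for p in psms] == expected[:keep]
    assert len(psms) <= keep


def test_scratch_search_empty_database(small_bundle):
    results, hists = scratch_search(
        small_bundle.spectra, ProteinDB([]), small_bundle.params
    )
    assert all(not p for p in results.psms.values())
    assert all(h.is_empty() for h in hists.values())


def test_scratch_search_rank1_matches_argmax_bruteforce():
    params = SearchParams(ntt=2, mc=1)
    db = gen_database(10, (40, 70), seed=9)
    spectra, _ = gen_spectra(db, 4, noise_peaks=5, seed=9, params=params)
    idx = CandidateIndex.build(db, params)
    results, _ = scratch_search(spectra, db, params)
    for spectrum in spectra:
        cands = candidates_for(spectrum, idx, params)
        if not cands:
            continue
        yprime = preprocess(spectrum, params)
        best = max(xcorr(yprime, c.sequence, 2, params) for c in cands)
        assert results.psms[spectrum.scan_id][0].xcorr == best


def test_scratch_search_is_deterministic(tmp_path, small_bundle):
    """Identical inputs give byte-identical results and histogram files."""
    b = small_bundle
    outs = []
    for tag in ("a", "b"):
        results, hists = scratch_search(b.spectra, b.d_old, b.params)
        rp, hp = tmp_path / f"{tag}.results.tsv", tmp_path / f"{tag}.hist.tsv"
        write_results(results, rp, b.params)
        write_histograms(hists, hp, b.params)
        outs.append((rp.read_bytes(), hp.read_bytes()))
    assert outs[0] == outs[1]


def test_candidate_multiset_additivity_over_partitions(small_bundle):
    """Per-occurrence candidate multisets of the shared and inserted
    partitions add up exactly to the new database's multiset."""
    b = small_bundle
    diff = diff_databases(b.d_old, b.d_new)
    idx_new = CandidateIndex.build(b.d_new, b.params)
    idx_srd = CandidateIndex.build(diff.srd, b.params)
    idx_ins = CandidateIndex.build(diff.ins, b.params)

    def occ_map(idx, spectrum):
        lo, hi = idx.window(spectrum)
        return {idx.seqs[i]: int(idx.occ[i]) for i in range(lo, hi)}

    for spectrum in b.spectra.spectra[:10]:
        merged = occ_map(idx_srd, spectrum)
        for pep, n in occ_map(idx_ins, spectrum).items():
            merged[pep] = merged.get(pep, 0) + n
        assert merged == occ_map(idx_new, spectrum)


def test_canonical_order_is_total(small_runs):
    for psms in small_runs["r_new"].psms.values():
        keys = [(-p.xcorr, p.peptide) for p in psms]
        assert keys == sorted(keys)
        assert len(set(keys)) == len(keys)
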