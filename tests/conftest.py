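import pytest

from progsearch.fixtures import standard_fixture
from progsearch.progressive_core import run_scratch


def assert_results_equal(a, b, candidate_counts=True):
    """Field-exact ResultSet equality: peptide, protein set, xcorr, deltaCn,
    E-value per (scan, rank), plus per-scan candidate totals."""
    scans_a = {s for s, p in a.psms.items() if p}
    scans_b = {s for s, p in b.psms.items() if p}
    assert scans_a == scans_b
    for scan in scans_a:
        pa, pb = a.psms[scan], b.psms[scan]
        assert len(pa) == len(pb), f"scan {scan}: stored list lengths differ"
        for x, y in zip(pa, pb):
            assert (x.rank, x.peptide, x.xcorr, x.proteins, x.deltacn, x.evalue) == (
                y.rank, y.peptide, y.xcorr, y.proteins, y.deltacn, y.evalue,
            ), f"scan {scan} rank {x.rank} differs"
    if candidate_counts:
        for scan in scans_a:
            assert a.candidate_count.get(scan, 0) == b.candidate_count.get(scan, 0)


def assert_histograms_equal(a, b):
    """Per-scan, per-bin exact integer equality (absent scans/bins are zero)."""
    for scan in set(a) | set(b):
        ca = a[scan].counts if scan in a else {}
        cb = b[scan].counts if scan in b else {}
        assert ca == cb, f"scan {scan}: histograms differ"


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced update scenario (120 proteins / 40 spectra) for unit tests;
    same construction as the full standard fixture."""
    return standard_fixture(5, n_proteins=120, n_spectra=40)


@pytest.fixture(scope="session")
def small_runs(small_bundle):
    """Old-database and new-database from-scratch runs over the small bundle."""
    b = small_bundle
    r_old, his_old = run_scratch(b.spectra, b.d_old, b.params)
    r_new, his_new = run_scratch(b.spectra, b.d_new, b.params)
    return {"r_old": r_old, "his_old": his_old, "r_new": r_new, "his_new": his_new}
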