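"""Partition an old and a new protein database into shared / deleted / inserted.

Protein identity is the exact amino-acid sequence, not the accession: a
renamed accession with an unchanged sequence is a shared protein, because the
sequence alone determines candidate peptides and hence scores.  The shared
partition carries the accessions of the NEW database, so that results pruned
against it report exactly what a from-scratch search of the new database
would report.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet

from .model import ProteinDB


@dataclass
class DBDiff:
    """Shared / deleted-only / inserted-only partitions of a database update."""

    srd: ProteinDB
    del_: ProteinDB
    ins: ProteinDB
    deleted_accessions: FrozenSet[str]
    inserted_accessions: FrozenSet[str]


def diff_databases(d_old: ProteinDB, d_new: ProteinDB) -> DBDiff:
    """Compare two databases by exact sequence.

    A sequence present in both goes to ``srd`` (as the new database's
    records); a sequence only in the old database goes to ``del_``; only in
    the new one, to ``ins``.  Accession-level adds/removes are reported
    separately in ``deleted_accessions`` / ``inserted_accessions``.
    """
    old_seqs = set(d_old.by_sequence)
    new_seqs = set(d_new.by_sequence)
    srd = ProteinDB([r for r in d_new.records if r.sequence in old_seqs])
    del_ = ProteinDB([r for r in d_old.records if r.sequence not in new_seqs])
    ins = ProteinDB([r for r in d_new.records if r.sequence not in old_seqs])
    old_accs = set(d_old.accessions)
    new_accs = set(d_new.accessions)
    return DBDiff(
        srd=srd,
        del_=del_,
        ins=ins,
        deleted_accessions=frozenset(old_accs - new_accs),
        inserted_accessions=frozenset(new_accs - old_accs),
    )
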