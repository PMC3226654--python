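"""Ranked homology hit lists, taxon-mapped and deduplicated.

Inputs are NCBI BLAST tabular (``-outfmt 6``) or HMMER3 ``--tblout`` files,
parsed through Bio.SearchIO, plus an explicit sequence-id -> taxid mapping.
Each per-query list is normalized to the scoring contract: hits sorted by
decreasing significance with at most one hit per taxon (the most
significant one). Because the profiling depth optimum depends on order,
ties are broken deterministically.

Significance ordering:

* BLAST lists: ascending E-value, then descending bit score, then
  ascending subject id.
* HMMER lists: descending full-sequence bit score, then ascending
  subject id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SearchIO

from .taxonomy import TaxonomyTree, ancestor_at_rank


class HitListError(ValueError):
    pass


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    taxon: int
    evalue: float
    bitscore: float


@dataclass
class HitList:
    """Ordered, per-taxon-deduplicated hits for one query sequence.

    ``sig_field`` names the column reported as the hit's significance
    ("evalue" for BLAST lists, "bitscore" for HMMER lists).
    """

    query_id: str
    hits: list[HitRecord] = field(default_factory=list)
    sig_field: str = "evalue"

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    def significance(self, hit: HitRecord) -> float:
        return getattr(hit, self.sig_field)

    def sort_key(self, hit: HitRecord):
        if self.sig_field == "evalue":
            return (hit.evalue, -hit.bitscore, hit.subject_id)
        return (-hit.bitscore, hit.subject_id)

    def taxa(self) -> list[int]:
        return [h.taxon for h in self.hits]

    def normalized(self) -> "HitList":
        """Sort by the significance key and keep the best hit per taxon."""
        best: dict[int, HitRecord] = {}
        for hit in sorted(self.hits, key=self.sort_key):
            best.setdefault(hit.taxon, hit)
        ordered = sorted(best.values(), key=self.sort_key)
        return HitList(self.query_id, ordered, self.sig_field)


def read_id2tax(path: str | Path) -> dict[str, int]:
    """Two-column TSV: sequence id, taxid. Conflicting duplicates error."""
    mapping: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise HitListError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            seqid, tax = fields[0], fields[1]
            try:
                taxid = int(tax)
            except ValueError:
                raise HitListError(f"{path}:{lineno}: bad taxid {tax!r}") from None
            if seqid in mapping and mapping[seqid] != taxid:
                raise HitListError(
                    f"{path}:{lineno}: id {seqid!r} mapped to conflicting taxids"
                )
            mapping[seqid] = taxid
    return mapping


def parse_blast_tab(
    path: str | Path, id2tax: dict[str, int]
) -> tuple[dict[str, HitList], int]:
    """Parse a 12-column BLAST tabular file into per-query hit lists.

    Subject ids without a taxon mapping are dropped; their count is
    returned alongside the lists (real BLAST output routinely contains
    deprecated identifiers).
    """
    lists: dict[str, HitList] = {}
    unmapped = 0
    try:
        for qresult in SearchIO.parse(str(path), "blast-tab"):
            hits = []
            for hit in qresult:
                for hsp in hit.hsps:
                    tax = id2tax.get(hit.id)
                    if tax is None:
                        unmapped += 1
                        continue
                    hits.append(
                        HitRecord(
                            query_id=qresult.id,
                            subject_id=hit.id,
                            taxon=tax,
                            evalue=hsp.evalue,
                            bitscore=hsp.bitscore,
                        )
                    )
            lists[qresult.id] = HitList(qresult.id, hits, "evalue").normalized()
    except (ValueError, IndexError) as exc:
        raise HitListError(f"{path}: malformed BLAST tabular input: {exc}") from exc
    return lists, unmapped


def parse_hmmer_tblout(
    path: str | Path, id2tax: dict[str, int], query_id: str | None = None
) -> tuple[HitList, int]:
    """Parse a HMMER3 ``--tblout`` file into a single bit-score-ordered list.

    ``query_id`` selects among multiple queries in the file; with a single
    query it may be omitted. Returns ``(hitlist, n_unmapped)``.
    """
    unmapped = 0
    results = {}
    try:
        for qresult in SearchIO.parse(str(path), "hmmer3-tab"):
            results[qresult.id] = qresult
    except (ValueError, IndexError) as exc:
        raise HitListError(f"{path}: malformed tblout input: {exc}") from exc
    if not results:
        return HitList(query_id or "", [], "bitscore"), 0
    if query_id is None:
        if len(results) > 1:
            raise HitListError(
                f"{path}: {len(results)} queries present; query_id is required"
            )
        query_id = next(iter(results))
    elif query_id not in results:
        raise HitListError(f"{path}: query {query_id!r} not found")
    hits = []
    for hit in results[query_id]:
        tax = id2tax.get(hit.id)
        if tax is None:
            unmapped += 1
            continue
        hits.append(
            HitRecord(
                query_id=query_id,
                subject_id=hit.id,
                taxon=tax,
                evalue=hit.evalue,
                bitscore=hit.bitscore,
            )
        )
    return HitList(query_id, hits, "bitscore").normalized(), unmapped


def collapse_hitlist(hl: HitList, tree: TaxonomyTree, rank: str) -> HitList:
    """Replace each hit's taxon by its ancestor at ``rank`` and re-dedup.

    Taxa whose lineage lacks the rank (or which are absent from the tree)
    keep their own id, so every hit stays countable. The most significant
    hit per collapsed taxon survives; ordering is otherwise preserved.
    """
    mapped = []
    for hit in hl.hits:
        if hit.taxon in tree:
            anc = ancestor_at_rank(tree, hit.taxon, rank)
        else:
            warnings.warn(f"taxid {hit.taxon} not in tree; kept uncollapsed")
            anc = hit.taxon
        mapped.append(replace(hit, taxon=anc))
    return HitList(hl.query_id, mapped, hl.sig_field).normalized()
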