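"""Curation of a plasmid multi-FASTA into a working plasmid set.

Public plasmid collections mix complete plasmid sequences with entries
that are really single deposited genes or replication origins.  Three
filters are applied in order, and every input record receives exactly one
audit decision:

1. header keyword screen -- a header carrying a *single* occurrence of the
   token ``origin`` or a single ``cds`` is taken to describe a gene-level
   entry and removed, unless the header also carries the token ``plasmid``
   (headers with two or more ``cds`` tokens are kept: a real plasmid
   annotation can mention many coding sequences);
2. deduplication on the exact uppercased sequence (first occurrence in
   file order wins);
3. an explicit accession exclusion list (crowd curation: sequences flagged
   by domain experts as wrongly included).

Keyword matching is case-insensitive and token-based (the header is split
on non-alphanumeric characters), so ``cds`` does not match inside
``cdsA``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PlasmidRecord",
    "FilterDecision",
    "CurationResult",
    "parse_plasmid_fasta",
    "keyword_filter",
    "deduplicate",
    "apply_exclusion_list",
    "curate",
    "load_exclusion_list",
    "write_fasta",
    "write_audit",
]

Reason = Literal["kept", "duplicate", "keyword_origin", "keyword_cds", "exclusion_list"]

_TOKEN_RE = re.compile(r"[^a-z0-9]+")


@dataclass(frozen=True)
class PlasmidRecord:
    """One curated sequence: accession, full header, sequence, length."""

    accession: str
    header: str
    sequence: str
    length_bp: int

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("empty accession")
        if self.length_bp != len(self.sequence) or self.length_bp <= 0:
            raise ValueError(
                f"{self.accession}: length_bp {self.length_bp} does not match "
                f"sequence of {len(self.sequence)} bp"
            )


@dataclass(frozen=True)
class FilterDecision:
    accession: str
    kept: bool
    reason: Reason


@dataclass
class CurationResult:
    """Survivors of the full filter chain plus one decision per input record."""

    kept: list[PlasmidRecord]
    decisions: list[FilterDecision]

    @property
    def removed(self) -> list[FilterDecision]:
        return [d for d in self.decisions if not d.kept]


def parse_plasmid_fasta(path: str | Path) -> list[PlasmidRecord]:
    """Parse a multi-FASTA into :class:`PlasmidRecord` objects, in file order.

    Sequences are uppercased.  An empty file, an empty sequence, or a
    repeated accession is an error.
    """
    records: list[PlasmidRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise ValueError(f"duplicate accession {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            PlasmidRecord(
                accession=rec.id,
                header=rec.description,
                sequence=seq,
                length_bp=len(seq),
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def _header_tokens(header: str) -> list[str]:
    return [t for t in _TOKEN_RE.split(header.lower()) if t]


def keyword_filter(
    header: str, *, plasmid_rescues_origin: bool = True
) -> FilterDecision:
    """Decide whether a header describes a plasmid or a gene-level entry.

    Removal requires exactly one ``origin`` token or exactly one ``cds``
    token and no ``plasmid`` token.  ``plasmid_rescues_origin`` controls
    whether the ``plasmid`` token also overrides a single-``origin`` hit
    (default) or only single-``cds`` hits.
    """
    if not header:
        raise ValueError("empty header")
    tokens = _header_tokens(header)
    accession = header.split()[0]
    has_plasmid = "plasmid" in tokens
    origin_hit = tokens.count("origin") == 1
    cds_hit = tokens.count("cds") == 1
    if origin_hit and not (has_plasmid and plasmid_rescues_origin):
        return FilterDecision(accession, False, "keyword_origin")
    if cds_hit and not has_plasmid:
        return FilterDecision(accession, False, "keyword_cds")
    return FilterDecision(accession, True, "kept")


def deduplicate(
    records: Sequence[PlasmidRecord],
) -> tuple[list[PlasmidRecord], list[FilterDecision]]:
    """Keep the first record of each group of byte-identical sequences."""
    kept: list[PlasmidRecord] = []
    removed: list[FilterDecision] = []
    seen: set[str] = set()
    for rec in records:
        if rec.sequence in seen:
            removed.append(FilterDecision(rec.accession, False, "duplicate"))
        else:
            seen.add(rec.sequence)
            kept.append(rec)
    return kept, removed


def apply_exclusion_list(
    records: Sequence[PlasmidRecord], excluded_accessions: Iterable[str]
) -> tuple[list[PlasmidRecord], list[FilterDecision]]:
    """Drop records whose accession is on the exclusion list, preserving order.

    Listed accessions absent from the records produce a warning only.
    """
    excluded = set(excluded_accessions)
    present = {r.accession for r in records}
    for acc in sorted(excluded - present):
        warnings.warn(f"excluded accession {acc!r} not present in records")
    kept = [r for r in records if r.accession not in excluded]
    removed = [
        FilterDecision(r.accession, False, "exclusion_list")
        for r in records
        if r.accession in excluded
    ]
    return kept, removed


def curate(
    records: Sequence[PlasmidRecord],
    excluded_accessions: Iterable[str] = (),
    *,
    plasmid_rescues_origin: bool = True,
) -> CurationResult:
    """Run the full filter chain: keyword screen, deduplication, exclusion list.

    The decision list covers every input record exactly once (first
    removing stage wins), in input order, so ``|kept| + |removed| ==
    |input|`` by construction.
    """
    decisions: dict[str, FilterDecision] = {}
    survivors: list[PlasmidRecord] = []
    for rec in records:
        decision = keyword_filter(
            rec.header, plasmid_rescues_origin=plasmid_rescues_origin
        )
        if decision.kept:
            survivors.append(rec)
        else:
            decisions[rec.accession] = FilterDecision(
                rec.accession, False, decision.reason
            )
    survivors, removed = deduplicate(survivors)
    decisions.update({d.accession: d for d in removed})
    survivors, removed = apply_exclusion_list(survivors, excluded_accessions)
    decisions.update({d.accession: d for d in removed})
    for rec in survivors:
        decisions[rec.accession] = FilterDecision(rec.accession, True, "kept")
    ordered = [decisions[rec.accession] for rec in records]
    return CurationResult(kept=survivors, decisions=ordered)


def load_exclusion_list(path: str | Path) -> set[str]:
    """Read an exclusion list: one accession per line, '#' comments allowed."""
    accessions: set[str] = set()
    for line in Path(path).read_text().splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            accessions.add(entry)
    return accessions


def write_fasta(records: Sequence[PlasmidRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.header[len(r.accession) :].strip())
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def write_audit(decisions: Sequence[FilterDecision], path: str | Path) -> None:
    """Tab-separated audit trail: accession, kept, reason."""
    lines = ["accession\tkept\treason"]
    lines += [f"{d.accession}\t{str(d.kept).lower()}\t{d.reason}" for d in decisions]
    Path(path).write_text("\n".join(lines) + "\n")
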