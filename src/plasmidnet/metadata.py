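"""Per-plasmid metadata, gene annotations, and the selection query algebra.

Host species and genus are parsed from RefSeq-style FASTA headers (the
host recorded at deposition, which need not reflect the plasmid's full
host range); family and order come from a genus-level taxonomy mapping
table.  Gene annotations arrive as ABRicate-style tab-separated rows from
four databases: resfinder and card (antibiotic resistance), vfdb
(virulence factors) and plasmidfinder (replicon-based plasmid families).
Selections -- accession sets with provenance -- are produced by length,
taxa, gene and plasmid-family queries and combined by union or
intersection, mirroring the sidebar query menus of a plasmid browser.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .curate import PlasmidRecord, write_fasta

__all__ = [
    "PlasmidMeta",
    "AnnotationHit",
    "Selection",
    "MetadataStore",
    "extract_name_and_taxa",
    "load_taxonomy",
    "attach_taxonomy",
    "ingest_annotations",
    "query_select",
    "combine_selections",
    "summary_table",
    "export_sequences",
    "length_histogram",
]

DATABASES = ("resfinder", "card", "vfdb", "plasmidfinder")

Database = Literal["resfinder", "card", "vfdb", "plasmidfinder"]


@dataclass(frozen=True)
class PlasmidMeta:
    accession: str
    length_bp: int
    plasmid_name: str | None = None
    species: str | None = None
    genus: str | None = None
    family: str | None = None
    order: str | None = None
    cluster: int | None = None


@dataclass(frozen=True)
class AnnotationHit:
    """One gene annotation on a plasmid (1-based inclusive coordinates)."""

    accession: str
    database: Database
    gene: str
    db_accession: str
    coverage: float
    identity: float
    start_bp: int
    end_bp: int
    aro: str | None = None  # antibiotic resistance ontology id, card only
    strand: str | None = None  # recorded if present, unused


@dataclass(frozen=True)
class Selection:
    """An accession set plus a description of the query that produced it."""

    accessions: frozenset[str]
    provenance: str

    def __len__(self) -> int:
        return len(self.accessions)


_TRAILING_PUNCT = ".,;:)]}'\""


def extract_name_and_taxa(
    header: str,
) -> tuple[str | None, str | None, str | None]:
    """Parse (plasmid_name, species, genus) from a RefSeq-style header.

    The species is taken as the first two tokens after the accession and
    the genus as the first; the plasmid name is the token following the
    word 'plasmid', with trailing punctuation stripped.  Headers too short
    to carry taxa yield absent values and a warning.
    """
    tokens = header.split()
    if len(tokens) < 3:
        warnings.warn(f"header too short for taxa: {header!r}")
        species = genus = None
    else:
        genus = tokens[1]
        species = f"{tokens[1]} {tokens[2]}"
    plasmid_name: str | None = None
    lowered = [t.lower().strip(_TRAILING_PUNCT) for t in tokens]
    for i, tok in enumerate(lowered[1:], start=1):
        if tok == "plasmid" and i + 1 < len(tokens):
            candidate = tokens[i + 1].strip(_TRAILING_PUNCT)
            if candidate:
                plasmid_name = candidate
            break
    return plasmid_name, species, genus


def load_taxonomy(path: str | Path) -> dict[str, tuple[str, str]]:
    """Load a genus -> (family, order) mapping from a tab-separated table."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = {c.lower(): c for c in df.columns}
    for needed in ("genus", "family", "order"):
        if needed not in cols:
            raise ValueError(f"taxonomy table missing column {needed!r}")
    return {
        row[cols["genus"]]: (row[cols["family"]], row[cols["order"]])
        for _, row in df.iterrows()
    }


class MetadataStore:
    """In-memory store of plasmid records, metadata and annotations."""

    def __init__(
        self,
        records: Sequence[PlasmidRecord],
        taxonomy: dict[str, tuple[str, str]] | None = None,
        cluster_of: dict[str, int | None] | None = None,
    ) -> None:
        self._records = {r.accession: r for r in records}
        self._meta: dict[str, PlasmidMeta] = {}
        self._hits: list[AnnotationHit] = []
        cluster_of = cluster_of or {}
        for rec in records:
            name, species, genus = extract_name_and_taxa(rec.header)
            self._meta[rec.accession] = PlasmidMeta(
                accession=rec.accession,
                length_bp=rec.length_bp,
                plasmid_name=name,
                species=species,
                genus=genus,
                cluster=cluster_of.get(rec.accession),
            )
        if taxonomy is not None:
            attach_taxonomy(self, taxonomy)

    # -- basic access ---------------------------------------------------

    @property
    def accessions(self) -> list[str]:
        return list(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, accession: str) -> bool:
        return accession in self._records

    def record_of(self, accession: str) -> PlasmidRecord:
        return self._records[accession]

    def meta_of(self, accession: str) -> PlasmidMeta:
        return self._meta[accession]

    def _set_meta(self, accession: str, meta: PlasmidMeta) -> None:
        self._meta[accession] = meta

    @property
    def annotation_hits(self) -> list[AnnotationHit]:
        return list(self._hits)

    def hits_of(self, accession: str) -> list[AnnotationHit]:
        return [h for h in self._hits if h.accession == accession]

    def add_hits(self, hits: Iterable[AnnotationHit]) -> None:
        self._hits.extend(hits)

    def all_selection(self) -> Selection:
        return Selection(frozenset(self._records), "all")

    # -- persistence ----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "records": [
                {
                    "accession": r.accession,
                    "header": r.header,
                    "sequence": r.sequence,
                }
                for r in self._records.values()
            ],
            "meta": [vars(m) | {} for m in self._meta.values()],
            "hits": [vars(h) | {} for h in self._hits],
        }
        Path(path).write_text(json.dumps(doc, sort_keys=True, separators=(",", ":")))

    @classmethod
    def from_json(cls, path: str | Path) -> "MetadataStore":
        doc = json.loads(Path(path).read_text())
        records = [
            PlasmidRecord(
                accession=r["accession"],
                header=r["header"],
                sequence=r["sequence"],
                length_bp=len(r["sequence"]),
            )
            for r in doc["records"]
        ]
        store = cls(records)
        store._meta = {m["accession"]: PlasmidMeta(**m) for m in doc["meta"]}
        store._hits = [AnnotationHit(**h) for h in doc["hits"]]
        return store


def attach_taxonomy(
    store: MetadataStore, mapping: dict[str, tuple[str, str]]
) -> None:
    """Fill family/order from a genus mapping; unmapped genera warn."""
    unmapped: set[str] = set()
    for acc in store.accessions:
        meta = store.meta_of(acc)
        if meta.genus is None:
            continue
        if meta.genus in mapping:
            family, order = mapping[meta.genus]
            store._set_meta(acc, replace(meta, family=family, order=order))
        else:
            unmapped.add(meta.genus)
    for genus in sorted(unmapped):
        warnings.warn(f"genus {genus!r} missing from taxonomy mapping")


_COLUMN_ALIASES = {
    "sequence": "sequence",
    "#file": "file",
    "file": "file",
    "start": "start",
    "end": "end",
    "gene": "gene",
    "%coverage": "coverage",
    "coverage_pct": "coverage",
    "%identity": "identity",
    "identity_pct": "identity",
    "database": "database",
    "accession": "db_accession",
    "aro": "aro",
    "strand": "strand",
}


def ingest_annotations(
    table: str | Path | pd.DataFrame, store: MetadataStore
) -> list[AnnotationHit]:
    """Ingest an ABRicate-style TSV of gene annotations into the store.

    Rows naming unknown plasmid accessions, or with coordinates outside
    the plasmid, are rejected with a warning; malformed numeric fields are
    an error naming the row.  For card rows the ARO ontology accession is
    captured when an ARO column is present.
    """
    if isinstance(table, (str, Path)):
        df = pd.read_csv(table, sep="\t", dtype=str)
    else:
        df = table.astype(str)
    renames = {
        c: _COLUMN_ALIASES[c.lower()]
        for c in df.columns
        if c.lower() in _COLUMN_ALIASES
    }
    df = df.rename(columns=renames)
    required = {"sequence", "start", "end", "gene", "coverage", "identity",
                "database", "db_accession"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    hits: list[AnnotationHit] = []
    for idx, row in df.iterrows():
        try:
            start = int(row["start"])
            end = int(row["end"])
            coverage = float(row["coverage"])
            identity = float(row["identity"])
        except ValueError as exc:
            raise ValueError(f"malformed numeric field in row {idx}: {exc}") from exc
        acc = row["sequence"]
        database = row["database"].lower()
        if database not in DATABASES:
            raise ValueError(f"unknown database {row['database']!r} in row {idx}")
        if acc not in store:
            warnings.warn(f"annotation row {idx} references unknown accession {acc!r}")
            continue
        length = store.meta_of(acc).length_bp
        if not (1 <= start <= end <= length):
            warnings.warn(
                f"annotation row {idx} coordinates {start}-{end} outside "
                f"{acc} (1-{length}); rejected"
            )
            continue
        if not (0 <= coverage <= 100 and 0 <= identity <= 100):
            warnings.warn(f"annotation row {idx} has out-of-range percent; rejected")
            continue
        aro = row.get("aro")
        if aro is not None and (pd.isna(aro) or aro in ("", "nan")):
            aro = None
        hits.append(
            AnnotationHit(
                accession=acc,
                database=database,  # type: ignore[arg-type]
                gene=row["gene"],
                db_accession=row["db_accession"],
                coverage=coverage,
                identity=identity,
                start_bp=start,
                end_bp=end,
                aro=aro if database == "card" else None,
                strand=row.get("strand") if "strand" in df.columns else None,
            )
        )
    store.add_hits(hits)
    return hits


# -- queries -----------------------------------------------------------


@dataclass(frozen=True)
class LengthQuery:
    lo: float = 0
    hi: float = float("inf")


@dataclass(frozen=True)
class TaxaQuery:
    level: Literal["species", "genus", "family", "order"]
    value: str


@dataclass(frozen=True)
class GeneQuery:
    database: str
    gene: str


@dataclass(frozen=True)
class FamilyQuery:
    """Plasmid family: a plasmidfinder replicon gene."""

    gene: str


Criterion = LengthQuery | TaxaQuery | GeneQuery | FamilyQuery


def query_select(store: MetadataStore, criterion: Criterion) -> Selection:
    """Accessions satisfying one criterion: length range, taxa, gene, family."""
    if isinstance(criterion, LengthQuery):
        hits = {
            acc
            for acc in store.accessions
            if criterion.lo <= store.meta_of(acc).length_bp <= criterion.hi
        }
        return Selection(frozenset(hits), f"length[{criterion.lo},{criterion.hi}]")
    if isinstance(criterion, TaxaQuery):
        hits = {
            acc
            for acc in store.accessions
            if getattr(store.meta_of(acc), criterion.level) == criterion.value
        }
        return Selection(frozenset(hits), f"{criterion.level}={criterion.value}")
    if isinstance(criterion, FamilyQuery):
        criterion = GeneQuery("plasmidfinder", criterion.gene)
    if isinstance(criterion, GeneQuery):
        db = criterion.database.lower()
        if db not in DATABASES:
            raise ValueError(f"unknown database {criterion.database!r}")
        hits = {
            h.accession
            for h in store.annotation_hits
            if h.database == db and h.gene == criterion.gene
        }
        return Selection(frozenset(hits), f"{db}:{criterion.gene}")
    raise TypeError(f"unsupported criterion {criterion!r}")


def combine_selections(
    selections: Sequence[Selection], mode: Literal["union", "intersection"]
) -> Selection:
    """Union or intersection of selections; provenance is concatenated."""
    if not selections:
        raise ValueError("no selections to combine")
    sets = [s.accessions for s in selections]
    if mode == "union":
        combined = frozenset().union(*sets)
        joiner = " | "
    elif mode == "intersection":
        combined = frozenset.intersection(*sets)
        joiner = " & "
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return Selection(combined, joiner.join(s.provenance for s in selections))


def summary_table(store: MetadataStore, selection: Selection) -> pd.DataFrame:
    """One row per selected plasmid: all metadata plus per-database gene lists."""
    rows = []
    for acc in sorted(selection.accessions):
        meta = store.meta_of(acc)
        row: dict[str, object] = dict(vars(meta))
        for db in DATABASES:
            genes = sorted(
                {h.gene for h in store.hits_of(acc) if h.database == db}
            )
            row[f"{db}_genes"] = ";".join(genes)
        rows.append(row)
    columns = [
        "accession", "plasmid_name", "species", "genus", "family", "order",
        "length_bp", "cluster",
    ] + [f"{db}_genes" for db in DATABASES]
    return pd.DataFrame(rows, columns=columns)


def export_sequences(
    store: MetadataStore, selection: Selection, path: str | Path
) -> None:
    """Write the selected records, with their original headers, as FASTA."""
    records = [store.record_of(acc) for acc in sorted(selection.accessions)]
    write_fasta(records, path)


def length_histogram(
    store: MetadataStore, selection: Selection, bins: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of selected plasmid lengths: (bin edges, counts)."""
    if bins < 1:
        raise ValueError("bins must be >= 1")
    if not selection.accessions:
        raise ValueError("cannot histogram an empty selection")
    lengths = np.array(
        [store.meta_of(acc).length_bp for acc in selection.accessions]
    )
    counts, edges = np.histogram(lengths, bins=bins)
    return edges, counts
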