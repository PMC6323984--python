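"""Deterministic synthetic plasmid collections with known ground truth.

Everything the other modules consume can be generated here without any
download: a multi-FASTA of plasmid "families" (descendants of a random
ancestor under substitution-only evolution at a chosen per-base rate),
planted duplicates and gene-level decoy headers for the curation filters,
an ABRicate-style annotation table, a genus taxonomy table, and
sample-hit documents for the scoring pipeline.  A manifest records the
ground truth -- expected filter decisions, exact canonical k-mer Jaccard
for every within-family pair, expected clusters and singletons, header
parses, annotation placements -- so downstream results can be verified
without recomputation.

Evolution is substitution-only (no indels): the exact Jaccard stays cheap
to compute and the Mash distance of a pair tracks its substitution rate
closely, which is what the network thresholds are calibrated against.
Defaults mirror the network's study conditions: k=21 sketches, families
diverged at a 2% per-base rate (well inside the d < 0.1 link threshold)
plus unrelated random plasmids that stay singletons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .curate import PlasmidRecord, write_fasta
from .network import PlasmidGraph
from .scoring import plasmid_weight
from .sketch import canonical_kmer_codes

__all__ = [
    "FamilySpec",
    "FixtureManifest",
    "SyntheticCollection",
    "random_sequence",
    "mutate_sequence",
    "exact_jaccard",
    "generate_plasmid_family",
    "generate_collection",
    "generate_annotation_table",
    "taxonomy_table",
    "generate_sample_hits",
    "write_fixture_files",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# host pool: (genus, species epithet, family, order)
_HOSTS = [
    ("Escherichia", "coli", "Enterobacteriaceae", "Enterobacterales"),
    ("Klebsiella", "pneumoniae", "Enterobacteriaceae", "Enterobacterales"),
    ("Salmonella", "enterica", "Enterobacteriaceae", "Enterobacterales"),
    ("Staphylococcus", "aureus", "Staphylococcaceae", "Bacillales"),
    ("Enterococcus", "faecium", "Enterococcaceae", "Lactobacillales"),
    ("Pseudomonas", "aeruginosa", "Pseudomonadaceae", "Pseudomonadales"),
]

# (database, gene, db accession, ARO id or None)
_GENE_POOL = [
    ("resfinder", "blaKPC-2", "AY034847", None),
    ("resfinder", "blaTEM-1B", "AY458016", None),
    ("resfinder", "tet(A)", "AJ517790", None),
    ("resfinder", "sul1", "U12338", None),
    ("card", "NDM-1", "ARO:3000589", "ARO:3000589"),
    ("card", "mecA", "ARO:3000617", "ARO:3000617"),
    ("vfdb", "hlyA", "VFG000874", None),
    ("vfdb", "cnf1", "VFG000238", None),
    ("plasmidfinder", "IncFII", "AY458016", None),
    ("plasmidfinder", "IncA/C2", "JN157804", None),
    ("plasmidfinder", "rep7a", "AB037671", None),
]


@dataclass(frozen=True)
class FamilySpec:
    """One plasmid family: descendants of a common ancestor."""

    ancestral_length: int = 8000
    n: int = 3
    rate: float = 0.02

    def __post_init__(self) -> None:
        if self.ancestral_length < 1000:
            raise ValueError("ancestral_length must be >= 1000")
        if not 0.0 <= self.rate <= 0.2:
            raise ValueError("rate must be in [0, 0.2]")


@dataclass
class FixtureManifest:
    """Ground truth for a generated collection."""

    seed: int
    k: int
    records: dict[str, dict] = field(default_factory=dict)
    families: list[dict] = field(default_factory=list)
    exact_jaccard: dict[str, float] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)
    expected_clusters: list[list[str]] = field(default_factory=list)
    expected_singletons: list[str] = field(default_factory=list)
    annotations: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def expected_reason(self, accession: str) -> str:
        return self.records[accession]["expected_reason"]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(vars(self), sort_keys=True, separators=(",", ":"))
        )


@dataclass
class SyntheticCollection:
    """Generated records (curation input) plus their manifest."""

    records: list[PlasmidRecord]
    manifest: FixtureManifest
    taxonomy: dict[str, tuple[str, str]]


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def mutate_sequence(
    rng: np.random.Generator, sequence: str, rate: float
) -> str:
    """Independent per-base substitutions at the given rate (no indels)."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    # substitute with a uniformly chosen *different* base
    shifts = rng.integers(1, 4, size=int(hit.sum()))
    idx = {b: i for i, b in enumerate(_BASES)}
    codes = np.array([idx[b] for b in arr[hit]], dtype=np.int64)
    arr[hit] = _BASES[(codes + shifts) % 4]
    return arr.tobytes().decode("ascii")


def exact_jaccard(seq_a: str, seq_b: str, k: int) -> float:
    """True Jaccard index of the canonical k-mer sets (direct set operations)."""
    a = canonical_kmer_codes(seq_a, k)
    b = canonical_kmer_codes(seq_b, k)
    inter = np.intersect1d(a, b, assume_unique=True).size
    union = a.size + b.size - inter
    return inter / union if union else 0.0


def _header(acc: str, host: tuple[str, str, str, str], name: str | None) -> str:
    genus, species, _, _ = host
    if name is None:
        return f"{acc} {genus} {species} unnamed sequence"
    return f"{acc} {genus} {species} strain S1 plasmid {name}, complete sequence"


def generate_plasmid_family(
    rng: np.random.Generator,
    spec: FamilySpec,
    family_id: int,
    host: tuple[str, str, str, str],
    k: int = 21,
    acc_start: int = 1,
) -> tuple[list[PlasmidRecord], dict, dict[str, float]]:
    """One ancestor, ``spec.n`` descendants, exact pairwise Jaccard values.

    Descendants are mutated independently from the ancestor, so the
    expected pairwise distance is roughly twice the per-branch rate.
    """
    ancestor = random_sequence(rng, spec.ancestral_length)
    records = []
    for i in range(spec.n):
        acc = f"NZ_SYN{family_id:02d}{acc_start + i:03d}.1"
        name = f"pSYN{family_id:02d}-{i + 1}"
        seq = mutate_sequence(rng, ancestor, spec.rate)
        records.append(
            PlasmidRecord(
                accession=acc,
                header=_header(acc, host, name),
                sequence=seq,
                length_bp=len(seq),
            )
        )
    jaccard = {
        f"{a.accession}|{b.accession}": exact_jaccard(a.sequence, b.sequence, k)
        for a, b in combinations(records, 2)
    }
    family_row = {
        "id": family_id,
        "ancestral_length": spec.ancestral_length,
        "n": spec.n,
        "rate": spec.rate,
        "members": [r.accession for r in records],
    }
    return records, family_row, jaccard


def generate_collection(
    seed: int,
    families: Sequence[FamilySpec] = (FamilySpec(), FamilySpec(), FamilySpec()),
    n_unrelated: int = 3,
    unrelated_length: int = 6000,
    n_duplicates: int = 1,
    n_decoys: int = 3,
    n_excluded: int = 1,
    k: int = 21,
) -> SyntheticCollection:
    """Full curation-input collection with manifest.

    Contains the plasmid families, unrelated random plasmids (expected
    singletons), planted sequence duplicates (expected ``duplicate``),
    gene-level decoy headers (expected ``keyword_origin`` /
    ``keyword_cds``, plus one rescued multi-cds header that is kept), and
    an exclusion list drawn from the unrelated plasmids.
    """
    rng = np.random.default_rng(seed)
    manifest = FixtureManifest(seed=seed, k=k)
    records: list[PlasmidRecord] = []

    def register(rec: PlasmidRecord, role: str, reason: str,
                 family: int | None = None, name: str | None = None,
                 host: tuple | None = None) -> None:
        records.append(rec)
        manifest.records[rec.accession] = {
            "header": rec.header,
            "length_bp": rec.length_bp,
            "role": role,
            "family": family,
            "expected_reason": reason,
            "plasmid_name": name,
            "species": f"{host[0]} {host[1]}" if host else None,
            "genus": host[0] if host else None,
        }

    for fid, spec in enumerate(families, start=1):
        host = _HOSTS[(fid - 1) % len(_HOSTS)]
        fam_records, fam_row, jaccard = generate_plasmid_family(
            rng, spec, fid, host, k=k
        )
        manifest.families.append(fam_row)
        manifest.exact_jaccard.update(jaccard)
        for i, rec in enumerate(fam_records):
            register(rec, "family", "kept", family=fid,
                     name=f"pSYN{fid:02d}-{i + 1}", host=host)

    unrelated_accs: list[str] = []
    for i in range(n_unrelated):
        host = _HOSTS[(len(families) + i) % len(_HOSTS)]
        acc = f"NZ_SYNU{i + 1:03d}.1"
        name = f"pUNR{i + 1}"
        seq = random_sequence(rng, unrelated_length)
        rec = PlasmidRecord(acc, _header(acc, host, name), seq, len(seq))
        register(rec, "unrelated", "kept", name=name, host=host)
        unrelated_accs.append(acc)

    family_members = [m for f in manifest.families for m in f["members"]]
    dup_sources = list(rng.choice(family_members, size=n_duplicates, replace=False))
    for i, source in enumerate(dup_sources):
        host = _HOSTS[i % len(_HOSTS)]
        acc = f"NZ_SYND{i + 1:03d}.1"
        src = next(r for r in records if r.accession == source)
        rec = PlasmidRecord(
            acc, _header(acc, host, f"pDUP{i + 1}"), src.sequence, src.length_bp
        )
        register(rec, "duplicate", "duplicate", name=f"pDUP{i + 1}", host=host)

    decoy_templates = [
        ("decoy_origin", "keyword_origin", _HOSTS[0],
         "{acc} {genus} {species} replication origin of strain RO{i}"),
        ("decoy_cds", "keyword_cds", _HOSTS[1],
         "{acc} {genus} {species} hypothetical protein cds"),
        ("decoy_multicds", "kept", _HOSTS[2],
         "{acc} {genus} {species} repA cds traX cds mobilization region"),
    ]
    for i in range(n_decoys):
        role, reason, host, template = decoy_templates[i % len(decoy_templates)]
        acc = f"NZ_SYNX{i + 1:03d}.1"
        seq = random_sequence(rng, 1500)
        header = template.format(acc=acc, genus=host[0], species=host[1], i=i + 1)
        rec = PlasmidRecord(acc, header, seq, len(seq))
        register(rec, role, reason, host=host)

    if n_excluded > n_unrelated:
        raise ValueError("cannot exclude more accessions than unrelated plasmids")
    excluded = unrelated_accs[:n_excluded]
    manifest.excluded = list(excluded)
    for acc in excluded:
        manifest.records[acc]["expected_reason"] = "exclusion_list"

    # expected network structure among curated survivors at the default
    # thresholds: each family is one cluster, everything else a singleton
    manifest.expected_clusters = [list(f["members"]) for f in manifest.families]
    manifest.expected_singletons = sorted(
        acc
        for acc, row in manifest.records.items()
        if row["expected_reason"] == "kept" and row["family"] is None
    )

    taxonomy = {h[0]: (h[2], h[3]) for h in _HOSTS}
    return SyntheticCollection(records=records, manifest=manifest, taxonomy=taxonomy)


def generate_annotation_table(
    collection: SyntheticCollection,
    seed: int,
    hits_per_plasmid: tuple[int, int] = (0, 3),
) -> pd.DataFrame:
    """ABRicate-style annotation TSV rows for the collection's kept plasmids.

    Each kept plasmid receives a uniform number of gene annotations from
    the pooled resfinder/card/vfdb/plasmidfinder genes, at random
    non-overlapping-agnostic positions; the manifest records which genes
    landed on which plasmid per database.
    """
    rng = np.random.default_rng(seed)
    manifest = collection.manifest
    rows = []
    for acc, row in manifest.records.items():
        if row["expected_reason"] != "kept":
            continue
        n_hits = int(rng.integers(hits_per_plasmid[0], hits_per_plasmid[1] + 1))
        chosen = rng.choice(len(_GENE_POOL), size=n_hits, replace=False)
        truth: dict[str, list[str]] = {}
        for gi in chosen:
            db, gene, db_acc, aro = _GENE_POOL[int(gi)]
            max_len = min(1500, row["length_bp"] - 10)
            gene_len = int(rng.integers(400, max(401, max_len)))
            start = int(rng.integers(1, row["length_bp"] - gene_len + 1))
            rows.append(
                {
                    "SEQUENCE": acc,
                    "START": start,
                    "END": start + gene_len - 1,
                    "STRAND": rng.choice(["+", "-"]),
                    "GENE": gene,
                    "%COVERAGE": round(float(rng.uniform(80, 100)), 2),
                    "%IDENTITY": round(float(rng.uniform(90, 100)), 2),
                    "DATABASE": db,
                    "ACCESSION": db_acc,
                    "ARO": aro if db == "card" else None,
                }
            )
            truth.setdefault(db, []).append(gene)
        if truth:
            manifest.annotations[acc] = {
                db: sorted(genes) for db, genes in truth.items()
            }
    return pd.DataFrame(
        rows,
        columns=["SEQUENCE", "START", "END", "STRAND", "GENE", "%COVERAGE",
                 "%IDENTITY", "DATABASE", "ACCESSION", "ARO"],
    )


def taxonomy_table(collection: SyntheticCollection) -> pd.DataFrame:
    rows = [
        {"genus": genus, "family": fam, "order": order}
        for genus, (fam, order) in sorted(collection.taxonomy.items())
    ]
    return pd.DataFrame(rows, columns=["genus", "family", "order"])


_METRIC_RANGES = {
    "mapping": {"cov": (0.5, 1.0)},
    "screen": {"ids": (0.8, 1.0)},
    "dist": {"idd": (0.85, 1.0), "sh": (0.2, 1.0)},
}


def generate_sample_hits(
    graph: PlasmidGraph,
    mode: Literal["mapping", "screen", "dist"],
    n_hits: int,
    seed: int,
    sample_name: str = "synthetic_sample",
) -> tuple[dict, set[str]]:
    """A sample-hits JSON document plus its ground-truth retained set.

    Metrics are uniform per mode; the retained set is computed here by the
    brute-force non-loser rule (iterate every graph edge, collect hits
    that never lose a strict comparison) for cross-checking redundancy
    removal.
    """
    rng = np.random.default_rng(seed)
    if n_hits > len(graph.nodes):
        raise ValueError("more hits requested than graph nodes")
    chosen = sorted(rng.choice(sorted(graph.nodes), size=n_hits, replace=False))
    hits: dict[str, dict] = {}
    for i, acc in enumerate(chosen):
        metrics = {
            name: round(float(rng.uniform(lo, hi)), 6)
            for name, (lo, hi) in _METRIC_RANGES[mode].items()
        }
        if mode == "dist":
            metrics["contig"] = f"contig_{i + 1}"
        hits[acc] = metrics
    doc = {"sample": sample_name, "mode": mode, "hits": hits}

    # brute-force ground truth: a hit survives iff no linked hit outweighs it
    def weight(acc: str) -> float:
        m = hits[acc]
        from .scoring import HitRecord  # local to keep the oracle explicit

        rec = HitRecord(**{k: v for k, v in m.items() if k != "contig"})
        return plasmid_weight(rec, graph.length_of[acc], mode)

    losers = set()
    for edge in graph.edges:
        a, b = edge.accession_a, edge.accession_b
        if a in hits and b in hits:
            if weight(a) > weight(b):
                losers.add(b)
            elif weight(b) > weight(a):
                losers.add(a)
    return doc, set(hits) - losers


def write_fixture_files(
    collection: SyntheticCollection, out_dir: str | Path, seed: int
) -> dict[str, Path]:
    """Write the full fixture set as plain-text files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "plasmids.fasta",
        "exclusions": out / "exclusions.txt",
        "annotations": out / "annotations.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "manifest": out / "manifest.json",
    }
    write_fasta(collection.records, paths["fasta"])
    paths["exclusions"].write_text(
        "# crowd-curation exclusion list\n"
        + "".join(f"{acc}\n" for acc in collection.manifest.excluded)
    )
    annotations = generate_annotation_table(collection, seed)
    annotations.to_csv(paths["annotations"], sep="\t", index=False)
    taxonomy_table(collection).to_csv(paths["taxonomy"], sep="\t", index=False)
    collection.manifest.to_json(paths["manifest"])
    return paths
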