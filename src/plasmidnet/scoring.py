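"""Scoring of externally detected plasmid hits and redundancy removal.

Plasmid-detection pipelines report, per candidate plasmid, either the
proportion of the plasmid covered by reads (``mapping`` mode), a
containment-screen identity (``screen`` mode), or an assembly-to-plasmid
sketch comparison (``dist`` mode: a similarity ``idd = 1 - mash distance``
and the proportion of shared sketch hashes ``sh``).  Because plasmids are
modular and the reference collection is redundant, several closely related
plasmids typically score at once.  For every pair of hits linked in the
relatedness network a signed score

    mapping:  S = cov_1 * len_1 - cov_2 * len_2
    screen:   S = ids_1 * len_1 - ids_2 * len_2
    dist:     S = idd_1 * sh_1 * len_1 - idd_2 * sh_2 * len_2

is computed; the hit on the losing side of any comparison (strictly
smaller weight) is dropped, ties keep both.  The shared-hash factor in
dist mode down-weights plasmids that merely share a small highly similar
subsequence with the assembly.  Elimination is one-shot per edge and
order-independent: a hit survives iff no linked hit has strictly greater
weight.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .network import PlasmidGraph

__all__ = [
    "Mode",
    "HitRecord",
    "SampleHits",
    "ScoreDecision",
    "load_sample",
    "sample_to_dict",
    "plasmid_weight",
    "pair_score",
    "remove_redundant",
    "heatmap_matrix",
    "write_retention_report",
]

Mode = Literal["mapping", "screen", "dist"]

_MODE_FIELDS: dict[str, tuple[str, ...]] = {
    "mapping": ("cov",),
    "screen": ("ids",),
    "dist": ("idd", "sh"),
}


@dataclass(frozen=True)
class HitRecord:
    """Per-plasmid detection metrics; exactly the fields of the mode are set.

    cov: proportion of plasmid positions covered >= 1x (mapping).
    ids: containment-screen identity proportion (screen).
    idd: 1 - mash distance of assembly vs plasmid; sh: shared-hash
    proportion; contig: optional source-contig label (dist).
    """

    cov: float | None = None
    ids: float | None = None
    idd: float | None = None
    sh: float | None = None
    contig: str | None = None


@dataclass
class SampleHits:
    """One imported sample: name, pipeline mode, per-accession hits."""

    sample_name: str
    mode: Mode
    hits: dict[str, HitRecord]
    unknown: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class ScoreDecision:
    pair: tuple[str, str]
    S: float
    outcome: Literal["keep_a", "keep_b", "keep_both"]


def _normalize_metric(value: float, name: str, accession: str) -> float:
    if 0.0 <= value <= 1.0:
        return float(value)
    if 1.0 < value <= 100.0:
        warnings.warn(
            f"{name}={value} for {accession} looks like a percentage; "
            "normalizing to a proportion"
        )
        return float(value) / 100.0
    raise ValueError(f"{name}={value} for {accession} outside [0, 1] / [0, 100]")


def load_sample(
    document: dict | str | Path, graph: PlasmidGraph | None = None
) -> SampleHits:
    """Load a sample-hits JSON document and validate it against the graph.

    Expected shape: ``{"sample": str, "mode": str, "hits": {accession:
    {metric fields}}}``.  Metrics must lie in [0, 1]; values in (1, 100]
    are taken to be percentages and normalized with a warning.  Hits on
    accessions absent from the graph are retained but flagged unknown.
    """
    if isinstance(document, (str, Path)):
        document = json.loads(Path(document).read_text())
    try:
        sample_name = document["sample"]
        mode = document["mode"]
        raw_hits = document["hits"]
    except KeyError as exc:
        raise ValueError(f"sample document missing field {exc}") from exc
    if mode not in _MODE_FIELDS:
        raise ValueError(f"unknown mode {mode!r}")
    hits: dict[str, HitRecord] = {}
    unknown: set[str] = set()
    for acc, metrics in raw_hits.items():
        fields: dict[str, object] = {}
        for name in _MODE_FIELDS[mode]:
            if name not in metrics:
                raise ValueError(
                    f"hit {acc!r} missing field {name!r} required by mode {mode!r}"
                )
            fields[name] = _normalize_metric(float(metrics[name]), name, acc)
        if mode == "dist" and "contig" in metrics:
            fields["contig"] = str(metrics["contig"])
        hits[acc] = HitRecord(**fields)  # type: ignore[arg-type]
        if graph is not None and acc not in graph.length_of:
            unknown.add(acc)
            warnings.warn(f"hit accession {acc!r} not present in the graph")
    return SampleHits(sample_name=sample_name, mode=mode, hits=hits, unknown=unknown)


def sample_to_dict(sample: SampleHits) -> dict:
    """Serialize a sample back to the import-document shape (lossless)."""
    hits: dict[str, dict] = {}
    for acc, hit in sample.hits.items():
        metrics = {
            name: getattr(hit, name) for name in _MODE_FIELDS[sample.mode]
        }
        if sample.mode == "dist" and hit.contig is not None:
            metrics["contig"] = hit.contig
        hits[acc] = metrics
    return {"sample": sample.sample_name, "mode": sample.mode, "hits": hits}


def plasmid_weight(hit: HitRecord, length_bp: int, mode: Mode) -> float:
    """Metric-weighted length of one hit (the per-plasmid term of the score)."""
    if mode == "mapping":
        return hit.cov * length_bp
    if mode == "screen":
        return hit.ids * length_bp
    if mode == "dist":
        return hit.idd * hit.sh * length_bp
    raise ValueError(f"unknown mode {mode!r}")


def pair_score(
    hit_a: HitRecord,
    hit_b: HitRecord,
    len_a: int,
    len_b: int,
    mode: Mode,
    pair: tuple[str, str] = ("P1", "P2"),
) -> ScoreDecision:
    """Signed score S = w(a) - w(b); positive keeps a, negative b, zero both."""
    s = plasmid_weight(hit_a, len_a, mode) - plasmid_weight(hit_b, len_b, mode)
    outcome = "keep_a" if s > 0 else "keep_b" if s < 0 else "keep_both"
    return ScoreDecision(pair=pair, S=s, outcome=outcome)


def remove_redundant(
    sample: SampleHits, graph: PlasmidGraph
) -> tuple[set[str], list[ScoreDecision]]:
    """Survivor set after pairwise elimination over linked hits.

    For every graph edge whose endpoints are both hits a score decision is
    computed; a hit is retained iff it never loses a comparison.  Hits
    with no linked hit (including accessions unknown to the graph) are
    always retained, and ties retain both, so at least one hit of every
    linked clique survives.
    """
    decisions: list[ScoreDecision] = []
    losers: set[str] = set()
    for edge in graph.edges:
        a, b = edge.accession_a, edge.accession_b
        if a not in sample.hits or b not in sample.hits:
            continue
        decision = pair_score(
            sample.hits[a],
            sample.hits[b],
            graph.length_of[a],
            graph.length_of[b],
            sample.mode,
            pair=(a, b),
        )
        decisions.append(decision)
        if decision.outcome == "keep_a":
            losers.add(b)
        elif decision.outcome == "keep_b":
            losers.add(a)
    retained = set(sample.hits) - losers
    return retained, decisions


def heatmap_matrix(
    samples: Sequence[SampleHits],
    *,
    retained_only: bool = False,
    graph: PlasmidGraph | None = None,
    values: Literal["metric", "weight"] = "metric",
) -> pd.DataFrame:
    """Samples x accessions matrix for cross-sample comparison.

    Rows follow input order and are labelled "sample (mode)"; columns are
    the lexicographically sorted union of hit accessions; entries are each
    sample's native metric (cov / ids / idd*sh) or, with
    ``values="weight"``, the metric-weighted length.  Absent hits are 0.
    With ``retained_only`` the redundancy-removal survivor sets (which
    require ``graph``) define the entries kept per row.
    """
    if not samples:
        raise ValueError("no samples to tabulate")
    if retained_only and graph is None:
        raise ValueError("retained_only requires the plasmid graph")
    if values == "weight" and graph is None:
        raise ValueError("weight values require the plasmid graph")
    columns = sorted({acc for s in samples for acc in s.hits})
    rows = []
    index = []
    for sample in samples:
        keep = (
            remove_redundant(sample, graph)[0] if retained_only else set(sample.hits)
        )
        row = {}
        for acc in columns:
            hit = sample.hits.get(acc)
            if hit is None or acc not in keep:
                row[acc] = 0.0
            elif values == "weight":
                row[acc] = plasmid_weight(hit, graph.length_of[acc], sample.mode)
            elif sample.mode == "mapping":
                row[acc] = hit.cov
            elif sample.mode == "screen":
                row[acc] = hit.ids
            else:
                row[acc] = hit.idd * hit.sh
        rows.append(row)
        index.append(f"{sample.sample_name} ({sample.mode})")
    return pd.DataFrame(rows, index=index, columns=columns)


def write_retention_report(
    sample: SampleHits,
    graph: PlasmidGraph,
    path: str | Path,
) -> set[str]:
    """TSV report: accession, weight, retained/dropped, eliminator if dropped."""
    retained, decisions = remove_redundant(sample, graph)
    eliminator: dict[str, str] = {}
    for dec in decisions:
        a, b = dec.pair
        if dec.outcome == "keep_a" and b not in eliminator:
            eliminator[b] = a
        elif dec.outcome == "keep_b" and a not in eliminator:
            eliminator[a] = b
    lines = ["accession\tweight\toutcome\teliminated_by"]
    for acc in sorted(sample.hits):
        length = graph.length_of.get(acc)
        weight = (
            plasmid_weight(sample.hits[acc], length, sample.mode)
            if length is not None
            else float("nan")
        )
        outcome = "retained" if acc in retained else "dropped"
        lines.append(f"{acc}\t{weight!r}\t{outcome}\t{eliminator.get(acc, '')}")
    Path(path).write_text("\n".join(lines) + "\n")
    return retained
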