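"""Corpus I/O: abstract records, annotation sets, folds and bundles.

Readers cover the two standard PubMed export dialects — PubMed XML
(``PubmedArticleSet``) and plain MEDLINE (``PMID- / TI  - / AB  - …`` tag
lines, parsed with :mod:`Bio.Medline`) — extracting for each article its
PMID, title, abstract, MeSH descriptors, chemical-substance list, journal
and year.  Annotation files map PMIDs to sets of taxonomy node labels; an
explicit empty label set marks a document that was reviewed but judged
irrelevant for the taxonomy (such documents are negatives for every node).

A *corpus bundle* is a directory holding a canonical MEDLINE records file,
a TSV annotation file and a JSON manifest; the bundle writers are
byte-deterministic so that write -> read -> write round-trips identically.
"""

from __future__ import annotations

import io
import json
import os
import re
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

from .taxonomy import Taxonomy

__all__ = [
    "DocumentRecord",
    "AnnotationSet",
    "FoldAssignment",
    "CorpusError",
    "read_pubmed_records",
    "read_medline_records",
    "read_pubmed_xml_records",
    "write_medline_records",
    "read_annotations",
    "write_annotations",
    "split_folds",
    "write_corpus_bundle",
    "read_corpus_bundle",
]


class CorpusError(ValueError):
    """Raised for malformed corpus, annotation or bundle inputs."""


@dataclass
class DocumentRecord:
    """One PubMed abstract record with its classification metadata."""

    pmid: str
    title: str = ""
    abstract: str = ""
    mesh_terms: list[str] = field(default_factory=list)
    chemicals: list[str] = field(default_factory=list)
    journal: str = ""
    year: int = 0

    def __post_init__(self) -> None:
        if not self.pmid:
            raise CorpusError("record has empty pmid")

    @property
    def has_abstract(self) -> bool:
        return bool(self.abstract.strip())


@dataclass
class AnnotationSet:
    """PMID -> set of taxonomy node slugs; empty set = reviewed, irrelevant."""

    labels: dict[str, set[str]]
    annotator: str = "default"

    @property
    def pmids(self) -> list[str]:
        return list(self.labels)

    def annotated_pmids(self) -> list[str]:
        return [p for p, labs in self.labels.items() if labs]

    def irrelevant_pmids(self) -> list[str]:
        return [p for p, labs in self.labels.items() if not labs]


@dataclass
class FoldAssignment:
    k: int
    seed: int
    assignment: dict[str, int]

    def fold(self, index: int) -> list[str]:
        return [p for p, f in self.assignment.items() if f == index]

    def sizes(self) -> list[int]:
        counts = [0] * self.k
        for f in self.assignment.values():
            counts[f] += 1
        return counts


# ----------------------------------------------------------------------
# record readers / writers


def _dedupe(records: list[DocumentRecord]) -> list[DocumentRecord]:
    by_pmid: dict[str, DocumentRecord] = {}
    for rec in records:
        if rec.pmid in by_pmid:
            warnings.warn(
                f"duplicate PMID {rec.pmid}; keeping the last record",
                stacklevel=3,
            )
        by_pmid[rec.pmid] = rec
    return list(by_pmid.values())


def _year_from_dp(dp: str) -> int:
    m = re.search(r"\d{4}", dp)
    return int(m.group(0)) if m else 0


def read_medline_records(stream: IO[str] | str) -> list[DocumentRecord]:
    """Parse plain MEDLINE tag-format records."""
    from Bio import Medline

    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[DocumentRecord] = []
    for raw in Medline.parse(stream):
        pmid = raw.get("PMID", "")
        if not pmid:
            raise CorpusError(f"MEDLINE record without PMID: {dict(raw)!r}")
        records.append(
            DocumentRecord(
                pmid=pmid,
                title=raw.get("TI", ""),
                abstract=raw.get("AB", ""),
                mesh_terms=list(raw.get("MH", [])),
                chemicals=list(raw.get("RN", [])),
                journal=raw.get("JT", ""),
                year=_year_from_dp(raw.get("DP", "")),
            )
        )
    return _dedupe(records)


def read_pubmed_xml_records(stream: IO[bytes] | IO[str] | str | bytes) -> list[DocumentRecord]:
    """Parse PubMed XML (``PubmedArticleSet``) records."""
    from lxml import etree

    if isinstance(stream, str):
        stream = io.BytesIO(stream.encode("utf-8"))
    elif isinstance(stream, bytes):
        stream = io.BytesIO(stream)
    try:
        tree = etree.parse(stream)
    except etree.XMLSyntaxError as exc:
        raise CorpusError(f"malformed PubMed XML: {exc}") from exc
    records: list[DocumentRecord] = []
    for citation in tree.iter("MedlineCitation"):
        pmid = citation.findtext("PMID", default="").strip()
        if not pmid:
            raise CorpusError("MedlineCitation without PMID element")
        article = citation.find("Article")
        title = ""
        abstract = ""
        journal = ""
        year = 0
        if article is not None:
            title = "".join(article.find("ArticleTitle").itertext()) if (
                article.find("ArticleTitle") is not None
            ) else ""
            parts = [
                "".join(el.itertext())
                for el in article.findall("Abstract/AbstractText")
            ]
            abstract = " ".join(p for p in parts if p)
            journal = article.findtext("Journal/Title", default="")
            ytext = article.findtext(
                "Journal/JournalIssue/PubDate/Year", default=""
            ) or article.findtext(
                "Journal/JournalIssue/PubDate/MedlineDate", default=""
            )
            year = _year_from_dp(ytext)
        mesh = [
            el.text or ""
            for el in citation.findall(
                "MeshHeadingList/MeshHeading/DescriptorName"
            )
        ]
        chems = [
            el.text or ""
            for el in citation.findall("ChemicalList/Chemical/NameOfSubstance")
        ]
        records.append(
            DocumentRecord(
                pmid=pmid,
                title=title.strip(),
                abstract=abstract.strip(),
                mesh_terms=[m for m in mesh if m],
                chemicals=[c for c in chems if c],
                journal=journal,
                year=year,
            )
        )
    return _dedupe(records)


def read_pubmed_records(stream: IO | str | bytes) -> list[DocumentRecord]:
    """Dispatch on dialect: PubMed XML if the payload starts with ``<``,
    otherwise plain MEDLINE tag format."""
    if hasattr(stream, "read"):
        payload = stream.read()
    else:
        payload = stream
    if isinstance(payload, bytes):
        head = payload.lstrip()[:1]
        if head == b"<":
            return read_pubmed_xml_records(payload)
        payload = payload.decode("utf-8")
    if payload.lstrip()[:1] == "<":
        return read_pubmed_xml_records(payload)
    return read_medline_records(payload)


def _oneline(text: str) -> str:
    return " ".join(str(text).split())


def write_medline_records(
    records: Sequence[DocumentRecord], stream: IO[str]
) -> None:
    """Write records in canonical single-line MEDLINE tag format."""
    for i, rec in enumerate(records):
        if i:
            stream.write("\n")
        stream.write(f"PMID- {rec.pmid}\n")
        if rec.year:
            stream.write(f"DP  - {rec.year}\n")
        if rec.title:
            stream.write(f"TI  - {_oneline(rec.title)}\n")
        if rec.abstract:
            stream.write(f"AB  - {_oneline(rec.abstract)}\n")
        if rec.journal:
            stream.write(f"JT  - {_oneline(rec.journal)}\n")
        for mh in rec.mesh_terms:
            stream.write(f"MH  - {_oneline(mh)}\n")
        for rn in rec.chemicals:
            stream.write(f"RN  - {_oneline(rn)}\n")


# ----------------------------------------------------------------------
# annotations


def read_annotations(
    stream: IO[str] | str,
    taxonomy: Taxonomy,
    annotator: str = "default",
) -> AnnotationSet:
    """Read a TSV (``pmid<TAB>semicolon-joined labels``) or JSON annotation
    file.  Labels are resolved against *taxonomy* (slug or display name);
    an empty label field marks an irrelevant (reviewed, unannotated) doc."""
    if isinstance(stream, str):
        text = stream
    else:
        text = stream.read()
    text_stripped = text.lstrip()
    labels: dict[str, set[str]] = {}
    if text_stripped.startswith("{"):
        payload = json.loads(text)
        annotator = payload.get("annotator", annotator)
        rows = payload.get("labels", {}).items()
    else:
        rows = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if "\t" not in line:
                raise CorpusError(
                    f"annotation line {lineno} has no tab separator: {line!r}"
                )
            pmid, _, labelfield = line.partition("\t")
            names = [x for x in labelfield.strip().split(";") if x]
            rows.append((pmid.strip(), names))
    for pmid, names in rows:
        if pmid in labels:
            raise CorpusError(f"duplicate annotation rows for pmid {pmid}")
        try:
            labels[pmid] = {taxonomy.resolve(n) for n in names}
        except Exception as exc:
            raise CorpusError(f"pmid {pmid}: {exc}") from exc
    return AnnotationSet(labels=labels, annotator=annotator)


def write_annotations(annotations: AnnotationSet, stream: IO[str]) -> None:
    """Write the canonical TSV form (pmids sorted, labels sorted)."""
    for pmid in sorted(annotations.labels):
        labs = ";".join(sorted(annotations.labels[pmid]))
        stream.write(f"{pmid}\t{labs}\n")


# ----------------------------------------------------------------------
# folds


def split_folds(pmids: Sequence[str], k: int, seed: int) -> FoldAssignment:
    """Deterministic seeded shuffle + round-robin fold assignment.

    Fold sizes differ by at most one; identical inputs reproduce the
    identical assignment.
    """
    if k < 2:
        raise CorpusError(f"fold count k must be >= 2, got {k}")
    pmids = list(pmids)
    if len(set(pmids)) != len(pmids):
        raise CorpusError("duplicate pmids in fold split")
    if k > len(pmids):
        raise CorpusError(
            f"cannot split {len(pmids)} documents into {k} folds"
        )
    order = sorted(pmids)
    rng = np.random.RandomState(seed)
    rng.shuffle(order)
    assignment = {pmid: i % k for i, pmid in enumerate(order)}
    return FoldAssignment(k=k, seed=seed, assignment=assignment)


# ----------------------------------------------------------------------
# corpus bundle

_RECORDS_FILE = "records.medline"
_ANNOTATIONS_FILE = "annotations.tsv"
_MANIFEST_FILE = "manifest.json"


def write_corpus_bundle(
    path: str | os.PathLike,
    records: Sequence[DocumentRecord],
    annotations: AnnotationSet,
    extra_manifest: Mapping[str, object] | None = None,
) -> None:
    """Write the canonical bundle directory {records, annotations, manifest}."""
    os.makedirs(path, exist_ok=True)
    path = os.fspath(path)
    ordered = sorted(records, key=lambda r: r.pmid)
    with open(os.path.join(path, _RECORDS_FILE), "w", encoding="utf-8") as fh:
        write_medline_records(ordered, fh)
    with open(
        os.path.join(path, _ANNOTATIONS_FILE), "w", encoding="utf-8"
    ) as fh:
        write_annotations(annotations, fh)
    manifest = {
        "format": "expotext-corpus-bundle",
        "version": 1,
        "n_records": len(records),
        "n_annotated": len(annotations.annotated_pmids()),
        "n_irrelevant": len(annotations.irrelevant_pmids()),
        "annotator": annotations.annotator,
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    with open(os.path.join(path, _MANIFEST_FILE), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_corpus_bundle(
    path: str | os.PathLike, taxonomy: Taxonomy
) -> tuple[list[DocumentRecord], AnnotationSet, dict]:
    path = os.fspath(path)
    with open(os.path.join(path, _RECORDS_FILE), "r", encoding="utf-8") as fh:
        records = read_medline_records(fh)
    with open(
        os.path.join(path, _ANNOTATIONS_FILE), "r", encoding="utf-8"
    ) as fh:
        annotations = read_annotations(fh, taxonomy)
    with open(os.path.join(path, _MANIFEST_FILE), "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    annotations.annotator = manifest.get("annotator", annotations.annotator)
    return records, annotations, manifest
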