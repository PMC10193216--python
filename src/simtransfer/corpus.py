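"""Labeled drug-mention corpora: data model, I/O, splitting, oversampling.

A :class:`Corpus` is an ordered list of documents, each tied to the drug
query that retrieved it and carrying one of four noncompliance labels:
``NC-u/m`` (noncompliant use or mention), ``NC-s`` (noncompliant sales),
``G-u`` (general, compliant use) and ``G-m`` (general mention).  The
subcorpus of drug *i* plays the role of a transfer-learning source or
target domain downstream.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

#: the closed label set, in canonical order
LABELS = ("NC-u/m", "NC-s", "G-u", "G-m")

#: separator appended to doc_ids of oversampled copies; everything before it
#: is the id of the source document
OVERSAMPLE_TAG = "#os"


@dataclass(frozen=True)
class Document:
    doc_id: str
    drug_query: str
    text: str
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError(f"document {self.doc_id!r}: empty text")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(
                f"document {self.doc_id!r}: unknown label {self.label!r}; "
                f"expected one of {LABELS}"
            )

    def source_id(self) -> str:
        """The originating doc_id (strips any oversampling suffix)."""
        return self.doc_id.split(OVERSAMPLE_TAG, 1)[0]


@dataclass(frozen=True)
class Corpus:
    documents: tuple[Document, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "documents", tuple(self.documents))
        ids = [d.doc_id for d in self.documents]
        if len(set(ids)) != len(ids):
            dup = [i for i, c in Counter(ids).items() if c > 1]
            raise ValueError(f"duplicate doc_ids: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __getitem__(self, idx: int) -> Document:
        return self.documents[idx]

    def labels(self) -> list[str]:
        out = []
        for d in self.documents:
            if d.label is None:
                raise ValueError(f"document {d.doc_id!r} is unlabeled")
            out.append(d.label)
        return out

    def label_counts(self) -> Counter[str]:
        return Counter(self.labels())

    def drug_queries(self) -> list[str]:
        """Distinct drug queries, in first-appearance order."""
        seen: dict[str, None] = {}
        for d in self.documents:
            seen.setdefault(d.drug_query, None)
        return list(seen)

    def doc_ids(self) -> set[str]:
        return {d.doc_id for d in self.documents}

    def source_ids(self) -> set[str]:
        return {d.source_id() for d in self.documents}


def read_corpus(path: str | Path, format: str | None = None) -> Corpus:
    """Read a corpus from JSONL or CSV (UTF-8).

    Records need keys/columns ``doc_id, drug_query, text, label``; ``label``
    may be empty/null for unlabeled prediction-time documents.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in {"jsonl", "csv"}:
        raise ValueError(f"unknown corpus format {format!r}")
    docs = []
    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                rec = json.loads(line)
                docs.append(_document_from_record(rec, f"{path}:{lineno}"))
    else:
        with open(path, encoding="utf-8", newline="") as fh:
            for lineno, rec in enumerate(csv.DictReader(fh), 2):
                docs.append(_document_from_record(rec, f"{path}:{lineno}"))
    return Corpus(tuple(docs))


def _document_from_record(rec: dict, where: str) -> Document:
    missing = {"doc_id", "drug_query", "text"} - set(rec)
    if missing:
        raise ValueError(f"{where}: missing fields {sorted(missing)}")
    label = rec.get("label")
    if label in ("", None):
        label = None
    try:
        return Document(
            doc_id=str(rec["doc_id"]),
            drug_query=str(rec["drug_query"]),
            text=str(rec["text"]),
            label=label,
        )
    except ValueError as exc:
        raise ValueError(f"{where}: {exc}") from exc


def write_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for d in corpus:
                rec = {
                    "doc_id": d.doc_id,
                    "drug_query": d.drug_query,
                    "text": d.text,
                    "label": d.label,
                }
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    elif format == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["doc_id", "drug_query", "text", "label"])
            for d in corpus:
                w.writerow([d.doc_id, d.drug_query, d.text, d.label or ""])
    else:
        raise ValueError(f"unknown corpus format {format!r}")


def subcorpus(corpus: Corpus, drugs: str | Sequence[str] | set[str]) -> Corpus:
    """Documents whose drug_query is in ``drugs``, original order preserved."""
    if isinstance(drugs, str):
        drugs = {drugs}
    drugs = set(drugs)
    if not drugs:
        raise ValueError("drugs must be non-empty")
    return Corpus(tuple(d for d in corpus if d.drug_query in drugs))


@dataclass(frozen=True)
class SplitSpec:
    """Ratios for a random, optionally label-stratified partition."""

    ratios: tuple[float, ...]
    seed: int
    stratify_by_label: bool = True

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios):
            raise ValueError("all split ratios must be > 0")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"split ratios must sum to 1, got {sum(self.ratios)}")


def _largest_remainder(total: int, ratios: Sequence[float]) -> list[int]:
    exact = [total * r for r in ratios]
    sizes = [int(np.floor(e)) for e in exact]
    short = total - sum(sizes)
    # distribute leftovers by descending fractional part, first part wins ties
    order = sorted(range(len(ratios)), key=lambda k: (-(exact[k] - sizes[k]), k))
    for k in order[:short]:
        sizes[k] += 1
    return sizes


def split(corpus: Corpus, spec: SplitSpec) -> list[Corpus]:
    """Randomly partition a corpus into parts matching ``spec.ratios``.

    Part sizes follow largest-remainder rounding of the ratios exactly; with
    stratification, each label's documents are spread across parts in the
    same proportions (within one document).  Deterministic in (seed, corpus
    order).  Parts preserve the original document order.
    """
    n = len(corpus)
    n_parts = len(spec.ratios)
    if n < n_parts:
        raise ValueError(f"cannot split {n} documents into {n_parts} parts")
    rng = np.random.default_rng(spec.seed)
    target = _largest_remainder(n, spec.ratios)

    if not spec.stratify_by_label:
        groups = [list(range(n))]
    else:
        by_label: dict[str, list[int]] = {}
        for idx, d in enumerate(corpus):
            if d.label is None:
                raise ValueError(f"stratified split requires labels; {d.doc_id!r} is unlabeled")
            by_label.setdefault(d.label, []).append(idx)
        groups = [by_label[l] for l in sorted(by_label)]

    # per-group largest-remainder allocation ...
    alloc = [_largest_remainder(len(g), spec.ratios) for g in groups]
    # ... corrected so that the global part sizes hit the target exactly;
    # each move shifts one document between parts within one group, keeping
    # per-label proportions within a document of the ideal.
    totals = [sum(a[p] for a in alloc) for p in range(n_parts)]
    while totals != target:
        p_over = next(p for p in range(n_parts) if totals[p] > target[p])
        p_under = next(p for p in range(n_parts) if totals[p] < target[p])
        g_idx = max(
            (g for g in range(len(groups)) if alloc[g][p_over] > 0),
            key=lambda g: alloc[g][p_over] - len(groups[g]) * spec.ratios[p_over],
        )
        alloc[g_idx][p_over] -= 1
        alloc[g_idx][p_under] += 1
        totals[p_over] -= 1
        totals[p_under] += 1

    part_indices: list[list[int]] = [[] for _ in range(n_parts)]
    for g, counts in zip(groups, alloc):
        perm = rng.permutation(len(g))
        start = 0
        for p, c in enumerate(counts):
            for k in perm[start : start + c]:
                part_indices[p].append(g[k])
            start += c
    return [
        Corpus(tuple(corpus[i] for i in sorted(idxs))) for idxs in part_indices
    ]


def oversample_balance(train: Corpus, seed: int) -> Corpus:
    """Random oversampling to equalize label counts at the largest class.

    Each label present in ``train`` is topped up to the size of the largest
    class by sampling its own documents with replacement.  Copies keep the
    original text and receive derived doc_ids (``<orig>#os<k>``) so corpus
    id-uniqueness holds and provenance stays traceable.  Absent labels are
    not fabricated.
    """
    counts = train.label_counts()  # raises on unlabeled documents
    if not counts:
        raise ValueError("cannot oversample an empty corpus")
    target = max(counts.values())
    rng = np.random.default_rng(seed)
    by_label: dict[str, list[Document]] = {}
    for d in train:
        by_label.setdefault(d.label, []).append(d)
    extra: list[Document] = []
    k = 0
    for label in sorted(by_label):
        docs = by_label[label]
        deficit = target - len(docs)
        for pick in rng.integers(0, len(docs), size=deficit):
            src = docs[int(pick)]
            extra.append(replace(src, doc_id=f"{src.doc_id}{OVERSAMPLE_TAG}{k}"))
            k += 1
    return Corpus(tuple(train.documents) + tuple(extra))
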