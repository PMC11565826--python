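"""Sequence collections, reverse-complement augmentation and concatenation.

A *document* is one named DNA sequence (a genome or haplotype).  For
indexing, the documents are joined into a single integer-coded text in
which every document is terminated by its own separator symbol and the
whole text by a sentinel.  Separators are pairwise distinct, ordered by
document index, and rank strictly below every DNA symbol (the sentinel
ranks below everything).  Distinct separators make cross-document suffix
comparisons well defined and guarantee that no exact match ever spans a
document boundary.

Integer code layout for a collection of ``d`` documents::

    0            sentinel (end of text)
    1 .. d-1     separator after document 1 .. d-1
    d .. d+4     A, C, G, N, T   (lexicographic DNA order)

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

DNA_ORDER = "ACGNT"  # lexicographic order used for the coded alphabet
DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


class InputError(ValueError):
    """Raised for malformed user input (files, sequences, names)."""


@dataclass(frozen=True)
class DocumentCollection:
    """An ordered collection of named DNA sequences.

    Invariants: names are unique, every sequence is non-empty, and all
    sequences are uppercase strings over {A,C,G,T,N}.
    """

    docs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.docs:
            raise InputError("collection contains no documents")
        names = [name for name, _ in self.docs]
        if len(set(names)) != len(names):
            raise InputError("duplicate document names")
        for name, seq in self.docs:
            if not seq:
                raise InputError(f"document {name!r} is empty")
            if not set(seq) <= DNA_ALPHABET:
                bad = sorted(set(seq) - DNA_ALPHABET)
                raise InputError(f"document {name!r} has invalid symbols {bad}")

    @property
    def d(self) -> int:
        return len(self.docs)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.docs]

    @property
    def seqs(self) -> list[str]:
        return [seq for _, seq in self.docs]

    def total_length(self) -> int:
        return sum(len(s) for _, s in self.docs)


def collection_from_seqs(seqs: Sequence[str], names: Sequence[str] | None = None) -> DocumentCollection:
    """Convenience constructor used heavily by tests and the simulator."""
    if names is None:
        names = [f"doc{i + 1}" for i in range(len(seqs))]
    return DocumentCollection(tuple(zip(names, [s.upper() for s in seqs])))


def _open_maybe_gzip(path: Path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path, *, n_policy: str = "strict") -> DocumentCollection:
    """Read a multi-FASTA file (optionally gzipped) into a collection.

    One record becomes one document, in file order; sequences are
    uppercased.  ``n_policy`` controls symbols outside {A,C,G,T,N}:
    ``"strict"`` rejects them, ``"mask"`` maps them to N.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    docs: list[tuple[str, str]] = []
    with _open_maybe_gzip(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            if n_policy == "mask":
                seq = "".join(c if c in DNA_ALPHABET else "N" for c in seq)
            docs.append((rec.id, seq))
    if not docs:
        raise InputError(f"no FASTA records in {path}")
    try:
        return DocumentCollection(tuple(docs))
    except InputError as exc:
        raise InputError(f"{path}: {exc}") from exc


def write_fasta(coll: DocumentCollection, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in coll.docs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def augment_revcomp(coll: DocumentCollection, *, junction: str = "direct") -> DocumentCollection:
    """Append each document's reverse complement to the document itself.

    Forward and reverse strands form a *single* document, joined either
    directly (``junction="direct"``) or through one N (``junction="n"``),
    so strand-agnostic matching needs no extra documents.
    """
    if junction not in ("direct", "n"):
        raise ValueError(f"unknown junction mode {junction!r}")
    joint = "" if junction == "direct" else "N"
    return DocumentCollection(
        tuple((name, seq + joint + revcomp(seq)) for name, seq in coll.docs)
    )


@dataclass
class ConcatText:
    """Separator-joined concatenation of a collection, integer coded.

    ``text`` holds the codes described in the module docstring; ``doc_of``
    maps every text position to its (0-based) document index, with each
    separator attributed to the document it terminates.
    """

    text: np.ndarray  # int32 codes, length n
    doc_of: np.ndarray  # int32, length n
    doc_start: np.ndarray  # int64, length d (start of each document's content)
    doc_len: np.ndarray  # int64, content length of each document
    d: int
    names: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return int(self.text.size)

    @property
    def base_code(self) -> int:
        """Code of 'A'; separators/sentinel are exactly the codes below it."""
        return self.d

    def code_of(self, ch: str) -> int:
        return self.d + DNA_ORDER.index(ch)

    def encode(self, seq: str) -> np.ndarray:
        lut = np.full(256, -1, dtype=np.int32)
        for i, ch in enumerate(DNA_ORDER):
            lut[ord(ch)] = self.d + i
        return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]

    def decode(self, codes: Iterable[int]) -> str:
        out = []
        for c in codes:
            c = int(c)
            if c == 0:
                out.append("$")
            elif c < self.d:
                out.append(f"#{c}")
            else:
                out.append(DNA_ORDER[c - self.d])
        return "".join(out)

    def is_content(self, pos: int | np.ndarray):
        """True where the position holds a DNA symbol (not separator/sentinel)."""
        return self.text[pos] >= self.base_code

    def doc_local(self, pos: int) -> tuple[int, int]:
        """Map a text position of document content to (doc index, offset)."""
        doc = int(self.doc_of[pos])
        return doc, int(pos - self.doc_start[doc])


def concatenate(coll: DocumentCollection) -> ConcatText:
    """Join documents with distinct separators and a final sentinel.

    Layout: ``T1 #1 T2 #2 ... T(d-1) #(d-1) Td $`` where ``#i`` has code
    ``i`` and ``$`` has code 0, so ``n = sum(|Ti|) + d``.
    """
    d = coll.d
    pieces: list[np.ndarray] = []
    doc_of_pieces: list[np.ndarray] = []
    doc_start = np.zeros(d, dtype=np.int64)
    doc_len = np.zeros(d, dtype=np.int64)
    lut = np.full(256, -1, dtype=np.int32)
    for i, ch in enumerate(DNA_ORDER):
        lut[ord(ch)] = d + i
    pos = 0
    for i, (_, seq) in enumerate(coll.docs):
        codes = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        doc_start[i] = pos
        doc_len[i] = len(seq)
        term = 0 if i == d - 1 else i + 1  # sentinel after the last document
        pieces.append(codes)
        pieces.append(np.array([term], dtype=np.int32))
        doc_of_pieces.append(np.full(len(seq) + 1, i, dtype=np.int32))
        pos += len(seq) + 1
    text = np.concatenate(pieces)
    doc_of = np.concatenate(doc_of_pieces)
    return ConcatText(
        text=text,
        doc_of=doc_of,
        doc_start=doc_start,
        doc_len=doc_len,
        d=d,
        names=list(coll.names),
    )


def strip_concat(ct: ConcatText) -> list[str]:
    """Recover the original document strings from a ConcatText."""
    out = []
    for i in range(ct.d):
        a = int(ct.doc_start[i])
        b = a + int(ct.doc_len[i])
        out.append(ct.decode(ct.text[a:b]))
    return out
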