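"""Genetic-code-aware CDS handling: parsing, validation, translation, counting.

All downstream frequency and bias computations run on :class:`CodonCountTable`
objects produced here.  Counting is vectorized over byte arrays so that
samples with millions of codons are processed in milliseconds.

Conventions
-----------
* Sequences are normalized to upper-case DNA (``U`` -> ``T``) before
  validation; the only accepted characters afterwards are ``ACGTN``.
* Codons containing ``N`` and stop codons are never counted.
* Sequences whose length is not a multiple of three are dropped, not trimmed:
  partial genes from metagenome assemblies have no well-defined frame.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

_BASES = "ACGT"
#: byte -> base index (A=0, C=1, G=2, T=3, anything else=4 i.e. N)
_BASE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _BASE_LUT[ord(_b)] = _i

#: the 64 codons in base-4 id order (id = 16*b1 + 4*b2 + b3)
CODONS64 = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)
DINUCLEOTIDES = tuple(a + b for a in _BASES for b in _BASES)


class GeneticCode:
    """A codon translation table restricted to unambiguous DNA codons.

    Parameters
    ----------
    table_id:
        NCBI translation table identifier.  The default throughout the
        package is table 11 (bacterial/archaeal/plant-plastid), appropriate
        for prokaryote-dominated metagenomes.
    """

    def __init__(self, table_id: int, codon_to_aa: Mapping[str, str],
                 stop_codons: Iterable[str]):
        self.table_id = int(table_id)
        self.codon_to_aa = dict(codon_to_aa)
        self.stop_codons = frozenset(stop_codons)
        self.sense_codons: tuple[str, ...] = tuple(sorted(self.codon_to_aa))
        fams: dict[str, list[str]] = {}
        for codon, aa in self.codon_to_aa.items():
            fams.setdefault(aa, []).append(codon)
        #: amino acid -> sorted tuple of synonymous codons
        self.families: dict[str, tuple[str, ...]] = {
            aa: tuple(sorted(cs)) for aa, cs in sorted(fams.items())
        }
        self.amino_acids: tuple[str, ...] = tuple(self.families)
        # vectorized lookups over the 64 codon ids
        aa64 = np.array(["X"] * 64, dtype="U1")
        stop64 = np.zeros(64, dtype=bool)
        for cid, codon in enumerate(CODONS64):
            if codon in self.codon_to_aa:
                aa64[cid] = self.codon_to_aa[codon]
            elif codon in self.stop_codons:
                aa64[cid] = "*"
                stop64[cid] = True
        self._aa64 = aa64
        self._stop64 = stop64
        self._sense_ids = np.array(
            [codon_id(c) for c in self.sense_codons], dtype=np.intp
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneticCode(table_id={self.table_id})"

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    @property
    def sense_codon_ids(self) -> np.ndarray:
        return self._sense_ids

    @classmethod
    @lru_cache(maxsize=None)
    def from_table_id(cls, table_id: int = 11) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        return cls(table_id, table.forward_table, table.stop_codons)


def standard_code() -> GeneticCode:
    """The package default genetic code (NCBI table 11)."""
    return GeneticCode.from_table_id(11)


def codon_id(codon: str) -> int:
    """Base-4 id of a codon over ``ACGT`` (``N`` anywhere yields an id >= 64)."""
    b = [int(_BASE_LUT[ord(ch)]) for ch in codon]
    if any(x == 4 for x in b):
        return 64
    return 16 * b[0] + 4 * b[1] + b[2]


def clean_sequence(seq: str, *, name: str = "<seq>") -> str:
    """Upper-case a nucleotide string, map ``U``->``T``, validate characters.

    Raises
    ------
    ValueError
        If a character outside ``ACGTN`` remains, with its position.
    """
    s = seq.upper().replace("U", "T")
    arr = np.frombuffer(s.encode("ascii", errors="replace"), dtype=np.uint8)
    ok = (_BASE_LUT[arr] < 4) | (arr == ord("N"))
    if not ok.all():
        pos = int(np.flatnonzero(~ok)[0])
        raise ValueError(
            f"{name}: invalid character {s[pos]!r} at position {pos}"
        )
    return s


@dataclass(frozen=True)
class CdsRecord:
    """A single validated protein-coding nucleotide sequence."""

    gene_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)

    def codon_ids(self) -> np.ndarray:
        """Base-4 codon ids, one per triplet; 64 marks an N-containing codon."""
        return _codon_id_array(self.sequence)


def _codon_id_array(seq: str) -> np.ndarray:
    arr = _BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = (len(arr) // 3) * 3
    tri = arr[:n].reshape(-1, 3).astype(np.intp)
    ids = 16 * tri[:, 0] + 4 * tri[:, 1] + tri[:, 2]
    ids[(tri >= 4).any(axis=1)] = 64
    return ids


@dataclass
class CdsCollection:
    """An ordered set of validated CDS records for one sample."""

    sample_id: str
    records: list[CdsRecord]
    provenance: str = ""
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CdsRecord]:
        return iter(self.records)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]


@dataclass(frozen=True)
class ValidationPolicy:
    """Filtering rules applied when building a :class:`CdsCollection`.

    ``require_triplet`` drops sequences whose length is not divisible by 3;
    ``allow_n`` keeps records containing N (N codons are skipped downstream).
    """

    require_triplet: bool = True
    allow_n: bool = True
    min_length: int = 3


DEFAULT_POLICY = ValidationPolicy()


def validate_record(gene_id: str, seq: str,
                    policy: ValidationPolicy = DEFAULT_POLICY
                    ) -> tuple[CdsRecord | None, str | None]:
    """Validate one raw sequence; return ``(record, None)`` or ``(None, reason)``."""
    try:
        s = clean_sequence(seq, name=gene_id)
    except ValueError as exc:
        return None, str(exc)
    if policy.require_triplet and len(s) % 3 != 0:
        return None, "length not divisible by 3"
    if len(s) < policy.min_length:
        return None, f"shorter than {policy.min_length} nt"
    if not policy.allow_n and "N" in s:
        return None, "contains N"
    return CdsRecord(gene_id, s), None


def build_collection(sample_id: str,
                     items: Iterable[tuple[str, str]],
                     policy: ValidationPolicy = DEFAULT_POLICY,
                     provenance: str = "") -> CdsCollection:
    """Validate ``(gene_id, sequence)`` pairs into a collection.

    Order of the input is preserved; failing records are logged with reason
    and retained in ``collection.dropped``.  Duplicate gene ids keep the
    first occurrence only.
    """
    records: list[CdsRecord] = []
    dropped: list[tuple[str, str]] = []
    seen: set[str] = set()
    for gene_id, seq in items:
        if gene_id in seen:
            dropped.append((gene_id, "duplicate gene id"))
            logger.warning("%s: dropped %s (duplicate gene id)", sample_id, gene_id)
            continue
        rec, reason = validate_record(gene_id, seq, policy)
        if rec is None:
            dropped.append((gene_id, reason or "invalid"))
            logger.warning("%s: dropped %s (%s)", sample_id, gene_id, reason)
            continue
        seen.add(gene_id)
        records.append(rec)
    return CdsCollection(sample_id, records, provenance, dropped)


def read_sample_fasta(path: str | Path, sample_id: str | None = None,
                      policy: ValidationPolicy = DEFAULT_POLICY) -> CdsCollection:
    """Read a (optionally gzipped) multi-FASTA of CDS sequences for one sample.

    Raises
    ------
    OSError
        If the file cannot be read.
    ValueError
        If no record survives validation.
    """
    path = Path(path)
    sid = sample_id if sample_id is not None else path.stem.removesuffix(".fasta")
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        coll = build_collection(
            sid, ((rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")),
            policy, provenance=str(path),
        )
    if len(coll) == 0:
        raise ValueError(f"sample {sid!r}: no CDS records survived validation "
                         f"({len(coll.dropped)} dropped)")
    return coll


def translate(seq: str, code: GeneticCode | None = None) -> str:
    """Translate an in-frame CDS; trailing stop dropped, internal stops -> ``*``.

    N-containing codons translate to ``X``.  A warning is logged when an
    internal stop codon is encountered.
    """
    if code is None:
        code = standard_code()
    if seq == "":
        return ""
    s = clean_sequence(seq)
    if len(s) % 3 != 0:
        raise ValueError("sequence length not divisible by 3")
    ids = _codon_id_array(s)
    aa = np.where(ids < 64, code._aa64[np.minimum(ids, 63)], "X")
    if aa[-1] == "*":
        aa = aa[:-1]
    prot = "".join(aa)
    if "*" in prot:
        logger.warning("internal stop codon(s) in translated sequence")
    return prot


class CodonCountTable:
    """Counts over the sense codons of a genetic code for a gene or sample."""

    def __init__(self, values: np.ndarray | Mapping[str, int],
                 code: GeneticCode | None = None):
        self.code = code if code is not None else standard_code()
        n = len(self.code.sense_codons)
        if isinstance(values, Mapping):
            arr = np.zeros(n, dtype=np.int64)
            index = {c: i for i, c in enumerate(self.code.sense_codons)}
            for codon, count in values.items():
                if codon not in index:
                    raise KeyError(f"{codon!r} is not a sense codon")
                arr[index[codon]] = int(count)
            values = arr
        self.values = np.asarray(values, dtype=np.int64)
        if self.values.shape != (n,):
            raise ValueError("count vector shape mismatch")
        if (self.values < 0).any():
            raise ValueError("negative codon counts")

    @property
    def total(self) -> int:
        return int(self.values.sum())

    def __getitem__(self, codon: str) -> int:
        return int(self.values[self.code.sense_codons.index(codon)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.code.sense_codons))

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        if other.code is not self.code and other.code.table_id != self.code.table_id:
            raise ValueError("genetic codes differ")
        return CodonCountTable(self.values + other.values, self.code)

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, CodonCountTable)
                and np.array_equal(self.values, other.values))


class DinucCountTable:
    """Counts of the 16 overlapping dinucleotides (within-gene windows only)."""

    def __init__(self, values: np.ndarray | Mapping[str, int]):
        if isinstance(values, Mapping):
            arr = np.zeros(16, dtype=np.int64)
            for dn, count in values.items():
                arr[DINUCLEOTIDES.index(dn)] = int(count)
            values = arr
        self.values = np.asarray(values, dtype=np.int64)
        if self.values.shape != (16,):
            raise ValueError("dinucleotide vector must have 16 entries")

    @property
    def total(self) -> int:
        return int(self.values.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(DINUCLEOTIDES))

    def frequencies(self) -> np.ndarray:
        t = self.total
        if t == 0:
            return np.zeros(16)
        return self.values / t


def _iter_sequences(obj: CdsCollection | CdsRecord | str) -> Iterator[str]:
    if isinstance(obj, CdsCollection):
        yield from obj.sequences()
    elif isinstance(obj, CdsRecord):
        yield obj.sequence
    else:
        yield obj


def count_codons(obj: CdsCollection | CdsRecord | str,
                 code: GeneticCode | None = None) -> CodonCountTable:
    """Count in-frame sense codons; stop and N-containing codons are skipped."""
    if code is None:
        code = standard_code()
    counts64 = np.zeros(65, dtype=np.int64)
    for seq in _iter_sequences(obj):
        ids = _codon_id_array(seq)
        counts64 += np.bincount(ids, minlength=65)
    return CodonCountTable(counts64[code.sense_codon_ids], code)


def count_dinucleotides(obj: CdsCollection | CdsRecord | str) -> DinucCountTable:
    """Overlapping dinucleotide counts, never crossing gene boundaries.

    Windows containing ``N`` are skipped.
    """
    counts = np.zeros(17, dtype=np.int64)
    for seq in _iter_sequences(obj):
        if len(seq) < 2:
            continue
        arr = _BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        a, b = arr[:-1].astype(np.intp), arr[1:].astype(np.intp)
        ids = 4 * a + b
        ids[(a >= 4) | (b >= 4)] = 16
        counts += np.bincount(ids, minlength=17)
    return DinucCountTable(counts[:16])
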