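"""Per-sample frequency profiles and feature-abundance matrix filtering.

Two codon normalizations are supported:

* ``absCUF`` — each codon count divided by the total over all sense codons
  of the sample; reflects amino-acid usage and synonymous preference jointly.
* ``synCUF`` — each codon count divided by the total of its synonymous
  family; independent of amino-acid composition, so it isolates synonymous
  codon usage bias.

Amino-acid and k-mer profiles complete the feature spaces the distance layer
operates on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqcore import (
    _BASE_LUT,
    CdsCollection,
    CodonCountTable,
    GeneticCode,
    count_codons,
    standard_code,
)

logger = logging.getLogger(__name__)

PROFILE_KINDS = ("absCUF", "synCUF", "aa", "kmer")


@dataclass
class FrequencyProfile:
    """A named, normalized feature vector attached to a sample."""

    sample_id: str
    kind: str
    values: pd.Series
    k: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in PROFILE_KINDS:
            raise ValueError(f"unknown profile kind {self.kind!r}")
        self.values = self.values.astype(float)
        v = self.values.to_numpy()
        if (v < -1e-12).any() or (v > 1 + 1e-9).any():
            raise ValueError("profile values must lie in [0, 1]")

    def array(self) -> np.ndarray:
        return self.values.to_numpy()


def abs_cufs(counts: CodonCountTable) -> FrequencyProfile:
    """Absolute codon usage frequencies: counts / total over all sense codons."""
    total = counts.total
    if total == 0:
        raise ValueError("cannot normalize an empty codon count table")
    return FrequencyProfile("", "absCUF", counts.as_series() / total)


def syn_cufs(counts: CodonCountTable,
             code: GeneticCode | None = None) -> FrequencyProfile:
    """Synonymous codon usage frequencies: counts normalized within each family.

    Families with zero total count are left all-zero.
    """
    code = code if code is not None else counts.code
    s = counts.as_series().astype(float)
    out = pd.Series(0.0, index=s.index)
    for _aa, codons in code.families.items():
        fam_total = s[list(codons)].sum()
        if fam_total > 0:
            out[list(codons)] = s[list(codons)] / fam_total
    return FrequencyProfile("", "synCUF", out)


def aa_frequencies(collection: CdsCollection | CodonCountTable,
                   code: GeneticCode | None = None) -> FrequencyProfile:
    """Amino-acid frequencies: total count of each residue over total protein length.

    Stop positions and N codons contribute neither counts nor length.
    """
    if isinstance(collection, CodonCountTable):
        counts = collection
        code = code if code is not None else counts.code
    else:
        code = code if code is not None else standard_code()
        counts = count_codons(collection, code)
    if counts.total == 0:
        raise ValueError("no countable codons")
    s = counts.as_series()
    aa_counts = pd.Series(0.0, index=list(code.amino_acids))
    for aa, codons in code.families.items():
        aa_counts[aa] = s[list(codons)].sum()
    return FrequencyProfile("", "aa", aa_counts / counts.total)


def gc_content(collection: CdsCollection | str) -> float:
    """Sample GC fraction (G+C)/(A+C+G+T) over all CDS nucleotides; N ignored."""
    seqs = collection.sequences() if isinstance(collection, CdsCollection) else [collection]
    gc = acgt = 0
    for seq in seqs:
        arr = _BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        acgt += int((arr < 4).sum())
        gc += int(((arr == 1) | (arr == 2)).sum())
    if acgt == 0:
        raise ValueError("no unambiguous nucleotides")
    return gc / acgt


def kmer_frequencies(collection: CdsCollection, k: int) -> FrequencyProfile:
    """k-mer frequencies over coding-strand CDS, overlapping windows, step 1.

    Windows containing ``N`` are skipped; windows never cross gene
    boundaries.  The returned series is indexed by the k-mers observed in
    the sample (absent k-mers are implicitly zero).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    total = np.zeros(4 ** k, dtype=np.int64) if k <= 10 else None
    if total is None:
        raise ValueError("k > 10 not supported")
    any_window = False
    for seq in collection.sequences():
        if len(seq) < k:
            continue
        arr = _BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].astype(np.int64)
        valid = arr < 4
        ids = np.zeros(len(arr) - k + 1, dtype=np.int64)
        ok = np.ones(len(arr) - k + 1, dtype=bool)
        for j in range(k):
            ids = ids * 4 + arr[j:len(arr) - k + 1 + j]
            ok &= valid[j:len(arr) - k + 1 + j]
        ids = ids[ok]
        if ids.size:
            any_window = True
            total += np.bincount(ids, minlength=4 ** k)
    if not any_window:
        raise ValueError(f"no sequence long enough for k={k}")
    nz = np.flatnonzero(total)
    names = ["".join("ACGT"[(i >> (2 * (k - 1 - j))) & 3] for j in range(k)) for i in nz]
    freqs = pd.Series(total[nz] / total.sum(), index=names).sort_index()
    return FrequencyProfile(collection.sample_id, "kmer", freqs, k=k)


def sample_profiles(collection: CdsCollection,
                    code: GeneticCode | None = None,
                    kinds: tuple[str, ...] = ("absCUF", "synCUF", "aa"),
                    ) -> dict[str, FrequencyProfile]:
    """Convenience: compute the requested codon/AA profiles for one sample."""
    code = code if code is not None else standard_code()
    counts = count_codons(collection, code)
    out: dict[str, FrequencyProfile] = {}
    for kind in kinds:
        if kind == "absCUF":
            prof = abs_cufs(counts)
        elif kind == "synCUF":
            prof = syn_cufs(counts, code)
        elif kind == "aa":
            prof = aa_frequencies(counts, code)
        else:
            raise ValueError(f"unsupported kind {kind!r} here")
        prof.sample_id = collection.sample_id
        out[kind] = prof
    return out


def profiles_to_frame(profiles: list[FrequencyProfile]) -> pd.DataFrame:
    """Stack profiles of one kind into a samples x features DataFrame (zeros fill)."""
    kinds = {p.kind for p in profiles}
    if len(kinds) != 1:
        raise ValueError(f"mixed profile kinds: {sorted(kinds)}")
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    frame = pd.DataFrame({p.sample_id: p.values for p in profiles}).T.fillna(0.0)
    return frame.loc[ids]


def select_top_features(matrix: pd.DataFrame, n: int,
                        rule: str = "presence",
                        min_presence: int = 0) -> pd.DataFrame:
    """Retain the top-``n`` columns of a samples x features abundance matrix.

    Columns are ranked by ``presence`` (number of samples with a nonzero
    entry) or ``mean_abundance``; ties break lexicographically by feature
    name.  Columns present in fewer than ``min_presence`` samples are
    dropped first.  If fewer than ``n`` columns survive, all survivors are
    returned with a warning.
    """
    if matrix.empty:
        raise ValueError("empty feature matrix")
    if rule not in ("presence", "mean_abundance"):
        raise ValueError(f"unknown rule {rule!r}")
    presence = (matrix > 0).sum(axis=0)
    kept = matrix.loc[:, presence[presence >= min_presence].index]
    if kept.shape[1] == 0:
        warnings.warn("min_presence filter removed every feature")
        return kept
    score = ((kept > 0).sum(axis=0) if rule == "presence"
             else kept.mean(axis=0))
    order = sorted(kept.columns, key=lambda c: (-score[c], c))
    if n > len(order):
        warnings.warn(
            f"requested {n} features but only {len(order)} survive; returning all")
        n = len(order)
    return kept.loc[:, order[:n]]
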