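"""Codon usage bias indices: CAI, ENC and DCBS.

CAI
    ``CAI_g = (prod w_i)^(1/L)`` over the gene's sense codons, where
    ``w_i = f_i / max(f_i)`` compares each codon's frequency in a reference
    set of highly expressed genes with the most frequent codon of its
    synonymous family.  The reference set is the top fraction (default 5%)
    of a sample's genes ranked by abundance.  A +0.5 pseudocount on the
    pooled reference counts (the classical Sharp-Li remedy) keeps every
    weight positive.

ENC
    Wright's effective number of codons computed on pooled sample counts:
    ``Nc = n_single + sum_k (n_k / F_k)`` over degeneracy classes k, which
    for the standard code reads ``2 + 9/F2 + 1/F3 + 5/F4 + 3/F6``.  Each
    class homozygosity ``F_k`` is the count-weighted mean over its families
    of Wright's estimator ``F_hat = (n * sum p_i^2 - 1) / (n - 1)``.  The
    result is capped to [20, 61].

DCBS
    Per codon ``d_xyz = (f(x,y,z) - f1(x) f2(y) f3(z)) / (f1(x) f2(y) f3(z))``
    with sample-level codon frequencies and positional nucleotide
    frequencies; a gene's score is the mean of ``d_xyz`` over its codons,
    a sample's score the mean over its genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .profiles import FrequencyProfile, abs_cufs
from .seqcore import (
    CODONS64,
    CdsCollection,
    CodonCountTable,
    GeneticCode,
    _codon_id_array,
    count_codons,
    standard_code,
)

logger = logging.getLogger(__name__)

ENC_MIN, ENC_MAX = 20.0, 61.0


# --------------------------------------------------------------------------
# CAI

@dataclass
class ReferenceSet:
    """The highly expressed genes used to derive CAI codon weights."""

    member_ids: tuple[str, ...]
    counts: CodonCountTable
    top_frac: float


def build_reference_set(collection: CdsCollection,
                        abundances: Mapping[str, float],
                        top_frac: float = 0.05) -> ReferenceSet:
    """Pick the ``ceil(top_frac * n)`` most abundant genes and pool their codons.

    Ties in abundance break by gene id (ascending) for determinism.
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must be in (0, 1]")
    missing = [g for g in collection.gene_ids() if g not in abundances]
    if missing:
        raise KeyError(f"genes without abundance: {missing[:10]}"
                       + ("..." if len(missing) > 10 else ""))
    n_ref = math.ceil(top_frac * len(collection))
    order = sorted(collection.records, key=lambda r: (-abundances[r.gene_id], r.gene_id))
    members = order[:n_ref]
    pooled = count_codons(
        CdsCollection(collection.sample_id, list(members)), None)
    return ReferenceSet(tuple(r.gene_id for r in members), pooled, top_frac)


@dataclass
class CodonWeights:
    """Per-codon CAI weights; the most frequent codon of each family has w=1."""

    w: dict[str, float]
    pseudocount: float = 0.5

    def log_lut(self, code: GeneticCode,
                exclude_single_codon_families: bool = False) -> np.ndarray:
        """log(w) indexed by base-4 codon id; NaN marks codons to skip."""
        lut = np.full(65, np.nan)
        for aa, codons in code.families.items():
            if exclude_single_codon_families and len(codons) == 1:
                continue
            for c in codons:
                w = self.w[c]
                lut[_codon_id(c)] = math.log(w) if w > 0 else -math.inf
        return lut


def _codon_id(codon: str) -> int:
    return CODONS64.index(codon)


def codon_weights(ref: ReferenceSet, code: GeneticCode | None = None,
                  pseudocount: float = 0.5) -> CodonWeights:
    """``w_i = f_i / max(f_i)`` within each synonymous family of the reference.

    The pseudocount is added to every sense-codon count first, so no weight
    is ever zero; in a family entirely absent from the reference all counts
    tie at the pseudocount and every codon gets w = 1.
    """
    code = code if code is not None else ref.counts.code
    s = ref.counts.as_series().astype(float) + pseudocount
    w: dict[str, float] = {}
    for _aa, codons in code.families.items():
        fam = s[list(codons)]
        top = fam.max()
        for c in codons:
            # top == 0 only without pseudocount in an absent family; give
            # such codons the neutral weight 1 rather than 0/0
            w[c] = float(fam[c] / top) if top > 0 else 1.0
    return CodonWeights(w, pseudocount)


def cai_gene(seq: str, weights: CodonWeights,
             code: GeneticCode | None = None,
             exclude_single_codon_families: bool = False) -> float:
    """CAI of one gene: geometric mean of codon weights, computed in log space.

    Stop codons, N-containing codons (and optionally single-codon families)
    are excluded from both the product and the length L.
    """
    code = code if code is not None else standard_code()
    lut = weights.log_lut(code, exclude_single_codon_families)
    return _cai_from_ids(_codon_id_array(seq), lut)


def _cai_from_ids(ids: np.ndarray, log_lut: np.ndarray) -> float:
    logs = log_lut[np.minimum(ids, 64)]
    logs = logs[~np.isnan(logs)]
    if logs.size == 0:
        raise ValueError("gene has no countable codons for CAI")
    return float(np.exp(logs.mean()))


# --------------------------------------------------------------------------
# ENC

def _wright_f_hat(counts: np.ndarray) -> float | None:
    """Wright's per-family homozygosity estimate; None when n < 2."""
    n = counts.sum()
    if n < 2:
        return None
    p = counts / n
    return float((n * (p ** 2).sum() - 1) / (n - 1))


def enc_sample(counts: CodonCountTable, code: GeneticCode | None = None,
               cap: bool = True) -> float:
    """Effective number of codons for pooled sample counts.

    Degeneracy classes are derived from the genetic code (for the standard
    code: 9 two-fold, 1 three-fold, 5 four-fold, 3 six-fold families plus 2
    single-codon amino acids).  Families with fewer than 2 counted codons
    are omitted from their class mean; a wholly missing three-fold class is
    imputed as the average of the two- and four-fold class homozygosities.
    The estimate is capped to [20, 61] unless ``cap`` is False.
    """
    code = code if code is not None else counts.code
    if counts.total == 0:
        raise ValueError("empty codon count table")
    s = counts.as_series()
    # degeneracy class -> list of (family n, F_hat)
    classes: dict[int, list[tuple[int, float]]] = {}
    class_sizes: dict[int, int] = {}
    n_single = 0
    for _aa, codons in code.families.items():
        k = len(codons)
        if k == 1:
            n_single += 1
            continue
        class_sizes[k] = class_sizes.get(k, 0) + 1
        fam = s[list(codons)].to_numpy()
        f_hat = _wright_f_hat(fam)
        if f_hat is not None:
            classes.setdefault(k, []).append((int(fam.sum()), f_hat))
    class_f: dict[int, float] = {}
    for k, items in classes.items():
        weights = np.array([n for n, _ in items], dtype=float)
        f_vals = np.array([f for _, f in items])
        class_f[k] = float((weights * f_vals).sum() / weights.sum())
    if 3 in class_sizes and 3 not in class_f:
        if 2 in class_f and 4 in class_f:
            class_f[3] = 0.5 * (class_f[2] + class_f[4])
            logger.info("three-fold class absent; imputed F3 from (F2+F4)/2")
    missing = [k for k in class_sizes if k not in class_f]
    if missing:
        raise ValueError(f"no usable family in degeneracy class(es) {missing}")
    if any(f <= 1e-12 for f in class_f.values()):
        # a vanishing class homozygosity sends the estimator to infinity
        logger.info("class homozygosity ~0; reporting the maximum ENC")
        return ENC_MAX if cap else math.inf
    enc = n_single + sum(class_sizes[k] / class_f[k] for k in class_sizes)
    if cap:
        if enc > ENC_MAX or enc < ENC_MIN:
            logger.debug("ENC %.3f capped to [%g, %g]", enc, ENC_MIN, ENC_MAX)
        enc = min(max(enc, ENC_MIN), ENC_MAX)
    return float(enc)


# --------------------------------------------------------------------------
# DCBS

@dataclass
class PositionalNucFreqs:
    """Nucleotide distributions at the three codon positions (A, C, G, T)."""

    f1: np.ndarray
    f2: np.ndarray
    f3: np.ndarray


def positional_nt_freqs(counts: CodonCountTable,
                        code: GeneticCode | None = None) -> PositionalNucFreqs:
    """Position-wise nucleotide frequencies derived from sense-codon counts."""
    code = code if code is not None else counts.code
    if counts.total == 0:
        raise ValueError("empty codon count table")
    pos = np.zeros((3, 4))
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    for codon, count in zip(code.sense_codons, counts.values):
        for j in range(3):
            pos[j, base_index[codon[j]]] += count
    pos /= counts.total
    return PositionalNucFreqs(pos[0], pos[1], pos[2])


def _dcbs_lut(sample_cufs: FrequencyProfile, pos: PositionalNucFreqs,
              code: GeneticCode) -> np.ndarray:
    """d_xyz per base-4 codon id; NaN for stop/N codons."""
    lut = np.full(65, np.nan)
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    vals = sample_cufs.values
    for codon in code.sense_codons:
        expected = (pos.f1[base_index[codon[0]]]
                    * pos.f2[base_index[codon[1]]]
                    * pos.f3[base_index[codon[2]]])
        observed = float(vals.get(codon, 0.0))
        if expected <= 0:
            if observed > 0:
                raise ValueError(f"zero positional product for observed codon {codon}")
            continue
        lut[_codon_id(codon)] = observed / expected - 1.0
    return lut


def dcbs_gene(seq: str, sample_cufs: FrequencyProfile,
              pos: PositionalNucFreqs, code: GeneticCode | None = None,
              geometric: bool = False) -> float:
    """DCBS of one gene against sample-level codon and positional frequencies.

    The default is the arithmetic mean of ``d_xyz`` over the gene's sense
    codons.  ``geometric=True`` switches to the geometric-mean variant
    ``exp(mean log(f/(f1 f2 f3))) - 1`` computed on the frequency ratios.
    """
    code = code if code is not None else standard_code()
    lut = _dcbs_lut(sample_cufs, pos, code)
    return _dcbs_from_ids(_codon_id_array(seq), lut, geometric)


def _dcbs_from_ids(ids: np.ndarray, lut: np.ndarray, geometric: bool) -> float:
    d = lut[np.minimum(ids, 64)]
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("gene has no countable codons for DCBS")
    if geometric:
        ratios = d + 1.0
        if (ratios <= 0).any():
            raise ValueError("geometric DCBS undefined for zero-frequency codons")
        return float(np.exp(np.log(ratios).mean()) - 1.0)
    return float(d.mean())


# --------------------------------------------------------------------------
# sample summary

@dataclass
class CUBScores:
    """Per-gene CAI/DCBS, sample ENC, and the per-sample means."""

    sample_id: str
    cai: dict[str, float]
    dcbs: dict[str, float]
    enc: float
    mean_cai: float
    mean_dcbs: float
    reference_size: int

    def per_gene_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cai": pd.Series(self.cai),
                             "dcbs": pd.Series(self.dcbs)})


def sample_cub_summary(collection: CdsCollection,
                       abundances: Mapping[str, float],
                       code: GeneticCode | None = None,
                       top_frac: float = 0.05,
                       pseudocount: float = 0.5,
                       exclude_single_codon_families: bool = False,
                       dcbs_geometric: bool = False,
                       reference: ReferenceSet | None = None,
                       enc_cap: bool = True) -> CUBScores:
    """All three indices for one sample.

    ``reference`` lets a caller reuse reference-set *membership* (e.g. for
    randomized replicates, where the abundance ranking is unchanged) while
    weights are still recomputed from this collection's sequences.
    """
    code = code if code is not None else standard_code()
    if reference is None:
        reference = build_reference_set(collection, abundances, top_frac)
    else:
        by_id = {r.gene_id: r for r in collection.records}
        members = [by_id[g] for g in reference.member_ids]
        reference = ReferenceSet(
            reference.member_ids,
            count_codons(CdsCollection(collection.sample_id, members), code),
            reference.top_frac)
    weights = codon_weights(reference, code, pseudocount)
    log_lut = weights.log_lut(code, exclude_single_codon_families)

    counts = count_codons(collection, code)
    cufs = abs_cufs(counts)
    pos = positional_nt_freqs(counts, code)
    dlut = _dcbs_lut(cufs, pos, code)

    cai: dict[str, float] = {}
    dcbs: dict[str, float] = {}
    for rec in collection.records:
        ids = rec.codon_ids()
        cai[rec.gene_id] = _cai_from_ids(ids, log_lut)
        dcbs[rec.gene_id] = _dcbs_from_ids(ids, dlut, dcbs_geometric)
    return CUBScores(
        sample_id=collection.sample_id,
        cai=cai,
        dcbs=dcbs,
        enc=enc_sample(counts, code, cap=enc_cap),
        mean_cai=float(np.mean(list(cai.values()))),
        mean_dcbs=float(np.mean(list(dcbs.values()))),
        reference_size=len(reference.member_ids),
    )
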