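"""Protein- and dinucleotide-preserving sequence randomization with Z-scores.

The null model asks: how biased would a sample's codon usage look if its
sequences carried the *same proteins* and the *same dinucleotide content*
but otherwise random synonymous codon choices?  Indices computed on the
real sample are compared with their distribution over randomized
replicates through a Z-score:

    z = (real - mean(randoms)) / sd(randoms)

For CAI and DCBS a positive z means the real sequences are more biased
than the null; for ENC (lower = more biased) the analogous signal is a
negative z.

The randomizer is a first-order Markov random field over each coding
sequence: every synonymous reconstruction s of a gene has probability
proportional to ``prod over adjacent bases (a,b) of W[a,b]``, i.e. a
Gibbs distribution in the sequence's dinucleotide counts.  Sampling is
exact via a backward (partition-function) recursion followed by a forward
draw — a plain left-to-right chain without the backward correction does
*not* sample this distribution and systematically distorts synonymous
usage.  The weight matrix ``W`` is initialized from the sample's observed
dinucleotide transitions and then calibrated by iterative proportional
fitting so that the *expected* dinucleotide counts of randomized
sequences match the real counts; with a dinucleotide-neutral sample the
calibrated sampler reduces to uniform synonymous choice.  Preservation of
dinucleotide content is exact in expectation, and replicate-to-replicate
deviations shrink with sample size.

An alternative exact mode (``method="swap"``) permutes the sample's
codons within each synonymous family; it preserves codon *counts* exactly
and is therefore unusable as a codon-usage-bias null, but serves as a
control for distance-level analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .cub import ReferenceSet, build_reference_set, sample_cub_summary
from .seqcore import (
    CdsCollection,
    CdsRecord,
    GeneticCode,
    count_dinucleotides,
    standard_code,
)

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class DinucTransitionModel:
    """First-order nucleotide transition probabilities P(b | a), rows sum to 1."""

    probs: np.ndarray  # 4x4
    source: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (4, 4):
            raise ValueError("transition matrix must be 4x4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")


def fit_dinuc_model(collection: CdsCollection) -> DinucTransitionModel:
    """Estimate transitions from pooled within-gene dinucleotide counts.

    Rows with zero support fall back to the uniform distribution.
    """
    if len(collection) == 0:
        raise ValueError("empty collection")
    counts = count_dinucleotides(collection).values.reshape(4, 4).astype(float)
    probs = np.empty((4, 4))
    for a in range(4):
        row_total = counts[a].sum()
        probs[a] = counts[a] / row_total if row_total > 0 else 0.25
    return DinucTransitionModel(probs, collection.sample_id)


# --------------------------------------------------------------------------
# gene plans: the fixed skeleton (protein + verbatim codons) of each gene

class _FamilyData:
    """Per-amino-acid codon base indices, precomputed once per genetic code."""

    def __init__(self, code: GeneticCode):
        self.codons: dict[str, list[str]] = {}
        self.c1: dict[str, np.ndarray] = {}
        self.c2: dict[str, np.ndarray] = {}
        self.c3: dict[str, np.ndarray] = {}
        for aa, codons in code.families.items():
            self.codons[aa] = list(codons)
            self.c1[aa] = np.array([_BASE_INDEX[c[0]] for c in codons])
            self.c2[aa] = np.array([_BASE_INDEX[c[1]] for c in codons])
            self.c3[aa] = np.array([_BASE_INDEX[c[2]] for c in codons])


def _gene_plan(seq: str, code: GeneticCode) -> list[tuple]:
    """Tokenize a CDS into resampleable amino-acid slots and verbatim codons.

    Tokens: ``("aa", aa_letter)`` or ``("fixed", codon, c1, c3)`` where c1/c3
    are base indices or None when the base is ambiguous.
    """
    plan = []
    for i in range(len(seq) // 3):
        codon = seq[3 * i:3 * i + 3]
        aa = code.codon_to_aa.get(codon)
        if aa is None:  # stop codon or N-containing codon: copied verbatim
            plan.append(("fixed", codon,
                         _BASE_INDEX.get(codon[0]), _BASE_INDEX.get(codon[2])))
        else:
            plan.append(("aa", aa))
    return plan


class SequenceRandomizer:
    """Exact sampler of the dinucleotide-Gibbs synonymous null for one sample.

    Parameters
    ----------
    collection:
        The real sample; its proteins, gene lengths, verbatim codons and
        dinucleotide counts define the null.
    model:
        Optional starting :class:`DinucTransitionModel`; fitted from the
        collection when omitted.
    calibrate:
        Run iterative proportional fitting so expected dinucleotide counts
        match the real ones (recommended; without it the sampler carries
        the raw transition matrix as Gibbs weights).
    """

    def __init__(self, collection: CdsCollection,
                 code: GeneticCode | None = None,
                 model: DinucTransitionModel | None = None,
                 calibrate: bool = True,
                 max_iter: int = 30, tol: float = 2e-3):
        self.code = code if code is not None else standard_code()
        self.collection = collection
        self.fam = _FamilyData(self.code)
        self.plans = [_gene_plan(r.sequence, self.code) for r in collection.records]
        if model is None:
            model = fit_dinuc_model(collection)
        self.log_w = np.log(np.maximum(model.probs, 1e-12))
        self.target = count_dinucleotides(collection).values.reshape(4, 4).astype(float)
        self.n_iterations = 0
        if calibrate:
            self._calibrate(max_iter, tol)
        self._tables = self._sampling_tables()

    # -- backward recursion -------------------------------------------------

    def _backward(self, w: np.ndarray, plan: list[tuple]) -> list[np.ndarray]:
        """Partition-function messages: b_after[i][prev] sums all completions
        of positions > i-1 ... i.e. entry i holds the message *after* slot i."""
        b_after = [np.ones(4)] * len(plan)
        b = np.ones(4)
        for i in range(len(plan) - 1, -1, -1):
            b_after[i] = b
            tok = plan[i]
            if tok[0] == "aa":
                aa = tok[1]
                contrib = (w[self.fam.c2[aa], self.fam.c3[aa]]
                           * w[self.fam.c1[aa], self.fam.c2[aa]]
                           * b[self.fam.c3[aa]])
                b = w[:, self.fam.c1[aa]] @ contrib
            else:
                _, _, c1, c3 = tok
                tail = b[c3] if c3 is not None else b.mean()
                b = w[:, c1] * tail if c1 is not None else np.full(4, tail)
            s = b.sum()
            if s <= 0 or not np.isfinite(s):
                b = np.ones(4)
            else:
                b = b / s
        return b_after

    # -- calibration --------------------------------------------------------

    def _expected_counts(self, w: np.ndarray) -> np.ndarray:
        """Exact expected within-gene dinucleotide counts under weights w."""
        expected = np.zeros((4, 4))
        for plan in self.plans:
            b_after = self._backward(w, plan)
            f = np.zeros(4)       # forward distribution of the previous base
            f_start = 1.0         # mass with no previous base (start / after N)
            for i, tok in enumerate(plan):
                if tok[0] == "aa":
                    aa = tok[1]
                    c1, c2, c3 = self.fam.c1[aa], self.fam.c2[aa], self.fam.c3[aa]
                    wint = w[c1, c2] * w[c2, c3] * b_after[i][c3]
                    joint = (f[:, None] * w[:, c1]) * wint[None, :]
                    start_row = f_start * wint
                    z = joint.sum() + start_row.sum()
                    joint /= z
                    start_row /= z
                    pk = joint.sum(axis=0) + start_row
                    np.add.at(expected, (c1, c2), pk)
                    np.add.at(expected, (c2, c3), pk)
                    for b4 in range(4):
                        np.add.at(expected[b4], c1, joint[b4])
                    f = np.zeros(4)
                    np.add.at(f, c3, pk)
                    f_start = 0.0
                else:
                    _, codon, c1, c3 = tok
                    if c1 is not None:
                        expected[:, c1] += f
                    for j in range(2):
                        a, b = codon[j], codon[j + 1]
                        if a in _BASE_INDEX and b in _BASE_INDEX:
                            expected[_BASE_INDEX[a], _BASE_INDEX[b]] += 1.0
                    if c3 is not None:
                        f = np.zeros(4)
                        f[c3] = 1.0
                        f_start = 0.0
                    else:
                        f = np.zeros(4)
                        f_start = 1.0
        return expected

    def _calibrate(self, max_iter: int, tol: float) -> None:
        for it in range(max_iter):
            w = np.exp(self.log_w)
            expected = self._expected_counts(w)
            update = np.log(self.target + 0.5) - np.log(expected + 0.5)
            self.n_iterations = it + 1
            if np.abs(update).max() < tol:
                break
            self.log_w = np.clip(self.log_w + update, -30.0, 30.0)
            self.log_w -= self.log_w.mean()   # remove gauge drift
        else:
            logger.debug("dinucleotide calibration stopped at max_iter=%d", max_iter)

    # -- sampling -----------------------------------------------------------

    def _sampling_tables(self) -> list[list]:
        """Per gene, per slot: cumulative codon weights for each previous-base
        state (4 bases + start), or the verbatim codon."""
        w = np.exp(self.log_w)
        tables = []
        for plan in self.plans:
            b_after = self._backward(w, plan)
            gene_tab = []
            for i, tok in enumerate(plan):
                if tok[0] == "aa":
                    aa = tok[1]
                    c1, c2, c3 = self.fam.c1[aa], self.fam.c2[aa], self.fam.c3[aa]
                    wint = w[c1, c2] * w[c2, c3] * b_after[i][c3]
                    full = np.vstack([w[:, c1] * wint[None, :], wint[None, :]])
                    cum = np.cumsum(full, axis=1)
                    cum /= cum[:, -1:]
                    gene_tab.append((self.fam.codons[aa], cum, c3))
                else:
                    gene_tab.append((tok[1], None, tok[3]))
            tables.append(gene_tab)
        return tables

    def replicate(self, rng: np.random.Generator) -> list[str]:
        """One randomized synonymous reconstruction of every gene."""
        seqs = []
        for gene_tab in self._tables:
            out = []
            prev = 4  # start state
            us = rng.random(len(gene_tab))
            for i, (codons, cum, c3) in enumerate(gene_tab):
                if cum is None:  # verbatim codon
                    out.append(codons)
                    prev = c3 if c3 is not None else 4
                    continue
                k = int(np.searchsorted(cum[prev], us[i], side="right"))
                k = min(k, len(codons) - 1)
                out.append(codons[k])
                prev = int(c3[k])
            seqs.append("".join(out))
        return seqs


def randomize_gene(seq: str, model: DinucTransitionModel,
                   code: GeneticCode | None = None,
                   rng: np.random.Generator | int | None = None) -> str:
    """Resample one CDS under the model's Gibbs weights (no calibration).

    Translation is preserved exactly; stop codons and N-containing codons
    are copied verbatim.  For sample-level analyses prefer
    :class:`SequenceRandomizer` / :func:`randomize_sample`, which calibrate
    the weights to the sample's dinucleotide content.
    """
    code = code if code is not None else standard_code()
    if len(seq) % 3 != 0:
        raise ValueError("sequence length not divisible by 3")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    collection = CdsCollection("_single", [CdsRecord("_g", seq)])
    sampler = SequenceRandomizer(collection, code, model=model, calibrate=False)
    return sampler.replicate(rng)[0]


def _swap_randomize(collection: CdsCollection, code: GeneticCode,
                    rng: np.random.Generator) -> list[str]:
    """Shuffle the sample's codons within each synonymous family (exact counts)."""
    pools: dict[str, list[str]] = {}
    layout: list[list[tuple[str | None, str]]] = []
    for rec in collection.records:
        gene = []
        for i in range(len(rec.sequence) // 3):
            codon = rec.sequence[3 * i:3 * i + 3]
            aa = code.codon_to_aa.get(codon)
            gene.append((aa, codon))
            if aa is not None:
                pools.setdefault(aa, []).append(codon)
        layout.append(gene)
    for aa in pools:
        pools[aa] = [pools[aa][j] for j in rng.permutation(len(pools[aa]))]
    cursors = {aa: 0 for aa in pools}
    seqs = []
    for gene in layout:
        parts = []
        for aa, codon in gene:
            if aa is None:
                parts.append(codon)
            else:
                parts.append(pools[aa][cursors[aa]])
                cursors[aa] += 1
        seqs.append("".join(parts))
    return seqs


@dataclass
class RandomizedReplicate:
    """One randomized version of a sample; proteins and lengths match the real one."""

    index: int
    collection: CdsCollection
    seed: int


def randomize_sample(collection: CdsCollection, n_replicates: int = 20,
                     seed: int | None = None,
                     code: GeneticCode | None = None,
                     method: str = "markov",
                     calibrate: bool = True) -> list[RandomizedReplicate]:
    """Generate seeded randomized replicates of a sample.

    The Gibbs weights are fitted (and, by default, calibrated) once from
    the real collection; each replicate uses an independent child seed so
    any replicate is reproducible on its own.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    if method not in ("markov", "swap"):
        raise ValueError(f"unknown method {method!r}")
    code = code if code is not None else standard_code()
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_replicates)]
    sampler = (SequenceRandomizer(collection, code, calibrate=calibrate)
               if method == "markov" else None)
    replicates = []
    for idx, child in enumerate(child_seeds):
        rng = np.random.default_rng(child)
        seqs = (sampler.replicate(rng) if sampler is not None
                else _swap_randomize(collection, code, rng))
        records = [CdsRecord(r.gene_id, s)
                   for r, s in zip(collection.records, seqs)]
        replicates.append(RandomizedReplicate(
            idx, CdsCollection(f"{collection.sample_id}~rand{idx}", records,
                               provenance=f"{method} randomization of {collection.sample_id}"),
            child))
    return replicates


@dataclass
class ZScoreResult:
    index_name: str
    real: float
    rand_mean: float
    rand_sd: float
    z: float
    n_replicates: int
    seed: int | None = None


def zscore(real: float, randoms: Sequence[float],
           index_name: str = "") -> ZScoreResult:
    """``z = (real - mean(randoms)) / sd(randoms)`` with the sample sd (ddof=1)."""
    randoms = np.asarray(randoms, dtype=float)
    if randoms.size < 2:
        raise ValueError("need at least 2 random values")
    sd = float(randoms.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate null: replicate values are identical")
    mean = float(randoms.mean())
    return ZScoreResult(index_name, float(real), mean, sd,
                        (float(real) - mean) / sd, int(randoms.size))


def selection_analysis(collection: CdsCollection,
                       abundances: Mapping[str, float],
                       n_replicates: int = 20,
                       seed: int | None = None,
                       code: GeneticCode | None = None,
                       top_frac: float = 0.05) -> dict[str, ZScoreResult]:
    """Z-scores of mean CAI, ENC and mean DCBS against the randomized null.

    The CAI reference membership is fixed by the real abundance ranking
    (synonymous substitution does not change abundances); reference codon
    weights are recomputed from each replicate's sequences.  ENC enters
    the Z-score uncapped: near the unbiased boundary the [20, 61] cap
    would clip the null distribution one-sidedly and distort z.
    """
    code = code if code is not None else standard_code()
    reference = build_reference_set(collection, abundances, top_frac)
    real = sample_cub_summary(collection, abundances, code,
                              top_frac=top_frac, reference=reference,
                              enc_cap=False)
    replicates = randomize_sample(collection, n_replicates, seed, code)
    rand_scores: dict[str, list[float]] = {"CAI": [], "ENC": [], "DCBS": []}
    for rep in replicates:
        scores = sample_cub_summary(rep.collection, abundances, code,
                                    top_frac=top_frac, reference=reference,
                                    enc_cap=False)
        rand_scores["CAI"].append(scores.mean_cai)
        rand_scores["ENC"].append(scores.enc)
        rand_scores["DCBS"].append(scores.mean_dcbs)
    real_vals = {"CAI": real.mean_cai, "ENC": real.enc, "DCBS": real.mean_dcbs}
    out = {}
    for name in ("CAI", "ENC", "DCBS"):
        res = zscore(real_vals[name], rand_scores[name], name)
        res.seed = seed
        out[name] = res
    return out
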