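"""Synthetic biome-structured communities for end-to-end pipeline testing.

The generator emulates the structure the analysis layer is built to
detect: several biomes, each with its own synonymous codon preference
(samples from the same biome more alike than samples from different
biomes), an optional GC tilt, lognormal gene abundances for CAI reference
selection, optional abundance-linked enrichment of family-optimal codons
(translational selection), and biome-correlated feature-abundance
matrices.

Every draw descends from a single master seed through a fixed
``SeedSequence`` spawn tree, so a study is byte-for-byte reproducible.

Key dials
---------
``effect_size``
    Between-biome divergence of synonymous preferences.  Biome archetypes
    are Dirichlet perturbations of a shared base profile with
    concentration ``kappa0 / effect_size``; 0 means identical archetypes
    (the null used for calibration tests).
``aa_effect_size``
    Same mechanism for amino-acid composition, independent of the codon
    dial, so codon-level signal can be isolated from AA-level signal.
``selection_strength``
    Tilts each gene's codon draws toward its family's preferred codon in
    proportion to the gene's abundance quantile — high-abundance genes
    become optimal-codon rich, which CAI/ENC/DCBS Z-scores should detect.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .seqcore import CODONS64, CdsCollection, CdsRecord, GeneticCode, standard_code

#: concentration of the biome-perturbation Dirichlet at effect_size = 1
_KAPPA0 = 50.0
_AA_KAPPA0 = 400.0

DEFAULT_BIOMES = ("soil", "marine", "freshwater", "digestive_system",
                  "wastewater", "plant_associated", "sediment")


@dataclass
class StudyConfig:
    """All knobs of the synthetic community generator."""

    n_biomes: int = 7
    samples_per_biome: int = 5
    genes_per_sample: int = 200
    median_gene_length: int = 300      # codons
    length_sigma: float = 0.6          # lognormal sigma of gene length
    min_gene_length: int = 30          # codons
    effect_size: float = 1.0           # between-biome synonymous divergence
    aa_effect_size: float = 0.0        # between-biome AA-composition divergence
    within_concentration: float = 300.0  # per-sample Dirichlet concentration
    abundance_sigma: float = 1.0       # lognormal sd of gene abundances
    selection_strength: float = 0.0    # abundance-linked optimal-codon tilt
    gc_biome_effect: float = 0.0       # biome-level GC3 preference tilt
    gc_gradient: float = 0.0           # biome-independent per-sample GC3 tilt
    uniform_preferences: bool = False  # no codon preference at all: flat,
                                       # noise-free synonymous choice (the
                                       # calibration null for selection tests)
    feature_matrix_sizes: dict = field(default_factory=lambda: {
        "GO_BP": 500, "GO_MF": 500, "GO_CC": 100})
    feature_concentration: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_biomes, self.samples_per_biome, self.genes_per_sample) < 1:
            raise ValueError("counts must be positive")
        if self.effect_size < 0 or self.aa_effect_size < 0:
            raise ValueError("effect sizes must be >= 0")


@dataclass
class BiomeArchetype:
    """Per-biome generative parameters."""

    name: str
    family_prefs: dict[str, np.ndarray]   # aa -> distribution over its codons
    aa_freqs: np.ndarray                  # over code.amino_acids
    gc_shift: float
    feature_centroids: dict[str, np.ndarray]


def _gc3_sign(code: GeneticCode) -> dict[str, np.ndarray]:
    out = {}
    for aa, codons in code.families.items():
        out[aa] = np.array([1.0 if c[2] in "GC" else -1.0 for c in codons])
    return out


def _tilt_gc(prefs: dict[str, np.ndarray], shift: float,
             signs: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    if shift == 0.0:
        return {aa: p.copy() for aa, p in prefs.items()}
    out = {}
    for aa, p in prefs.items():
        w = p * np.exp(shift * signs[aa])
        out[aa] = w / w.sum()
    return out


def _perturb(dist: np.ndarray, effect: float, kappa0: float,
             rng: np.random.Generator) -> np.ndarray:
    """Dirichlet perturbation whose divergence from ``dist`` grows with effect."""
    if effect == 0.0:
        return dist.copy()
    if len(dist) == 1:
        return dist.copy()
    alpha = np.maximum(dist * (kappa0 / effect), 1e-3)
    return rng.dirichlet(alpha)


def make_archetypes(config: StudyConfig,
                    code: GeneticCode | None = None) -> list[BiomeArchetype]:
    """Draw the shared base profile and its per-biome perturbations."""
    code = code if code is not None else standard_code()
    root = np.random.SeedSequence(config.seed)
    arch_ss, _samples_ss, feat_ss = root.spawn(3)
    rng = np.random.default_rng(arch_ss)
    signs = _gc3_sign(code)

    # shared base: moderately skewed synonymous preferences, near-flat AA use
    base_prefs: dict[str, np.ndarray] = {}
    for aa, codons in code.families.items():
        if config.uniform_preferences:
            base_prefs[aa] = np.full(len(codons), 1.0 / len(codons))
        else:
            base_prefs[aa] = rng.dirichlet(np.full(len(codons), 3.0))
    base_aa = (np.full(len(code.amino_acids), 1.0 / len(code.amino_acids))
               if config.uniform_preferences
               else rng.dirichlet(np.full(len(code.amino_acids), 12.0)))

    feat_rng = np.random.default_rng(feat_ss)
    names = [DEFAULT_BIOMES[i] if i < len(DEFAULT_BIOMES) else f"biome{i + 1:02d}"
             for i in range(config.n_biomes)]
    gc_shifts = (config.gc_biome_effect
                 * (np.linspace(-1, 1, config.n_biomes)
                    if config.n_biomes > 1 else np.zeros(1)))
    archetypes = []
    for b, name in enumerate(names):
        prefs = {aa: _perturb(base_prefs[aa], config.effect_size, _KAPPA0, rng)
                 for aa in code.families}
        prefs = _tilt_gc(prefs, float(gc_shifts[b]), signs)
        aa_freqs = _perturb(base_aa, config.aa_effect_size, _AA_KAPPA0, rng)
        centroids = {
            mname: feat_rng.dirichlet(np.full(nfeat, 0.8))
            for mname, nfeat in sorted(config.feature_matrix_sizes.items())
        }
        archetypes.append(BiomeArchetype(name, prefs, aa_freqs,
                                         float(gc_shifts[b]), centroids))
    return archetypes


def generate_sample(archetype: BiomeArchetype, config: StudyConfig,
                    rng: np.random.Generator | int, sample_id: str,
                    gc_shift_extra: float = 0.0,
                    code: GeneticCode | None = None,
                    ) -> tuple[CdsCollection, pd.Series]:
    """One sample: a CDS collection plus its lognormal gene-abundance table."""
    code = code if code is not None else standard_code()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    signs = _gc3_sign(code)
    n = config.genes_per_sample

    lengths = np.maximum(
        config.min_gene_length,
        np.round(rng.lognormal(np.log(config.median_gene_length),
                               config.length_sigma, n)).astype(int))
    abundances = rng.lognormal(0.0, config.abundance_sigma, n)

    # per-sample preference: within-biome noise around the archetype.
    # uniform_preferences means *no* codon preference at all, so the
    # per-sample Dirichlet draw (itself a small persistent preference)
    # is skipped in that mode.
    prefs = {}
    for aa, p in archetype.family_prefs.items():
        if len(p) == 1 or config.uniform_preferences:
            prefs[aa] = p.copy()
        else:
            prefs[aa] = rng.dirichlet(np.maximum(p * config.within_concentration, 1e-3))
    prefs = _tilt_gc(prefs, gc_shift_extra, signs)

    # abundance-linked tilt toward the archetype's family-optimal codon
    quantile = rankdata(abundances) / n
    tilt = np.clip(config.selection_strength * quantile, 0.0, 0.97)

    amino_acids = list(code.families)
    aa_codon_ids = {aa: np.array([CODONS64.index(c) for c in code.families[aa]])
                    for aa in amino_acids}
    optimal_idx = {aa: int(np.argmax(archetype.family_prefs[aa]))
                   for aa in amino_acids}

    total = int(lengths.sum())
    gene_of_pos = np.repeat(np.arange(n), lengths)
    aa_idx = rng.choice(len(amino_acids), size=total, p=archetype.aa_freqs)
    codon_ids = np.empty(total, dtype=np.intp)
    for a, aa in enumerate(amino_acids):
        mask = aa_idx == a
        npos = int(mask.sum())
        if npos == 0:
            continue
        fam_ids = aa_codon_ids[aa]
        k = len(fam_ids)
        if k == 1:
            codon_ids[mask] = fam_ids[0]
            continue
        cum = np.cumsum(prefs[aa])
        t = tilt[gene_of_pos[mask]][:, None]
        opt_step = (np.arange(k) >= optimal_idx[aa]).astype(float)
        cum_pos = (1.0 - t) * cum[None, :] + t * opt_step[None, :]
        u = rng.random(npos)
        sel = np.clip((cum_pos < u[:, None]).sum(axis=1), 0, k - 1)
        codon_ids[mask] = fam_ids[sel]

    codon_strs = np.array(CODONS64)
    stops = sorted(code.stop_codons)
    stop_choice = rng.integers(0, len(stops), n)
    records = []
    start = 0
    for g in range(n):
        end = start + lengths[g]
        seq = "".join(codon_strs[codon_ids[start:end]]) + stops[stop_choice[g]]
        records.append(CdsRecord(f"{sample_id}_g{g:05d}", seq))
        start = end
    collection = CdsCollection(sample_id, records, provenance="synthetic")
    abund = pd.Series(abundances, index=[r.gene_id for r in records])
    return collection, abund


@dataclass
class CommunityStudy:
    """A full synthetic (or loaded) study: samples, labels, abundances, features."""

    collections: dict[str, CdsCollection]
    labels: dict[str, str]
    abundances: dict[str, pd.Series]
    feature_matrices: dict[str, pd.DataFrame]
    config: StudyConfig | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.collections)

    def write(self, outdir: str | Path) -> None:
        """Serialize to FASTA + TSV + a reproducibility manifest."""
        outdir = Path(outdir)
        (outdir / "fasta").mkdir(parents=True, exist_ok=True)
        (outdir / "abundances").mkdir(exist_ok=True)
        (outdir / "features").mkdir(exist_ok=True)
        rows = []
        for sid, coll in self.collections.items():
            fasta = outdir / "fasta" / f"{sid}.fasta"
            with open(fasta, "w") as fh:
                for rec in coll:
                    fh.write(f">{rec.gene_id}\n{rec.sequence}\n")
            if sid in self.abundances:
                ab = outdir / "abundances" / f"{sid}.tsv"
                self.abundances[sid].rename("abundance").to_csv(
                    ab, sep="\t", index_label="gene_id", float_format="%.10g")
            rows.append({"sample_id": sid, "biome": self.labels[sid],
                         "path": str(fasta.relative_to(outdir))})
        pd.DataFrame(rows).to_csv(outdir / "metadata.tsv", sep="\t", index=False)
        for name, mat in self.feature_matrices.items():
            mat.to_csv(outdir / "features" / f"{name}.tsv", sep="\t",
                       index_label="sample_id", float_format="%.10g")
        if self.config is not None:
            with open(outdir / "manifest.json", "w") as fh:
                json.dump(asdict(self.config), fh, indent=2, sort_keys=True)


def generate_study(config: StudyConfig,
                   code: GeneticCode | None = None) -> CommunityStudy:
    """Generate the full study deterministically from ``config.seed``."""
    code = code if code is not None else standard_code()
    archetypes = make_archetypes(config, code)
    root = np.random.SeedSequence(config.seed)
    _arch_ss, samples_ss, feat_ss = root.spawn(3)
    n_total = config.n_biomes * config.samples_per_biome
    sample_seeds = samples_ss.spawn(n_total)

    # biome-independent GC gradient: offsets interleave across biomes
    if config.gc_gradient != 0.0 and n_total > 1:
        gradient = config.gc_gradient * np.linspace(-1, 1, n_total)
    else:
        gradient = np.zeros(n_total)

    collections: dict[str, CdsCollection] = {}
    labels: dict[str, str] = {}
    abundances: dict[str, pd.Series] = {}
    for b, arch in enumerate(archetypes):
        for j in range(config.samples_per_biome):
            global_idx = j * config.n_biomes + b  # round-robin: gradient not
            sid = f"{arch.name}_s{j + 1}"         # confounded with biome
            rng = np.random.default_rng(sample_seeds[b * config.samples_per_biome + j])
            coll, ab = generate_sample(arch, config, rng, sid,
                                       gc_shift_extra=float(gradient[global_idx]),
                                       code=code)
            collections[sid] = coll
            labels[sid] = arch.name
            abundances[sid] = ab

    feat_rng = np.random.default_rng(feat_ss.spawn(1)[0])
    matrices: dict[str, pd.DataFrame] = {}
    sample_order = list(collections)
    for mname, nfeat in sorted(config.feature_matrix_sizes.items()):
        rows = []
        for sid in sample_order:
            arch = archetypes[[a.name for a in archetypes].index(labels[sid])]
            centroid = arch.feature_centroids[mname]
            rows.append(feat_rng.dirichlet(
                np.maximum(centroid * config.feature_concentration, 1e-3)))
        matrices[mname] = pd.DataFrame(
            rows, index=sample_order,
            columns=[f"{mname}_f{j:04d}" for j in range(nfeat)])
    return CommunityStudy(collections, labels, abundances, matrices, config)


def load_study(directory: str | Path) -> CommunityStudy:
    """Read a study from the on-disk layout produced by ``CommunityStudy.write``."""
    from .seqcore import read_sample_fasta

    directory = Path(directory)
    meta = pd.read_csv(directory / "metadata.tsv", sep="\t")
    collections, labels, abundances = {}, {}, {}
    for _, row in meta.iterrows():
        sid = str(row["sample_id"])
        collections[sid] = read_sample_fasta(directory / row["path"], sid)
        labels[sid] = str(row["biome"])
        ab_path = directory / "abundances" / f"{sid}.tsv"
        if ab_path.exists():
            tab = pd.read_csv(ab_path, sep="\t", index_col="gene_id")
            abundances[sid] = tab["abundance"]
    matrices = {}
    feat_dir = directory / "features"
    if feat_dir.is_dir():
        for path in sorted(feat_dir.glob("*.tsv")):
            matrices[path.stem] = pd.read_csv(path, sep="\t", index_col="sample_id")
    return CommunityStudy(collections, labels, abundances, matrices, None)
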