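"""End-to-end orchestration: profiles -> distances -> statistics -> report.

``run_pipeline`` wires the library modules together in the order a full
community codon-usage study runs them, writing every intermediate table as
TSV plus a manifest listing all outputs.  The CLI is a thin wrapper over
this module.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, cub, distances, groupstats, nullmodels, profiles
from .seqcore import GeneticCode, standard_code
from .synthetic import CommunityStudy, StudyConfig, generate_study, load_study

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """What to run and with which parameters; serializable to the manifest."""

    input_dir: str | None = None             # load a study from disk ...
    simulate: StudyConfig | None = None      # ... or generate one
    output_dir: str = "metacodon_out"
    kinds: tuple[str, ...] = ("absCUF", "synCUF", "aa")
    methods: tuple[str, ...] = ("EU", "ES", "BC")
    genetic_code: int = 11
    anosim_permutations: int = 10_000
    ci_randomizations: int = 100
    null_replicates: int = 20
    cai_top_frac: float = 0.05
    run_anosim: bool = True
    run_ci: bool = True
    run_cub: bool = True
    run_zscores: bool = False                # costly; opt in
    run_association: bool = True
    seed: int = 0

    def to_jsonable(self) -> dict:
        d = dict(self.__dict__)
        if self.simulate is not None:
            d["simulate"] = dict(self.simulate.__dict__)
        d["kinds"] = list(self.kinds)
        d["methods"] = list(self.methods)
        d.pop("output_dir", None)  # implied by the manifest's location
        return d


def _write(frame: pd.DataFrame, path: Path, manifest: list[str], **kw) -> None:
    frame.to_csv(path, sep="\t", float_format="%.10g", **kw)
    manifest.append(path.name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the result bundle in memory."""
    if (config.input_dir is None) == (config.simulate is None):
        raise ValueError("provide exactly one of input_dir or simulate")
    code = GeneticCode.from_table_id(config.genetic_code)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    study: CommunityStudy = (generate_study(config.simulate, code)
                             if config.simulate is not None
                             else load_study(config.input_dir))
    labels = study.labels
    results: dict = {"study": study}

    # ---- profiles ------------------------------------------------------
    per_kind: dict[str, list[profiles.FrequencyProfile]] = {k: [] for k in config.kinds}
    gc_values: dict[str, float] = {}
    for sid, coll in study.collections.items():
        profs = profiles.sample_profiles(coll, code, tuple(config.kinds))
        for kind, prof in profs.items():
            per_kind[kind].append(prof)
        gc_values[sid] = profiles.gc_content(coll)
    results["profiles"] = per_kind
    results["gc"] = gc_values
    for kind, plist in per_kind.items():
        _write(profiles.profiles_to_frame(plist), outdir / f"profile_{kind}.tsv",
               manifest, index_label="sample_id")
    _write(pd.Series(gc_values, name="gc").to_frame(), outdir / "gc_content.tsv",
           manifest, index_label="sample_id")

    # ---- distance matrices --------------------------------------------
    matrices: dict[tuple[str, str], distances.DistanceMatrix] = {}
    for kind, plist in per_kind.items():
        for method in config.methods:
            dm = distances.distance_matrix(plist, method)
            matrices[(kind, method)] = dm
            _write(dm.to_dataframe(), outdir / f"dist_{kind}_{method}.tsv",
                   manifest, index_label="sample_id")
    results["distances"] = matrices

    rng = np.random.default_rng(config.seed)

    # ---- group statistics ---------------------------------------------
    if config.run_anosim:
        rows = []
        for (kind, method), dm in matrices.items():
            res = groupstats.anosim(dm, labels, config.anosim_permutations,
                                    seed=int(rng.integers(2 ** 31)))
            rows.append({"kind": kind, "method": method, "R": res.R,
                         "p": res.p, "n_permutations": res.n_permutations,
                         "seed": res.seed})
        results["anosim"] = pd.DataFrame(rows)
        _write(results["anosim"], outdir / "anosim.tsv", manifest, index=False)

    if config.run_ci:
        rows = []
        biomes = sorted(set(labels.values()))
        for (kind, method), dm in matrices.items():
            for biome in biomes:
                if sum(1 for v in labels.values() if v == biome) < 2:
                    continue
                res = groupstats.ci_permutation_test(
                    dm, labels, biome, config.ci_randomizations,
                    seed=int(rng.integers(2 ** 31)))
                rows.append({"kind": kind, "method": method, "biome": biome,
                             "CI": res.ci, "p": res.p,
                             "n_random": res.n_random, "seed": res.seed})
        results["ci"] = pd.DataFrame(rows)
        _write(results["ci"], outdir / "clustering_index.tsv", manifest, index=False)

    # ---- CUB indices ---------------------------------------------------
    if config.run_cub:
        if not study.abundances:
            raise ValueError("CUB stage requires gene abundance tables "
                             "(for the CAI reference set)")
        rows = []
        cub_scores = {}
        for sid, coll in study.collections.items():
            scores = cub.sample_cub_summary(coll, study.abundances[sid], code,
                                            top_frac=config.cai_top_frac)
            cub_scores[sid] = scores
            rows.append({"sample_id": sid, "biome": labels[sid],
                         "mean_cai": scores.mean_cai, "enc": scores.enc,
                         "mean_dcbs": scores.mean_dcbs,
                         "n_genes": len(coll),
                         "reference_size": scores.reference_size})
        results["cub"] = pd.DataFrame(rows).set_index("sample_id")
        _write(results["cub"], outdir / "cub_indices.tsv", manifest,
               index_label="sample_id")

        if config.run_zscores:
            zrows = []
            for sid, coll in study.collections.items():
                zs = nullmodels.selection_analysis(
                    coll, study.abundances[sid], config.null_replicates,
                    seed=int(rng.integers(2 ** 31)), code=code,
                    top_frac=config.cai_top_frac)
                for name, res in zs.items():
                    zrows.append({"sample_id": sid, "index": name,
                                  "real": res.real, "rand_mean": res.rand_mean,
                                  "rand_sd": res.rand_sd, "z": res.z,
                                  "n_replicates": res.n_replicates,
                                  "seed": res.seed})
            results["zscores"] = pd.DataFrame(zrows)
            _write(results["zscores"], outdir / "zscores.tsv", manifest, index=False)

    # ---- association layer --------------------------------------------
    if config.run_association:
        cols: dict[str, object] = {}
        for (kind, method), dm in matrices.items():
            cols[f"{kind}_{method}"] = dm
        table = association.build_distance_table(cols)
        table["gc"] = association.gc_distance_column(
            gc_values, table.index)
        for mname, mat in study.feature_matrices.items():
            plist = [profiles.FrequencyProfile(
                sid, "kmer", mat.loc[sid].clip(lower=0.0), k=0)
                for sid in study.sample_ids]
            dm = distances.distance_matrix(plist, "BC")
            table[f"feature_{mname}_BC"] = dm.pair_series()
        results["distance_table"] = table
        _write(table, outdir / "distance_table.tsv", manifest,
               index_label=["sample_a", "sample_b"])

        target = ("absCUF_EU" if "absCUF_EU" in table.columns
                  else table.columns[0])
        others = [c for c in table.columns if c != target]
        rows = []
        for test_col in others:
            rho, p = association.spearman(table[target], table[test_col])
            controls = [c for c in others if c != test_col]
            try:
                prho, pp = association.partial_correlation(
                    table, target, test_col, controls)
            except ValueError:
                prho, pp = float("nan"), float("nan")
            rows.append({"target": target, "test": test_col, "rho": rho,
                         "p": p, "partial_rho": prho, "partial_p": pp})
        results["correlations"] = pd.DataFrame(rows)
        _write(results["correlations"], outdir / "correlations.tsv",
               manifest, index=False)

        reg = association.fit_regression(table, target, others)
        results["regression"] = reg
        reg_frame = pd.DataFrame({"beta": reg.beta, "p": reg.p_values})
        reg_frame.loc["(R_squared)"] = [reg.r_squared, float("nan")]
        _write(reg_frame, outdir / f"regression_{target}.tsv", manifest,
               index_label="predictor")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"config": config.to_jsonable(), "outputs": sorted(manifest)},
                  fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
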