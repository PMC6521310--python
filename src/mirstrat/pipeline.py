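"""Pipeline driver: preprocess -> stratify -> diffexpr -> subtyping ->
enrichment -> pathway impact -> clinical association, with a machine-readable
run manifest. Rerunning with the same configuration is bit-identical.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from . import __version__
from .clinical_stats import association_table
from .diffexpr import moderated_t_test, select_degs
from .enrichment import run_target_enrichment
from .pathway_impact import run_spia
from .preprocess import filter_expressed, normalize_log2, remove_outliers, stratify
from .subtyping import consensus_nmf, extract_features

log = logging.getLogger(__name__)

STAGES = [
    "preprocess",
    "stratify",
    "diffexpr",
    "subtyping",
    "enrichment",
    "pathway_impact",
    "clinical_stats",
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed and a stable hash of the
    stage name, so stage-level streams are independent of stage order."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class PipelineConfig:
    expression_path: str
    mirna_path: str
    targets_path: str
    output_dir: str
    pathways_path: str | None = None
    gene_sets_path: str | None = None
    clinical_path: str | None = None
    q: float = 0.25
    min_nonzero_frac: float = 0.8
    outlier_z: float = 5.0
    outlier_tail: str = "both"
    deg_alpha: float = 0.05
    top_k: int = 200
    k_min: int = 2
    k_max: int = 6
    n_runs: int = 200
    enrichment_B: int = 10_000
    spia_n_boot: int = 20_000
    spia_threshold: float = 2e-6
    seed: int = 0
    clinical_features: list[str] = field(
        default_factory=lambda: ["depth_of_invasion", "lymphatic_invasion"]
    )
    clinical_covariates: list[str] = field(default_factory=lambda: ["gender", "age", "location"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write results plus a manifest to the output dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "mirstrat",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
    }

    def _run(stage: str, fn):
        try:
            counts = fn()
        except FileNotFoundError as exc:
            raise RuntimeError(f"stage {stage!r} failed: missing input file {exc.filename}") from exc
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = counts
        log.info("stage %s done: %s", stage, counts)

    state: dict = {}

    def _preprocess():
        expr = mio.read_expression_tsv(config.expression_path)
        expr = filter_expressed(expr, config.min_nonzero_frac)
        expr, removed = remove_outliers(expr, z_cut=config.outlier_z, tail=config.outlier_tail)
        expr = normalize_log2(expr)
        state["expr"] = expr
        mio.write_expression_tsv(expr, out / "expression_normalized.tsv")
        return {"genes": int(expr.shape[0]), "samples": int(expr.shape[1]),
                "outliers_removed": removed}

    def _stratify():
        mirna = mio.read_vector_tsv(config.mirna_path)
        mirna = mirna.loc[[s for s in state["expr"].columns if s in mirna.index]]
        strat = stratify(mirna, q=config.q)
        state["strat"] = strat
        mio.write_stratification_tsv(strat.labels, out / "stratification.tsv")
        return {"high": int((strat.labels == "high").sum()),
                "low": int((strat.labels == "low").sum()),
                "excluded": int((strat.labels == "excluded").sum())}

    def _diffexpr():
        degs = moderated_t_test(state["expr"], state["strat"])
        state["degs"] = degs
        degs.to_csv(out / "deg_table.tsv", sep="\t", index_label="gene")
        sig = degs[degs["p_adj"] < config.deg_alpha]
        return {"genes_tested": int(len(degs)),
                "significant": int(len(sig)),
                "up": int((sig["direction"] == "up").sum()),
                "down": int((sig["direction"] == "down").sum()),
                "d0": float(degs.attrs["d0"]) if np.isfinite(degs.attrs["d0"]) else "inf"}

    def _subtyping():
        top = select_degs(state["degs"], alpha=1.0, top_k=config.top_k)
        sub = state["expr"].loc[top.index]
        result = consensus_nmf(
            sub, k_min=config.k_min, k_max=config.k_max, n_runs=config.n_runs,
            seed=stage_seed(config.seed, "subtyping"),
        )
        state["consensus"] = result
        result.assignments.to_csv(out / "cluster_assignments.tsv", sep="\t",
                                  index_label="sample")
        pd.DataFrame(result.consensus[result.selected_rank],
                     index=result.sample_ids, columns=result.sample_ids).to_csv(
            out / "consensus_matrix.tsv", sep="\t", index_label="sample")
        # metagene features at the selected rank (single full factorization)
        from .subtyping import nmf_brunet

        fac = nmf_brunet(sub.to_numpy(), result.selected_rank,
                         seed=stage_seed(config.seed, "subtyping-features"))
        feats = extract_features(fac, gene_ids=list(sub.index))
        state["features"] = feats
        feats.table.to_csv(out / "metagene_features.tsv", sep="\t")
        return {"selected_rank": int(result.selected_rank),
                "cophenetic": {str(k): round(v, 4) for k, v in result.cophenetic.items()},
                "features_selected": int(feats.table["selected"].sum())}

    def _enrichment():
        targets = mio.read_target_list(config.targets_path)
        assoc, mag = run_target_enrichment(
            state["degs"], targets, B=config.enrichment_B,
            seed=stage_seed(config.seed, "enrichment"),
        )
        rows = [
            {"statistic": r.statistic_kind, "ES": r.es_observed, "NES": r.nes,
             "p_empirical": r.p_empirical, "B": r.B, "targets": r.target_set_size}
            for r in (assoc, mag)
        ]
        pd.DataFrame(rows).to_csv(out / "target_enrichment.tsv", sep="\t", index=False)
        state["enrichment"] = (assoc, mag)
        return {"association_p": assoc.p_empirical, "magnitude_p": mag.p_empirical,
                "targets_in_universe": assoc.target_set_size}

    def _pathway_impact():
        if config.pathways_path is None:
            return {"skipped": True}
        if not Path(config.pathways_path).exists():
            raise FileNotFoundError(2, "no such file", config.pathways_path)
        pathways = mio.read_pathways_tsv(config.pathways_path)
        spia = run_spia(
            pathways, state["degs"], alpha_de=config.deg_alpha,
            threshold=config.spia_threshold, n_boot=config.spia_n_boot,
            seed=stage_seed(config.seed, "pathway_impact"),
        )
        spia.to_csv(out / "spia_results.tsv", sep="\t", index_label="pathway")
        return {"pathways": int(len(spia)),
                "significant": int(spia["significant"].sum())}

    def _clinical():
        if config.clinical_path is None:
            return {"skipped": True}
        clinical = mio.read_clinical_tsv(config.clinical_path)
        clusters = state["consensus"].assignments
        common = [s for s in clusters.index if s in clinical.index]
        table = association_table(
            clinical.loc[common], clusters.loc[common],
            features=config.clinical_features,
            covariate_cols=config.clinical_covariates,
        )
        table.to_csv(out / "clinical_associations.tsv", sep="\t", index_label="feature")
        return {"features_tested": int(len(table))}

    for stage, fn in zip(
        STAGES,
        [_preprocess, _stratify, _diffexpr, _subtyping, _enrichment, _pathway_impact, _clinical],
    ):
        _run(stage, fn)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
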