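"""End-to-end analysis runs: config in, reproducible output directory out.

``run_full_analysis`` wires the stages together -- load or simulate the
bundle, preprocess with QC, permutation-based PCA-dimension selection,
CCA at the chosen dimension with FWE p-values per mode, loadings and
interpretation tables -- and writes every result as deterministic JSON/TSV
plus a timestamped log.  The run configuration is serialized verbatim
into the output directory, and a MANIFEST listing all outputs is written
last so an interrupted run is detectable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cca_core import fit_cca, fix_mode_signs, pca_reduce, variable_loadings
from .dataio import (
    DatasetBundle,
    align_subjects,
    read_confound_table,
    read_data_matrix,
    read_region_metadata,
)
from .perm_inference import (
    DEFAULT_ALPHA,
    DEFAULT_CANDIDATE_DS,
    DEFAULT_N_PERM,
    select_pca_dimension,
    significant_modes,
)
from .preprocess import PreprocessConfig, preprocess_pipeline
from .report import loading_table_tsv, rank_loadings, select_top
from .synthetic import SyntheticConfig, generate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative description of one analysis run.

    Either the three input paths or ``synthetic`` must be given.  All
    thresholds default to the study's values.
    """

    brain_path: str | None = None
    behaviour_path: str | None = None
    confounds_path: str | None = None
    region_metadata_path: str | None = None
    synthetic: dict | None = None
    site_label_order: list[str] | None = None
    z_cut: float = -1.96
    max_fd_cut: float = 1.3
    mean_fd_cut: float = 0.3
    modal_share_cut: float = 0.95
    candidate_ds: list[int] = field(default_factory=lambda: list(DEFAULT_CANDIDATE_DS))
    n_perm: int = DEFAULT_N_PERM
    alpha: float = DEFAULT_ALPHA
    top_k: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _load_bundle(config: RunConfig) -> DatasetBundle:
    if config.synthetic is not None:
        syn = SyntheticConfig(**config.synthetic)
        if syn.seed is None:
            syn.seed = config.seed
        bundle, _ = generate(syn)
        return bundle
    if not (config.brain_path and config.behaviour_path and config.confounds_path):
        raise ValueError("give brain/behaviour/confounds paths or a synthetic block")
    brain = read_data_matrix(config.brain_path)
    behaviour = read_data_matrix(config.behaviour_path, allow_missing=True)
    confounds = read_confound_table(config.confounds_path, config.site_label_order)
    return align_subjects(brain, behaviour, confounds)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_full_analysis(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the whole pipeline and write results under ``out_dir``.

    Returns the output directory.  "No significant mode" is a valid,
    successful outcome recorded in the results, not an error.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("neurocca")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    written: list[str] = []
    try:
        logger.info("neurocca %s starting run (seed=%d)", __version__, config.seed)
        config.to_yaml(out / "run_config.yaml")
        written.append("run_config.yaml")

        bundle = _load_bundle(config)
        logger.info("bundle: %d subjects, %d brain vars, %d behaviour vars",
                    bundle.n_subjects, bundle.brain.n_variables,
                    bundle.behaviour.n_variables)
        pp_cfg = PreprocessConfig(
            config.z_cut, config.max_fd_cut, config.mean_fd_cut,
            config.modal_share_cut, config.site_label_order,
        )
        processed, qc = preprocess_pipeline(bundle, pp_cfg)
        qc.to_json(out / "qc_report.json")
        written.append("qc_report.json")

        max_d = min(
            processed.n_subjects - 2,
            processed.brain.n_variables,
            processed.behaviour.n_variables,
        )
        grid = [d for d in config.candidate_ds if d <= max_d]
        if not grid:
            raise ValueError("no candidate d fits the data size")
        if grid != list(config.candidate_ds):
            logger.info("restricting candidate grid to %s (data size)", grid)
        selection = select_pca_dimension(
            processed, grid, config.n_perm, config.alpha, config.seed
        )
        _dump_json(
            {
                "candidate_ds": selection.candidate_ds,
                "first_mode_p": {str(d): p for d, p in selection.first_mode_p.items()},
                "bonferroni_alpha": selection.bonferroni_alpha,
                "chosen_d": selection.chosen_d,
                "n_perm": config.n_perm,
                "seed": config.seed,
            },
            out / "model_selection.json",
        )
        written.append("model_selection.json")

        if selection.chosen_d is None:
            logger.info("no candidate dimensionality reached significance")
            _dump_json(
                {"significant_modes": [], "note": "no significant mode"},
                out / "modes.json",
            )
            written.append("modes.json")
        else:
            d = selection.chosen_d
            perm = selection.results[d]
            pca_x = pca_reduce(processed.brain, d)
            pca_y = pca_reduce(processed.behaviour, d)
            model = fit_cca(pca_x.component_scores, pca_y.component_scores)
            model, _ = fix_mode_signs(model, processed.behaviour)
            sig = significant_modes(perm, config.alpha)
            _dump_json(
                {
                    "chosen_d": d,
                    "canonical_correlations": [round(float(q), 10) for q in model.correlations],
                    "p_fwe": [round(float(p), 10) for p in perm.p_fwe],
                    "p_display": [perm.display_p(i) for i in range(d)],
                    "significant_modes": [i + 1 for i in sig],
                    "explained_variance_brain": round(float(pca_x.explained_variance_fractions.sum()), 10),
                    "explained_variance_behaviour": round(float(pca_y.explained_variance_fractions.sum()), 10),
                },
                out / "modes.json",
            )
            written.append("modes.json")
            brain_load = variable_loadings(processed.brain, model.variates_x)
            behav_load = variable_loadings(processed.behaviour, model.variates_y)
            loading_table_tsv(brain_load, out / "loadings_brain.tsv")
            loading_table_tsv(behav_load, out / "loadings_behaviour.tsv")
            written += ["loadings_brain.tsv", "loadings_behaviour.tsv"]
            for mode in [i + 1 for i in sig]:
                for name, table in (("brain", brain_load), ("behaviour", behav_load)):
                    k = min(config.top_k, len(table) // 2)
                    selection_tbl = select_top(table, mode, k=k)
                    frame = (
                        rank_loadings(table, mode)
                        .loc[selection_tbl.ids]
                        .rename("loading")
                        .to_frame()
                    )
                    fname = f"top_{name}_mode{mode}.tsv"
                    frame.to_csv(out / fname, sep="\t", index_label="variable_id")
                    written.append(fname)
            if config.region_metadata_path:
                # Region metadata is consumed by report-module helpers; the
                # run archives it for provenance.
                meta = read_region_metadata(config.region_metadata_path)
                meta.to_csv(out / "region_metadata.tsv", sep="\t", index=False)
                written.append("region_metadata.tsv")
        _dump_json({"files": sorted(written), "complete": True}, out / "MANIFEST.json")
        logger.info("run complete: %d result files", len(written))
    except Exception:
        logger.exception("run failed; outputs are partial")
        _dump_json({"files": sorted(written), "complete": False}, out / "MANIFEST.json")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
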