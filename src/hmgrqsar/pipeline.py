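"""End-to-end orchestration: curate -> descriptors -> eda -> scaffolds ->
qsar -> design, with a manifest recording what ran.

Every stage writes plain CSV/JSON artifacts into the run directory and can
also be run standalone through the CLI from prior-stage files.  The run is
fully determined by the configuration (including the seed): re-running an
identical config reproduces numerically identical stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from . import design, eda, qsar, scaffolds, synthetic
from .dataset import (
    ActivityThresholds,
    cleanse,
    read_activity_csv,
    records_to_frame,
    write_curated_csv,
)
from .descriptors import DESCRIPTOR_COLUMNS, descriptor_table
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

STAGES = ("curate", "descriptors", "eda", "scaffolds", "qsar", "design")

#: reduced default grid so a full run stays fast on one core
PIPELINE_GRID: Mapping[str, Sequence] = {
    "n_estimators": [100, 300],
    "max_depth": [3, 5],
    "learning_rate": [0.05, 0.1],
}


@dataclass
class PipelineConfig:
    """Everything a full run needs; None input means 'generate synthetic'."""

    input_csv: str | None = None
    output_dir: str = "run"
    seed: int = 42
    id_col: str = "compound_id"
    smiles_col: str = "smiles"
    ic50_col: str = "ic50"
    units_col: str | None = None
    active_min: float = 8.0
    inactive_max: float = 6.0
    fp_radius: int = 2
    fp_bits: int = 2048
    test_fraction: float = 0.2
    n_folds: int = 5
    tune_grid: Mapping[str, Sequence] = field(
        default_factory=lambda: {k: list(v) for k, v in PIPELINE_GRID.items()}
    )
    profile_path: str | None = None
    fragment_library_path: str | None = None
    design_scaffolds: Mapping[str, str] = field(
        default_factory=lambda: dict(synthetic.DEFAULT_SCAFFOLDS)
    )
    design_cap: int = 50
    render_svg: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise ConfigurationError(f"input file not found: {self.input_csv}")
        for attr in ("profile_path", "fragment_library_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{attr} not found: {p}")
        ActivityThresholds(self.active_min, self.inactive_max)
        qsar.SplitSpec(self.test_fraction, self.n_folds, self.seed)

    def config_hash(self) -> str:
        """Hash of the result-determining settings (paths/logging excluded)."""
        data = asdict(self)
        for key in ("output_dir", "log_level"):
            data.pop(key, None)
        blob = json.dumps(data, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns the manifest dictionary."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    thresholds = ActivityThresholds(config.active_min, config.inactive_max)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    def _done(stage: str, **counts) -> None:
        manifest["stages"][stage] = {"status": "completed", **counts}
        logger.info("stage %s completed: %s", stage, counts)

    try:
        # ------------------------------------------------ input / curate
        if config.input_csv is None:
            table, ledger = synthetic.generate(
                synthetic.GeneratorSpec(seed=config.seed)
            )
            synthetic.write_dataset(table, ledger, out)
        else:
            table = read_activity_csv(config.input_csv)
        records, report = cleanse(
            table,
            id_col=config.id_col,
            smiles_col=config.smiles_col,
            ic50_col=config.ic50_col,
            units_col=config.units_col,
            thresholds=thresholds,
        )
        write_curated_csv(records, out / "curated.csv")
        report.to_json(out / "curation_report.json")
        _done("curate", n_input=report.n_input, n_retained=report.n_retained)

        # ------------------------------------------------ descriptors
        desc = descriptor_table(records)
        desc.to_csv(out / "descriptors.csv")
        _done("descriptors", n_rows=len(desc))

        # ------------------------------------------------ eda
        classes = records_to_frame(records).set_index("compound_id")[
            "activity_class"
        ]
        classes = classes.loc[desc.index]
        full = desc.copy()
        full["pic50"] = [r.pic50 for r in records]
        eda.class_summary_table(full, classes).to_csv(
            out / "class_summary.csv", index=False
        )
        eda.rank_test_table(full, classes).to_csv(
            out / "rank_tests.csv", index=False
        )
        pca = eda.run_pca(desc[list(DESCRIPTOR_COLUMNS)])
        pca.loadings_frame().to_csv(out / "pca_loadings.csv")
        pca.scores_frame(index=desc.index).to_csv(out / "pca_scores.csv")
        eda.plot_pca_scores(pca, classes, out / "pca_scatter.svg")
        _done("eda", n_components=pca.loadings.shape[1])

        # ------------------------------------------------ scaffolds
        scaffolds.diversity_table(records).to_csv(
            out / "diversity.csv", index=False
        )
        groups, acyclic = scaffolds.group_by_scaffold(records, thresholds)
        scaffolds.scaffold_table(groups).to_csv(
            out / "scaffold_groups.csv", index=False
        )
        top = [g.scaffold_smiles for g in groups[:9]]
        scaffolds.functional_group_table(top).to_csv(
            out / "functional_groups.csv", index=False
        )
        if config.render_svg:
            svg_dir = out / "scaffold_svg"
            svg_dir.mkdir(exist_ok=True)
            for i, smi in enumerate(top, 1):
                scaffolds.render_scaffold_svg(smi, svg_dir / f"scaffold_{i}.svg")
        _done("scaffolds", n_groups=len(groups), n_acyclic=len(acyclic))

        # ------------------------------------------------ qsar
        split = qsar.SplitSpec(config.test_fraction, config.n_folds, config.seed)
        X = qsar.featurize(records, radius=config.fp_radius, n_bits=config.fp_bits)
        y = [r.pic50 for r in records]
        reports = qsar.train_suite(X, y, split)
        tuned = qsar.tune_boosted(X, y, split, grid=config.tune_grid)
        qsar.reports_to_frame(reports + [tuned]).to_csv(
            out / "model_reports.csv", index=False
        )
        import xgboost as xgb

        best = xgb.XGBRegressor(
            random_state=split.seed, n_jobs=1, verbosity=0, tree_method="hist",
            **tuned.hyperparameters,
        )
        train_idx, _ = qsar.make_split(X.bits.shape[0], split)
        best.fit(X.bits[train_idx].astype(float),
                 pd.Series(y).to_numpy()[train_idx])
        qsar.save_model(out / "model.joblib", best, X,
                        model_name=tuned.model_name)
        _done("qsar", n_models=len(reports) + 1,
              tuned_cv_r2=round(tuned.cv_r2_mean, 4))

        # ------------------------------------------------ design
        profile = (
            design.DesirabilityProfile.from_yaml(config.profile_path)
            if config.profile_path
            else design.DEFAULT_PROFILE
        )
        library = (
            design.read_fragment_library(config.fragment_library_path)
            if config.fragment_library_path
            else list(synthetic.DEFAULT_EFFECTS)
        )
        all_recs = []
        opt_frames = []
        for name, scaf in config.design_scaffolds.items():
            recs = design.enumerate_analogues(
                scaf, library, cap=config.design_cap, profile=profile
            )
            all_recs.extend(recs)
            rep_frame = design.optimization_report(
                design.strip_attachment_points(scaf), recs, profile, top_k=5
            )
            rep_frame.insert(0, "scaffold", name)
            opt_frames.append(rep_frame)
        design.enumeration_table(all_recs).to_csv(
            out / "ranked_analogues.csv", index=False
        )
        pd.concat(opt_frames, ignore_index=True).to_csv(
            out / "optimization_report.csv", index=False
        )
        _done("design", n_analogues=len(all_recs))
    except Exception as err:
        manifest["stages"].setdefault("failed", str(err))
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
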