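"""End-to-end experiment orchestration from a single configuration.

``run_full_study`` ties the stages together: synthesize (or load) a
density-graded patch dataset, then run the density experiments — the
overall pool plus one experiment per density grade — for each requested
classifier, writing a per-fold AUC table (CSV), a JSON summary with mean
AUC and 95% CI per stratum, a prototype bookkeeping table, and a JSONL log
of every seed and grid decision.  Outputs record a hash of the canonical
configuration, so a run can be reproduced bit-for-bit from its own records.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import classify as _classify
from . import evaluate as _evaluate
from .synthetic import SyntheticConfig, generate_patch_dataset

__all__ = ["ExperimentConfig", "PRESETS", "run_full_study", "build_patches"]

VALID_SIDES = (32, 64)
VALID_COMPONENTS = tuple(range(10, 66, 5))


@dataclass
class ExperimentConfig:
    """Configuration of a full density study.

    ``patch_side`` and ``n_components`` are restricted to the study grids
    (sides 32/64; component counts 10-65 in steps of 5) unless ``extended``
    is set.  ``preset`` names a shipped configuration; field overrides
    applied on top of a preset are reflected in the config hash.
    """

    seed: int = 0
    patch_side: int = 64
    n_components: int = 10
    classifier: str = "both"  # mlp | svm | both
    strata: tuple[str, ...] = ("overall", "1", "2", "3", "4")
    n_folds: int = 30
    val_frac: float = 0.2
    n_images_per_density: int = 94
    mass_fraction: float = 75.0 / 94.0
    n_normal_per_image: int = 4
    class_mix_preset: str | None = None  # e.g. "ddsm-mix"
    hidden_grid: tuple[int, ...] = _classify.DEFAULT_HIDDEN_GRID
    mlp_restarts: int = 4
    mlp_max_epochs: int = 2000
    mlp_patience: int = 30
    gamma_grid: tuple[float, ...] = _classify.DEFAULT_GAMMA_GRID
    C_grid: tuple[float, ...] = _classify.DEFAULT_C_GRID
    shared_basis: bool = False
    permute_labels: bool = False
    extended: bool = False
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.extended:
            if self.patch_side not in VALID_SIDES:
                raise ValueError(f"patch_side must be one of {VALID_SIDES} (or set extended)")
            if self.n_components not in VALID_COMPONENTS:
                raise ValueError(
                    f"n_components must be in {{10..65 step 5}} (or set extended)"
                )
        if self.classifier not in ("mlp", "svm", "both"):
            raise ValueError("classifier must be mlp, svm or both")
        for s in self.strata:
            if s not in ("overall", "1", "2", "3", "4"):
                raise ValueError(f"unknown stratum {s!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # execution detail, not part of the experiment identity
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _reduced_grids() -> dict:
    return dict(
        hidden_grid=(50, 100),
        mlp_restarts=2,
        mlp_max_epochs=300,
        mlp_patience=25,
        gamma_grid=tuple(2.0 ** np.array([-3.0, -1.0, 1.0])),
        C_grid=tuple(2.0 ** np.array([0.0, 2.0, 4.0])),
    )


#: Shipped study configurations.
#:
#: - ``smoke``: minimal wiring check, one stratum, minutes-scale nothing.
#: - ``desk``: the reduced synthetic study — 4 densities x ~150 patches,
#:   64 px, 10 components, 10-fold CV, reduced classifier grids.
#: - ``paper-nn`` / ``paper-svm``: the optimal single-classifier extractor
#:   configurations at full grids (64 px; 10 components for the perceptron,
#:   15 for the SVM) with 30-fold CV.
PRESETS: dict[str, dict] = {
    "smoke": dict(
        patch_side=32,
        n_components=10,
        strata=("overall",),
        n_folds=5,
        n_images_per_density=40,
        mass_fraction=0.5,
        n_normal_per_image=1,
        **{**_reduced_grids(), "hidden_grid": (50,), "mlp_restarts": 1,
           "mlp_max_epochs": 150,
           "gamma_grid": (0.125, 0.5), "C_grid": (1.0, 4.0)},
    ),
    "desk": dict(
        patch_side=64,
        n_components=10,
        strata=("overall", "1", "2", "3", "4"),
        n_folds=10,
        n_images_per_density=94,
        mass_fraction=75.0 / 94.0,
        n_normal_per_image=4,
        **_reduced_grids(),
    ),
    "paper-nn": dict(patch_side=64, n_components=10, classifier="mlp", n_folds=30),
    "paper-svm": dict(patch_side=64, n_components=15, classifier="svm", n_folds=30),
}


def make_config(preset: str | None = None, **overrides) -> ExperimentConfig:
    """Build a configuration, optionally starting from a named preset."""
    fields = {}
    if preset is not None:
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; have {sorted(PRESETS)}")
        fields.update(PRESETS[preset])
    fields.update(overrides)
    return ExperimentConfig(**fields)


def build_patches(config: ExperimentConfig):
    """Synthesize the labelled patch dataset a study config describes."""
    syn = SyntheticConfig(
        seed=config.seed,
        n_images_per_density=config.n_images_per_density,
        mass_fraction=config.mass_fraction,
    )
    return generate_patch_dataset(
        syn,
        patch_side=config.patch_side,
        n_normal_per_image=config.n_normal_per_image,
        preset=config.class_mix_preset,
    )


def run_full_study(config: ExperimentConfig, patches=None) -> dict:
    """Run every requested stratum x classifier experiment.

    Returns the summary dict (also written to ``out_dir`` as
    ``summary.json`` with sibling ``fold_aucs.csv``, ``prototypes.csv`` and
    ``study_log.jsonl`` when ``out_dir`` is set).
    """
    t0 = time.time()
    cfg_hash = config.hash()
    log: list[dict] = [{"event": "start", "config_hash": cfg_hash, "seed": config.seed}]
    if patches is None:
        patches = build_patches(config)
    log.append(
        {
            "event": "dataset",
            "n_patches": len(patches),
            "n_mass": sum(p.is_mass for p in patches),
            "per_density": {
                d: sum(p.density == d for p in patches) for d in (1, 2, 3, 4)
            },
        }
    )
    ss = np.random.SeedSequence([config.seed, 0xD5])
    stratum_seeds = ss.generate_state(len(config.strata)) % (2**31)

    results: dict[str, dict[str, _evaluate.ExperimentResult]] = {}
    rows = []
    for stratum, sseed in zip(config.strata, stratum_seeds):
        res = _evaluate.run_experiment(
            patches,
            stratum=stratum,
            n_components=config.n_components,
            classifier=config.classifier,
            seed=int(sseed),
            n_folds=config.n_folds,
            val_frac=config.val_frac,
            hidden_grid=config.hidden_grid,
            mlp_restarts=config.mlp_restarts,
            mlp_max_epochs=config.mlp_max_epochs,
            mlp_patience=config.mlp_patience,
            gamma_grid=config.gamma_grid,
            C_grid=config.C_grid,
            shared_basis=config.shared_basis,
            permute_labels=config.permute_labels,
        )
        results[stratum] = res
        for kind, r in res.items():
            log.append({"event": "experiment", "stratum": stratum, "classifier": kind,
                        "seed": int(sseed), "mean_auc": r.mean_auc,
                        "selections": r.selections})
            for fold_i, auc in enumerate(r.fold_aucs):
                rows.append({"stratum": stratum, "classifier": kind,
                             "fold": fold_i, "auc": auc})

    summary = {
        "config_hash": cfg_hash,
        "config": config.to_dict(),
        "n_patches": len(patches),
        "results": {
            stratum: {kind: r.to_dict() for kind, r in res.items()}
            for stratum, res in results.items()
        },
    }
    log.append({"event": "done", "runtime_s": round(time.time() - t0, 1)})

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rows).to_csv(out / "fold_aucs.csv", index=False)
        plan = _evaluate.make_cv_plan(
            np.arange(len(patches)), n_folds=config.n_folds,
            val_frac=config.val_frac, seed=config.seed,
        )
        _evaluate.prototype_table(plan, patches).to_csv(out / "prototypes.csv")
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        with open(out / "study_log.jsonl", "w") as fh:
            for entry in log:
                fh.write(json.dumps(entry, sort_keys=True, default=str) + "\n")
    return summary
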