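"""Canonical desk-scale evaluation experiments.

These functions bundle the study designs the package is validated
against — the feature-ablation comparison (embeddings-only baseline,
single-block variants, full integration), the predicted-features
scenario, imputer reconstruction on held-out drugs, the no-signal
leakage control, and the pair-based versus drug-based cross-validation
contrast — at the small synthetic scale, so they run end-to-end on one
CPU in minutes.  Each is a thin composition of the library's public
pieces; everything derives deterministically from the given seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .core_data import DatasetBundle
from .evaluation import EvalReport
from .featurization import FeatureConfig
from .imputation import ImputerTrainConfig, build_imputer, reconstruction_auc, train_imputer
from .pipeline import (
    RunConfig,
    baseline_config,
    desk_hidti_config,
    run_crossval,
    run_pair_crossval,
)
from .synthetic import generate_bundle, null_config, scale_preset


def desk_bundle(seed: int) -> tuple[DatasetBundle, dict]:
    """The small synthetic benchmark drawn with the given seed."""
    return generate_bundle(replace(scale_preset("desk"), seed=seed))


def _desk_run_config(seed: int, mode: str = "available") -> RunConfig:
    return RunConfig(mode=mode, ratio=1, hidti=desk_hidti_config(seed=seed), seed=seed)


def crossval_suite(bundle: DatasetBundle, seed: int) -> dict[str, EvalReport]:
    """Drug-based 10-fold CV for the model variants compared in the study.

    Returns reports keyed ``baseline`` (embeddings only, no residual
    blocks, two hidden layers), ``single_DDI`` / ``single_PDIS``
    (embeddings plus one association block), ``available`` (all blocks,
    true values) and ``predicted`` (test drugs' blocks imputed).
    """
    rc = _desk_run_config(seed)
    reports = {
        "baseline": run_crossval(
            bundle,
            replace(
                rc,
                hidti=baseline_config(
                    seed=seed, batch_size=128, max_epochs=300, patience=30,
                    early_stopping_metric="auc",
                ),
                feature_config=FeatureConfig.baseline(),
            ),
        ),
        "single_DDI": run_crossval(
            bundle, replace(rc, feature_config=FeatureConfig.single_info("DDI"))
        ),
        "single_PDIS": run_crossval(
            bundle, replace(rc, feature_config=FeatureConfig.single_info("PDIS"))
        ),
        "available": run_crossval(bundle, rc),
        "predicted": run_crossval(bundle, replace(rc, mode="predicted")),
    }
    return reports


def imputer_reconstruction(bundle: DatasetBundle, seed: int) -> dict[str, float]:
    """Held-out reconstruction AUC for each of the four imputers.

    Drug-side imputers train on a seeded 5/6 split of drugs and are
    scored on the rest; the protein-side PDIS imputer likewise on
    proteins.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    drug_order = [bundle.drugs.ids[i] for i in rng.permutation(len(bundle.drugs))]
    n_train = int(0.83 * len(drug_order))
    train_d, held_d = drug_order[:n_train], drug_order[n_train:]
    prot_order = [bundle.proteins.ids[i] for i in rng.permutation(len(bundle.proteins))]
    n_train_p = int(0.85 * len(prot_order))
    train_p, held_p = prot_order[:n_train_p], prot_order[n_train_p:]

    specs = [
        ("DDI", bundle.drug_embeddings, train_d, held_d),
        ("DSIE", bundle.drug_embeddings, train_d, held_d),
        ("DDIS", bundle.drug_embeddings, train_d, held_d),
        ("PDIS", bundle.protein_embeddings, train_p, held_p),
    ]
    for name, emb, train_ids, held_ids in specs:
        matrix = bundle.matrices[name]
        model = build_imputer(
            name, emb.dim, len(matrix.cols), hidden_dims=(256, 128, 64),
            seed=seed, dropout_rate=0.2,
        )
        train_imputer(model, emb, matrix, train_ids, ImputerTrainConfig(seed=seed))
        out[name], _ = reconstruction_auc(model, emb, matrix, held_ids)
    return out


def null_control(seed: int, n_seeds: int = 5, folds=(0, 1, 2)) -> tuple[float, list[float]]:
    """Mean test AUC with no planted DTI signal (expected: chance level).

    Each replicate draws a fresh signal-free bundle and evaluates a few
    cross-validation folds; systematic deviation from 0.5 would indicate
    leakage between the cold-start splits.
    """
    aucs: list[float] = []
    base = null_config(scale_preset("desk"))
    for i in range(n_seeds):
        s = (seed * 131 + 17 * i + 11) % (2**31)
        bundle, _ = generate_bundle(replace(base, seed=s))
        report = run_crossval(bundle, _desk_run_config(s), folds=list(folds))
        aucs.extend(report.per_fold["auc"].tolist())
    return float(np.mean(aucs)), aucs


def pair_vs_drug(
    bundle: DatasetBundle, seed: int, drug_auc: float | None = None
) -> tuple[float, float]:
    """Mean AUC of drug-based (cold-start) vs pair-based (random) CV.

    A pre-computed drug-based mean may be passed to avoid re-running it.
    """
    rc = _desk_run_config(seed)
    if drug_auc is None:
        drug_auc = run_crossval(bundle, rc).mean("auc")
    pair_auc = run_pair_crossval(bundle, rc).mean("auc")
    return float(drug_auc), pair_auc
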