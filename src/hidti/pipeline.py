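"""End-to-end orchestration: folds -> imputers -> features -> model -> metrics.

Three evaluation scenarios are supported, mirroring how much
heterogeneous information is assumed known for the unseen (test) drugs:

``available``
    True association rows are used for every drug, including test
    drugs.
``predicted``
    The drug-side association blocks (DDI, DSIE, DDIS) of test drugs
    are replaced by zero-masked imputer predictions; the protein-side
    PDIS block of test pairs is likewise replaced by imputed vectors.
    Imputers for drug-side matrices are trained only on non-test drugs.
``available_pdis``
    As ``predicted``, but the true PDIS rows are kept.

Every run is reproducible from (config, seed): fold assignment,
negative sampling, validation sampling, weight initialization and
mini-batch shuffling all derive from the run seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .core_data import DatasetBundle, PairSet, write_pairs
from .cv import (
    FoldPlan,
    assign_drug_folds,
    make_pair_folds,
    make_splits,
    merge_pairsets,
    pair_fold_splits,
    sample_negatives,
)
from .evaluation import EvalReport, PredictionRecord, report_from_folds
from .featurization import (
    FeatureConfig,
    FeatureMatrix,
    assemble_drug_features,
    assemble_pair_matrix,
    assemble_protein_features,
)
from .imputation import ImputerTrainConfig, build_imputer, impute, train_imputer
from .model import HIDTIConfig, HIDTIModel, train_hidti

MODES = ("available", "predicted", "available_pdis")


@dataclass
class RunConfig:
    mode: str = "available"
    ratio: int = 1
    k: int = 10
    val_fraction: float = 0.05
    zero_positive_count: int = 3
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    hidti: HIDTIConfig = field(default_factory=HIDTIConfig)
    imputer: ImputerTrainConfig = field(default_factory=ImputerTrainConfig)
    imputer_hidden: tuple[int, int, int] | None = (256, 128, 64)
    imputer_dropout: float = 0.2
    leakage_safe: bool = False
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.ratio < 1:
            raise ValueError("ratio must be positive")


def desk_hidti_config(seed: int = 0, **overrides) -> HIDTIConfig:
    """Model settings sized for the small synthetic preset.

    The batch size is scaled to the desk training-set size (hundreds of
    pairs rather than thousands) and early stopping monitors validation
    AUC, the quantity grid selection also uses.
    """
    base = dict(
        n_residual_blocks=1,
        n_classifier_hidden=1,
        learning_rate=1e-3,
        m1=256,
        m2=128,
        classifier_hidden=128,
        batch_size=128,
        max_epochs=300,
        patience=30,
        early_stopping_metric="auc",
        seed=seed,
    )
    base.update(overrides)
    return HIDTIConfig(**base)


def baseline_config(seed: int = 0, **overrides) -> HIDTIConfig:
    """The reference architecture: no residual blocks, two hidden layers."""
    return desk_hidti_config(
        seed=seed, use_residual=False, n_classifier_hidden=2, **overrides
    )


def build_labelled_pairs(bundle: DatasetBundle, cfg: RunConfig) -> tuple[FoldPlan, PairSet]:
    """Fold plan on positive counts plus the full positive+negative pair set."""
    counts = {d: 0 for d in bundle.drugs.ids}
    for d, _, _ in bundle.dti.pairs:
        counts[d] += 1
    plan = assign_drug_folds(counts, cfg.k)
    plan.ratio = cfg.ratio
    plan.seed = cfg.seed
    negatives = sample_negatives(
        bundle.dti,
        bundle.drugs,
        bundle.proteins,
        ratio=cfg.ratio,
        zero_positive_count=cfg.zero_positive_count,
        seed=cfg.seed,
    )
    return plan, merge_pairsets(bundle.dti, negatives)


def _imputed_drug_features(
    bundle: DatasetBundle,
    D: FeatureMatrix,
    train_drugs: list[str],
    test_drugs: list[str],
    cfg: RunConfig,
    fold_seed: int,
) -> FeatureMatrix:
    """Replace test drugs' association blocks with zero-masked imputations."""
    emb = bundle.drug_embeddings
    test_idx = bundle.drugs.indices(test_drugs)
    out = D
    for name in ("DDI", "DSIE", "DDIS"):
        if name not in D.offsets:
            continue
        matrix = bundle.matrices[name]
        model = build_imputer(
            name,
            emb.dim,
            len(matrix.cols),
            hidden_dims=cfg.imputer_hidden,
            seed=fold_seed,
            dropout_rate=cfg.imputer_dropout,
        )
        train_imputer(model, emb, matrix, train_drugs, replace(cfg.imputer, seed=fold_seed))
        block = out.block(name).copy()
        block[test_idx] = impute(model, emb.values[test_idx])
        out = out.with_block(name, block)
    return out


def _imputed_pdis_features(
    bundle: DatasetBundle,
    P: FeatureMatrix,
    cfg: RunConfig,
    fold_seed: int,
) -> FeatureMatrix:
    """Replace the PDIS block of every protein with imputed vectors."""
    if "PDIS" not in P.offsets:
        return P
    emb = bundle.protein_embeddings
    matrix = bundle.matrices["PDIS"]
    model = build_imputer(
        "PDIS",
        emb.dim,
        len(matrix.cols),
        hidden_dims=cfg.imputer_hidden,
        seed=fold_seed,
        dropout_rate=cfg.imputer_dropout,
    )
    train_imputer(
        model, emb, matrix, list(bundle.proteins.ids), replace(cfg.imputer, seed=fold_seed)
    )
    return P.with_block("PDIS", impute(model, emb.values))


def _leakage_safe_ddi(D: FeatureMatrix, bundle: DatasetBundle, test_drugs: list[str]) -> FeatureMatrix:
    """Zero the DDI columns that reference test drugs in every drug's row."""
    if "DDI" not in D.offsets:
        return D
    block = D.block("DDI").copy()
    block[:, bundle.drugs.indices(test_drugs)] = 0.0
    return D.with_block("DDI", block)


def run_fold(
    bundle: DatasetBundle,
    cfg: RunConfig,
    train: PairSet,
    val: PairSet,
    test: PairSet,
    fold: int,
) -> tuple[list[PredictionRecord], HIDTIModel, list[dict]]:
    """Train on one split and score the test pairs."""
    fold_seed = int(cfg.seed * 1009 + fold) % (2**31)
    fc = cfg.feature_config
    D_true = assemble_drug_features(bundle, fc)
    P_true = assemble_protein_features(bundle, fc)
    test_drugs = sorted(test.drugs)
    train_drugs = sorted(train.drugs | val.drugs)

    D_train = D_true
    if cfg.leakage_safe:
        D_train = _leakage_safe_ddi(D_train, bundle, test_drugs)
    D_test, P_test = D_train, P_true
    if cfg.mode in ("predicted", "available_pdis"):
        D_test = _imputed_drug_features(
            bundle, D_train, train_drugs, test_drugs, cfg, fold_seed
        )
        if cfg.mode == "predicted":
            P_test = _imputed_pdis_features(bundle, P_true, cfg, fold_seed)

    X_train = assemble_pair_matrix(D_train, P_true, train.pairs)
    X_val = assemble_pair_matrix(D_train, P_true, val.pairs)
    X_test = assemble_pair_matrix(D_test, P_test, test.pairs)
    y_train, y_val = train.labels, val.labels

    model_cfg = replace(cfg.hidti, seed=fold_seed)
    model = HIDTIModel(X_train.shape[1], model_cfg)
    history = train_hidti(model, X_train, y_train, X_val, y_val, model_cfg)
    probs = model.predict_proba(X_test)
    records = [
        PredictionRecord(d, p, float(pr), lab, fold)
        for (d, p, lab), pr in zip(test.pairs, probs)
    ]
    return records, model, history


def run_crossval(
    bundle: DatasetBundle, cfg: RunConfig, folds: list[int] | None = None
) -> EvalReport:
    """Drug-based k-fold cold-start cross-validation.

    ``folds`` restricts evaluation to a subset of test folds (all by
    default).  The report carries per-fold metrics, the raw prediction
    records (``extras['records']``) and the fold plan.
    """
    plan, all_pairs = build_labelled_pairs(bundle, cfg)
    fold_records: dict[int, list[PredictionRecord]] = {}
    for fold in folds if folds is not None else range(cfg.k):
        train, val, test = make_splits(
            plan, all_pairs, fold, cfg.val_fraction, seed=int(cfg.seed * 1009 + fold) % (2**31)
        )
        records, _, _ = run_fold(bundle, cfg, train, val, test, fold)
        fold_records[fold] = records
    report = report_from_folds(fold_records, tag=f"{cfg.mode}:1:{cfg.ratio}")
    report.extras["records"] = [r for recs in fold_records.values() for r in recs]
    report.extras["fold_plan"] = plan
    if cfg.outdir:
        _write_artifacts(report, cfg, all_pairs)
    return report


def run_pair_crossval(
    bundle: DatasetBundle, cfg: RunConfig, folds: list[int] | None = None
) -> EvalReport:
    """Conventional pair-based random CV (drugs may appear on both sides)."""
    _, all_pairs = build_labelled_pairs(bundle, cfg)
    assignment = make_pair_folds(all_pairs, cfg.k, seed=cfg.seed)
    fold_records: dict[int, list[PredictionRecord]] = {}
    for fold in folds if folds is not None else range(cfg.k):
        train, val, test = pair_fold_splits(
            all_pairs,
            assignment,
            fold,
            cfg.val_fraction,
            seed=int(cfg.seed * 1009 + fold) % (2**31),
        )
        records, _, _ = run_fold(bundle, cfg, train, val, test, fold)
        fold_records[fold] = records
    report = report_from_folds(fold_records, tag=f"pair-cv:1:{cfg.ratio}")
    report.extras["records"] = [r for recs in fold_records.values() for r in recs]
    return report


def run_ablation(bundle: DatasetBundle, cfg: RunConfig, drop: set[str]) -> EvalReport:
    """Cross-validation with the given association blocks removed."""
    reduced = replace(cfg, feature_config=cfg.feature_config.drop(drop))
    report = run_crossval(bundle, reduced)
    report.tag = f"{report.tag} drop={sorted(drop)}"
    return report


def _write_artifacts(report: EvalReport, cfg: RunConfig, all_pairs: PairSet) -> None:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "predictions.tsv", "w") as fh:
        fh.write("# drug_id\tprotein_id\tprobability\tlabel\tfold\n")
        for r in report.extras["records"]:
            fh.write(f"{r.drug_id}\t{r.protein_id}\t{r.probability:.6f}\t{r.label}\t{r.fold}\n")
    report.per_fold.to_csv(outdir / "per_fold_metrics.tsv", sep="\t")
    summary = {
        "tag": report.tag,
        "mode": cfg.mode,
        "ratio": cfg.ratio,
        "seed": cfg.seed,
        **{m: report.mean(m) for m in EvalReport.METRICS},
        **{f"{m}_sd": report.sd(m) for m in EvalReport.METRICS},
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    plan: FoldPlan = report.extras.get("fold_plan")
    if plan is not None:
        with open(outdir / "fold_plan.tsv", "w") as fh:
            fh.write("# drug_id\tfold\n")
            for d, f in sorted(plan.assignment.items()):
                fh.write(f"{d}\t{f}\n")
    write_pairs(all_pairs, outdir / "pairs.tsv")
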