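"""Drug-based cold-start cross-validation protocol.

Drugs — not pairs — are partitioned into folds, so every test drug is
unseen during training.  Folds are balanced on positive-interaction
counts by a greedy rule: drugs sorted by descending count (ties broken
lexicographically by id) are each assigned to the currently
least-loaded fold (ties to the lowest fold index); drugs with no
positives are then spread round-robin.  Negatives are sampled per drug
from its non-interacting proteins at a fixed ratio (1, 3 or 5 negatives
per positive), with exactly ``zero_positive_count`` negatives for drugs
that have no positives at all.  Within each round, 85/5/10% of pairs go
to train/validation/test: the test fold's drugs supply the 10%, and the
5% validation slice is drawn at pair level from the remaining folds.

A pair-level random k-fold mode (the conventional, non-cold-start
protocol) and a train/test drug-similarity redundancy filter are also
provided for the comparison experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import EntityRegistry, PairSet


@dataclass
class FoldPlan:
    k: int
    assignment: dict[str, int]
    fold_positive_counts: list[int]
    ratio: int = 1
    seed: int | None = None

    def drugs_in_fold(self, fold: int) -> list[str]:
        return [d for d, f in self.assignment.items() if f == fold]

    def fold_of(self, drug_id: str) -> int:
        return self.assignment[drug_id]


def assign_drug_folds(positive_counts: dict[str, int], k: int = 10) -> FoldPlan:
    """Greedy balanced assignment of drugs to k folds by positive count."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(positive_counts) < k:
        raise ValueError(
            f"cannot split {len(positive_counts)} drugs into {k} folds"
        )
    if any(c < 0 for c in positive_counts.values()):
        raise ValueError("positive counts must be non-negative")
    with_pos = sorted(
        (d for d, c in positive_counts.items() if c > 0),
        key=lambda d: (-positive_counts[d], d),
    )
    zero = sorted(d for d, c in positive_counts.items() if c == 0)
    totals = [0] * k
    assignment: dict[str, int] = {}
    for d in with_pos:
        fold = int(np.argmin(totals))  # lowest index wins ties
        assignment[d] = fold
        totals[fold] += positive_counts[d]
    for i, d in enumerate(zero):
        assignment[d] = i % k
    return FoldPlan(k=k, assignment=assignment, fold_positive_counts=totals)


def sample_negatives(
    positives: PairSet,
    drugs: EntityRegistry,
    proteins: EntityRegistry,
    ratio: int,
    zero_positive_count: int = 3,
    seed: int = 0,
) -> PairSet:
    """Per-drug uniform negative sampling without replacement.

    Each drug receives exactly ``ratio x (its positives)`` negatives
    drawn from its non-interacting proteins; drugs with no positives
    receive ``zero_positive_count`` negatives.
    """
    if ratio < 1:
        raise ValueError("ratio must be a positive integer")
    rng = np.random.default_rng(seed)
    pos_by_drug: dict[str, set[str]] = {d: set() for d in drugs.ids}
    for d, p, lab in positives.pairs:
        if lab != 1:
            raise ValueError("positives PairSet must contain only label-1 pairs")
        pos_by_drug[d].add(p)
    all_proteins = np.array(proteins.ids)
    negatives: list[tuple[str, str, int]] = []
    for d in drugs.ids:
        pos = pos_by_drug[d]
        want = ratio * len(pos) if pos else zero_positive_count
        candidates = np.array([p for p in all_proteins if p not in pos])
        if want > candidates.size:
            raise ValueError(
                f"drug {d!r}: cannot sample {want} negatives from "
                f"{candidates.size} non-positive proteins"
            )
        chosen = rng.choice(candidates, size=want, replace=False)
        negatives.extend((d, str(p), 0) for p in chosen)
    return PairSet(negatives)


def merge_pairsets(*sets: PairSet, role: str = "unassigned") -> PairSet:
    pairs = [t for s in sets for t in s.pairs]
    return PairSet(pairs, role=role)


def make_splits(
    plan: FoldPlan,
    all_pairs: PairSet,
    test_fold: int,
    val_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[PairSet, PairSet, PairSet]:
    """(train, val, test) pair sets for one cross-validation round.

    Test = every pair whose drug lies in ``test_fold``; validation is a
    seeded pair-level sample of size ~``val_fraction`` of all pairs from
    the remaining pairs; train is the rest.  Train and validation drugs
    are disjoint from test drugs by construction.
    """
    if not 0 <= test_fold < plan.k:
        raise ValueError(f"test_fold {test_fold} out of range [0, {plan.k})")
    test_pairs, rest = [], []
    for t in all_pairs.pairs:
        (test_pairs if plan.fold_of(t[0]) == test_fold else rest).append(t)
    rng = np.random.default_rng(seed)
    n_val = int(round(val_fraction * len(all_pairs)))
    n_val = min(n_val, len(rest))
    val_idx = set(rng.choice(len(rest), size=n_val, replace=False).tolist())
    val_pairs = [t for i, t in enumerate(rest) if i in val_idx]
    train_pairs = [t for i, t in enumerate(rest) if i not in val_idx]
    return (
        PairSet(train_pairs, role="train", fold=test_fold),
        PairSet(val_pairs, role="val", fold=test_fold),
        PairSet(test_pairs, role="test", fold=test_fold),
    )


def make_pair_folds(all_pairs: PairSet, k: int, seed: int = 0) -> dict[tuple[str, str], int]:
    """Random pair-level k-fold partition (drugs may straddle folds)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    n = len(all_pairs)
    order = rng.permutation(n)
    assignment: dict[tuple[str, str], int] = {}
    for pos, idx in enumerate(order):
        d, p, _ = all_pairs.pairs[idx]
        assignment[(d, p)] = pos % k
    return assignment


def pair_fold_splits(
    all_pairs: PairSet,
    assignment: dict[tuple[str, str], int],
    test_fold: int,
    val_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[PairSet, PairSet, PairSet]:
    """Train/val/test split for the pair-based random CV mode."""
    test_pairs, rest = [], []
    for t in all_pairs.pairs:
        (test_pairs if assignment[(t[0], t[1])] == test_fold else rest).append(t)
    rng = np.random.default_rng(seed)
    n_val = min(int(round(val_fraction * len(all_pairs))), len(rest))
    val_idx = set(rng.choice(len(rest), size=n_val, replace=False).tolist())
    val_pairs = [t for i, t in enumerate(rest) if i in val_idx]
    train_pairs = [t for i, t in enumerate(rest) if i not in val_idx]
    return (
        PairSet(train_pairs, role="train", fold=test_fold),
        PairSet(val_pairs, role="val", fold=test_fold),
        PairSet(test_pairs, role="test", fold=test_fold),
    )


def filter_redundant_test_drugs(
    test_drugs: list[str],
    train_drugs: list[str],
    similarity: "DrugSimilarity",
    threshold: float = 0.6,
) -> list[str]:
    """Keep only test drugs whose similarity to every train drug is < threshold.

    The threshold is strict: a test drug at exactly ``threshold`` is
    removed.  The similarity source is metric-agnostic (e.g. fingerprint
    Tanimoto computed upstream).
    """
    retained = []
    for td in test_drugs:
        if all(similarity(td, rd) < threshold for rd in train_drugs):
            retained.append(td)
    return retained


@dataclass
class DrugSimilarity:
    """A symmetric drug x drug similarity lookup backed by a dense matrix."""

    ids: list[str]
    values: np.ndarray
    _index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("similarity matrix shape mismatch")
        self._index = {d: i for i, d in enumerate(self.ids)}

    def __call__(self, a: str, b: str) -> float:
        try:
            return float(self.values[self._index[a], self._index[b]])
        except KeyError as e:
            raise KeyError(f"no similarity entry for drug {e.args[0]!r}") from None
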