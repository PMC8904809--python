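"""Assembly of the concatenated drug- and protein-related feature vectors.

A drug is described by the concatenation ``D_i = [Drug_i; DDI_i; DSIE_i;
DDIS_i]``: its chemical embedding followed by its rows of the drug-drug,
drug-side-effect and drug-disease association matrices.  A protein is
described by ``P_j = [Protein_j; PPI_j; PSIM_j; PDIS_j]``.  A candidate
pair feeds the classifier with ``x = [D_i; P_j]``.

Block order is fixed; ablations drop blocks but never reorder the ones
that remain, so column offsets are stable and each block can be sliced
back out exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_data import DatasetBundle, EmbeddingTable, EntityRegistry

DRUG_BLOCK_ORDER = ("Drug", "DDI", "DSIE", "DDIS")
PROTEIN_BLOCK_ORDER = ("Protein", "PPI", "PSIM", "PDIS")


@dataclass(frozen=True)
class FeatureConfig:
    """Which feature blocks are active, in canonical concatenation order.

    The embedding blocks (``Drug``, ``Protein``) are always present —
    every model variant includes them; only association blocks are
    optional.
    """

    drug_blocks: tuple[str, ...] = DRUG_BLOCK_ORDER
    protein_blocks: tuple[str, ...] = PROTEIN_BLOCK_ORDER

    def __post_init__(self) -> None:
        for b in self.drug_blocks:
            if b not in DRUG_BLOCK_ORDER:
                raise ValueError(f"unknown drug block {b!r}")
        for b in self.protein_blocks:
            if b not in PROTEIN_BLOCK_ORDER:
                raise ValueError(f"unknown protein block {b!r}")
        if "Drug" not in self.drug_blocks or "Protein" not in self.protein_blocks:
            raise ValueError("embedding blocks Drug/Protein cannot be dropped")
        # enforce canonical order regardless of the order given
        object.__setattr__(
            self,
            "drug_blocks",
            tuple(b for b in DRUG_BLOCK_ORDER if b in self.drug_blocks),
        )
        object.__setattr__(
            self,
            "protein_blocks",
            tuple(b for b in PROTEIN_BLOCK_ORDER if b in self.protein_blocks),
        )

    @classmethod
    def baseline(cls) -> "FeatureConfig":
        """Embeddings only — the reference model with no association blocks."""
        return cls(("Drug",), ("Protein",))

    @classmethod
    def single_info(cls, block: str) -> "FeatureConfig":
        """Embeddings plus exactly one association block."""
        if block in DRUG_BLOCK_ORDER[1:]:
            return cls(("Drug", block), ("Protein",))
        if block in PROTEIN_BLOCK_ORDER[1:]:
            return cls(("Drug",), ("Protein", block))
        raise ValueError(f"unknown association block {block!r}")

    def drop(self, blocks: set[str] | tuple[str, ...]) -> "FeatureConfig":
        blocks = set(blocks)
        if "Drug" in blocks or "Protein" in blocks:
            raise ValueError("embedding blocks cannot be dropped")
        return FeatureConfig(
            tuple(b for b in self.drug_blocks if b not in blocks),
            tuple(b for b in self.protein_blocks if b not in blocks),
        )


@dataclass
class EmbeddingProvider:
    """Source of per-entity dense vectors.

    ``kind='table'`` wraps pre-computed vectors (e.g. Mol2vec for drugs,
    ProtVec for proteins) loaded from disk.  ``kind='synthetic'`` derives
    a reproducible standard-normal vector per id from a hash of
    ``(seed, id)`` — a deterministic stand-in used when no pre-trained
    table is supplied.
    """

    kind: str
    table: EmbeddingTable | None = None
    seed: int = 0
    dim: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("table", "synthetic"):
            raise ValueError(f"unknown provider kind {self.kind!r}")
        if self.kind == "table" and self.table is None:
            raise ValueError("table provider requires an EmbeddingTable")
        if self.kind == "synthetic" and self.dim <= 0:
            raise ValueError("synthetic provider requires a positive dim")

    def _synthetic_vector(self, eid: str) -> np.ndarray:
        digest = hashlib.blake2b(
            f"{self.seed}:{eid}".encode(), digest_size=8
        ).digest()
        sub = np.random.default_rng(int.from_bytes(digest, "little"))
        return sub.standard_normal(self.dim)


def embed(provider: EmbeddingProvider, registry: EntityRegistry) -> EmbeddingTable:
    """Produce a |registry| x dim table with rows in registry order."""
    if provider.kind == "table":
        table = provider.table
        missing = [e for e in registry.ids if e not in table.registry]
        if missing:
            raise ValueError(f"missing embeddings for ids: {missing[:10]}")
        values = np.stack([table.vector(e) for e in registry.ids])
        return EmbeddingTable(registry, values)
    values = np.stack([provider._synthetic_vector(e) for e in registry.ids])
    return EmbeddingTable(registry, values)


@dataclass
class FeatureMatrix:
    """A stacked feature matrix plus the half-open column range of each block."""

    registry: EntityRegistry
    values: np.ndarray
    offsets: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def row(self, eid: str) -> np.ndarray:
        return self.values[self.registry.index(eid)]

    def block(self, name: str) -> np.ndarray:
        start, end = self.offsets[name]
        return self.values[:, start:end]

    def with_block(self, name: str, new_values: np.ndarray) -> "FeatureMatrix":
        """Return a copy with one block's columns replaced."""
        start, end = self.offsets[name]
        out = self.values.copy()
        out[:, start:end] = new_values
        return FeatureMatrix(self.registry, out, dict(self.offsets))


def _assemble(
    registry: EntityRegistry,
    blocks: tuple[str, ...],
    sources: dict[str, np.ndarray],
) -> FeatureMatrix:
    parts, offsets, pos = [], {}, 0
    for name in blocks:
        arr = sources[name]
        if arr.shape[0] != len(registry):
            raise ValueError(f"block {name} has {arr.shape[0]} rows, expected {len(registry)}")
        parts.append(arr)
        offsets[name] = (pos, pos + arr.shape[1])
        pos += arr.shape[1]
    return FeatureMatrix(registry, np.concatenate(parts, axis=1), offsets)


def assemble_drug_features(bundle: DatasetBundle, config: FeatureConfig) -> FeatureMatrix:
    """Build the drug feature matrix D (one row per drug)."""
    sources = {"Drug": bundle.drug_embeddings.values}
    for name in ("DDI", "DSIE", "DDIS"):
        if name in config.drug_blocks:
            sources[name] = bundle.matrices[name].values
    return _assemble(bundle.drugs, config.drug_blocks, sources)


def assemble_protein_features(bundle: DatasetBundle, config: FeatureConfig) -> FeatureMatrix:
    """Build the protein feature matrix P (one row per protein)."""
    sources = {"Protein": bundle.protein_embeddings.values}
    for name in ("PPI", "PSIM", "PDIS"):
        if name in config.protein_blocks:
            sources[name] = bundle.matrices[name].values
    return _assemble(bundle.proteins, config.protein_blocks, sources)


def assemble_pair_input(
    D: FeatureMatrix, P: FeatureMatrix, pair: tuple[str, str]
) -> np.ndarray:
    """Concatenate one drug row and one protein row into the classifier input."""
    drug_id, protein_id = pair[0], pair[1]
    return np.concatenate([D.row(drug_id), P.row(protein_id)])


def assemble_pair_matrix(
    D: FeatureMatrix, P: FeatureMatrix, pairs
) -> np.ndarray:
    """Vectorized pair inputs: one row per (drug, protein) pair."""
    di = D.registry.indices([t[0] for t in pairs])
    pi = P.registry.indices([t[1] for t in pairs])
    return np.concatenate([D.values[di], P.values[pi]], axis=1)


def export_features(fm: FeatureMatrix, path: str | Path) -> None:
    """Write the matrix as TSV plus a JSON sidecar of block offsets."""
    path = Path(path)
    with open(path, "w") as fh:
        for eid, row in zip(fm.registry.ids, fm.values):
            fh.write(eid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    sidecar = {name: list(rng) for name, rng in fm.offsets.items()}
    with open(path.with_suffix(path.suffix + ".offsets.json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)
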