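"""Domain containers and delimited-text I/O for the DTI benchmark layout.

The dataset is a collection of entity tables (drugs with SMILES, proteins
with sequences, side effects, diseases), six association matrices between
them, dense per-entity embeddings, and a list of positive drug-protein
interactions.  Everything is plain TSV; a leading ``#`` line is treated
as a comment/header and skipped.

Matrix names and axes:

====== ==================== =========================
name   rows x cols           values
====== ==================== =========================
DDI    drugs x drugs         binary, symmetric
DSIE   drugs x side effects  binary
DDIS   drugs x diseases      binary
PPI    proteins x proteins   binary, symmetric
PSIM   proteins x proteins   non-negative real, symmetric
PDIS   proteins x diseases   binary
====== ==================== =========================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

MATRIX_NAMES = ("DDI", "DSIE", "DDIS", "PPI", "PSIM", "PDIS")
SYMMETRIC_NAMES = ("DDI", "PPI", "PSIM")
ENTITY_KINDS = ("drug", "protein", "side_effect", "disease")

#: (row kind, column kind) for each matrix
MATRIX_AXES = {
    "DDI": ("drug", "drug"),
    "DSIE": ("drug", "side_effect"),
    "DDIS": ("drug", "disease"),
    "PPI": ("protein", "protein"),
    "PSIM": ("protein", "protein"),
    "PDIS": ("protein", "disease"),
}


class EntityRegistry:
    """Ordered, unique id <-> 0-based index mapping for one entity kind.

    Optionally carries a payload per id (SMILES string for drugs,
    amino-acid sequence for proteins).
    """

    def __init__(self, kind: str, ids: Iterable[str], payloads: dict[str, str] | None = None):
        if kind not in ENTITY_KINDS:
            raise ValueError(f"unknown entity kind {kind!r}")
        self.kind = kind
        self.ids = list(ids)
        if not self.ids:
            raise ValueError(f"empty registry for kind {kind!r}")
        self._index: dict[str, int] = {}
        for i, eid in enumerate(self.ids):
            if eid in self._index:
                raise ValueError(f"duplicate {kind} id {eid!r}")
            self._index[eid] = i
        self.payloads = dict(payloads or {})

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, eid: str) -> bool:
        return eid in self._index

    def index(self, eid: str) -> int:
        try:
            return self._index[eid]
        except KeyError:
            raise KeyError(f"unknown {self.kind} id {eid!r}") from None

    def indices(self, eids: Iterable[str]) -> np.ndarray:
        return np.array([self.index(e) for e in eids], dtype=int)

    def payload(self, eid: str) -> str | None:
        self.index(eid)  # validate
        return self.payloads.get(eid)


@dataclass
class HeteroMatrix:
    """One named association matrix with its row/column registries."""

    name: str
    rows: EntityRegistry
    cols: EntityRegistry
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.name not in MATRIX_NAMES:
            raise ValueError(f"unknown matrix name {self.name!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.rows), len(self.cols)):
            raise ValueError(
                f"{self.name}: values shape {self.values.shape} != "
                f"({len(self.rows)}, {len(self.cols)})"
            )

    @property
    def is_binary_kind(self) -> bool:
        return self.name != "PSIM"

    def row(self, eid: str) -> np.ndarray:
        return self.values[self.rows.index(eid)]

    def density(self) -> float:
        return float(np.count_nonzero(self.values)) / self.values.size


@dataclass
class EmbeddingTable:
    """Dense real vectors, one row per registry entry, fixed width."""

    registry: EntityRegistry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.registry):
            raise ValueError(
                f"embedding shape {self.values.shape} inconsistent with "
                f"registry of size {len(self.registry)}"
            )

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def vector(self, eid: str) -> np.ndarray:
        return self.values[self.registry.index(eid)]


@dataclass
class PairSet:
    """Labelled (drug_id, protein_id, label) triples with split provenance."""

    pairs: list[tuple[str, str, int]]
    role: str = "unassigned"
    fold: int | None = None

    def __post_init__(self) -> None:
        if self.role not in ("train", "val", "test", "unassigned"):
            raise ValueError(f"unknown role {self.role!r}")
        seen = set()
        for d, p, lab in self.pairs:
            if lab not in (0, 1):
                raise ValueError(f"label {lab!r} not binary for pair ({d}, {p})")
            if (d, p) in seen:
                raise ValueError(f"duplicate pair ({d!r}, {p!r})")
            seen.add((d, p))

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def drugs(self) -> set[str]:
        return {d for d, _, _ in self.pairs}

    @property
    def labels(self) -> np.ndarray:
        return np.array([lab for _, _, lab in self.pairs], dtype=int)

    def subset(self, keep, role: str | None = None, fold: int | None = None) -> "PairSet":
        kept = [t for t in self.pairs if keep(t)]
        return PairSet(kept, role=role or self.role, fold=self.fold if fold is None else fold)


@dataclass
class DatasetBundle:
    """A complete dataset: registries, six matrices, embeddings, positives."""

    drugs: EntityRegistry
    proteins: EntityRegistry
    side_effects: EntityRegistry
    diseases: EntityRegistry
    matrices: dict[str, HeteroMatrix]
    drug_embeddings: EmbeddingTable
    protein_embeddings: EmbeddingTable
    dti: PairSet

    def registry_for(self, kind: str) -> EntityRegistry:
        return {
            "drug": self.drugs,
            "protein": self.proteins,
            "side_effect": self.side_effects,
            "disease": self.diseases,
        }[kind]


# ---------------------------------------------------------------------------
# I/O


def _read_lines(path: str | Path) -> list[list[str]]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            records.append([lineno, line.split("\t")])
    return records


def load_entities(path: str | Path, kind: str) -> EntityRegistry:
    """Read a TSV entity table ``id<TAB>payload`` (payload optional).

    File order is preserved; duplicate ids and empty files are hard
    errors.
    """
    records = _read_lines(path)
    if not records:
        raise ValueError(f"entity file {path} is empty")
    ids: list[str] = []
    payloads: dict[str, str] = {}
    for lineno, fields in records:
        eid = fields[0]
        if eid in payloads or eid in ids:
            raise ValueError(f"duplicate id {eid!r} at {path}:{lineno}")
        ids.append(eid)
        if len(fields) > 1 and fields[1]:
            payloads[eid] = fields[1]
    return EntityRegistry(kind, ids, payloads)


def load_edge_list(
    path: str | Path,
    rows: EntityRegistry,
    cols: EntityRegistry,
    name: str,
) -> HeteroMatrix:
    """Materialize a dense matrix from a TSV edge list.

    Each line is ``row_id<TAB>col_id[<TAB>weight]``; a weight column is
    legal only for PSIM.  Edges of square symmetric matrices (DDI, PPI,
    PSIM) are mirrored.
    """
    values = np.zeros((len(rows), len(cols)))
    symmetric = name in SYMMETRIC_NAMES
    for lineno, fields in _read_lines(path):
        if len(fields) < 2:
            raise ValueError(f"malformed edge at {path}:{lineno}")
        rid, cid = fields[0], fields[1]
        if rid not in rows:
            raise ValueError(f"unknown row id {rid!r} at {path}:{lineno}")
        if cid not in cols:
            raise ValueError(f"unknown column id {cid!r} at {path}:{lineno}")
        if len(fields) >= 3 and fields[2] != "":
            if name != "PSIM":
                raise ValueError(
                    f"weight given for binary matrix {name} at {path}:{lineno}"
                )
            w = float(fields[2])
            if w < 0:
                raise ValueError(f"negative weight at {path}:{lineno}")
        else:
            w = 1.0
        i, j = rows.index(rid), cols.index(cid)
        values[i, j] = w
        if symmetric:
            values[j, i] = w
    return HeteroMatrix(name, rows, cols, values)


def write_edge_list(matrix: HeteroMatrix, path: str | Path) -> None:
    """Write nonzero cells as a TSV edge list (upper triangle for symmetric)."""
    with open(path, "w") as fh:
        fh.write(f"# {matrix.name}\t{matrix.rows.kind}\t{matrix.cols.kind}\n")
        sym = matrix.name in SYMMETRIC_NAMES
        rr, cc = np.nonzero(matrix.values)
        for i, j in zip(rr, cc):
            if sym and j < i:
                continue
            rid, cid = matrix.rows.ids[i], matrix.cols.ids[j]
            if matrix.name == "PSIM":
                fh.write(f"{rid}\t{cid}\t{matrix.values[i, j]:.10g}\n")
            else:
                fh.write(f"{rid}\t{cid}\n")


def load_embeddings(path: str | Path, registry: EntityRegistry) -> EmbeddingTable:
    """Read ``id<TAB>v1<TAB>...<TAB>vK`` rows; rows realigned to registry order."""
    vectors: dict[str, np.ndarray] = {}
    dim = None
    for lineno, fields in _read_lines(path):
        eid = fields[0]
        vec = np.array([float(v) for v in fields[1:]])
        if dim is None:
            dim = vec.size
        elif vec.size != dim:
            raise ValueError(f"embedding width varies at {path}:{lineno}")
        vectors[eid] = vec
    missing = [eid for eid in registry.ids if eid not in vectors]
    if missing:
        raise ValueError(f"missing embeddings for ids: {missing[:10]}")
    values = np.stack([vectors[eid] for eid in registry.ids])
    return EmbeddingTable(registry, values)


def write_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for eid, row in zip(table.registry.ids, table.values):
            fh.write(eid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def load_pairs(
    path: str | Path,
    drugs: EntityRegistry,
    proteins: EntityRegistry,
    default_label: int = 1,
) -> PairSet:
    """Read a DTI pair list ``drug_id<TAB>protein_id[<TAB>label]``."""
    pairs: list[tuple[str, str, int]] = []
    for lineno, fields in _read_lines(path):
        if len(fields) < 2:
            raise ValueError(f"malformed pair at {path}:{lineno}")
        d, p = fields[0], fields[1]
        if d not in drugs:
            raise ValueError(f"unknown drug id {d!r} at {path}:{lineno}")
        if p not in proteins:
            raise ValueError(f"unknown protein id {p!r} at {path}:{lineno}")
        lab = int(fields[2]) if len(fields) >= 3 else default_label
        pairs.append((d, p, lab))
    return PairSet(pairs)


def write_pairs(pairset: PairSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# drug_id\tprotein_id\tlabel\trole\n")
        for d, p, lab in pairset.pairs:
            fh.write(f"{d}\t{p}\t{lab}\t{pairset.role}\n")


# ---------------------------------------------------------------------------
# Validation


@dataclass
class ValidationReport:
    checks: list[tuple[str, bool, str]] = field(default_factory=list)

    def add(self, name: str, ok: bool, detail: str = "") -> None:
        self.checks.append((name, bool(ok), detail))

    @property
    def passed(self) -> bool:
        return all(ok for _, ok, _ in self.checks)

    def failures(self) -> list[str]:
        return [f"{name}: {detail}" for name, ok, detail in self.checks if not ok]

    def summary(self) -> str:
        lines = []
        for name, ok, detail in self.checks:
            status = "PASS" if ok else "FAIL"
            lines.append(f"[{status}] {name}" + (f" — {detail}" if detail else ""))
        return "\n".join(lines)


def validate_bundle(bundle: DatasetBundle) -> ValidationReport:
    """Check axis consistency, symmetry, binarity and label invariants.

    Returns a report with pass/fail flags rather than raising.
    """
    rep = ValidationReport()
    for name in MATRIX_NAMES:
        if name not in bundle.matrices:
            rep.add(f"{name}.present", False, "matrix missing")
            continue
        m = bundle.matrices[name]
        rkind, ckind = MATRIX_AXES[name]
        exp_shape = (len(bundle.registry_for(rkind)), len(bundle.registry_for(ckind)))
        rep.add(
            f"{name}.shape",
            m.values.shape == exp_shape,
            f"shape {m.values.shape}, expected {exp_shape}",
        )
        rep.add(f"{name}.nonnegative", bool(np.all(m.values >= 0)))
        rep.add(f"{name}.density", True, f"{m.density():.4f}")
        if m.is_binary_kind:
            rep.add(
                f"{name}.binary",
                bool(np.all((m.values == 0) | (m.values == 1))),
                "non 0/1 entries present" if not np.all((m.values == 0) | (m.values == 1)) else "",
            )
        if name in SYMMETRIC_NAMES:
            rep.add(f"{name}.symmetric", bool(np.allclose(m.values, m.values.T)))
    rep.add(
        "drug_embeddings.rows",
        bundle.drug_embeddings.values.shape[0] == len(bundle.drugs),
    )
    rep.add(
        "protein_embeddings.rows",
        bundle.protein_embeddings.values.shape[0] == len(bundle.proteins),
    )
    dti_ok = all(
        d in bundle.drugs and p in bundle.proteins for d, p, _ in bundle.dti.pairs
    )
    rep.add("dti.ids_resolvable", dti_ok)
    rep.add("dti.all_positive", bool(np.all(bundle.dti.labels == 1)))
    return rep
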