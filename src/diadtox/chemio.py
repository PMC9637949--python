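"""Reading, standardizing, deduplicating and splitting labeled structure sets.

The modeling endpoint is binary DIAD toxicity (drug-induced autoimmune
disease): label 1 = reported to cause DIAD, label 0 = reported not to.
Structures come in as SMILES (CSV/TSV) or SDF and are cleaned the way QSAR
datasets usually are: keep the main ingredient of a mixture, neutralize
salts to the parent form, drop inorganics and organometallics, canonicalize.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize
from sklearn.base import BaseEstimator, TransformerMixin

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "CompoundRecord",
    "LabeledDataset",
    "Rejection",
    "SplitSpec",
    "SchemaError",
    "StructureStandardizer",
    "read_dataset",
    "standardize",
    "deduplicate",
    "split_dataset",
]

# Elements allowed in an "organic" structure; everything else is a metal
# for the purpose of the organometallic exclusion. Ionic metal counter-ions
# never trigger it because salt stripping removes them first.
ORGANIC_ELEMENTS = frozenset(
    ["H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"]
)


class SchemaError(ValueError):
    """Input file violates the expected (id, smiles, label) schema."""


class DataError(ValueError):
    """Dataset-level contract violation (empty class, infeasible split...)."""


@dataclass(frozen=True)
class CompoundRecord:
    """One labeled structure.

    label is 1 for DIAD-positive, 0 for DIAD-negative; source is a free-text
    provenance tag (input file, generator name, ...).
    """

    id: str
    smiles: str
    label: int
    source: str = ""

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:
            raise ValueError(f"record {self.id!r}: unparseable SMILES {self.smiles!r}")
        return m


@dataclass(frozen=True)
class Rejection:
    """A structure removed from the pipeline, with a machine-readable reason."""

    id: str
    smiles: str
    reason: str  # parse_error | inorganic | organometallic | empty | missing_label | label_conflict
    detail: str = ""


@dataclass
class LabeledDataset:
    records: list[CompoundRecord]
    name: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n_pos(self) -> int:
        return sum(r.label == 1 for r in self.records)

    @property
    def n_neg(self) -> int:
        return sum(r.label == 0 for r in self.records)

    def class_counts(self) -> tuple[int, int]:
        return self.n_pos, self.n_neg

    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    def labels(self) -> np.ndarray:
        return np.asarray([r.label for r in self.records], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "label": [r.label for r in self.records],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class SplitSpec:
    """Per-class train partition, as fractions in (0,1) or explicit counts.

    The realized published partition (115/148 positives, 125/450 negatives in
    training) is expressible only through the count interface, since
    round(0.80*148) = 118 != 115.
    """

    pos_train: float | int
    neg_train: float | int
    seed: int = 0

    def __post_init__(self):
        for v in (self.pos_train, self.neg_train):
            if isinstance(v, float) and not (0.0 < v < 1.0):
                raise ValueError(f"fractional split {v} must lie strictly in (0,1)")
            if isinstance(v, (int, np.integer)) and not isinstance(v, bool) and v <= 0:
                raise ValueError(f"count split {v} must be positive")

    def train_count(self, which: str, n: int) -> int:
        v = self.pos_train if which == "pos" else self.neg_train
        k = int(round(v * n)) if isinstance(v, float) else int(v)
        if not (0 < k < n):
            raise DataError(
                f"{which} train partition of size {k} out of {n} leaves an empty side"
            )
        return k


# ---------------------------------------------------------------------------
# Reading

_COLUMN_ALIASES = {"id": {"id", "name"}, "smiles": {"smiles", "smile", "structure"},
                   "label": {"label", "class", "y", "diad"}}


def _resolve_columns(columns: Sequence[str]) -> dict[str, str]:
    lower = {c.lower().strip(): c for c in columns}
    out = {}
    for want, aliases in _COLUMN_ALIASES.items():
        hit = next((lower[a] for a in aliases if a in lower), None)
        if hit is None:
            raise SchemaError(f"missing required column {want!r} (have {list(columns)})")
        out[want] = hit
    return out


def _coerce_label(raw, where: str) -> int:
    try:
        val = float(str(raw).strip())
    except ValueError:
        raise SchemaError(f"{where}: label {raw!r} is not binary") from None
    if val not in (0.0, 1.0):
        raise SchemaError(f"{where}: label {raw!r} not in {{0,1}}")
    return int(val)


def read_dataset(
    path: str | Path,
    format: str | None = None,
    name: str | None = None,
    label_prop: str = "label",
) -> tuple[LabeledDataset, list[Rejection]]:
    """Read a labeled structure set from CSV/TSV (id, smiles, label) or SDF.

    Rows whose structure text does not parse are collected into the returned
    rejects list, never silently dropped. A non-binary label in tabular input
    is a hard :class:`SchemaError` naming the row; an SDF molecule lacking
    the label property is rejected per-record (SDF carries no global schema).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".sdf": "sdf"}.get(path.suffix.lower(), "csv")
    if format not in {"csv", "tsv", "sdf"}:
        raise ValueError(f"unknown format {format!r}")
    name = name or path.stem

    records: list[CompoundRecord] = []
    rejects: list[Rejection] = []

    if format in {"csv", "tsv"}:
        df = pd.read_csv(path, sep="\t" if format == "tsv" else ",", dtype=str)
        cols = _resolve_columns(df.columns)
        for i, row in df.iterrows():
            rid = str(row[cols["id"]])
            smi = str(row[cols["smiles"]])
            lab = _coerce_label(row[cols["label"]], f"row {i} (id {rid!r})")
            if Chem.MolFromSmiles(smi) is None:
                rejects.append(Rejection(rid, smi, "parse_error"))
            else:
                records.append(CompoundRecord(rid, smi, lab, source=str(path)))
    else:
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                rejects.append(Rejection(f"sdf_{i}", "", "parse_error"))
                continue
            rid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf_{i}"
            if not mol.HasProp(label_prop):
                rejects.append(Rejection(rid, Chem.MolToSmiles(mol), "missing_label"))
                continue
            lab = _coerce_label(mol.GetProp(label_prop), f"molecule {i} (id {rid!r})")
            records.append(CompoundRecord(rid, Chem.MolToSmiles(mol), lab, source=str(path)))

    return LabeledDataset(records, name=name), rejects


# ---------------------------------------------------------------------------
# Standardization

_UNCHARGER = rdMolStandardize.Uncharger()


def _is_metal(atom: Chem.Atom) -> bool:
    return atom.GetSymbol() not in ORGANIC_ELEMENTS


def _largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol | None:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if not frags:
        return None
    def has_carbon(f):
        return any(a.GetAtomicNum() == 6 for a in f.GetAtoms())
    pool = [f for f in frags if has_carbon(f)] or list(frags)
    # most heavy atoms, then higher MW, then lexicographically smallest SMILES
    def key(f):
        return (-f.GetNumHeavyAtoms(), -Descriptors.MolWt(f), Chem.MolToSmiles(f))
    return sorted(pool, key=key)[0]


def standardize(record: CompoundRecord) -> CompoundRecord | Rejection:
    """Standardize one structure to its canonical parent form.

    In order: (1) reduce a mixture to its largest organic fragment (the main
    ingredient), (2) neutralize to the parent (free acid/base) form,
    (3) reject inorganic (carbon-free) and organometallic (carbon-metal bond)
    structures, (4) emit canonical SMILES. Idempotent on accepted output.
    """
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        return Rejection(record.id, record.smiles, "parse_error")
    mol = _largest_organic_fragment(mol)
    if mol is None or mol.GetNumAtoms() == 0:
        return Rejection(record.id, record.smiles, "empty")
    try:
        Chem.SanitizeMol(mol)
        mol = _UNCHARGER.uncharge(mol)
    except Exception as exc:  # rare valence/kekulization failures
        return Rejection(record.id, record.smiles, "parse_error", detail=str(exc))
    if not any(a.GetAtomicNum() == 6 for a in mol.GetAtoms()):
        return Rejection(record.id, record.smiles, "inorganic")
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if (a.GetAtomicNum() == 6 and _is_metal(b)) or (b.GetAtomicNum() == 6 and _is_metal(a)):
            return Rejection(record.id, record.smiles, "organometallic",
                             detail=f"C-{b.GetSymbol() if _is_metal(b) else a.GetSymbol()} bond")
    return replace(record, smiles=Chem.MolToSmiles(mol))


def standardize_dataset(
    dataset: LabeledDataset,
) -> tuple[LabeledDataset, list[Rejection]]:
    """Standardize every record; accepted + rejected counts equal the input."""
    kept, rejects = [], []
    for rec in dataset:
        out = standardize(rec)
        (kept if isinstance(out, CompoundRecord) else rejects).append(out)
    return LabeledDataset(kept, name=dataset.name), rejects


class StructureStandardizer(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer over SMILES lists.

    ``transform`` maps a sequence of SMILES to canonical parent-form SMILES;
    structures the cleanup rejects become ``None`` entries, with the parallel
    :class:`Rejection` list kept on ``rejections_``.
    """

    def fit(self, X: Iterable[str], y=None):  # noqa: D102 - stateless
        return self

    def transform(self, X: Iterable[str]) -> list[str | None]:
        out, rej = [], []
        for i, smi in enumerate(X):
            res = standardize(CompoundRecord(str(i), smi, 0))
            if isinstance(res, Rejection):
                rej.append(res)
                out.append(None)
            else:
                out.append(res.smiles)
        self.rejections_ = rej
        return out


# ---------------------------------------------------------------------------
# Deduplication and splitting

def deduplicate(dataset: LabeledDataset) -> tuple[LabeledDataset, list[Rejection]]:
    """Collapse records sharing a canonical SMILES.

    Same-label duplicates keep the first occurrence. Duplicates with
    conflicting labels are removed entirely and reported: keeping either
    label would inject class noise.
    """
    by_smiles: dict[str, list[CompoundRecord]] = {}
    order: list[str] = []
    for rec in dataset:
        if rec.smiles not in by_smiles:
            order.append(rec.smiles)
        by_smiles.setdefault(rec.smiles, []).append(rec)

    kept, rejects = [], []
    for smi in order:
        group = by_smiles[smi]
        labels = {r.label for r in group}
        if len(labels) == 1:
            kept.append(group[0])
        else:
            for r in group:
                rejects.append(Rejection(r.id, r.smiles, "label_conflict",
                                         detail=f"{len(group)} records with labels 0 and 1"))
    return LabeledDataset(kept, name=dataset.name), rejects


def split_dataset(
    dataset: LabeledDataset, spec: SplitSpec
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified random train/validation split with per-class proportions.

    Positives and negatives are shuffled independently (seeded) and cut at
    the requested fraction or count; the published 240/358 partition
    corresponds to ``SplitSpec(pos_train=115, neg_train=125)`` on a 148+450
    set. Train and validation are disjoint and jointly exhaust the input.
    """
    pos = [r for r in dataset if r.label == 1]
    neg = [r for r in dataset if r.label == 0]
    if not pos or not neg:
        raise DataError("split requires both classes present")
    rng = np.random.RandomState(spec.seed)
    train, valid = [], []
    for which, group in (("pos", pos), ("neg", neg)):
        k = spec.train_count(which, len(group))
        idx = rng.permutation(len(group))
        chosen = set(idx[:k])
        train.extend(group[i] for i in sorted(chosen))
        valid.extend(g for i, g in enumerate(group) if i not in chosen)
    return (
        LabeledDataset(train, name=f"{dataset.name}_train"),
        LabeledDataset(valid, name=f"{dataset.name}_valid"),
    )


def write_rejects(rejects: list[Rejection], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "smiles", "reason", "detail"])
        for r in rejects:
            w.writerow([r.id, r.smiles, r.reason, r.detail])
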