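"""Binary molecular fingerprints under the seven benchmark schemes.

Schemes and widths: Estate 79, FP 1024, ExtendFP 1024, KRFP 4860, MACCS 166,
PubChem 881, SubFP 307. Dictionary-based schemes carry a bit-definition
registry (bit index -> SMARTS), which the alert miner relies on to report
matchable patterns; hashed path schemes (FP, ExtendFP) do not.

Providers:

* ``MACCS`` — RDKit MACCS keys (bits 1-166 of RDKit's 167-bit vector).
* ``Estate`` — the 79 electrotopological-state atom types.
* ``SubFP`` — the 307 functional-group SMARTS shipped with OpenBabel
  (located in the environment at run time).
* ``FP`` / ``ExtendFP`` — hashed 1024-bit RDKit path and Morgan(r=2)
  fingerprints; hashed bits are implementation-defined across toolkits, and
  these are declared equivalents of the CDK path schemes, not bit-exact.
* ``KRFP`` / ``PubChem`` — dictionary schemes whose published definitions are
  not redistributable here; supply an ``index<TAB>SMARTS`` file via
  :func:`register_bit_definitions`, otherwise computing them raises
  :class:`UnsupportedSchemeError` (never a silent zero vector).

Aromaticity is RDKit's default perception, applied at SMILES parse time and
recorded in matrix metadata.
"""

from __future__ import annotations

import glob
import hashlib
import json
import os
import shutil
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import MACCSkeys, rdMolDescriptors
from rdkit.Chem.EState import AtomTypes as _EStateAtomTypes
from sklearn.base import BaseEstimator, TransformerMixin

from .chemio import CompoundRecord, LabeledDataset

__all__ = [
    "SCHEME_WIDTHS",
    "FingerprintScheme",
    "FingerprintMatrix",
    "UnsupportedSchemeError",
    "FingerprintTransformer",
    "compute_fingerprint",
    "featurize_dataset",
    "bit_pattern",
    "get_provider",
    "register_bit_definitions",
    "make_dictionary_provider",
]

SCHEME_WIDTHS = {
    "Estate": 79,
    "FP": 1024,
    "ExtendFP": 1024,
    "KRFP": 4860,
    "MACCS": 166,
    "PubChem": 881,
    "SubFP": 307,
}

AROMATICITY_MODEL = "rdkit-default"


class UnsupportedSchemeError(RuntimeError):
    """Scheme has no usable backend (unknown name, or missing definitions)."""


@dataclass(frozen=True)
class FingerprintScheme:
    name: str
    width: int
    kind: str  # "dictionary" | "hashed"

    def __post_init__(self):
        if self.name in SCHEME_WIDTHS and SCHEME_WIDTHS[self.name] != self.width:
            raise ValueError(
                f"{self.name} width {self.width} != required {SCHEME_WIDTHS[self.name]}"
            )


@dataclass
class FingerprintMatrix:
    """n x width binary matrix aligned to a dataset, plus provenance."""

    scheme: FingerprintScheme
    bits: np.ndarray  # uint8, shape (n, width)
    ids: list[str]
    failed: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)
    provider: object | None = None  # backing provider (pattern lookups)

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2 or self.bits.shape != (len(self.ids), self.scheme.width):
            raise ValueError(
                f"bits shape {self.bits.shape} inconsistent with "
                f"{len(self.ids)} ids x width {self.scheme.width}"
            )
        if self.bits.size and self.bits.max() > 1:
            raise ValueError("fingerprint matrix must be binary")


def _mol_from(structure) -> Chem.Mol:
    if isinstance(structure, Chem.Mol):
        return structure
    if isinstance(structure, CompoundRecord):
        return structure.mol()
    mol = Chem.MolFromSmiles(str(structure))
    if mol is None:
        raise ValueError(f"unparseable SMILES {structure!r}")
    return mol


# ---------------------------------------------------------------------------
# Providers

class DictionaryProvider:
    """Fingerprint provider defined by an explicit list of SMARTS patterns.

    Entry ``(smarts, min_count)`` sets its bit when the structure contains
    strictly more than ``min_count - 1`` (i.e. at least ``min_count``) unique
    matches; plain presence keys use ``min_count=1``. Entries may be ``None``
    for keys whose published definition is not expressible as one SMARTS
    (a few MACCS keys); such bits compute via the backend but report no
    pattern.
    """

    kind = "dictionary"

    def __init__(self, name: str, patterns: Sequence[tuple[str, int] | None],
                 width: int | None = None, version: str = ""):
        self.name = name
        self.version = version
        self.patterns = list(patterns)
        self.width = width if width is not None else len(self.patterns)
        if len(self.patterns) != self.width:
            raise ValueError(f"{name}: {len(self.patterns)} patterns != width {self.width}")
        self._queries = []
        self.unmatchable: list[int] = []
        for i, entry in enumerate(self.patterns):
            if entry is None:
                self._queries.append(None)
                continue
            smarts, count = entry
            q = Chem.MolFromSmarts(smarts)
            if q is None:
                # e.g. multi-component queries "(...).(...)" outside the
                # matcher's SMARTS subset; the bit stays 0 and reports no
                # pattern rather than failing the whole scheme
                self._queries.append(None)
                self.unmatchable.append(i)
                self.patterns[i] = None
                continue
            self._queries.append((q, count))

    @property
    def scheme(self) -> FingerprintScheme:
        return FingerprintScheme(self.name, self.width, "dictionary")

    def bits(self, mol: Chem.Mol) -> np.ndarray:
        out = np.zeros(self.width, dtype=np.uint8)
        for i, q in enumerate(self._queries):
            if q is None:
                continue
            query, count = q
            if count <= 1:
                out[i] = mol.HasSubstructMatch(query)
            else:
                out[i] = len(mol.GetSubstructMatches(query, uniquify=True)) >= count
        return out

    def bit_pattern(self, bit: int) -> str:
        if not (0 <= bit < self.width):
            raise IndexError(f"{self.name}: bit {bit} out of range [0,{self.width})")
        entry = self.patterns[bit]
        if entry is None:
            raise UnsupportedSchemeError(
                f"{self.name} bit {bit} has no single-SMARTS definition"
            )
        return entry[0]


class MACCSProvider(DictionaryProvider):
    """166-bit MACCS keys; bit i here is RDKit key i+1.

    Bit values come from RDKit's reference implementation (which handles the
    count-threshold and composite keys); the SMARTS registry mirrors its key
    definitions for pattern reporting.
    """

    def __init__(self):
        patterns: list[tuple[str, int] | None] = []
        for key in range(1, 167):
            smarts, count = MACCSkeys.smartsPatts[key]
            # '?' marks keys RDKit special-cases (ring count, fragment count);
            # RDKit's count field means "strictly more than count matches"
            patterns.append(None if smarts == "?" else (smarts, count + 1))
        super().__init__("MACCS", patterns, width=166, version="rdkit")

    def bits(self, mol: Chem.Mol) -> np.ndarray:
        fp = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
        arr = np.zeros((167,), dtype=np.uint8)
        DataStructs.ConvertToNumpyArray(fp, arr)
        return arr[1:]


def _estate_provider() -> DictionaryProvider:
    _EStateAtomTypes.BuildPatts()
    patterns = [(Chem.MolToSmarts(q), 1) for _, q in _EStateAtomTypes.esPatterns]
    return DictionaryProvider("Estate", patterns, width=79, version="rdkit-estate")


def _find_openbabel_smarts() -> Path | None:
    candidates = []
    obabel = shutil.which("obabel")
    roots = []
    if obabel:
        roots.append(Path(obabel).resolve().parent.parent / "share" / "openbabel")
    if "BABEL_DATADIR" in os.environ:
        roots.append(Path(os.environ["BABEL_DATADIR"]))
    roots.append(Path(sys.prefix) / "share" / "openbabel")
    for root in roots:
        candidates.extend(glob.glob(str(root / "**" / "SMARTS_InteLigand.txt"), recursive=True))
        if candidates:
            break
    return Path(candidates[0]) if candidates else None


_SUBFP_NAMES: list[str] = []


def _subfp_provider() -> DictionaryProvider:
    path = _find_openbabel_smarts()
    if path is None:
        raise UnsupportedSchemeError(
            "SubFP needs OpenBabel's SMARTS_InteLigand.txt functional-group "
            "registry; not found in this environment"
        )
    patterns, names = [], []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, smarts = line.split(":", 1)
        names.append(name.strip())
        patterns.append((smarts.strip(), 1))
    _SUBFP_NAMES[:] = names
    return DictionaryProvider("SubFP", patterns, width=307, version=f"openbabel:{path.name}")


class HashedProvider:
    """Hashed-path fingerprint; bits carry no pattern registry."""

    kind = "hashed"

    def __init__(self, name: str, width: int, fn, version: str):
        self.name, self.width, self._fn, self.version = name, width, fn, version

    @property
    def scheme(self) -> FingerprintScheme:
        return FingerprintScheme(self.name, self.width, "hashed")

    def bits(self, mol: Chem.Mol) -> np.ndarray:
        fp = self._fn(mol)
        arr = np.zeros((self.width,), dtype=np.uint8)
        DataStructs.ConvertToNumpyArray(fp, arr)
        return arr

    def bit_pattern(self, bit: int) -> str:
        raise UnsupportedSchemeError(
            f"{self.name} is a hashed scheme; bits have no SMARTS definition"
        )


def _load_definition_file(path: str | Path) -> list[tuple[str, int] | None]:
    """Parse an ``index<TAB>SMARTS`` registry file (0-based, one per line)."""
    entries: dict[int, tuple[str, int]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        idx_s, smarts = line.split("\t", 1)
        entries[int(idx_s)] = (smarts.strip(), 1)
    width = max(entries) + 1 if entries else 0
    return [entries.get(i) for i in range(width)]


_EXTERNAL_DEFINITIONS: dict[str, Path] = {}


def register_bit_definitions(scheme: str, path: str | Path) -> None:
    """Attach a SMARTS registry file to a definition-gated scheme (KRFP, PubChem)."""
    if scheme not in {"KRFP", "PubChem"}:
        raise ValueError(f"{scheme} does not take external definitions")
    _EXTERNAL_DEFINITIONS[scheme] = Path(path)
    _PROVIDER_CACHE.pop(scheme, None)


def _external_provider(name: str) -> DictionaryProvider:
    if name not in _EXTERNAL_DEFINITIONS:
        raise UnsupportedSchemeError(
            f"{name} ({SCHEME_WIDTHS[name]} bits) requires an external bit-definition "
            f"file; supply one with register_bit_definitions({name!r}, path)"
        )
    patterns = _load_definition_file(_EXTERNAL_DEFINITIONS[name])
    if len(patterns) != SCHEME_WIDTHS[name]:
        raise ValueError(
            f"{name} definition file has {len(patterns)} bits, expected {SCHEME_WIDTHS[name]}"
        )
    return DictionaryProvider(name, patterns, width=SCHEME_WIDTHS[name],
                              version=str(_EXTERNAL_DEFINITIONS[name]))


_PROVIDER_FACTORIES = {
    "MACCS": MACCSProvider,
    "Estate": _estate_provider,
    "SubFP": _subfp_provider,
    "FP": lambda: HashedProvider(
        "FP", 1024, lambda m: Chem.RDKFingerprint(m, fpSize=1024), "rdkit-path"),
    "ExtendFP": lambda: HashedProvider(
        "ExtendFP", 1024,
        lambda m: rdMolDescriptors.GetMorganFingerprintAsBitVect(m, 2, nBits=1024),
        "rdkit-morgan2"),
    "KRFP": lambda: _external_provider("KRFP"),
    "PubChem": lambda: _external_provider("PubChem"),
}

_PROVIDER_CACHE: dict[str, object] = {}


def get_provider(scheme: str):
    """Resolve a scheme name (or pass through a provider instance)."""
    if hasattr(scheme, "bits"):
        return scheme
    if scheme not in _PROVIDER_FACTORIES:
        raise UnsupportedSchemeError(
            f"unknown scheme {scheme!r}; choose from {sorted(_PROVIDER_FACTORIES)}"
        )
    if scheme not in _PROVIDER_CACHE:
        _PROVIDER_CACHE[scheme] = _PROVIDER_FACTORIES[scheme]()
    return _PROVIDER_CACHE[scheme]


def make_dictionary_provider(name: str, smarts_list: Sequence[str]) -> DictionaryProvider:
    """Build an ad-hoc dictionary scheme from plain SMARTS (one bit each)."""
    return DictionaryProvider(name, [(s, 1) for s in smarts_list], version="adhoc")


# ---------------------------------------------------------------------------
# Public operations

def compute_fingerprint(structure, scheme: str = "MACCS") -> np.ndarray:
    """Binary bitvector of the scheme's exact width for one structure."""
    provider = get_provider(scheme)
    return provider.bits(_mol_from(structure))


def bit_pattern(scheme: str, bit: int) -> str:
    """SMARTS definition of a dictionary-scheme bit (errors on hashed schemes)."""
    return get_provider(scheme).bit_pattern(bit)


def _dataset_hash(smiles: Sequence[str], provider) -> str:
    h = hashlib.sha256()
    h.update(f"{provider.name}:{provider.version}:{AROMATICITY_MODEL}\n".encode())
    for s in smiles:
        h.update(s.encode())
        h.update(b"\n")
    return h.hexdigest()[:16]


def featurize_dataset(
    dataset: LabeledDataset,
    scheme: str = "MACCS",
    cache_dir: str | Path | None = None,
) -> FingerprintMatrix:
    """Fingerprint every record of a dataset into an aligned binary matrix.

    Rows follow dataset order; a record whose structure fails to fingerprint
    is excluded and listed in ``failed``. With ``cache_dir`` set, the matrix
    is cached on disk keyed by (dataset content, scheme, provider) and
    reloaded byte-identically on re-runs.
    """
    if len(dataset) == 0:
        raise ValueError("cannot featurize an empty dataset")
    provider = get_provider(scheme)
    key = _dataset_hash(dataset.smiles(), provider)

    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        npz = cache_dir / f"{provider.name}_{key}.npz"
        if npz.exists():
            import scipy.sparse as sp
            bits = np.asarray(sp.load_npz(npz).todense(), dtype=np.uint8)
            meta = json.loads(npz.with_suffix(".json").read_text())
            return FingerprintMatrix(provider.scheme, bits, meta["ids"],
                                     failed=meta["failed"], meta=meta,
                                     provider=provider)

    rows, ids, failed = [], [], []
    for rec in dataset:
        try:
            rows.append(provider.bits(rec.mol()))
            ids.append(rec.id)
        except Exception:
            failed.append(rec.id)
    if not rows:
        raise ValueError("every record failed fingerprinting")
    meta = {
        "scheme": provider.name,
        "provider": provider.version,
        "aromaticity": AROMATICITY_MODEL,
        "dataset_hash": key,
        "ids": ids,
        "failed": failed,
    }
    fpm = FingerprintMatrix(provider.scheme, np.array(rows, dtype=np.uint8), ids,
                            failed=failed, meta=meta, provider=provider)

    if cache_dir is not None:
        import scipy.sparse as sp
        cache_dir.mkdir(parents=True, exist_ok=True)
        sp.save_npz(npz, sp.csc_matrix(fpm.bits))
        npz.with_suffix(".json").write_text(json.dumps(meta))
    return fpm


class FingerprintTransformer(BaseEstimator, TransformerMixin):
    """sklearn transformer: SMILES sequence -> (n, width) binary matrix.

    Parameters
    ----------
    scheme : str or provider, default "MACCS"
        One of the seven registered schemes or an ad-hoc dictionary provider.
    """

    def __init__(self, scheme="MACCS"):
        self.scheme = scheme

    def fit(self, X: Iterable, y=None):
        provider = get_provider(self.scheme)
        self.width_ = provider.width
        self.kind_ = provider.kind
        return self

    def transform(self, X: Iterable) -> np.ndarray:
        provider = get_provider(self.scheme)
        return np.array([provider.bits(_mol_from(x)) for x in X], dtype=np.uint8)

    def get_feature_names_out(self, input_features=None):
        provider = get_provider(self.scheme)
        return np.asarray([f"{provider.name}_{i}" for i in range(provider.width)])
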