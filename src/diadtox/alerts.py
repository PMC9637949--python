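"""Structural-alert mining from dictionary fingerprint bits.

A structural alert is a substructure occurring preferentially in
DIAD-positive structures. Candidate fragments are the bits of a
dictionary-based fingerprint scheme; each bit is scored by

* support — number of structures (either class) containing the fragment;
* positive rate PR = num_p / (num_p + num_n), the fraction of
  fragment-bearing structures that are DIAD-positive;
* f-score — a between-class over within-class discrimination ratio.
  For a binary feature with class occurrence fractions
  xp = num_p/n_pos, xn = num_n/n_neg and pooled fraction
  x = (num_p+num_n)/(n_pos+n_neg):

      f = ((xp - x)^2 + (xn - x)^2) / (s_pos + s_neg)

  where s_c = n_c * x_c * (1 - x_c) / (n_c - 1) is the Bessel-corrected
  within-class scatter of the 0/1 column.

Default thresholds (support >= 6, f-score >= 0.018, PR >= 0.75, all
inclusive) are the published operating point; mining is performed on the
full labeled set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json

import numpy as np
import pandas as pd
from rdkit import Chem
from sklearn.base import BaseEstimator, TransformerMixin

from .chemio import CompoundRecord
from .fingerprints import (
    FingerprintMatrix,
    UnsupportedSchemeError,
    featurize_dataset,
    get_provider,
)

__all__ = [
    "FragmentStat",
    "AlertSet",
    "AlertMiner",
    "fragment_counts",
    "positive_rate",
    "fscore_binary",
    "mine_alerts",
    "screen_structure",
]


@dataclass(frozen=True)
class FragmentStat:
    """One fragment bit's class statistics."""

    scheme: str
    bit: int
    pattern: str
    num_p: int
    num_n: int
    pr: float
    fscore: float
    degenerate: bool = False

    @property
    def support(self) -> int:
        return self.num_p + self.num_n


@dataclass
class AlertSet:
    alerts: list[FragmentStat]
    thresholds: dict
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.alerts)

    def __iter__(self):
        return iter(self.alerts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "No.": np.arange(1, len(self.alerts) + 1),
                "scheme": [a.scheme for a in self.alerts],
                "bit": [a.bit for a in self.alerts],
                "pattern": [a.pattern for a in self.alerts],
                "Num_P": [a.num_p for a in self.alerts],
                "Num_N": [a.num_n for a in self.alerts],
                "f-score": [a.fscore for a in self.alerts],
                "PR": [a.pr for a in self.alerts],
            }
        )

    def save(self, path: str | Path) -> None:
        """TSV of the alert table plus a JSON sidecar with thresholds."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(
            {"thresholds": self.thresholds, "provenance": self.provenance}, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "AlertSet":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        alerts = []
        for _, r in df.iterrows():
            num_p, num_n = int(r["Num_P"]), int(r["Num_N"])
            alerts.append(FragmentStat(str(r["scheme"]), int(r["bit"]),
                                       str(r["pattern"]), num_p, num_n,
                                       pr=float(r["PR"]), fscore=float(r["f-score"])))
        return cls(alerts, meta.get("thresholds", {}), meta.get("provenance", {}))


# ---------------------------------------------------------------------------
# Statistics

def fragment_counts(X, y) -> tuple[np.ndarray, np.ndarray]:
    """Per-bit positive/negative occurrence counts (exact integers)."""
    bits = X.bits if isinstance(X, FingerprintMatrix) else np.asarray(X)
    y = np.asarray(y, dtype=int)
    if bits.shape[0] != len(y):
        raise ValueError(f"{bits.shape[0]} fingerprint rows vs {len(y)} labels")
    b = bits.astype(np.int64)
    num_p = (b[y == 1]).sum(axis=0)
    num_n = (b[y == 0]).sum(axis=0)
    return num_p, num_n


def positive_rate(num_p: int, num_n: int) -> float:
    """PR = num_p / (num_p + num_n); undefined at zero support."""
    support = num_p + num_n
    if support <= 0:
        raise ValueError("positive rate undefined for a fragment with no support")
    return num_p / support


def fscore_binary(num_p: int, num_n: int, n_pos: int, n_neg: int) -> float:
    """Discrimination f-score of a binary fragment feature (closed form).

    Equals the generic two-class feature-selection f-score evaluated on the
    expanded 0/1 occurrence vectors. Returns 0 when the fragment is constant
    within both classes (no within-class scatter, no discrimination).
    """
    if n_pos <= 1 or n_neg <= 1:
        raise ValueError("class sizes must exceed 1")
    if not (0 <= num_p <= n_pos and 0 <= num_n <= n_neg):
        raise ValueError("occurrence counts outside class sizes")
    xp = num_p / n_pos
    xn = num_n / n_neg
    x = (num_p + num_n) / (n_pos + n_neg)
    s_pos = n_pos * xp * (1.0 - xp) / (n_pos - 1)
    s_neg = n_neg * xn * (1.0 - xn) / (n_neg - 1)
    denom = s_pos + s_neg
    if denom == 0.0:
        return 0.0
    return ((xp - x) ** 2 + (xn - x) ** 2) / denom


# ---------------------------------------------------------------------------
# Mining and screening

def mine_alerts(
    X: FingerprintMatrix,
    y,
    min_support: int = 6,
    min_fscore: float = 0.018,
    min_pr: float = 0.75,
) -> AlertSet:
    """Mine alert fragments from a dictionary-scheme fingerprint matrix.

    Bits are kept when support >= min_support, then when both
    f-score >= min_fscore and PR >= min_pr (inclusive thresholds). Bits with
    identical occurrence columns are collapsed to the lowest index. Output
    is sorted by descending PR, then f-score, then bit index. Bits without a
    reportable SMARTS (a few composite dictionary keys) are skipped and
    listed in provenance.
    """
    if not isinstance(X, FingerprintMatrix):
        raise TypeError("mine_alerts needs a FingerprintMatrix (scheme-aware)")
    if X.scheme.kind != "dictionary":
        raise UnsupportedSchemeError(
            f"{X.scheme.name} is hashed; alerts need reportable patterns")
    y = np.asarray(y, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError("both classes must have at least 2 members")

    num_p, num_n = fragment_counts(X, y)
    support = num_p + num_n

    # collapse bits with identical match sets (columns) to the lowest index
    candidates = np.where(support >= min_support)[0]
    seen_columns: dict[bytes, int] = {}
    skipped_no_pattern: list[int] = []
    alerts: list[FragmentStat] = []
    for bit in candidates:
        col_key = X.bits[:, bit].tobytes()
        if col_key in seen_columns:
            continue
        pr = positive_rate(int(num_p[bit]), int(num_n[bit]))
        fs = fscore_binary(int(num_p[bit]), int(num_n[bit]), n_pos, n_neg)
        if pr < min_pr or fs < min_fscore:
            continue
        try:
            pattern = _pattern_for(X, bit)
        except UnsupportedSchemeError:
            skipped_no_pattern.append(int(bit))
            continue
        seen_columns[col_key] = int(bit)
        alerts.append(FragmentStat(X.scheme.name, int(bit), pattern,
                                   int(num_p[bit]), int(num_n[bit]), pr, fs))

    alerts.sort(key=lambda a: (-a.pr, -a.fscore, a.bit))
    return AlertSet(
        alerts,
        thresholds={"min_support": min_support, "min_fscore": min_fscore,
                    "min_pr": min_pr},
        provenance={
            "scheme": X.scheme.name,
            "dataset_hash": X.meta.get("dataset_hash", ""),
            "n_pos": n_pos,
            "n_neg": n_neg,
            "skipped_no_pattern": skipped_no_pattern,
            "collapsed_duplicates": True,
        },
    )


def _pattern_for(X: FingerprintMatrix, bit: int) -> str:
    provider = X.provider if X.provider is not None else get_provider(X.scheme.name)
    return provider.bit_pattern(int(bit))


def screen_structure(record, alert_set: AlertSet) -> list[tuple[FragmentStat, tuple]]:
    """Match a structure against every alert pattern.

    Returns one entry per alert that matches, with the matched atom index
    tuples for visualization; an empty list means no alert flagged.
    """
    if isinstance(record, CompoundRecord):
        mol = record.mol()
    elif isinstance(record, Chem.Mol):
        mol = record
    else:
        mol = Chem.MolFromSmiles(str(record))
        if mol is None:
            raise ValueError(f"unparseable structure {record!r}")
    hits = []
    for alert in alert_set:
        query = Chem.MolFromSmarts(alert.pattern)
        if query is None:
            raise ValueError(f"alert bit {alert.bit} has invalid SMARTS {alert.pattern!r}")
        matches = mol.GetSubstructMatches(query, uniquify=True)
        if matches:
            hits.append((alert, matches))
    return hits


class AlertMiner(BaseEstimator, TransformerMixin):
    """sklearn-style miner: fit on (structures, labels), screen via transform.

    Parameters
    ----------
    scheme : dictionary fingerprint scheme (name or ad-hoc provider)
    min_support, min_fscore, min_pr : inclusive mining thresholds
        (defaults are the published operating point: 6 / 0.018 / 0.75)

    Attributes
    ----------
    alerts_ : AlertSet of mined fragments, PR-then-f-score ordered
    """

    def __init__(self, scheme="MACCS", min_support=6, min_fscore=0.018, min_pr=0.75):
        self.scheme = scheme
        self.min_support = min_support
        self.min_fscore = min_fscore
        self.min_pr = min_pr

    def fit(self, X, y):
        from .chemio import LabeledDataset

        if isinstance(X, FingerprintMatrix):
            fpm = X
        else:
            if not isinstance(X, LabeledDataset):
                records = [CompoundRecord(str(i), str(s), int(lab))
                           for i, (s, lab) in enumerate(zip(X, y))]
                X = LabeledDataset(records, name="alertminer_input")
            fpm = featurize_dataset(X, self.scheme)
        self.alerts_ = mine_alerts(fpm, y, self.min_support, self.min_fscore,
                                   self.min_pr)
        return self

    def transform(self, X) -> np.ndarray:
        """Binary (n, n_alerts) hit matrix for a sequence of structures."""
        out = np.zeros((len(X), len(self.alerts_)), dtype=np.uint8)
        for i, s in enumerate(X):
            hits = {a.bit for a, _ in screen_structure(s, self.alerts_)}
            for j, alert in enumerate(self.alerts_):
                out[i, j] = alert.bit in hits
        return out

    def predict(self, X) -> np.ndarray:
        """Flag = 1 when any mined alert matches the structure."""
        return (self.transform(X).sum(axis=1) > 0).astype(int)
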