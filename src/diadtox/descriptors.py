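"""Molecular-property profiles, class comparison, and the PCA chemical space.

Eight properties characterize each structure: molecular weight (MW, g/mol),
molecular polar surface area (MPSA, A^2), AlogP, aqueous solubility
(LogS, log mol/L), hydrogen-bond acceptor/donor counts (nHAcc, nHDon),
rotatable bonds (nRotB) and aromatic rings (nAR). Property distributions are
skewed, so classes are summarized as median (P25, P75) and compared with the
two-sided Wilcoxon rank-sum test; p < 0.05 flags significance.

Providers: MPSA is topological polar surface area, AlogP is the Crippen
atom-contribution logP, and LogS is the ESOL regression
``0.16 - 0.63*clogP - 0.0062*MW + 0.066*nRotB - 0.74*AP`` (AP = aromatic
proportion of heavy atoms). These are open-implementation analogues of the
properties, adequate for ordinal class comparison; absolute values differ
slightly across descriptor software.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .chemio import CompoundRecord

__all__ = [
    "PROPERTY_NAMES",
    "GroupComparison",
    "ChemicalSpace",
    "PropertyCalculator",
    "compute_properties",
    "compare_groups",
    "chemical_space",
]

PROPERTY_NAMES = ["MW", "MPSA", "AlogP", "LogS", "nHAcc", "nHDon", "nRotB", "nAR"]

# exact rank-sum null enumeration below this per-group size (tie-free only)
EXACT_RANKSUM_MAX_N = 25


def _esol_logs(mol: Chem.Mol) -> float:
    mw = Descriptors.MolWt(mol)
    clogp = Crippen.MolLogP(mol)
    rotb = Lipinski.NumRotatableBonds(mol)
    heavy = mol.GetNumHeavyAtoms()
    ap = sum(a.GetIsAromatic() for a in mol.GetAtoms()) / heavy if heavy else 0.0
    return 0.16 - 0.63 * clogp - 0.0062 * mw + 0.066 * rotb - 0.74 * ap


def compute_properties(record) -> dict[str, float]:
    """The eight-property row for one structure (SMILES, Mol or record)."""
    if isinstance(record, CompoundRecord):
        mol = record.mol()
    elif isinstance(record, Chem.Mol):
        mol = record
    else:
        mol = Chem.MolFromSmiles(str(record))
        if mol is None:
            raise ValueError(f"unparseable SMILES {record!r}")
    return {
        "MW": Descriptors.MolWt(mol),
        "MPSA": rdMolDescriptors.CalcTPSA(mol),
        "AlogP": Crippen.MolLogP(mol),
        "LogS": _esol_logs(mol),
        "nHAcc": Lipinski.NumHAcceptors(mol),
        "nHDon": Lipinski.NumHDonors(mol),
        "nRotB": Lipinski.NumRotatableBonds(mol),
        "nAR": rdMolDescriptors.CalcNumAromaticRings(mol),
    }


class PropertyCalculator(BaseEstimator, TransformerMixin):
    """sklearn transformer: structures -> (n, 8) property DataFrame.

    Structures that fail descriptor calculation yield all-NaN rows and are
    listed on ``failed_`` after transform.
    """

    def fit(self, X: Iterable, y=None):
        self.feature_names_ = list(PROPERTY_NAMES)
        return self

    def transform(self, X: Iterable) -> pd.DataFrame:
        rows, failed = [], []
        for i, x in enumerate(X):
            try:
                rows.append(compute_properties(x))
            except Exception:
                rows.append({k: np.nan for k in PROPERTY_NAMES})
                failed.append(i)
        self.failed_ = failed
        return pd.DataFrame(rows, columns=PROPERTY_NAMES)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(PROPERTY_NAMES)


# ---------------------------------------------------------------------------
# Group comparison

@dataclass(frozen=True)
class GroupComparison:
    property: str
    median_pos: float
    p25_pos: float
    p75_pos: float
    median_neg: float
    p25_neg: float
    p75_neg: float
    p_value: float
    significant: bool
    degenerate: bool = False

    def summary_pos(self) -> str:
        return f"{self.median_pos:.2f} ({self.p25_pos:.2f}, {self.p75_pos:.2f})"

    def summary_neg(self) -> str:
        return f"{self.median_neg:.2f} ({self.p25_neg:.2f}, {self.p75_neg:.2f})"


def ranksum_pvalue(a: Sequence[float], b: Sequence[float]) -> tuple[float, bool]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution for tie-free groups of at most
    ``EXACT_RANKSUM_MAX_N`` each; otherwise the normal approximation with
    tie correction and continuity correction. A sample constant across both
    groups is degenerate: p = 1 with a flag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0, True
    tie_free = len(np.unique(pooled)) == len(pooled)
    small = max(len(a), len(b)) <= EXACT_RANKSUM_MAX_N
    method = "exact" if (tie_free and small) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0)), False


def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    # linear-interpolation convention (numpy default)
    p25, med, p75 = np.percentile(x, [25, 50, 75])
    return float(med), float(p25), float(p75)


def compare_groups(
    properties: pd.DataFrame, labels: Sequence[int], alpha: float = 0.05
) -> list[GroupComparison]:
    """Per-property class summary (median, quartiles) and rank-sum test.

    ``properties`` rows align with ``labels`` (1 = DIAD, 0 = non-DIAD).
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(properties):
        raise ValueError("labels and property rows misaligned")
    if not ((labels == 1).any() and (labels == 0).any()):
        raise ValueError("both classes must be non-empty")
    out = []
    for prop in properties.columns:
        col = properties[prop].to_numpy(dtype=float)
        ok = ~np.isnan(col)
        pos = col[ok & (labels == 1)]
        neg = col[ok & (labels == 0)]
        p, degenerate = ranksum_pvalue(pos, neg)
        mp, p25p, p75p = _quartiles(pos)
        mn, p25n, p75n = _quartiles(neg)
        out.append(GroupComparison(prop, mp, p25p, p75p, mn, p25n, p75n,
                                   p, significant=(p < alpha and not degenerate),
                                   degenerate=degenerate))
    return out


def comparison_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "property": [c.property for c in comparisons],
            "DIAD M (P25, P75)": [c.summary_pos() for c in comparisons],
            "non-DIAD M (P25, P75)": [c.summary_neg() for c in comparisons],
            "p_value": [c.p_value for c in comparisons],
            "significant": [c.significant for c in comparisons],
        }
    )


# ---------------------------------------------------------------------------
# Chemical space

@dataclass
class ChemicalSpace:
    scores: np.ndarray       # (n, 2) sample coordinates
    loadings: np.ndarray     # (n_properties, 2)
    explained: float         # cumulative explained-variance proportion, 2 PCs
    explained_ratio: np.ndarray  # per-component proportions

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)


def chemical_space(properties: pd.DataFrame | np.ndarray, n_components: int = 2) -> ChemicalSpace:
    """Two-component PCA of the standardized property table.

    Columns are z-scored first (correlation-matrix PCA — the properties mix
    units). Sign convention: within each component the loading of largest
    magnitude is made positive, so scores are reproducible across runs.
    """
    X = np.asarray(properties, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need at least 3 rows of properties")
    if X.shape[0] <= n_components:
        raise ValueError("fewer rows than components")
    Xs = StandardScaler().fit_transform(X)
    # constant columns z-score to nan; they carry no variance
    Xs = np.nan_to_num(Xs, nan=0.0)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xs)
    loadings = pca.components_.T.copy()  # (d, k)
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    ratio = pca.explained_variance_ratio_
    return ChemicalSpace(scores, loadings, float(ratio.sum()), ratio)


def plot_chemical_space(space: ChemicalSpace, labels: Sequence[str], path) -> None:
    """Scatter of the first two PCs colored by group tag (e.g. train/valid)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(6, 5))
    for tag, marker in zip(pd.unique(labels), "so^v"):
        m = labels == tag
        ax.scatter(space.scores[m, 0], space.scores[m, 1], s=14, alpha=0.6,
                   marker=marker, label=str(tag))
    ax.set_xlabel(f"PC1")
    ax.set_ylabel(f"PC2")
    ax.set_title(f"Chemical space (cumulative explained {100 * space.explained:.2f}%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
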