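"""Synthetic labeled SMILES sets with planted, class-enriched substructures.

The generator emulates the statistical shape of a structural-alert study:
two classes of drug-like molecules in which chosen fragments occur at
controlled positive rates and supports. Molecules are assembled from a
hand-written library of drug-like scaffolds with open substitution slots,
decorated with small substituents; a planted fragment is grafted onto a
deterministic, seeded selection of molecules so that substructure matching
afterwards reproduces the target (num_p, num_n) exactly.

Plant fragments are fused heterocyclic or otherwise distinctive motifs that
cannot arise from any scaffold x decorator combination (verified after
generation; a collision raises). The decoy fragment is planted at the class
base rate so a correct miner must not report it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chemio import CompoundRecord, LabeledDataset
from .fingerprints import DictionaryProvider, make_dictionary_provider

__all__ = [
    "PlantSpec",
    "GeneratorConfig",
    "PLANT_LIBRARY",
    "generate",
    "paperlike_fixture",
    "plant_scheme",
]


@dataclass(frozen=True)
class PlantSpec:
    """One fragment to plant: attachable branch SMILES + match SMARTS.

    target_pr and target_support set the realized occurrence pattern:
    num_p = round(target_pr * target_support) positives carry the fragment,
    the remaining support goes to negatives.
    """

    name: str
    branch: str        # SMILES branch, e.g. "(N1c2ccccc2Sc2ccccc21)"
    smarts: str        # substructure query that matches the planted fragment
    target_pr: float
    target_support: int

    def __post_init__(self):
        if not (0.0 <= self.target_pr <= 1.0):
            raise ValueError("target_pr must lie in [0,1]")
        if self.target_support < 0:
            raise ValueError("target_support must be non-negative")

    @property
    def num_p(self) -> int:
        return int(round(self.target_pr * self.target_support))

    @property
    def num_n(self) -> int:
        return self.target_support - self.num_p


# Named plantable fragments. Each is distinctive enough that no scaffold or
# decorator combination can produce an accidental match (checked at
# generation time).
# Branch SMILES use ring-closure digits 6-9 so they can be spliced into
# scaffold templates (which use digits 1-2) without closure collisions.
PLANT_LIBRARY: dict[str, tuple[str, str]] = {
    # phenothiazine tricycle, N-linked
    "phenothiazine": ("(N6c7ccccc7Sc8ccccc86)", "c1ccc2c(c1)Nc1ccccc1S2"),
    # 5-nitrofuran-2-yl
    "nitrofuran": ("(c6ccc([N+](=O)[O-])o6)", "[O-][N+](=O)c1ccco1"),
    # arylsulfonyl hydrazide
    "sulfonohydrazide": ("(S(=O)(=O)NN)", "S(=O)(=O)NN"),
    # thioamide
    "thioamide": ("(C(N)=S)", "NC=S"),
    # isoxazole ring, 3-linked
    "isoxazole": ("(c6cc(C)on6)", "c1conc1"),
    # propiolamide (alkyne amide), decoy-grade rarity
    "propiolamide": ("(NC(=O)C#C)", "C#CC(N)=O"),
}


@dataclass(frozen=True)
class GeneratorConfig:
    n_pos: int
    n_neg: int
    plants: tuple[PlantSpec, ...] = ()
    # positive-class bias toward H-bond-donor decorators, in [0,1]
    donor_shift: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pos <= 0 or self.n_neg <= 0:
            raise ValueError("class sizes must be positive")
        for p in self.plants:
            if p.num_p > self.n_pos or p.num_n > self.n_neg:
                raise ValueError(
                    f"plant {p.name!r} needs ({p.num_p},{p.num_n}) carriers; "
                    f"classes hold only ({self.n_pos},{self.n_neg})")


# Scaffold templates: format-string SMILES with substitution slots. Slots sit
# on aromatic carbons or amide nitrogens and accept branch strings like
# "(CC)" or "" (hydrogen).
_SCAFFOLDS = [
    "c1cc{0}cc{1}c1{2}",
    "c1ccc(-c2ccc{0}cc2{1})cc1{2}",
    "c1ccc2c(c1)cc{0}cc2{1}",
    "O=C(N{0}c1ccc{1}cc1)c1ccc{2}cc1",
    "c1ccc(C{0}N2CCN(C{1})CC2)cc1{2}",
    "O=C1N{0}C(=O)c2ccccc21",
    "c1ccc(OCC(O)CN{0}C(C)C)cc1{1}",
    "c1cnc2[nH]c{0}cc2c1{1}",
    "O=C(O)c1ccccc1N{0}c1ccc{1}cc1",
    "c1c{1}sc(NC(=O)C{0})n1",
    "O=S(=O)(c1ccc{0}cc1)c1ccc{1}cc1",
    "c1ccc(CC{0}NCC(O)c2ccc(O)c{1}c2)cc1",
    "O=C(C{0})Nc1ccc(N2CCOCC2)c{1}c1",
    "c1cc2cccnc2c{0}c1{1}",
    "C1CCC(C{0}N2CCCC2{1})CC1",
    "c1cc(-c2noc{0}n2)cc{1}c1",
    "O=C(NCC{0})C1CCN(C{1})CC1",
    "c1ccc(N2CCN(CCC{0})CC2)c{1}c1",
    "O=C(C=Cc1ccc{0}cc1)N1CCCC1{2}C{1}",
    "c1nc2ccccc2n1C{0}C{1}",
]

# Substituent branches; "" leaves the slot as H. Chosen to avoid every
# fragment in PLANT_LIBRARY (no N-N, C#C, C=S, S(=O)(=O)N, nitro, fused
# N/S tricycle, isoxazole).
_DECORATORS = ["", "", "", "(C)", "(C)", "(CC)", "(C(C)C)", "(OC)", "(F)",
               "(Cl)", "(Br)", "(C(F)(F)F)", "(CC(C)C)", "(OCC)", "(C(C)=O)"]
# decorators that add H-bond donors, favoured in the positive class under
# donor_shift
_DONOR_DECORATORS = ["(O)", "(N)", "(CO)", "(CN)", "(C(N)=O)", "(CCO)"]


def _assemble(rng: np.random.Generator, scaffold: str, n_slots: int,
              donor_p: float, forced: dict[int, str] | None = None) -> str | None:
    fills = []
    for slot in range(n_slots):
        if forced and slot in forced:
            fills.append(forced[slot])
        elif rng.random() < donor_p:
            fills.append(_DONOR_DECORATORS[rng.integers(len(_DONOR_DECORATORS))])
        else:
            fills.append(_DECORATORS[rng.integers(len(_DECORATORS))])
    smi = scaffold.format(*fills)
    mol = Chem.MolFromSmiles(smi)
    return Chem.MolToSmiles(mol) if mol is not None else None


def _slot_count(scaffold: str) -> int:
    return max(int(c) for c in scaffold if c.isdigit() and "{" + c + "}" in scaffold) + 1 \
        if "{" in scaffold else 0


def generate(config: GeneratorConfig) -> LabeledDataset:
    """Generate a labeled synthetic set honouring every plant exactly.

    Deterministic in ``config.seed`` (same seed, byte-identical SMILES).
    Structures are built salt-free and organic, so they survive
    standardization unchanged. After generation every plant's realized
    (num_p, num_n) is verified by substructure matching; a mismatch
    (an accidental match or failed graft) raises ``RuntimeError``.
    """
    rng = np.random.default_rng(config.seed)
    slots = {s: _slot_count(s) for s in _SCAFFOLDS}

    # deterministic carrier assignment: molecule indices per class
    carriers: dict[str, tuple[set[int], set[int]]] = {}
    free_pos = list(range(config.n_pos))
    free_neg = list(range(config.n_neg))
    for plant in config.plants:
        # sample without replacement among molecules not yet carrying a plant
        # (keeps realized counts independent across plants)
        if plant.num_p > len(free_pos) or plant.num_n > len(free_neg):
            raise ValueError(f"plant {plant.name!r} infeasible: not enough free molecules")
        pos_pick = rng.choice(len(free_pos), size=plant.num_p, replace=False)
        chosen_p = {free_pos[i] for i in pos_pick}
        free_pos = [i for i in free_pos if i not in chosen_p]
        neg_pick = rng.choice(len(free_neg), size=plant.num_n, replace=False)
        chosen_n = {free_neg[i] for i in neg_pick}
        free_neg = [i for i in free_neg if i not in chosen_n]
        carriers[plant.name] = (chosen_p, chosen_n)

    records: list[CompoundRecord] = []
    seen: set[str] = set()
    for label, n, prefix in ((1, config.n_pos, "P"), (0, config.n_neg, "N")):
        donor_p = 0.12 + (config.donor_shift if label == 1 else 0.0)
        for i in range(n):
            forced = None
            for plant in config.plants:
                pool = carriers[plant.name][0 if label == 1 else 1]
                if i in pool:
                    forced = {0: plant.branch}
                    break
            smi = None
            for _ in range(60):  # bounded retries for invalid/duplicate draws
                scaffold = _SCAFFOLDS[rng.integers(len(_SCAFFOLDS))]
                if forced and slots[scaffold] == 0:
                    continue
                cand = _assemble(rng, scaffold, slots[scaffold], donor_p, forced)
                if cand is not None and cand not in seen:
                    smi = cand
                    break
            if smi is None:
                raise RuntimeError("generator exhausted retries building a molecule")
            seen.add(smi)
            records.append(CompoundRecord(f"{prefix}{i:04d}", smi, label,
                                          source="synthdata"))

    dataset = LabeledDataset(records, name=f"synth_seed{config.seed}")
    _verify_plants(dataset, config)
    return dataset


def _verify_plants(dataset: LabeledDataset, config: GeneratorConfig) -> None:
    for plant in config.plants:
        query = Chem.MolFromSmarts(plant.smarts)
        got_p = got_n = 0
        for rec in dataset:
            if rec.mol().HasSubstructMatch(query):
                if rec.label == 1:
                    got_p += 1
                else:
                    got_n += 1
        if (got_p, got_n) != (plant.num_p, plant.num_n):
            raise RuntimeError(
                f"plant {plant.name!r}: realized counts ({got_p},{got_n}) != "
                f"target ({plant.num_p},{plant.num_n}) — accidental match or failed graft")


# Generic background patterns so a planted-fragment scheme has non-alert
# bits too (rings, common functional groups).
_BACKGROUND_SMARTS = [
    "c1ccccc1", "[OX2H]", "[NX3;H2,H1;!$(NC=O)]", "C(=O)[NX3]", "C(=O)[OX2H1]",
    "F", "Cl", "[#7r6]", "[#8r6]", "[CX4H3]", "[sX2r5]", "C=C",
]


def plant_scheme(plants: Sequence[PlantSpec], name: str = "PLANTS") -> DictionaryProvider:
    """Ad-hoc dictionary fingerprint whose first bits are the plant queries.

    Bit i < len(plants) is plants[i]; background bits follow. Useful for
    mining studies where the candidate dictionary must contain the planted
    fragments.
    """
    smarts = [p.smarts for p in plants] + _BACKGROUND_SMARTS
    return make_dictionary_provider(name, smarts)


def paperlike_fixture(seed: int = 0) -> tuple[LabeledDataset, GeneratorConfig]:
    """A 148+450 two-class set mirroring the study's statistical shape.

    Three fragments planted at PR 1.0 (support 14), 0.9 (support 20) and
    0.78 (support 18 -> counts 14/4), plus a decoy at PR 0.5 (support 20),
    with a mild positive-class H-bond-donor excess.
    """
    config = GeneratorConfig(
        n_pos=148,
        n_neg=450,
        plants=(
            PlantSpec("phenothiazine", *PLANT_LIBRARY["phenothiazine"], 1.0, 14),
            PlantSpec("nitrofuran", *PLANT_LIBRARY["nitrofuran"], 0.9, 20),
            PlantSpec("thioamide", *PLANT_LIBRARY["thioamide"], 0.78, 18),
            PlantSpec("isoxazole", *PLANT_LIBRARY["isoxazole"], 0.5, 20),
        ),
        donor_shift=0.15,
        seed=seed,
    )
    return generate(config), config
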