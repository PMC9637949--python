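# Methods

This note records what the package computes, the defaults it ships, the
choices that were genuinely open, and what its tests do and do not
demonstrate.

## Endpoint and data model

The endpoint is binary: label 1 for structures reported to induce autoimmune
disease in humans, 0 for structures with good evidence of not doing so. A
dataset is an ordered list of `(id, canonical SMILES, label, source)`
records; class sizes of the reference collection are 148 positives and 450
negatives (598 total), split 115/125 into training and 33/325 into
validation. Because 0.80 × 148 rounds to 118, not 115, the split interface
accepts explicit per-class counts in addition to fractions; the published
partition is reproduced with counts (115, 125).

## Structure standardization

Applied in order: (1) reduce multi-fragment inputs to the largest organic
fragment — most heavy atoms, ties by molecular weight, then lexicographically
smallest canonical SMILES; fragments containing carbon are preferred over
carbon-free ones regardless of size; (2) neutralize to the parent form with
RDKit's uncharger; (3) reject carbon-free structures as `inorganic` and
structures with a covalent carbon–metal bond as `organometallic`, where a
metal is any element outside {H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I} —
ionic metal counter-ions never trigger this because fragment reduction
removes them first; (4) emit RDKit canonical SMILES. The operation is
idempotent on accepted output (tested), and accepted + rejected counts always
equal the input count. Duplicates (same canonical SMILES) collapse to the
first occurrence; duplicates with conflicting labels are removed entirely
and reported, since keeping either label would inject class noise. Tautomer
canonicalization and stereochemistry repair are out of scope.

## Fingerprints

Seven schemes with fixed widths: Estate 79, FP 1024, ExtendFP 1024,
KRFP 4860, MACCS 166, PubChem 881, SubFP 307. All emit presence/absence
bits only. The module separates the *scheme* (name, width, kind) from the
*provider* (the backend that computes it):

* **MACCS** — RDKit's MACCS keys (bits 1–166); the SMARTS registry mirrors
  RDKit's key definitions. A few composite keys (ring/fragment counting)
  have no single-SMARTS definition and report no pattern.
* **Estate** — the 79 electrotopological-state atom types from RDKit.
* **SubFP** — the 307 functional-group SMARTS shipped with OpenBabel,
  located in the environment at run time. One published pattern uses a
  multi-component query outside the matcher's SMARTS subset; that bit stays
  0 and reports no pattern (listed on the provider as `unmatchable`).
* **FP / ExtendFP** — hashed 1024-bit RDKit path and Morgan (radius 2)
  fingerprints. Hashed bits are implementation-defined across toolkits;
  these are declared equivalents of the CDK path schemes, not bit-exact
  reproductions, and they expose no bit patterns.
* **KRFP / PubChem** — dictionary schemes whose published definitions are
  not redistributable with this package. They are definition-gated: supply
  an `index<TAB>SMARTS` registry via `register_bit_definitions`, otherwise
  any attempt to compute them raises `UnsupportedSchemeError` (never a
  silent zero vector). Widths of supplied registries are checked exactly.

Aromaticity is RDKit's default perception, applied at parse time and
recorded in matrix metadata. Matrices cache to disk as compressed
column-sparse files keyed by (dataset content, scheme, provider) with a JSON
sidecar.

Dictionary-bit semantics — bit set iff the structure matches the bit's
pattern at least its threshold count — are property-tested against
independent substructure matching. Monotonicity under superstructure
(fragment bits never turn off when atoms are added) is asserted only for
bits whose SMARTS is a plain substructure claim; patterns with H-count,
degree, charge or negation specs describe an atom's environment, which
substitution legitimately changes, so they carry no monotonicity guarantee.

## Classifier benchmark

Five algorithms, as scikit-learn estimators:

| name | estimator | fixed defaults |
|------|-----------|----------------|
| SVM | RBF-kernel SVC | C, γ grid-searched |
| NB | Bernoulli naive Bayes | add-one smoothing |
| kNN | k-nearest neighbours, Jaccard (= 1 − Tanimoto) distance | k grid-searched; score = positive-neighbour fraction |
| DT | CART decision tree | minimum leaf 2 |
| RF | random forest | 100 trees, √d features per split |

The SVM grid is C ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³ in powers-of-4 steps (the
canonical grid for RBF-kernel SVM libraries); k runs over odd 1–21.
Selection maximizes mean 5-fold CV accuracy; ties break toward the less
complex model (smaller C, then smaller γ; larger k). Tree, forest and
naive-Bayes run with the fixed defaults above, declared in the model
config.

Cross-validation is stratified 5-fold with a seeded shuffle. Out-of-fold
predictions and decision scores are **pooled** and scored once — a single
confusion matrix per model rather than per-fold averaging. Pooling was an
open choice; it is stable at 240 training records and makes one well-defined
ACC/SE/SP/MCC per model. ROC uses the signed SVM margin where available and
the positive-class probability otherwise; AUC is the trapezoid area, which
equals the pairwise-concordance (rank-sum) formulation — asserted to 1e−12
in tests. MCC with a zero denominator is reported as 0 with a degeneracy
flag. All stochastic components (fold shuffle, forest bootstrap) consume one
named seed.

## Molecular properties and chemical space

Eight properties per structure: MW (g/mol), MPSA (topological polar surface
area, Å²), AlogP (Crippen atom contributions), LogS (ESOL regression:
0.16 − 0.63·clogP − 0.0062·MW + 0.066·nRotB − 0.74·AP, AP = aromatic
fraction of heavy atoms), nHAcc, nHDon, nRotB, nAR. These are
open-implementation analogues of the conventional descriptors; absolute
values differ slightly from other descriptor software, which matters for
reproducing published absolute medians but not for ordinal class
comparison. The LogS method is a configurable provider choice, recorded
here because no single method is canonical.

Classes are summarized as median (P25, P75) with linear-interpolation
quartiles and compared by the two-sided Wilcoxon rank-sum test: exact null
distribution when both groups have ≤ 25 observations and no ties, normal
approximation with tie and continuity correction otherwise. A property
constant across the pooled sample reports p = 1 with a degenerate flag.
Significance is p < 0.05. The implementation is property-tested against an
exact enumeration oracle over all label assignments for small groups.

The chemical space is a 2-component PCA of the z-scored property table
(correlation-matrix PCA — the properties mix units). Sign convention: the
largest-magnitude loading of each component is made positive, so scores are
reproducible. Constant columns carry no variance and are zeroed after
scaling.

## Structural-alert mining

Candidate fragments are the bits of a dictionary scheme. Per bit: `num_p`
and `num_n` (exact occurrence counts per class), support = num_p + num_n,
positive rate PR = num_p/support, and the binary-feature f-score in the
closed form given in the README, with Bessel-corrected within-class scatter.
The closed form equals the generic two-class f-score evaluated on the
expanded 0/1 vectors (property-tested to 1e−12). A fragment constant within
both classes has zero scatter and scores 0.

Mining keeps bits with support ≥ 6, then f-score ≥ 0.018 **and** PR ≥ 0.75;
all thresholds are inclusive, matching reference rows that sit exactly at
support 6, PR 0.75 and f-score 0.019. Mining operates on the full labeled
set, not the training split: recomputing the reference table's printed
f-scores from its counts works only with N⁺ = 148, N⁻ = 450, which pins the
scope. Bits with identical occurrence columns collapse to the lowest index;
output is ordered by descending PR, then f-score, then bit. Screening
re-matches each alert's SMARTS and reports matched atom indices; mining
consistency (mined counts == re-matched counts) is asserted in tests.

## Synthetic data

The generator assembles molecules from ~20 hand-written drug-like scaffold
templates (arylamides, sulfonylureas-like cores, piperazines, azaindoles,
phthalimides, β-blocker-like ethers, …) with 1–3 substitution slots filled
from a decorator pool. Plants — distinctive fragments such as phenothiazine,
5-nitrofuran, thioamide, sulfonohydrazide, isoxazole — are grafted onto a
seeded, deterministic selection of molecules so that num_p = round(PR ×
support) positives and the remaining negatives carry the fragment; realized
counts are verified by substructure matching after generation and any
accidental match raises. Scaffolds and decorators are chosen (and checked
exhaustively in tests) never to produce a plant motif by accident. A
`donor_shift` parameter biases hydroxyl/amine decorators into the positive
class to emulate the published H-bond-donor excess among positives.

The study-shaped fixture is 148 + 450 structures with plants at PR 1.0
(support 14), 0.9 (support 20) and 0.78 (support 18), plus a decoy planted
evenly (PR 0.5, support 20), generated deterministically from a seed rather
than shipped as a file.

What the generator does **not** emulate: real pharmacology, scaffold
diversity of marketed drugs, correlated property distributions, or the
KRFP-scale dictionary (planted-fragment studies use a compact ad-hoc
dictionary containing the plant queries plus background patterns). Passing
tests therefore demonstrate that the statistics, mining logic and pipeline
plumbing are correct — not that any particular accuracy is attainable on
real DIAD data. Conversely, the published absolute benchmark and property
medians require the original drug structures (and, for full mining
fidelity, the Klekota-Roth registry); `scripts/repro_full_study.py` runs
that computation when those inputs are supplied.

## Problem sizes in routine runs

Default test and validation runs use 100–598-molecule synthetic sets, 16-bit
planted dictionaries, and 5-fold CV on ≤ 240 records — sizes at which every
result in the suite is recomputed from scratch in seconds while exercising
the same code paths as a full study.

## Known limitations

* KRFP and PubChem bits compute only with user-supplied registries; hashed
  FP/ExtendFP bits are not comparable across toolkits.
* Descriptor values are RDKit-based analogues; published absolute medians
  from other descriptor software will differ slightly.
* No applicability-domain estimate accompanies predictions.
* Alert patterns mined from a limited chemical space do not generalize
  beyond it; screening hits are alerts, not verdicts.
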