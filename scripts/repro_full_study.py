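#!/usr/bin/env python
"""End-to-end study reproduction recipe, for when the real compound list is
available.

The original 598-drug DIAD dataset (148 positives / 450 negatives) is
distributed as supplementary material of its study and is not bundled here.
Given that list as a CSV (columns id, smiles, label) this script runs the
full workflow: standardization and deduplication, the 115/125 stratified
split, the fingerprint x algorithm benchmark with 5-fold cross-validation
and validation-set scoring, the eight-property class comparison, and
structural-alert mining at the published thresholds (support >= 6,
f-score >= 0.018, PR >= 0.75).

Mining at full fidelity additionally needs the Klekota-Roth bit-definition
registry (4860 SMARTS, not redistributable here); pass it with --krfp and
the script will register it, otherwise mining falls back to MACCS keys.

Usage:
    python scripts/repro_full_study.py --in sm1.csv --out-dir results/full \
        [--krfp krfp_smarts.tsv] [--seed 0]
"""

from __future__ import annotations

import argparse
from pathlib import Path

from diadtox import chemio, descriptors, fingerprints, models
from diadtox.alerts import mine_alerts
from diadtox.models import DiadClassifier, evaluate


def main(argv=None) -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in", dest="in_path", required=True, type=Path)
    parser.add_argument("--out-dir", required=True, type=Path)
    parser.add_argument("--krfp", type=Path, default=None,
                        help="Klekota-Roth bit-definition file (index<TAB>SMARTS)")
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--tune", action="store_true",
                        help="grid-search SVM/kNN hyperparameters (slow)")
    args = parser.parse_args(argv)
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    dataset, rejects = chemio.read_dataset(args.in_path)
    std, std_rej = chemio.standardize_dataset(dataset)
    clean, dup_rej = chemio.deduplicate(std)
    chemio.write_rejects(rejects + std_rej + dup_rej, out / "rejects.csv")
    print(f"standardized {len(clean)} structures "
          f"({clean.n_pos} positive / {clean.n_neg} negative)")

    train, valid = chemio.split_dataset(clean, chemio.SplitSpec(115, 125,
                                                               seed=args.seed))
    train.write_csv(out / "train.csv")
    valid.write_csv(out / "valid.csv")

    schemes = ["MACCS", "Estate", "SubFP", "FP", "ExtendFP"]
    if args.krfp is not None:
        fingerprints.register_bit_definitions("KRFP", args.krfp)
        schemes.append("KRFP")

    table = models.benchmark_grid(train, schemes, models.ALGORITHMS,
                                  seed=args.seed, tune=args.tune)
    table.to_csv(out / "benchmark_cv.csv", index=False)
    best = models.select_best(table)
    print(f"best CV model: {best}")

    scheme, algo = best.rsplit("_", 1)
    clf = DiadClassifier(scheme=scheme, algorithm=algo, tune=args.tune,
                         seed=args.seed)
    clf.fit(train.smiles(), train.labels())
    bits_valid = clf.transformer_.transform(valid.smiles())
    report = evaluate(clf.model_, bits_valid, valid.labels())
    (out / "validation_metrics.txt").write_text(str(report.as_row()))
    print(f"validation: {report.as_row()}")

    props = descriptors.PropertyCalculator().fit_transform(clean.smiles())
    comps = descriptors.compare_groups(props, clean.labels())
    descriptors.comparison_frame(comps).to_csv(out / "property_comparison.csv",
                                               index=False)

    mine_scheme = "KRFP" if args.krfp is not None else "MACCS"
    fpm = fingerprints.featurize_dataset(clean, mine_scheme)
    alerts = mine_alerts(fpm, clean.labels())
    alerts.save(out / "alerts.tsv")
    print(f"mined {len(alerts)} alerts from {mine_scheme} "
          f"({sum(1 for a in alerts if a.num_n == 0)} positive-only)")


if __name__ == "__main__":
    main()
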