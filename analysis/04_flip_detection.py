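#!/usr/bin/env python
"""Select candidate genes by PCA over the skew matrix and test for flips.

Genes are ranked by |loading| on the principal component of the pairs x genes
skew matrix that best separates control from knockdown pairs; the top 500 are
Welch-tested (control vs knockdown skews, BH-adjusted) and classified as
anti-correlated (flipped side), lost, retained or not significant. Calls are
benchmarked against the simulation's ground truth.
"""

import pathlib

import pandas as pd

from halfcell import flips as hflips
from halfcell import io as hio
from halfcell import skew as hskew

SIM = pathlib.Path("results/simulated")
OUT = pathlib.Path("results")


def main() -> None:
    sheet = hio.read_sample_sheet(SIM / "sample_sheet.tsv")
    files = {sid: SIM / f"{sid}.abundance.tsv" for sid in sheet["sample_id"]}
    matrix = hio.assemble_matrix(files, sheet)
    truth = pd.read_csv(SIM / "ground_truth.tsv", sep="\t", index_col=0)

    adjusted = hskew.log1_adjust(matrix)
    report = hskew.filter_genes(matrix, adjusted)
    adj = hskew.AdjustedMatrix(
        adjusted.values.loc[report.index[report["retained"]]], adjusted.offsets
    )
    skew = hskew.compute_skew(adj, sheet)

    candidates = hflips.select_candidates(skew, k=500)
    results = hflips.test_candidates(candidates, skew)
    hio.write_table(results, OUT / "flip_results.tsv")

    counts = results["class"].value_counts()
    print(f"selection component: PC{candidates.component} "
          f"(condition |t| = {abs(candidates.condition_t):.1f})")
    print(f"of {len(results)} candidates tested:")
    for name in ("anti_correlated", "lost", "retained", "not_significant"):
        print(f"  {name:16s} {int(counts.get(name, 0))}")

    called = set(results.index[results["class"] == "anti_correlated"])
    true_flip = set(truth.index[truth["kd_class"] == "flipped"])
    tp = len(called & true_flip)
    print(f"\nagainst ground truth ({len(true_flip)} truly flipped genes):")
    print(f"  sensitivity {tp / len(true_flip):.3f}   "
          f"false-discovery proportion "
          f"{(len(called) - tp) / max(len(called), 1):.3f}")


if __name__ == "__main__":
    main()
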