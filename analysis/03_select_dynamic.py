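#!/usr/bin/env python
"""Shape-based selection of candidate regulated profiles.

Applies the localization-confidence filter (mean probability >= 0.75),
the 10-of-15 quantification rule, cubic polynomial fitting with the
strict R^2 > 0.9 criterion, and the protein-abundance drift exclusion
(max |log2FC| > 1), then writes the per-profile decision table to
results/selection/.
"""

from phosphodyn.io import localization_filter, read_protein_quant, read_site_table, \
    write_results
from phosphodyn.selection import abundance_exclusion, select_candidates

IN = "results/simulated"
OUT = "results/selection"


def main() -> None:
    matrix = read_site_table(f"{IN}/profiles.tsv", dialect="simple")
    matrix = localization_filter(matrix, 0.75)
    tracks = read_protein_quant(f"{IN}/protein_quant.tsv")

    result = select_candidates(matrix, r2_threshold=0.9, degree=3, min_obs=10)
    n_quality = int(result.table["passed_quality"].sum())
    n_r2 = int(result.table["candidate"].sum())
    result = abundance_exclusion(result, tracks, max_abs_log2fc=1.0)
    n_final = int(result.table["candidate"].sum())

    write_results({"selection": result.table}, OUT)

    reasons = result.table["exclusion_reason"].value_counts()
    print(f"{len(result.table)} profiles after localization filter")
    print(f"{n_quality} pass the 10-of-15 quantification rule")
    print(f"{n_r2} pass R^2 > 0.9; {n_r2 - n_final} removed for protein drift")
    print(f"exclusion reasons:\n{reasons.to_string()}")


if __name__ == "__main__":
    main()
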