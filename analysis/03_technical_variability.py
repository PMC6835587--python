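"""Step 3 — technical (analysis) variability from the sILC spike-ins.

Computes the per-sILC coefficient of variation over all included samples
and the median absolute variation at the most extreme condition of each
storage series, then derives the 1 +/- MAV analysis-variability bands the
stability classifier uses.  Writes qc_table.csv and variability_bands.csv.
"""

import dims_stability as ds
from study import RESULTS, load_annotated


def main() -> None:
    library, design, annotated = load_annotated()
    table = ds.silc_qc_table(annotated, design, library)
    bands = ds.variability_bands(table)
    table.to_csv(RESULTS / "qc_table.csv", float_format="%.10g")
    bands.to_csv(RESULTS / "variability_bands.csv", float_format="%.10g")

    print(f"median sILC CV: {table.loc['median', 'cv']:.3f}")
    for series, row in bands.iterrows():
        print(f"  {series:<12s} MAV {row['mav']:.3f} -> band "
              f"{row['band_low']:.3f} - {row['band_high']:.3f}")


if __name__ == "__main__":
    main()
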