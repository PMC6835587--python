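"""Step 1 — simulate the storage-stability study.

Generates the fixture mass library (neurometabolic panel + 17 sILC
channels + unnamed fillers), the 3-pool x 23-sample x 3-replicate design
with four excluded infusions, and the long peak table with injected
storage effects and lognormal technical noise.  Writes library.tsv,
design.tsv and peaks.csv under results/study/.
"""

import argparse
import json

import dims_stability as ds
from study import RESULTS, TRUE_DRIFTS, build_study


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    library, design, effects = build_study(args.seed)
    issues = ds.validate_inputs(library, design)
    assert issues == [], issues

    peaks = ds.simulate_peak_tables(library, design, effects)
    RESULTS.mkdir(parents=True, exist_ok=True)
    library.to_tsv(RESULTS / "library.tsv")
    design.to_tsv(RESULTS / "design.tsv")
    peaks.to_csv(RESULTS / "peaks.csv", index=False, float_format="%.10g")
    (RESULTS / "true_effects.json").write_text(
        json.dumps(TRUE_DRIFTS, indent=1, sort_keys=True)
    )

    base = design.base_samples()
    print(f"library: {len(library)} entries "
          f"({len(library.panel_names)} panel, {len(library.silc_names)} sILC)")
    print(f"design: {len(base)} samples "
          f"({int(base['excluded'].sum())} excluded), "
          f"{len(design.samples)} infusions")
    print(f"peaks: {len(peaks)} rows -> {RESULTS / 'peaks.csv'}")
    print(f"injected storage effects on {len(TRUE_DRIFTS)} metabolites")


if __name__ == "__main__":
    main()
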