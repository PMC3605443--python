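"""Fit the alpha-vs-fat-fraction calibration and derive grade cutoffs.

Reads the cohort produced by 01_simulate_cohort.py (or regenerates it),
fits the one-parameter model alpha = k f / (k f + 1 - f) to the patients'
(HIS-MORPH, alpha) pairs, fits the HIS-MORPH ~ HIS-VIS regression line, and
translates the 5 / 33 / 66 % visual grade boundaries into morphometric
fractions.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

import steatopipe as sp


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", default="results")
    ap.add_argument("--cohort", default=None, help="cohort CSV (default: <out-dir>/cohort.csv)")
    args = ap.parse_args()

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_path = Path(args.cohort) if args.cohort else out / "cohort.csv"
    if cohort_path.exists():
        df = pd.read_csv(cohort_path)
    else:
        df = sp.cohort_to_frame(sp.generate_cohort(seed=args.seed))
    pat = df[df.group == "patient"]

    model = sp.fit_k(pat.alpha, pat.his_morph_frac)
    model.to_json(out / "calibration.json")
    link = sp.fit_linear_link(pat.his_vis_pct, pat.his_morph_frac)
    cutoffs = sp.derive_morph_cutoffs(link)
    pd.DataFrame(
        {"vis_cutoff_pct": [5.0, 33.0, 66.0], "morph_cutoff_frac": cutoffs}
    ).to_csv(out / "morph_cutoffs.csv", index=False)

    print(f"calibration constant k = {model.k:.3f} (r^2 = {model.r_squared:.3f}, n = {model.n})")
    print(f"HIS-MORPH ~ HIS-VIS: slope {link.slope:.5f}/%, intercept {link.intercept:.4f} "
          f"(r^2 = {link.r_squared:.3f})")
    print("morphometric grade cutoffs:",
          ", ".join(f"{v:.1f}% -> {c:.4f}" for v, c in zip((5, 33, 66), cutoffs)))
    print(f"wrote {out / 'calibration.json'} and {out / 'morph_cutoffs.csv'}")


if __name__ == "__main__":
    main()
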