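"""Demonstrate the alpha estimator on simulated triple-echo signals.

Two experiments on the ROI signal model:

1. with T1 weighting switched off (90-degree flip, long TR), the
   T2*-corrected estimator recovers the fat proton fraction exactly,
   independent of the simulated decay rate;
2. with the protocol's deliberate T1 weighting (70 degrees, TR 88 ms),
   alpha overshoots the true fraction — the sensitivity enhancement the
   calibration constant k captures.
"""

import argparse
import json
from pathlib import Path

import numpy as np

import steatopipe as sp


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fracs = np.arange(0.0, 0.46, 0.05)
    worst = 0.0
    for f in fracs:
        for t2 in (5.0, 12.0, 20.0, 40.0):
            p = sp.MRISignalParams(flip_angle=90.0, tr=1e9, t2star=t2)
            a = sp.alpha_from_slices([sp.simulate_roi_signals(float(f), p)]).alpha
            worst = max(worst, abs(a - f))
    print(f"no-T1-weighting round trip: max |alpha - f| = {worst:.2e} "
          f"over f in [0, 0.45], T2* in [5, 40] ms")

    p = sp.MRISignalParams()  # protocol defaults
    k_eff = p.weight_ratio
    rows = []
    for f in fracs[1:]:
        a = sp.alpha_from_slices([sp.simulate_roi_signals(float(f), p)]).alpha
        rows.append((float(f), float(a)))
    print(f"T1-weighted protocol: per-proton fat/water weight ratio k = {k_eff:.3f}")
    for f, a in rows[:4]:
        print(f"  f = {f:.2f} -> alpha = {a:.3f} (model predicts "
              f"{sp.alpha_model(f, k_eff):.3f})")

    payload = {
        "roundtrip_max_abs_error": worst,
        "protocol_weight_ratio_k": k_eff,
        "alpha_vs_fraction": rows,
    }
    (out / "signal_roundtrip.json").write_text(json.dumps(payload, indent=2))
    print(f"wrote {out / 'signal_roundtrip.json'}")


if __name__ == "__main__":
    main()
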