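"""qPCR pipeline on synthetic dilution series and samples.

Generates a standard curve and per-condition duplicate Ct values from true
hydrogenotrophic-marker abundances that rise with pH by the fold changes
seen in the study (1.8x at 0.1 eq/L, 5.7x at 0.6 eq/L, 9.3x at 1.2 eq/L),
then recovers calibration, copy numbers and fold changes end to end.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from methalk.qpcr_quant import AbundancePair, calibrate, copies_from_ct, fold_change
from methalk.synthetic_data import SyntheticConfig, simulate_qpcr

#: true hydrogenotrophic relative-abundance trajectories per alkalinity group
TRUE_TRAJECTORIES = {
    0.1: {(0.1, 8.4): 0.30, (0.1, 9.2): 0.40, (0.1, 10.35): 0.54},
    0.6: {(0.6, 8.4): 0.10, (0.6, 9.2): 0.30, (0.6, 10.0): 0.57},
    1.2: {(1.2, 8.26): 0.06, (1.2, 9.1): 0.40, (1.2, 9.68): 0.558},
}


def recovered_fold(alk: float, seed: int) -> tuple[float, float]:
    truth = TRUE_TRAJECTORIES[alk]
    series, samples = simulate_qpcr(SyntheticConfig(seed=seed, qpcr_truth=truth))
    cal = calibrate(series)
    pairs = [
        AbundancePair(
            copies_from_ct(np.mean(s["hydrogenotrophic"]), cal),
            copies_from_ct(np.mean(s["acetoclastic"]), cal),
        )
        for s in sorted(samples, key=lambda s: s["condition"][1])
    ]
    fracs = sorted(truth.values())
    true_fold = (fracs[-1] * 100) / (fracs[0] * 100)
    return fold_change(pairs), true_fold


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-seeds", type=int, default=25)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    series, _ = simulate_qpcr(SyntheticConfig(seed=args.seed, qpcr_truth=TRUE_TRAJECTORIES[0.6]))
    cal = calibrate(series)
    print(f"standard curve: slope {cal.slope:.3f}, intercept {cal.intercept:.2f}, "
          f"R2 {cal.r_squared:.4f}, efficiency {cal.efficiency:.1%}")

    rows = []
    for alk in sorted(TRUE_TRAJECTORIES):
        folds = [recovered_fold(alk, args.seed + k)[0] for k in range(args.n_seeds)]
        _, truth = recovered_fold(alk, args.seed)
        rows.append(
            {
                "alkalinity": alk,
                "true_fold": truth,
                "recovered_fold_mean": np.mean(folds),
                "recovered_fold_sd": np.std(folds),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(args.out_dir / "qpcr_fold_changes.csv", index=False)
    print(df.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
    print("\nthe hydrogenotrophic marker's rise with pH steepens with alkalinity,")
    print("and the two-target pipeline recovers each group's fold change.")


if __name__ == "__main__":
    main()
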