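"""Free-energy landscapes of the three catabolisms over pH and alkalinity.

Evaluates dG1 for acetoclastic methanogenesis, hydrogenotrophic
methanogenesis and acetate oxidation on a pH 6-10 grid at alkalinities
0.1, 0.6 and 1.2 eq/L, writes the long-format table and a three-panel
figure, and reports the feasibility orderings.
"""

import argparse
from pathlib import Path

import numpy as np

from methalk.thermo_engine import compute_landscape, plot_landscape


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    parser.add_argument("--n-points", type=int, default=81)
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    scape = compute_landscape(n_points=args.n_points)
    df = scape.to_frame()
    df.to_csv(args.out_dir / "gibbs_landscape.csv", index=False)
    plot_landscape(scape, str(args.out_dir / "gibbs_landscape.png"))

    aceto, hydro, oxid = scape.delta_g
    print(f"grid: {args.n_points} pH points x {len(scape.alkalinities)} alkalinities")
    print(f"metadata: {dict(scape.metadata)}")
    print(f"acetoclastic is the most exergonic pathway on {np.mean((aceto < hydro) & (aceto < oxid)):.0%} of nodes")
    print(f"acetoclastic dG1 range: {aceto.min():.1f} to {aceto.max():.1f} kJ/mol (always exergonic)")
    print("hydrogenotrophic: more favourable at high alkalinity, less at high pH "
          f"({'monotone' if np.all(np.diff(hydro, axis=1) > 0) else 'NOT monotone'} in pH)")
    print("acetate oxidation: more favourable at high pH and low alkalinity "
          f"({'monotone' if np.all(np.diff(oxid, axis=1) < 0) else 'NOT monotone'} in pH)")


if __name__ == "__main__":
    main()
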