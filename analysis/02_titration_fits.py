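"""Four-parameter logistic fits of single-inducer titration slices.

For each system, the P titration at saturating I and the I titration at
saturating P are fitted; EC50, Hill coefficient, EC10/EC90 and the dynamic
range of ligand response (DRLR = EC90/EC10) are tabulated to
results/titration_fits.csv. Small DRLR = digital switch, large = analogue
rheostat.
"""

import pandas as pd

from common import RESULTS, SYSTEMS, matrix_path
from gatefit import fit_four_pl, slice_matrix
from gatefit import io as gio


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for name in SYSTEMS:
        m = gio.read_matrix(matrix_path(name), dialect="long")
        for axis, co_levels in (("P", m.i_levels), ("I", m.p_levels)):
            fit = fit_four_pl(slice_matrix(m, axis, float(co_levels[-1])))
            if not fit.converged:
                print(f"{name} {axis}-titration: no fit ({'; '.join(fit.warnings)})")
                rows.append({"system": name, "axis": axis, "converged": False})
                continue
            rows.append(
                {
                    "system": name,
                    "axis": axis,
                    "converged": True,
                    "ec50_uM": fit.params.ec50,
                    "hill_n": fit.params.n,
                    "ec10_uM": fit.ec10,
                    "ec90_uM": fit.ec90,
                    "drlr": fit.drlr,
                    "basal": fit.params.y0,
                    "max": fit.params.ymax,
                }
            )
            kind = "digital" if fit.drlr < 20 else "analogue"
            print(
                f"{name} {axis}-titration: EC50 {fit.params.ec50:7.1f} uM, "
                f"n {fit.params.n:5.2f}, DRLR {fit.drlr:6.1f} ({kind})"
            )
    df = pd.DataFrame(rows)
    out = RESULTS / "titration_fits.csv"
    df.to_csv(out, index=False)
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
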