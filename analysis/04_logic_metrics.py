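"""Boolean-logic classification and induction summaries per system.

Corner outputs are digitized at the 10% threshold (D-OUT), the analogue
synergy ratio A-OUT is computed, and matrix-wide fold induction and basal
fractions are tabulated against the transcription-only reference system.
Table: results/logic_summary.csv.
"""

import numpy as np
import pandas as pd

from common import RESULTS, SYSTEMS, matrix_path
from gatefit import CornerOutputs, induction_summary, truth_table
from gatefit import io as gio


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    matrices = {
        name: gio.read_matrix(matrix_path(name), dialect="long") for name in SYSTEMS
    }
    reference = matrices["single-single"]  # transcription-only benchmark
    rows = []
    for name, m in matrices.items():
        tt = truth_table(CornerOutputs.from_matrix(m), threshold=0.10)
        summ = induction_summary(m, reference=reference)
        rows.append(
            {
                "system": name,
                "gate_label": tt.gate_label,
                "d_out": "".join(str(int(b)) for b in tt.d_out),
                "a_out": tt.a_out,
                "fold_induction": summ.fold_induction,
                "basal_pct_of_max": summ.basal_fraction,
                "pct_max_vs_reference": summ.percent_max_vs_reference,
                "basal_fold_decrease_vs_reference":
                    summ.basal_fold_decrease_vs_reference,
            }
        )
        a_txt = "inf" if np.isinf(tt.a_out) else f"{tt.a_out:.2f}"
        print(
            f"{name}: gate={tt.gate_label:13s} D-OUT={rows[-1]['d_out']} "
            f"A-OUT={a_txt:>5s}  fold-induction={summ.fold_induction:7.1f}  "
            f"basal={summ.basal_fraction:.2f}% of max"
        )
    df = pd.DataFrame(rows)
    out = RESULTS / "logic_summary.csv"
    df.to_csv(out, index=False)
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
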