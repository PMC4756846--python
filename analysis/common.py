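"""Shared scenario definitions for the numbered analysis drivers.

Three synthetic expression systems spanning the design space of a
two-inducer (I = transcriptional, P = translational) cascade:

* ``dual-dual`` — riboswitch control on both the polymerase and the target
  gene: tight basal level, 12-fold dual-induction enhancement (f1 = 1/12),
  analogue P response, K2 = 66 uM.
* ``dual-single`` — riboswitch on the polymerase only: 3-fold enhancement.
* ``single-single`` — transcription-only control: P-independent (f1 = 1),
  leaky basal, steep digital I response (n ~ 1.9, DRLR ~ 10).
"""

from pathlib import Path

from gatefit import ANDGateParams

ROOT = Path(__file__).resolve().parent.parent
INPUTS = ROOT / "scratch" / "inputs"
RESULTS = ROOT / "results"

SEED = 20150923

SYSTEMS = {
    "dual-dual": ANDGateParams(
        y0=10.0, dy=10000.0, n=1.0, k1=120.0, k2=66.0, f1=1.0 / 12.0
    ),
    "dual-single": ANDGateParams(
        y0=25.0, dy=14000.0, n=1.0, k1=100.0, k2=40.0, f1=1.0 / 3.0
    ),
    "single-single": ANDGateParams(
        y0=220.0, dy=14300.0, n=1.90848, k1=40.0, k2=50.0, f1=1.0
    ),
}

# kinetic scenario: specific expression rates (RFU/OD/h) and growth
RATES = {"dual-dual": 23e3, "dual-single": 60e3, "single-single": 102e3}
MU = {"dual-dual": 0.55, "dual-single": 0.45, "single-single": 0.30}


def matrix_path(name: str) -> Path:
    return INPUTS / f"matrix_{name}.csv"
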