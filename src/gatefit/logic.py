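"""Boolean-logic and induction summary statistics for two-input gates.

Corner responses (neither inducer, each alone, both) are digitized into a
truth table with a threshold cut-off (D-OUT) and summarized by the analogue
synergy ratio A-OUT = dual output over the sum of single-inducer outputs.
Whole-matrix induction summaries (fold induction, basal fraction) and two
simple viability ratios (LDH release, OD-normalized CFU) round out the
reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import ExpressionMatrix

__all__ = [
    "DegenerateGateError",
    "CornerOutputs",
    "TruthTable",
    "InductionSummary",
    "truth_table",
    "a_out",
    "induction_summary",
    "ldh_percent",
    "cfu_normalize",
]


class DegenerateGateError(ValueError):
    """The gate has no dynamic range (dual-induced equals uninduced)."""


@dataclass(frozen=True)
class CornerOutputs:
    """Responses (RFU/OD) at the four corner induction states."""

    uu: float  # neither inducer
    i_only: float
    p_only: float
    ip: float  # both inducers

    def __post_init__(self) -> None:
        vals = (self.uu, self.i_only, self.p_only, self.ip)
        if not np.isfinite(vals).all() or any(v < 0 for v in vals):
            raise ValueError("corner outputs must be finite and >= 0")

    @classmethod
    def from_matrix(cls, m: ExpressionMatrix) -> "CornerOutputs":
        """Corner cell means: requires zero on both axes."""
        if m.i_levels[0] != 0 or m.p_levels[0] != 0:
            raise ValueError("corner extraction requires zero on both axes")
        means = m.cell_means()
        return cls(uu=float(means[0, 0]), i_only=float(means[-1, 0]),
                   p_only=float(means[0, -1]), ip=float(means[-1, -1]))


# canonical two-input truth patterns, states ordered (0,0),(1,0),(0,1),(1,1)
_GATE_LABELS = {
    (False, False, False, True): "AND",
    (False, True, False, True): "I-only",
    (False, False, True, True): "P-only",
    (False, True, True, True): "OR",
    (True, True, True, True): "constitutive",
    (False, False, False, False): "dead",
}


@dataclass(frozen=True)
class TruthTable:
    """Digitized gate logic plus the analogue synergy ratio."""

    threshold: float
    d_out: tuple[bool, bool, bool, bool]  # states (0,0),(1,0),(0,1),(1,1)
    a_out: float
    gate_label: str


def truth_table(
    c: CornerOutputs, threshold: float = 0.10, subtract_basal: bool = True
) -> TruthTable:
    """Digitize corner outputs: a state is ON when its normalized response
    meets ``threshold`` (default 10% of the dual-induced output).

    With ``subtract_basal`` (default) the uninduced response is removed
    before normalizing, so a leaky system is judged on its induced signal;
    without it, raw fractions of the dual-induced output are thresholded.
    """
    span = c.ip - c.uu
    if span <= 0:
        raise DegenerateGateError("ip <= uu: gate has no dynamic range")
    if subtract_basal:
        norm = [(v - c.uu) / span for v in (c.uu, c.i_only, c.p_only, c.ip)]
    else:
        if c.ip <= 0:
            raise DegenerateGateError("ip = 0: cannot normalize")
        norm = [v / c.ip for v in (c.uu, c.i_only, c.p_only, c.ip)]
    d = tuple(v >= threshold for v in norm)
    try:
        synergy = a_out(c, subtract_basal=subtract_basal)
    except DegenerateGateError:
        # strict gate with no single-inducer signal: synergy is unbounded
        synergy = np.inf
    return TruthTable(
        threshold=threshold,
        d_out=d,
        a_out=synergy,
        gate_label=_GATE_LABELS.get(d, "other"),
    )


def a_out(c: CornerOutputs, subtract_basal: bool = True) -> float:
    """Analogue synergy ratio: dual output over the sum of single outputs.

    A value of 1 means the two inducers act additively; values above 1
    quantify the synergistic enhancement of inducing through both layers.
    """
    if subtract_basal:
        denom = (c.i_only - c.uu) + (c.p_only - c.uu)
        num = c.ip - c.uu
    else:
        denom = c.i_only + c.p_only
        num = c.ip
    if denom <= 0:
        raise DegenerateGateError(
            "synergy undefined: single-inducer outputs do not exceed basal"
        )
    return num / denom


@dataclass(frozen=True)
class InductionSummary:
    """Matrix-wide regulatory-control summary."""

    fold_induction: float  # max/basal; inf when basal is zero
    basal_fraction: float  # basal as % of max
    unbounded: bool = False
    percent_max_vs_reference: float | None = None
    basal_fold_decrease_vs_reference: float | None = None


def induction_summary(
    m: ExpressionMatrix, reference: ExpressionMatrix | None = None
) -> InductionSummary:
    """Fold induction (max cell mean / basal cell mean) and basal fraction.

    The maximum is taken over all grid cells, not assumed to be a corner.
    With a ``reference`` matrix, also reports the maximal output as a
    percent of the reference maximum and the fold decrease in basal leak.
    """
    if m.i_levels[0] != 0 or m.p_levels[0] != 0:
        raise ValueError("induction summary requires the (0, 0) cell")
    means = m.cell_means()
    basal = float(means[0, 0])
    mx = float(np.nanmax(means))
    if basal <= 0:
        fold, frac, unbounded = np.inf, 0.0, True
    else:
        fold, frac, unbounded = mx / basal, 100.0 * basal / mx, False
    pct = dec = None
    if reference is not None:
        rmeans = reference.cell_means()
        rmax = float(np.nanmax(rmeans))
        rbasal = float(rmeans[0, 0])
        pct = 100.0 * mx / rmax
        dec = np.inf if basal <= 0 else rbasal / basal
    return InductionSummary(
        fold_induction=fold,
        basal_fraction=frac,
        unbounded=unbounded,
        percent_max_vs_reference=pct,
        basal_fold_decrease_vs_reference=dec,
    )


def ldh_percent(a_media: float, a_lysed: float) -> float:
    """Membrane-leakage viability readout: % LDH activity (A490-630) in
    cell-free media relative to fully (chemically) lysed cells."""
    if a_lysed <= 0:
        raise ValueError("lysed-control absorbance must be positive")
    if a_media < 0:
        raise ValueError("media absorbance must be >= 0")
    return 100.0 * a_media / a_lysed


def cfu_normalize(
    colonies: float, dilution_factor: float, plated_volume_ml: float, od600: float
) -> float:
    """Colony counts scaled to CFU/ml at OD600 = 1.0."""
    if colonies < 0:
        raise ValueError("colony count must be >= 0")
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    if plated_volume_ml <= 0 or od600 <= 0:
        raise ValueError("plated volume and OD600 must be positive")
    return colonies * dilution_factor / plated_volume_ml / od600
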