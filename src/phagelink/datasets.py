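"""Reference measurement sets for the equimolar co-expression experiment.

The numbers are the published plate readouts of the two-phage (wild type
vs single tail-fiber mutant) equimolar cell-free co-expression: titers on
the permissive and restrictive hosts, ReLPS-challenge survivor titers
against the equal-volume control, and the post-amplification titers, all
in PFU/mL with their reported standard deviations.
"""

from __future__ import annotations

from .linkage import CoExpressionMeasurements
from .titer import TiterMeasurement
from .uncertain import UncertainValue

__all__ = ["coexpression_equimolar", "printed_fractions", "mutant_eop_titers"]


def coexpression_equimolar() -> CoExpressionMeasurements:
    """The equimolar co-expression titer set.

    Host mapping: the restrictive-host co-expression titer is 4e8 and the
    permissive-host titer 8e8 PFU/mL — the assignment consistent with the
    reported ~8e8 permissive titer of the co-synthesis and with the
    reported 50% infectious-mutant fraction.
    """
    def tm(host, value, sd):
        return TiterMeasurement(host, UncertainValue(value, sd))

    return CoExpressionMeasurements(
        T_perm_co=tm("permissive", 8e8, 1e8),
        T_restr_co=tm("restrictive", 4e8, 1e8),
        T_relps_co=tm("permissive", 1.9e6, 0.4e6),
        T_relps_ctrl=tm("permissive", 1.7e7, 0.4e7),
        T_amp_perm=tm("permissive", 6e10, 2e10),
        T_amp_restr=tm("restrictive", 2e7, 1e7),
        eop_mut=UncertainValue(0.18, 0.04),
        ctrl_wt_content=0.5,
        genotype_mix=0.5,
    )


def printed_fractions() -> dict[str, UncertainValue]:
    """The three class fractions as printed (rounded) in the study report:
    F1 = 50 +/- 18 %, F2 = 6 +/- 2 %, F3 (mut/WT) = 0.03 +/- 0.02 %."""
    return {
        "F1": UncertainValue(0.50, 0.18),
        "F2": UncertainValue(0.06, 0.02),
        "F3": UncertainValue(3e-4, 2e-4),
    }


def mutant_eop_titers() -> tuple[TiterMeasurement, TiterMeasurement]:
    """Separately synthesized mutant phage titers on the restrictive and
    permissive hosts (EOP reference pair, 5.8e7 / 3.2e8 PFU/mL)."""
    return (
        TiterMeasurement("restrictive", UncertainValue(5.8e7, 0.7e7)),
        TiterMeasurement("permissive", UncertainValue(3.2e8, 0.6e8)),
    )
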