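"""Deconvolution of the six genotype/phenotype classes from titer data.

The equimolar two-phage co-expression experiment yields three measurable
fractions of the particle population:

* ``F1 = mut/MUT + mut/MIX`` — restrictive-host over permissive-host titer
  of the co-expression (only mutant-genotype particles displaying at least
  one mutant fiber plate *and* propagate on the restrictive host);
* ``F2 = wt/WT + mut/WT`` — the ReLPS-challenge survivors (only particles
  displaying exclusively wild-type fibers escape genome ejection), read
  out against an equal-volume control of separately assembled phages;
* ``F3`` — the mut/WT readout: survivors are amplified on the permissive
  host (progeny display reverts to the genotype) and re-titered on both
  hosts.

Two symmetry assumptions close the system: with equimolar genotypes, the
pure-class fraction is the same on both genotype backgrounds (wt/WT =
mut/MUT) and so is the opposing-class fraction (wt/MUT = mut/WT).  Given
(F1, F2, F3) the full six-class table follows, along with the linkage
metrics: the pure fraction (the linkage estimate, full linkage expecting
1), the pure/opposing asymmetry, and the fold over the fully random
assembly model.

:class:`GPLinkageModel` wraps the measurement set; ``fit()`` returns a
:class:`GPLinkageResults` carrying the fractions with propagated
uncertainties, the class table, the metrics and a ``summary()`` table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .fiber import (CLASSES, H0, AssemblyHypothesis, GPClassTable,
                    GPModelParams, gp_class_probs)
from .titer import TiterMeasurement
from .uncertain import UncertainValue, uv, uv_ratio, uv_scale

__all__ = [
    "CoExpressionMeasurements",
    "fraction_mut_infectious",
    "fraction_wt_phenotype",
    "fraction_opposing",
    "solve_gp_table",
    "linkage_metrics",
    "GPLinkageModel",
    "GPLinkageResults",
]


@dataclass
class CoExpressionMeasurements:
    """Titer set of one co-expression/challenge/amplification experiment.

    ``T_perm_co`` / ``T_restr_co``: co-expression titers on the permissive
    and restrictive hosts.  ``T_relps_co`` / ``T_relps_ctrl``: permissive
    titers after the ReLPS challenge of the co-expression and of the
    equal-volume control (separately assembled phages, wild-type content
    ``ctrl_wt_content``).  ``T_amp_perm`` / ``T_amp_restr``: titers after
    amplifying the survivors on the permissive host.  ``eop_mut``: the
    mutant phage's restrictive/permissive efficiency of plating.
    """

    T_perm_co: TiterMeasurement
    T_restr_co: TiterMeasurement
    T_relps_co: TiterMeasurement
    T_relps_ctrl: TiterMeasurement
    T_amp_perm: TiterMeasurement
    T_amp_restr: TiterMeasurement
    eop_mut: Optional[UncertainValue] = None
    ctrl_wt_content: float = 0.5
    genotype_mix: float = 0.5  # mutant-genome fraction of the assembly mix

    def __post_init__(self) -> None:
        if not 0.0 <= self.ctrl_wt_content <= 1.0:
            raise ValueError("ctrl_wt_content must be in [0, 1]")
        if not 0.0 < self.genotype_mix < 1.0:
            raise ValueError("genotype_mix must be in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "CoExpressionMeasurements":
        """Build from a plain mapping: each titer as {value, sd, host}."""
        def tm(key, default_host):
            e = d[key]
            return TiterMeasurement(e.get("host", default_host),
                                    UncertainValue(e["value"], e.get("sd", 0.0)))
        eop_entry = d.get("eop_mut")
        return cls(
            T_perm_co=tm("T_perm_co", "permissive"),
            T_restr_co=tm("T_restr_co", "restrictive"),
            T_relps_co=tm("T_relps_co", "permissive"),
            T_relps_ctrl=tm("T_relps_ctrl", "permissive"),
            T_amp_perm=tm("T_amp_perm", "permissive"),
            T_amp_restr=tm("T_amp_restr", "restrictive"),
            eop_mut=None if eop_entry is None
            else UncertainValue(eop_entry["value"], eop_entry.get("sd", 0.0)),
            ctrl_wt_content=d.get("ctrl_wt_content", 0.5),
            genotype_mix=d.get("genotype_mix", 0.5),
        )

    @classmethod
    def from_json(cls, path) -> "CoExpressionMeasurements":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fraction_mut_infectious(meas: CoExpressionMeasurements,
                            correct_eop: bool = False) -> UncertainValue:
    """F1 = mut/MUT + mut/MIX from the co-expression titer ratio.

    ``correct_eop=True`` divides by the mutant reference EOP; default off —
    the experiment's own ratio is already on the plaque-count scale and
    correcting typically overshoots past the genotype fraction.
    """
    if meas.T_perm_co.titer.value == 0:
        raise ValueError("permissive co-expression titer is zero")
    f1 = uv_ratio(meas.T_restr_co.titer, meas.T_perm_co.titer)
    if correct_eop:
        if meas.eop_mut is None:
            raise ValueError("correct_eop requested but eop_mut not provided")
        f1 = f1 / meas.eop_mut
    if f1.value > meas.genotype_mix + 2 * f1.sd:
        f1 = f1.flagged(f"inconsistent: exceeds genotype mix {meas.genotype_mix}")
    return f1


def fraction_wt_phenotype(meas: CoExpressionMeasurements) -> UncertainValue:
    """F2 = wt/WT + mut/WT from the ReLPS-challenge survivor ratio.

    The equal-volume control contains ``ctrl_wt_content`` wild-type-display
    phages, so the survivor ratio times that content is the co-expression's
    wild-type-display fraction (the challenge survival factor cancels).
    """
    if meas.T_relps_ctrl.titer.value == 0:
        raise ValueError("control challenge titer is zero")
    ratio = uv_ratio(meas.T_relps_co.titer, meas.T_relps_ctrl.titer)
    return uv_scale(ratio, meas.ctrl_wt_content)


def fraction_opposing(meas: CoExpressionMeasurements) -> UncertainValue:
    """F3, the mut/WT readout: post-amplification restrictive/permissive ratio."""
    if meas.T_amp_perm.titer.value == 0:
        raise ValueError("permissive amplification titer is zero")
    return uv_ratio(meas.T_amp_restr.titer, meas.T_amp_perm.titer)


def solve_gp_table(F1: UncertainValue | float | None,
                   F2: UncertainValue | float,
                   F3: UncertainValue | float,
                   genotype_mix: float = 0.5,
                   convention: str = "paper") -> GPClassTable:
    """Solve the six-class table from the three measured fractions.

    Conventions differ in how the F3 readout maps onto the population
    fraction of mut/WT:

    * ``"paper"`` (default): mut/WT = F3 directly — F3 is taken as a
      whole-population fraction;
    * ``"strict"``: mut/WT = F2 * F3 — F3 is read as a fraction of the
      survivor pool that was amplified (both agree when F2 = 1).

    With the symmetry assumptions (general genotype mix ``g``):
    wt/MUT = mut/WT * (1-g)/g, wt/WT = F2 - mut/WT, mut/MUT = wt/WT *
    g/(1-g), MIX classes by complement within each genotype.  If F1 is
    given, the residual |mut/MUT + mut/MIX - F1| is reported in the
    table's metadata as a consistency check.
    """
    g = genotype_mix
    if not 0.0 < g < 1.0:
        raise ValueError("genotype_mix must be in (0, 1)")
    F2, F3 = uv(F2), uv(F3)
    for name, F in (("F2", F2), ("F3", F3)):
        if not 0.0 <= F.value <= 1.0:
            raise ValueError(f"{name} central value outside [0, 1]: {F.value}")
    if convention == "paper":
        mut_wt = F3
    elif convention == "strict":
        mut_wt = F2 * F3
    else:
        raise ValueError(f"unknown convention {convention!r}")
    wt_mut = uv_scale(mut_wt, (1 - g) / g)
    wt_wt = F2 - mut_wt
    mut_mut = uv_scale(wt_wt, g / (1 - g))
    wt_mix = uv(1 - g) - wt_wt - wt_mut
    mut_mix = uv(g) - mut_mut - mut_wt
    fr = {"wt/WT": wt_wt, "wt/MIX": wt_mix, "wt/MUT": wt_mut,
          "mut/WT": mut_wt, "mut/MIX": mut_mix, "mut/MUT": mut_mut}
    negative_within_noise = []
    for cls, val in fr.items():
        if val.value < -(3 * val.sd + 1e-12):
            raise ValueError(f"derived fraction {cls} is negative ({val.value:.3g} "
                             f"+/- {val.sd:.3g}); measurements inconsistent with "
                             "the symmetry assumptions")
        if val.value < 0:
            negative_within_noise.append(cls)
    meta = {"convention": convention, "genotype_mix": g}
    if negative_within_noise:
        meta["negative_within_noise"] = negative_within_noise
    # exact uncertainty propagation for the derived sums: mut/MUT and wt/MUT
    # are deterministic rescalings of wt/WT and mut/WT, so the pure and
    # opposing fractions are scalings too (summing the table entries under
    # independence would understate their sds)
    meta["pure_fraction"] = uv_scale(wt_wt, 1.0 / (1 - g))
    meta["opposing_fraction"] = uv_scale(mut_wt, 1.0 / g)
    if F1 is not None:
        F1 = uv(F1)
        meta["F1"] = F1
        meta["f1_residual"] = abs((mut_mut + mut_mix).value - F1.value)
    table = GPClassTable(fr, metadata=meta)
    table.validate(None)
    return table


def linkage_metrics(table: GPClassTable, hyp: AssemblyHypothesis = H0,
                    f: float = 0.5) -> dict:
    """Linkage summary metrics recomputed from a class table.

    ``pure_fraction`` = wt/WT + mut/MUT; ``lambda_hat`` equals it (full
    linkage would make every particle pure); ``asymmetry`` = pure /
    opposing; ``fold_over_random`` compares the pure fraction with the
    fully random assembly model at the same monomer fraction, and
    ``log10_orders`` is its decimal log.
    """
    table.validate(None)
    # prefer the solver's exactly-propagated sums when available (they track
    # the correlation between derived classes); fall back to independence
    pure = table.metadata.get("pure_fraction", table.pure_fraction)
    opposing = table.metadata.get("opposing_fraction", table.opposing_fraction)
    if opposing.value > 0:
        asymmetry = pure / opposing
    elif opposing.sd > 0 or opposing.is_bound:
        # detection-limited: quote a lower bound at the opposing-limit value
        limit = opposing.value if opposing.is_bound and opposing.value > 0 else opposing.sd
        asymmetry = UncertainValue(pure.value / limit, 0.0, bound="lower",
                                   note="opposing fraction below detection")
    else:
        asymmetry = UncertainValue(math.inf, 0.0, bound="lower",
                                   note="opposing fraction exactly zero")
    random_pure = gp_class_probs(GPModelParams(f, 0.0), hyp.geometry).pure_fraction
    fold = uv_scale(pure, 1.0 / random_pure.value)
    return {
        "pure_fraction": pure,
        "lambda_hat": pure,
        "asymmetry": asymmetry,
        "fold_over_random": fold,
        "log10_orders": math.log10(fold.value) if fold.value > 0 else -math.inf,
    }


class GPLinkageModel:
    """Genotype/phenotype linkage model for one co-expression experiment.

    Parameters
    ----------
    measurements : CoExpressionMeasurements
        The titer set (permissive/restrictive co-expression, ReLPS
        challenge, post-amplification).
    convention : {"paper", "strict"}
        How the F3 readout maps to the mut/WT population fraction.
    correct_eop : bool
        Divide F1 by the mutant reference EOP (default off).
    hypothesis : AssemblyHypothesis
        Infectivity hypothesis used for the random-assembly comparison.
    """

    def __init__(self, measurements: CoExpressionMeasurements,
                 convention: str = "paper", correct_eop: bool = False,
                 hypothesis: AssemblyHypothesis = H0) -> None:
        if convention not in ("paper", "strict"):
            raise ValueError(f"unknown convention {convention!r}")
        self.measurements = measurements
        self.convention = convention
        self.correct_eop = correct_eop
        self.hypothesis = hypothesis

    @classmethod
    def from_json(cls, path, **kwargs) -> "GPLinkageModel":
        return cls(CoExpressionMeasurements.from_json(path), **kwargs)

    def fit(self) -> "GPLinkageResults":
        meas = self.measurements
        F1 = fraction_mut_infectious(meas, correct_eop=self.correct_eop)
        F2 = fraction_wt_phenotype(meas)
        F3 = fraction_opposing(meas)
        table = solve_gp_table(F1, F2, F3, genotype_mix=meas.genotype_mix,
                               convention=self.convention)
        metrics = linkage_metrics(table, self.hypothesis, f=meas.genotype_mix)
        return GPLinkageResults(self, F1, F2, F3, table, metrics)


@dataclass
class GPLinkageResults:
    """Fitted class fractions, table and linkage metrics."""

    model: GPLinkageModel
    F1: UncertainValue
    F2: UncertainValue
    F3: UncertainValue
    table: GPClassTable
    metrics: dict

    @property
    def f1_residual(self) -> float:
        return self.table.metadata.get("f1_residual", math.nan)

    def predicted_random(self) -> GPClassTable:
        """Class table under the fully random assembly model (lam = 0)."""
        return gp_class_probs(GPModelParams(self.model.measurements.genotype_mix, 0.0),
                              self.model.hypothesis.geometry)

    def to_frame(self) -> pd.DataFrame:
        """Measured vs random-predicted class fractions (one row per class)."""
        random = self.predicted_random()
        rows = []
        for cls in CLASSES:
            v = self.table.uncertain(cls)
            rows.append({"class": cls, "measured": v.value, "sd": v.sd,
                         "random_predicted": random.value(cls)})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        m = self.metrics
        return {
            "F1": {"value": self.F1.value, "sd": self.F1.sd},
            "F2": {"value": self.F2.value, "sd": self.F2.sd},
            "F3": {"value": self.F3.value, "sd": self.F3.sd},
            "table": {c: {"value": self.table.uncertain(c).value,
                          "sd": self.table.uncertain(c).sd} for c in CLASSES},
            "metrics": {
                "pure_fraction": m["pure_fraction"].value,
                "lambda_hat": m["lambda_hat"].value,
                "asymmetry": m["asymmetry"].value,
                "fold_over_random": m["fold_over_random"].value,
                "log10_orders": m["log10_orders"],
            },
            "f1_residual": self.f1_residual,
            "convention": self.model.convention,
        }

    def summary(self) -> str:
        m = self.metrics
        lines = [
            "Genotype/phenotype linkage deconvolution",
            "=" * 56,
            f"convention: {self.model.convention:>8}   "
            f"genotype mix: {self.model.measurements.genotype_mix}",
            "-" * 56,
            f"F1 (mut/MUT + mut/MIX) : {self.F1}",
            f"F2 (wt/WT + mut/WT)    : {self.F2}",
            f"F3 (mut/WT readout)    : {self.F3}",
            "-" * 56,
        ]
        random = self.predicted_random()
        lines.append(f"{'class':>8} {'measured':>12} {'sd':>10} {'random':>12}")
        for cls in CLASSES:
            v = self.table.uncertain(cls)
            lines.append(f"{cls:>8} {v.value:>12.4g} {v.sd:>10.2g} "
                         f"{random.value(cls):>12.4g}")
        lines += [
            "-" * 56,
            f"pure fraction (lambda_hat) : {m['lambda_hat']}",
            f"pure/opposing asymmetry    : {m['asymmetry']}",
            f"fold over random assembly  : {m['fold_over_random']}",
            f"orders of magnitude        : {m['log10_orders']:.2f}",
            f"F1 consistency residual    : {self.f1_residual:.3g}",
        ]
        return "\n".join(lines)
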