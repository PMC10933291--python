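"""Combinatorics of tail-fiber monomer incorporation.

A T7-like virion carries six trimeric tail fibers (18 monomers).  When two
genomes — wild type and a single-point tail-fiber mutant — are expressed
together in one batch cell-free reaction, each particle packages one
genotype but may display fibers drawn from the shared monomer pool.  The
joint distribution of (genotype, displayed composition) is modelled as an
all-or-nothing linkage mixture:

* with probability ``lam`` (linkage) every monomer matches the packaged
  genotype (pure self-assembly);
* with probability ``1 - lam`` each of the 18 monomers is mutant
  independently with probability ``f``, the mutant fraction of the genome
  (and hence monomer) pool.

Displayed classes are defined on monomer counts: WT = no mutant monomer,
MUT = all mutant, MIX otherwise.  Whether a particle can plate on a
truncated-LPS (ReLPS) host is parameterized by an
:class:`AssemblyHypothesis` ``(m, j)``: the display is infectious when at
least ``j`` fibers each carry at least ``m`` mutant monomers.  The null
hypothesis H0 is ``(m=1, j=1)`` — a single mutant monomer anywhere
suffices.  Forming a visible plaque additionally requires a mutant
genotype (a wt genome cannot propagate on the restrictive host).

Closed forms are binomial; :func:`brute_force_oracle` re-derives every
quantity by exact enumeration over per-fiber compositions and is the
verification oracle for the closed forms.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .uncertain import UncertainValue, uv

__all__ = [
    "CLASSES",
    "AssemblyGeometry",
    "AssemblyHypothesis",
    "GPModelParams",
    "GPClassTable",
    "H0",
    "gp_class_probs",
    "display_meets_prob",
    "infectivity_prob",
    "brute_force_oracle",
    "class_meet_probs",
    "dilution_curve",
    "dilution_table",
    "estimate_lambda",
]

#: the six genotype/display classes, genotype lower case, display upper case
CLASSES = ("wt/WT", "wt/MIX", "wt/MUT", "mut/WT", "mut/MIX", "mut/MUT")


@dataclass(frozen=True)
class AssemblyGeometry:
    """Monomers per fiber and fibers per phage (default 3 x 6 = 18)."""

    monomers_per_fiber: int = 3
    fibers_per_phage: int = 6

    def __post_init__(self) -> None:
        if self.monomers_per_fiber < 1 or self.fibers_per_phage < 1:
            raise ValueError("geometry counts must be >= 1")

    @property
    def monomers_per_phage(self) -> int:
        return self.monomers_per_fiber * self.fibers_per_phage


DEFAULT_GEOMETRY = AssemblyGeometry()


@dataclass(frozen=True)
class AssemblyHypothesis:
    """What displayed composition confers plating on the ReLPS host.

    The display qualifies when >= ``min_qualifying_fibers`` fibers each
    carry >= ``min_mut_monomers_per_fiber`` mutant monomers.
    """

    geometry: AssemblyGeometry = DEFAULT_GEOMETRY
    min_mut_monomers_per_fiber: int = 1
    min_qualifying_fibers: int = 1
    label: str = "H0"

    def __post_init__(self) -> None:
        m, j = self.min_mut_monomers_per_fiber, self.min_qualifying_fibers
        if not 1 <= m <= self.geometry.monomers_per_fiber:
            raise ValueError(f"m={m} outside [1, {self.geometry.monomers_per_fiber}]")
        if not 1 <= j <= self.geometry.fibers_per_phage:
            raise ValueError(f"j={j} outside [1, {self.geometry.fibers_per_phage}]")


#: one mutant monomer in one fiber is necessary and sufficient
H0 = AssemblyHypothesis()


@dataclass(frozen=True)
class GPModelParams:
    """Mutant genome fraction ``f`` and linkage probability ``lam``.

    ``lam = 0`` is a fully random monomer pool, ``lam = 1`` full
    self-assembly.  The equimolar co-expression experiment has f = 0.5.
    """

    f: float
    lam: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must be in [0, 1], got {self.f}")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lam must be in [0, 1], got {self.lam}")


@dataclass
class GPClassTable:
    """Fractions of the six genotype/display classes.

    Values may be plain floats or :class:`UncertainValue`.  The table must
    sum to 1 (within tolerance) possibly less an explicit ``unassigned``
    remainder.
    """

    fractions: dict[str, float | UncertainValue]
    unassigned: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.fractions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown class keys: {sorted(unknown)}")
        for c in CLASSES:
            self.fractions.setdefault(c, 0.0)

    def value(self, cls: str) -> float:
        return float(self.fractions[cls])

    def uncertain(self, cls: str) -> UncertainValue:
        return uv(self.fractions[cls])

    def validate(self, tol: float | None = 1e-9) -> None:
        """Check non-negativity and normalization.

        With ``tol=None`` the tolerance widens to three propagated
        standard deviations, so noisy-but-consistent measured tables pass
        while genuinely inconsistent ones are rejected.
        """
        if tol is None:
            tol = 1e-9 + 3 * max((uv(self.fractions[c]).sd for c in CLASSES),
                                 default=0.0)
        vals = [self.value(c) for c in CLASSES]
        if any(v < -tol for v in vals):
            raise ValueError("negative class fraction")
        total = sum(vals) + self.unassigned
        if abs(total - 1.0) > tol:
            raise ValueError(f"class fractions sum to {total}, not 1")

    @property
    def pure_fraction(self) -> UncertainValue:
        """wt/WT + mut/MUT (display matches genotype everywhere)."""
        return self.uncertain("wt/WT") + self.uncertain("mut/MUT")

    @property
    def opposing_fraction(self) -> UncertainValue:
        """wt/MUT + mut/WT (display contradicts genotype everywhere)."""
        return self.uncertain("wt/MUT") + self.uncertain("mut/WT")

    def as_series(self) -> pd.Series:
        return pd.Series({c: self.value(c) for c in CLASSES})

    def __repr__(self) -> str:  # compact, for interactive use
        body = ", ".join(f"{c}={self.value(c):.4g}" for c in CLASSES)
        return f"GPClassTable({body})"


def _display_class(total_mut: int, monomers: int) -> str:
    if total_mut == 0:
        return "WT"
    if total_mut == monomers:
        return "MUT"
    return "MIX"


def gp_class_probs(params: GPModelParams,
                   geometry: AssemblyGeometry = DEFAULT_GEOMETRY) -> GPClassTable:
    """Closed-form probabilities of the six genotype/display classes.

    Under the linkage mixture: with probability ``lam`` the display is pure
    (WT display for a wt genome, MUT for a mutant genome); otherwise each
    of the M monomers is independently mutant with probability ``f``, so
    the display is all-wild-type with probability ``(1-f)**M``, all-mutant
    with ``f**M`` and mixed otherwise — independent of the genotype.
    """
    f, lam = params.f, params.lam
    M = geometry.monomers_per_phage
    p_wt_disp = (1.0 - f) ** M
    p_mut_disp = f**M
    p_mix = 1.0 - p_wt_disp - p_mut_disp
    fr = {
        "wt/WT": (1 - f) * (lam + (1 - lam) * p_wt_disp),
        "wt/MIX": (1 - f) * (1 - lam) * p_mix,
        "wt/MUT": (1 - f) * (1 - lam) * p_mut_disp,
        "mut/WT": f * (1 - lam) * p_wt_disp,
        "mut/MIX": f * (1 - lam) * p_mix,
        "mut/MUT": f * (lam + (1 - lam) * p_mut_disp),
    }
    table = GPClassTable(fr, metadata={"f": f, "lam": lam, "monomers": M})
    table.validate(1e-12)
    return table


def display_meets_prob(f: float, hyp: AssemblyHypothesis) -> float:
    """P(display meets the hypothesis) under a fully random pool.

    Each fiber has Binomial(K, f) mutant monomers and qualifies when the
    count is >= m; the number of qualifying fibers is Binomial(J, q).
    """
    K = hyp.geometry.monomers_per_fiber
    J = hyp.geometry.fibers_per_phage
    m, j = hyp.min_mut_monomers_per_fiber, hyp.min_qualifying_fibers
    q = float(stats.binom.sf(m - 1, K, f))
    return float(stats.binom.sf(j - 1, J, q))


def infectivity_prob(params: GPModelParams, hyp: AssemblyHypothesis,
                     genotype: str) -> float:
    """P(display meets the hypothesis) for a particle of the given genotype.

    This is plating competence on the restrictive (ReLPS) host; a visible
    plaque additionally requires genotype == "mut" (propagation).
    """
    if genotype not in ("wt", "mut"):
        raise ValueError(f"genotype must be 'wt' or 'mut', got {genotype!r}")
    pure = 1.0 if genotype == "mut" else 0.0  # pure display: all-mut vs all-wt
    return params.lam * pure + (1.0 - params.lam) * display_meets_prob(params.f, hyp)


@dataclass(frozen=True)
class OracleResult:
    table: GPClassTable
    infectivity: dict[str, float]  # genotype -> P(display meets hypothesis)


def brute_force_oracle(params: GPModelParams, hyp: AssemblyHypothesis) -> OracleResult:
    """Exact enumeration over all per-fiber mutant-monomer configurations.

    Independent of the closed forms: iterates over every tuple of per-fiber
    counts (K+1)**J with binomial weights, classifying display and
    hypothesis satisfaction per configuration, then mixes in the linked
    branch.  Refuses geometries above 24 monomers per phage.
    """
    K = hyp.geometry.monomers_per_fiber
    J = hyp.geometry.fibers_per_phage
    M = K * J
    if M > 24:
        raise ValueError(f"geometry too large for exact enumeration ({M} monomers > 24)")
    f, lam = params.f, params.lam
    m, j = hyp.min_mut_monomers_per_fiber, hyp.min_qualifying_fibers

    per_fiber = [math.comb(K, b) * f**b * (1 - f) ** (K - b) for b in range(K + 1)]
    disp_rand = {"WT": 0.0, "MIX": 0.0, "MUT": 0.0}
    meets_rand = 0.0
    for counts in itertools.product(range(K + 1), repeat=J):
        w = math.prod(per_fiber[b] for b in counts)
        total = sum(counts)
        disp_rand[_display_class(total, M)] += w
        if sum(b >= m for b in counts) >= j:
            meets_rand += w

    fr = {}
    for genotype, g_prob in (("wt", 1 - f), ("mut", f)):
        pure_disp = "MUT" if genotype == "mut" else "WT"
        for disp in ("WT", "MIX", "MUT"):
            p = (1 - lam) * disp_rand[disp] + (lam if disp == pure_disp else 0.0)
            fr[f"{genotype}/{disp}"] = g_prob * p
    infectivity = {
        "wt": (1 - lam) * meets_rand,
        "mut": lam + (1 - lam) * meets_rand,
    }
    return OracleResult(GPClassTable(fr), infectivity)


def class_meet_probs(params: GPModelParams,
                     hyp: AssemblyHypothesis) -> dict[tuple[str, str, bool], float]:
    """Joint probabilities of (genotype, display class, meets hypothesis).

    The resolution the experiment simulator needs: plating on the
    restrictive host keys on *meets*, the ReLPS challenge keys on the same,
    and the class table keys on *display*.  Computed exactly by dynamic
    programming over fibers (joint distribution of total mutant monomers
    and qualifying-fiber count).
    """
    K = hyp.geometry.monomers_per_fiber
    J = hyp.geometry.fibers_per_phage
    M = K * J
    f, lam = params.f, params.lam
    m, j = hyp.min_mut_monomers_per_fiber, hyp.min_qualifying_fibers

    per_fiber = stats.binom.pmf(np.arange(K + 1), K, f)
    qualifies = np.arange(K + 1) >= m
    # dp[t, q] = P(total mutant monomers = t, qualifying fibers = q)
    dp = np.zeros((M + 1, J + 1))
    dp[0, 0] = 1.0
    for _ in range(J):
        new = np.zeros_like(dp)
        for b in range(K + 1):
            dq = 1 if qualifies[b] else 0
            new[b:, dq:] += dp[: M + 1 - b, : J + 1 - dq] * per_fiber[b]
        dp = new

    out: dict[tuple[str, str, bool], float] = {}
    for genotype, g_prob in (("wt", 1 - f), ("mut", f)):
        # linked branch: display is pure and meets iff genotype is mutant
        pure_key = (genotype, "MUT" if genotype == "mut" else "WT", genotype == "mut")
        out[pure_key] = out.get(pure_key, 0.0) + g_prob * lam
        for t in range(M + 1):
            for q in range(J + 1):
                p = dp[t, q]
                if p == 0.0:
                    continue
                key = (genotype, _display_class(t, M), q >= j)
                out[key] = out.get(key, 0.0) + g_prob * (1 - lam) * p
    return out


def dilution_curve(f_values, lam: float, hyp: AssemblyHypothesis = H0) -> np.ndarray:
    """Predicted restrictive:permissive plaque-count ratio per mutant fraction.

    Only mutant-genotype particles whose display meets the hypothesis form
    plaques on the restrictive host, so ratio(f) = f * P(display ok | mut).
    Full linkage (lam=1) gives the identity ratio(f) = f; a fully random
    pool under H0 gives f * (1 - (1-f)**18).
    """
    f_values = np.asarray(f_values, dtype=float)
    if np.any((f_values < 0) | (f_values > 1)):
        raise ValueError("all f values must lie in [0, 1]")
    meets = np.array([display_meets_prob(f, hyp) for f in f_values])
    return f_values * (lam + (1.0 - lam) * meets)


def dilution_table(f_values, hyp: AssemblyHypothesis = H0) -> pd.DataFrame:
    """Linked vs random dilution-response curves as a tidy frame."""
    f_values = np.asarray(f_values, dtype=float)
    return pd.DataFrame({
        "f": f_values,
        "ratio_linked": dilution_curve(f_values, 1.0, hyp),
        "ratio_random": dilution_curve(f_values, 0.0, hyp),
    })


def estimate_lambda(table: GPClassTable) -> UncertainValue:
    """Linkage estimate: the pure-class fraction, full linkage expecting 1.

    Under full self-assembly every particle is pure, so
    ``lambda_hat = (wt/WT + mut/MUT) / 1``.  Uncertainty is propagated from
    the class fractions when they carry sds.
    """
    table.validate(None)
    return table.pure_fraction
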