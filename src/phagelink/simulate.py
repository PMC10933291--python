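"""Synthetic-data generators: the in-silico counterpart of every wet input.

Three generator families replace the laboratory steps:

* a two-phage co-expression experiment with a known linkage level —
  particles are drawn from the genotype/display mixture, challenged with
  ReLPS (phages displaying an infectious composition eject their genome;
  wild-type-display phages survive the stringent overnight incubation
  with probability 0.1, matching the observed ten-fold titer drop),
  amplified on the permissive host (progeny display reverts to genotype)
  and titrated by simulated 3.5-uL ten-fold spot series with Poisson
  counting noise, three replicate series per titer;
* error-prone PCR amplicon libraries: substitution counts per 516-bp
  fragment are Poisson with the kit-tuned mean (1 / 2.5 / 5 for the low,
  medium and high mutation-rate libraries), positions uniform without
  replacement, alternative base uniform over the three non-reference
  bases unless a bias matrix is supplied; reads copy fragments with an
  optional flat error rate;
* random genome fixtures with placed marker genes, sized like the 39.9-kbp
  phage genome, for fragment-design and mutation-calling tests.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .fiber import (DEFAULT_GEOMETRY, H0, AssemblyHypothesis, GPModelParams,
                    class_meet_probs)
from .linkage import CoExpressionMeasurements
from .mutspec import AmpliconReads, AmpliconReference
from .titer import Spot, SpotSeries, TiterMeasurement, titer_from_spots
from .uncertain import UncertainValue

__all__ = [
    "InfectivityMatrix",
    "SimulationConfig",
    "simulate_population",
    "simulate_spot_series",
    "simulate_experiment",
    "MutantLibrary",
    "simulate_mut_library",
    "make_genome_fixture",
    "make_amplicon_reference",
]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class InfectivityMatrix:
    """Plating efficiencies and propagation rules per host class.

    On the permissive host every display class plates and both genotypes
    propagate.  On the restrictive (ReLPS) host plating requires a display
    meeting the hypothesis (efficiency ``plating_restrictive``) and plaque
    formation additionally requires a mutant genotype.
    """

    plating_permissive: float = 1.0
    plating_restrictive: float = 1.0
    propagation_restrictive_requires_mut: bool = True

    def __post_init__(self) -> None:
        for v in (self.plating_permissive, self.plating_restrictive):
            if not 0.0 <= v <= 1.0:
                raise ValueError("plating efficiencies must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the simulated co-expression experiment."""

    f: float = 0.5                      # mutant-genome fraction (equimolar)
    lam: float = 0.12                   # linkage probability
    hypothesis: AssemblyHypothesis = H0
    n_phages: int = 10_000_000
    stock_pfu_per_ml: float = 8e8       # co-expression titer scale
    infectivity: InfectivityMatrix = InfectivityMatrix()
    survival_infectious_display: float = 0.0   # ReLPS+ display, stringent challenge
    survival_wt_display: float = 0.1           # ten-fold overnight titer drop
    ctrl_wt_content: float = 0.5
    amplified_pfu_per_ml: float = 6e10
    n_replicates: int = 3
    dilution_base: float = 10.0
    spot_volume_ul: float = 3.5
    max_exponent: int = 12
    sampling_noise: bool = True   # False: expected counts, exact titers (no spots)
    seed: int = 0


def simulate_population(config: SimulationConfig,
                        rng: np.random.Generator | None = None):
    """Sample explicit particles: genotypes plus per-fiber mutant counts.

    Returns ``(genotypes, fiber_counts)`` where ``genotypes`` is an int8
    array (1 = mutant genome) of length N and ``fiber_counts`` an (N, J)
    int8 array of mutant monomers per fiber.  Intended for distributional
    checks at moderate N; the experiment simulator uses exact class
    probabilities instead and scales to any N.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    geom = config.hypothesis.geometry
    N, J, K = config.n_phages, geom.fibers_per_phage, geom.monomers_per_fiber
    genotypes = (rng.random(N) < config.f).astype(np.int8)
    linked = rng.random(N) < config.lam
    fiber_counts = rng.binomial(K, config.f, size=(N, J)).astype(np.int8)
    fiber_counts[linked] = (genotypes[linked, None] * K).astype(np.int8)
    return genotypes, fiber_counts


def simulate_spot_series(true_titer: float, config: SimulationConfig,
                         rng: np.random.Generator) -> SpotSeries:
    """Poisson plaque counts of a ten-fold serial dilution spot assay."""
    vol_ml = config.spot_volume_ul / 1000.0
    spots = []
    for rep in range(config.n_replicates):
        for e in range(config.max_exponent + 1):
            mu = true_titer * vol_ml / config.dilution_base**e
            if mu > 1e6:    # uncountable lawn-clearing spot; record as saturated
                count = int(mu)
            else:
                count = int(rng.poisson(mu))
            spots.append(Spot(e, count, rep))
    return SpotSeries(spots, config.dilution_base, config.spot_volume_ul)


def _measure(true_titer: float, host: str, config: SimulationConfig,
             rng: np.random.Generator, max_respot: int = 10) -> TiterMeasurement:
    """Spot-titrate a true titer; re-spot (fresh plate) if no countable spot."""
    for _ in range(max_respot):
        series = simulate_spot_series(true_titer, config, rng)
        try:
            return TiterMeasurement(host, titer_from_spots(series), "simulated")
        except ValueError:
            continue
    raise RuntimeError(f"no countable spot after {max_respot} re-spots "
                       f"(true titer {true_titer:.3g})")


def simulate_experiment(config: SimulationConfig):
    """Run the full co-expression / challenge / amplification experiment.

    Exact class probabilities are computed from the linkage mixture, a
    finite population of ``n_phages`` is drawn multinomially, the ReLPS
    challenge thins it binomially per display class, survivors are
    amplified with display reset to genotype, and every titer is read out
    through a simulated spot assay.  Returns
    ``(CoExpressionMeasurements, truth)`` where ``truth`` records the
    generating parameters and exact class fractions.
    """
    rng = np.random.default_rng(config.seed)
    noisy = config.sampling_noise
    params = GPModelParams(config.f, config.lam)
    probs = class_meet_probs(params, config.hypothesis)
    keys = sorted(probs)
    pvec = np.array([probs[k] for k in keys])
    pvec = pvec / pvec.sum()
    N = config.n_phages
    if noisy:
        counts = dict(zip(keys, rng.multinomial(N, pvec)))
    else:
        counts = dict(zip(keys, N * pvec))
    inf = config.infectivity

    def total(pred) -> float:
        return sum(c for k, c in counts.items() if pred(k))

    def thin(count, p):
        """Binomial survival, or its expectation in noiseless mode."""
        if noisy and 0 < p < 1:
            return float(rng.binomial(int(count), p))
        return count * p

    scale = config.stock_pfu_per_ml / N
    # co-expression titers: everything plates on the permissive host; the
    # restrictive host needs an infectious display AND a mutant genome
    t_perm_co = total(lambda k: True) * scale * inf.plating_permissive
    t_restr_co = total(lambda k: k[2] and (k[0] == "mut" or
                                           not inf.propagation_restrictive_requires_mut)
                       ) * scale * inf.plating_restrictive

    # ReLPS challenge: infectious displays eject, the rest survive ~10%
    survivors = {}
    for k, c in counts.items():
        p = (config.survival_infectious_display if k[2]
             else config.survival_wt_display)
        survivors[k] = thin(c, p)
    n_surv = sum(survivors.values())
    t_relps_co = n_surv * scale * inf.plating_permissive

    # equal-volume control: separately assembled, fully linked pools
    ctrl_wt = N * config.ctrl_wt_content
    ctrl_surv = (thin(ctrl_wt, config.survival_wt_display)
                 + thin(N - ctrl_wt, config.survival_infectious_display))
    t_relps_ctrl = ctrl_surv * scale * inf.plating_permissive

    # amplification on the permissive host: progeny display = genotype
    surv_mut = sum(c for k, c in survivors.items() if k[0] == "mut")
    extinct = n_surv == 0
    frac_mut = surv_mut / n_surv if n_surv else 0.0
    t_amp_perm = config.amplified_pfu_per_ml if not extinct else 0.0
    t_amp_restr = t_amp_perm * frac_mut * inf.plating_restrictive

    if noisy:
        def readout(true_titer, host):
            return _measure(true_titer, host, config, rng)
    else:
        def readout(true_titer, host):
            return TiterMeasurement(host, UncertainValue(true_titer, 0.0), "exact")

    meas = CoExpressionMeasurements(
        T_perm_co=readout(t_perm_co, "permissive"),
        T_restr_co=readout(t_restr_co, "restrictive"),
        T_relps_co=readout(t_relps_co, "permissive"),
        T_relps_ctrl=readout(t_relps_ctrl, "permissive"),
        T_amp_perm=readout(t_amp_perm, "permissive"),
        T_amp_restr=readout(t_amp_restr, "restrictive"),
        eop_mut=UncertainValue(inf.plating_restrictive, 0.0),
        ctrl_wt_content=config.ctrl_wt_content,
        genotype_mix=config.f,
    )
    class_fractions = {}
    for (g, d, _), c in counts.items():
        cls = f"{g}/{d}"
        class_fractions[cls] = class_fractions.get(cls, 0.0) + c / N
    truth = {
        "f": config.f,
        "lam": config.lam,
        "class_fractions": class_fractions,
        "survivor_mut_fraction": frac_mut,
        "extinct": extinct,
        "true_titers": {
            "T_perm_co": t_perm_co, "T_restr_co": t_restr_co,
            "T_relps_co": t_relps_co, "T_relps_ctrl": t_relps_ctrl,
            "T_amp_perm": t_amp_perm, "T_amp_restr": t_amp_restr,
        },
    }
    return meas, truth


# -- error-prone library ---------------------------------------------------

@dataclass
class MutantLibrary:
    """A mutagenized fragment pool plus its (possibly error-bearing) reads."""

    reference: AmpliconReference
    fragments: np.ndarray          # (n, L) uint8 base matrix
    loads: np.ndarray              # planted substitutions per fragment
    reads: AmpliconReads

    def __len__(self) -> int:
        return self.fragments.shape[0]

    def fragment_reads(self) -> AmpliconReads:
        """The fragments themselves as error-free reads."""
        return AmpliconReads(self.fragments)


def _unique_positions(rng: np.random.Generator, rows: int, k: int,
                      length: int) -> np.ndarray:
    """(rows, k) uniform positions, distinct within each row."""
    pos = rng.integers(0, length, size=(rows, k))
    while True:
        srt = np.sort(pos, axis=1)
        bad = np.any(srt[:, 1:] == srt[:, :-1], axis=1)
        if not bad.any():
            return pos
        pos[bad] = rng.integers(0, length, size=(int(bad.sum()), k))


def _mutate_bases(rng: np.random.Generator, ref_bases: np.ndarray,
                  bias: Optional[np.ndarray]) -> np.ndarray:
    """Alternative bases for each reference base (never the reference)."""
    lut = np.zeros(256, dtype=np.int64)
    lut[_BASE_BYTES] = np.arange(4)
    ref_idx = lut[ref_bases]
    if bias is None:
        alt_idx = (ref_idx + rng.integers(1, 4, size=ref_idx.shape)) % 4
    else:
        bias = np.asarray(bias, dtype=float)
        if bias.shape != (4, 4) or np.any(np.diagonal(bias) != 0):
            raise ValueError("bias must be 4x4 (A,C,G,T order) with a zero diagonal")
        alt_idx = np.empty_like(ref_idx)
        for b in range(4):
            mask = ref_idx == b
            p = bias[b] / bias[b].sum()
            alt_idx[mask] = rng.choice(4, size=int(mask.sum()), p=p)
    return _BASE_BYTES[alt_idx]


def simulate_mut_library(n_fragments: int, mean_load: float,
                         ref: AmpliconReference,
                         read_error_rate: float = 0.0,
                         seed: int | np.random.Generator = 0,
                         substitution_bias: Optional[np.ndarray] = None) -> MutantLibrary:
    """Generate an error-prone PCR fragment library and its read set.

    Substitution counts per fragment are Poisson(``mean_load``) at uniform
    distinct positions; the alternative base is uniform over the three
    non-reference bases unless a 4x4 ``substitution_bias`` matrix is
    given.  Reads copy the fragments with a flat per-base error rate.
    """
    if mean_load < 0:
        raise ValueError("mean_load must be >= 0")
    L = len(ref)
    if mean_load > L:
        raise ValueError(f"mean_load {mean_load} exceeds fragment length {L}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    loads = np.minimum(rng.poisson(mean_load, size=n_fragments), L)
    mat = np.tile(ref.as_bytes, (n_fragments, 1))
    for k in np.unique(loads):
        if k == 0:
            continue
        rows = np.flatnonzero(loads == k)
        pos = _unique_positions(rng, len(rows), int(k), L)
        ref_bases = mat[rows[:, None], pos]
        mat[rows[:, None], pos] = _mutate_bases(rng, ref_bases, substitution_bias)

    if read_error_rate > 0:
        reads_mat = mat.copy()
        n_err = rng.binomial(reads_mat.size, read_error_rate)
        flat = rng.integers(0, reads_mat.size, size=n_err)
        r, c = np.unravel_index(flat, reads_mat.shape)
        reads_mat[r, c] = _mutate_bases(rng, reads_mat[r, c], None)
    else:
        reads_mat = mat
    return MutantLibrary(ref, mat, loads, AmpliconReads(reads_mat))


# -- genome fixtures -------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASE_BYTES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def make_genome_fixture(length: int = 39_937,
                        gene_table: Optional[Sequence[tuple[str, int, str]]] = None,
                        seed: int = 0):
    """Seeded random genome with placed marker genes.

    ``gene_table`` rows are ``(name, start, sequence)``: each marker
    sequence is written into the random backbone at its start coordinate.
    Overlapping placements are rejected.  Returns ``(sequence,
    annotations)`` with annotations as ``(name, start, end)`` half-open
    intervals.
    """
    if length < 1000:
        raise ValueError("fixture length must be >= 1 kbp")
    rng = np.random.default_rng(seed)
    seq = list(_random_sequence(rng, length))
    annotations = []
    placed: list[tuple[int, int, str]] = []
    for name, start, gene_seq in gene_table or []:
        end = start + len(gene_seq)
        if start < 0 or end > length:
            raise ValueError(f"gene {name} outside the fixture")
        for s, e, other in placed:
            if start < e and s < end:
                raise ValueError(f"gene placements overlap: {name} vs {other}")
        placed.append((start, end, name))
        seq[start:end] = list(gene_seq.upper())
        annotations.append((name, start, end))
    return "".join(seq), annotations


#: marker codons planted in the amplicon fixture: residue -> (codon, amino acid)
_AMPLICON_MARKERS = {
    480: ("GGT", "G"),
    500: ("GCT", "A"),
    501: ("AAC", "N"),
    521: ("GGC", "G"),
    540: ("GAT", "D"),
    541: ("TCT", "S"),
}


def make_amplicon_reference(seed: int = 0, length: int = 516,
                            aa_offset: int = 382,
                            gene_offset: int = 1146) -> AmpliconReference:
    """Random 516-bp amplicon fixture with landmark tail-fiber codons.

    A stand-in for the real tail-fiber fragment: codons at the residues
    most often recovered in host-range selections (e.g. a serine codon at
    residue 541, glycines at 480 and 521) are fixed so amino-acid-calling
    tests have a planted truth; all other codons are random and stop-free.
    """
    if length % 3:
        raise ValueError("amplicon length must be a codon multiple")
    rng = np.random.default_rng(seed)
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    for ordinal in range(length // 3):
        residue = aa_offset + ordinal
        marker = _AMPLICON_MARKERS.get(residue)
        if marker is not None:
            codons.append(marker[0])
            continue
        while True:
            c = _random_sequence(rng, 3)
            if c not in stops:
                break
        codons.append(c)
    return AmpliconReference("".join(codons), gene_offset=gene_offset,
                             aa_offset=aa_offset, name=f"synthetic-amplicon-seed{seed}")
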