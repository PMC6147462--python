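"""Two-compartment 13C label-propagation simulator.

Generates synthetic dual-tracer isotopomer data with the labeling structure
expected from [1-13C]glucose (neuronal route) and [1,2-13C]acetate
(astrocytic route):

* neurons: glucose → pyruvate → acetyl → TCA (``turns`` discrete turns) →
  glutamate → GABA, with alanine and lactate drawn position-preservingly
  from pyruvate;
* astrocytes: acetate → acetyl → TCA → glutamate → glutamine, with a
  configurable fraction of glutamine returned to the neuronal glutamate
  pool (glutamate-glutamine cycle).

Metabolite pools are represented as exact probability distributions over
binary labeling vectors (one bit per carbon, index 0 = C1).  The engine is
discrete-turn bookkeeping, not kinetics: each TCA turn condenses a fresh,
independently drawn acetyl unit with the oxaloacetate regenerated from the
previous turn, and positional information is lost at the symmetric
succinate/fumarate stage (end-to-end scrambling).  Per-group flux scales
multiply labeled-substrate delivery, which is the knob used to emulate a
hypermetabolic knockout.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    METABOLITE_CARBONS,
    CalibrationTable,
    IsotopomerTable,
    LabelPattern,
    PeakTable,
    TotalPoolTable,
)

__all__ = [
    "PoolDistribution",
    "SimulationConfig",
    "unlabeled",
    "bernoulli_pool",
    "mix",
    "glycolysis_map",
    "pdh_step",
    "acetate_to_acetyl",
    "tca_turn",
    "og_to_glu",
    "glu_to_gaba",
    "oaa_to_asp",
    "observable_class",
    "aggregate_to_classes",
    "run_two_compartment",
    "synthetic_calibration",
    "simulate_peaks",
]

# A pool distribution maps binary label vectors (tuple of 0/1, index 0 = C1)
# to probabilities summing to 1.
PoolDistribution = dict[tuple[int, ...], float]

_SUM_TOL = 1e-9


def _check(dist: PoolDistribution, n: int) -> PoolDistribution:
    total = 0.0
    for vec, p in dist.items():
        if len(vec) != n:
            raise ValueError(f"label vector {vec} has length {len(vec)}, expected {n}")
        if p < -_SUM_TOL:
            raise ValueError(f"negative probability {p} for {vec}")
        total += p
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"pool distribution sums to {total}, expected 1")
    return dist


def unlabeled(n_carbons: int) -> PoolDistribution:
    """Point mass on the all-12C vector."""
    return {(0,) * n_carbons: 1.0}


def bernoulli_pool(n_carbons: int, labeled_positions: tuple[int, ...], p: float) -> PoolDistribution:
    """Pool that is labeled at ``labeled_positions`` (1-based) with
    probability ``p`` and unlabeled otherwise."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"labeled fraction {p} outside [0, 1]")
    hot = tuple(1 if i + 1 in labeled_positions else 0 for i in range(n_carbons))
    cold = (0,) * n_carbons
    if p == 1.0:
        return {hot: 1.0}
    dist = {cold: 1.0 - p}
    if p > 0.0:
        dist[hot] = dist.get(hot, 0.0) + p
    return dist


def mix(dists_weights: list[tuple[PoolDistribution, float]]) -> PoolDistribution:
    """Probability mixture of pools over the same carbon skeleton."""
    out: PoolDistribution = {}
    for dist, w in dists_weights:
        if w == 0.0:
            continue
        for vec, p in dist.items():
            out[vec] = out.get(vec, 0.0) + w * p
    return out


def _map_vec(dist: PoolDistribution, fn) -> PoolDistribution:
    out: PoolDistribution = {}
    for vec, p in dist.items():
        new = fn(vec)
        out[new] = out.get(new, 0.0) + p
    return out


def expected_label_count(dist: PoolDistribution) -> float:
    """Expected number of 13C atoms per molecule."""
    return sum(p * sum(vec) for vec, p in dist.items())


# ---------------------------------------------------------------------------
# Carbon-fate maps
# ---------------------------------------------------------------------------


def glycolysis_map(glucose: PoolDistribution) -> PoolDistribution:
    """Split each 6-carbon glucose into its two triose-derived pyruvates.

    Upper half: glucose C1→pyruvate C3, C2→C2, C3→C1; lower half: C4→C1,
    C5→C2, C6→C3.  The result is the equal mixture of both halves.
    """
    _check(glucose, 6)
    out: PoolDistribution = {}
    for vec, p in glucose.items():
        upper = (vec[2], vec[1], vec[0])
        lower = (vec[3], vec[4], vec[5])
        out[upper] = out.get(upper, 0.0) + 0.5 * p
        out[lower] = out.get(lower, 0.0) + 0.5 * p
    return out


def pdh_step(pyruvate: PoolDistribution) -> PoolDistribution:
    """Pyruvate dehydrogenase: C1 released as CO2; C2→acetyl C1 (carboxyl),
    C3→acetyl C2 (methyl)."""
    _check(pyruvate, 3)
    return _map_vec(pyruvate, lambda v: (v[1], v[2]))


def acetate_to_acetyl(acetate: PoolDistribution) -> PoolDistribution:
    """Acetate activation is position-preserving (C1→C1, C2→C2)."""
    _check(acetate, 2)
    return dict(acetate)


def _condense(acetyl_vec: tuple[int, ...], oaa_vec: tuple[int, ...]) -> tuple[int, ...]:
    # Citrate-synthase/aconitase/IDH fates: OAA C1 is released as CO2 at the
    # isocitrate decarboxylation; oxoglutarate C1←OAA C4, C2←OAA C3,
    # C3←OAA C2, C4←acetyl C2 (methyl), C5←acetyl C1 (carboxyl).
    return (oaa_vec[3], oaa_vec[2], oaa_vec[1], acetyl_vec[1], acetyl_vec[0])


def _og_to_next_oaa(og: PoolDistribution) -> PoolDistribution:
    # OG C1 is lost in the oxoglutarate→succinate decarboxylation; the
    # symmetric succinate/fumarate stage assigns each 4-carbon outcome and
    # its end-to-end reversal equal probability; malate→OAA preserves order.
    out: PoolDistribution = {}
    for vec, p in og.items():
        succ = vec[1:]
        rev = succ[::-1]
        out[succ] = out.get(succ, 0.0) + 0.5 * p
        out[rev] = out.get(rev, 0.0) + 0.5 * p
    return out


def tca_turn(
    acetyl: PoolDistribution, oaa: PoolDistribution
) -> tuple[PoolDistribution, PoolDistribution]:
    """One discrete TCA turn.

    Condenses an independent acetyl unit with oxaloacetate and returns the
    oxoglutarate pool of this turn plus the oxaloacetate regenerated for
    the next turn (after the C1 loss and succinate scrambling).
    """
    _check(acetyl, 2)
    _check(oaa, 4)
    og: PoolDistribution = {}
    for a_vec, a_p in acetyl.items():
        for o_vec, o_p in oaa.items():
            new = _condense(a_vec, o_vec)
            og[new] = og.get(new, 0.0) + a_p * o_p
    return og, _og_to_next_oaa(og)


def og_to_glu(og: PoolDistribution, dilution: float = 0.0) -> PoolDistribution:
    """Transamination to glutamate is position-preserving; ``dilution`` mixes
    in that fraction of unlabeled glutamate."""
    _check(og, 5)
    if not 0.0 <= dilution <= 1.0:
        raise ValueError(f"dilution {dilution} outside [0, 1]")
    if dilution == 0.0:
        return dict(og)
    return mix([(og, 1.0 - dilution), (unlabeled(5), dilution)])


def glu_to_gaba(glu: PoolDistribution) -> PoolDistribution:
    """Glutamate decarboxylation: Glu C1 lost; Glu C5→GABA C1, C4→C2,
    C3→C3, C2→C4."""
    _check(glu, 5)
    return _map_vec(glu, lambda v: (v[4], v[3], v[2], v[1]))


def oaa_to_asp(oaa: PoolDistribution) -> PoolDistribution:
    """Transamination to aspartate is the identity on carbon positions."""
    _check(oaa, 4)
    return dict(oaa)


# ---------------------------------------------------------------------------
# Observable-class aggregation
# ---------------------------------------------------------------------------


def observable_class(metabolite: str, vec: tuple[int, ...]) -> LabelPattern | None:
    """Map a labeling vector to its NMR-observable reporting class.

    Singly labeled vectors and adjacent doubly labeled vectors map to their
    own pattern; vectors with three or more labels, or non-adjacent double
    labels, fall into the aggregate ``other`` class; the unlabeled vector
    maps to ``None`` (it is the 12C pool, not an isotopomer).
    """
    positions = tuple(i + 1 for i, b in enumerate(vec) if b)
    if not positions:
        return None
    if len(positions) == 1 or (
        len(positions) == 2 and positions[1] - positions[0] == 1
    ):
        return LabelPattern(metabolite, positions)
    return LabelPattern.other(metabolite)


def aggregate_to_classes(
    metabolite: str, dist: PoolDistribution
) -> dict[LabelPattern, float]:
    """Total probability per observable class, excluding the 12C pool.

    Mass in unobservable patterns is retained under the ``other`` class so
    label-conservation audits remain possible.
    """
    out: dict[LabelPattern, float] = {}
    for vec, p in dist.items():
        cls = observable_class(metabolite, vec)
        if cls is None or p == 0.0:
            continue
        out[cls] = out.get(cls, 0.0) + p
    return out


# ---------------------------------------------------------------------------
# Whole-simulation configuration and driver
# ---------------------------------------------------------------------------

_DEFAULT_POOL_SIZES = {
    "Glu": 12.0,
    "Gln": 5.0,
    "Asp": 2.7,
    "GABA": 2.7,
    "Ala": 1.2,
    "Lac": 2.5,
}


@dataclass
class SimulationConfig:
    """Free parameters of the discrete-turn generator.

    The tracer protocol fixes which substrates are labeled; everything the
    underlying study leaves unstated (turn count, dilution, the
    astrocyte→neuron glutamine transfer fraction, pool sizes, noise) is an
    explicit field here.
    """

    glucose_c1_fraction: float = 0.15
    acetate_c12_fraction: float = 0.15
    turns: int = 2
    glucose_flux_scale: dict[str, float] = field(
        default_factory=lambda: {"CTL": 1.0, "KO": 1.3}
    )
    acetate_flux_scale: dict[str, float] = field(
        default_factory=lambda: {"CTL": 1.0, "KO": 1.3}
    )
    dilution: dict[str, float] = field(default_factory=dict)  # per pool, default 0
    gln_to_neuron_fraction: float = 0.4
    astro_asp_fraction: float = 0.3
    pool_sizes_mM: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_POOL_SIZES)
    )
    n_replicates: int = 4
    cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("glucose_c1_fraction", "acetate_c12_fraction",
                     "gln_to_neuron_fraction", "astro_asp_fraction", "cv"):
            v = getattr(self, name)
            if not 0.0 <= v <= (1.0 if name != "cv" else math.inf):
                raise ValueError(f"{name}={v} out of range")
        if not 1 <= self.turns <= 6:
            raise ValueError("turns must be between 1 and 6")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if set(self.glucose_flux_scale) != set(self.acetate_flux_scale):
            raise ValueError("flux-scale dicts must cover the same groups")
        for d in self.dilution.values():
            if not 0.0 <= d <= 1.0:
                raise ValueError("dilution fractions must be in [0, 1]")

    @property
    def groups(self) -> list[str]:
        return sorted(self.glucose_flux_scale)

    def with_overrides(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def _group_pool_means(config: SimulationConfig, group: str) -> dict[str, PoolDistribution]:
    """Noise-free labeling distribution of each reported pool for a group."""
    p_glc = config.glucose_c1_fraction * config.glucose_flux_scale[group]
    p_ace = config.acetate_c12_fraction * config.acetate_flux_scale[group]
    if p_glc > 1.0 or p_ace > 1.0:
        raise ValueError("flux scale drives a labeled fraction above 1")
    dil = config.dilution

    def run_tca(acetyl: PoolDistribution) -> tuple[PoolDistribution, PoolDistribution]:
        """Returns (final-turn oxoglutarate, OAA entering the final turn)."""
        oaa = unlabeled(4)
        og = None
        oaa_in = oaa
        for _ in range(config.turns):
            oaa_in = oaa
            og, oaa = tca_turn(acetyl, oaa)
        assert og is not None
        return og, oaa_in

    # Neuronal route: glucose-derived.
    glucose = bernoulli_pool(6, (1,), p_glc)
    pyruvate = glycolysis_map(glucose)
    acetyl_n = pdh_step(pyruvate)
    og_n, oaa_in_n = run_tca(acetyl_n)
    glu_n = og_to_glu(og_n, dil.get("Glu", 0.0))

    # Astrocytic route: acetate-derived, exported as glutamine.
    acetate = bernoulli_pool(2, (1, 2), p_ace)
    acetyl_a = acetate_to_acetyl(acetate)
    og_a, oaa_in_a = run_tca(acetyl_a)
    glu_a = og_to_glu(og_a, dil.get("Gln", 0.0))
    gln = dict(glu_a)  # glutamine synthetase is position-preserving

    # Glutamate-glutamine cycle: part of the neuronal transmitter glutamate
    # pool is regenerated from astrocytic glutamine.
    m = config.gln_to_neuron_fraction
    glu = mix([(glu_n, 1.0 - m), (gln, m)])
    gaba = glu_to_gaba(glu)

    a = config.astro_asp_fraction
    asp = mix([(oaa_to_asp(oaa_in_n), 1.0 - a), (oaa_to_asp(oaa_in_a), a)])

    ala = mix([(pyruvate, 1.0 - dil.get("Ala", 0.0)),
               (unlabeled(3), dil.get("Ala", 0.0))])
    lac = mix([(pyruvate, 1.0 - dil.get("Lac", 0.0)),
               (unlabeled(3), dil.get("Lac", 0.0))])

    return {"Glu": glu, "Gln": gln, "GABA": gaba, "Asp": asp, "Ala": ala, "Lac": lac}


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise factors with mean 1 and the given CV."""
    if cv == 0.0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def run_two_compartment(
    config: SimulationConfig,
) -> tuple[IsotopomerTable, TotalPoolTable]:
    """Run the full two-compartment simulation.

    Returns replicate-level isotopomer concentrations (mM), aggregated to
    NMR-observable classes, and matching total-pool concentrations.  Only
    classes with nonzero expected concentration are emitted.  The seed is
    recorded in both tables' ``meta``.
    """
    rng = np.random.default_rng(config.seed)
    iso_rows: list[tuple[str, str, LabelPattern, float]] = []
    total_rows: list[dict] = []
    for group in config.groups:
        pools = _group_pool_means(config, group)
        for metabolite in sorted(pools):
            dist = pools[metabolite]
            pool_size = config.pool_sizes_mM.get(metabolite)
            if pool_size is None:
                raise ValueError(f"no pool size configured for {metabolite}")
            classes = aggregate_to_classes(metabolite, dist)
            for pattern in sorted(classes):
                mean_conc = pool_size * classes[pattern]
                factors = _lognormal_factors(rng, config.cv, config.n_replicates)
                for i, f in enumerate(factors, start=1):
                    iso_rows.append((group, f"r{i}", pattern, mean_conc * f))
            factors = _lognormal_factors(rng, config.cv, config.n_replicates)
            for i, f in enumerate(factors, start=1):
                total_rows.append(
                    {
                        "group": group,
                        "replicate": f"r{i}",
                        "metabolite": metabolite,
                        "total_mM": pool_size * f,
                    }
                )
    meta = {"seed": config.seed, "turns": config.turns, "groups": config.groups}
    iso = IsotopomerTable.from_records(iso_rows, meta=dict(meta))
    totals = TotalPoolTable(pd.DataFrame(total_rows), meta=dict(meta))
    return iso, totals


# ---------------------------------------------------------------------------
# Synthetic peak areas and calibration data
# ---------------------------------------------------------------------------


def synthetic_calibration(
    patterns: list[LabelPattern] | None = None,
    metabolites: list[str] | None = None,
    slope_au_per_mM: float = 1000.0,
    intercept_au: float = 5.0,
    levels_mM: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0),
    seed: int | None = None,
    noise_cv: float = 0.0,
) -> CalibrationTable:
    """Generate a standard-curve table covering the requested carbons.

    Each (metabolite, carbon) pair gets peak areas on an exact line
    ``area = slope * conc + intercept`` at the given concentration levels,
    optionally perturbed by multiplicative noise.  Per-carbon slopes are
    varied deterministically so curve recovery is a non-trivial check.
    """
    carbons: set[tuple[str, int]] = set()
    if patterns:
        for pat in patterns:
            for pos in pat.positions:
                carbons.add((pat.metabolite, pos))
    if metabolites:
        for met in metabolites:
            for pos in range(1, METABOLITE_CARBONS[met] + 1):
                carbons.add((met, pos))
    if not carbons:
        raise ValueError("no (metabolite, carbon) pairs requested")
    rng = np.random.default_rng(seed)
    rows = []
    for met, carbon in sorted(carbons):
        # deterministic per-carbon slope spread (+/- 20%); crc32 rather than
        # hash() because string hashing is salted per process
        digest = zlib.crc32(f"{met}:C{carbon}".encode())
        slope = slope_au_per_mM * (1.0 + 0.2 * math.sin(digest % 97))
        for conc in levels_mM:
            area = slope * conc + intercept_au
            if noise_cv > 0.0:
                area *= float(_lognormal_factors(rng, noise_cv, 1)[0])
            rows.append(
                {"metabolite": met, "carbon": carbon, "conc_mM": conc, "area": area}
            )
    return CalibrationTable(pd.DataFrame(rows))


def _multiplet_class(pattern: LabelPattern, carbon: int) -> str:
    """Doublet when an adjacent carbon in the same molecule is also labeled."""
    if carbon - 1 in pattern.positions or carbon + 1 in pattern.positions:
        return "doublet"
    return "singlet"


def simulate_peaks(
    iso: IsotopomerTable,
    calibration: CalibrationTable,
    internal_standard_area: float = 1.0e5,
    seed: int | None = None,
    noise_cv: float = 0.0,
) -> PeakTable:
    """Invert quantification: emit per-carbon peak areas for a table.

    ``area = conc * slope + intercept`` through each carbon's fitted
    calibration line, times multiplicative noise; doubly labeled
    adjacent-carbon patterns emit doublets.  At zero noise this is the exact
    inverse of :func:`neurotracer.quantify.areas_to_concentrations`.
    """
    from .core import parse_pattern
    from .quantify import fit_standard_curve  # local import to avoid cycle

    if internal_standard_area <= 0:
        raise ValueError("internal-standard area must be > 0")
    curves = fit_standard_curve(calibration)
    rng = np.random.default_rng(seed)
    rows = []
    for row in iso.df.itertuples():
        pattern = parse_pattern(row.pattern)
        if pattern.is_other:
            continue  # aggregate classes have no defined peak positions
        spectrum = f"{row.group}:{row.replicate}"
        for carbon in pattern.positions:
            key = (pattern.metabolite, carbon)
            if key not in curves:
                raise KeyError(f"no calibration for {key[0]} C{key[1]}")
            curve = curves[key]
            area = row.conc_mM * curve.slope + curve.intercept
            if noise_cv > 0.0:
                area *= float(_lognormal_factors(rng, noise_cv, 1)[0])
            rows.append(
                {
                    "spectrum": spectrum,
                    "group": row.group,
                    "replicate": row.replicate,
                    "metabolite": pattern.metabolite,
                    "carbon": carbon,
                    "pattern": str(pattern),
                    "multiplet": _multiplet_class(pattern, carbon),
                    "area": area,
                    "is_area": internal_standard_area,
                }
            )
    return PeakTable(pd.DataFrame(rows, columns=list(PeakTable.COLUMNS)))
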