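"""Synthetic dual-enrichment datasets with known ground truth.

Two generators:

* :func:`generate_enrichment_dataset` builds OTU count tables, sample
  metadata and ddPCR totals for a two-line (D, SD), multi-replicate serial
  enrichment by running the shared-capacity competition model over a
  community of planted digestate specialists, soil specialists, generalists,
  washout taxa and relic-DNA pools, then sampling multinomial read counts at
  a fixed sequencing depth and lognormal ddPCR totals.  The true niche label
  and the noise-free abundance of every OTU are returned, so classification
  and clustering stages can be scored against ground truth.

* :func:`generate_gas_series` forward-simulates closed-vial headspace
  kinetics of one or more N2O-respiring populations (O2 respired first, then
  N2O reduced to N2 with 2:1 N2O-N to N2-N conservation), including periodic
  headspace sampling with He replacement and N2O reinjection to a setpoint,
  emitting both the raw "measured" series and the true cumulative
  production used as an oracle by the gas-correction tests.

All randomness flows from a single seeded generator per call; identical
seeds give identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from dualenrich.community import OTUTable, SampleMeta
from dualenrich.gas import GasSeries, VialSpec

__all__ = [
    "CommunitySpec",
    "EnrichmentDataset",
    "GasPopulation",
    "GasSimSpec",
    "generate_enrichment_dataset",
    "generate_gas_series",
]


@dataclass(frozen=True)
class CommunitySpec:
    """Composition and noise model of the planted community.

    Category trait ranges are uniform draws per taxon (h^-1): specialists
    grow only in their preferred substrate and die in the other; generalists
    grow in both, more slowly than any specialist; washout taxa neither grow
    nor die and so decline exactly by the transfer dilution.  Relic-DNA
    pools are material-bound OTU sets present in the inoculum at high copy
    numbers that decline by dilution only (plus an optional first-order
    decay once live organisms are present).
    """

    n_digestate_specialists: int = 50
    n_soil_specialists: int = 50
    n_generalists: int = 25
    n_washout: int = 315
    n_relic_digestate: int = 30
    n_relic_soil: int = 30
    mu_specialist: tuple[float, float] = (0.25, 0.40)
    d_specialist: tuple[float, float] = (0.05, 0.10)
    mu_generalist: tuple[float, float] = (0.12, 0.20)
    relic_copies: tuple[float, float] = (1e8, 1e9)
    relic_decay_rate: float = 0.0
    generalist_initial_fraction: float = 1e-5
    sequencing_depth: int = 9000
    ddpcr_noise_cv: float = 0.1
    n_replicates: int = 7
    n_cycles: int = 7
    carrying_capacity: float = 1e10
    duration: float = 48.0
    transfer_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_digestate_specialists,
            self.n_soil_specialists,
            self.n_generalists,
            self.n_washout,
            self.n_relic_digestate,
            self.n_relic_soil,
        )
        if min(counts) < 0 or sum(counts) == 0:
            raise ValueError("taxon counts must be >= 0 with at least one taxon")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be > 0")

    @property
    def n_otus(self) -> int:
        return (
            self.n_digestate_specialists
            + self.n_soil_specialists
            + self.n_generalists
            + self.n_washout
            + self.n_relic_digestate
            + self.n_relic_soil
        )


@dataclass
class EnrichmentDataset:
    """Synthetic OTU dataset plus its ground truth."""

    table: OTUTable
    meta: dict[str, SampleMeta]
    ddpcr_totals: dict[str, float]
    truth: pd.DataFrame            # per-OTU: category, is_relic, mu/d per substrate
    true_abundance: pd.DataFrame   # noise-free copies per vial, samples x OTUs


def _draw_traits(spec: CommunitySpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []

    def add(n, category, is_relic, mu_s, mu_d, d_s, d_d):
        for _ in range(n):
            rows.append(
                {
                    "category": category,
                    "is_relic": is_relic,
                    "mu_soil": mu_s(),
                    "mu_digestate": mu_d(),
                    "d_soil": d_s(),
                    "d_digestate": d_d(),
                }
            )

    u = lambda lo_hi: (lambda: rng.uniform(*lo_hi))
    zero = lambda: 0.0
    decay = lambda: spec.relic_decay_rate
    add(spec.n_digestate_specialists, "digestate_specialist", False,
        zero, u(spec.mu_specialist), u(spec.d_specialist), zero)
    add(spec.n_soil_specialists, "soil_specialist", False,
        u(spec.mu_specialist), zero, zero, u(spec.d_specialist))
    add(spec.n_generalists, "generalist", False,
        u(spec.mu_generalist), u(spec.mu_generalist), zero, zero)
    add(spec.n_washout, "washout", False, zero, zero, zero, zero)
    add(spec.n_relic_digestate, "washout", True, zero, zero, decay, decay)
    add(spec.n_relic_soil, "washout", True, zero, zero, decay, decay)
    truth = pd.DataFrame(rows, index=[f"OTU{i + 1}" for i in range(len(rows))])
    truth.index.name = "otu_id"
    relic_material = [""] * len(truth)
    start = spec.n_otus - spec.n_relic_digestate - spec.n_relic_soil
    for i in range(spec.n_relic_digestate):
        relic_material[start + i] = "digestate"
    for i in range(spec.n_relic_soil):
        relic_material[start + spec.n_relic_digestate + i] = "soil"
    truth["relic_material"] = relic_material
    return truth


def _initial_abundances(
    spec: CommunitySpec, truth: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Inoculum copies per vial: specialists and washouts dominate, planted
    generalists start several orders of magnitude lower."""
    total = 0.5 * spec.carrying_capacity
    n = np.zeros(len(truth))
    cat = truth["category"].to_numpy()
    relic = truth["is_relic"].to_numpy()
    for mask, share in (
        ((cat == "digestate_specialist") & ~relic, 0.15),
        ((cat == "soil_specialist") & ~relic, 0.15),
        ((cat == "washout") & ~relic, 0.70),
    ):
        k = int(mask.sum())
        if k:
            w = rng.dirichlet(np.full(k, 5.0))
            n[mask] = share * total * w
    gmask = cat == "generalist"
    k = int(gmask.sum())
    if k:
        w = rng.dirichlet(np.full(k, 5.0))
        n[gmask] = spec.generalist_initial_fraction * total * w * k
    if relic.any():
        n[relic] = rng.uniform(*spec.relic_copies, size=int(relic.sum()))
    return n


def _rhs(t, n, mu, d, K):
    return n * (mu * (1.0 - n.sum() / K) - d)


def _simulate_line(
    spec: CommunitySpec, truth: pd.DataFrame, n0: np.ndarray, substrates: list[str]
) -> np.ndarray:
    """End-of-enrichment true abundances (cycles x OTUs), cycle 0 = inoculum."""
    states = [n0.copy()]
    state = n0.copy()
    f = spec.transfer_fraction
    for sub in substrates:
        state = state * f
        mu = truth[f"mu_{sub}"].to_numpy(dtype=float)
        d = truth[f"d_{sub}"].to_numpy(dtype=float)
        sol = solve_ivp(
            _rhs,
            (0.0, spec.duration),
            state,
            args=(mu, d, spec.carrying_capacity),
            method="RK45",
            rtol=1e-7,
            atol=1e-12 * spec.carrying_capacity,
        )
        if not sol.success:
            raise ArithmeticError(f"enrichment integration failed: {sol.message}")
        state = np.clip(sol.y[:, -1], 0.0, None)
        states.append(state.copy())
    return np.vstack(states)


def generate_enrichment_dataset(
    spec: CommunitySpec,
    lines: tuple[str, ...] = ("D", "SD"),
) -> EnrichmentDataset:
    """Generate the full two-line dual-enrichment OTU dataset.

    The substrate of cycle j alternates, starting in digestate (the live
    inoculum is enriched in digestate first); replicates share the same
    deterministic trajectory and differ by multinomial sequencing noise and
    lognormal ddPCR noise.  Sterile-material control samples carry only the
    relic pools of their material.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _draw_traits(spec, rng)
    substrates = ["digestate" if j % 2 == 1 else "soil" for j in range(1, spec.n_cycles + 1)]
    reps = [chr(ord("A") + i) for i in range(spec.n_replicates)]

    counts: dict[str, np.ndarray] = {}
    meta: dict[str, SampleMeta] = {}
    totals: dict[str, float] = {}
    true_rows: dict[str, np.ndarray] = {}

    def emit(sid: str, m: SampleMeta, true_n: np.ndarray) -> None:
        meta[sid] = m
        true_rows[sid] = true_n
        total = true_n.sum()
        rel = true_n / total if total > 0 else np.full_like(true_n, 1.0 / len(true_n))
        counts[sid] = rng.multinomial(spec.sequencing_depth, rel)
        noise = rng.lognormal(mean=0.0, sigma=spec.ddpcr_noise_cv) if spec.ddpcr_noise_cv > 0 else 1.0
        totals[sid] = float(total * noise) if total > 0 else 1.0

    for line in lines:
        n0 = _initial_abundances(spec, truth, rng)
        states = _simulate_line(spec, truth, n0, substrates)
        for rep in reps:
            sid0 = f"{line}_{rep}.0"
            emit(sid0, SampleMeta(sid0, line, rep, 0, "inoculum"), states[0])
            for j, sub in enumerate(substrates, start=1):
                sid = f"{line}_{rep}.{j}"
                emit(sid, SampleMeta(sid, line, rep, j, sub), states[j])

    # sterile-material controls: relic pools only
    for material in ("digestate", "soil"):
        mask = (truth["relic_material"] == material).to_numpy()
        if not mask.any():
            continue
        n = np.zeros(len(truth))
        n[mask] = rng.uniform(*spec.relic_copies, size=int(mask.sum()))
        sid = f"sterile_{material}"
        emit(sid, SampleMeta(sid, "D", "A", 0, "sterile_control"), n)

    count_df = pd.DataFrame.from_dict(
        counts, orient="index", columns=truth.index, dtype=np.int64
    )
    count_df.index.name = "sample_id"
    true_df = pd.DataFrame.from_dict(true_rows, orient="index", columns=truth.index)
    true_df.index.name = "sample_id"
    return EnrichmentDataset(
        table=OTUTable(counts=count_df, meta=meta),
        meta=meta,
        ddpcr_totals=totals,
        truth=truth,
        true_abundance=true_df,
    )


# ---------------------------------------------------------------------------
# gas series generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GasPopulation:
    """One N2O-respiring population: activity ``r0 * exp(k t)`` umol e- h^-1
    (equivalently umol N2O-N h^-1 during anoxic respiration)."""

    initial_rate: float
    exponent: float

    def __post_init__(self) -> None:
        if self.initial_rate < 0:
            raise ValueError("initial_rate must be >= 0")


@dataclass(frozen=True)
class GasSimSpec:
    """Scenario for the closed-vial gas kinetics generator.

    Doses are umol of gas: the standard enrichment receives 124.7 umol of
    both O2 and N2O (3 mL each); phenotyping incubations use 41.6 umol.
    N2O is reinjected to the setpoint whenever the headspace amount falls
    below ``n2o_reinject_threshold`` at a sampling event, up to
    ``max_reinjections`` times; O2 is left to be depleted.  Amounts for N
    gases are tracked in umol N (1 umol N2O = 2 umol N2O-N).

    ``aerobic_rate_factor`` scales whole-community aerobic respiration
    relative to the N2O-respiring activity: the community at large respires
    O2 much faster than its NRB members alone would, producing the short
    initial oxic phase of each enrichment.
    """

    populations: tuple[GasPopulation, ...] = (GasPopulation(8.0, -0.03), GasPopulation(0.001, 0.1))
    o2_dose: float = 124.7
    n2o_dose: float = 124.7
    aerobic_rate_factor: float = 20.0
    n2o_reinject_threshold_n: float = 50.0
    max_reinjections: int = 60
    vial: VialSpec = field(default_factory=VialSpec)
    duration: float = 100.0
    sample_interval: float = 2.0
    substeps: int = 40
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.o2_dose, self.n2o_dose) < 0:
            raise ValueError("doses must be >= 0")


def generate_gas_series(spec: GasSimSpec) -> tuple[GasSeries, pd.DataFrame]:
    """Forward-simulate one incubation; return the raw measured series and
    the true cumulative production (umol; umol N for N gases).

    Electron flow goes to O2 (4 e- per umol) until it is depleted, then to
    N2O (1 e- per umol N); every umol of N2O-N consumed yields one umol of
    N2-N.  At each sampling the measured amounts are recorded (optionally
    with multiplicative lognormal noise), a headspace sample is withdrawn
    and replaced with He, and N2O is topped up per the reinjection policy.

    Raises RuntimeError if the policy demands more than ``max_reinjections``.
    """
    rng = np.random.default_rng(spec.seed)
    v = spec.vial
    dil = v.dilution_factor
    gases = ["O2", "N2O", "N2"]
    state = {"O2": spec.o2_dose, "N2O": 2.0 * spec.n2o_dose, "N2": 0.0}
    true_cum = {"O2": 0.0, "N2O": 0.0, "N2": 0.0}

    times = np.arange(0.0, spec.duration + 0.5 * spec.sample_interval, spec.sample_interval)
    measured = []
    cum_rows = []
    injections: list[tuple[float, str, float]] = []
    n_inject = 0

    def record(t: float) -> None:
        row = {}
        for g in gases:
            noise = rng.lognormal(0.0, spec.noise_cv) if spec.noise_cv > 0 else 1.0
            row[g] = state[g] * noise
        measured.append(pd.Series(row, name=t))
        cum_rows.append(pd.Series(dict(true_cum), name=t))

    clock = 0.0
    record(clock)
    dt = spec.sample_interval / spec.substeps
    for t_next in times[1:]:
        # post-measurement events at the previous timepoint
        for g in gases:
            state[g] *= dil
        if state["N2O"] < spec.n2o_reinject_threshold_n:
            if n_inject >= spec.max_reinjections:
                raise RuntimeError(
                    f"reinjection policy exceeded the cap of {spec.max_reinjections}"
                )
            add = 2.0 * spec.n2o_dose - state["N2O"]
            if add > 0:
                injections.append((clock, "N2O", add))
                state["N2O"] += add
                n_inject += 1
        # integrate respiration to the next sampling time
        while clock < t_next - 1e-9:
            h = min(dt, t_next - clock)
            activity = sum(p.initial_rate * np.exp(p.exponent * clock) for p in spec.populations)
            if state["O2"] > 1e-9:
                cons = min(spec.aerobic_rate_factor * activity / 4.0 * h, state["O2"])
                state["O2"] -= cons
                true_cum["O2"] -= cons
            else:
                cons = min(activity * h, state["N2O"])
                state["N2O"] -= cons
                state["N2"] += cons
                true_cum["N2O"] -= cons
                true_cum["N2"] += cons
            clock += h
        clock = t_next
        record(clock)

    amounts = pd.DataFrame(measured)
    amounts.index.name = "time_h"
    sampled = np.ones(len(times), dtype=bool)
    sampled[-1] = False  # no sample withdrawn after the final measurement
    raw = GasSeries(amounts=amounts, sampled=sampled, injections=injections)
    true_df = pd.DataFrame(cum_rows)
    true_df.index.name = "time_h"
    return raw, true_df
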