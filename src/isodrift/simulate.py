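"""Label-resolved transaminase futile-cycle kinetics and synthetic LC-MS data.

Residual aspartate–glutamate transaminase left in a metabolite extract runs
the reversible reaction

    Glu + OAA  <=>  aKG + Asp

after extracts are dried and resuspended. Stable-isotope labels spiked at
resuspension are scrambled by this futile cycle with three transfer rules:

* the amine ¹⁵N of the donor amino acid moves to the product amino acid;
* the ¹³C₅ skeleton stays with the five-carbon backbone (Glu <-> aKG);
* the α-carbon deuterium of the donor is lost to solvent on deamination,
  and reamination installs an unlabeled hydrogen.

The reaction network is expanded over a restricted isotopologue space and
integrated as deterministic mass-action ODEs (fixed-step RK4); pool sizes
are µM scale, so stochastic fluctuations are irrelevant. The simulator
records a hidden counter of true Glu -> aKG transamination events so the
label-based futile-cycle estimate can be tested against ground truth.

Three intervention scenarios map onto the bench conditions: ``active``
(unfiltered extract, full enzyme activity), ``filtered`` (3 kDa filtration,
no enzyme), and ``aoa`` (aminooxyacetic acid, enzyme activity decaying as
E0*exp(-t/tau) with a short tau to allow brief pre-inhibition turnover).

On top of a time course, :func:`observe_injection_series` applies an LC-MS
observation model (per-feature response factors, multiplicative lognormal
noise, ppm mass error, retention-time jitter) to produce repeat-injection
feature tables, and :func:`generate_ms2_fixtures` builds MS2 spectra with a
planted diagnostic fragment for screening tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import (
    Adduct,
    ChemistryError,
    IonSpecies,
    LabelSpec,
    MolecularFormula,
    ion_mz,
)
from .screen import MS2Record

__all__ = [
    "SimulationError",
    "SCENARIOS",
    "METABOLITE_FORMULAS",
    "SpeciesState",
    "ReactionSystem",
    "TimeCourse",
    "InjectionSeries",
    "SimulationConfig",
    "parse_species",
    "species_name",
    "build_transaminase_system",
    "apply_intervention",
    "simulate_timecourse",
    "label_based_cycle_estimate",
    "observe_injection_series",
    "generate_ms2_fixtures",
]


class SimulationError(ValueError):
    """Invalid simulation configuration or solver failure."""


SCENARIOS = ("active", "filtered", "aoa")

METABOLITE_FORMULAS: dict[str, MolecularFormula] = {
    "Glu": MolecularFormula.parse("C5H9NO4"),
    "aKG": MolecularFormula.parse("C5H6O5"),
    "Asp": MolecularFormula.parse("C4H7NO4"),
    "OAA": MolecularFormula.parse("C4H4O5"),
}

AMINO_ACIDS = ("Glu", "Asp")
KETO_ACIDS = ("aKG", "OAA")

#: canonical retention times (min) for the simulated ion-paired method
_CANONICAL_RT_MIN = {"Glu": 8.1, "aKG": 9.5, "Asp": 7.6, "OAA": 9.9}


def _validate_restricted_labels(metabolite: str, labels: LabelSpec) -> None:
    """Enforce the restricted label space of the transaminase model."""
    if metabolite not in METABOLITE_FORMULAS:
        raise SimulationError(f"unknown metabolite {metabolite!r}")
    try:
        labels.validate_against(METABOLITE_FORMULAS[metabolite])
    except ChemistryError as exc:
        raise SimulationError(str(exc)) from exc
    if labels.n_13C not in (0, 5):
        raise SimulationError("n_13C restricted to {0, 5} (whole C5 skeletons)")
    if labels.n_15N not in (0, 1):
        raise SimulationError("n_15N restricted to {0, 1}")
    if labels.n_D not in (0, 4, 5):
        raise SimulationError("n_D restricted to {0, 4, 5}")
    if metabolite in KETO_ACIDS and (labels.n_15N or labels.alpha_D):
        raise SimulationError("ketoacids carry no 15N and no alpha-deuterium")


def species_name(metabolite: str, labels: LabelSpec) -> str:
    """Readable species tag, e.g. ``"Glu:13C5,15N"`` or ``"Glu:D5,alphaD"``."""
    tokens = []
    if labels.n_13C:
        tokens.append(f"13C{labels.n_13C}")
    if labels.n_15N:
        tokens.append("15N")
    if labels.n_D:
        tokens.append(f"D{labels.n_D}")
    if labels.alpha_D:
        tokens.append("alphaD")
    return metabolite if not tokens else f"{metabolite}:{','.join(tokens)}"


def parse_species(name: str) -> tuple[str, LabelSpec]:
    """Inverse of :func:`species_name`."""
    metabolite, _, tag = name.partition(":")
    n_13C = n_15N = n_D = 0
    alpha_D = False
    if tag:
        for token in tag.split(","):
            token = token.strip()
            if token.startswith("13C"):
                n_13C = int(token[3:]) if token[3:] else 1
            elif token.startswith("15N"):
                n_15N = int(token[3:]) if token[3:] else 1
            elif token == "alphaD":
                alpha_D = True
            elif token.startswith("D"):
                n_D = int(token[1:]) if token[1:] else 1
            else:
                raise SimulationError(f"cannot parse label token {token!r} in {name!r}")
    labels = LabelSpec(n_13C=n_13C, n_15N=n_15N, n_D=n_D, alpha_D=alpha_D)
    _validate_restricted_labels(metabolite, labels)
    return metabolite, labels


@dataclass(frozen=True)
class SpeciesState:
    """One isotopologue-resolved metabolite pool."""

    metabolite: str
    labels: LabelSpec
    concentration_uM: float = 0.0

    def __post_init__(self) -> None:
        _validate_restricted_labels(self.metabolite, self.labels)
        if self.concentration_uM < 0:
            raise SimulationError("concentration must be non-negative")

    @property
    def name(self) -> str:
        return species_name(self.metabolite, self.labels)


def _forward_products(glu: LabelSpec) -> tuple[LabelSpec, LabelSpec]:
    """Glu + OAA -> aKG + Asp label transfer (amine N to Asp, skeleton to aKG,
    α-deuterium lost)."""
    akg = LabelSpec(
        n_13C=glu.n_13C,
        n_15N=0,
        n_D=glu.n_D - (1 if glu.alpha_D else 0),
        alpha_D=False,
    )
    asp = LabelSpec(n_13C=0, n_15N=glu.n_15N, n_D=0, alpha_D=False)
    return akg, asp


def _reverse_products(akg: LabelSpec, asp: LabelSpec) -> tuple[LabelSpec, LabelSpec]:
    """aKG + Asp -> Glu + OAA; Glu inherits the aKG skeleton plus the Asp
    amine nitrogen, with an unlabeled hydrogen installed at the α position."""
    glu = LabelSpec(n_13C=akg.n_13C, n_15N=asp.n_15N, n_D=akg.n_D, alpha_D=False)
    oaa = LabelSpec(
        n_13C=asp.n_13C,
        n_15N=0,
        n_D=asp.n_D - (1 if asp.alpha_D else 0),
        alpha_D=False,
    )
    return glu, oaa


@dataclass
class ReactionSystem:
    """Isotopologue-expanded Glu + OAA <=> aKG + Asp reaction network.

    ``enzyme_activity`` is the dimensionless factor E multiplying both rate
    constants; ``inhibition_tau_hr`` > 0 makes E decay as
    ``E0 * exp(-t/tau)`` (the AOA schedule), and ``None`` keeps E constant.
    """

    species: list[SpeciesState]
    k_fwd: float
    k_rev: float
    enzyme_activity: float = 1.0
    inhibition_tau_hr: float | None = None
    scenario: str = "active"

    # channel arrays built in __post_init__
    _don: np.ndarray = field(init=False, repr=False)
    _acc: np.ndarray = field(init=False, repr=False)
    _p1: np.ndarray = field(init=False, repr=False)
    _p2: np.ndarray = field(init=False, repr=False)
    _k: np.ndarray = field(init=False, repr=False)
    _is_fwd: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.k_fwd < 0 or self.k_rev < 0 or self.enzyme_activity < 0:
            raise SimulationError("rates and enzyme activity must be non-negative")
        self._close_species()
        self._build_channels()

    # -- network construction -------------------------------------------------

    def _close_species(self) -> None:
        """Extend the species list with every state reachable by the rules."""
        states: dict[tuple[str, LabelSpec], float] = {}
        order: list[tuple[str, LabelSpec]] = []
        for sp in self.species:
            key = (sp.metabolite, sp.labels)
            if key not in states:
                states[key] = 0.0
                order.append(key)
            states[key] += sp.concentration_uM
        changed = True
        while changed:
            changed = False
            glus = [k for k in order if k[0] == "Glu"]
            oaas = [k for k in order if k[0] == "OAA"]
            akgs = [k for k in order if k[0] == "aKG"]
            asps = [k for k in order if k[0] == "Asp"]
            new: list[tuple[str, LabelSpec]] = []
            if oaas:
                for _, g in glus:
                    akg, asp = _forward_products(g)
                    new += [("aKG", akg), ("Asp", asp)]
            for _, a in akgs:
                for _, s in asps:
                    glu, oaa = _reverse_products(a, s)
                    new += [("Glu", glu), ("OAA", oaa)]
            for key in new:
                if key not in states:
                    states[key] = 0.0
                    order.append(key)
                    changed = True
        self.species = [
            SpeciesState(m, lab, states[(m, lab)]) for m, lab in order
        ]
        self._index = {(sp.metabolite, sp.labels): i for i, sp in enumerate(self.species)}

    def _build_channels(self) -> None:
        don, acc, p1, p2, k, is_fwd = [], [], [], [], [], []
        idx = self._index
        glus = [(i, sp.labels) for i, sp in enumerate(self.species) if sp.metabolite == "Glu"]
        oaas = [(i, sp.labels) for i, sp in enumerate(self.species) if sp.metabolite == "OAA"]
        akgs = [(i, sp.labels) for i, sp in enumerate(self.species) if sp.metabolite == "aKG"]
        asps = [(i, sp.labels) for i, sp in enumerate(self.species) if sp.metabolite == "Asp"]
        for gi, g in glus:
            for oi, _ in oaas:
                akg, asp = _forward_products(g)
                don.append(gi); acc.append(oi)
                p1.append(idx[("aKG", akg)]); p2.append(idx[("Asp", asp)])
                k.append(self.k_fwd); is_fwd.append(True)
        for ai, a in akgs:
            for si, s in asps:
                glu, oaa = _reverse_products(a, s)
                don.append(si); acc.append(ai)
                p1.append(idx[("Glu", glu)]); p2.append(idx[("OAA", oaa)])
                k.append(self.k_rev); is_fwd.append(False)
        self._don = np.asarray(don, dtype=np.intp)
        self._acc = np.asarray(acc, dtype=np.intp)
        self._p1 = np.asarray(p1, dtype=np.intp)
        self._p2 = np.asarray(p2, dtype=np.intp)
        self._k = np.asarray(k, dtype=float)
        self._is_fwd = np.asarray(is_fwd, dtype=bool)

    # -- accessors ------------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_index(self, metabolite: str, labels: LabelSpec) -> int:
        try:
            return self._index[(metabolite, labels)]
        except KeyError:
            raise SimulationError(
                f"species {species_name(metabolite, labels)} not in system"
            ) from None

    def initial_concentrations(self) -> np.ndarray:
        return np.array([sp.concentration_uM for sp in self.species], dtype=float)

    def enzyme_at(self, t_hr: float) -> float:
        if self.inhibition_tau_hr is None or self.inhibition_tau_hr == 0:
            return self.enzyme_activity
        return self.enzyme_activity * math.exp(-t_hr / self.inhibition_tau_hr)

    def rhs(self, t_hr: float, y: np.ndarray) -> tuple[np.ndarray, float]:
        """Mass-action derivative and total forward (Glu -> aKG) flux."""
        e = self.enzyme_at(t_hr)
        flux = e * self._k * y[self._don] * y[self._acc]
        dy = np.zeros_like(y)
        np.add.at(dy, self._don, -flux)
        np.add.at(dy, self._acc, -flux)
        np.add.at(dy, self._p1, flux)
        np.add.at(dy, self._p2, flux)
        return dy, float(flux[self._is_fwd].sum())


@dataclass
class TimeCourse:
    """Isotopologue-resolved concentration trajectories plus ground truth.

    ``true_cycle_events_uM`` is the cumulative µM of Glu -> aKG
    transamination events at each time point — the hidden oracle against
    which label-based futile-cycle estimates are judged.
    """

    system: ReactionSystem
    t_hr: np.ndarray
    conc_uM: np.ndarray  # (n_species, n_t)
    true_cycle_events_uM: np.ndarray

    def concentration(self, metabolite: str, labels: LabelSpec = LabelSpec()) -> np.ndarray:
        return self.conc_uM[self.system.species_index(metabolite, labels)]

    def _total_with(self, predicate) -> np.ndarray:
        rows = [i for i, sp in enumerate(self.system.species) if predicate(sp)]
        if not rows:
            return np.zeros_like(self.t_hr)
        return self.conc_uM[rows].sum(axis=0)

    def total_13C5_skeletons(self) -> np.ndarray:
        """µM of intact ¹³C₅ skeletons (Glu + aKG pools); conserved."""
        return self._total_with(
            lambda sp: sp.labels.n_13C == 5 and sp.metabolite in ("Glu", "aKG")
        )

    def total_15N(self) -> np.ndarray:
        """µM of ¹⁵N label (Glu + Asp pools); conserved."""
        return self._total_with(lambda sp: sp.labels.n_15N == 1)

    def total_alpha_D(self) -> np.ndarray:
        """µM of α-position deuterium; non-increasing, constant when E=0."""
        return self._total_with(lambda sp: sp.labels.alpha_D)

    def at_time(self, t_hr: float) -> np.ndarray:
        """Linearly interpolated concentrations at an arbitrary time."""
        return np.array(
            [np.interp(t_hr, self.t_hr, row) for row in self.conc_uM]
        )


@dataclass
class SimulationConfig:
    """Study conditions for one simulated extract.

    Defaults emulate the dual-tracer resuspension experiment: 82 µM of
    doubly labeled [¹³C₅,¹⁵N]-glutamate and 82 µM of D₅-glutamate spiked
    into an extract with 82 µM endogenous unlabeled glutamate, a large
    endogenous aspartate pool (250 µM — the amine sink that lets ¹⁵N
    exchange out of glutamate), and a small (~1:100 vs glutamate) ketoacid
    pool, followed over 0–84 hr with 25 repeat injections. Rate constants
    are effective mass-action defaults calibrated once so the doubly
    labeled tracer is ~80–90% consumed by 24 h in the active scenario.
    """

    scenario: str = "active"
    seed: int = 0
    noise_cv: float = 0.05
    mass_error_ppm_sd: float = 1.0
    rt_jitter_sd_min: float = 0.02
    initial_uM: Mapping[str, float] = field(
        default_factory=lambda: {
            "Glu": 82.0,
            "Glu:13C5,15N": 82.0,
            "Glu:D5,alphaD": 82.0,
            "Asp": 250.0,
            "aKG": 2.5,
            "OAA": 2.5,
        }
    )
    k_fwd: float = 0.05  # µM⁻¹ hr⁻¹
    k_rev: float = 0.05
    inhibition_tau_hr: float = 0.01
    solver_step_hr: float = 0.01
    t_end_hr: float = 84.0
    n_injections: int = 25
    n_inert_features: int = 20
    inert_drift_ln_sd: float = 0.35
    area_scale: float = 1e4

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise SimulationError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if self.noise_cv < 0:
            raise SimulationError("noise CV must be non-negative")
        if self.solver_step_hr <= 0:
            raise SimulationError("solver step must be positive")


def build_transaminase_system(config: SimulationConfig) -> ReactionSystem:
    """Construct the isotopologue-expanded reaction system for a scenario."""
    species = [
        SpeciesState(*parse_species(name), concentration_uM=float(c))
        for name, c in config.initial_uM.items()
    ]
    system = ReactionSystem(
        species=species,
        k_fwd=config.k_fwd,
        k_rev=config.k_rev,
        enzyme_activity=1.0,
        inhibition_tau_hr=None,
        scenario="active",
    )
    return apply_intervention(system, config.scenario, config.inhibition_tau_hr)


def apply_intervention(
    system: ReactionSystem,
    scenario: str,
    inhibition_tau_hr: float = 0.01,
) -> ReactionSystem:
    """Return a copy of the system under an intervention scenario.

    ``active`` leaves the system unchanged; ``filtered`` (3 kDa protein
    removal) zeroes enzyme activity; ``aoa`` schedules exponential
    inhibition with time constant ``inhibition_tau_hr``.
    """
    if scenario not in SCENARIOS:
        raise SimulationError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if scenario == "active":
        e, tau = system.enzyme_activity, None
    elif scenario == "filtered":
        e, tau = 0.0, None
    else:  # aoa
        e, tau = system.enzyme_activity, float(inhibition_tau_hr)
    return ReactionSystem(
        species=list(system.species),
        k_fwd=system.k_fwd,
        k_rev=system.k_rev,
        enzyme_activity=e,
        inhibition_tau_hr=tau,
        scenario=scenario,
    )


def simulate_timecourse(
    system: ReactionSystem,
    t_grid_hr: Sequence[float],
    step_hr: float = 0.01,
) -> TimeCourse:
    """Integrate the mass-action ODEs with fixed-step RK4.

    ``t_grid_hr`` must be increasing and start at 0; within each grid
    interval the step is shrunk uniformly so that save points are hit
    exactly, keeping the result deterministic for a given step size.
    """
    t_grid = np.asarray(t_grid_hr, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 1 or t_grid[0] != 0.0:
        raise SimulationError("time grid must be 1-D, non-empty and start at 0")
    if t_grid.size > 1 and not np.all(np.diff(t_grid) > 0):
        raise SimulationError("time grid must be strictly increasing")

    y = system.initial_concentrations()
    events = 0.0
    conc = np.empty((system.n_species, t_grid.size))
    cum = np.empty(t_grid.size)
    conc[:, 0] = y
    cum[0] = 0.0

    def f(t, y):
        return system.rhs(t, y)

    for seg in range(1, t_grid.size):
        t0, t1 = t_grid[seg - 1], t_grid[seg]
        n_sub = max(1, int(math.ceil((t1 - t0) / step_hr - 1e-12)))
        h = (t1 - t0) / n_sub
        t = t0
        for _ in range(n_sub):
            k1, e1 = f(t, y)
            k2, e2 = f(t + h / 2, y + h / 2 * k1)
            k3, e3 = f(t + h / 2, y + h / 2 * k2)
            k4, e4 = f(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            events += h / 6 * (e1 + 2 * e2 + 2 * e3 + e4)
            t += h
            if np.any(y < -1e-9):
                raise SimulationError(
                    "concentration became negative during integration; "
                    "use a smaller solver step"
                )
        conc[:, seg] = y
        cum[seg] = events
    return TimeCourse(system=system, t_hr=t_grid, conc_uM=conc, true_cycle_events_uM=cum)


def label_based_cycle_estimate(tc: TimeCourse) -> float:
    """Futile-cycle turnover inferred from singly labeled glutamate (µM).

    Counts the [¹³C₅-only] and [¹⁵N-only] glutamate present at the end of
    the time course — what an observer sees from a dual-label tracer. By
    construction it never exceeds the true forward-event count: every
    singly labeled glutamate was made by one reverse event, and (with no
    initial aspartate) reverse events cannot outnumber forward events.
    Regenerated doubly labeled glutamate is invisible, so the estimate
    under-counts true cycling.
    """
    est = 0.0
    for labels in (LabelSpec(n_13C=5), LabelSpec(n_15N=1)):
        try:
            est += float(tc.concentration("Glu", labels)[-1])
        except SimulationError:
            pass
    return est


@dataclass
class InjectionSeries:
    """Repeat-injection feature table with per-feature ground-truth metadata.

    ``table`` is tidy (feature_id, mz, rt_min, injection_index, time_hr,
    area); ``feature_meta`` carries the true identity, theoretical m/z and
    response factor of every feature, including the inert (non-reacting)
    features added to emulate the rest of the metabolome.
    """

    injection_times_hr: np.ndarray
    table: pd.DataFrame
    feature_meta: pd.DataFrame
    seed: int
    scenario: str

    def wide(self) -> pd.DataFrame:
        """Features x injections peak-area matrix."""
        return self.table.pivot(index="feature_id", columns="injection_index", values="area")


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv**2))
    return np.exp(rng.normal(-sigma**2 / 2, sigma, size))


def observe_injection_series(tc: TimeCourse, config: SimulationConfig) -> InjectionSeries:
    """Apply the LC-MS observation model to a time course.

    Each species pool becomes a feature observed at ``n_injections``
    equally spaced injections: area = concentration x response factor x
    lognormal noise; m/z gets a Normal(0, sd) ppm error and RT a Gaussian
    jitter around the metabolite's canonical retention time. Inert features
    with constant true abundance are appended. Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    times = np.linspace(0.0, config.t_end_hr, config.n_injections)
    species = tc.system.species
    n_sp = len(species)
    n_inert = config.n_inert_features
    n_feat = n_sp + n_inert

    # ground truth concentration per feature per injection
    conc = np.empty((n_feat, times.size))
    for j, t in enumerate(times):
        conc[:n_sp, j] = tc.at_time(t)
    # Inert features are non-reacting metabolites. They still show a slow,
    # protein-independent monotone drift (solubilization kinetics, slow
    # oxidation) shared by every scenario, on top of injection noise.
    inert_levels = rng.lognormal(mean=math.log(50.0), sigma=0.8, size=n_inert)
    inert_drift = rng.normal(0.0, config.inert_drift_ln_sd, size=n_inert)
    frac = times / times[-1] if times[-1] > 0 else np.zeros_like(times)
    conc[n_sp:, :] = inert_levels[:, None] * np.exp(inert_drift[:, None] * frac[None, :])

    # response factors are per metabolite: isotopologues co-elute and ionize
    # identically, which is exactly what label-ratio quantitation relies on
    metab_rf = {
        m: rng.lognormal(mean=0.0, sigma=0.3)
        for m in sorted(METABOLITE_FORMULAS)
    }
    response = np.empty(n_feat)
    response[:n_sp] = [metab_rf[sp.metabolite] for sp in species]
    response[n_sp:] = rng.lognormal(mean=0.0, sigma=0.3, size=n_inert)
    ppm_err = rng.normal(0.0, config.mass_error_ppm_sd, size=n_feat)
    rt_jitter = rng.normal(0.0, config.rt_jitter_sd_min, size=n_feat)

    meta_rows = []
    neg = IonSpecies(Adduct.M_MINUS_H)
    for i, sp in enumerate(species):
        theo = ion_mz(METABOLITE_FORMULAS[sp.metabolite], sp.labels, neg)
        meta_rows.append(
            dict(
                feature_id=sp.name,
                metabolite=sp.metabolite,
                labels=sp.name.partition(":")[2],
                theoretical_mz=theo,
                mz=theo * (1 + ppm_err[i] * 1e-6),
                rt_min=_CANONICAL_RT_MIN[sp.metabolite] + rt_jitter[i],
                response_factor=response[i],
                is_inert=False,
            )
        )
    inert_mz = rng.uniform(100.0, 600.0, size=n_inert)
    inert_rt = rng.uniform(1.0, 15.0, size=n_inert)
    for k in range(n_inert):
        i = n_sp + k
        meta_rows.append(
            dict(
                feature_id=f"inert_{k:03d}",
                metabolite="",
                labels="",
                theoretical_mz=inert_mz[k],
                mz=inert_mz[k] * (1 + ppm_err[i] * 1e-6),
                rt_min=inert_rt[k] + rt_jitter[i],
                response_factor=response[i],
                is_inert=True,
            )
        )
    meta = pd.DataFrame(meta_rows)

    noise = _lognormal_factor(rng, config.noise_cv, (n_feat, times.size))
    areas = conc * response[:, None] * config.area_scale * noise

    records = []
    for i, row in meta.iterrows():
        for j, t in enumerate(times):
            records.append(
                dict(
                    feature_id=row.feature_id,
                    mz=row.mz,
                    rt_min=row.rt_min,
                    injection_index=j,
                    time_hr=t,
                    area=areas[i, j],
                )
            )
    table = pd.DataFrame(records)
    return InjectionSeries(
        injection_times_hr=times,
        table=table,
        feature_meta=meta,
        seed=config.seed,
        scenario=tc.system.scenario,
    )


GLUTATHIONE_FRAGMENT_MZ = 308.0912


def generate_ms2_fixtures(
    config: SimulationConfig,
    n_planted: int = 14,
    n_decoys: int = 50,
    fragment_mz: float = GLUTATHIONE_FRAGMENT_MZ,
    fragment_ppm_err: float = 2.0,
) -> list[MS2Record]:
    """MS2 spectra with ``n_planted`` precursors carrying a diagnostic
    fragment (within ``fragment_ppm_err`` ppm) plus fragment-free decoys.

    Planted precursors are spaced > 10 ppm apart so isobaric grouping at
    ±2 ppm resolves them as distinct hits; decoy fragment lists are kept
    at least 10 ppm away from the diagnostic m/z. Ground truth is stored in
    each record's ``meta["planted"]``.
    """
    rng = np.random.default_rng(config.seed + 7)
    records: list[MS2Record] = []

    # well-separated precursor m/z for the planted conjugates
    planted_mz: list[float] = []
    while len(planted_mz) < n_planted:
        cand = float(rng.uniform(330.0, 750.0))
        if all(abs(cand - m) / m > 10e-6 for m in planted_mz):
            planted_mz.append(cand)
    for i, pmz in enumerate(sorted(planted_mz)):
        n_frag = int(rng.integers(4, 9))
        frags = list(rng.uniform(60.0, pmz - 1.0, size=n_frag))
        err = float(rng.uniform(-fragment_ppm_err, fragment_ppm_err))
        frags.append(fragment_mz * (1 + err * 1e-6))
        frags = np.sort(frags)
        intens = rng.uniform(1e4, 1e6, size=frags.size)
        records.append(
            MS2Record(
                precursor_mz=pmz,
                rt_min=float(rng.uniform(2.0, 14.0)),
                fragments_mz=frags,
                fragments_intensity=intens,
                id=f"planted_{i:02d}",
                meta={"planted": True},
            )
        )
    for i in range(n_decoys):
        pmz = float(rng.uniform(150.0, 800.0))
        n_frag = int(rng.integers(3, 9))
        frags = []
        while len(frags) < n_frag:
            f = float(rng.uniform(60.0, pmz - 1.0))
            if abs(f - fragment_mz) / fragment_mz > 10e-6:
                frags.append(f)
        frags = np.sort(frags)
        intens = rng.uniform(1e4, 1e6, size=n_frag)
        records.append(
            MS2Record(
                precursor_mz=pmz,
                rt_min=float(rng.uniform(2.0, 14.0)),
                fragments_mz=frags,
                fragments_intensity=intens,
                id=f"decoy_{i:02d}",
                meta={"planted": False},
            )
        )
    return records
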