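"""Per-timestep colony dynamics: departures, feeding, returns, exchanges.

The simulation advances a colony of ``n_ants`` workers over ``n_steps``
one-second timesteps.  All ants start in the nest as non-foragers with an
empty crop.  Each step applies, in order:

1. ongoing trophallactic pairs transfer ``transfer_rate`` food units from
   donor to receiver (truncated if the donor empties, which ends the event),
   then separate with probability ``phi``;
2. each unpaired ant in the nest leaves for the food source with the
   crop-dependent probability alpha(Q); a first departure makes the ant a
   forager (permanently) and, under the TEC regime, resamples its
   trophallactic traits;
3. each ant at the source ingests ``intake_rate`` units and starts its
   return with probability ``beta``;
4. each unpaired nest ant, visited in random order, draws one uniformly
   random unpaired nest partner j; the encounter starts an exchange i -> j
   with probability theta_i(Q_i) * gamma_j(Q_j), or failing that j -> i with
   probability theta_j(Q_j) * gamma_i(Q_i).  A freshly formed pair makes its
   first transfer (and separation draw) in the same step, so an event
   lasting a single timestep moves exactly ``transfer_rate`` units.

The source is unlimited; food is conserved exactly: the summed crop load of
the colony always equals the total amount withdrawn from the source.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from trophallaxis.heterogeneity import (
    AlphaDistributionSpec,
    CasteRegime,
    RegimeKind,
    sample_alpha0,
    sample_trait,
)
from trophallaxis.model_core import (
    AntState,
    AntTraits,
    Caste,
    GlobalParams,
    Location,
    PairRole,
)

__all__ = [
    "SimulationConfig", "TrophallaxisEvent", "SimulationResult", "ColonyState",
    "init_colony", "step", "run_simulation", "run_ensemble",
]

_LOC_NEST, _LOC_SOURCE, _LOC_RETURNING = 0, 1, 2
_LOC_ENUM = {_LOC_NEST: Location.IN_NEST, _LOC_SOURCE: Location.AT_SOURCE,
             _LOC_RETURNING: Location.RETURNING}

EVENT_COLUMNS = [
    "donor_id", "receiver_id", "t_start", "t_end", "amount",
    "donor_caste_at_start", "receiver_caste_at_start",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one simulation (besides the seed)."""

    params: GlobalParams = field(default_factory=GlobalParams)
    regime: CasteRegime = None  # type: ignore[assignment]
    alpha_spec: AlphaDistributionSpec = field(default_factory=AlphaDistributionSpec)
    k: float = 120.0
    n: float = 2.0
    record_trajectory: bool = False
    trajectory_interval: int = 60
    pairing_before_departures: bool = False  # phase-order sensitivity switch

    def __post_init__(self) -> None:
        if self.regime is None:
            raise ValueError("SimulationConfig requires a CasteRegime")
        if self.k <= 0 or self.n <= 0:
            raise ValueError("k and n must be positive")
        if self.trajectory_interval < 1:
            raise ValueError("trajectory_interval must be >= 1")

    def to_dict(self) -> dict:
        from trophallaxis.config import config_to_dict
        return config_to_dict(self)


@dataclass
class TrophallaxisEvent:
    """One directed food exchange, from formation to separation (inclusive)."""

    donor_id: int
    receiver_id: int
    t_start: int
    t_end: int
    amount: float
    donor_caste_at_start: Caste
    receiver_caste_at_start: Caste

    @property
    def duration(self) -> int:
        return self.t_end - self.t_start + 1


class ColonyState:
    """Array-backed state of the whole colony at one timestep."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        n = config.params.n_ants
        regime, aspec = config.regime, config.alpha_spec
        self.config = config
        self.t = 0
        self.crop = np.zeros(n)
        self.loc = np.zeros(n, dtype=np.int8)
        self.is_forager = np.zeros(n, dtype=bool)
        self.theta0 = np.asarray(sample_trait(regime.theta_nf, rng, size=n))
        self.gamma0 = np.asarray(sample_trait(regime.gamma_nf, rng, size=n))
        self.alpha0 = np.asarray(sample_alpha0(aspec, rng, size=n))
        self.alpha_max = self.alpha0.copy()
        self.partner = np.full(n, -1, dtype=np.int64)
        self.is_donor = np.zeros(n, dtype=bool)
        self.return_timer = np.zeros(n, dtype=np.int64)
        self.source_streak = np.zeros(n, dtype=np.int64)      # current consecutive steps feeding
        self.max_source_streak = np.zeros(n, dtype=np.int64)  # longest feeding bout ever
        self.total_withdrawn = 0.0
        self._kn = float(config.k) ** float(config.n)
        self.first_visit_time: dict[int, int] = {}
        self.events: list[TrophallaxisEvent] = []
        self._active: dict[int, TrophallaxisEvent] = {}  # donor id -> open event

    # -- views ------------------------------------------------------------
    def ant_state(self, i: int) -> AntState:
        """Object view of one ant (for inspection; the arrays are authoritative)."""
        traits = AntTraits(
            theta0=float(self.theta0[i]), gamma0=float(self.gamma0[i]),
            alpha0=float(self.alpha0[i]),
            alpha0_forager=float(min(1.0, self.alpha0[i] * self.config.alpha_spec.forager_multiplier)),
            k=self.config.k, n=self.config.n,
        )
        partner = int(self.partner[i])
        return AntState(
            id=i, traits=traits, location=_LOC_ENUM[int(self.loc[i])],
            caste=Caste.F if self.is_forager[i] else Caste.NF,
            crop=float(self.crop[i]),
            pair_partner=None if partner < 0 else partner,
            pair_role=None if partner < 0 else (PairRole.DONOR if self.is_donor[i] else PairRole.RECEIVER),
        )

    def validate(self) -> None:
        """Assert the structural invariants (used by tests and --validate runs)."""
        assert np.all(self.crop >= 0), "negative crop"
        total = self.crop.sum()
        assert total == self.total_withdrawn, (
            f"food not conserved: crops sum to {total}, withdrawn {self.total_withdrawn}"
        )
        paired = np.flatnonzero(self.partner >= 0)
        for i in paired:
            j = self.partner[i]
            assert self.partner[j] == i, "pairing is not a symmetric matching"
            assert self.loc[i] == _LOC_NEST, "paired ant outside the nest"
            assert self.is_donor[i] != self.is_donor[j], "pair without one donor and one receiver"


def init_colony(config: SimulationConfig, rng: np.random.Generator) -> ColonyState:
    return ColonyState(config, rng)


def _promote(state: ColonyState, ants: np.ndarray, rng: np.random.Generator) -> None:
    """First source visit: absorbing caste flip, alpha boost, TEC trait resampling."""
    cfg = state.config
    state.is_forager[ants] = True
    for i in ants:
        state.first_visit_time[int(i)] = state.t
    state.alpha_max[ants] = np.minimum(
        1.0, state.alpha0[ants] * cfg.alpha_spec.forager_multiplier
    )
    if cfg.regime.kind is RegimeKind.TEC:
        k = len(ants)
        state.theta0[ants] = sample_trait(cfg.regime.theta_f, rng, size=k)
        state.gamma0[ants] = sample_trait(cfg.regime.gamma_f, rng, size=k)


def _transfer_and_maybe_separate(state: ColonyState, donor: int, rng: np.random.Generator) -> None:
    """One timestep of an ongoing event: move food, then test separation."""
    p = state.config.params
    recv = int(state.partner[donor])
    amt = min(p.transfer_rate, state.crop[donor])
    state.crop[donor] -= amt
    state.crop[recv] += amt
    ev = state._active[donor]
    ev.amount += amt
    if state.crop[donor] <= 0 or rng.random() < p.phi:
        ev.t_end = state.t
        state.events.append(ev)
        del state._active[donor]
        state.partner[donor] = -1
        state.partner[recv] = -1
        state.is_donor[donor] = False


def _phase_transfers(state: ColonyState, rng: np.random.Generator) -> None:
    for donor in list(state._active):
        _transfer_and_maybe_separate(state, donor, rng)


def _phase_departures(state: ColonyState, rng: np.random.Generator) -> None:
    cfg = state.config
    candidates = np.flatnonzero((state.loc == _LOC_NEST) & (state.partner < 0))
    if candidates.size == 0:
        return
    kn = state._kn
    alpha = state.alpha_max[candidates] * (kn / (kn + state.crop[candidates] ** cfg.n))
    leaving = candidates[rng.random(candidates.size) < alpha]
    if leaving.size == 0:
        return
    state.loc[leaving] = _LOC_SOURCE
    first = leaving[~state.is_forager[leaving]]
    if first.size:
        _promote(state, first, rng)


def _phase_source(state: ColonyState, rng: np.random.Generator) -> None:
    p = state.config.params
    if p.return_delay:  # ants in transit home
        returning = np.flatnonzero(state.loc == _LOC_RETURNING)
        if returning.size:
            state.return_timer[returning] -= 1
            arrived = returning[state.return_timer[returning] <= 0]
            state.loc[arrived] = _LOC_NEST
    at_source = np.flatnonzero(state.loc == _LOC_SOURCE)
    if at_source.size == 0:
        return
    state.crop[at_source] += p.intake_rate
    state.total_withdrawn += p.intake_rate * at_source.size
    state.source_streak[at_source] += 1
    state.max_source_streak[at_source] = np.maximum(
        state.max_source_streak[at_source], state.source_streak[at_source])
    done = at_source[rng.random(at_source.size) < p.beta]
    if done.size:
        state.source_streak[done] = 0
        if p.return_delay == 0:
            state.loc[done] = _LOC_NEST
        else:
            state.loc[done] = _LOC_RETURNING
            state.return_timer[done] = p.return_delay


def _phase_pairing(state: ColonyState, rng: np.random.Generator) -> None:
    """Random-encounter pair formation.

    Every unpaired nest ant, in uniformly random order, draws one uniformly
    random unpaired nest partner j.  The encounter of initiator i with j
    starts an exchange i -> j with probability theta_i(Q_i) * gamma_j(Q_j)
    or, failing that, an exchange j -> i with probability
    theta_j(Q_j) * gamma_i(Q_i): every nest ant can engage either as donor
    or as receiver, and the pair forms with the product of the two
    individual probabilities.  At most one attempt per initiator per step.

    Implementation note: the acceptance uniform of each initiator is
    pre-drawn and initiators whose uniform already exceeds the bound
    theta_i * max(gamma) + gamma_i * max(theta) are rejected without a
    partner draw -- an exact thinning, valid because the crop of an ant
    still in the pairing pool cannot change within the phase (a formed pair
    leaves the pool immediately).
    """
    cfg = state.config
    n = cfg.n
    kn = state._kn
    available = (state.loc == _LOC_NEST) & (state.partner < 0)
    pool = np.flatnonzero(available)
    if pool.size < 2:
        return
    qn = state.crop[pool] ** n
    denom = kn + qn
    theta_p = state.theta0[pool] * (qn / denom)   # realized donor probabilities
    gamma_p = state.gamma0[pool] * (kn / denom)   # realized receiver probabilities
    u = rng.random(pool.size)
    potential = np.flatnonzero(u < theta_p * gamma_p.max() + gamma_p * theta_p.max())
    if potential.size == 0:
        return
    theta_full = np.zeros(state.crop.size)
    gamma_full = np.zeros(state.crop.size)
    theta_full[pool] = theta_p
    gamma_full[pool] = gamma_p
    avail = available.copy()
    for idx in rng.permutation(potential):
        i = int(pool[idx])
        if not avail[i]:
            continue
        others = np.flatnonzero(avail)
        others = others[others != i]
        if others.size == 0:
            break
        j = int(others[rng.integers(others.size)])
        forward = theta_full[i] * gamma_full[j]           # i donates to j
        backward = theta_full[j] * gamma_full[i]          # j donates to i
        if u[idx] < forward:
            donor, recv = i, j
        elif u[idx] < forward + (1.0 - forward) * backward:
            donor, recv = j, i
        else:
            continue
        avail[i] = avail[j] = False
        state.partner[donor] = recv
        state.partner[recv] = donor
        state.is_donor[donor] = True
        state._active[donor] = TrophallaxisEvent(
            donor_id=donor, receiver_id=recv, t_start=state.t, t_end=state.t,
            amount=0.0,
            donor_caste_at_start=Caste.F if state.is_forager[donor] else Caste.NF,
            receiver_caste_at_start=Caste.F if state.is_forager[recv] else Caste.NF,
        )
        # first transfer (and separation draw) happens in the formation step
        _transfer_and_maybe_separate(state, donor, rng)


def step(state: ColonyState, params: GlobalParams, rng: np.random.Generator) -> ColonyState:
    """Advance the colony by one timestep (mutates and returns ``state``).

    ``params`` must be the state's configured :class:`GlobalParams`; it is
    accepted explicitly to make the update signature self-describing.
    """
    if params is not state.config.params and params != state.config.params:
        raise ValueError("params must match the colony's configuration")
    state.t += 1
    _phase_transfers(state, rng)
    if state.config.pairing_before_departures:
        _phase_pairing(state, rng)
        _phase_departures(state, rng)
        _phase_source(state, rng)
    else:
        _phase_departures(state, rng)
        _phase_source(state, rng)
        _phase_pairing(state, rng)
    return state


@dataclass
class SimulationResult:
    """Event log and per-ant outcomes of one seeded simulation."""

    events: list[TrophallaxisEvent]
    forager_ids: frozenset[int]
    first_visit_times: dict[int, int]
    final_crop: np.ndarray
    n_ants: int
    seed: int
    config: SimulationConfig
    crop_trajectory: Optional[pd.DataFrame] = None
    max_source_streak: Optional[np.ndarray] = None

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def n_foragers(self) -> int:
        return len(self.forager_ids)

    def events_dataframe(self) -> pd.DataFrame:
        rows = [
            (e.donor_id, e.receiver_id, e.t_start, e.t_end, e.amount,
             e.donor_caste_at_start.value, e.receiver_caste_at_start.value)
            for e in self.events
        ]
        return pd.DataFrame(rows, columns=EVENT_COLUMNS)

    def caste_labels(self) -> dict[int, Caste]:
        """Final caste of every colony member (forager status is absorbing)."""
        return {i: (Caste.F if i in self.forager_ids else Caste.NF)
                for i in range(self.n_ants)}


def run_simulation(config: SimulationConfig, seed: int, validate: bool = False) -> SimulationResult:
    """Run one simulation; deterministic and replayable given (config, seed)."""
    rng = np.random.default_rng(seed)
    state = init_colony(config, rng)
    params = config.params
    traj_rows = [] if config.record_trajectory else None
    for _ in range(params.n_steps):
        step(state, params, rng)
        if validate:
            state.validate()
        if traj_rows is not None and state.t % config.trajectory_interval == 0:
            traj_rows.append((state.t, *state.crop))
    # events still open at the horizon are closed as censored at n_steps
    for donor in list(state._active):
        ev = state._active.pop(donor)
        ev.t_end = state.t
        state.events.append(ev)
    trajectory = None
    if traj_rows is not None:
        trajectory = pd.DataFrame(
            traj_rows, columns=["t"] + [f"ant_{i}" for i in range(params.n_ants)]
        ).set_index("t")
    return SimulationResult(
        events=sorted(state.events, key=lambda e: (e.t_start, e.donor_id)),
        forager_ids=frozenset(state.first_visit_time),
        first_visit_times=dict(state.first_visit_time),
        final_crop=state.crop.copy(),
        n_ants=params.n_ants,
        seed=seed,
        config=config,
        crop_trajectory=trajectory,
        max_source_streak=state.max_source_streak.copy(),
    )


def run_ensemble(config: SimulationConfig, n_reps: int, base_seed: int,
                 validate: bool = False):
    """Run ``n_reps`` replicate simulations with per-rep seeds base_seed + rep.

    Returns ``(results, summary)`` where ``summary`` is an
    :class:`~trophallaxis.compare.EnsembleSummary` with per-rep statistics
    and their ensemble means/SDs.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    from trophallaxis.compare import summarize_ensemble
    results = [run_simulation(config, base_seed + rep, validate=validate)
               for rep in range(n_reps)]
    return results, summarize_ensemble(results)
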