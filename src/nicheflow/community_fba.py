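"""Shared-environment community models and MILP exchange enumeration.

Individual species models are combined into a community in which every member
interacts with a common environment pool through its exchange reactions: each
species can secrete into the pool and take up from it, the pool is fed from
outside according to a medium definition, and unconsumed secretions drain to
waste. Inter-species transfers are explicit non-negative variables
``v[met, donor, receiver]`` so that donor/receiver attribution is read
directly off a certifying flux distribution.

Exchange-set enumeration follows the mixed-integer scheme used for community
interaction analysis: the growth of every member is imposed as a lower-bound
constraint (no growth objective is optimized), each candidate transfer flux
``v`` is linked to a binary indicator ``y`` via ``v <= M*y``, total indicator
count is minimized, and previously found active sets are excluded with
integer cuts until the problem becomes infeasible or a solution cap is hit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .model_io import MediumDefinition, Reaction, SpeciesModel

__all__ = [
    "CommunityModel",
    "FluxSolution",
    "ExchangeSolution",
    "EnumerationResult",
    "build_community",
    "curate_auxotrophies",
    "apply_medium",
    "solve_fba",
    "member_growth_feasible",
    "enumerate_exchange_sets",
    "brute_force_exchange_sets",
    "summarize_exchanges",
    "UnboundedObjectiveError",
]

BIG_M = 1000.0
ACTIVITY_THRESHOLD = 1e-6
DEFAULT_MU_MIN = 0.01


class UnboundedObjectiveError(RuntimeError):
    """The FBA objective is unbounded under the given constraints."""


@dataclass
class FluxSolution:
    status: str  # optimal | feasible | infeasible
    fluxes: dict[str, float]
    objective: float | None = None

    @property
    def feasible(self) -> bool:
        return self.status != "infeasible"


@dataclass(frozen=True)
class Transfer:
    metabolite: str
    donor: str
    receiver: str

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.metabolite, self.donor, self.receiver)


@dataclass
class ExchangeSolution:
    """One enumerated exchange configuration supporting all-member growth."""

    transfers: frozenset[tuple[str, str, str]]
    transfer_fluxes: dict[tuple[str, str, str], float]
    member_growths: dict[str, float]
    is_minimal: bool | None = None


class EnumerationResult(list):
    """List of :class:`ExchangeSolution` with a community feasibility flag."""

    def __init__(self, solutions=(), community_feasible: bool = True):
        super().__init__(solutions)
        self.community_feasible = community_feasible


# ---------------------------------------------------------------------------
# single-species FBA


def apply_medium(model: SpeciesModel, medium: MediumDefinition) -> SpeciesModel:
    """Restrict exchange-reaction uptake bounds to the medium caps."""
    new = model.copy()
    ex_ids = set(new.exchange_reaction_ids)
    reactions = []
    for r in new.reactions:
        if r.id in ex_ids:
            met = next(iter(r.stoichiometry))
            cap = medium.cap(met)
            reactions.append(r.with_bounds(max(r.lb, -cap), r.ub))
        else:
            reactions.append(r)
    new.reactions = reactions
    return new


def _species_matrix(model: SpeciesModel):
    mets = sorted({m for r in model.reactions for m in r.stoichiometry})
    met_idx = {m: i for i, m in enumerate(mets)}
    rows, cols, vals = [], [], []
    for j, r in enumerate(model.reactions):
        for m, c in r.stoichiometry.items():
            rows.append(met_idx[m])
            cols.append(j)
            vals.append(c)
    S = sp.csr_matrix((vals, (rows, cols)), shape=(len(mets), len(model.reactions)))
    lb = np.array([r.lb for r in model.reactions])
    ub = np.array([r.ub for r in model.reactions])
    return S, lb, ub


def solve_fba(
    model: SpeciesModel,
    objective_reaction: str | None = None,
    medium: MediumDefinition | None = None,
) -> FluxSolution:
    """Maximize a reaction flux at steady state (S·v = 0, lb ≤ v ≤ ub).

    Raises :class:`UnboundedObjectiveError` if the optimum is unbounded
    rather than returning a silently large value.
    """
    if medium is not None:
        model = apply_medium(model, medium)
    if objective_reaction is None:
        objective_reaction = model.biomass_reaction_id
    rids = model.reaction_ids
    if objective_reaction not in rids:
        raise KeyError(f"objective reaction {objective_reaction!r} not in model")
    S, lb, ub = _species_matrix(model)
    c = np.zeros(len(rids))
    c[rids.index(objective_reaction)] = -1.0  # linprog minimizes
    res = linprog(
        c, A_eq=S, b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)), method="highs",
    )
    if res.status == 3:
        raise UnboundedObjectiveError(
            f"objective {objective_reaction!r} is unbounded; check exchange bounds"
        )
    if res.status != 0:
        return FluxSolution(status="infeasible", fluxes={})
    return FluxSolution(
        status="optimal",
        fluxes=dict(zip(rids, res.x)),
        objective=-res.fun,
    )


# ---------------------------------------------------------------------------
# auxotrophy curation


def curate_auxotrophies(
    model: SpeciesModel,
    add_uptakes: list[str] = (),
    add_reactions: list[Reaction] = (),
    block_reactions: list[str] = (),
) -> SpeciesModel:
    """Return a curated copy: new uptake routes, extra reactions, blocked ids.

    ``add_uptakes`` lists bare metabolite names; for each, an exchange
    reaction on ``<met>_e`` plus a reversible transporter to ``<met>_c`` is
    appended (created only if not already present). ``block_reactions`` are
    forced to zero flux (lb = ub = 0). The input model is left untouched.
    """
    existing = set(model.reaction_ids)
    missing = [rid for rid in block_reactions if rid not in existing]
    if missing:
        raise KeyError(f"cannot block unknown reactions: {missing}")
    new = model.copy()
    for met in add_uptakes:
        ex_id, tr_id = f"EX_{met}", f"T_{met}"
        if ex_id not in existing:
            new.reactions.append(
                Reaction(ex_id, {f"{met}_e": -1.0}, lb=-1000.0, ub=1000.0)
            )
        if tr_id not in existing:
            new.reactions.append(
                Reaction(tr_id, {f"{met}_e": -1.0, f"{met}_c": 1.0}, lb=-1000.0, ub=1000.0)
            )
        existing.update((ex_id, tr_id))
    for r in add_reactions:
        new.reactions.append(r)
    blocked = set(block_reactions)
    new.reactions = [
        r.with_bounds(0.0, 0.0) if r.id in blocked else r for r in new.reactions
    ]
    new.metabolites = {m for r in new.reactions for m in r.stoichiometry}
    return new


# ---------------------------------------------------------------------------
# community construction


@dataclass
class CommunityModel:
    """Members coupled through a shared environment pool under a medium.

    Internal (and species-extracellular) metabolites are namespaced
    ``species:met`` so they are never shared; the only coupling is through
    pair-transfer variables, medium import, and waste export attached to
    each member's exchange reactions.
    """

    members: list[SpeciesModel]
    medium: MediumDefinition
    mu_min: float = DEFAULT_MU_MIN
    big_m: float = BIG_M

    # derived (filled by __post_init__)
    pool_metabolites: list[str] = field(default_factory=list, repr=False)
    pair_candidates: list[tuple[str, str, str]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        ids = [m.species_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate species ids: {sorted(ids)}")
        # order-insensitive construction
        self.members = sorted(self.members, key=lambda m: m.species_id)
        secrete: dict[str, set[str]] = {}
        uptake: dict[str, set[str]] = {}
        pool: set[str] = set(self.medium.entries)
        for mem in self.members:
            for rid in mem.exchange_reaction_ids:
                r = mem.reaction(rid)
                met = next(iter(r.stoichiometry))
                pool.add(met)
                if r.ub > 0:
                    secrete.setdefault(met, set()).add(mem.species_id)
                if r.lb < 0:
                    uptake.setdefault(met, set()).add(mem.species_id)
        self.pool_metabolites = sorted(pool)
        self.pair_candidates = sorted(
            (met, d, r)
            for met in pool
            for d in secrete.get(met, ())
            for r in uptake.get(met, ())
            if d != r
        )
        self._build_lp()

    # ---------------- LP assembly ----------------

    def _build_lp(self) -> None:
        names: list[str] = []
        lb: list[float] = []
        ub: list[float] = []

        def add_var(name, lo, hi):
            names.append(name)
            lb.append(lo)
            ub.append(hi)
            return len(names) - 1

        self.rx_idx: dict[tuple[str, str], int] = {}
        self.biomass_idx: dict[str, int] = {}
        exch: dict[tuple[str, str], list[int]] = {}  # (species, met) -> EX var idx
        for mem in self.members:
            ex_ids = set(mem.exchange_reaction_ids)
            for r in mem.reactions:
                j = add_var(f"{mem.species_id}:{r.id}", r.lb, r.ub)
                self.rx_idx[(mem.species_id, r.id)] = j
                if r.id in ex_ids:
                    met = next(iter(r.stoichiometry))
                    exch.setdefault((mem.species_id, met), []).append(j)
            self.biomass_idx[mem.species_id] = self.rx_idx[
                (mem.species_id, mem.biomass_reaction_id)
            ]

        self.med_idx: dict[tuple[str, str], int] = {}
        self.out_idx: dict[tuple[str, str], int] = {}
        for (species, met) in sorted(exch):
            if met in self.medium and self.medium.cap(met) > 0:
                self.med_idx[(species, met)] = add_var(
                    f"med[{species},{met}]", 0.0, self.medium.cap(met)
                )
            self.out_idx[(species, met)] = add_var(
                f"out[{species},{met}]", 0.0, np.inf
            )
        self.pair_idx: dict[tuple[str, str, str], int] = {}
        for cand in self.pair_candidates:
            met, d, r = cand
            self.pair_idx[cand] = add_var(f"pair[{met},{d}->{r}]", 0.0, self.big_m)

        self.var_names = names
        self.var_lb = np.array(lb)
        self.var_ub = np.array(ub)
        n = len(names)

        eq_rows: list[dict[int, float]] = []
        # species-internal steady state over namespaced metabolites
        for mem in self.members:
            met_rows: dict[str, dict[int, float]] = {}
            for r in mem.reactions:
                j = self.rx_idx[(mem.species_id, r.id)]
                for met, coef in r.stoichiometry.items():
                    met_rows.setdefault(met, {})[j] = (
                        met_rows.setdefault(met, {}).get(j, 0.0) + coef
                    )
            for met in sorted(met_rows):
                eq_rows.append(met_rows[met])
        # exchange routing: EX = out + pairs_out - med - pairs_in
        for (species, met), ex_vars in sorted(exch.items()):
            row: dict[int, float] = {j: 1.0 for j in ex_vars}
            row[self.out_idx[(species, met)]] = -1.0
            if (species, met) in self.med_idx:
                row[self.med_idx[(species, met)]] = 1.0
            for cand, k in self.pair_idx.items():
                cmet, d, r = cand
                if cmet != met:
                    continue
                if d == species:
                    row[k] = row.get(k, 0.0) - 1.0
                if r == species:
                    row[k] = row.get(k, 0.0) + 1.0
            eq_rows.append(row)

        ub_rows: list[dict[int, float]] = []
        ub_rhs: list[float] = []
        # shared medium caps
        for met in self.pool_metabolites:
            if met not in self.medium or self.medium.cap(met) <= 0:
                continue
            row = {
                j: 1.0
                for (s, m), j in self.med_idx.items()
                if m == met
            }
            if row:
                ub_rows.append(row)
                ub_rhs.append(self.medium.cap(met))

        def to_sparse(rows):
            ri, ci, vals = [], [], []
            for i, row in enumerate(rows):
                for j, v in row.items():
                    ri.append(i)
                    ci.append(j)
                    vals.append(v)
            return sp.csr_matrix((vals, (ri, ci)), shape=(len(rows), n))

        self.A_eq = to_sparse(eq_rows)
        self.b_eq = np.zeros(len(eq_rows))
        self.A_ub = to_sparse(ub_rows)
        self.b_ub = np.array(ub_rhs)

    # ---------------- solving ----------------

    def _bounds(
        self,
        growth_lbs: dict[str, float] | None,
        allowed_pairs=None,
    ):
        lo, hi = self.var_lb.copy(), self.var_ub.copy()
        if growth_lbs:
            for species, mu in growth_lbs.items():
                j = self.biomass_idx[species]
                lo[j] = max(lo[j], mu)
        if allowed_pairs is not None:
            allowed = set(allowed_pairs)
            for cand, k in self.pair_idx.items():
                if cand not in allowed:
                    hi[k] = 0.0
        return lo, hi

    def solve(
        self,
        growth_lbs: dict[str, float] | None = None,
        allowed_pairs=None,
        objective: np.ndarray | None = None,
    ) -> FluxSolution:
        """Feasibility LP (or minimize ``objective``·v) under growth bounds."""
        lo, hi = self._bounds(growth_lbs, allowed_pairs)
        c = np.zeros(len(self.var_names)) if objective is None else objective
        res = linprog(
            c, A_ub=self.A_ub, b_ub=self.b_ub, A_eq=self.A_eq, b_eq=self.b_eq,
            bounds=list(zip(lo, hi)), method="highs",
        )
        if res.status != 0:
            return FluxSolution(status="infeasible", fluxes={})
        return FluxSolution(
            status="feasible" if objective is None else "optimal",
            fluxes=dict(zip(self.var_names, res.x)),
            objective=res.fun if objective is not None else None,
        )

    def member_ids(self) -> list[str]:
        return [m.species_id for m in self.members]


def build_community(
    models: list[SpeciesModel],
    medium: MediumDefinition,
    mu_min: float = DEFAULT_MU_MIN,
) -> CommunityModel:
    if not models:
        raise ValueError("need at least one species model")
    return CommunityModel(members=[m.copy() for m in models], medium=medium, mu_min=mu_min)


def member_growth_feasible(
    community: CommunityModel, member: str, mu_min: float | None = None
) -> bool:
    """True iff a community flux distribution gives ``member`` growth ≥ mu_min.

    Other members are left unconstrained (they may grow or not).
    """
    if member not in community.member_ids():
        raise KeyError(f"{member!r} not in community {community.member_ids()}")
    mu = community.mu_min if mu_min is None else mu_min
    return community.solve(growth_lbs={member: mu}).feasible


# ---------------------------------------------------------------------------
# exchange enumeration


def _active_pairs(community: CommunityModel, fluxes: dict[str, float]):
    out = {}
    for cand, k in community.pair_idx.items():
        v = fluxes[community.var_names[k]]
        if v > ACTIVITY_THRESHOLD:
            out[cand] = v
    return out


def _solution_from_fluxes(community, fluxes, is_minimal=None) -> ExchangeSolution:
    active = _active_pairs(community, fluxes)
    growths = {
        s: fluxes[community.var_names[j]] for s, j in community.biomass_idx.items()
    }
    return ExchangeSolution(
        transfers=frozenset(active),
        transfer_fluxes=dict(sorted(active.items())),
        member_growths=growths,
        is_minimal=is_minimal,
    )


def _is_subset_minimal(community, active, growth_lbs) -> bool:
    # feasibility is monotone in the allowed-pair set, so testing every
    # single-element deletion suffices
    for t in active:
        sub = set(active) - {t}
        if community.solve(growth_lbs=growth_lbs, allowed_pairs=sub).feasible:
            return False
    return True


def enumerate_exchange_sets(
    community: CommunityModel,
    mu_min: float | None = None,
    max_solutions: int = 100,
    minimal_only: bool = True,
) -> EnumerationResult:
    """Enumerate inter-species transfer sets supporting all-member growth.

    Solves a sequence of MILPs: binaries gate each candidate transfer
    (``v ≤ M·y``), every member's growth is constrained to at least
    ``mu_min``, the number of open transfers is minimized (no growth
    optimality is assumed), and each found active set is excluded by an
    integer cut before re-solving. With ``minimal_only`` the returned sets
    are certified subset-minimal by LP deletion checks; non-minimal sets
    discovered later in the sequence are cut away without being reported.
    """
    if max_solutions < 1:
        raise ValueError("max_solutions must be >= 1")
    mu = community.mu_min if mu_min is None else mu_min
    growth_lbs = {s: mu for s in community.member_ids()}

    if not community.solve(growth_lbs=growth_lbs).feasible:
        return EnumerationResult([], community_feasible=False)

    n_cont = len(community.var_names)
    pairs = community.pair_candidates
    n_pairs = len(pairs)
    if n_pairs == 0:
        sol = community.solve(growth_lbs=growth_lbs)
        return EnumerationResult(
            [_solution_from_fluxes(community, sol.fluxes, is_minimal=True)],
            community_feasible=True,
        )

    n = n_cont + n_pairs
    lo, hi = community._bounds(growth_lbs, None)
    # v - M*y <= 0 rows
    link_ri, link_ci, link_v = [], [], []
    for i, cand in enumerate(pairs):
        k = community.pair_idx[cand]
        link_ri += [i, i]
        link_ci += [k, n_cont + i]
        link_v += [1.0, -community.big_m]
    A_link = sp.csr_matrix((link_v, (link_ri, link_ci)), shape=(n_pairs, n))

    def pad(A):
        if A.shape[0] == 0:
            return sp.csr_matrix((0, n))
        return sp.hstack([A, sp.csr_matrix((A.shape[0], n_pairs))]).tocsr()

    base_constraints = [
        LinearConstraint(pad(community.A_eq), community.b_eq, community.b_eq),
        LinearConstraint(A_link, -np.inf, np.zeros(n_pairs)),
    ]
    if community.A_ub.shape[0]:
        base_constraints.append(
            LinearConstraint(pad(community.A_ub), -np.inf, community.b_ub)
        )

    c = np.zeros(n)
    c[n_cont:] = 1.0
    integrality = np.zeros(n)
    integrality[n_cont:] = 1
    var_lo = np.concatenate([lo, np.zeros(n_pairs)])
    var_hi = np.concatenate([hi, np.ones(n_pairs)])

    cuts: list[LinearConstraint] = []
    solutions: list[ExchangeSolution] = []
    while len(solutions) < max_solutions:
        res = milp(
            c,
            constraints=base_constraints + cuts,
            integrality=integrality,
            bounds=Bounds(var_lo, var_hi),
        )
        if res.status != 0 or res.x is None:
            break
        fluxes = dict(zip(community.var_names, res.x[:n_cont]))
        active = sorted(_active_pairs(community, fluxes))
        minimal = _is_subset_minimal(community, active, growth_lbs)
        if not minimal_only or minimal:
            solutions.append(
                _solution_from_fluxes(community, fluxes, is_minimal=minimal)
            )
        # exclude this active set (and, under minimization, its supersets)
        row = np.zeros(n)
        if active:
            for cand in active:
                row[n_cont + pairs.index(cand)] = 1.0
            cuts.append(LinearConstraint(row, -np.inf, len(active) - 1))
        else:
            break  # empty set found; nothing smaller exists
    return EnumerationResult(solutions, community_feasible=True)


def brute_force_exchange_sets(
    community: CommunityModel,
    mu_min: float | None = None,
    max_candidates: int = 12,
) -> tuple[list[frozenset], list[frozenset]]:
    """Exhaustive LP feasibility over all transfer subsets (oracle-grade).

    Returns ``(feasible_sets, minimal_sets)`` over the 2^k subsets of pair
    candidates. Only intended for toy instances (k ≤ ``max_candidates``).
    """
    pairs = community.pair_candidates
    if len(pairs) > max_candidates:
        raise ValueError(
            f"{len(pairs)} transfer candidates exceed brute-force cap {max_candidates}"
        )
    mu = community.mu_min if mu_min is None else mu_min
    growth_lbs = {s: mu for s in community.member_ids()}
    feasible: list[frozenset] = []
    for k in range(len(pairs) + 1):
        for combo in itertools.combinations(pairs, k):
            S = frozenset(combo)
            if any(f <= S for f in feasible):
                feasible.append(S)  # monotone: superset of feasible is feasible
                continue
            if community.solve(growth_lbs=growth_lbs, allowed_pairs=S).feasible:
                feasible.append(S)
    minimal = [S for S in feasible if not any(f < S for f in feasible)]
    return feasible, minimal


def summarize_exchanges(solutions) -> pd.DataFrame:
    """Per-transfer frequency across enumerated solutions."""
    cols = ["metabolite", "donor", "receiver", "fraction"]
    if len(solutions) == 0:
        return pd.DataFrame(columns=cols)
    counts: dict[tuple[str, str, str], int] = {}
    for sol in solutions:
        for t in sol.transfers:
            counts[t] = counts.get(t, 0) + 1
    rows = [
        {"metabolite": m, "donor": d, "receiver": r, "fraction": c / len(solutions)}
        for (m, d, r), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=cols)
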