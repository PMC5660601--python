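"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the data classes the analysis consumes:

* **exo-metabolome ion tables** — one intensity series per ion over a yeast
  conditioning phase and a bacterial growth phase, drawn from four profile
  archetypes (bell, accumulating, depleting, flat) under multiplicative
  log-normal noise;
* **toy cross-feeding communities** — 2–3 species stoichiometric models with
  designed obligate metabolite exchanges, certified by exhaustive
  feasibility search before being returned;
* **regulation datasets** — expression matrices across a handful of strains
  in which designated gene sets carry a true correlation with LAB growth.

Every generator is deterministic given its seed; noise-free settings produce
exactly the configured archetype geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community_fba import (
    DEFAULT_MU_MIN,
    brute_force_exchange_sets,
    build_community,
    solve_fba,
)
from .exometabolome import ARCHETYPES, IonTable
from .masses import ADDUCT_OFFSETS
from .model_io import MediumDefinition, MetaboliteRef, Reaction, SpeciesModel

__all__ = [
    "ProfileSimConfig",
    "CommunitySimSpec",
    "RegulationSimSpec",
    "SimConfigError",
    "generate_exometabolome",
    "generate_toy_community",
    "generate_regulation_dataset",
]

# sampling grid: conditioning until harvest at 18 h, then bacterial growth
DEFAULT_TIMEPOINTS_H = (0.0, 3.0, 6.0, 9.0, 12.0, 18.0, 24.0, 30.0, 36.0, 42.0)
DEFAULT_PHASE_BOUNDARY_H = 18.0
CARBON = "carbon"


class SimConfigError(ValueError):
    """A simulation configuration violates its invariants."""


# ---------------------------------------------------------------------------
# exo-metabolome


@dataclass
class ProfileSimConfig:
    """Design of a synthetic two-phase ion-intensity table.

    ``archetype_fractions`` must sum to 1; ``amplitude_fold`` is the true
    fold change of the rising/falling segments (≥ 1, before noise);
    ``noise_sd`` is the standard deviation of multiplicative log-normal
    noise in natural-log units.
    """

    n_ions: int = 500
    archetype_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "bell": 0.10, "accumulating": 0.20, "depleting": 0.20, "flat": 0.50,
        }
    )
    timepoints_h: tuple[float, ...] = DEFAULT_TIMEPOINTS_H
    phase_boundary_h: float = DEFAULT_PHASE_BOUNDARY_H
    amplitude_fold: float = 4.0
    noise_sd: float = 0.2
    baseline_intensity: float = 1000.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_ions < 1:
            raise SimConfigError("n_ions must be positive")
        unknown = set(self.archetype_fractions) - set(ARCHETYPES)
        if unknown:
            raise SimConfigError(f"unknown archetypes: {sorted(unknown)}")
        total = sum(self.archetype_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise SimConfigError(f"archetype fractions sum to {total}, not 1")
        if any(f < 0 for f in self.archetype_fractions.values()):
            raise SimConfigError("archetype fractions must be non-negative")
        tps = np.asarray(self.timepoints_h, dtype=float)
        if len(tps) < 3 or np.any(np.diff(tps) <= 0):
            raise SimConfigError("timepoints must be strictly increasing (>= 3 points)")
        if not (tps[0] < self.phase_boundary_h < tps[-1]):
            raise SimConfigError("phase boundary must lie strictly inside the time range")
        if self.amplitude_fold < 1:
            raise SimConfigError("amplitude_fold must be >= 1")
        if self.noise_sd < 0 or self.baseline_intensity <= 0:
            raise SimConfigError("noise_sd must be >= 0 and baseline positive")


def _archetype_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    # largest-remainder apportionment: every count within 1 of n*fraction
    quotas = {a: n * fractions.get(a, 0.0) for a in ARCHETYPES}
    counts = {a: int(np.floor(q)) for a, q in quotas.items()}
    short = n - sum(counts.values())
    remainders = sorted(
        ARCHETYPES, key=lambda a: (quotas[a] - counts[a]), reverse=True
    )
    for a in remainders[:short]:
        counts[a] += 1
    return counts


def _noise_free_profile(
    archetype: str, tps: np.ndarray, boundary: float, amplitude: float, baseline: float
) -> np.ndarray:
    """Piecewise log-linear archetype geometry (exact at zero noise)."""
    log_b = np.log(baseline)
    log_a = np.log(amplitude)
    t0, t_end = tps[0], tps[-1]
    y = np.empty_like(tps)
    for i, t in enumerate(tps):
        if archetype == "flat":
            y[i] = log_b
        elif archetype == "accumulating":
            y[i] = log_b + log_a * min(t - t0, boundary - t0) / (boundary - t0)
        elif archetype == "depleting":
            if t <= boundary:
                y[i] = log_b + log_a
            else:
                y[i] = log_b + log_a * (t_end - t) / (t_end - boundary)
        elif archetype == "bell":
            if t <= boundary:
                y[i] = log_b + log_a * (t - t0) / (boundary - t0)
            else:
                y[i] = log_b + log_a * (t_end - t) / (t_end - boundary)
        else:
            raise SimConfigError(f"unknown archetype {archetype!r}")
    return np.exp(y)


def _random_mz(rng, n: int, forbidden_centers: np.ndarray, min_gap: float = 0.02):
    mz = rng.uniform(60.0, 400.0, size=n)
    if forbidden_centers.size:
        for i in range(n):
            while np.min(np.abs(mz[i] - forbidden_centers)) < min_gap:
                mz[i] = rng.uniform(60.0, 400.0)
    return mz


def generate_exometabolome(
    config: ProfileSimConfig,
    reference: list[MetaboliteRef] | None = None,
) -> tuple[IonTable, dict[str, str]]:
    """Simulate a two-phase ion table; returns (table, ion → true archetype).

    When a metabolite ``reference`` is given, bell ions are placed at the
    [M-H]⁻ m/z of reference metabolites (cycling through the list) so the
    annotation stage can identify them; all other ions get random m/z kept
    clear of every reference adduct window.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tps = np.asarray(config.timepoints_h, dtype=float)
    counts = _archetype_counts(config.archetype_fractions, config.n_ions)

    labels: list[str] = []
    for a in ARCHETYPES:
        labels += [a] * counts[a]
    order = rng.permutation(config.n_ions)
    labels = [labels[i] for i in order]

    rows = np.empty((config.n_ions, len(tps)))
    for i, arch in enumerate(labels):
        clean = _noise_free_profile(
            arch, tps, config.phase_boundary_h, config.amplitude_fold,
            config.baseline_intensity,
        )
        noise = (
            np.exp(config.noise_sd * rng.standard_normal(len(tps)))
            if config.noise_sd > 0 else 1.0
        )
        rows[i] = clean * noise

    ion_ids = [f"ion{i:05d}" for i in range(config.n_ions)]
    if reference:
        centers = np.array(
            [m.monoisotopic_mass + off for m in reference for off in ADDUCT_OFFSETS.values()]
        )
        mz = _random_mz(rng, config.n_ions, centers)
        bell_pos = [i for i, a in enumerate(labels) if a == "bell"]
        for j, i in enumerate(bell_pos):
            ref = reference[j % len(reference)]
            mz[i] = ref.monoisotopic_mass + ADDUCT_OFFSETS["[M-H]-"]
    else:
        mz = _random_mz(rng, config.n_ions, np.array([]))

    table = IonTable(
        intensities=pd.DataFrame(rows, index=ion_ids, columns=tps),
        mz=pd.Series(mz, index=ion_ids, name="mz"),
        phase_boundary=config.phase_boundary_h,
    )
    truth = dict(zip(ion_ids, labels))
    return table, truth


# ---------------------------------------------------------------------------
# toy communities


@dataclass
class CommunitySimSpec:
    """Design of a toy community with known obligate exchanges.

    ``designed_exchanges`` lists (metabolite, donor, receiver) triples; each
    exchanged metabolite must be required by the receiver's biomass, absent
    from the medium, and the receiver gets no biosynthesis route for it.
    ``biomass_requirements`` maps species id → required precursor
    metabolites (bare names, no compartment suffix).
    """

    biomass_requirements: dict[str, list[str]]
    designed_exchanges: list[tuple[str, str, str]] = field(default_factory=list)
    medium_metabolites: dict[str, float] = field(default_factory=dict)
    carbon_cap: float = 10.0
    mu_min: float = DEFAULT_MU_MIN

    @property
    def n_species(self) -> int:
        return len(self.biomass_requirements)

    def validate(self) -> None:
        species = set(self.biomass_requirements)
        if not species:
            raise SimConfigError("at least one species required")
        for met, donor, receiver in self.designed_exchanges:
            if donor == receiver:
                raise SimConfigError(f"exchange {met}: donor equals receiver")
            if donor not in species or receiver not in species:
                raise SimConfigError(f"exchange {met}: unknown species {donor}/{receiver}")
            if met in self.medium_metabolites:
                raise SimConfigError(
                    f"exchange metabolite {met!r} is in the medium; the receiver "
                    "would not depend on the donor"
                )
            if met not in self.biomass_requirements[receiver]:
                raise SimConfigError(
                    f"exchange metabolite {met!r} is not required by receiver {receiver!r}"
                )
        if any(c < 0 for c in self.medium_metabolites.values()):
            raise SimConfigError("medium caps must be non-negative")


def _build_toy_species(spec: CommunitySimSpec, species: str) -> SpeciesModel:
    required = spec.biomass_requirements[species]
    received = {m for m, d, r in spec.designed_exchanges if r == species}
    donated = {m for m, d, r in spec.designed_exchanges if d == species}
    rxns: list[Reaction] = [
        Reaction(f"EX_{CARBON}", {f"{CARBON}_e": -1.0}, lb=-1000.0, ub=0.0),
        Reaction(f"T_{CARBON}", {f"{CARBON}_e": -1.0, f"{CARBON}_c": 1.0}, lb=0.0, ub=1000.0),
    ]
    exchanged_mets = set(required) & (received | set(spec.medium_metabolites)) | donated
    for met in sorted(exchanged_mets):
        can_uptake = met in received or met in spec.medium_metabolites
        can_secrete = met in donated
        lb = -1000.0 if can_uptake else 0.0
        ub = 1000.0 if can_secrete else 0.0
        rxns.append(Reaction(f"EX_{met}", {f"{met}_e": -1.0}, lb=lb, ub=ub))
        rxns.append(
            Reaction(
                f"T_{met}", {f"{met}_e": -1.0, f"{met}_c": 1.0},
                lb=-1000.0 if can_secrete else 0.0, ub=1000.0 if can_uptake else 0.0,
            )
        )
    # biosynthesis from carbon for everything not received and not in medium,
    # plus anything this species donates (receivers never get a SYN route)
    synth = (set(required) - received - set(spec.medium_metabolites)) | donated
    for met in sorted(synth):
        rxns.append(Reaction(f"SYN_{met}", {f"{CARBON}_c": -1.0, f"{met}_c": 1.0}))
    stoich = {f"{m}_c": -1.0 for m in required}
    stoich[f"{CARBON}_c"] = stoich.get(f"{CARBON}_c", 0.0) - 1.0
    rxns.append(Reaction("BIOMASS", stoich))
    return SpeciesModel(species_id=species, reactions=rxns, biomass_reaction_id="BIOMASS")


def generate_toy_community(
    spec: CommunitySimSpec,
) -> tuple[list[SpeciesModel], MediumDefinition, set[tuple[str, str, str]]]:
    """Build species models, a restricted medium, and the certified truth set.

    Post-conditions verified before returning: every species grows alone in
    the complete medium (restricted medium plus all exchanged metabolites);
    receivers of designed exchanges cannot grow alone in the restricted
    medium; the full community is feasible; and — by exhaustive LP
    feasibility search over transfer subsets — every designed exchange is
    present in every feasible transfer set.
    """
    spec.validate()
    models = [_build_toy_species(spec, s) for s in sorted(spec.biomass_requirements)]
    entries = {f"{CARBON}_e": spec.carbon_cap}
    entries.update({f"{m}_e": c for m, c in spec.medium_metabolites.items()})
    medium = MediumDefinition(entries)

    complete = medium
    for met, _, _ in spec.designed_exchanges:
        complete = complete.with_added(f"{met}_e", spec.carbon_cap)
    receivers = {r for _, _, r in spec.designed_exchanges}
    for model in models:
        grown = solve_fba(model, medium=complete)
        if not (grown.feasible and grown.objective > spec.mu_min):
            raise SimConfigError(
                f"{model.species_id} cannot grow alone in the complete medium"
            )
        alone = solve_fba(model, medium=medium)
        alone_ok = alone.feasible and alone.objective > spec.mu_min
        if model.species_id in receivers and alone_ok:
            raise SimConfigError(
                f"receiver {model.species_id} grows alone in the restricted medium; "
                "designed exchange is not obligate"
            )

    community = build_community(models, medium, mu_min=spec.mu_min)
    feasible, _minimal = brute_force_exchange_sets(community, mu_min=spec.mu_min)
    if not feasible:
        raise SimConfigError("full community is infeasible even with all transfers open")
    truth = {
        (f"{met}_e", d, r) for met, d, r in spec.designed_exchanges
    }
    for S in feasible:
        missing = truth - S
        if missing:
            raise SimConfigError(
                f"designed exchanges {sorted(missing)} are not obligate: "
                f"feasible without them ({sorted(S)})"
            )
    return models, medium, truth


# ---------------------------------------------------------------------------
# regulation datasets


@dataclass
class RegulationSimSpec:
    """Design of an expression/growth dataset with known enriched sets.

    ``effect_sets`` are the gene-set names whose member genes carry a true
    correlation of ``effect_size`` with LAB growth across strains; all other
    genes are uncorrelated noise. Each gene set needs at least 5 members.
    """

    n_genes: int
    n_strains: int
    gene_sets: dict[str, list[str]]
    effect_sets: set[str] = field(default_factory=set)
    effect_size: float = 0.9
    noise_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_strains < 3:
            raise SimConfigError("need at least 3 strains")
        if not 0 <= self.effect_size <= 1:
            raise SimConfigError("effect_size must lie in [0, 1]")
        if self.noise_sd < 0:
            raise SimConfigError("noise_sd must be non-negative")
        unknown = set(self.effect_sets) - set(self.gene_sets)
        if unknown:
            raise SimConfigError(f"effect sets not among gene sets: {sorted(unknown)}")
        for name, genes in self.gene_sets.items():
            if len(genes) < 5:
                raise SimConfigError(f"gene set {name!r} has fewer than 5 genes")

    @classmethod
    def random(
        cls,
        n_genes: int = 1000,
        n_strains: int = 5,
        n_sets: int = 20,
        set_size: int = 10,
        n_effect_sets: int = 2,
        effect_size: float = 0.9,
        noise_sd: float = 0.1,
        seed: int = 0,
    ) -> "RegulationSimSpec":
        """Disjoint random gene sets; the first ``n_effect_sets`` carry effect."""
        if n_sets * set_size > n_genes:
            raise SimConfigError("gene sets would not fit disjointly into the genome")
        rng = np.random.default_rng(seed)
        genes = [f"g{i:05d}" for i in range(n_genes)]
        picked = rng.permutation(n_genes)[: n_sets * set_size]
        gene_sets = {
            f"set{j:03d}": [genes[i] for i in picked[j * set_size:(j + 1) * set_size]]
            for j in range(n_sets)
        }
        effect = {f"set{j:03d}" for j in range(n_effect_sets)}
        spec = cls(
            n_genes=n_genes, n_strains=n_strains, gene_sets=gene_sets,
            effect_sets=effect, effect_size=effect_size, noise_sd=noise_sd, seed=seed,
        )
        spec.validate()
        return spec


def generate_regulation_dataset(
    spec: RegulationSimSpec,
) -> tuple[pd.DataFrame, pd.Series, dict[str, list[str]], set[str]]:
    """Simulate (expression matrix, growth table, gene sets, true set names).

    Genes in effect sets follow x = ρ·z_g + √(1−ρ²)·ε₁ + σ·ε₂ where z_g is
    the standardized growth vector, giving expected correlation
    ρ/√(1+σ²) ≈ effect_size for small σ; all other genes are pure noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    strains = [f"strain{j}" for j in range(spec.n_strains)]
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]

    g = rng.uniform(0.2, 1.0, size=spec.n_strains)
    zg = (g - g.mean()) / g.std()

    effect_genes = {
        gene for name in spec.effect_sets for gene in spec.gene_sets[name]
    }
    rho = spec.effect_size
    X = rng.standard_normal((spec.n_genes, spec.n_strains))
    mask = np.array([gene in effect_genes for gene in genes])
    X[mask] = (
        rho * zg
        + np.sqrt(max(0.0, 1.0 - rho**2)) * X[mask]
        + spec.noise_sd * rng.standard_normal((int(mask.sum()), spec.n_strains))
    )
    expr = pd.DataFrame(X, index=genes, columns=strains)
    growth = pd.Series(g, index=strains, name="lab_od600")
    return expr, growth, dict(spec.gene_sets), set(spec.effect_sets)
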