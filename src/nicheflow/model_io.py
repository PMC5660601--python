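"""Plain-text I/O for stoichiometric species models, media, and tabular data.

The model dialect is a bioopt-style reaction list, one reaction per line::

    # species: lab
    # biomass: BIOMASS
    EX_glc : 1 glc_e <-> [-10, 1000]
    PTS    : 1 glc_e -> 1 glc_c [0, 1000]
    BIOMASS: 1 glc_c -> [0, 1000]

``<->`` marks a reversible reaction (lb < 0), ``->`` an irreversible one.
Compartments are encoded as metabolite-id suffixes: ``_e`` for the shared
environment, ``_c`` for cytosol. Exchange (boundary) reactions are detected
mechanically as single-metabolite reactions on an environment-tagged
metabolite; by convention positive flux through an exchange reaction is
secretion and negative flux is uptake.

Media, metabolite references, ion tables, expression matrices, growth tables
and gene sets are all tab-separated text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .masses import formula_mass

__all__ = [
    "Reaction",
    "SpeciesModel",
    "MediumDefinition",
    "MetaboliteRef",
    "ModelParseError",
    "ModelValidationError",
    "read_model",
    "write_model",
    "model_to_text",
    "read_medium",
    "write_medium",
    "validate_model",
    "read_metabolite_reference",
    "read_expression",
    "read_growth",
    "read_gene_sets",
    "write_gene_sets",
]

ENV_SUFFIX = "_e"


class ModelParseError(ValueError):
    """A model or medium file could not be parsed."""


class ModelValidationError(ValueError):
    """A parsed model violates a structural invariant."""


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction with flux bounds (mmol·gDW⁻¹·h⁻¹).

    ``stoichiometry`` maps metabolite id to a signed coefficient; negative
    coefficients are consumed, positive produced. A reaction is reversible
    iff its lower bound is negative.
    """

    id: str
    stoichiometry: dict[str, float]
    lb: float = 0.0
    ub: float = 1000.0

    @property
    def reversible(self) -> bool:
        return self.lb < 0

    @property
    def metabolites(self) -> set[str]:
        return set(self.stoichiometry)

    def with_bounds(self, lb: float, ub: float) -> "Reaction":
        return replace(self, lb=lb, ub=ub)


@dataclass
class SpeciesModel:
    """A species-level metabolic network with biomass and boundary reactions."""

    species_id: str
    reactions: list[Reaction]
    biomass_reaction_id: str
    metabolites: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        declared = {m for r in self.reactions for m in r.stoichiometry}
        if not self.metabolites:
            self.metabolites = declared

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"reaction {rid!r} not in model {self.species_id!r}")

    @property
    def exchange_reaction_ids(self) -> list[str]:
        """Boundary reactions: single environment-tagged metabolite."""
        out = []
        for r in self.reactions:
            if len(r.stoichiometry) == 1:
                (met,) = r.stoichiometry
                if met.endswith(ENV_SUFFIX):
                    out.append(r.id)
        return out

    def exchanged_metabolite(self, rid: str) -> str:
        r = self.reaction(rid)
        (met,) = r.stoichiometry
        return met

    def copy(self) -> "SpeciesModel":
        return SpeciesModel(
            species_id=self.species_id,
            reactions=list(self.reactions),
            biomass_reaction_id=self.biomass_reaction_id,
            metabolites=set(self.metabolites),
        )


@dataclass
class MediumDefinition:
    """Maximum uptake flux per environment metabolite (mmol·gDW⁻¹·h⁻¹).

    Metabolites absent from ``entries`` are closed (zero uptake). Caps must
    be non-negative.
    """

    entries: dict[str, float] = field(default_factory=dict)

    def cap(self, met: str) -> float:
        return float(self.entries.get(met, 0.0))

    def __contains__(self, met: str) -> bool:
        return met in self.entries

    def with_added(self, met: str, cap: float) -> "MediumDefinition":
        new = dict(self.entries)
        new[met] = cap
        return MediumDefinition(new)


@dataclass(frozen=True)
class MetaboliteRef:
    """Reference metabolite used for accurate-mass ion annotation."""

    id: str
    name: str
    formula: str
    monoisotopic_mass: float

    def validate(self, tol: float = 0.001) -> None:
        if self.monoisotopic_mass <= 0:
            raise ModelValidationError(f"{self.id}: non-positive mass")
        calc = formula_mass(self.formula)
        if abs(calc - self.monoisotopic_mass) > tol:
            raise ModelValidationError(
                f"{self.id}: formula {self.formula} gives {calc:.4f} Da, "
                f"stated {self.monoisotopic_mass:.4f} Da"
            )


# ---------------------------------------------------------------------------
# model text dialect

_ARROW_RE = re.compile(r"<->|->")
_BOUNDS_RE = re.compile(r"\[\s*([^,\]]+)\s*,\s*([^,\]]+)\s*\]\s*$")


def _parse_side(text: str, lineno: int) -> dict[str, float]:
    out: dict[str, float] = {}
    text = text.strip()
    if not text:
        return out
    for term in text.split("+"):
        parts = term.split()
        if len(parts) == 1:
            coef, met = 1.0, parts[0]
        elif len(parts) == 2:
            try:
                coef = float(parts[0])
            except ValueError:
                raise ModelParseError(f"line {lineno}: bad coefficient in {term!r}")
            met = parts[1]
        else:
            raise ModelParseError(f"line {lineno}: cannot parse term {term!r}")
        out[met] = out.get(met, 0.0) + coef
    return out


def _parse_reaction_line(line: str, lineno: int) -> Reaction:
    if ":" not in line:
        raise ModelParseError(f"line {lineno}: missing ':' in {line!r}")
    rid, rest = line.split(":", 1)
    rid = rid.strip()
    if not rid:
        raise ModelParseError(f"line {lineno}: empty reaction id")
    m = _BOUNDS_RE.search(rest)
    if m:
        try:
            lb, ub = float(m.group(1)), float(m.group(2))
        except ValueError:
            raise ModelParseError(f"line {lineno}: bad bounds in {line!r}")
        rest = rest[: m.start()]
        explicit = True
    else:
        lb = ub = 0.0
        explicit = False
    arrow = _ARROW_RE.search(rest)
    if not arrow:
        raise ModelParseError(f"line {lineno}: missing '->' or '<->' in {line!r}")
    reversible = arrow.group(0) == "<->"
    if not explicit:
        lb, ub = (-1000.0, 1000.0) if reversible else (0.0, 1000.0)
    left = _parse_side(rest[: arrow.start()], lineno)
    right = _parse_side(rest[arrow.end():], lineno)
    stoich: dict[str, float] = {}
    for met, c in left.items():
        stoich[met] = stoich.get(met, 0.0) - c
    for met, c in right.items():
        stoich[met] = stoich.get(met, 0.0) + c
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    if not stoich:
        raise ModelParseError(f"line {lineno}: reaction {rid!r} has empty stoichiometry")
    return Reaction(id=rid, stoichiometry=stoich, lb=lb, ub=ub)


def _format_number(x: float) -> str:
    return f"{x:g}"


def _reaction_to_line(r: Reaction) -> str:
    left = [(m, -c) for m, c in r.stoichiometry.items() if c < 0]
    right = [(m, c) for m, c in r.stoichiometry.items() if c > 0]
    fmt = lambda side: " + ".join(f"{_format_number(c)} {m}" for m, c in sorted(side))
    arrow = "<->" if r.reversible else "->"
    lhs, rhs = fmt(left), fmt(right)
    body = f"{lhs} {arrow} {rhs}".strip()
    return f"{r.id} : {body} [{_format_number(r.lb)}, {_format_number(r.ub)}]"


def model_to_text(model: SpeciesModel) -> str:
    lines = [f"# species: {model.species_id}", f"# biomass: {model.biomass_reaction_id}"]
    lines += [_reaction_to_line(r) for r in model.reactions]
    return "\n".join(lines) + "\n"


def write_model(model: SpeciesModel, path: str | Path) -> None:
    Path(path).write_text(model_to_text(model))


def read_model(path: str | Path, dialect: str = "bioopt") -> SpeciesModel:
    """Parse a plain-text species model.

    ``dialect`` must be ``"bioopt"`` (the reaction-list format above) or
    ``"tabular"`` (TSV with columns id, equation, lb, ub — the equation uses
    the same arrow syntax).
    """
    path = Path(path)
    if dialect not in ("bioopt", "tabular"):
        raise ValueError(f"unknown dialect {dialect!r}")
    species_id = path.stem
    biomass_id: str | None = None
    reactions: list[Reaction] = []
    if dialect == "tabular":
        df = pd.read_csv(path, sep="\t", comment="#")
        for i, row in df.iterrows():
            line = f"{row['id']} : {row['equation']} [{row['lb']}, {row['ub']}]"
            reactions.append(_parse_reaction_line(line, lineno=i + 2))
        header = [
            ln for ln in path.read_text().splitlines() if ln.startswith("#")
        ]
    else:
        header = []
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                header.append(line)
                continue
            reactions.append(_parse_reaction_line(line, lineno))
    for h in header:
        body = h.lstrip("#").strip()
        if body.startswith("species:"):
            species_id = body.split(":", 1)[1].strip()
        elif body.startswith("biomass:"):
            biomass_id = body.split(":", 1)[1].strip()
    if biomass_id is None:
        raise ModelParseError(f"{path}: biomass reaction not found (missing '# biomass:' header)")
    model = SpeciesModel(species_id=species_id, reactions=reactions, biomass_reaction_id=biomass_id)
    problems = validate_model(model)
    if problems:
        raise ModelValidationError(f"{path}: " + "; ".join(problems))
    return model


def validate_model(model: SpeciesModel) -> list[str]:
    """Return every structural violation found (empty list means valid)."""
    problems: list[str] = []
    ids = [r.id for r in model.reactions]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        problems.append(f"duplicate reaction ids: {dupes}")
    if model.biomass_reaction_id not in ids:
        problems.append(f"biomass reaction not found: {model.biomass_reaction_id!r}")
    for r in model.reactions:
        if not r.stoichiometry:
            problems.append(f"{r.id}: empty stoichiometry")
        if r.lb > r.ub:
            problems.append(f"{r.id}: lb {r.lb} > ub {r.ub}")
        undeclared = r.metabolites - model.metabolites
        if undeclared:
            problems.append(f"{r.id}: undeclared metabolites {sorted(undeclared)}")
    return problems


# ---------------------------------------------------------------------------
# tabular formats

def read_medium(path: str | Path) -> MediumDefinition:
    path = Path(path)
    text = path.read_text()
    entries: dict[str, float] = {}
    rows = [
        ln for ln in text.splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not rows:
        return MediumDefinition({})
    start = 1 if rows[0].split("\t")[0] in ("metabolite", "met") else 0
    for lineno, ln in enumerate(rows[start:], start=start + 1):
        parts = ln.split("\t")
        if len(parts) < 2:
            raise ModelParseError(f"{path} line {lineno}: expected 'metabolite<TAB>max_uptake'")
        met, cap = parts[0].strip(), float(parts[1])
        if cap < 0:
            raise ModelValidationError(f"{path}: negative uptake cap for {met}: {cap}")
        entries[met] = cap
    return MediumDefinition(entries)


def write_medium(medium: MediumDefinition, path: str | Path) -> None:
    lines = ["metabolite\tmax_uptake"]
    lines += [f"{m}\t{_format_number(c)}" for m, c in sorted(medium.entries.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def read_metabolite_reference(path: str | Path, validate: bool = True) -> list[MetaboliteRef]:
    df = pd.read_csv(path, sep="\t", comment="#")
    refs = [
        MetaboliteRef(
            id=str(r["id"]), name=str(r["name"]), formula=str(r["formula"]),
            monoisotopic_mass=float(r["monoisotopic_mass"]),
        )
        for _, r in df.iterrows()
    ]
    if validate:
        for ref in refs:
            ref.validate()
    return refs


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes × strains matrix of normalized (log-scale) expression."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_growth(path: str | Path) -> pd.Series:
    """Strain → final OD₆₀₀ of the LAB grown in that strain's conditioned medium."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Gene-set file: one ``set_name<TAB>gene`` row per membership."""
    sets: dict[str, list[str]] = {}
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) < 2:
            raise ModelParseError(f"{path} line {lineno}: expected 'set_name<TAB>gene'")
        sets.setdefault(parts[0], []).append(parts[1])
    return sets


def write_gene_sets(sets: dict[str, list[str]], path: str | Path) -> None:
    lines = [f"{name}\t{gene}" for name, genes in sets.items() for gene in genes]
    Path(path).write_text("\n".join(lines) + "\n")
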