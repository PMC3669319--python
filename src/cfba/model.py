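"""Domain types for species and community metabolic models.

A community model merges the stoichiometric matrices of its member species
into one block-structured matrix.  Rows are variable metabolites — each
species' intracellular metabolites plus the shared extracellular pool —
and columns are the species' reactions, one biomass column per species,
and one exchange column per environmental exchange.  Species blocks are
disjoint except for the rows of cross-fed (shared extracellular)
metabolites and the exchange columns acting on them.

Units: all species-level fluxes are specific fluxes in mmol·gDW⁻¹·h⁻¹ and
the growth rate is in h⁻¹.  Environmental exchanges carry absolute bounds
in mmol·h⁻¹; they are converted to specific bounds by dividing by the
total community biomass ``X_T`` (gDW) when the balanced-growth LP is
built, so the whole program is dimensionally uniform.

Sign conventions: exchange columns are export-positive (the exchanged
metabolite has coefficient −1), so uptake from the environment is a
negative exchange flux.  Biomass composition coefficients are signed with
consumed components negative (mmol per gDW of that species' biomass).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "MetaboliteRole",
    "ReactionKind",
    "Metabolite",
    "Reaction",
    "SpeciesModel",
    "CommunityModel",
    "FractionVector",
    "PartitionedMatrix",
    "ValidationReport",
    "ModelError",
    "build_species_model",
    "partition_species_matrix",
    "assemble_community",
    "validate_community",
    "parse_formula",
    "SPECIES_SEP",
]

#: separator used to namespace species-scoped identifiers on merge
SPECIES_SEP = "__"

#: default magnitude used when a bound is unspecified
DEFAULT_BOUND = 1000.0


class ModelError(ValueError):
    """Raised when a model violates a structural precondition."""


class MetaboliteRole(str, Enum):
    INTRACELLULAR = "intracellular"
    CROSSFED_EXTRACELLULAR = "crossfed"
    UNIQUE_EXTRACELLULAR = "unique_extracellular"


class ReactionKind(str, Enum):
    INTRACELLULAR = "intracellular"
    CROSSFEED_TRANSPORT = "crossfeed_transport"
    UNIQUE_TRANSPORT = "unique_transport"
    ENV_EXCHANGE = "env_exchange"
    BIOMASS = "biomass"


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(formula: str) -> dict[str, float]:
    """Parse an elemental formula such as ``C6H12O6`` or ``C3N0.2``.

    Fractional element counts are allowed: coarse-grained models commonly
    use non-integer pseudo-elemental compositions for lumped metabolites.
    """
    out: dict[str, float] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ModelError(f"cannot parse formula {formula!r}")
        pos = m.end()
        count = float(m.group(2)) if m.group(2) else 1.0
        out[m.group(1)] = out.get(m.group(1), 0.0) + count
    if pos != len(formula):
        raise ModelError(f"cannot parse formula {formula!r}")
    return out


@dataclass
class Metabolite:
    """A variable metabolite: its amount is balanced, never integrated."""

    id: str
    name: str = ""
    role: MetaboliteRole = MetaboliteRole.INTRACELLULAR
    owner_species: str | None = None
    formula: str | None = None
    charge: float | None = None

    def __post_init__(self) -> None:
        if isinstance(self.role, str):
            self.role = MetaboliteRole(self.role)
        if self.role is MetaboliteRole.CROSSFED_EXTRACELLULAR and self.owner_species:
            raise ModelError(
                f"cross-fed metabolite {self.id!r} cannot have an owner species"
            )

    @property
    def is_extracellular(self) -> bool:
        return self.role is not MetaboliteRole.INTRACELLULAR

    def elements(self) -> dict[str, float] | None:
        return parse_formula(self.formula) if self.formula else None


@dataclass
class Reaction:
    """A reaction with signed stoichiometry and specific-flux bounds.

    Species reactions carry bounds in mmol·gDW⁻¹·h⁻¹; environmental
    exchange reactions (``kind=ENV_EXCHANGE``) carry absolute bounds in
    mmol·h⁻¹ on the community-level flux J.
    """

    id: str
    stoichiometry: Mapping[str, float] = field(default_factory=dict)
    kind: ReactionKind | None = None
    owner_species: str | None = None
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND

    def __post_init__(self) -> None:
        if isinstance(self.kind, str):
            self.kind = ReactionKind(self.kind)
        self.stoichiometry = dict(self.stoichiometry)
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            kind=self.kind,
            owner_species=self.owner_species,
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
        )


@dataclass
class SpeciesModel:
    """One organism: stoichiometric matrix N plus biomass composition c.

    ``N`` has one row per metabolite (in the order of ``metabolites``) and
    one column per non-biomass reaction (in the order of ``reactions``).
    ``c`` is the biomass composition vector in mmol per gDW of this
    species' biomass, with consumed components negative; it is stored
    alongside as the stoichiometry of the single biomass reaction.
    """

    species_id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass: Reaction
    N: sparse.csr_matrix
    c: np.ndarray

    def metabolite_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    def reaction_index(self) -> dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def get_metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def get_reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def extracellular_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if m.is_extracellular]

    def copy(self) -> "SpeciesModel":
        return build_species_model(
            self.species_id,
            [Metabolite(m.id, m.name, m.role, m.owner_species, m.formula, m.charge)
             for m in self.metabolites],
            [r.copy() for r in self.reactions] + [self.biomass.copy()],
        )


@dataclass
class FractionVector:
    """Fractional biomass abundances f_j = X_j / X_T on the unit simplex."""

    f: dict[str, float]

    ATOL = 1e-12

    def __post_init__(self) -> None:
        self.f = {k: float(v) for k, v in self.f.items()}
        for sp, v in self.f.items():
            if v < -self.ATOL:
                raise ModelError(f"negative biomass fraction for {sp!r}: {v}")
        total = sum(self.f.values())
        if abs(total - 1.0) > 1e-9:
            raise ModelError(f"biomass fractions sum to {total}, expected 1")
        # renormalize away accumulated float error so downstream sums are exact
        self.f = {k: max(v, 0.0) / total for k, v in self.f.items()}

    def __getitem__(self, sp: str) -> float:
        return self.f[sp]

    def as_array(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.f[sp] for sp in order])

    @classmethod
    def from_array(cls, order: Sequence[str], values: Iterable[float]) -> "FractionVector":
        return cls(dict(zip(order, values)))


# ---------------------------------------------------------------------------
# species model construction
# ---------------------------------------------------------------------------

def _classify_reaction(rxn: Reaction, mets: dict[str, Metabolite]) -> ReactionKind:
    roles = {mets[m].role for m in rxn.stoichiometry}
    has_intra = MetaboliteRole.INTRACELLULAR in roles
    has_cross = MetaboliteRole.CROSSFED_EXTRACELLULAR in roles
    has_unique = MetaboliteRole.UNIQUE_EXTRACELLULAR in roles
    if not roles:
        raise ModelError(f"reaction {rxn.id!r} touches no metabolite")
    if has_cross and not has_intra:
        # pure extracellular conversions belong to the environment
        return ReactionKind.ENV_EXCHANGE
    if has_cross:
        return ReactionKind.CROSSFEED_TRANSPORT
    if has_unique:
        return ReactionKind.UNIQUE_TRANSPORT if has_intra else ReactionKind.ENV_EXCHANGE
    return ReactionKind.INTRACELLULAR


def build_species_model(
    species_id: str,
    metabolites: Iterable[Metabolite],
    reactions: Iterable[Reaction],
) -> SpeciesModel:
    """Assemble a classified species model from metabolites and reactions.

    ``reactions`` must contain exactly one reaction of kind ``BIOMASS``
    whose stoichiometry is the biomass composition vector.  Reaction kinds
    are inferred from the roles of the metabolites they touch when not
    given, and checked for consistency when they are.
    """
    metabolites = list(metabolites)
    met_by_id: dict[str, Metabolite] = {}
    for m in metabolites:
        if m.id in met_by_id:
            raise ModelError(f"duplicate metabolite id {m.id!r} in {species_id!r}")
        if m.role is MetaboliteRole.INTRACELLULAR:
            m.owner_species = species_id
        met_by_id[m.id] = m

    biomass: Reaction | None = None
    ordinary: list[Reaction] = []
    seen: set[str] = set()
    for r in reactions:
        if r.id in seen:
            raise ModelError(f"duplicate reaction id {r.id!r} in {species_id!r}")
        seen.add(r.id)
        for met_id in r.stoichiometry:
            if met_id not in met_by_id:
                raise ModelError(
                    f"reaction {r.id!r} references unknown metabolite {met_id!r}"
                )
        if r.kind is ReactionKind.BIOMASS:
            if biomass is not None:
                raise ModelError(f"species {species_id!r} has two biomass reactions")
            biomass = r
        else:
            inferred = _classify_reaction(r, met_by_id)
            if r.kind is None:
                r.kind = inferred
            elif r.kind is not inferred:
                raise ModelError(
                    f"reaction {r.id!r} declared {r.kind.value} but its "
                    f"stoichiometry implies {inferred.value}"
                )
            if r.kind is ReactionKind.ENV_EXCHANGE:
                raise ModelError(
                    f"reaction {r.id!r} touches only extracellular metabolites; "
                    "environmental exchanges belong to the community, not a species"
                )
            r.owner_species = species_id
            if not r.reversible and r.lower_bound < 0:
                raise ModelError(f"irreversible reaction {r.id!r} has negative lb")
            ordinary.append(r)
    if biomass is None:
        raise ModelError(f"species {species_id!r} has no biomass reaction")
    biomass.owner_species = species_id

    midx = {m.id: i for i, m in enumerate(metabolites)}
    rows, cols, vals = [], [], []
    for j, r in enumerate(ordinary):
        for met_id, coef in r.stoichiometry.items():
            if coef != 0:
                rows.append(midx[met_id])
                cols.append(j)
                vals.append(float(coef))
    N = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(metabolites), len(ordinary))
    )
    c = np.zeros(len(metabolites))
    for met_id, coef in biomass.stoichiometry.items():
        c[midx[met_id]] = float(coef)
    return SpeciesModel(species_id, metabolites, ordinary, biomass, N, c)


# ---------------------------------------------------------------------------
# matrix partition
# ---------------------------------------------------------------------------

@dataclass
class PartitionedMatrix:
    """The rearranged species matrix split into its functional blocks.

    Row order: intracellular, cross-fed extracellular, unique
    extracellular.  Column order: intracellular reactions, cross-feeding
    transports, unique transports.  The recorded permutations allow the
    original N to be reconstructed exactly.
    """

    species_id: str
    row_perm: np.ndarray
    col_perm: np.ndarray
    n_rows: tuple[int, int, int]  # intracellular / crossfed / unique rows
    n_cols: tuple[int, int, int]  # intracellular / crossfeed / unique columns
    rearranged: sparse.csr_matrix

    def block(self, row_class: str, col_class: str) -> sparse.csr_matrix:
        r = {"intracellular": 0, "crossfed": 1, "unique": 2}[row_class]
        c = {"intracellular": 0, "crossfeed": 1, "unique": 2}[col_class]
        r0 = sum(self.n_rows[:r])
        c0 = sum(self.n_cols[:c])
        return self.rearranged[r0:r0 + self.n_rows[r], c0:c0 + self.n_cols[c]]

    def unpermuted(self) -> sparse.csr_matrix:
        inv_r = np.argsort(self.row_perm)
        inv_c = np.argsort(self.col_perm)
        return self.rearranged[inv_r][:, inv_c].tocsr()


def partition_species_matrix(m: SpeciesModel) -> PartitionedMatrix:
    """Rearrange N into the modular block layout of a community member."""
    role_order = {
        MetaboliteRole.INTRACELLULAR: 0,
        MetaboliteRole.CROSSFED_EXTRACELLULAR: 1,
        MetaboliteRole.UNIQUE_EXTRACELLULAR: 2,
    }
    kind_order = {
        ReactionKind.INTRACELLULAR: 0,
        ReactionKind.CROSSFEED_TRANSPORT: 1,
        ReactionKind.UNIQUE_TRANSPORT: 2,
    }
    for r in m.reactions:
        if not r.stoichiometry:
            raise ModelError(f"reaction {r.id!r} touches no metabolite")
    row_keys = [role_order[met.role] for met in m.metabolites]
    col_keys = [kind_order[r.kind] for r in m.reactions]
    row_perm = np.argsort(row_keys, kind="stable")
    col_perm = np.argsort(col_keys, kind="stable")
    n_rows = tuple(row_keys.count(k) for k in (0, 1, 2))
    n_cols = tuple(col_keys.count(k) for k in (0, 1, 2))
    rearranged = m.N[row_perm][:, col_perm].tocsr()
    return PartitionedMatrix(m.species_id, row_perm, col_perm, n_rows, n_cols, rearranged)


# ---------------------------------------------------------------------------
# community assembly
# ---------------------------------------------------------------------------

@dataclass
class CommunityModel:
    """Merged community model with the block-structured matrix C.

    Rows of ``C`` are all distinct variable metabolites: species-scoped
    intracellular metabolites (keys ``"<species>__<met>"``) followed by
    shared extracellular ones (global ids).  Columns are every species
    reaction (keys ``"<species>__<rxn>"``), one biomass column per species
    (``"BIOMASS__<species>"``), then one column per environmental
    exchange.  Exchange bounds are absolute (mmol·h⁻¹) and are divided by
    ``X_T`` wherever specific bounds are needed.
    """

    species: list[SpeciesModel]
    crossfed_metabolites: list[str]
    env_exchanges: list[Reaction]
    X_T: float
    C: sparse.csr_matrix
    row_keys: list[str]
    col_keys: list[str]

    @property
    def species_ids(self) -> list[str]:
        return [s.species_id for s in self.species]

    def get_species(self, species_id: str) -> SpeciesModel:
        for s in self.species:
            if s.species_id == species_id:
                return s
        raise KeyError(species_id)

    def exchange_ids(self) -> list[str]:
        return [ex.id for ex in self.env_exchanges]

    def get_exchange(self, ex_id: str) -> Reaction:
        for ex in self.env_exchanges:
            if ex.id == ex_id:
                return ex
        raise KeyError(ex_id)

    def exchanged_metabolite(self, ex_id: str) -> str:
        stoich = self.get_exchange(ex_id).stoichiometry
        (met_id,) = stoich.keys()
        return met_id

    def phi_bounds(self, ex_id: str) -> tuple[float, float]:
        """Specific exchange-flux bounds φ = J / X_T (mmol·gDW⁻¹·h⁻¹)."""
        ex = self.get_exchange(ex_id)
        return ex.lower_bound / self.X_T, ex.upper_bound / self.X_T

    def copy(self) -> "CommunityModel":
        return assemble_community(
            [s.copy() for s in self.species],
            list(self.crossfed_metabolites),
            [ex.copy() for ex in self.env_exchanges],
            X_T=self.X_T,
        )

    def with_reaction_bounds(
        self, updates: Mapping[tuple[str, str] | str, tuple[float, float]]
    ) -> "CommunityModel":
        """Return a copy with species reaction / exchange bounds replaced.

        Keys are ``(species_id, reaction_id)`` for species reactions or a
        bare exchange id for environmental exchanges (absolute units).
        """
        cm = self.copy()
        for key, (lb, ub) in updates.items():
            if isinstance(key, tuple):
                rxn = cm.get_species(key[0]).get_reaction(key[1])
            else:
                rxn = cm.get_exchange(key)
            rxn.lower_bound, rxn.upper_bound = float(lb), float(ub)
        return cm


def assemble_community(
    species: Sequence[SpeciesModel],
    crossfed_ids: Sequence[str],
    env_exchanges: Sequence[Reaction] = (),
    X_T: float = 1.0,
    allow_env_supply_of_crossfed: bool = False,
) -> CommunityModel:
    """Merge species models into a community model.

    Extracellular metabolites listed in ``crossfed_ids`` are merged into
    single shared rows across species (identity is by exact id match, by
    design — never by name heuristics).  Every cross-fed metabolite
    without an explicit environmental exchange gets an overflow exchange,
    irreversible (efflux-only) unless ``allow_env_supply_of_crossfed``.
    An extracellular metabolite not declared cross-fed must be unique to
    one species.
    """
    if X_T <= 0:
        raise ModelError(f"total biomass X_T must be positive, got {X_T}")
    species = list(species)
    ids = [s.species_id for s in species]
    if len(set(ids)) != len(ids):
        raise ModelError("duplicate species ids in community")
    crossfed = list(dict.fromkeys(crossfed_ids))

    # reconcile extracellular roles against the community-level declaration
    ext_owner: dict[str, str] = {}
    known_ext: set[str] = set()
    for s in species:
        for m in s.metabolites:
            if not m.is_extracellular:
                continue
            known_ext.add(m.id)
            if m.id in crossfed:
                m.role = MetaboliteRole.CROSSFED_EXTRACELLULAR
                m.owner_species = None
            else:
                if m.id in ext_owner and ext_owner[m.id] != s.species_id:
                    raise ModelError(
                        f"extracellular metabolite {m.id!r} appears in species "
                        f"{ext_owner[m.id]!r} and {s.species_id!r}; shared "
                        "metabolites must be declared cross-fed"
                    )
                ext_owner[m.id] = s.species_id
                m.role = MetaboliteRole.UNIQUE_EXTRACELLULAR
    for cid in crossfed:
        if cid not in known_ext:
            raise ModelError(f"cross-fed metabolite {cid!r} unknown to every species")
    # roles may have changed: rebuild species models with kinds re-inferred
    rebuilt = []
    for s in species:
        fresh = []
        for r in s.reactions:
            r = r.copy()
            r.kind = None
            fresh.append(r)
        rebuilt.append(
            build_species_model(s.species_id, s.metabolites, fresh + [s.biomass.copy()])
        )
    species = rebuilt

    ext_meta: dict[str, Metabolite] = {}
    for s in species:
        for m in s.metabolites:
            if m.is_extracellular:
                ext_meta.setdefault(m.id, m)

    exchanges: list[Reaction] = []
    exchanged: set[str] = set()
    for ex in env_exchanges:
        ex = ex.copy()
        ex.kind = ReactionKind.ENV_EXCHANGE
        if len(ex.stoichiometry) != 1:
            raise ModelError(
                f"exchange {ex.id!r} must act on exactly one metabolite"
            )
        (met_id,) = ex.stoichiometry
        if met_id not in ext_meta:
            raise ModelError(
                f"exchange {ex.id!r} references {met_id!r}, which is not an "
                "extracellular metabolite of any species"
            )
        exchanges.append(ex)
        exchanged.add(met_id)
    for cid in crossfed:
        if cid not in exchanged:
            lb = -np.inf if allow_env_supply_of_crossfed else 0.0
            exchanges.append(
                Reaction(
                    id=f"EX_{cid}",
                    stoichiometry={cid: -1.0},
                    kind=ReactionKind.ENV_EXCHANGE,
                    lower_bound=lb,
                    upper_bound=np.inf,
                )
            )

    # rows: species-scoped intracellular metabolites, then extracellular pool
    row_keys: list[str] = []
    for s in species:
        row_keys.extend(
            f"{s.species_id}{SPECIES_SEP}{m.id}"
            for m in s.metabolites
            if not m.is_extracellular
        )
    ext_order = sorted(ext_meta)
    row_keys.extend(ext_order)
    ridx = {k: i for i, k in enumerate(row_keys)}

    col_keys: list[str] = []
    rows, cols, vals = [], [], []

    def row_of(sp: str, met: Metabolite | str) -> int:
        met_obj = met if isinstance(met, Metabolite) else None
        met_id = met.id if isinstance(met, Metabolite) else met
        if met_obj is not None and not met_obj.is_extracellular:
            return ridx[f"{sp}{SPECIES_SEP}{met_id}"]
        key = f"{sp}{SPECIES_SEP}{met_id}"
        return ridx[key] if key in ridx else ridx[met_id]

    for s in species:
        met_by_id = {m.id: m for m in s.metabolites}
        for r in s.reactions:
            j = len(col_keys)
            col_keys.append(f"{s.species_id}{SPECIES_SEP}{r.id}")
            for met_id, coef in r.stoichiometry.items():
                rows.append(row_of(s.species_id, met_by_id[met_id]))
                cols.append(j)
                vals.append(float(coef))
    for s in species:
        met_by_id = {m.id: m for m in s.metabolites}
        j = len(col_keys)
        col_keys.append(f"BIOMASS{SPECIES_SEP}{s.species_id}")
        for met_id, coef in s.biomass.stoichiometry.items():
            rows.append(row_of(s.species_id, met_by_id[met_id]))
            cols.append(j)
            vals.append(float(coef))
    for ex in exchanges:
        j = len(col_keys)
        col_keys.append(ex.id)
        (met_id,) = ex.stoichiometry
        rows.append(ridx[met_id])
        cols.append(j)
        vals.append(float(ex.stoichiometry[met_id]))

    C = sparse.csr_matrix((vals, (rows, cols)), shape=(len(row_keys), len(col_keys)))
    cm = CommunityModel(
        species=species,
        crossfed_metabolites=crossfed,
        env_exchanges=exchanges,
        X_T=float(X_T),
        C=C,
        row_keys=row_keys,
        col_keys=col_keys,
    )
    _check_crossfed_connectivity(cm)
    return cm


def _crossfed_touching(cm: CommunityModel, met_id: str):
    """(producers, consumers, exchanges) potentially acting on a cross-fed row."""
    producers, consumers = [], []
    for s in cm.species:
        for r in s.reactions:
            coef = r.stoichiometry.get(met_id, 0.0)
            if coef == 0:
                continue
            # a positive coefficient can produce if flux may be positive, etc.
            if (coef > 0 and r.upper_bound > 0) or (coef < 0 and r.lower_bound < 0):
                producers.append((s.species_id, r.id))
            if (coef < 0 and r.upper_bound > 0) or (coef > 0 and r.lower_bound < 0):
                consumers.append((s.species_id, r.id))
    exs = [ex.id for ex in cm.env_exchanges if met_id in ex.stoichiometry]
    return producers, consumers, exs


def _check_crossfed_connectivity(cm: CommunityModel) -> None:
    for cid in cm.crossfed_metabolites:
        producers, consumers, exs = _crossfed_touching(cm, cid)
        if not producers and not consumers and not exs:
            raise ModelError(
                f"cross-fed metabolite {cid!r} is touched by no transport or "
                "exchange column"
            )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    ok: bool
    issues: list[str]
    n_reactions_balance_checked: int
    n_reactions_balance_skipped: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        head = "OK" if self.ok else f"{len(self.issues)} issue(s)"
        return "\n".join([f"community validation: {head}"] + self.issues)


def _reaction_balance_issues(
    rxn_label: str,
    stoich: Mapping[str, float],
    mets: Mapping[str, Metabolite],
    tol: float = 1e-6,
) -> tuple[list[str], bool]:
    """Check element and charge conservation; returns (issues, checked)."""
    issues: list[str] = []
    involved = [mets[m] for m in stoich]
    if any(m.formula is None for m in involved):
        return issues, False  # unannotated carriers (e.g. energy/redox): skip
    totals: dict[str, float] = {}
    for m in involved:
        for el, n in parse_formula(m.formula).items():  # type: ignore[arg-type]
            totals[el] = totals.get(el, 0.0) + stoich[m.id] * n
    for el, t in totals.items():
        if abs(t) > tol:
            issues.append(f"reaction {rxn_label}: element {el} imbalanced by {t:+g}")
    if all(m.charge is not None for m in involved):
        qt = sum(stoich[m.id] * m.charge for m in involved)  # type: ignore[operator]
        if abs(qt) > tol:
            issues.append(f"reaction {rxn_label}: charge imbalanced by {qt:+g}")
    return issues, True


def validate_community(cm: CommunityModel) -> ValidationReport:
    """Report dead ends, elemental/charge imbalances and bound problems."""
    issues: list[str] = []
    checked = skipped = 0

    for cid in cm.crossfed_metabolites:
        producers, consumers, exs = _crossfed_touching(cm, cid)
        if producers and not consumers and not exs:
            issues.append(
                f"cross-fed metabolite {cid!r} has a producer but no consumer "
                "or exchange (dead end)"
            )
        can_supply = any(cm.get_exchange(e).lower_bound < 0 for e in exs)
        if consumers and not producers and not can_supply:
            issues.append(
                f"cross-fed metabolite {cid!r} has a consumer but no source"
            )

    for s in cm.species:
        mets = {m.id: m for m in s.metabolites}
        for r in s.reactions:
            if r.lower_bound > r.upper_bound:
                issues.append(f"reaction {s.species_id}::{r.id}: lb > ub")
            iss, was_checked = _reaction_balance_issues(
                f"{s.species_id}::{r.id}", r.stoichiometry, mets
            )
            issues.extend(iss)
            checked += was_checked
            skipped += not was_checked
    for ex in cm.env_exchanges:
        if ex.lower_bound > ex.upper_bound:
            issues.append(f"exchange {ex.id}: lb > ub")

    return ValidationReport(not issues, issues, checked, skipped)
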