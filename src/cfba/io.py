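"""Readers and writers: SBML, a tabular reaction-list dialect, configs.

Species models travel either as SBML Level 3 (with the flux-balance
constraints package for bounds and the biomass objective) or as a plain
two-section TSV that is convenient for coarse-grained models:

    [metabolites]
    id  name  role  owner  formula  charge
    [reactions]
    id  kind  equation  lb  ub

Equations use " + "-separated terms with optional coefficients and an
arrow (``->`` or ``<->``), e.g. ``1 glc + 0.2 NH3_e -> 1 bm``.  A
community configuration (JSON or YAML) lists the species files, the
cross-fed metabolite ids, environmental exchange bounds (absolute,
mmol·h⁻¹), the total biomass and optional chemostat settings.

On merge, species-scoped identifiers are prefixed ``<species>__`` while
extracellular ids stay global; cross-species metabolite identity is
always by declared extracellular id match, never by name heuristics.
All floats are serialized with 12 significant digits.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .lp import BalancedGrowthSolution, LinearConstraint, SolutionStatus
from .model import (
    CommunityModel,
    FractionVector,
    Metabolite,
    MetaboliteRole,
    ModelError,
    Reaction,
    ReactionKind,
    SpeciesModel,
    assemble_community,
    build_species_model,
)

__all__ = [
    "CommunityConfig",
    "ConfigError",
    "read_species_tabular",
    "write_species_tabular",
    "read_species_sbml",
    "write_species_sbml",
    "read_community_config",
    "write_community_config",
    "build_community_from_config",
    "write_solution",
    "read_solution",
    "write_scan",
    "parse_equation",
    "format_equation",
]

log = logging.getLogger("cfba")

#: bounds assumed when an SBML file carries no flux-bound information
FALLBACK_REVERSIBLE_BOUNDS = (-1000.0, 1000.0)
FALLBACK_IRREVERSIBLE_BOUNDS = (0.0, 1000.0)

_BIOMASS_NAME_RE = re.compile(r"biomass|growth", re.IGNORECASE)


class ConfigError(ModelError):
    """A community configuration violates its schema."""


def _fmt(x: float) -> str:
    if math.isinf(x):
        return "inf" if x > 0 else "-inf"
    return f"{x:.12g}"


def _round12(x: float) -> float:
    if x is None or math.isinf(x) or math.isnan(x):
        return x
    return float(f"{x:.12g}")


# ---------------------------------------------------------------------------
# reaction equations
# ---------------------------------------------------------------------------

_ARROWS = ("<->", "->", "→", "↔")


def parse_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse ``"1 A + 0.2 B -> 1 C"`` into signed stoichiometry.

    Returns (stoichiometry, reversible_flag).  Either side may be empty
    (pure sources or sinks such as a maintenance drain).
    """
    arrow = None
    for a in _ARROWS:
        if a in text:
            arrow = a
            break
    if arrow is None:
        raise ModelError(f"equation {text!r} has no arrow")
    lhs, rhs = text.split(arrow, 1)
    reversible = arrow in ("<->", "↔")
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 1:
                coef, met = 1.0, parts[0]
            elif len(parts) == 2:
                coef, met = float(parts[0]), parts[1]
            else:
                raise ModelError(f"cannot parse equation term {term!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef
    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    return stoich, reversible


def format_equation(stoich: dict[str, float]) -> str:
    lhs = [f"{_fmt(-c)} {m}" for m, c in stoich.items() if c < 0]
    rhs = [f"{_fmt(c)} {m}" for m, c in stoich.items() if c > 0]
    return f"{' + '.join(lhs)} -> {' + '.join(rhs)}"


# ---------------------------------------------------------------------------
# tabular dialect
# ---------------------------------------------------------------------------

def write_species_tabular(sp: SpeciesModel, path: str | Path) -> None:
    lines = ["[metabolites]", "id\tname\trole\towner\tformula\tcharge"]
    for m in sp.metabolites:
        lines.append("\t".join([
            m.id, m.name, m.role.value, m.owner_species or "",
            m.formula or "", "" if m.charge is None else _fmt(m.charge),
        ]))
    lines.append("[reactions]")
    lines.append("id\tkind\tequation\tlb\tub")
    for r in list(sp.reactions) + [sp.biomass]:
        lines.append("\t".join([
            r.id, r.kind.value, format_equation(dict(r.stoichiometry)),
            _fmt(r.lower_bound), _fmt(r.upper_bound),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_species_tabular(path: str | Path, species_id: str | None = None) -> SpeciesModel:
    text = Path(path).read_text()
    section = None
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    header: list[str] = []
    for raw in text.splitlines():
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if line.strip() in ("[metabolites]", "[reactions]"):
            section = line.strip()
            header = []
            continue
        if section is None:
            raise ModelError(f"{path}: content before any section header")
        if not header:
            header = line.split("\t")
            continue
        fields = dict(zip(header, line.split("\t")))
        if section == "[metabolites]":
            mets.append(Metabolite(
                id=fields["id"],
                name=fields.get("name", ""),
                role=MetaboliteRole(fields["role"]),
                owner_species=fields.get("owner") or None,
                formula=fields.get("formula") or None,
                charge=float(fields["charge"]) if fields.get("charge") else None,
            ))
        else:
            stoich, _ = parse_equation(fields["equation"])
            rxns.append(Reaction(
                id=fields["id"],
                kind=ReactionKind(fields["kind"]) if fields.get("kind") else None,
                stoichiometry=stoich,
                lower_bound=float(fields["lb"]),
                upper_bound=float(fields["ub"]),
            ))
    sid = species_id or Path(path).stem
    return build_species_model(sid, mets, rxns)


# ---------------------------------------------------------------------------
# SBML (Level 3 + fbc)
# ---------------------------------------------------------------------------

def _notes_xml(pairs: dict[str, str]) -> str:
    body = "".join(f"<p>{k}: {v}</p>" for k, v in pairs.items())
    return (
        '<notes><body xmlns="http://www.w3.org/1999/xhtml">'
        f"{body}</body></notes>"
    )


def _parse_notes(node) -> dict[str, str]:
    out: dict[str, str] = {}
    if node is None or not node.isSetNotes():
        return out
    text = node.getNotesString()
    for m in re.finditer(r"<p>\s*([^:<]+)\s*:\s*([^<]*)</p>", text):
        out[m.group(1).strip()] = m.group(2).strip()
    return out


def write_species_sbml(sp: SpeciesModel, path: str | Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.setId(sp.species_id)
    mplug = model.getPlugin("fbc")
    mplug.setStrict(True)

    for cid in ("cyt", "ext"):
        comp = model.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)

    for m in sp.metabolites:
        s = model.createSpecies()
        s.setId(m.id)
        s.setName(m.name or m.id)
        s.setCompartment("ext" if m.is_extracellular else "cyt")
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)
        splug = s.getPlugin("fbc")
        notes = {"role": m.role.value}
        if m.formula:
            # fbc only admits integer atom counts; fractional pseudo-
            # elemental compositions of lumped metabolites go in notes
            if re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", m.formula):
                splug.setChemicalFormula(m.formula)
            notes["formula"] = m.formula
        if m.charge is not None:
            splug.setCharge(int(m.charge))
        s.setNotes(_notes_xml(notes))

    def add_param(pid: str, value: float) -> str:
        p = model.createParameter()
        p.setId(pid)
        p.setValue(value if math.isfinite(value) else
                   (math.inf if value > 0 else -math.inf))
        p.setConstant(True)
        return pid

    for k, r in enumerate(list(sp.reactions) + [sp.biomass]):
        rx = model.createReaction()
        rx.setId(r.id)
        rx.setReversible(r.lower_bound < 0)
        rx.setFast(False)
        for met_id, coef in r.stoichiometry.items():
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies(met_id)
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(add_param(f"lb_{k}", r.lower_bound))
        rplug.setUpperFluxBound(add_param(f"ub_{k}", r.upper_bound))
        rx.setNotes(_notes_xml({"kind": r.kind.value}))

    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fo = obj.createFluxObjective()
    fo.setReaction(sp.biomass.id)
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")
    libsbml.writeSBMLToFile(doc, str(path))


def read_species_sbml(
    path: str | Path,
    species_id: str | None = None,
    crossfed_ids: tuple[str, ...] = (),
) -> SpeciesModel:
    """Read one organism from SBML.

    The biomass reaction is taken from the active flux objective when
    present, otherwise identified by a biomass/growth name pattern.
    Files without flux-bound information fall back to the conventional
    (−1000, 1000) / (0, 1000) defaults, with a logged warning.
    Extracellular species default to the unique-extracellular role (the
    community assembly reclassifies declared cross-fed ids); roles
    stored in notes by :func:`write_species_sbml` take precedence.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ModelError(
            f"unparseable SBML {path}: "
            + doc.getErrorLog().toString().strip()
        )
    model = doc.getModel()
    if model is None:
        raise ModelError(f"unparseable SBML {path}: no model element")
    sid = species_id or model.getId() or Path(path).stem

    ext_compartments = {
        c.getId() for c in model.getListOfCompartments()
        if re.search(r"^e$|ext|external|extracellular", c.getId(), re.IGNORECASE)
    }
    mets: list[Metabolite] = []
    for s in model.getListOfSpecies():
        notes = _parse_notes(s)
        if "role" in notes:
            role = MetaboliteRole(notes["role"])
        elif s.getCompartment() in ext_compartments:
            role = MetaboliteRole.UNIQUE_EXTRACELLULAR
        else:
            role = MetaboliteRole.INTRACELLULAR
        if s.getId() in crossfed_ids:
            role = MetaboliteRole.CROSSFED_EXTRACELLULAR
        splug = s.getPlugin("fbc")
        formula = notes.get("formula")
        charge = None
        if splug is not None:
            if formula is None and splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
            if splug.isSetCharge():
                charge = float(splug.getCharge())
        mets.append(Metabolite(
            id=s.getId(), name=s.getName() or "", role=role,
            formula=formula, charge=charge,
        ))

    biomass_ids: set[str] = set()
    mplug = model.getPlugin("fbc")
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getActiveObjective() or mplug.getObjective(0)
        if obj is not None:
            for fo in obj.getListOfFluxObjectives():
                if fo.getCoefficient() != 0:
                    biomass_ids.add(fo.getReaction())
    if not biomass_ids:
        biomass_ids = {
            r.getId() for r in model.getListOfReactions()
            if _BIOMASS_NAME_RE.search(r.getId())
            or _BIOMASS_NAME_RE.search(r.getName() or "")
        }
    if len(biomass_ids) > 1:
        raise ModelError(
            f"{path}: several biomass-flagged reactions: {sorted(biomass_ids)}"
        )
    if not biomass_ids:
        raise ModelError(f"{path}: no biomass reaction identifiable")
    (biomass_id,) = biomass_ids

    params = {p.getId(): p.getValue() for p in model.getListOfParameters()}
    rxns: list[Reaction] = []
    warned = False
    for r in model.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref in r.getListOfReactants():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for ref in r.getListOfProducts():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rplug = r.getPlugin("fbc")
        lb = ub = None
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = params.get(rplug.getLowerFluxBound())
            if rplug.isSetUpperFluxBound():
                ub = params.get(rplug.getUpperFluxBound())
        if lb is None or ub is None:
            fallback = (FALLBACK_REVERSIBLE_BOUNDS if r.getReversible()
                        else FALLBACK_IRREVERSIBLE_BOUNDS)
            lb = fallback[0] if lb is None else lb
            ub = fallback[1] if ub is None else ub
            if not warned:
                log.warning(
                    "%s: no flux bounds for some reactions; assuming %s/%s",
                    path, FALLBACK_REVERSIBLE_BOUNDS, FALLBACK_IRREVERSIBLE_BOUNDS,
                )
                warned = True
        notes = _parse_notes(r)
        kind = None
        if r.getId() == biomass_id:
            kind = ReactionKind.BIOMASS
        elif "kind" in notes and notes["kind"] != ReactionKind.BIOMASS.value:
            kind = ReactionKind(notes["kind"])
        rxns.append(Reaction(
            id=r.getId(), stoichiometry=stoich, kind=kind,
            lower_bound=float(lb), upper_bound=float(ub),
        ))
    return build_species_model(sid, mets, rxns)


# ---------------------------------------------------------------------------
# community configuration
# ---------------------------------------------------------------------------

@dataclass
class CommunityConfig:
    """Declarative description of a consortium and its environment."""

    species_files: list[str]
    crossfed_ids: list[str] = field(default_factory=list)
    exchange_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    X_T: float = 1.0
    fixed_mu: float | None = None
    extra_constraints: list[LinearConstraint] = field(default_factory=list)
    allow_env_supply_of_crossfed: bool = False

    def validate(self) -> None:
        if not self.species_files:
            raise ConfigError("species_files: at least one species required")
        if self.X_T <= 0:
            raise ConfigError(f"X_T: must be positive, got {self.X_T}")
        if self.fixed_mu is not None and self.fixed_mu < 0:
            raise ConfigError(f"fixed_mu: must be >= 0, got {self.fixed_mu}")
        for met, (lb, ub) in self.exchange_bounds.items():
            if lb > ub:
                raise ConfigError(f"exchange_bounds.{met}: lb {lb} > ub {ub}")


def _as_float(v, where: str) -> float:
    if isinstance(v, str):
        s = v.strip().lower()
        if s in ("inf", "+inf", "infinity"):
            return math.inf
        if s in ("-inf", "-infinity"):
            return -math.inf
    try:
        return float(v)
    except (TypeError, ValueError):
        raise ConfigError(f"{where}: expected a number, got {v!r}") from None


def read_community_config(path: str | Path) -> CommunityConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {
        "species_files", "crossfed_ids", "exchange_bounds", "X_T",
        "fixed_mu", "extra_constraints", "allow_env_supply_of_crossfed",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    files = raw.get("species_files")
    if not isinstance(files, list) or not all(isinstance(f, str) for f in files):
        raise ConfigError("species_files: must be a list of paths")
    exchange_bounds: dict[str, tuple[float, float]] = {}
    for met, pair in (raw.get("exchange_bounds") or {}).items():
        if not isinstance(pair, (list, tuple)) or len(pair) != 2:
            raise ConfigError(f"exchange_bounds.{met}: expected [lb, ub]")
        exchange_bounds[met] = (
            _as_float(pair[0], f"exchange_bounds.{met}[0]"),
            _as_float(pair[1], f"exchange_bounds.{met}[1]"),
        )
    constraints = []
    for i, c in enumerate(raw.get("extra_constraints") or []):
        if not isinstance(c, dict) or "coeffs" not in c:
            raise ConfigError(f"extra_constraints[{i}]: expected a mapping with coeffs")
        constraints.append(LinearConstraint(
            coeffs={k: _as_float(v, f"extra_constraints[{i}].coeffs.{k}")
                    for k, v in c["coeffs"].items()},
            sense=c.get("sense", "<="),
            rhs=_as_float(c.get("rhs", 0.0), f"extra_constraints[{i}].rhs"),
        ))
    cfg = CommunityConfig(
        species_files=list(files),
        crossfed_ids=list(raw.get("crossfed_ids") or []),
        exchange_bounds=exchange_bounds,
        X_T=_as_float(raw.get("X_T", 1.0), "X_T"),
        fixed_mu=(None if raw.get("fixed_mu") is None
                  else _as_float(raw["fixed_mu"], "fixed_mu")),
        extra_constraints=constraints,
        allow_env_supply_of_crossfed=bool(
            raw.get("allow_env_supply_of_crossfed", False)
        ),
    )
    cfg.validate()
    return cfg


def write_community_config(cfg: CommunityConfig, path: str | Path) -> None:
    data = {
        "species_files": cfg.species_files,
        "crossfed_ids": cfg.crossfed_ids,
        "exchange_bounds": {
            met: [_round12(lb), _round12(ub)]
            for met, (lb, ub) in cfg.exchange_bounds.items()
        },
        "X_T": _round12(cfg.X_T),
    }
    if cfg.fixed_mu is not None:
        data["fixed_mu"] = _round12(cfg.fixed_mu)
    if cfg.extra_constraints:
        data["extra_constraints"] = [
            {"coeffs": c.coeffs, "sense": c.sense, "rhs": _round12(c.rhs)}
            for c in cfg.extra_constraints
        ]
    if cfg.allow_env_supply_of_crossfed:
        data["allow_env_supply_of_crossfed"] = True
    text = yaml.safe_dump(data, sort_keys=False, default_flow_style=None)
    # YAML has no native infinity spelling shared with JSON; use .inf form
    Path(path).write_text(text)


def build_community_from_config(
    cfg: CommunityConfig, base_dir: str | Path = "."
) -> CommunityModel:
    cfg.validate()
    base = Path(base_dir)
    species = []
    for fname in cfg.species_files:
        p = base / fname
        if not p.exists():
            raise ConfigError(f"species file not found: {p}")
        if p.suffix.lower() in (".xml", ".sbml"):
            species.append(read_species_sbml(p, crossfed_ids=tuple(cfg.crossfed_ids)))
        else:
            species.append(read_species_tabular(p))
    exchanges = [
        Reaction(f"EX_{met}", {met: -1.0}, kind=ReactionKind.ENV_EXCHANGE,
                 lower_bound=lb, upper_bound=ub)
        for met, (lb, ub) in cfg.exchange_bounds.items()
    ]
    return assemble_community(
        species, crossfed_ids=cfg.crossfed_ids, env_exchanges=exchanges,
        X_T=cfg.X_T,
        allow_env_supply_of_crossfed=cfg.allow_env_supply_of_crossfed,
    )


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def _solution_payload(sol: BalancedGrowthSolution) -> dict:
    payload: dict = {"status": sol.status.value}
    if sol.fractions is not None:
        payload["fractions"] = {k: _round12(v) for k, v in sol.fractions.f.items()}
    if sol.status is SolutionStatus.OPTIMAL:
        payload["mu"] = _round12(sol.mu)
        payload["objective_value"] = _round12(sol.objective_value)
        payload["q"] = {
            f"{sp}__{rxn}": _round12(v) for (sp, rxn), v in sol.q.items()
        }
        payload["phi"] = {k: _round12(v) for k, v in sol.phi.items()}
        payload["binding"] = list(sol.binding)
    return payload


def write_solution(
    sol: BalancedGrowthSolution, path: str | Path, format: str = "json"
) -> None:
    """Serialize a solved state; infeasible solutions carry no fluxes."""
    path = Path(path)
    payload = _solution_payload(sol)
    if format == "json":
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif format == "tsv":
        lines = [f"# status\t{payload['status']}"]
        if "mu" in payload:
            lines.append(f"# mu\t{_fmt(payload['mu'])}")
        for sp, v in (payload.get("fractions") or {}).items():
            lines.append(f"# fraction_{sp}\t{_fmt(v)}")
        lines.append("type\tflux_id\tvalue")
        for k, v in (payload.get("q") or {}).items():
            lines.append(f"q\t{k}\t{_fmt(v)}")
        for k, v in (payload.get("phi") or {}).items():
            lines.append(f"phi\t{k}\t{_fmt(v)}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ModelError(f"unknown solution format {format!r}")


def read_solution(path: str | Path) -> BalancedGrowthSolution:
    payload = json.loads(Path(path).read_text())
    status = SolutionStatus(payload["status"])
    sol = BalancedGrowthSolution(status=status)
    if "fractions" in payload:
        sol.fractions = FractionVector(payload["fractions"])
    if status is SolutionStatus.OPTIMAL:
        sol.mu = payload["mu"]
        sol.objective_value = payload.get("objective_value")
        for key, v in payload.get("q", {}).items():
            sp, _, rxn = key.partition("__")
            sol.q[(sp, rxn)] = v
        sol.phi = dict(payload.get("phi", {}))
        sol.binding = list(payload.get("binding", []))
    return sol


def write_scan(scan, path: str | Path) -> None:
    """Write a fraction scan as TSV, one row per grid point."""
    df = scan.to_dataframe()
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
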