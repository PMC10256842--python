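"""Constraint-based analysis of metabolite supplementation rescue.

This module asks which metabolic lesion best explains an observed pattern of
growth rescue by nutrient supplements.  A drug of unknown mechanism inhibits
growth; feeding the culture different metabolites rescues some of that
inhibition for some supplements and not others.  Each candidate lesion is
expressed as a constraint on a stoichiometric model — a fractional cap on the
flux of a target pathway, an enforced drain on a cofactor (e.g. a charged
folate species), or a hard knockout — and flux balance analysis (FBA) predicts
the growth benefit of every supplement under that lesion.  The lesion whose
predicted benefit vector correlates best with the experimental rescue pattern
is the mechanistic hypothesis the data supports.

FBA here is a linear program: maximize the biomass flux mu subject to
steady-state mass balance S·v = 0 and flux bounds l <= v <= u.  Because the
optimum is usually degenerate, reference fluxes (needed for fractional caps)
are taken from a parsimonious FBA (pFBA) solution: biomass is fixed at its
optimum and total absolute flux is minimized, which selects a unique,
thermodynamically sensible flux distribution.

The LP is solved with scipy's HiGHS backend directly from the stoichiometric
matrix; no external modelling framework is required.
"""

from __future__ import annotations

import ast
import copy
import json
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxSolution",
    "InhibitionScenario",
    "ModelValidationError",
    "read_model",
    "write_model",
    "fba",
    "pfba",
    "evaluate_gene_rule",
    "apply_expression_shutoff",
    "close_spontaneous_reactions",
    "inhibit_pathway",
    "add_cofactor_drain",
    "supplement",
    "remove_supplement",
    "growth_benefit",
    "benefit_vector",
    "random_inhibition_null",
    "enumerate_knockout_benefits",
    "rank_scenarios",
]

FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-8
_BIG = 1000.0


class ModelValidationError(ValueError):
    """Raised when a model file or in-memory model violates its contract."""


@dataclass
class Metabolite:
    id: str
    compartment: str = "c"
    name: str = ""


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = _BIG
    gene_rule: str = ""
    spontaneous: bool = False
    objective_coefficient: float = 0.0
    name: str = ""

    def copy(self) -> "Reaction":
        r = copy.copy(self)
        r.stoichiometry = dict(self.stoichiometry)
        return r


@dataclass
class MetabolicModel:
    """Stoichiometric model: metabolites, bounded reactions, one objective.

    Exchange reactions are those touching a single metabolite (system
    boundary); uptake is negative exchange flux, secretion positive.
    """

    id: str = "model"
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)

    # -- lookups ---------------------------------------------------------
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction {rid!r} in model {self.id!r}")

    def has_metabolite(self, mid: str) -> bool:
        return any(m.id == mid for m in self.metabolites)

    @property
    def objective_id(self) -> str:
        for r in self.reactions:
            if r.objective_coefficient:
                return r.id
        raise ModelValidationError("model has no objective reaction")

    @property
    def exchanges(self) -> list[str]:
        return [r.id for r in self.reactions if len(r.stoichiometry) == 1]

    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= _rule_genes(r.gene_rule)
        return out

    def stoichiometric_matrix(self) -> pd.DataFrame:
        """Dense S as metabolite x reaction DataFrame."""
        mets = self.metabolite_ids()
        S = pd.DataFrame(0.0, index=mets, columns=self.reaction_ids())
        for r in self.reactions:
            for m, coef in r.stoichiometry.items():
                S.loc[m, r.id] = coef
        return S

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=[copy.copy(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
        )

    def validate(self) -> None:
        mids = self.metabolite_ids()
        if len(set(mids)) != len(mids):
            raise ModelValidationError("duplicate metabolite ids")
        rids = self.reaction_ids()
        if len(set(rids)) != len(rids):
            raise ModelValidationError("duplicate reaction ids")
        known = set(mids)
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(
                    f"reaction {r.id!r}: lower bound {r.lower_bound} exceeds "
                    f"upper bound {r.upper_bound}"
                )
            dangling = set(r.stoichiometry) - known
            if dangling:
                raise ModelValidationError(
                    f"reaction {r.id!r} references unknown metabolites {sorted(dangling)}"
                )
            if not r.stoichiometry:
                raise ModelValidationError(f"reaction {r.id!r} has empty stoichiometry")
        self.objective_id  # raises if absent


@dataclass
class FluxSolution:
    """Result of one FBA/pFBA solve.

    fluxes are in the model's flux units (mmol/gDW/hr conventionally);
    objective_value is the biomass flux mu (1/hr for a growth objective).
    """

    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: pd.Series

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


# ---------------------------------------------------------------------------
# JSON i/o (community constraint-based schema: metabolites/reactions/genes)
# ---------------------------------------------------------------------------

def write_model(model: MetabolicModel, path) -> None:
    doc = {
        "id": model.id,
        "version": "1",
        "compartments": {c: c for c in {m.compartment for m in model.metabolites}},
        "metabolites": [
            {"id": m.id, "name": m.name or m.id, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name or r.id,
                "metabolites": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gene_rule,
                "objective_coefficient": r.objective_coefficient,
                "notes": {"spontaneous": r.spontaneous} if r.spontaneous else {},
            }
            for r in model.reactions
        ],
        "genes": [{"id": g, "name": g} for g in sorted(model.genes())],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=False)


def read_model(path) -> MetabolicModel:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        mets = [
            Metabolite(d["id"], d.get("compartment", "c"), d.get("name", ""))
            for d in doc["metabolites"]
        ]
        rxns = [
            Reaction(
                id=d["id"],
                stoichiometry={k: float(v) for k, v in d["metabolites"].items()},
                lower_bound=float(d.get("lower_bound", 0.0)),
                upper_bound=float(d.get("upper_bound", _BIG)),
                gene_rule=d.get("gene_reaction_rule", ""),
                spontaneous=bool(d.get("notes", {}).get("spontaneous", False)),
                objective_coefficient=float(d.get("objective_coefficient", 0.0)),
                name=d.get("name", ""),
            )
            for d in doc["reactions"]
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelValidationError(f"malformed model file {path}: {exc}") from exc
    model = MetabolicModel(id=doc.get("id", "model"), metabolites=mets, reactions=rxns)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# LP core
# ---------------------------------------------------------------------------

def _lp_arrays(model: MetabolicModel):
    mets = model.metabolite_ids()
    midx = {m: i for i, m in enumerate(mets)}
    n = len(model.reactions)
    S = np.zeros((len(mets), n))
    lb = np.empty(n)
    ub = np.empty(n)
    c = np.zeros(n)
    for j, r in enumerate(model.reactions):
        for m, coef in r.stoichiometry.items():
            S[midx[m], j] = coef
        lb[j], ub[j], c[j] = r.lower_bound, r.upper_bound, r.objective_coefficient
    return S, lb, ub, c


def fba(model: MetabolicModel, parsimonious: bool = True) -> FluxSolution:
    """Maximize the objective flux; optionally follow with a pFBA step.

    The parsimonious step fixes the objective at its optimum and minimizes
    total absolute flux, selecting a unique representative among degenerate
    optima.  It never changes the objective value.
    """
    model.validate()
    S, lb, ub, c = _lp_arrays(model)
    res = linprog(-c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    if res.status == 2:
        return FluxSolution("infeasible", math.nan,
                            pd.Series(math.nan, index=model.reaction_ids()))
    if res.status == 3:
        return FluxSolution("unbounded", math.inf,
                            pd.Series(math.nan, index=model.reaction_ids()))
    if res.status != 0:
        raise RuntimeError(f"LP solver failure: {res.message}")
    mu = -res.fun
    fluxes = res.x
    if parsimonious:
        fluxes = _pfba_fluxes(S, lb, ub, c, mu)
    return FluxSolution("optimal", mu, pd.Series(fluxes, index=model.reaction_ids()))


def pfba(model: MetabolicModel) -> FluxSolution:
    """Parsimonious FBA: the unique minimal-total-flux optimum."""
    return fba(model, parsimonious=True)


def _pfba_fluxes(S, lb, ub, c, mu) -> np.ndarray:
    # v = p - q with p, q >= 0; fix c.v = mu (tiny relaxation for solver noise)
    n = S.shape[1]
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(S.shape[0])
    bounds = []
    for j in range(n):
        bounds.append((max(lb[j], 0.0), max(ub[j], 0.0)))
    for j in range(n):
        bounds.append((max(-ub[j], 0.0), max(-lb[j], 0.0)))
    cc = np.concatenate([c, -c])
    A_ub = np.vstack([cc, -cc])
    eps = max(1e-9, abs(mu) * 1e-9)
    b_ub = np.array([mu + eps, -(mu - eps)])
    res = linprog(np.ones(2 * n), A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub,
                  bounds=bounds, method="highs")
    if res.status != 0:  # pragma: no cover - fixed-point LP is always feasible
        raise RuntimeError(f"pFBA LP failure: {res.message}")
    return res.x[:n] - res.x[n:]


# ---------------------------------------------------------------------------
# Gene rules (GPR)
# ---------------------------------------------------------------------------

def _rule_genes(rule: str) -> set[str]:
    if not rule.strip():
        return set()
    tree = _parse_rule(rule)
    out: set[str] = set()

    def walk(node):
        if isinstance(node, ast.Name):
            out.add(node.id)
        elif isinstance(node, ast.BoolOp):
            for v in node.values:
                walk(v)
        else:
            raise ModelValidationError(f"unsupported token in gene rule {rule!r}")

    walk(tree)
    return out


def _parse_rule(rule: str):
    try:
        tree = ast.parse(rule, mode="eval").body
    except SyntaxError as exc:
        raise ModelValidationError(f"unparseable gene rule {rule!r}") from exc
    return tree


def evaluate_gene_rule(rule: str, unexpressed: set[str]) -> bool:
    """Evaluate a boolean AND/OR gene rule; genes are active unless listed.

    An empty rule means no genetic requirement and always evaluates True.
    """
    if not rule.strip():
        return True
    tree = _parse_rule(rule)

    def ev(node) -> bool:
        if isinstance(node, ast.Name):
            return node.id not in unexpressed
        if isinstance(node, ast.BoolOp):
            vals = [ev(v) for v in node.values]
            return all(vals) if isinstance(node.op, ast.And) else any(vals)
        raise ModelValidationError(f"unsupported token in gene rule {rule!r}")

    return ev(tree)


# ---------------------------------------------------------------------------
# Scenario construction
# ---------------------------------------------------------------------------

def _metabolite_neighborhood(model: MetabolicModel, seeds: list[str], k: int) -> set[str]:
    """Reaction ids within k reaction-steps of the seed metabolites."""
    consumers_producers: dict[str, list[Reaction]] = {}
    for r in model.reactions:
        for m in r.stoichiometry:
            consumers_producers.setdefault(m, []).append(r)
    seen_m = set(seeds)
    seen_r: set[str] = set()
    frontier = deque((m, 0) for m in seeds)
    while frontier:
        met, depth = frontier.popleft()
        if depth >= k:
            continue
        for r in consumers_producers.get(met, []):
            if r.id in seen_r:
                continue
            seen_r.add(r.id)
            for m2 in r.stoichiometry:
                if m2 not in seen_m:
                    seen_m.add(m2)
                    frontier.append((m2, depth + 1))
    return seen_r


def apply_expression_shutoff(
    model: MetabolicModel,
    unexpressed_genes,
    scope: str = "neighborhood",
    around_metabolites: list[str] | None = None,
    k: int = 2,
) -> MetabolicModel:
    """Close reactions whose gene rule is unsatisfied by the expressed genes.

    scope="global" closes every such reaction; scope="neighborhood" (default)
    closes only reactions within k reaction-steps of `around_metabolites`
    (typically the supplemented metabolites), because a global shutoff of a
    genome-scale model is often lethal in silico even when the cell grows.
    """
    unexpressed = set(unexpressed_genes)
    out = model.copy()
    if scope == "global" or around_metabolites is None:
        allowed = None
    elif scope == "neighborhood":
        allowed = _metabolite_neighborhood(out, around_metabolites, k)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    for r in out.reactions:
        if allowed is not None and r.id not in allowed:
            continue
        if not evaluate_gene_rule(r.gene_rule, unexpressed):
            r.lower_bound = 0.0
            r.upper_bound = 0.0
    return out


def close_spontaneous_reactions(model: MetabolicModel) -> MetabolicModel:
    """Close all reactions flagged spontaneous (uncatalyzed, low-rate)."""
    out = model.copy()
    for r in out.reactions:
        if r.spontaneous:
            r.lower_bound = 0.0
            r.upper_bound = 0.0
    return out


def inhibit_pathway(
    model: MetabolicModel,
    reactions: list[str],
    fraction: float,
    reference: FluxSolution | None = None,
) -> MetabolicModel:
    """Cap each target reaction's flux magnitude at fraction x its pFBA flux.

    A target carrying zero reference flux is capped at zero.  The resulting
    optimum can only decrease.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if reference is None:
        reference = pfba(model)
    if not reference.optimal:
        raise ValueError("reference FBA is not optimal; cannot derive caps")
    out = model.copy()
    for rid in reactions:
        r = out.get_reaction(rid)
        cap = fraction * abs(reference.fluxes[rid])
        r.upper_bound = min(r.upper_bound, cap)
        r.lower_bound = max(r.lower_bound, -cap)
    return out


def add_cofactor_drain(
    model: MetabolicModel,
    charged_id: str,
    discharged_id: str,
    drain_rate: float,
) -> MetabolicModel:
    """Add an enforced charged->discharged cofactor conversion.

    The drain reaction has a lower bound equal to drain_rate, forcing the
    network to regenerate at least that much charged cofactor on top of its
    biosynthetic demands — a flux model of cofactor sequestration/depletion.
    """
    for mid in (charged_id, discharged_id):
        if not model.has_metabolite(mid):
            raise KeyError(f"metabolite {mid!r} not in model")
    if drain_rate < 0:
        raise ValueError("drain_rate must be >= 0")
    out = model.copy()
    out.reactions.append(
        Reaction(
            id=f"DRAIN_{charged_id}_{discharged_id}",
            stoichiometry={charged_id: -1.0, discharged_id: 1.0},
            lower_bound=drain_rate,
            upper_bound=_BIG,
            name=f"enforced {charged_id} drain",
        )
    )
    return out


def _exchange_for(model: MetabolicModel, metabolite: str) -> str | None:
    candidates = {metabolite, metabolite + "_e"}
    for r in model.reactions:
        if len(r.stoichiometry) == 1 and next(iter(r.stoichiometry)) in candidates:
            return r.id
    return None


def supplement(
    model: MetabolicModel,
    metabolite: str,
    rate: float = 0.1,
    create_exchange: bool = False,
) -> MetabolicModel:
    """Open uptake of a metabolite at up to `rate` mmol/gDW/hr.

    Exchange sign convention: negative flux is uptake, so the exchange lower
    bound is set to -rate.  With create_exchange=True a missing exchange (and
    importer, if the external species is also absent) is added; otherwise a
    metabolite with no exchange raises KeyError.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if not (model.has_metabolite(metabolite) or model.has_metabolite(metabolite + "_e")):
        raise KeyError(f"metabolite {metabolite!r} not in model")
    out = model.copy()
    ex = _exchange_for(out, metabolite)
    if ex is None:
        if not create_exchange:
            raise KeyError(f"no exchange reaction for metabolite {metabolite!r}")
        ext = metabolite + "_e"
        if not out.has_metabolite(ext):
            out.metabolites.append(Metabolite(ext, compartment="e"))
            out.reactions.append(
                Reaction(id=f"{metabolite.upper()}t_auto",
                         stoichiometry={ext: -1.0, metabolite: 1.0})
            )
        ex = f"EX_{ext}"
        out.reactions.append(Reaction(id=ex, stoichiometry={ext: -1.0}))
    exr = out.get_reaction(ex)
    exr.lower_bound = min(exr.lower_bound, -rate)
    return out


def remove_supplement(model: MetabolicModel, metabolite: str) -> MetabolicModel:
    """Close uptake of a metabolite (exchange lower bound back to 0)."""
    out = model.copy()
    ex = _exchange_for(out, metabolite)
    if ex is None:
        raise KeyError(f"no exchange for metabolite {metabolite!r}")
    out.get_reaction(ex).lower_bound = max(out.get_reaction(ex).lower_bound, 0.0)
    return out


# ---------------------------------------------------------------------------
# Scenarios and benefits
# ---------------------------------------------------------------------------

@dataclass
class InhibitionScenario:
    """A named candidate lesion applied to a model.

    kind:
      pathway_fraction — cap |flux| of `targets` at `fraction` x pFBA reference
      cofactor_drain   — force `drain_rate` flux through charged->discharged
      knockout         — constrain `targets` to zero flux
    """

    name: str
    kind: str
    targets: list[str] = field(default_factory=list)
    fraction: float = 0.9
    charged: str = ""
    discharged: str = ""
    drain_rate: float = 0.0

    def apply(self, model: MetabolicModel) -> MetabolicModel:
        if self.kind == "pathway_fraction":
            return inhibit_pathway(model, self.targets, self.fraction)
        if self.kind == "cofactor_drain":
            return add_cofactor_drain(model, self.charged, self.discharged, self.drain_rate)
        if self.kind == "knockout":
            out = model.copy()
            for rid in self.targets:
                r = out.get_reaction(rid)
                r.lower_bound = 0.0
                r.upper_bound = 0.0
            return out
        raise ValueError(f"unknown scenario kind {self.kind!r}")


def growth_benefit(
    model: MetabolicModel,
    scenario: InhibitionScenario | None,
    metabolite: str,
    rate: float = 0.1,
) -> float:
    """Growth benefit of one supplement under one lesion.

    benefit = mu(lesioned + supplemented) - mu(lesioned).  A supplement is a
    pure relaxation of bounds, so the benefit is never negative (up to solver
    tolerance).  NaN if the lesioned model itself is infeasible.
    """
    lesioned = scenario.apply(model) if scenario is not None else model
    base = fba(lesioned, parsimonious=False)
    if not base.optimal:
        return math.nan
    try:
        supped = supplement(lesioned, metabolite, rate)
    except KeyError:
        return 0.0  # no uptake route: the supplement cannot confer anything
    supp = fba(supped, parsimonious=False)
    return supp.objective_value - base.objective_value


def benefit_vector(
    model: MetabolicModel,
    scenario: InhibitionScenario | None,
    supplements: list[str],
    rate: float = 0.1,
) -> pd.Series:
    """Growth benefit of each supplement under one lesion."""
    lesioned = scenario.apply(model) if scenario is not None else model
    base = fba(lesioned, parsimonious=False)
    vals = {}
    for met in supplements:
        if not base.optimal:
            vals[met] = math.nan
            continue
        try:
            supped = supplement(lesioned, met, rate)
        except KeyError:
            vals[met] = 0.0
            continue
        supp = fba(supped, parsimonious=False)
        vals[met] = supp.objective_value - base.objective_value
    name = scenario.name if scenario is not None else "baseline"
    return pd.Series(vals, name=name)


def enumerate_knockout_benefits(
    model: MetabolicModel,
    supplements: list[str],
    rate: float = 0.1,
    exclude: set[str] | None = None,
) -> pd.DataFrame:
    """Benefit vectors for every single-reaction knockout (scenario x supplement)."""
    exclude = set(exclude or ())
    obj = model.objective_id
    rows = []
    for r in model.reactions:
        if r.id == obj or r.id in exclude or len(r.stoichiometry) == 1:
            continue
        sc = InhibitionScenario(name=f"ko:{r.id}", kind="knockout", targets=[r.id])
        rows.append(benefit_vector(model, sc, supplements, rate))
    return pd.DataFrame(rows)


def random_inhibition_null(
    model: MetabolicModel,
    supplements: list[str],
    n_scenarios: int,
    seed: int,
    rate: float = 0.1,
) -> pd.DataFrame:
    """Benefit vectors for randomly sampled single-reaction knockouts.

    Sampling (with replacement across draws, deterministic under seed) from
    the internal reactions excluding the objective.
    """
    if n_scenarios < 1:
        raise ValueError("n_scenarios must be >= 1")
    rng = np.random.default_rng(seed)
    obj = model.objective_id
    pool = [r.id for r in model.reactions if r.id != obj and len(r.stoichiometry) > 1]
    picks = rng.choice(len(pool), size=n_scenarios, replace=n_scenarios > len(pool))
    rows = []
    for i in picks:
        sc = InhibitionScenario(name=f"ko:{pool[i]}", kind="knockout", targets=[pool[i]])
        rows.append(benefit_vector(model, sc, supplements, rate))
    return pd.DataFrame(rows)


def rank_scenarios(
    benefit_tables: pd.DataFrame,
    experimental: pd.Series,
) -> pd.DataFrame:
    """Rank lesion scenarios by Pearson correlation with experimental rescue.

    benefit_tables: scenario x supplement growth benefits.
    experimental:   supplement -> observed rescue growth rate (1/hr).
    Scenarios with undefined correlation (zero-variance or NaN benefits) sort
    last; ties break by scenario name.
    """
    shared = [s for s in benefit_tables.columns if s in experimental.index]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared supplements to correlate")
    exp = experimental[shared].astype(float)
    recs = []
    for name, row in benefit_tables[shared].iterrows():
        vals = row.astype(float)
        if vals.isna().any() or np.isclose(vals.std(ddof=0), 0.0) or np.isclose(exp.std(ddof=0), 0.0):
            r = math.nan
        else:
            r = float(np.corrcoef(vals.to_numpy(), exp.to_numpy())[0, 1])
        recs.append({"scenario": name, "pearson_r": r})
    out = pd.DataFrame(recs)
    out["_undef"] = out["pearson_r"].isna()
    out = out.sort_values(["_undef", "pearson_r", "scenario"],
                          ascending=[True, False, True]).drop(columns="_undef")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)
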