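"""Reaction-network ODE models: representation, SBML I/O, knockouts, RHS assembly.

The central object is :class:`ReactionNetwork`, an explicit list of species,
reactions (each with an infix rate-law expression) and parameter values.  It
represents the single-cell TNF-R1 signaling model — receptor complex, NF-κB
pathway and caspase-activation pathway — as deposited in SBML, as well as the
small closed-form toy networks used to validate the downstream estimators.

Only the ODE fragment of SBML level 2 is supported (compartments, species,
parameters, reactions with kinetic laws).  Constructs that alter the ODE
semantics — events, rules of any kind, function definitions, constraints,
initial assignments — raise :class:`~tnfpop.errors.UnsupportedSBMLError`
rather than being silently dropped.
"""

from __future__ import annotations

import copy as _copy
import json
import re
from dataclasses import dataclass, field

import numpy as np
import sympy as sp
from lxml import etree

from .errors import (
    NetworkValidationError,
    ProductionRateError,
    SBMLParseError,
    UnsupportedSBMLError,
)

_MATHML_NS = "http://www.w3.org/1998/Math/MathML"
_ANNOT_NS = "https://tnfpop.invalid/metadata"

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "DerivativeFunction",
    "load_sbml",
    "write_sbml",
    "identify_production_rates",
    "apply_knockout",
    "build_rhs",
]


@dataclass
class Species:
    id: str
    name: str
    initial_amount: float
    compartment: str
    boundary: bool = False  # boundary species keep a zero derivative


@dataclass
class Reaction:
    """One reaction: stoichiometry plus an infix rate-law expression.

    ``reactants`` and ``products`` map species id -> positive integer
    stoichiometric coefficient.  ``rate_law`` is an infix expression over
    species ids, global parameter ids, local parameter ids and compartment
    ids; ``local_params`` shadow global parameters of the same id.
    """

    id: str
    name: str
    reactants: dict[str, int]
    products: dict[str, int]
    rate_law: str
    modifiers: list[str] = field(default_factory=list)
    local_params: dict[str, float] = field(default_factory=dict)


@dataclass
class ReactionNetwork:
    """Species, reactions and parameters of one ODE reaction network.

    ``production_rate_ids`` lists, in document order, the parameter ids of
    the zeroth-order protein synthesis ("expression") reactions eligible for
    population distribution; for the nominal TNF-R1 cell model this list has
    exactly 19 entries.  ``metadata`` carries model-level conventions that
    SBML itself does not encode: the id of the free-TNF species, the
    ng/ml -> model-unit dose conversion factor, the death readout and
    whether an unstimulated steady state exists (pure source models such as
    the toy death timer have none).
    """

    species: list[Species]
    reactions: list[Reaction]
    parameters: dict[str, float]
    compartments: dict[str, float] = field(default_factory=dict)
    production_rate_ids: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    # -- basic introspection -------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def species_index(self, species_id: str) -> int:
        try:
            return self.species_ids.index(species_id)
        except ValueError:
            raise KeyError(f"unknown species id {species_id!r}") from None

    def reaction(self, reaction_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise KeyError(
            f"unknown reaction id {reaction_id!r}; available: "
            f"{[r.id for r in self.reactions]}"
        )

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_amount for s in self.species], dtype=float)

    def copy(self) -> "ReactionNetwork":
        return _copy.deepcopy(self)

    # -- validation ----------------------------------------------------------
    def validate(self) -> None:
        """Check structural invariants; raise NetworkValidationError on the first hit."""
        ids = set(self.species_ids)
        if len(ids) != len(self.species):
            raise NetworkValidationError("duplicate species ids")
        known = ids | set(self.parameters) | set(self.compartments) | {"t"}
        for s in self.species:
            if not np.isfinite(s.initial_amount) or s.initial_amount < 0:
                raise NetworkValidationError(
                    f"species {s.id!r}: initial amount must be finite and >= 0"
                )
        for pid, v in self.parameters.items():
            if not np.isfinite(v):
                raise NetworkValidationError(f"parameter {pid!r} is not finite")
        for r in self.reactions:
            for side_name, side in (("reactant", r.reactants), ("product", r.products)):
                for sid, coef in side.items():
                    if sid not in ids:
                        raise NetworkValidationError(
                            f"reaction {r.id!r}: unknown {side_name} species {sid!r}"
                        )
                    if not (isinstance(coef, (int, np.integer)) and coef > 0):
                        raise NetworkValidationError(
                            f"reaction {r.id!r}: stoichiometry of {sid!r} must be a "
                            f"positive integer, got {coef!r}"
                        )
            for sym in _rate_law_symbols(r.rate_law):
                if sym not in known and sym not in r.local_params:
                    raise NetworkValidationError(
                        f"reaction {r.id!r}: rate law references unknown id {sym!r}"
                    )
        for pid in self.production_rate_ids:
            if pid not in self.parameters and not any(
                pid in r.local_params for r in self.reactions
            ):
                raise NetworkValidationError(
                    f"production rate id {pid!r} not found among parameters"
                )

    # -- provenance ----------------------------------------------------------
    def summary(self) -> dict:
        """Normalized model summary (JSON-serializable) for provenance logging."""
        return {
            "species": [
                {
                    "id": s.id,
                    "name": s.name,
                    "initial_amount": s.initial_amount,
                    "compartment": s.compartment,
                    "boundary": s.boundary,
                }
                for s in self.species
            ],
            "reactions": [
                {
                    "id": r.id,
                    "name": r.name,
                    "reactants": r.reactants,
                    "products": r.products,
                    "rate_law": r.rate_law,
                    "local_params": r.local_params,
                }
                for r in self.reactions
            ],
            "parameters": dict(self.parameters),
            "compartments": dict(self.compartments),
            "production_rate_ids": list(self.production_rate_ids),
            "metadata": self.metadata,
        }

    def write_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# rate-law expression handling (sympy-backed)
# ---------------------------------------------------------------------------

_ID_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_FUNC_NAMES = {"exp", "log", "ln", "sqrt", "Abs", "abs", "Max", "Min"}


def _rate_law_symbols(expr: str) -> set[str]:
    return {m.group(0) for m in _ID_RE.finditer(expr)} - _FUNC_NAMES - {"E", "pi"}


def _sympify_rate_law(expr: str, known_ids) -> sp.Expr:
    """Parse an infix rate law, binding every known id to a plain Symbol.

    Explicit binding prevents sympy from hijacking ids such as ``I`` (the
    imaginary unit) or ``E``.
    """
    local = {name: sp.Symbol(name) for name in known_ids}
    local.setdefault("t", sp.Symbol("t"))
    try:
        parsed = sp.sympify(expr, locals=local, evaluate=True)
    except (sp.SympifyError, SyntaxError, TypeError) as exc:
        raise NetworkValidationError(f"cannot parse rate law {expr!r}: {exc}") from exc
    extra = {str(s) for s in parsed.free_symbols} - set(local)
    if extra:
        raise NetworkValidationError(
            f"rate law {expr!r} references unknown ids {sorted(extra)}"
        )
    return parsed


def _reaction_rate_expr(network: ReactionNetwork, reaction: Reaction) -> sp.Expr:
    ids = (
        set(network.species_ids)
        | set(network.parameters)
        | set(network.compartments)
        | set(reaction.local_params)
    )
    return _sympify_rate_law(reaction.rate_law, ids)


# ---------------------------------------------------------------------------
# RHS assembly
# ---------------------------------------------------------------------------


@dataclass
class DerivativeFunction:
    """ODE right-hand side f(t, y) for one cell.

    ``species_order`` fixes the state-vector layout (document order of the
    network's species).  ``fluxes(t, y)`` exposes the per-reaction rate
    vector, which is useful for flux-level assertions (knockouts, washout
    continuity).  Evaluation is side-effect free.
    """

    fun: object
    flux_fun: object
    species_order: list[str]

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        return self.fun(t, y)

    def fluxes(self, t: float, y: np.ndarray) -> np.ndarray:
        return self.flux_fun(t, y)


def _compiled_rhs(network: ReactionNetwork):
    """Compile the network's flux vector once, production rates left symbolic.

    Returns (flux_lam, prod_nominal, stoich): ``flux_lam(t, y, p)`` takes
    the production-rate vector ``p`` (one entry per production_rate_ids);
    all other parameters and compartment sizes are substituted numerically.
    The compilation is cached on the network instance, keyed on the rate
    laws and parameter values, so per-cell RHS construction is cheap.
    """
    key = (
        tuple((r.id, r.rate_law, tuple(sorted(r.local_params.items()))) for r in network.reactions),
        tuple(sorted(network.parameters.items())),
        tuple(sorted(network.compartments.items())),
        tuple(network.production_rate_ids),
        tuple((s.id, s.boundary) for s in network.species),
    )
    cached = network.__dict__.get("_compiled")
    if cached is not None and cached[0] == key:
        return cached[1]

    prod_ids = list(network.production_rate_ids)
    prod_syms = [sp.Symbol(f"_prod_{i}") for i in range(len(prod_ids))]
    species_syms = [sp.Symbol(s.id) for s in network.species]
    t_sym = sp.Symbol("t")

    prod_nominal = np.empty(len(prod_ids))
    for i, pid in enumerate(prod_ids):
        if pid in network.parameters:
            prod_nominal[i] = network.parameters[pid]
        else:
            prod_nominal[i] = next(
                r.local_params[pid] for r in network.reactions if pid in r.local_params
            )

    flux_exprs = []
    for r in network.reactions:
        expr = _reaction_rate_expr(network, r)
        subs = {}
        for pid, v in network.parameters.items():
            if pid in prod_ids:
                subs[sp.Symbol(pid)] = prod_syms[prod_ids.index(pid)]
            else:
                subs[sp.Symbol(pid)] = v
        for pid, v in r.local_params.items():
            if pid in prod_ids:
                subs[sp.Symbol(pid)] = prod_syms[prod_ids.index(pid)]
            else:
                subs[sp.Symbol(pid)] = v  # locals shadow globals
        for cid, v in network.compartments.items():
            subs[sp.Symbol(cid)] = v
        flux_exprs.append(expr.subs(subs))

    flux_lam = sp.lambdify(
        (t_sym, species_syms, prod_syms), sp.Matrix(flux_exprs), modules="numpy"
    )

    n_sp = len(species_syms)
    stoich = np.zeros((n_sp, len(network.reactions)))
    idx = {sid: i for i, sid in enumerate(network.species_ids)}
    for j, r in enumerate(network.reactions):
        for sid, coef in r.reactants.items():
            stoich[idx[sid], j] -= coef
        for sid, coef in r.products.items():
            stoich[idx[sid], j] += coef
    for i, s in enumerate(network.species):
        if s.boundary:
            stoich[i, :] = 0.0

    compiled = (flux_lam, prod_nominal, stoich)
    network.__dict__["_compiled"] = (key, compiled)
    return compiled


def build_rhs(network: ReactionNetwork, cell_params=None, clamp=()) -> DerivativeFunction:
    """Assemble the ODE right-hand side with per-cell production multipliers.

    Each distributed production rate enters as (nominal value × multiplier);
    multiplier keys must be a subset of ``network.production_rate_ids``.
    Species ids in ``clamp`` are held constant (zero derivative) on top of
    any boundary species the model declares — used for ligand washout.
    """
    from .ensemble import CellParameterSet  # local import to avoid a cycle

    multipliers: dict[str, float] = {}
    if cell_params is not None:
        if isinstance(cell_params, CellParameterSet):
            multipliers = dict(cell_params.multipliers)
        else:
            multipliers = dict(cell_params)
    unknown = set(multipliers) - set(network.production_rate_ids)
    if unknown:
        raise KeyError(
            f"multipliers for non-distributed parameter ids {sorted(unknown)}; "
            f"distributed ids are {network.production_rate_ids}"
        )

    flux_lam, prod_nominal, stoich = _compiled_rhs(network)
    mult = np.array(
        [multipliers.get(pid, 1.0) for pid in network.production_rate_ids]
    )
    prod_values = prod_nominal * mult
    if clamp:
        stoich = stoich.copy()
        for sid in clamp:
            stoich[network.species_index(sid), :] = 0.0

    def flux_fun(t, y):
        return np.asarray(flux_lam(t, list(y), prod_values), dtype=float).ravel()

    def fun(t, y):
        return stoich @ flux_fun(t, y)

    return DerivativeFunction(fun=fun, flux_fun=flux_fun, species_order=list(network.species_ids))


# ---------------------------------------------------------------------------
# production-rate identification and knockouts
# ---------------------------------------------------------------------------


def identify_production_rates(network: ReactionNetwork) -> list[str]:
    """Parameter ids of all zeroth-order synthesis reactions, in document order.

    A production (expression) reaction has no reactant species; its rate
    constant is the unique parameter in which the rate law is homogeneous of
    degree one (doubling the parameter doubles the flux at any state, and a
    zero parameter silences the flux).  Reactions whose rate law offers no
    such parameter, or more than one, raise :class:`ProductionRateError`
    rather than guessing.
    """
    rng = np.random.default_rng(20111228)  # fixed probe states; not a model choice
    out: list[str] = []
    for r in network.reactions:
        if r.reactants:
            continue
        expr = _reaction_rate_expr(network, r)
        param_ids = [
            str(s)
            for s in sorted(expr.free_symbols, key=lambda s: r.rate_law.find(str(s)))
            if str(s) in network.parameters or str(s) in r.local_params
        ]
        if not param_ids:
            raise ProductionRateError(
                f"zeroth-order reaction {r.id!r} has no parameter in its rate law; "
                "cannot identify a production rate to distribute"
            )
        linear = []
        for pid in param_ids:
            if _is_degree_one(network, r, expr, pid, rng):
                linear.append(pid)
        if len(linear) != 1:
            raise ProductionRateError(
                f"zeroth-order reaction {r.id!r}: expected exactly one rate constant "
                f"(degree-1 parameter), found {linear or 'none'} among {param_ids}"
            )
        out.append(linear[0])
    return out


def _is_degree_one(network, reaction, expr, pid, rng) -> bool:
    base = dict(network.parameters)
    base.update(reaction.local_params)
    psym = sp.Symbol(pid)
    other = {sp.Symbol(k): v for k, v in base.items() if k != pid}
    other.update({sp.Symbol(c): v for c, v in network.compartments.items()})
    f = sp.lambdify(
        (psym, [sp.Symbol(s) for s in network.species_ids]),
        expr.subs(other),
        modules="numpy",
    )
    p0 = base[pid] if base[pid] != 0 else 1.0
    for _ in range(3):
        y = rng.uniform(0.1, 2.0, size=len(network.species_ids))
        v1, v2, v0 = f(p0, list(y)), f(2 * p0, list(y)), f(0.0, list(y))
        scale = max(abs(v1), 1e-300)
        if abs(v2 - 2 * v1) > 1e-9 * scale or abs(v0) > 1e-9 * scale:
            return False
    return True


def apply_knockout(network: ReactionNetwork, reaction_id: str) -> ReactionNetwork:
    """Return a copy of the network with one reaction's rate identically zero.

    This is the in-silico knockout device: e.g. zeroing the IKKa-mediated
    release-and-degradation of bound IκBα abolishes TNF-induced NF-κB
    activation.  The original network is untouched; applying the knockout
    twice equals applying it once.
    """
    ko = network.copy()
    ko.reaction(reaction_id).rate_law = "0"
    return ko


# ---------------------------------------------------------------------------
# SBML subset I/O
# ---------------------------------------------------------------------------

_UNSUPPORTED_LISTS = {
    "listOfEvents": "events",
    "listOfRules": "rules",
    "listOfFunctionDefinitions": "function definitions",
    "listOfConstraints": "constraints",
    "listOfInitialAssignments": "initial assignments",
}


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def load_sbml(path) -> ReactionNetwork:
    """Load an SBML level-2 file into a :class:`ReactionNetwork`.

    Species, reaction and parameter ids are preserved verbatim, so the
    simulated dynamics match the SBML semantics.  Unsupported constructs
    raise; malformed XML raises :class:`SBMLParseError` naming the element.
    """
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise SBMLParseError(f"cannot parse SBML file {path}: {exc}") from exc
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise SBMLParseError(f"root element is <{_local(root.tag)}>, expected <sbml>")
    level = root.get("level")
    if level != "2":
        raise UnsupportedSBMLError(
            f"SBML level {level!r} is not supported; only level 2 ODE models are"
        )
    model = next((c for c in root if _local(c.tag) == "model"), None)
    if model is None:
        raise SBMLParseError("missing <model> element")

    for child in model:
        name = _local(child.tag)
        if name in _UNSUPPORTED_LISTS and len(child):
            raise UnsupportedSBMLError(
                f"SBML {_UNSUPPORTED_LISTS[name]} are not supported "
                f"(<{name}> is non-empty); refusing to silently alter ODE semantics"
            )

    compartments: dict[str, float] = {}
    for c in _iter_list(model, "listOfCompartments", "compartment"):
        compartments[_req(c, "id")] = float(c.get("size", "1"))

    species: list[Species] = []
    for s in _iter_list(model, "listOfSpecies", "species"):
        sid = _req(s, "id")
        comp = s.get("compartment", "")
        if s.get("initialAmount") is not None:
            amt = float(s.get("initialAmount"))
        elif s.get("initialConcentration") is not None:
            amt = float(s.get("initialConcentration")) * compartments.get(comp, 1.0)
        else:
            amt = 0.0
        species.append(
            Species(
                id=sid,
                name=s.get("name", sid),
                initial_amount=amt,
                compartment=comp,
                boundary=s.get("boundaryCondition", "false") == "true",
            )
        )

    parameters: dict[str, float] = {}
    for p in _iter_list(model, "listOfParameters", "parameter"):
        parameters[_req(p, "id")] = float(p.get("value", "nan"))

    reactions: list[Reaction] = []
    for r in _iter_list(model, "listOfReactions", "reaction"):
        rid = _req(r, "id")
        reactants = _read_side(r, "listOfReactants", rid)
        products = _read_side(r, "listOfProducts", rid)
        modifiers = [
            _req(sr, "species")
            for sr in _iter_list(r, "listOfModifiers", "modifierSpeciesReference")
        ]
        kl = next((c for c in r if _local(c.tag) == "kineticLaw"), None)
        if kl is None:
            raise SBMLParseError(f"reaction {rid!r} has no <kineticLaw>")
        local_params = {}
        for p in _iter_list(kl, "listOfParameters", "parameter"):
            local_params[_req(p, "id")] = float(p.get("value", "nan"))
        math = next((c for c in kl if _local(c.tag) == "math"), None)
        if math is None:
            raise SBMLParseError(f"reaction {rid!r}: <kineticLaw> has no <math>")
        children = [c for c in math if isinstance(c.tag, str)]
        if len(children) != 1:
            raise SBMLParseError(f"reaction {rid!r}: <math> must have one child")
        rate_law = _mathml_to_infix(children[0], rid)
        reactions.append(
            Reaction(
                id=rid,
                name=r.get("name", rid),
                reactants=reactants,
                products=products,
                rate_law=rate_law,
                modifiers=modifiers,
                local_params=local_params,
            )
        )

    metadata = {}
    annot = next((c for c in model if _local(c.tag) == "annotation"), None)
    if annot is not None:
        meta_el = annot.find(f"{{{_ANNOT_NS}}}metadata")
        if meta_el is not None and meta_el.text:
            metadata = json.loads(meta_el.text)

    net = ReactionNetwork(
        species=species,
        reactions=reactions,
        parameters=parameters,
        compartments=compartments,
        metadata=metadata,
    )
    net.production_rate_ids = identify_production_rates(net)
    net.validate()
    return net


def _iter_list(parent, list_name, item_name):
    lst = next((c for c in parent if _local(c.tag) == list_name), None)
    if lst is None:
        return []
    return [c for c in lst if _local(c.tag) == item_name]


def _req(el, attr):
    v = el.get(attr)
    if v is None:
        raise SBMLParseError(f"<{_local(el.tag)}> element is missing required attribute {attr!r}")
    return v


def _read_side(rxn_el, list_name, rid) -> dict[str, int]:
    side = {}
    for sr in _iter_list(rxn_el, list_name, "speciesReference"):
        sid = _req(sr, "species")
        st_raw = sr.get("stoichiometry", "1")
        st = float(st_raw)
        if st <= 0 or st != int(st):
            raise SBMLParseError(
                f"reaction {rid!r}: stoichiometry {st_raw!r} for species {sid!r} "
                "must be a positive integer"
            )
        side[sid] = side.get(sid, 0) + int(st)
    return side


# -- content MathML <-> infix ------------------------------------------------

_MATHML_BINOPS = {"plus": "+", "times": "*", "minus": "-", "divide": "/", "power": "**"}
_MATHML_FUNCS = {"exp": "exp", "ln": "log", "root": "sqrt", "abs": "Abs"}


def _mathml_to_infix(node, context: str) -> str:
    tag = _local(node.tag)
    if tag == "cn":
        return _cn_to_str(node, context)
    if tag == "ci":
        return (node.text or "").strip()
    if tag == "csymbol":
        url = node.get("definitionURL", "")
        if url.endswith("/time"):
            return "t"
        raise UnsupportedSBMLError(f"reaction {context!r}: csymbol {url!r} unsupported")
    if tag == "pi":
        return "pi"
    if tag == "exponentiale":
        return "E"
    if tag == "apply":
        children = [c for c in node if isinstance(c.tag, str)]
        if not children:
            raise SBMLParseError(f"reaction {context!r}: empty <apply>")
        op = _local(children[0].tag)
        args = [_mathml_to_infix(c, context) for c in children[1:]]
        if op in _MATHML_BINOPS:
            if op == "minus" and len(args) == 1:
                return f"(-({args[0]}))"
            if len(args) < 2:
                raise SBMLParseError(f"reaction {context!r}: <{op}> needs 2+ operands")
            return "(" + f" {_MATHML_BINOPS[op]} ".join(f"({a})" for a in args) + ")"
        if op in _MATHML_FUNCS and len(args) == 1:
            return f"{_MATHML_FUNCS[op]}({args[0]})"
        raise UnsupportedSBMLError(
            f"reaction {context!r}: MathML operator <{op}> is not supported"
        )
    raise UnsupportedSBMLError(f"reaction {context!r}: MathML element <{tag}> unsupported")


def _cn_to_str(node, context: str) -> str:
    ctype = node.get("type", "real")
    if ctype in ("real", "integer", "double"):
        return (node.text or "").strip()
    if ctype == "e-notation":
        parts = [t.strip() for t in node.itertext() if t.strip()]
        if len(parts) != 2:
            raise SBMLParseError(f"reaction {context!r}: malformed e-notation <cn>")
        return f"({parts[0]}e{parts[1]})"
    if ctype == "rational":
        parts = [t.strip() for t in node.itertext() if t.strip()]
        if len(parts) != 2:
            raise SBMLParseError(f"reaction {context!r}: malformed rational <cn>")
        return f"(({parts[0]})/({parts[1]}))"
    raise UnsupportedSBMLError(f"reaction {context!r}: <cn type={ctype!r}> unsupported")


def _expr_to_mathml(expr: sp.Expr, parent) -> None:
    M = lambda tag: etree.SubElement(parent, f"{{{_MATHML_NS}}}{tag}")  # noqa: E731
    if isinstance(expr, sp.Symbol):
        el = M("ci")
        el.text = expr.name
        return
    if expr is sp.pi:
        M("pi")
        return
    if expr is sp.E:
        M("exponentiale")
        return
    if expr.is_Integer or expr.is_Float:
        el = M("cn")
        el.text = repr(int(expr)) if expr.is_Integer else repr(float(expr))
        return
    if expr.is_Rational:
        ap = M("apply")
        etree.SubElement(ap, f"{{{_MATHML_NS}}}divide")
        _expr_to_mathml(sp.Integer(expr.p), ap)
        _expr_to_mathml(sp.Integer(expr.q), ap)
        return
    ops = {sp.Add: "plus", sp.Mul: "times", sp.Pow: "power"}
    for cls, tag in ops.items():
        if isinstance(expr, cls):
            ap = M("apply")
            etree.SubElement(ap, f"{{{_MATHML_NS}}}{tag}")
            for a in expr.args:
                _expr_to_mathml(a, ap)
            return
    if isinstance(expr, sp.exp):
        ap = M("apply")
        etree.SubElement(ap, f"{{{_MATHML_NS}}}exp")
        _expr_to_mathml(expr.args[0], ap)
        return
    if isinstance(expr, sp.log):
        ap = M("apply")
        etree.SubElement(ap, f"{{{_MATHML_NS}}}ln")
        _expr_to_mathml(expr.args[0], ap)
        return
    raise UnsupportedSBMLError(f"cannot serialize expression {expr} to MathML")


def write_sbml(network: ReactionNetwork, path) -> None:
    """Emit the network as an SBML level-2 version-4 document.

    load_sbml(write_sbml(net)) reproduces the parameter map, stoichiometry
    and rate-law semantics.  Package metadata travels in a model annotation.
    """
    SBML_NS = "http://www.sbml.org/sbml/level2/version4"
    E = lambda parent, tag, **attrs: etree.SubElement(  # noqa: E731
        parent, f"{{{SBML_NS}}}{tag}", {k: str(v) for k, v in attrs.items()}
    )
    root = etree.Element(
        f"{{{SBML_NS}}}sbml", {"level": "2", "version": "4"}, nsmap={None: SBML_NS}
    )
    model = E(root, "model", id="model")

    if network.metadata:
        annot = E(model, "annotation")
        meta = etree.SubElement(annot, f"{{{_ANNOT_NS}}}metadata")
        meta.text = json.dumps(network.metadata, sort_keys=True)

    loc = E(model, "listOfCompartments")
    comps = dict(network.compartments) or {"cell": 1.0}
    for cid, size in comps.items():
        E(loc, "compartment", id=cid, size=repr(size))
    default_comp = next(iter(comps))

    los = E(model, "listOfSpecies")
    for s in network.species:
        attrs = {
            "id": s.id,
            "name": s.name,
            "initialAmount": repr(s.initial_amount),
            "compartment": s.compartment or default_comp,
        }
        if s.boundary:
            attrs["boundaryCondition"] = "true"
        E(los, "species", **attrs)

    if network.parameters:
        lop = E(model, "listOfParameters")
        for pid, v in network.parameters.items():
            E(lop, "parameter", id=pid, value=repr(v))

    lor = E(model, "listOfReactions")
    for r in network.reactions:
        rx = E(lor, "reaction", id=r.id, name=r.name, reversible="false")
        if r.reactants:
            lrt = E(rx, "listOfReactants")
            for sid, coef in r.reactants.items():
                E(lrt, "speciesReference", species=sid, stoichiometry=coef)
        if r.products:
            lpd = E(rx, "listOfProducts")
            for sid, coef in r.products.items():
                E(lpd, "speciesReference", species=sid, stoichiometry=coef)
        if r.modifiers:
            lmd = E(rx, "listOfModifiers")
            for sid in r.modifiers:
                E(lmd, "modifierSpeciesReference", species=sid)
        kl = E(rx, "kineticLaw")
        math = etree.SubElement(kl, f"{{{_MATHML_NS}}}math", nsmap={None: _MATHML_NS})
        expr = _reaction_rate_expr(network, r)
        _expr_to_mathml(expr, math)
        if r.local_params:
            lp = E(kl, "listOfParameters")
            for pid, v in r.local_params.items():
                E(lp, "parameter", id=pid, value=repr(v))

    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )
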