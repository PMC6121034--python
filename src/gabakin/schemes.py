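"""Kinetic schemes for ligand-gated ion-channel gating.

A scheme is a continuous-time Markov chain over receptor conformations
(closed, open, flipped/pre-activated, desensitized).  Transitions carry
unimolecular rates (s^-1) or bimolecular binding rates (M^-1 s^-1) that are
multiplied by a ligand concentration.  From a scheme and a concentration
map the generator (Q) matrix is built; everything downstream — macroscopic
relaxation, dwell-time theory, stochastic simulation — works off Q.

The shipped fixtures describe the alpha1-beta2-gamma2 GABA_A receptor:

* a spontaneous (agonist-free) branch ``R <-> O0, R <-> O0', R <-> D0``
  with two open states of distinct lifetimes and an unliganded
  desensitized state;
* a benzodiazepine-modulated copy of that branch reached through an
  explicit modulator binding step ``R + M <-> RM``;
* a flipped (pre-activated) di-liganded activation scheme
  ``R <-> AR <-> A2R <-> A2F <-> A2O`` with fast (``A2D``) and slow
  (``A2D'``) desensitized states branching from the flipped state.

Rate values in the fixtures are package calibrations chosen to reproduce
the qualitative wild-type/mutant/modulator phenotypes the package is built
to analyse; they are not measured constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import yaml
from scipy.sparse.csgraph import connected_components

__all__ = [
    "StateSpec",
    "TransitionSpec",
    "KineticScheme",
    "ModulationSet",
    "SchemeError",
    "UnknownStateError",
    "InvalidRateError",
    "DisconnectedSchemeError",
    "UnknownRateError",
    "MissingConcentrationError",
    "ReducibleChainError",
    "load_scheme",
    "load_fixture",
    "load_modulation",
    "list_fixtures",
    "merge_schemes",
    "q_matrix",
    "steady_state",
    "check_detailed_balance",
    "apply_modulation",
]

STATE_CLASSES = ("closed", "open", "flipped", "desensitized")


class SchemeError(ValueError):
    """Base class for scheme validation failures."""


class UnknownStateError(SchemeError):
    pass


class InvalidRateError(SchemeError):
    pass


class DisconnectedSchemeError(SchemeError):
    pass


class UnknownRateError(SchemeError):
    pass


class MissingConcentrationError(SchemeError):
    pass


class ReducibleChainError(SchemeError):
    def __init__(self, message: str, unreachable: list[str]):
        super().__init__(message)
        self.unreachable = unreachable


@dataclass(frozen=True)
class StateSpec:
    """One receptor conformation.

    ``conductance_weight`` is > 0 exactly for open states (1.0 for a
    full-conductance open level); ``bound`` maps ligand label to the number
    of molecules bound in this state.
    """

    name: str
    klass: str
    conductance_weight: float = 0.0
    bound: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.klass not in STATE_CLASSES:
            raise SchemeError(
                f"state {self.name!r}: unknown class {self.klass!r} "
                f"(expected one of {STATE_CLASSES})"
            )
        if (self.klass == "open") != (self.conductance_weight > 0):
            raise SchemeError(
                f"state {self.name!r}: conductance_weight must be > 0 "
                "iff the state is open"
            )
        if any(v < 0 for v in self.bound.values()):
            raise SchemeError(f"state {self.name!r}: negative stoichiometry")

    @property
    def is_open(self) -> bool:
        return self.klass == "open"


@dataclass(frozen=True)
class TransitionSpec:
    """A directed transition ``from_state -> to_state``.

    ``order`` 0 means the rate is ``base_value`` (s^-1); order 1 means the
    rate is ``base_value * [ligand]`` with ``base_value`` in M^-1 s^-1.
    """

    from_state: str
    to_state: str
    rate_name: str
    base_value: float
    ligand: str | None = None
    order: int = 0

    def __post_init__(self):
        # zero is tolerated programmatically (limiting cases such as a
        # switched-off spontaneous opening); scheme documents must be > 0
        if not np.isfinite(self.base_value) or self.base_value < 0:
            raise InvalidRateError(
                f"transition {self.rate_name!r} "
                f"({self.from_state}->{self.to_state}): "
                f"rate must be non-negative and finite, got {self.base_value!r}"
            )
        if self.from_state == self.to_state:
            raise SchemeError(
                f"transition {self.rate_name!r}: self-loop on {self.from_state!r}"
            )
        if (self.order == 1) != (self.ligand is not None):
            raise SchemeError(
                f"transition {self.rate_name!r}: ligand must be set iff order = 1"
            )
        if self.order not in (0, 1):
            raise SchemeError(
                f"transition {self.rate_name!r}: order must be 0 or 1"
            )


@dataclass(frozen=True)
class KineticScheme:
    """A validated state graph with rate-labelled transitions."""

    name: str
    states: tuple[StateSpec, ...]
    transitions: tuple[TransitionSpec, ...]
    ligands: tuple[str, ...] = ()

    def __post_init__(self):
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise SchemeError(f"scheme {self.name!r}: duplicate state names")
        rate_names = [t.rate_name for t in self.transitions]
        if len(set(rate_names)) != len(rate_names):
            dupes = sorted({r for r in rate_names if rate_names.count(r) > 1})
            raise SchemeError(f"scheme {self.name!r}: duplicate rate names {dupes}")
        known = set(names)
        for t in self.transitions:
            for endpoint in (t.from_state, t.to_state):
                if endpoint not in known:
                    raise UnknownStateError(
                        f"scheme {self.name!r}: transition {t.rate_name!r} "
                        f"references undeclared state {endpoint!r}"
                    )
            if t.ligand is not None and t.ligand not in self.ligands:
                raise SchemeError(
                    f"scheme {self.name!r}: transition {t.rate_name!r} "
                    f"references undeclared ligand {t.ligand!r}"
                )
        if not any(s.is_open for s in self.states):
            raise SchemeError(f"scheme {self.name!r}: no open-class state")
        self._check_connected()

    def _check_connected(self):
        n = len(self.states)
        idx = {s.name: i for i, s in enumerate(self.states)}
        adj = np.zeros((n, n), dtype=bool)
        for t in self.transitions:
            adj[idx[t.from_state], idx[t.to_state]] = True
        ncomp, labels = connected_components(adj, directed=True, connection="weak")
        if ncomp > 1:
            main = labels[0]
            stray = [s.name for s, l in zip(self.states, labels) if l != main]
            raise DisconnectedSchemeError(
                f"scheme {self.name!r}: state graph is disconnected; "
                f"states {stray} are not linked to {self.states[0].name!r}"
            )

    # -- lookups -----------------------------------------------------------
    @property
    def state_names(self) -> list[str]:
        return [s.name for s in self.states]

    def state_index(self, name: str) -> int:
        try:
            return self.state_names.index(name)
        except ValueError:
            raise UnknownStateError(
                f"scheme {self.name!r}: no state named {name!r}"
            ) from None

    def rate(self, rate_name: str) -> TransitionSpec:
        for t in self.transitions:
            if t.rate_name == rate_name:
                return t
        raise UnknownRateError(f"scheme {self.name!r}: no rate named {rate_name!r}")

    @property
    def conductance_weights(self) -> np.ndarray:
        return np.array([s.conductance_weight for s in self.states])

    @property
    def open_mask(self) -> np.ndarray:
        return np.array([s.is_open for s in self.states])

    def class_mask(self, klass: str) -> np.ndarray:
        """Boolean mask over states; ``open``/``shut`` select conductance
        classes, the four structural class names select exactly that class."""
        if klass == "open":
            return self.open_mask
        if klass == "shut":
            return ~self.open_mask
        if klass in STATE_CLASSES:
            return np.array([s.klass == klass for s in self.states])
        raise SchemeError(f"unknown state class {klass!r}")

    def with_rates(self, updates: Mapping[str, float]) -> "KineticScheme":
        """Return a copy with selected base rate values replaced."""
        known = {t.rate_name for t in self.transitions}
        for key in updates:
            if key not in known:
                raise UnknownRateError(
                    f"scheme {self.name!r}: no rate named {key!r}"
                )
        new = tuple(
            replace(t, base_value=float(updates.get(t.rate_name, t.base_value)))
            for t in self.transitions
        )
        return replace(self, transitions=new)

    def rate_values(self) -> dict[str, float]:
        return {t.rate_name: t.base_value for t in self.transitions}

    def to_json(self) -> str:
        doc = {
            "name": self.name,
            "ligands": list(self.ligands),
            "states": [
                {
                    "name": s.name,
                    "class": s.klass,
                    "conductance_weight": s.conductance_weight,
                    "bound": dict(s.bound),
                }
                for s in self.states
            ],
            "transitions": [
                {
                    "from": t.from_state,
                    "to": t.to_state,
                    "rate_name": t.rate_name,
                    "base_value": t.base_value,
                    "ligand": t.ligand,
                    "order": t.order,
                }
                for t in self.transitions
            ],
        }
        return json.dumps(doc, indent=2)


@dataclass(frozen=True)
class ModulationSet:
    """Named multiplicative perturbation of selected rates.

    Used to represent an allosteric modulator (or a mutation) as fold
    changes of rate constants, e.g. flurazepam on the cysteine mutant:
    flipping rate up, slow-desensitization entry down.
    """

    name: str
    multipliers: Mapping[str, float]

    def __post_init__(self):
        for k, v in self.multipliers.items():
            if not np.isfinite(v) or v <= 0:
                raise InvalidRateError(
                    f"modulation {self.name!r}: factor for {k!r} must be "
                    f"positive, got {v!r}"
                )

    def inverse(self) -> "ModulationSet":
        return ModulationSet(
            name=f"{self.name}-inverse",
            multipliers={k: 1.0 / v for k, v in self.multipliers.items()},
        )


# ---------------------------------------------------------------------------
# loading


def _parse_document(doc: Mapping) -> KineticScheme:
    try:
        name = doc["name"]
        states_doc = doc["states"]
        transitions_doc = doc["transitions"]
    except KeyError as e:
        raise SchemeError(f"scheme document missing required key {e}") from None
    ligands = tuple(doc.get("ligands", []))
    states = tuple(
        StateSpec(
            name=s["name"],
            klass=s["class"],
            conductance_weight=float(s.get("conductance_weight", 0.0)),
            bound=dict(s.get("bound", {})),
        )
        for s in states_doc
    )
    transitions = []
    for t in transitions_doc:
        base = float(t["base_value"])
        if base <= 0:
            raise InvalidRateError(
                f"scheme {name!r}: transition {t.get('rate_name')!r} has "
                f"non-positive rate {base!r}"
            )
        transitions.append(TransitionSpec(
            from_state=t["from"],
            to_state=t["to"],
            rate_name=t["rate_name"],
            base_value=base,
            ligand=t.get("ligand"),
            order=int(t.get("order", 1 if t.get("ligand") else 0)),
        ))
    transitions = tuple(transitions)
    return KineticScheme(name=name, states=states, transitions=transitions, ligands=ligands)


def load_scheme(source) -> KineticScheme:
    """Load and validate a scheme from a YAML/JSON document.

    ``source`` may be a mapping, a YAML string, or a path to a file.
    """
    if isinstance(source, Mapping):
        return _parse_document(source)
    text = None
    try:
        import os

        if isinstance(source, (str,)) and os.path.exists(source) and len(source) < 4096:
            with open(source) as fh:
                text = fh.read()
    except (OSError, ValueError):
        pass
    if text is None:
        if hasattr(source, "read"):
            text = source.read()
        else:
            text = str(source)
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise SchemeError("scheme document is not a mapping")
    return _parse_document(doc)


def _fixture_dir():
    return resources.files("gabakin") / "fixtures"


def list_fixtures() -> list[str]:
    names = []
    for entry in _fixture_dir().iterdir():
        if entry.name.endswith(".yaml") and not entry.name.startswith("mod_"):
            names.append(entry.name[: -len(".yaml")])
    return sorted(names) + ["combined_wt", "combined_cys"]


def load_fixture(name: str) -> KineticScheme:
    """Load a shipped scheme fixture by name.

    ``combined_wt`` / ``combined_cys`` are built by joining the liganded and
    spontaneous branches on their shared resting state ``R``.
    """
    if name == "combined_wt":
        return merge_schemes(load_fixture("glig_wt"), load_fixture("spont_wt"),
                             name="combined_wt")
    if name == "combined_cys":
        return merge_schemes(load_fixture("glig_cys"), load_fixture("spont_cys"),
                             name="combined_cys")
    path = _fixture_dir() / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise SchemeError(
            f"no fixture named {name!r}; available: {list_fixtures()}"
        ) from None
    return load_scheme(yaml.safe_load(text))


def load_modulation(name: str) -> ModulationSet:
    path = _fixture_dir() / f"mod_{name}.yaml"
    try:
        doc = yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raise SchemeError(f"no modulation set named {name!r}") from None
    return ModulationSet(name=doc["name"], multipliers=dict(doc["multipliers"]))


def merge_schemes(a: KineticScheme, b: KineticScheme, shared_state: str = "R",
                  name: str | None = None) -> KineticScheme:
    """Join two schemes that share one state (branches of one receptor).

    States other than ``shared_state`` must be disjoint between the two
    schemes; rate names must be disjoint.
    """
    a_names = set(a.state_names)
    b_names = set(b.state_names)
    if shared_state not in a_names or shared_state not in b_names:
        raise UnknownStateError(
            f"shared state {shared_state!r} must exist in both schemes"
        )
    overlap = (a_names & b_names) - {shared_state}
    if overlap:
        raise SchemeError(f"cannot merge: states {sorted(overlap)} appear in both schemes")
    shared_a = next(s for s in a.states if s.name == shared_state)
    states = a.states + tuple(s for s in b.states if s.name != shared_state)
    transitions = a.transitions + b.transitions
    ligands = tuple(dict.fromkeys(a.ligands + b.ligands))
    return KineticScheme(
        name=name or f"{a.name}+{b.name}",
        states=states,
        transitions=transitions,
        ligands=ligands,
    )


# ---------------------------------------------------------------------------
# generator matrix and friends


def q_matrix(scheme: KineticScheme, concentrations: Mapping[str, float] | None = None
             ) -> np.ndarray:
    """Generator matrix at the given ligand concentrations (molar).

    Off-diagonal ``Q[i, j]`` is the transition rate i -> j (s^-1); each row
    sums to zero.  Every ligand that appears on a concentration-dependent
    transition must be present in ``concentrations``.
    """
    concentrations = dict(concentrations or {})
    n = len(scheme.states)
    idx = {s.name: i for i, s in enumerate(scheme.states)}
    Q = np.zeros((n, n))
    for t in scheme.transitions:
        rate = t.base_value
        if t.order == 1:
            if t.ligand not in concentrations:
                raise MissingConcentrationError(
                    f"scheme {scheme.name!r}: transition {t.rate_name!r} needs "
                    f"a concentration for ligand {t.ligand!r}"
                )
            c = float(concentrations[t.ligand])
            if c < 0:
                raise MissingConcentrationError(
                    f"negative concentration for ligand {t.ligand!r}"
                )
            rate = rate * c
        Q[idx[t.from_state], idx[t.to_state]] += rate
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _closed_classes(Q: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Strongly connected components and the subset that are closed
    (no transitions leaving the component)."""
    adj = Q > 0
    ncomp, labels = connected_components(adj, directed=True, connection="strong")
    closed = []
    for c in range(ncomp):
        members = np.flatnonzero(labels == c)
        outside = np.setdiff1d(np.arange(Q.shape[0]), members)
        if outside.size == 0 or not adj[np.ix_(members, outside)].any():
            closed.append(members)
    return labels, closed


def steady_state(Q: np.ndarray, state_names: Iterable[str] | None = None,
                 tol: float = 1e-10) -> np.ndarray:
    """Stationary occupancy vector p with p @ Q = 0, sum(p) = 1.

    A unique stationary distribution exists iff the chain has exactly one
    closed communicating class; transient states (e.g. liganded states at
    zero agonist) receive zero occupancy.  Multiple closed classes raise
    :class:`ReducibleChainError` naming the states involved.
    """
    Q = np.asarray(Q, dtype=float)
    n = Q.shape[0]
    names = list(state_names) if state_names is not None else [str(i) for i in range(n)]
    _, closed = _closed_classes(Q)
    if len(closed) != 1:
        groups = [[names[i] for i in members] for members in closed]
        raise ReducibleChainError(
            f"chain is reducible: {len(closed)} closed classes {groups}; "
            "no unique stationary distribution",
            unreachable=[n for g in groups for n in g],
        )
    members = closed[0]
    Qc = Q[np.ix_(members, members)]
    m = len(members)
    A = np.vstack([Qc.T, np.ones(m)])
    b = np.zeros(m + 1)
    b[-1] = 1.0
    p_c, *_ = np.linalg.lstsq(A, b, rcond=None)
    p_c = np.clip(p_c, 0.0, None)
    p_c /= p_c.sum()
    p = np.zeros(n)
    p[members] = p_c
    resid = np.abs(p @ Q).max()
    if resid > tol * max(1.0, np.abs(Q).max()):
        raise np.linalg.LinAlgError(
            f"stationary solve residual {resid:.2e} exceeds tolerance"
        )
    return p


def check_detailed_balance(scheme: KineticScheme,
                           concentrations: Mapping[str, float] | None = None,
                           rtol: float = 1e-6) -> list[dict]:
    """Microscopic-reversibility audit.

    For every independent cycle of the (undirected) state graph, report the
    ratio of the clockwise to counterclockwise rate products.  An empty
    report means no cycles (tree topology) or all cycles balanced; entries
    with ``ok = False`` violate detailed balance beyond ``rtol``.
    """
    import networkx as nx

    Q = q_matrix(scheme, concentrations or {l: 1.0 for l in scheme.ligands})
    names = scheme.state_names
    g = nx.Graph()
    g.add_nodes_from(range(len(names)))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if Q[i, j] > 0 or Q[j, i] > 0:
                g.add_edge(i, j)
    report = []
    for cycle in nx.cycle_basis(g):
        if len(cycle) < 3:
            continue
        fwd, rev = 1.0, 1.0
        ok_cycle = True
        ring = cycle + [cycle[0]]
        for u, v in zip(ring[:-1], ring[1:]):
            if Q[u, v] <= 0 or Q[v, u] <= 0:
                ok_cycle = False  # one-way cycle: trivially irreversible
                break
            fwd *= Q[u, v]
            rev *= Q[v, u]
        if not ok_cycle:
            ratio = np.inf
        else:
            ratio = fwd / rev
        report.append({
            "cycle": [names[i] for i in cycle],
            "ratio": ratio,
            "ok": np.isfinite(ratio) and abs(ratio - 1.0) <= rtol,
        })
    return report


def apply_modulation(scheme: KineticScheme, mod: ModulationSet) -> KineticScheme:
    """Return a new scheme with each named rate multiplied by its factor."""
    known = {t.rate_name for t in scheme.transitions}
    unknown = sorted(set(mod.multipliers) - known)
    if unknown:
        raise UnknownRateError(
            f"modulation {mod.name!r}: rates {unknown} do not exist in "
            f"scheme {scheme.name!r}"
        )
    new = tuple(
        replace(t, base_value=t.base_value * mod.multipliers.get(t.rate_name, 1.0))
        for t in scheme.transitions
    )
    return replace(scheme, transitions=new, name=f"{scheme.name}[{mod.name}]")
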