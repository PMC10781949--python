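"""Finite transition systems and category-theoretic consistency checks.

Three views of a biological time course share one discrete shape — a
finite set of states acted on by a finite set of actions through a total
transition map:

* causal model: states are organism types, actions are genetic or
  environmental factors;
* surrogate model: states are feature vectors, actions are time steps
  (natural numbers under addition, a monoid);
* message-field model: states are message-network configurations,
  actions are force-field changes.

The module represents each as a labelled transition system, checks the
algebraic laws that make the views compatible (monoid-action laws,
functoriality of maps between systems), and verifies adjunction
witnesses between the finite categories freely generated by two systems,
by exhaustive enumeration of morphisms up to a path-length bound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

__all__ = [
    "TransitionSystem",
    "ModelMap",
    "AdjunctionWitness",
    "CheckResult",
    "Morphism",
    "step",
    "orbit",
    "check_monoid_action",
    "check_functor",
    "check_adjunction",
    "compose_maps",
    "identity_map",
    "iterated_system",
    "argmax_surrogate",
    "hom_set",
    "apply_to_morphism",
    "isomorphism_witness",
]

State = Hashable
Action = Hashable


@dataclass(frozen=True)
class CheckResult:
    """Outcome of a law check; composes without exceptions."""

    ok: bool
    law: str | None = None
    counterexample: dict | None = None

    def __bool__(self) -> bool:
        return self.ok


@dataclass(frozen=True)
class TransitionSystem:
    """Finite states x finite actions with a total transition map."""

    role: str  # "causal" | "surrogate" | "message"
    states: tuple[State, ...]
    actions: tuple[Action, ...]
    transition: Mapping[tuple[Action, State], State]

    def __post_init__(self) -> None:
        if self.role not in ("causal", "surrogate", "message"):
            raise ValueError(f"role must be causal/surrogate/message, got {self.role!r}")
        states = tuple(self.states)
        actions = tuple(self.actions)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "actions", actions)
        object.__setattr__(self, "transition", dict(self.transition))
        sset, aset = set(states), set(actions)
        if len(sset) != len(states) or len(aset) != len(actions):
            raise ValueError("states and actions must be duplicate-free")
        for a in actions:
            for s in states:
                if (a, s) not in self.transition:
                    raise ValueError(f"transition map is not total: missing ({a!r}, {s!r})")
        for (a, s), t in self.transition.items():
            if a not in aset:
                raise ValueError(f"transition uses unknown action {a!r}")
            if s not in sset or t not in sset:
                raise ValueError(f"transition ({a!r}, {s!r}) -> {t!r} leaves the state set")

    # -- JSON document form ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "role": self.role,
            "states": list(self.states),
            "actions": list(self.actions),
            "transitions": [
                {"action": a, "from": s, "to": t} for (a, s), t in sorted(self.transition.items(), key=repr)
            ],
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "TransitionSystem":
        trans = {(e["action"], e["from"]): e["to"] for e in doc["transitions"]}
        return cls(
            role=doc["role"],
            states=tuple(doc["states"]),
            actions=tuple(doc["actions"]),
            transition=trans,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TransitionSystem":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def step(system: TransitionSystem, action: Action, state: State) -> State:
    """Apply one action; unknown elements are rejected by name."""
    if action not in set(system.actions):
        raise KeyError(f"unknown action {action!r}")
    if state not in set(system.states):
        raise KeyError(f"unknown state {state!r}")
    return system.transition[(action, state)]


def orbit(system: TransitionSystem, actions: Sequence[Action], state: State) -> list[State]:
    """Left-fold of step: the visited state sequence, starting state included."""
    states = [state]
    for a in actions:
        states.append(step(system, a, states[-1]))
    return states


def iterated_system(role: str, states: Sequence[State], one_step: Mapping[State, State], max_t: int) -> TransitionSystem:
    """System whose numeric actions 0..max_t act by iterating a one-step map.

    By construction this is a monoid action of (N, +, 0) truncated at
    ``max_t``: phi(t, s) = one_step^t(s).
    """
    trans: dict[tuple[Action, State], State] = {}
    for s in states:
        cur = s
        trans[(0, s)] = s
        for t in range(1, max_t + 1):
            cur = one_step[cur]
            trans[(t, s)] = cur
    return TransitionSystem(role=role, states=tuple(states), actions=tuple(range(max_t + 1)), transition=trans)


def check_monoid_action(system: TransitionSystem) -> CheckResult:
    """Verify the monoid-action laws for numeric time actions.

    Unit law: phi(0, d) = d.  Composition law: phi(t+s, d) = phi(t, phi(s, d))
    for every t, s in the action set whose sum is also an action.  Returns
    the first violating triple, if any.
    """
    if not all(isinstance(a, int) for a in system.actions):
        raise ValueError("monoid-action check requires integer time actions")
    aset = set(system.actions)
    if 0 not in aset:
        raise ValueError("monoid-action check requires the unit action 0")
    for d in system.states:
        if system.transition[(0, d)] != d:
            return CheckResult(False, law="unit", counterexample={"state": d, "got": system.transition[(0, d)]})
    for t in system.actions:
        for s in system.actions:
            if t + s not in aset:
                continue
            for d in system.states:
                lhs = system.transition[(t + s, d)]
                rhs = system.transition[(t, system.transition[(s, d)])]
                if lhs != rhs:
                    return CheckResult(
                        False,
                        law="composition",
                        counterexample={"t": t, "s": s, "state": d, "phi(t+s,d)": lhs, "phi(t,phi(s,d))": rhs},
                    )
    return CheckResult(True)


@dataclass(frozen=True)
class ModelMap:
    """A map between transition systems: states to states, actions to actions."""

    source: TransitionSystem
    target: TransitionSystem
    state_map: Mapping[State, State]
    action_map: Mapping[Action, Action]

    def __post_init__(self) -> None:
        object.__setattr__(self, "state_map", dict(self.state_map))
        object.__setattr__(self, "action_map", dict(self.action_map))
        for s in self.source.states:
            if s not in self.state_map:
                raise ValueError(f"state_map is not total: missing {s!r}")
            if self.state_map[s] not in set(self.target.states):
                raise ValueError(f"state_map sends {s!r} outside the target states")
        for a in self.source.actions:
            if a not in self.action_map:
                raise ValueError(f"action_map is not total: missing {a!r}")
            if self.action_map[a] not in set(self.target.actions):
                raise ValueError(f"action_map sends {a!r} outside the target actions")


def identity_map(system: TransitionSystem) -> ModelMap:
    return ModelMap(
        source=system,
        target=system,
        state_map={s: s for s in system.states},
        action_map={a: a for a in system.actions},
    )


def compose_maps(first: ModelMap, second: ModelMap) -> ModelMap:
    """second after first (first.target must be second.source)."""
    if first.target is not second.source and first.target != second.source:
        raise ValueError("maps do not compose: target of first != source of second")
    return ModelMap(
        source=first.source,
        target=second.target,
        state_map={s: second.state_map[first.state_map[s]] for s in first.source.states},
        action_map={a: second.action_map[first.action_map[a]] for a in first.source.actions},
    )


def check_functor(m: ModelMap) -> CheckResult:
    """Verify commutation with transitions on every (action, state) pair.

    state_map(mu_src(a, s)) must equal mu_tgt(action_map(a), state_map(s)).
    """
    for a in m.source.actions:
        for s in m.source.states:
            lhs = m.state_map[m.source.transition[(a, s)]]
            rhs = m.target.transition[(m.action_map[a], m.state_map[s])]
            if lhs != rhs:
                return CheckResult(
                    False,
                    law="functoriality",
                    counterexample={"action": a, "state": s, "mapped_transition": lhs, "transition_of_mapped": rhs},
                )
    return CheckResult(True)


# --- free categories and adjunction verification -------------------------------
#
# The category freely generated by a transition system has the states as
# objects and action sequences as morphisms (the empty sequence is the
# identity; composition is concatenation).  The free category is infinite,
# so all enumeration is truncated at a configurable path-length bound,
# which keeps verification decidable.

Morphism = tuple[State, tuple[Action, ...]]  # (source object, action word); target is implied


def morphism_target(system: TransitionSystem, mor: Morphism) -> State:
    src, word = mor
    return orbit(system, list(word), src)[-1]


def hom_set(system: TransitionSystem, src: State, dst: State, bound: int) -> list[Morphism]:
    """All morphisms src -> dst of word length <= bound, in length/lex order."""
    out: list[Morphism] = []
    frontier: list[tuple[State, tuple[Action, ...]]] = [(src, ())]
    if src == dst:
        out.append((src, ()))
    for _ in range(bound):
        nxt = []
        for state, word in frontier:
            for a in system.actions:
                t = system.transition[(a, state)]
                w = word + (a,)
                nxt.append((t, w))
                if t == dst:
                    out.append((src, w))
        frontier = nxt
    return out


def apply_to_morphism(m: ModelMap, mor: Morphism) -> Morphism:
    """Image of a free-category morphism under the functor induced by a ModelMap."""
    src, word = mor
    return (m.state_map[src], tuple(m.action_map[a] for a in word))


def compose_morphisms(first: Morphism, second: Morphism) -> Morphism:
    """first then second (as action words: concatenation)."""
    return (first[0], first[1] + second[1])


@dataclass
class AdjunctionWitness:
    """Data claimed to exhibit F (C -> D) left adjoint-style to G (D -> C).

    ``hom_maps[(c, d)]`` maps each morphism in Hom_C(G(d), c) to a morphism
    in Hom_D(d, F(c)); checked to be a bijection natural in both slots.
    """

    F: ModelMap  # C -> D
    G: ModelMap  # D -> C
    hom_maps: dict[tuple[State, State], dict[Morphism, Morphism]]
    bound: int = 4


MAX_ADJUNCTION_OBJECTS = 10


def check_adjunction(witness: AdjunctionWitness) -> CheckResult:
    """Exhaustively verify an adjunction witness on small free categories.

    Checks, up to the witness's path-length bound: (i) F and G are
    functorial; (ii) every hom table is a bijection between
    Hom_C(G(d), c) and Hom_D(d, F(c)); (iii) both naturality squares
    commute for every generating morphism whose composites stay within
    the bound.  Returns the first failure found.
    """
    C = witness.F.source
    D = witness.F.target
    if witness.G.source != D or witness.G.target != C:
        return CheckResult(False, law="typing", counterexample={"reason": "G must map D back to C"})
    if len(C.states) > MAX_ADJUNCTION_OBJECTS or len(D.states) > MAX_ADJUNCTION_OBJECTS:
        raise ValueError(
            f"too large to verify: at most {MAX_ADJUNCTION_OBJECTS} objects per category"
        )
    for name, m in (("F", witness.F), ("G", witness.G)):
        res = check_functor(m)
        if not res:
            return CheckResult(False, law=f"functoriality of {name}", counterexample=res.counterexample)
    bound = witness.bound

    def phi(c: State, d: State, mor: Morphism) -> Morphism | None:
        table = witness.hom_maps.get((c, d))
        if table is None:
            return None
        return table.get(mor)

    # (ii) bijection tables
    for c in C.states:
        for d in D.states:
            dom = hom_set(C, witness.G.state_map[d], c, bound)
            cod = hom_set(D, d, witness.F.state_map[c], bound)
            table = witness.hom_maps.get((c, d))
            if table is None:
                return CheckResult(False, law="bijection", counterexample={"hom_pair": (c, d), "reason": "missing table"})
            if set(table.keys()) != set(dom):
                return CheckResult(
                    False,
                    law="bijection",
                    counterexample={"hom_pair": (c, d), "reason": "table domain != Hom_C(G(d), c)"},
                )
            values = list(table.values())
            if len(set(values)) != len(values) or set(values) != set(cod):
                return CheckResult(
                    False,
                    law="bijection",
                    counterexample={"hom_pair": (c, d), "reason": "table is not a bijection onto Hom_D(d, F(c))"},
                )

    # (iii) naturality, on generating morphisms
    for c in C.states:
        for d in D.states:
            for alpha in hom_set(C, witness.G.state_map[d], c, bound):
                img = phi(c, d, alpha)
                # natural in c: f : c -> c' a generator
                if len(alpha[1]) < bound:
                    for a in C.actions:
                        c2 = C.transition[(a, c)]
                        lhs = phi(c2, d, compose_morphisms(alpha, (c, (a,))))
                        rhs = compose_morphisms(img, (witness.F.state_map[c], (witness.F.action_map[a],)))
                        if lhs != rhs:
                            return CheckResult(
                                False,
                                law="naturality in c",
                                counterexample={"hom_pair": (c, d), "generator": a, "alpha": alpha},
                            )
                # natural in d: g : d' -> d, i.e. d' with transition(g, d') = d
                if len(alpha[1]) < bound:
                    for g in D.actions:
                        for d_prime in D.states:
                            if D.transition[(g, d_prime)] != d:
                                continue
                            lhs = phi(c, d_prime, compose_morphisms(apply_to_morphism(witness.G, (d_prime, (g,))), alpha))
                            rhs = compose_morphisms((d_prime, (g,)), img)
                            if lhs != rhs:
                                return CheckResult(
                                    False,
                                    law="naturality in d",
                                    counterexample={"hom_pair": (c, d), "generator": g, "alpha": alpha, "d_prime": d_prime},
                                )
    return CheckResult(True)


def isomorphism_witness(F: ModelMap, G: ModelMap, bound: int = 4) -> AdjunctionWitness:
    """Adjunction witness for mutually inverse functors: Phi(alpha) = F(alpha).

    When G inverts F on states and actions, Hom_C(G(d), c) maps bijectively
    onto Hom_D(d, F(c)) by applying F to the action word; an isomorphism of
    categories is in particular an adjunction.
    """
    C, D = F.source, F.target
    hom_maps: dict[tuple[State, State], dict[Morphism, Morphism]] = {}
    for c in C.states:
        for d in D.states:
            table = {}
            for alpha in hom_set(C, G.state_map[d], c, bound):
                table[alpha] = apply_to_morphism(F, alpha)
            hom_maps[(c, d)] = table
    return AdjunctionWitness(F=F, G=G, hom_maps=hom_maps, bound=bound)


# --- stochastic surrogate helper -----------------------------------------------


def argmax_surrogate(
    states: Sequence[State],
    actions: Sequence[Action],
    probabilities: Mapping[tuple[Action, State], Mapping[State, float]],
    role: str = "surrogate",
) -> TransitionSystem:
    """Reduce a row-stochastic surrogate to a deterministic system by argmax.

    Each (action, state) row of transition probabilities must sum to ~1;
    the most probable successor wins, ties broken by state order.
    """
    trans: dict[tuple[Action, State], State] = {}
    order = {s: i for i, s in enumerate(states)}
    for a in actions:
        for s in states:
            row = probabilities[(a, s)]
            total = sum(row.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"probability row for ({a!r}, {s!r}) sums to {total}, not 1")
            best = max(row.items(), key=lambda kv: (kv[1], -order[kv[0]]))
            trans[(a, s)] = best[0]
    return TransitionSystem(role=role, states=tuple(states), actions=tuple(actions), transition=trans)
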