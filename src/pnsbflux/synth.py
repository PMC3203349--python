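"""Small stoichiometric fixture networks with known FVA answers.

These toys exercise every pipeline stage without external data and
provide the independent oracle for the LP engine:
:func:`brute_force_fva` enumerates the vertices of the constrained flux
polytope in exact rational arithmetic, so its per-coordinate min/max are
ground truth against which :func:`pnsbflux.fva.solve_fva` is checked.

The ``redox_toy`` reproduces, in five reactions, the uniqueness
mechanism of photoheterotrophic growth: with the hydrogen valve closed,
carbon and electron balances pin the biomass-like drain flux to a unique
value; opening the valve introduces an external electron sink and the
drain becomes a proper interval.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations, product

from pnsbflux.core import MetabolicModel, Metabolite, Reaction
from pnsbflux.scenarios import Scenario

__all__ = ["ToySpec", "make_toy", "brute_force_fva"]

_F = Fraction
_ALL = frozenset(("rru", "rsp", "rpa"))


@dataclass(frozen=True)
class ToySpec:
    """Specification of a fixture network.

    topology: "chain", "diamond", "redox_toy" or "random_dag".
    size: chain length / number of internal metabolites (random_dag).
    uptake: fixed substrate uptake rate of the scenario.
    seed: deterministic seed for the random topology (byte-identical
    output for equal seeds).
    """

    topology: str
    size: int = 3
    uptake: float = 1.0
    seed: int = 0
    h2_valve_open: bool = False

    def __post_init__(self):
        if self.topology not in ("chain", "diamond", "redox_toy", "random_dag"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.size < 1:
            raise ValueError("size must be >= 1")


def _met(mid, external=False, formula=None):
    return Metabolite(id=mid, external=external, formula=formula)


def _rxn(rid, stoich, reversible=False):
    return Reaction(
        id=rid,
        stoich={m: _F(c) for m, c in stoich.items()},
        reversible=reversible,
        species=_ALL,
    )


def _chain(spec: ToySpec):
    n = spec.size
    mets = [_met("S_ext", external=True)]
    mets += [_met(f"M{i}") for i in range(1, n)]
    mets += [_met("P_ext", external=True)]
    rxns = [_rxn("up", {"S_ext": -1, "M1" if n > 1 else "P_ext": 1})]
    if n > 1:
        for i in range(1, n - 1):
            rxns.append(_rxn(f"v{i}", {f"M{i}": -1, f"M{i+1}": 1}))
        rxns.append(_rxn("ex", {f"M{n-1}": -1, "P_ext": 1}))
    model = MetabolicModel(mets, rxns, name=f"chain({n})")
    u = spec.uptake
    expected = {r.id: (u, u) for r in rxns}
    scenario = Scenario(name="toy", fixed_fluxes={"up": u})
    return model, scenario, expected


def _diamond(spec: ToySpec):
    mets = [_met("S_ext", external=True), _met("A"), _met("B"),
            _met("P_ext", external=True)]
    rxns = [
        _rxn("up", {"S_ext": -1, "A": 1}),
        _rxn("b1", {"A": -1, "B": 1}),
        _rxn("b2", {"A": -1, "B": 1}),
        _rxn("ex", {"B": -1, "P_ext": 1}),
    ]
    model = MetabolicModel(mets, rxns, name="diamond")
    u = spec.uptake
    expected = {"up": (u, u), "b1": (0.0, u), "b2": (0.0, u), "ex": (u, u)}
    scenario = Scenario(name="toy", fixed_fluxes={"up": u})
    return model, scenario, expected


def _redox_toy(spec: ToySpec):
    # substrate S (3 C, 2 electron pairs in excess of the precursor X),
    # a Calvin-like sink refixing CO2 at 2 NADH each, a biomass-like
    # drain consuming X + NADH, and an H2 valve.
    mets = [
        _met("S_ext", external=True), _met("S"), _met("X"), _met("NADH"),
        _met("CO2"), _met("CO2_ext", external=True),
        _met("H2_ext", external=True), _met("BM_ext", external=True),
    ]
    rxns = [
        _rxn("up", {"S_ext": -1, "S": 1}),
        _rxn("cat", {"S": -1, "X": 1, "CO2": 1, "NADH": 2}),
        _rxn("drain", {"X": -1, "NADH": -1, "BM_ext": 1}),
        _rxn("calv", {"CO2": -1, "NADH": -2, "X": 1}),
        _rxn("valve", {"NADH": -1, "H2_ext": 1}),
        _rxn("co2ex", {"CO2": -1, "CO2_ext": 1}, reversible=True),
    ]
    model = MetabolicModel(mets, rxns, name="redox_toy")
    u = spec.uptake
    fixes = {"up": u}
    if spec.h2_valve_open:
        # valve free: drain in [u, 4u/3], calvin in [0, u/3], valve in [0, u]
        expected = {
            "up": (u, u), "cat": (u, u), "drain": (u, 4 * u / 3),
            "calv": (0.0, u / 3), "valve": (0.0, u), "co2ex": (2 * u / 3, u),
        }
    else:
        fixes["valve"] = 0.0
        expected = {
            "up": (u, u), "cat": (u, u), "drain": (4 * u / 3, 4 * u / 3),
            "calv": (u / 3, u / 3), "valve": (0.0, 0.0),
            "co2ex": (2 * u / 3, 2 * u / 3),
        }
    scenario = Scenario(name="toy", fixed_fluxes=fixes)
    return model, scenario, expected


def _random_dag(spec: ToySpec):
    # Acyclic, count-conserving network: every reaction converts one
    # unit of an earlier metabolite into one unit of a later one, so all
    # fluxes are bounded and the polytope is non-degenerate.
    rng = random.Random(spec.seed)
    k = max(2, min(spec.size, 5))
    mets = [_met("S_ext", external=True)]
    mets += [_met(f"M{i}") for i in range(1, k + 1)]
    mets += [_met("P_ext", external=True)]
    rxns = [_rxn("up", {"S_ext": -1, "M1": 1})]
    # spanning path guarantees a route to the sink
    for i in range(1, k):
        rxns.append(_rxn(f"p{i}", {f"M{i}": -1, f"M{i+1}": 1}))
    extra = min(8, k + 3) - len(rxns) - 1
    pairs = [(i, j) for i in range(1, k) for j in range(i + 1, k + 1)]
    rng.shuffle(pairs)
    for n, (i, j) in enumerate(pairs[:max(0, extra)]):
        rxns.append(_rxn(f"e{n}", {f"M{i}": -1, f"M{j}": 1}))
    rxns.append(_rxn("ex", {f"M{k}": -1, "P_ext": 1}))
    model = MetabolicModel(mets, rxns, name=f"random_dag(seed={spec.seed})")
    scenario = Scenario(name="toy", fixed_fluxes={"up": spec.uptake})
    expected = {
        rid: (float(lo), float(hi))
        for rid, (lo, hi) in brute_force_fva(model, scenario).items()
    }
    return model, scenario, expected


def make_toy(spec: ToySpec):
    """Build a fixture network.

    Returns ``(model, scenario, expected)`` where ``expected`` maps
    reaction id to the exact (min, max) flux range under the scenario —
    closed-form for chain/diamond/redox_toy, from the brute-force oracle
    for random_dag.
    """
    builder = {
        "chain": _chain,
        "diamond": _diamond,
        "redox_toy": _redox_toy,
        "random_dag": _random_dag,
    }[spec.topology]
    return builder(spec)


# ---------------------------------------------------------------------------
# exact brute-force oracle


def _solve_square(rows, rhs):
    """Solve a square rational system; None if singular."""
    n = len(rows)
    M = [list(rows[i]) + [rhs[i]] for i in range(n)]
    for col in range(n):
        piv = next((r for r in range(col, n) if M[r][col] != 0), None)
        if piv is None:
            return None
        M[col], M[piv] = M[piv], M[col]
        pv = M[col][col]
        M[col] = [x / pv for x in M[col]]
        for r in range(n):
            if r != col and M[r][col] != 0:
                f = M[r][col]
                M[r] = [a - f * b for a, b in zip(M[r], M[col])]
    return [M[i][n] for i in range(n)]


def _rref(matrix):
    """Reduced row echelon form over Fractions; returns (rref, pivots)."""
    M = [row[:] for row in matrix]
    rows = len(M)
    cols = len(M[0]) if rows else 0
    pivots = []
    r = 0
    for c in range(cols):
        piv = next((i for i in range(r, rows) if M[i][c] != 0), None)
        if piv is None:
            continue
        M[r], M[piv] = M[piv], M[r]
        pv = M[r][c]
        M[r] = [x / pv for x in M[r]]
        for i in range(rows):
            if i != r and M[i][c] != 0:
                f = M[i][c]
                M[i] = [a - f * b for a, b in zip(M[i], M[r])]
        pivots.append(c)
        r += 1
        if r == rows:
            break
    return M[:r], pivots


def brute_force_fva(
    model: MetabolicModel, scenario: Scenario, max_reactions: int = 10
) -> dict[str, tuple[Fraction, Fraction]]:
    """Exact FVA by vertex enumeration of the flux polytope.

    The polytope {r : N r = 0, fixed rates, box bounds} attains each
    coordinate's min/max at a vertex; every vertex is a basic solution
    obtained by pinning d = q - rank free coordinates to a box bound and
    solving the equality system.  Only for fixtures (refuses q > 10).
    """
    q = len(model.reactions)
    if q > max_reactions:
        raise ValueError(
            f"brute-force oracle limited to {max_reactions} reactions, got {q}"
        )
    from pnsbflux.core import build_stoich_matrix

    N = build_stoich_matrix(model)
    fixes = scenario.effective_fixes()
    lo, hi = [], []
    for rxn in model.reactions:
        if rxn.id in fixes:
            v = _F(str(fixes[rxn.id]))
            lo.append(v)
            hi.append(v)
        else:
            b = _F(str(model.default_bound))
            lo.append(-b if rxn.reversible else _F(0))
            hi.append(b)

    A, pivots = _rref(N) if N else ([], [])
    rank = len(A)
    d = q - rank
    vertices = []
    idx = list(range(q))
    for free_set in combinations(idx, d):
        basic = [j for j in idx if j not in free_set]
        for corner in product(*[(lo[j], hi[j]) for j in free_set]):
            rhs = []
            rows = []
            for row in A:
                rows.append([row[j] for j in basic])
                rhs.append(-sum(row[j] * v for j, v in zip(free_set, corner)))
            sol = _solve_square(rows, rhs)
            if sol is None:
                continue
            r = [None] * q
            for j, v in zip(free_set, corner):
                r[j] = v
            for j, v in zip(basic, sol):
                r[j] = v
            if all(lo[j] <= r[j] <= hi[j] for j in idx):
                vertices.append(r)
        if d == 0:
            break
    if not vertices:
        return {}
    out = {}
    for j, rxn in enumerate(model.reactions):
        vals = [v[j] for v in vertices]
        out[rxn.id] = (min(vals), max(vals))
    return out
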