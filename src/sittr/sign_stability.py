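"""Qualitative (sign) stability testing for community matrices.

A real square matrix A is *sign stable* when every matrix with the same
sign pattern is stable — stability decided by the signs alone, which is
precisely the robustness question that matters when a biological model's
parameter values are error-prone.  The tester implements the classical
five-condition criterion (Quirk–Ruppert / Jeffries colour test):

  (i)   every diagonal entry is nonpositive;
  (ii)  no off-diagonal pair satisfies a_ij·a_ji > 0;
  (iii) the directed graph D_A (edges (i,j), i≠j, a_ij ≠ 0) has no
        simple cycle of length ≥ 3;
  (iv)  in every R_A-colouring of the undirected graph G_A all vertices
        are black (R_A = vertices with nonzero diagonal);
  (v)   G_A admits a matching covering every vertex outside R_A.

G_A keeps an edge {i, j} only when both a_ij and a_ji are nonzero — the
standard definition.  Conditions (iii)–(v) are decided by exhaustive
enumeration, capped at n ≤ 20 (the model needs n = 5); correctness over
scale, no heuristic fallback.

Applied to the SIT1T2R model: the linearization at the endemic
equilibrium Q* has a positive diagonal entry in its N row whenever
γ > α, so the community matrix is *not* sign stable there — condition
(i) fails with a diagonal witness.  ``MATRIX_B`` ships the 5×5 reference
sign pattern used in that argument.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "SignPattern",
    "SignStabilityVerdict",
    "MATRIX_B",
    "sign_pattern",
    "condition_i_diag",
    "condition_ii_antisym",
    "condition_iii_no_long_cycle",
    "condition_iv_coloring",
    "condition_v_matching",
    "is_sign_stable",
    "sample_same_pattern",
    "MAX_DIMENSION",
]

#: Hard cap for the exhaustive enumerations in conditions (iii)-(v).
MAX_DIMENSION = 20

#: Reference 5×5 sign pattern of the (S, I, T1, T2, N) community matrix
#: at the endemic equilibrium, as used in the model's qualitative
#: stability argument.  Its (5,5) entry is +1 (the N row diagonal is
#: γ−α > 0), which alone defeats condition (i).  NOTE: its (2,1) entry
#: is 0, whereas the analytic Jacobian of the system carries
#: +β(ηT1*+ζT2*) there at any positive equilibrium; the discrepancy does
#: not affect the verdict.
MATRIX_B = np.array(
    [
        [-1, 0, -1, -1, 1],
        [0, -1, 1, 1, 0],
        [0, 1, -1, 0, 0],
        [0, 1, 1, -1, 0],
        [0, 0, 0, -1, 1],
    ]
)


@dataclass(frozen=True)
class SignPattern:
    """Entrywise sign pattern of a square matrix, entries in {−1, 0, +1}."""

    signs: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.signs)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError(f"sign pattern must be square, got shape {s.shape}")
        if not np.all(np.isin(s, (-1, 0, 1))):
            raise ValueError("sign pattern entries must be -1, 0 or +1")
        object.__setattr__(self, "signs", s.astype(int))

    @property
    def n(self) -> int:
        return self.signs.shape[0]

    def vertices_with_nonzero_diagonal(self) -> frozenset[int]:
        """R_A, 0-based."""
        return frozenset(int(i) for i in range(self.n) if self.signs[i, i] != 0)

    def directed_edges(self) -> list[tuple[int, int]]:
        """D_A edges: ordered (i, j), i ≠ j, a_ij ≠ 0 (0-based)."""
        s = self.signs
        return [(i, j) for i in range(self.n) for j in range(self.n)
                if i != j and s[i, j] != 0]

    def undirected_edges(self) -> list[tuple[int, int]]:
        """G_A edges: {i, j}, i < j, with a_ij ≠ 0 ≠ a_ji (0-based)."""
        s = self.signs
        return [(i, j) for i in range(self.n) for j in range(i + 1, self.n)
                if s[i, j] != 0 and s[j, i] != 0]


def sign_pattern(matrix, zero_tol: float = 0.0) -> SignPattern:
    """Strict entrywise sign of a real square matrix.

    Entries with |a_ij| ≤ zero_tol map to 0.  The default zero_tol = 0
    suits patterns coming from symbolic structure; for numerically
    computed Jacobians pass e.g. ``1e-12 * abs(matrix).max()``.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix must be square, got shape {m.shape}")
    if zero_tol < 0:
        raise ValueError("zero_tol must be nonnegative")
    s = np.sign(m).astype(int)
    s[np.abs(m) <= zero_tol] = 0
    return SignPattern(signs=s)


def _as_pattern(obj, zero_tol: float = 0.0) -> SignPattern:
    return obj if isinstance(obj, SignPattern) else sign_pattern(obj, zero_tol)


def condition_i_diag(sp: SignPattern) -> bool:
    """(i) Every diagonal entry nonpositive (a_ii ≤ 0)."""
    return bool(np.all(np.diag(sp.signs) <= 0))


def condition_ii_antisym(sp: SignPattern) -> bool:
    """(ii) No off-diagonal 2-cycle with positive sign product."""
    s = sp.signs
    prod = s * s.T
    off = ~np.eye(sp.n, dtype=bool)
    return bool(np.all(prod[off] <= 0))


def _check_dimension(sp: SignPattern) -> None:
    if sp.n > MAX_DIMENSION:
        raise ValueError(
            f"exhaustive enumeration capped at n <= {MAX_DIMENSION}, got n = {sp.n}"
        )


def condition_iii_no_long_cycle(sp: SignPattern) -> bool:
    """(iii) D_A has no simple directed cycle of length ≥ 3."""
    _check_dimension(sp)
    return _find_long_cycle(sp) is None


def _find_long_cycle(sp: SignPattern) -> list[int] | None:
    g = nx.DiGraph()
    g.add_nodes_from(range(sp.n))
    g.add_edges_from(sp.directed_edges())
    for cycle in nx.simple_cycles(g):
        if len(cycle) >= 3:
            return [int(v) for v in cycle]
    return None


def _valid_colorings(sp: SignPattern):
    """Yield all valid R_A-colourings as frozensets of black vertices.

    A colouring paints every vertex black or white such that: each
    vertex of R_A is black, no black vertex has precisely one white
    neighbour (in G_A), and each white vertex has at least one white
    neighbour.
    """
    n = sp.n
    r_a = sp.vertices_with_nonzero_diagonal()
    adj: list[set[int]] = [set() for _ in range(n)]
    for i, j in sp.undirected_edges():
        adj[i].add(j)
        adj[j].add(i)
    free = sorted(set(range(n)) - r_a)
    for whites in itertools.chain.from_iterable(
        itertools.combinations(free, k) for k in range(len(free) + 1)
    ):
        white = set(whites)
        ok = all(len(adj[v] & white) != 1 for v in range(n) if v not in white) and all(
            len(adj[v] & white) >= 1 for v in white
        )
        if ok:
            yield frozenset(set(range(n)) - white)


def condition_iv_coloring(sp: SignPattern) -> bool:
    """(iv) The only valid R_A-colouring of G_A is all-black."""
    _check_dimension(sp)
    all_black = frozenset(range(sp.n))
    return all(coloring == all_black for coloring in _valid_colorings(sp))


def _matching_covering(sp: SignPattern) -> list[tuple[int, int]] | None:
    """Backtracking search for disjoint G_A edges covering V − R_A."""
    adj: list[set[int]] = [set() for _ in range(sp.n)]
    for i, j in sp.undirected_edges():
        adj[i].add(j)
        adj[j].add(i)
    to_cover = sorted(set(range(sp.n)) - sp.vertices_with_nonzero_diagonal())

    def extend(uncovered: list[int], used: set[int], acc: list[tuple[int, int]]):
        while uncovered and uncovered[0] in used:
            uncovered = uncovered[1:]
        if not uncovered:
            return acc
        v = uncovered[0]
        for w in sorted(adj[v] - used):
            res = extend(uncovered[1:], used | {v, w}, acc + [(v, w)])
            if res is not None:
                return res
        return None

    return extend(to_cover, set(), [])


def condition_v_matching(sp: SignPattern) -> bool:
    """(v) G_A admits a matching covering every vertex outside R_A."""
    _check_dimension(sp)
    return _matching_covering(sp) is not None


@dataclass(frozen=True)
class SignStabilityVerdict:
    """Per-condition outcome plus an overall verdict and a witness.

    ``witness`` describes the first failing object (indices 1-based): a
    positive diagonal entry, a violating off-diagonal pair, a k-cycle, a
    valid non-all-black colouring, or the absence of a covering
    matching.  Empty iff ``overall`` is true.
    """

    cond_i: bool
    cond_ii: bool
    cond_iii: bool
    cond_iv: bool
    cond_v: bool
    overall: bool
    failed_conditions: tuple[str, ...] = ()
    witness: str = ""

    def to_flat_dict(self) -> dict[str, object]:
        return {
            "cond_i": self.cond_i, "cond_ii": self.cond_ii,
            "cond_iii": self.cond_iii, "cond_iv": self.cond_iv,
            "cond_v": self.cond_v, "overall": self.overall,
            "failed_conditions": ";".join(self.failed_conditions),
            "witness": self.witness,
        }

    def to_text(self) -> str:
        lines = [f"{k} = {v}" for k, v in self.to_flat_dict().items()]
        return "\n".join(lines) + "\n"


def _first_witness(sp: SignPattern) -> tuple[str, str] | None:
    """Name of the first failing condition and its witness, in order (i)-(v)."""
    s = sp.signs
    for i in range(sp.n):
        if s[i, i] > 0:
            return "i", f"diagonal entry ({i + 1},{i + 1}) is positive"
    for i in range(sp.n):
        for j in range(sp.n):
            if i != j and s[i, j] * s[j, i] > 0:
                return "ii", (
                    f"off-diagonal pair ({i + 1},{j + 1})/({j + 1},{i + 1}) "
                    "has positive sign product"
                )
    cycle = _find_long_cycle(sp)
    if cycle is not None:
        pretty = "→".join(str(v + 1) for v in cycle + cycle[:1])
        return "iii", f"directed {len(cycle)}-cycle {pretty}"
    for coloring in _valid_colorings(sp):
        if coloring != frozenset(range(sp.n)):
            white = sorted(set(range(sp.n)) - coloring)
            return "iv", (
                "valid R_A-coloring with white vertices "
                + ",".join(str(v + 1) for v in white)
            )
    if _matching_covering(sp) is None:
        return "v", "no matching of G_A covers all vertices outside R_A"
    return None


def is_sign_stable(matrix, zero_tol: float = 0.0) -> SignStabilityVerdict:
    """Run conditions (i)–(v) on a matrix (or SignPattern).

    The verdict depends only on the sign pattern of the input.  All five
    condition booleans are reported; the witness describes the first
    failure in the (i)–(v) order.
    """
    sp = _as_pattern(matrix, zero_tol)
    _check_dimension(sp)
    conds = {
        "i": condition_i_diag(sp),
        "ii": condition_ii_antisym(sp),
        "iii": condition_iii_no_long_cycle(sp),
        "iv": condition_iv_coloring(sp),
        "v": condition_v_matching(sp),
    }
    failed = tuple(name for name, ok in conds.items() if not ok)
    overall = not failed
    witness = ""
    if failed:
        found = _first_witness(sp)
        assert found is not None
        witness = f"condition ({found[0]}): {found[1]}"
    return SignStabilityVerdict(
        cond_i=conds["i"], cond_ii=conds["ii"], cond_iii=conds["iii"],
        cond_iv=conds["iv"], cond_v=conds["v"],
        overall=overall, failed_conditions=failed, witness=witness,
    )


def sample_same_pattern(
    pattern,
    n_samples: int,
    rng: np.random.Generator,
    low: float = 0.1,
    high: float = 10.0,
):
    """Yield random matrices sharing a sign pattern.

    Each nonzero entry gets an independent magnitude drawn uniform(low,
    high); used as the Monte-Carlo eigenvalue soundness oracle for
    patterns the tester declares sign stable.
    """
    sp = _as_pattern(pattern)
    s = sp.signs.astype(float)
    for _ in range(int(n_samples)):
        yield s * rng.uniform(low, high, size=s.shape)
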