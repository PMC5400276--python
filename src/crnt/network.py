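"""Reaction networks, their complex graphs and structural analysis.

A reaction network is a set of *N* species participating in *R* directed
reactions between *M* complexes (multisets of species).  The module provides:

* a plain-text reaction-list parser / writer,
* the structural matrices: molecularity matrix ``Y`` (N x M), stoichiometric
  matrix ``S`` (N x R), linkage-class incidence ``Lambda`` (M x l),
* graph-theoretic classification (linkage classes, terminal strong linkage
  classes, uniterminality, weak reversibility),
* deficiency ``delta = M - l - s`` and the open/closed test via a strictly
  positive left annihilator of ``S``,
* nonnegative conservation bases (conserved moieties), and
* the semi-diffusive extension used by the injectivity-oriented search.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import linprog

from .cone import nonnegative_nullspace_rays

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "SemiDiffusiveNetwork",
    "StructuralSummary",
    "ConservationBasis",
    "NetworkSyntaxError",
    "parse_network",
    "write_network",
    "structural_summary",
    "linkage_classes",
    "terminal_strong_linkage_classes",
    "is_uniterminal",
    "is_weakly_reversible",
    "conservation_basis",
    "make_semidiffusive",
    "rank_tol",
    "matrix_rank",
]

Complex = tuple[tuple[str, int], ...]  # sorted ((species, molecularity), ...); () is the zero complex


def rank_tol(M: np.ndarray) -> float:
    """Singular-value threshold max(dim) * eps * sigma_max for rank decisions."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if M.size == 0:
        return 0.0
    smax = np.linalg.norm(M, 2)
    return max(M.shape) * np.finfo(float).eps * max(smax, 1.0)


def matrix_rank(M: np.ndarray, tol: float | None = None) -> int:
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if M.size == 0:
        return 0
    if tol is None:
        tol = rank_tol(M)
    sv = np.linalg.svd(M, compute_uv=False)
    return int(np.sum(sv > tol))


class NetworkSyntaxError(ValueError):
    """Raised on malformed reaction-list input (carries the line number)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


@dataclass(frozen=True)
class Reaction:
    source: int  # complex index
    product: int
    label: str
    kind: str  # 'true' | 'outflow' | 'inflow'

    def __post_init__(self):
        if self.kind not in ("true", "outflow", "inflow"):
            raise ValueError(f"unknown reaction kind {self.kind!r}")


class ReactionNetwork:
    """Immutable reaction network with its graph of complexes.

    Parameters
    ----------
    species : ordered species names.
    complexes : ordered list of complexes; each a mapping/iterable of
        (species, molecularity) pairs with positive integer molecularities.
        The empty complex is the zero complex (environment).
    reactions : list of :class:`Reaction` (source/product are complex indices).
    """

    def __init__(self, species: Sequence[str], complexes: Sequence, reactions: Sequence[Reaction]):
        self.species: tuple[str, ...] = tuple(species)
        self.complexes: tuple[Complex, ...] = tuple(_normalize_complex(c) for c in complexes)
        self.reactions: tuple[Reaction, ...] = tuple(reactions)
        self._validate()

    # -- basic counts ------------------------------------------------------
    @property
    def N(self) -> int:
        return len(self.species)

    @property
    def M(self) -> int:
        return len(self.complexes)

    @property
    def R(self) -> int:
        return len(self.reactions)

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def _validate(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species names")
        if len(set(self.complexes)) != len(self.complexes):
            raise ValueError("duplicate complexes in complex list")
        seen_labels = set()
        used = set()
        known = set(self.species)
        for cx in self.complexes:
            for sp, m in cx:
                if sp not in known:
                    raise ValueError(f"complex references unknown species {sp!r}")
                if m <= 0:
                    raise ValueError("molecularities must be positive integers")
                used.add(sp)
        for sp in self.species:
            if sp not in used:
                raise ValueError(f"species {sp!r} appears in no complex")
        zero = self.zero_complex_index()
        for r in self.reactions:
            if r.source == r.product:
                raise ValueError(f"reaction {r.label!r}: source equals product complex")
            if not (0 <= r.source < self.M and 0 <= r.product < self.M):
                raise ValueError(f"reaction {r.label!r}: complex index out of range")
            if r.label in seen_labels:
                raise ValueError(f"duplicate rate label {r.label!r}")
            seen_labels.add(r.label)
            if r.kind == "outflow" and r.product != zero:
                raise ValueError(f"outflow reaction {r.label!r} must end at the zero complex")
            if r.kind == "inflow" and r.source != zero:
                raise ValueError(f"inflow reaction {r.label!r} must start at the zero complex")

    def zero_complex_index(self) -> int | None:
        try:
            return self.complexes.index(())
        except ValueError:
            return None

    # -- structural matrices ----------------------------------------------
    @property
    def Y(self) -> np.ndarray:
        """N x M molecularity matrix: Y[i, j] = molecularity of species i in complex j."""
        Y = np.zeros((self.N, self.M), dtype=int)
        idx = {sp: i for i, sp in enumerate(self.species)}
        for j, cx in enumerate(self.complexes):
            for sp, m in cx:
                Y[idx[sp], j] = m
        return Y

    @property
    def S(self) -> np.ndarray:
        """N x R stoichiometric matrix, column j = Y[:, product_j] - Y[:, source_j]."""
        Y = self.Y
        S = np.zeros((self.N, self.R), dtype=int)
        for j, r in enumerate(self.reactions):
            S[:, j] = Y[:, r.product] - Y[:, r.source]
        return S

    @property
    def source_indices(self) -> np.ndarray:
        return np.array([r.source for r in self.reactions], dtype=int)

    @property
    def product_indices(self) -> np.ndarray:
        return np.array([r.product for r in self.reactions], dtype=int)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.label for r in self.reactions)

    def reactions_of_kind(self, kind: str) -> list[int]:
        return [j for j, r in enumerate(self.reactions) if r.kind == kind]

    def complex_name(self, j: int) -> str:
        cx = self.complexes[j]
        if not cx:
            return "0"
        return " + ".join((f"{m} {sp}" if m != 1 else sp) for sp, m in cx)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<ReactionNetwork N={self.N} R={self.R} M={self.M}>"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ReactionNetwork)
            and self.species == other.species
            and self.complexes == other.complexes
            and self.reactions == other.reactions
        )

    def __hash__(self):
        return hash((self.species, self.complexes, self.reactions))


def _normalize_complex(c) -> Complex:
    if isinstance(c, dict):
        items = c.items()
    else:
        items = tuple(c)
    merged: dict[str, int] = {}
    for sp, m in items:
        merged[sp] = merged.get(sp, 0) + int(m)
    return tuple(sorted(merged.items()))


# ---------------------------------------------------------------------------
# reaction-list text format
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^\s*(?:(\d+)\s+)?([A-Za-z_][A-Za-z0-9_*'.-]*)\s*$")


def _parse_side(text: str, line: int) -> Complex:
    text = text.strip()
    if text == "0":
        return ()
    items: list[tuple[str, int]] = []
    for term in text.split("+"):
        m = _TERM_RE.match(term)
        if not m:
            raise NetworkSyntaxError(f"cannot parse term {term.strip()!r}", line)
        coeff = int(m.group(1)) if m.group(1) else 1
        if coeff <= 0:
            raise NetworkSyntaxError("stoichiometric coefficients must be positive", line)
        items.append((m.group(2), coeff))
    return _normalize_complex(items)


def parse_network(text: str) -> ReactionNetwork:
    """Parse a reaction-list document into a :class:`ReactionNetwork`.

    One reaction per line: ``[label:] educts ARROW products [@kind]`` with
    ``ARROW`` one of ``->`` / ``<->``; a side is ``0`` (the zero complex) or
    ``+``-separated ``[int] species`` terms; ``#`` starts a comment.
    Reversible lines expand into two reactions with distinct rate labels.
    Reaction kinds are inferred from the zero complex (source 0 => inflow,
    product 0 => outflow, else true) unless overridden by ``@kind``.
    """
    complexes: list[Complex] = []
    cindex: dict[Complex, int] = {}
    reactions: list[Reaction] = []
    species_order: list[str] = []
    seen_species = set()
    labels_used: set[str] = set()
    auto = 0

    def complex_id(cx: Complex) -> int:
        if cx not in cindex:
            cindex[cx] = len(complexes)
            complexes.append(cx)
            for sp, _ in cx:
                if sp not in seen_species:
                    seen_species.add(sp)
                    species_order.append(sp)
        return cindex[cx]

    def next_label() -> str:
        nonlocal auto
        auto += 1
        return f"k{auto}"

    def add(src: Complex, dst: Complex, label: str | None, kind: str | None, ln: int) -> None:
        nonlocal auto
        if label is None:
            label = next_label()
        else:
            auto += 1  # explicit labels still advance the counter to keep file order readable
        if label in labels_used:
            raise NetworkSyntaxError(f"duplicate rate label {label!r}", ln)
        labels_used.add(label)
        if kind is None:
            kind = "inflow" if src == () else ("outflow" if dst == () else "true")
        i, j = complex_id(src), complex_id(dst)
        if i == j:
            raise NetworkSyntaxError("source and product complexes coincide", ln)
        reactions.append(Reaction(i, j, label, kind))

    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        kind = None
        mk = re.search(r"@(\w+)\s*$", line)
        if mk:
            kind = mk.group(1)
            if kind not in ("true", "outflow", "inflow"):
                raise NetworkSyntaxError(f"unknown reaction kind {kind!r}", ln)
            line = line[: mk.start()].strip()
        label = None
        if ":" in line:
            head, line = line.split(":", 1)
            label = head.strip()
            if not label:
                raise NetworkSyntaxError("empty rate label", ln)
        if "<->" in line:
            lhs, rhs = line.split("<->", 1)
            src, dst = _parse_side(lhs, ln), _parse_side(rhs, ln)
            if label is not None:
                add(src, dst, label, kind, ln)
                add(dst, src, label + "_rev", None, ln)
            else:
                add(src, dst, None, kind, ln)
                add(dst, src, None, None, ln)
        elif "->" in line:
            lhs, rhs = line.split("->", 1)
            add(_parse_side(lhs, ln), _parse_side(rhs, ln), label, kind, ln)
        else:
            raise NetworkSyntaxError("expected '->' or '<->'", ln)

    if not reactions:
        raise NetworkSyntaxError("no reactions found")
    return ReactionNetwork(species_order, complexes, reactions)


def write_network(net: ReactionNetwork) -> str:
    """Serialize a network back to the reaction-list format (parser inverse)."""
    lines = []
    for r in net.reactions:
        src = net.complex_name(r.source)
        dst = net.complex_name(r.product)
        inferred = "inflow" if r.source == net.zero_complex_index() else (
            "outflow" if r.product == net.zero_complex_index() else "true"
        )
        suffix = f" @{r.kind}" if r.kind != inferred else ""
        lines.append(f"{r.label}: {src} -> {dst}{suffix}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# graph structure
# ---------------------------------------------------------------------------

def _complex_digraph(net: ReactionNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(range(net.M))
    for r in net.reactions:
        g.add_edge(r.source, r.product)
    return g


def linkage_classes(net: ReactionNetwork) -> tuple[list[list[int]], np.ndarray]:
    """Connected components of the undirected complex graph and the M x l incidence Lambda.

    Classes are ordered by their smallest complex index; complexes within a
    class keep network order.
    """
    g = _complex_digraph(net).to_undirected()
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])
    Lam = np.zeros((net.M, len(comps)), dtype=int)
    for j, comp in enumerate(comps):
        for i in comp:
            Lam[i, j] = 1
    return comps, Lam


def terminal_strong_linkage_classes(net: ReactionNetwork) -> list[list[int]]:
    """Terminal strong linkage classes: sinks of the condensation DAG."""
    g = _complex_digraph(net)
    cond = nx.condensation(g)
    out = []
    for node in cond.nodes:
        if cond.out_degree(node) == 0:
            out.append(sorted(cond.nodes[node]["members"]))
    out.sort(key=lambda c: c[0])
    return out


def is_uniterminal(net: ReactionNetwork) -> bool:
    comps, _ = linkage_classes(net)
    return len(terminal_strong_linkage_classes(net)) == len(comps)


def is_weakly_reversible(net: ReactionNetwork) -> bool:
    comps, _ = linkage_classes(net)
    tslc = {tuple(t) for t in terminal_strong_linkage_classes(net)}
    return all(tuple(c) in tslc for c in comps)


# ---------------------------------------------------------------------------
# closedness and structural summary
# ---------------------------------------------------------------------------

def closedness_certificate(net: ReactionNetwork) -> np.ndarray | None:
    """A strictly positive row vector theta with theta @ S = 0, or None if open.

    Feasibility of {theta S = 0, theta >= 1} (scale invariance makes the
    bound equivalent to strict positivity) decided by linear programming.
    """
    S = net.S
    if S.shape[1] == 0:
        return np.ones(net.N)
    res = linprog(
        c=np.ones(net.N),
        A_eq=S.T.astype(float),
        b_eq=np.zeros(S.shape[1]),
        bounds=[(1.0, None)] * net.N,
        method="highs",
    )
    if not res.success:
        return None
    theta = res.x
    # clean up to small integers when possible
    scaled = theta / np.min(theta)
    rounded = np.round(scaled)
    if np.allclose(scaled, rounded, atol=1e-7) and np.max(np.abs(rounded @ S)) == 0:
        return rounded.astype(int)
    return theta


@dataclass
class StructuralSummary:
    Y: np.ndarray
    S: np.ndarray
    rho: int  # rank of Y
    s: int  # rank of S
    l: int  # number of linkage classes
    Lambda: np.ndarray  # M x l incidence
    lam: int  # number of conservation laws, N - s
    delta: int  # deficiency M - l - s
    uniterminal: bool
    weakly_reversible: bool
    closed: bool
    theta: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {
            "N": self.Y.shape[0],
            "M": self.Y.shape[1],
            "R": self.S.shape[1],
            "rho": self.rho,
            "s": self.s,
            "l": self.l,
            "lambda": self.lam,
            "delta": self.delta,
            "uniterminal": self.uniterminal,
            "weakly_reversible": self.weakly_reversible,
            "closed": self.closed,
        }


def structural_summary(net: ReactionNetwork, zero_complex: str = "shared") -> StructuralSummary:
    """Compute all structural indices of a network.

    ``zero_complex`` selects the linkage-class convention for open networks:
    ``"shared"`` treats the environment as one ordinary node of the complex
    graph; ``"split"`` gives every exchange reaction its own copy of the
    environment node, so pseudo-reactions never merge otherwise disconnected
    subgraphs.  The two conventions can yield different ``M``, ``l`` and hence
    ``delta`` for open networks; they agree on closed ones.
    """
    if zero_complex not in ("shared", "split"):
        raise ValueError("zero_complex must be 'shared' or 'split'")
    work = net
    if zero_complex == "split" and net.zero_complex_index() is not None:
        work = _split_environment(net)
    Y, S = work.Y, net.S
    comps, Lam = linkage_classes(work)
    theta = closedness_certificate(net)
    s = matrix_rank(S)
    summary = StructuralSummary(
        Y=net.Y,
        S=S,
        rho=matrix_rank(net.Y),
        s=s,
        l=len(comps),
        Lambda=Lam,
        lam=net.N - s,
        delta=work.M - len(comps) - s,
        uniterminal=is_uniterminal(work),
        weakly_reversible=is_weakly_reversible(work),
        closed=theta is not None,
        theta=theta,
    )
    return summary


def _split_environment(net: ReactionNetwork) -> ReactionNetwork:
    """Rewrite a network so each exchange reaction uses a private environment species.

    Only a combinatorial device for the alternative linkage-class convention;
    the private placeholders are inert species appearing in one complex each.
    """
    species = list(net.species)
    complexes = [dict(c) for c in net.complexes]
    reactions = []
    zero = net.zero_complex_index()
    extra = 0
    for r in net.reactions:
        if zero is not None and (r.source == zero or r.product == zero):
            extra += 1
            env = f"_env{extra}"
            species.append(env)
            complexes.append({env: 1})
            j = len(complexes) - 1
            src = j if r.source == zero else r.source
            dst = j if r.product == zero else r.product
            reactions.append(Reaction(src, dst, r.label, "true"))
        else:
            reactions.append(r)
    # drop the now-unused zero complex if nothing references it
    used = {r.source for r in reactions} | {r.product for r in reactions}
    if zero is not None and zero not in used:
        keep = [j for j in range(len(complexes)) if j != zero]
        remap = {old: new for new, old in enumerate(keep)}
        complexes = [complexes[j] for j in keep]
        reactions = [Reaction(remap[r.source], remap[r.product], r.label, r.kind) for r in reactions]
    return ReactionNetwork(species, complexes, reactions)


# ---------------------------------------------------------------------------
# conservation basis
# ---------------------------------------------------------------------------

@dataclass
class ConservationBasis:
    B: np.ndarray  # N x lam nonnegative integer matrix, S^T B = 0
    moieties: tuple[str, ...]
    sigma: np.ndarray  # conservation constants B^T c0
    c0: np.ndarray

    @property
    def lam(self) -> int:
        return self.B.shape[1]

    def W(self, c: np.ndarray, sigma: np.ndarray | None = None) -> np.ndarray:
        """Conservation residual W(c, sigma) = B^T c - sigma."""
        if sigma is None:
            sigma = self.sigma
        return self.B.T @ np.asarray(c, dtype=float) - np.asarray(sigma, dtype=float)


def conservation_basis(net: ReactionNetwork, c0: Iterable[float] | None = None) -> ConservationBasis:
    """Nonnegative basis of the left nullspace of S (conserved moieties).

    Extreme rays of the cone ``{b >= 0 : S^T b = 0}`` are enumerated exactly;
    a maximal independent subset in ray order gives the basis.  Raises if the
    rays do not span the full left nullspace, which signals a conservation
    relation that is not a conserved moiety.
    """
    S = net.S
    lam = net.N - matrix_rank(S)
    if c0 is None:
        c0 = np.ones(net.N)
    c0 = np.asarray(list(c0), dtype=float)
    if lam == 0:
        return ConservationBasis(np.zeros((net.N, 0), dtype=int), (), np.zeros(0), c0)
    rays = nonnegative_nullspace_rays(S)
    chosen: list[np.ndarray] = []
    for ray in rays:
        cand = chosen + [ray]
        if _exact_rank(np.array(cand)) == len(cand):
            chosen.append(ray)
        if len(chosen) == lam:
            break
    if len(chosen) < lam:
        raise ValueError(
            "left nullspace of S admits no nonnegative spanning basis: "
            "the network has a conservation relation that is not a conserved moiety"
        )
    B = np.array(chosen, dtype=int).T  # N x lam
    names = tuple(f"M{i+1}" for i in range(lam))
    return ConservationBasis(B, names, B.T @ c0, c0)


def _exact_rank(A: np.ndarray) -> int:
    """Rank of an integer matrix by fraction-free Gaussian elimination."""
    A = [[Fraction(int(x)) for x in row] for row in np.atleast_2d(A)]
    rows, cols = len(A), len(A[0]) if A else 0
    rank = 0
    r = 0
    for c in range(cols):
        piv = next((i for i in range(r, rows) if A[i][c] != 0), None)
        if piv is None:
            continue
        A[r], A[piv] = A[piv], A[r]
        for i in range(rows):
            if i != r and A[i][c] != 0:
                f = A[i][c] / A[r][c]
                A[i] = [a - f * b for a, b in zip(A[i], A[r])]
        r += 1
        rank += 1
        if r == rows:
            break
    return rank


def reorder_species(net: ReactionNetwork, order: Sequence[str]) -> ReactionNetwork:
    """Same network with rows of Y/S permuted to the given species order."""
    if sorted(order) != sorted(net.species):
        raise ValueError("order must be a permutation of the species")
    return ReactionNetwork(order, net.complexes, net.reactions)


def reorder_complexes(net: ReactionNetwork, order: Sequence[int]) -> ReactionNetwork:
    """Same network with the complex list permuted (reaction edges remapped)."""
    if sorted(order) != list(range(net.M)):
        raise ValueError("order must be a permutation of complex indices")
    remap = {old: new for new, old in enumerate(order)}
    complexes = [net.complexes[j] for j in order]
    reactions = [Reaction(remap[r.source], remap[r.product], r.label, r.kind) for r in net.reactions]
    return ReactionNetwork(net.species, complexes, reactions)


def relabel_reactions(net: ReactionNetwork, mapping: dict[str, str]) -> ReactionNetwork:
    """Rename rate-constant labels (e.g. pair convention -> reaction-index)."""
    reactions = [
        Reaction(r.source, r.product, mapping.get(r.label, r.label), r.kind) for r in net.reactions
    ]
    cls = type(net)
    if isinstance(net, SemiDiffusiveNetwork):
        return cls(net.species, net.complexes, reactions, net.key_species, net.true_net)
    return ReactionNetwork(net.species, net.complexes, reactions)


# ---------------------------------------------------------------------------
# semi-diffusive extension
# ---------------------------------------------------------------------------

class SemiDiffusiveNetwork(ReactionNetwork):
    """A true-reaction subsystem extended with outflow of every species and
    inflow of one key species per conserved moiety of the true subsystem.

    Carries the matrices used by the injectivity-oriented search:
    ``Y_to`` (molecularities incl. the environment column and outflow-only
    species columns), ``S_to = [S_true | -I]``, the source-complex matrix
    ``Y_r`` of the true + outflow reactions, and the inflow pattern of ``K``.
    """

    def __init__(self, species, complexes, reactions, key_species: tuple[str, ...], true_net: ReactionNetwork):
        super().__init__(species, complexes, reactions)
        self.key_species = tuple(key_species)
        self.true_net = true_net

    @property
    def true_indices(self) -> list[int]:
        return self.reactions_of_kind("true")

    @property
    def outflow_indices(self) -> list[int]:
        return self.reactions_of_kind("outflow")

    @property
    def inflow_indices(self) -> list[int]:
        return self.reactions_of_kind("inflow")

    @property
    def R_to(self) -> int:
        return len(self.true_indices) + len(self.outflow_indices)

    @property
    def to_indices(self) -> list[int]:
        return self.true_indices + self.outflow_indices

    @property
    def S_to(self) -> np.ndarray:
        """N x R_to stoichiometry of the true + outflow reactions ([S | -I])."""
        return self.S[:, self.to_indices]

    @property
    def Y_r(self) -> np.ndarray:
        """N x R_to source-complex molecularities of the true + outflow reactions."""
        Y = self.Y
        return Y[:, [self.reactions[j].source for j in self.to_indices]]

    @property
    def Y_to(self) -> np.ndarray:
        """Molecularity matrix of the true subsystem extended with the
        environment column and columns for outflow-only singleton complexes."""
        return self.Y

    @property
    def key_indices(self) -> list[int]:
        return [self.species_index(sp) for sp in self.key_species]

    def inflow_pattern(self) -> np.ndarray:
        """0/1 vector marking the species receiving a constant inflow."""
        K = np.zeros(self.N, dtype=int)
        for i in self.key_indices:
            K[i] = 1
        return K


def _free_forms(true_net: ReactionNetwork, basis: ConservationBasis) -> list[str]:
    """Default key species: the free (monomeric) form of each conserved moiety.

    A free form of moiety m is a species composed of exactly one unit of m and
    of no other moiety; ties prefer species that participate in multi-species
    (binding) complexes, then the lowest species index.
    """
    B = basis.B
    binds = {
        sp
        for cx in true_net.complexes
        for sp, _ in cx
        if len(cx) > 1 or (len(cx) == 1 and cx[0][1] > 1)
    }
    keys = []
    for m in range(B.shape[1]):
        candidates = []
        for i, sp in enumerate(true_net.species):
            if B[i, m] > 0 and all(B[i, mm] == 0 for mm in range(B.shape[1]) if mm != m):
                candidates.append((B[i, m], sp not in binds, i, sp))
        if not candidates:
            raise ValueError(f"no free form found for moiety {basis.moieties[m]}")
        candidates.sort()
        keys.append(candidates[0][3])
    return keys


def make_semidiffusive(
    true_net: ReactionNetwork, key_species: Sequence[str] | None = None
) -> SemiDiffusiveNetwork:
    """Extend a true-reaction network to its semi-diffusive version.

    Adds an outflow (degradation) reaction for every species and an inflow
    (basal formation) reaction for the key species of each conserved moiety of
    the true subsystem.  The result has no conservation laws.
    """
    if any(r.kind != "true" for r in true_net.reactions):
        raise ValueError("make_semidiffusive expects a network of true reactions only")
    basis = conservation_basis(true_net)
    if key_species is None:
        key_species = _free_forms(true_net, basis)
    else:
        key_species = list(key_species)
        if len(key_species) != basis.lam:
            raise ValueError(
                f"need exactly one key species per conservation law ({basis.lam}), got {len(key_species)}"
            )
        for sp in key_species:
            if sp not in true_net.species:
                raise ValueError(f"unknown key species {sp!r}")
    if not is_weakly_reversible(true_net):
        # compatibility of the key-species choice with a positive steady state
        # cannot be decided structurally; it is re-checked at recovered points.
        pass

    species = list(true_net.species)
    complexes = [dict(c) for c in true_net.complexes]
    cindex = {cx: j for j, cx in enumerate(true_net.complexes)}

    def ensure_complex(cx: Complex) -> int:
        if cx not in cindex:
            cindex[cx] = len(complexes)
            complexes.append(dict(cx))
        return cindex[cx]

    zero = ensure_complex(())
    reactions = list(true_net.reactions)
    n_true = len(reactions)
    counter = n_true
    for sp in species:
        counter += 1
        j = ensure_complex(((sp, 1),))
        reactions.append(Reaction(j, zero, f"k{counter}", "outflow"))
    for sp in key_species:
        counter += 1
        j = cindex[((sp, 1),)]
        reactions.append(Reaction(zero, j, f"k{counter}", "inflow"))
    return SemiDiffusiveNetwork(species, complexes, reactions, tuple(key_species), true_net)
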