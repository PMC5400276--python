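"""Packaged case-study networks and a random-network generator for property tests.

The catalog covers the interferon-signaling case studies: the didactic
association/activation example, the autocatalytic signal-transduction motif,
the ternary IFN-receptor complex formation (with and without IFN in excess),
the early STAT signaling module, STAT signaling with transcriptional STAT1
feedback, and the coupled receptor + STAT network.  Networks whose reaction
lists are fully determined by published text carry provenance ``"text"``;
the STAT-level networks are reconstructed from figure narratives and carry
provenance ``"figure-transcribed"`` (see data/PROVENANCE.md) — tests assert
their internal consistency and qualitative search outcomes only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .network import (
    Reaction,
    ReactionNetwork,
    SemiDiffusiveNetwork,
    make_semidiffusive,
    parse_network,
    relabel_reactions,
    reorder_complexes,
    reorder_species,
    structural_summary,
)

__all__ = [
    "fixture",
    "fixture_names",
    "fixture_info",
    "random_network",
    "receptor_stat_operating_point",
    "FixtureInfo",
]


@dataclass
class FixtureInfo:
    name: str
    description: str
    provenance: str  # 'text' | 'figure-transcribed' | 'derived'
    expected: dict = field(default_factory=dict)  # structural values stated in text


def _read(fname: str) -> str:
    return resources.files("crnt.data").joinpath(fname).read_text()


def _example_open() -> ReactionNetwork:
    return parse_network(_read("example_open.crn"))


def _example_closed() -> ReactionNetwork:
    return parse_network(_read("example_closed.crn"))


_MOTIF_SPECIES = ("A", "E1", "E2", "A*", "AE1", "A*E2", "AA*")
# complex numbering used by the published matrix displays
_MOTIF_COMPLEXES = ("AE1", "A*E2", "AA*", "2 A*", "A + E1", "A* + E1", "A + E2", "A* + E2", "A + A*")


def _motif_closed() -> ReactionNetwork:
    net = reorder_species(parse_network(_read("motif_closed.crn")), _MOTIF_SPECIES)
    names = [net.complex_name(j) for j in range(net.M)]
    return reorder_complexes(net, [names.index(nm) for nm in _MOTIF_COMPLEXES])


def _motif_semidiffusive() -> SemiDiffusiveNetwork:
    # reaction-index labels k1..k9 for the true part, k10..k16 outflow,
    # k17..k19 inflow of the key species A, E1, E2
    true = _motif_closed()
    pair_to_index = {lbl: f"k{i+1}" for i, lbl in enumerate(true.labels)}
    true = relabel_reactions(true, pair_to_index)
    return make_semidiffusive(true, key_species=("A", "E1", "E2"))


def _ternary_true() -> ReactionNetwork:
    return parse_network(_read("ternary_true.crn"))


def _ternary_excess() -> ReactionNetwork:
    return parse_network(_read("ternary_excess_true.crn"))


def _stat_early_closed() -> ReactionNetwork:
    return parse_network(_read("stat_early.crn"))


def _stat_feedback_true() -> ReactionNetwork:
    return parse_network(_read("stat_feedback.crn"))


def _receptor_stat() -> ReactionNetwork:
    return parse_network(_read("receptor_stat.crn"))


_CATALOG: dict[str, tuple] = {
    "example_open": (
        _example_open,
        FixtureInfo(
            "example_open",
            "A/B association-activation example with basal formation and degradation",
            "text",
            {"N": 4, "R": 7, "M": 6, "s": 4, "lambda": 0},
        ),
    ),
    "example_closed": (
        _example_closed,
        FixtureInfo(
            "example_closed",
            "A/B association-activation example, closed",
            "text",
            {"N": 4, "R": 3, "lambda": 2, "closed": True},
        ),
    ),
    "motif_closed": (
        _motif_closed,
        FixtureInfo(
            "motif_closed",
            "autocatalytic signal transduction motif, closed",
            "text",
            {"N": 7, "R": 9, "M": 9, "l": 3, "lambda": 3, "delta": 2, "closed": True},
        ),
    ),
    "motif_semidiffusive": (
        _motif_semidiffusive,
        FixtureInfo(
            "motif_semidiffusive",
            "motif with degradation of all species and basal formation of A, E1, E2",
            "text",
            {"N": 7, "R": 19, "lambda": 0},
        ),
    ),
    "ternary_true": (
        _ternary_true,
        FixtureInfo(
            "ternary_true",
            "ternary IFN-receptor complex formation, true reactions",
            "text",
            {"N": 6, "lambda": 3, "delta": 1, "weakly_reversible": True},
        ),
    ),
    "ternary_excess": (
        _ternary_excess,
        FixtureInfo(
            "ternary_excess",
            "ternary complex formation with IFN in excess",
            "text",
            {"N": 5, "lambda": 2, "delta": 1, "weakly_reversible": True},
        ),
    ),
    "ternary_semidiffusive": (
        lambda: make_semidiffusive(_ternary_true()),
        FixtureInfo(
            "ternary_semidiffusive",
            "ternary complex formation with degradation of all species, basal "
            "formation of R1, R2 and constant IFN inflow",
            "text",
            {"lambda": 0},
        ),
    ),
    "ternary_excess_semidiffusive": (
        lambda: make_semidiffusive(_ternary_excess()),
        FixtureInfo(
            "ternary_excess_semidiffusive",
            "IFN-in-excess ternary network with degradation and basal R1/R2 formation",
            "text",
            {"lambda": 0},
        ),
    ),
    "stat_early_closed": (
        _stat_early_closed,
        FixtureInfo(
            "stat_early_closed",
            "early STAT signaling upon IFN stimulation, closed",
            "figure-transcribed",
            {"closed": True},
        ),
    ),
    "stat_early_semidiffusive": (
        lambda: make_semidiffusive(_stat_early_closed()),
        FixtureInfo(
            "stat_early_semidiffusive",
            "early STAT signaling with degradation of all species, basal "
            "formation of STAT1/STAT2 and constant active-receptor input",
            "figure-transcribed",
            {"lambda": 0},
        ),
    ),
    "stat_feedback": (
        lambda: make_semidiffusive(_stat_feedback_true()),
        FixtureInfo(
            "stat_feedback",
            "STAT signaling with STAT1 expression feedback via IRF1 and CBP "
            "(semi-diffusive)",
            "figure-transcribed",
            {"lambda": 0},
        ),
    ),
    "receptor_stat": (
        _receptor_stat,
        FixtureInfo(
            "receptor_stat",
            "early STAT signaling coupled with receptor complex formation, closed",
            "figure-transcribed",
            {"closed": True},
        ),
    ),
}


def fixture_names() -> list[str]:
    return list(_CATALOG)


def fixture(name: str) -> ReactionNetwork:
    """Build a packaged case-study network by name."""
    try:
        builder, _ = _CATALOG[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {', '.join(_CATALOG)}") from None
    return builder()


def fixture_info(name: str) -> FixtureInfo:
    try:
        return _CATALOG[name][1]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}") from None


def receptor_stat_operating_point(stat_certificate, *, reservoir: float = 200.0,
                                  binary_level: float = 20.0) -> tuple[np.ndarray, dict]:
    """Construct an equilibrium operating point of the coupled receptor + STAT
    network from a saddle-node certificate of the closed STAT module.

    The STAT species adopt the certified state (the ternary complex T playing
    the activated receptor); the receptor periphery (I, R1, R2 at the
    ``reservoir`` level, the binary complexes at ``binary_level``) is placed
    at detailed balance around the certified free-T concentration, with the
    IR2 route kinetically negligible so that the IFN association constant k29
    controls the delivery of ternary complex.  Sweeping k29 then moves the
    STAT module through its bistable window, which is how the hysteresis
    experiments are set up.
    """
    net = fixture("receptor_stat")
    cs = dict(zip(stat_certificate.species, stat_certificate.c))
    T = cs["Ra"]
    level = {"T": T, "TS2": cs["RaS2"], "TS2S1": cs["RaS2S1"]}
    c0 = np.array([
        level.get(sp, reservoir if sp in ("I", "R1", "R2") else
                  binary_level if sp in ("IR1", "IR2") else cs.get(sp))
        for sp in net.species
    ], dtype=float)
    eps = 1e-4
    k = dict(stat_certificate.k)
    k.update({
        "k29": 1.0, "k21": reservoir * reservoir / binary_level,
        "k22": eps, "k23": eps * reservoir * reservoir / binary_level,
        "k24": 1.0, "k25": binary_level * reservoir / T,
        "k26": eps, "k27": eps * binary_level * reservoir / T,
    })
    return c0, k


# ---------------------------------------------------------------------------
# random structured networks
# ---------------------------------------------------------------------------

def random_network(
    seed: int,
    N: int = 5,
    R: int = 8,
    *,
    weakly_reversible: bool = False,
    deficiency_zero: bool = False,
    uniterminal: bool = False,
    semidiffusive: bool = False,
    moiety_conserved: bool = False,
    max_molecularity: int = 2,
    max_attempts: int = 400,
) -> ReactionNetwork:
    """A random mass-action network with controllable structural properties.

    Rejection sampling over randomly assembled complex graphs; raises if no
    network satisfying the requested constraints is found within the attempt
    budget (possible for contradictory or tight size constraints).
    """
    if N > 10 or R > 25:
        raise ValueError("random_network is intended for small sizes (N <= 10, R <= 25)")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        net = _random_candidate(rng, N, R, weakly_reversible, max_molecularity)
        if net is None:
            continue
        if semidiffusive:
            try:
                net = make_semidiffusive(net)
            except ValueError:
                continue
        summ = structural_summary(net)
        if weakly_reversible and not summ.weakly_reversible:
            continue
        if uniterminal and not summ.uniterminal:
            continue
        if deficiency_zero and summ.delta != 0:
            continue
        if moiety_conserved:
            from .network import conservation_basis

            if summ.lam < 1:
                continue
            try:
                conservation_basis(net)
            except ValueError:
                continue
        return net
    raise ValueError("could not generate a network with the requested properties")


def _random_candidate(rng, N, R, weakly_reversible, max_molecularity):
    species = [f"X{i+1}" for i in range(N)]

    def random_complex():
        n_sp = rng.integers(1, 3)
        chosen = rng.choice(N, size=min(n_sp, N), replace=False)
        return tuple(sorted((species[i], int(rng.integers(1, max_molecularity + 1))) for i in chosen))

    n_cx = int(rng.integers(max(2, R // 2), R + 2))
    complexes = []
    seen = set()
    for _ in range(n_cx * 3):
        cx = random_complex()
        if cx not in seen:
            seen.add(cx)
            complexes.append(cx)
        if len(complexes) == n_cx:
            break
    if len(complexes) < 2:
        return None

    edges: set[tuple[int, int]] = set()
    if weakly_reversible:
        # build disjoint directed cycles covering the complexes
        idx = list(rng.permutation(len(complexes)))
        while idx and len(edges) < R:
            size = int(rng.integers(2, min(4, len(idx)) + 1)) if len(idx) > 1 else 1
            cycle = idx[:size]
            idx = idx[size:]
            if len(cycle) == 1:
                continue
            for a, b in zip(cycle, cycle[1:] + cycle[:1]):
                edges.add((a, b))
    else:
        for _ in range(R * 3):
            a, b = rng.integers(0, len(complexes), 2)
            if a != b:
                edges.add((int(a), int(b)))
            if len(edges) >= R:
                break
    if not edges:
        return None
    edges = sorted(edges)[:R] if not weakly_reversible else sorted(edges)

    used = sorted({j for e in edges for j in e})
    remap = {old: new for new, old in enumerate(used)}
    complexes = [complexes[j] for j in used]
    edges = [(remap[a], remap[b]) for a, b in edges]
    used_species = sorted({sp for cx in complexes for sp, _ in cx})
    if not used_species:
        return None
    reactions = [Reaction(a, b, f"k{i+1}", "true") for i, (a, b) in enumerate(edges)]
    try:
        return ReactionNetwork(used_species, complexes, reactions)
    except ValueError:
        return None
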