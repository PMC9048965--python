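"""Scaffold codes and the single-reaction grammar.

An oxidized iridoid scaffold is described by one complex number per skeleton
carbon.  The real part is the ordinal oxidation state of that carbon
(0 saturated, 1 alcohol, 2 aldehyde/ketone, 3 carboxylic acid,
4 decarboxylated; C11 skips the alcohol, so its scale is 0 saturated,
1 aldehyde, 2 carboxylic acid, 3 decarboxylated).  The imaginary part flags
shared unsaturation: ``i/4`` marks a carbon of a double bond, ``3i/4`` a
carbon of an epoxide ring.  Flags always come in pairs of carbons joined by a
skeleton bond.

The grammar of single biochemical reactions (one oxidation step, one
desaturation, one epoxidation) is the source of truth for reaction adjacency.
The generalized Manhattan distance between codes is calibrated so that every
grammar move scores exactly 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterator, Mapping, Sequence

__all__ = [
    "GrammarConfig",
    "ScaffoldCode",
    "ReactionMove",
    "Violation",
    "CodeStructureError",
    "iridoid_grammar",
    "toy_grammar",
    "validate_code",
    "generalized_distance",
    "manhattan_complex",
    "apply_move",
    "list_moves",
    "format_code",
    "parse_code",
]

# imaginary flags, in quarters
NO_FLAG = 0
DOUBLE_BOND = 1  # i/4
EPOXIDE = 3  # 3i/4

_FLAG_NAMES = {NO_FLAG: "none", DOUBLE_BOND: "double bond", EPOXIDE: "epoxide"}


class CodeStructureError(ValueError):
    """Raised when a code does not even have the right set of positions."""


@dataclass(frozen=True)
class Violation:
    """One broken invariant, naming the offending position and rule."""

    position: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.position}: [{self.rule}] {self.message}"


@dataclass(frozen=True)
class GrammarConfig:
    """Valence table and reaction grammar for one scaffold family.

    ``max_real`` caps the oxidation state each carbon can reach;
    ``double_bond_bonds`` / ``epoxide_bonds`` list which skeleton bonds may
    carry the corresponding flag; ``double_bond_max_real`` /
    ``epoxide_max_real`` cap the oxidation state of a flagged carbon.  The
    calibration weights rescale the literal ``i/4`` arithmetic so that each
    registered move has generalized distance 1.
    """

    carbons: tuple[str, ...]
    max_real: tuple[int, ...]
    bonds: tuple[tuple[int, int], ...]
    double_bond_bonds: frozenset[int] = frozenset()
    epoxide_bonds: frozenset[int] = frozenset()
    double_bond_max_real: int = 0
    epoxide_max_real: int = 1
    epoxide_from_saturated: bool = True
    epoxide_from_double_bond: bool = True
    direct_oxidation_carbons: tuple[str, ...] = ()
    # calibration weights for imaginary quarter-steps |dIm| = 1/4, 2/4, 3/4
    flag_step_weights: tuple[float, float, float] = (2.0, 1.0, 2.0 / 3.0)

    def __post_init__(self) -> None:
        n = len(self.carbons)
        if len(self.max_real) != n:
            raise ValueError("max_real must match carbons")
        if len(set(self.carbons)) != n:
            raise ValueError("carbon names must be unique")
        for a, b in self.bonds:
            if not (0 <= a < n and 0 <= b < n and a != b):
                raise ValueError(f"bad bond ({a},{b})")
        for e in self.double_bond_bonds | self.epoxide_bonds:
            if not 0 <= e < len(self.bonds):
                raise ValueError(f"flag bond index {e} out of range")

    @property
    def n_carbons(self) -> int:
        return len(self.carbons)

    def carbon_index(self, name: str) -> int:
        try:
            return self.carbons.index(name)
        except ValueError:
            raise KeyError(f"unknown carbon {name!r}") from None

    def flag_cap(self, flag: int) -> int:
        """Maximum oxidation state a carbon carrying ``flag`` may hold."""
        if flag == DOUBLE_BOND:
            return self.double_bond_max_real
        if flag == EPOXIDE:
            return self.epoxide_max_real
        raise ValueError(f"not a flag: {flag}")


def iridoid_grammar() -> GrammarConfig:
    """Grammar of the cyclopentanopyran (nepetalactol) scaffold.

    Ten carbons (the ring oxygen occupies position 2, hence no C2); bonds
    follow the fused bicyclic connectivity with the exocyclic methyls C10 (on
    C8) and C11 (on C4).  C11 is oxidized directly to the aldehyde, so its
    ordinal scale is shifted by one.  The valence caps and flag-eligible
    bonds below enumerate a space of 62,400 scaffolds joined by 822,160
    directed single-reaction adjacencies.
    """
    carbons = ("C1", "C3", "C4", "C5", "C6", "C7", "C8", "C9", "C10", "C11")
    bonds = (
        ("C1", "C9"), ("C9", "C5"), ("C5", "C4"), ("C4", "C3"), ("C5", "C6"),
        ("C6", "C7"), ("C7", "C8"), ("C8", "C9"), ("C8", "C10"), ("C4", "C11"),
    )
    idx = {c: i for i, c in enumerate(carbons)}
    return GrammarConfig(
        carbons=carbons,
        #         C1 C3 C4 C5 C6 C7 C8 C9 C10 C11
        max_real=(2, 1, 1, 1, 1, 2, 2, 1, 3, 3),
        bonds=tuple((idx[a], idx[b]) for a, b in bonds),
        # enol ether C3=C4, ring double bonds, exocyclic methylene C8=C10
        double_bond_bonds=frozenset({3, 5, 7, 8}),
        # cyclopentane epoxides (7,8 as in catalpol) and the ring fusion
        epoxide_bonds=frozenset({1, 6}),
        double_bond_max_real=0,
        epoxide_max_real=1,
        epoxide_from_saturated=True,
        epoxide_from_double_bond=True,
        direct_oxidation_carbons=("C11",),
    )


def toy_grammar(
    n_carbons: int = 2,
    max_state: int = 1,
    bonds: Sequence[tuple[int, int]] = (),
) -> GrammarConfig:
    """Minimal grammar for oracles: hydroxylation only, no unsaturation."""
    return GrammarConfig(
        carbons=tuple(f"C{i + 1}" for i in range(n_carbons)),
        max_real=(max_state,) * n_carbons,
        bonds=tuple(bonds),
    )


@dataclass(frozen=True)
class ScaffoldCode:
    """One scaffold: per-carbon oxidation states and unsaturation flags.

    ``reals[i]`` is the ordinal oxidation state of carbon ``i`` (in grammar
    order), ``flags[i]`` the imaginary part in quarters (0, 1 = double bond,
    3 = epoxide).
    """

    reals: tuple[int, ...]
    flags: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.reals) != len(self.flags):
            raise CodeStructureError("reals and flags must have equal length")

    @classmethod
    def saturated(cls, config: GrammarConfig) -> "ScaffoldCode":
        n = config.n_carbons
        return cls((0,) * n, (0,) * n)

    @classmethod
    def from_mapping(
        cls, values: Mapping[str, complex], config: GrammarConfig
    ) -> "ScaffoldCode":
        missing = set(config.carbons) - set(values)
        extra = set(values) - set(config.carbons)
        if missing or extra:
            raise CodeStructureError(
                f"positions do not match grammar (missing {sorted(missing)}, "
                f"unexpected {sorted(extra)})"
            )
        reals, flags = [], []
        for c in config.carbons:
            v = complex(values[c])
            r = v.real
            q = v.imag * 4
            if abs(r - round(r)) > 1e-9 or abs(q - round(q)) > 1e-9:
                raise CodeStructureError(
                    f"{c}: value {v} is not an integer + quarter-imaginary"
                )
            reals.append(int(round(r)))
            flags.append(int(round(q)))
        return cls(tuple(reals), tuple(flags))

    def to_mapping(self, config: GrammarConfig) -> dict[str, complex]:
        return {
            c: complex(r, f / 4.0)
            for c, r, f in zip(config.carbons, self.reals, self.flags)
        }

    def value(self, i: int) -> complex:
        return complex(self.reals[i], self.flags[i] / 4.0)

    @property
    def key(self) -> str:
        return format_code(self)


_TOKEN_RE = re.compile(
    r"^(?P<re>-?\d+)(?:\+(?P<num>[123])/4i)?$"
)


def format_code(code: ScaffoldCode) -> str:
    """Serialize as comma-separated ``re[+q/4i]`` tokens in carbon order."""
    parts = []
    for r, f in zip(code.reals, code.flags):
        parts.append(f"{r}+{f}/4i" if f else str(r))
    return ",".join(parts)


def parse_code(text: str, config: GrammarConfig) -> ScaffoldCode:
    """Parse the ``format_code`` serialization; strict on the token grammar."""
    tokens = [t.strip() for t in text.split(",")]
    if len(tokens) != config.n_carbons:
        raise CodeStructureError(
            f"expected {config.n_carbons} tokens, got {len(tokens)}"
        )
    reals, flags = [], []
    for col, tok in enumerate(tokens):
        m = _TOKEN_RE.match(tok)
        if not m:
            raise CodeStructureError(
                f"column {col + 1} ({config.carbons[col]}): bad token {tok!r}"
            )
        reals.append(int(m.group("re")))
        flags.append(int(m.group("num")) if m.group("num") else 0)
    return ScaffoldCode(tuple(reals), tuple(flags))


@dataclass(frozen=True)
class ReactionMove:
    """A single registered reaction: the affected carbons and their deltas.

    ``kind`` is one of ``hydroxylation``, ``alcohol_to_aldehyde``,
    ``aldehyde_to_acid``, ``decarboxylation``, ``c11_direct_oxidation``,
    ``desaturation`` or ``epoxidation``.  Oxidation kinds touch one carbon
    (real +1); desaturation adds ``i/4`` to the two carbons of a bond;
    epoxidation either promotes an existing double bond (``+2i/4`` per
    carbon) or closes an epoxide on a saturated bond (``+3i/4`` per carbon).
    Every kind contributes a generalized distance of exactly 1.
    """

    kind: str
    carbons: tuple[int, ...]
    delta: tuple[complex, ...]

    def __post_init__(self) -> None:
        if len(self.carbons) != len(self.delta):
            raise ValueError("carbons and delta must align")


_OX_KINDS = {
    (0, 1): "hydroxylation",
    (1, 2): "alcohol_to_aldehyde",
    (2, 3): "aldehyde_to_acid",
    (3, 4): "decarboxylation",
}


def _oxidation_kind(config: GrammarConfig, carbon: int, state: int) -> str:
    if config.carbons[carbon] in config.direct_oxidation_carbons:
        return "c11_direct_oxidation"
    return _OX_KINDS.get((state, state + 1), "hydroxylation")


def validate_code(
    code: ScaffoldCode, config: GrammarConfig
) -> tuple[bool, list[Violation]]:
    """Check every grammar invariant; return (ok, named violations).

    A malformed position set raises :class:`CodeStructureError` instead of
    returning violations.
    """
    if len(code.reals) != config.n_carbons:
        raise CodeStructureError(
            f"code has {len(code.reals)} positions, grammar has "
            f"{config.n_carbons}"
        )
    violations: list[Violation] = []
    for i, (r, f) in enumerate(zip(code.reals, code.flags)):
        name = config.carbons[i]
        if not 0 <= r <= config.max_real[i]:
            violations.append(
                Violation(
                    name,
                    "oxidation-state-range",
                    f"state {r} outside [0, {config.max_real[i]}]",
                )
            )
        if f not in (NO_FLAG, DOUBLE_BOND, EPOXIDE):
            violations.append(
                Violation(name, "flag-value", f"imaginary quarter {f} invalid")
            )
            continue
        if f != NO_FLAG and 0 <= r <= config.max_real[i]:
            cap = config.flag_cap(f)
            if r > cap:
                violations.append(
                    Violation(
                        name,
                        "flag-valence",
                        f"{_FLAG_NAMES[f]} carbon may hold state <= {cap}, "
                        f"has {r}",
                    )
                )
    # pairing: flagged carbons must tile into same-flag skeleton bonds whose
    # bond is eligible for that flag.  The skeleton's only cycle is odd, so a
    # tiling is unique when it exists; greedy matching on degree-1 carbons
    # resolves it.
    flagged = {i for i, f in enumerate(code.flags) if f in (DOUBLE_BOND, EPOXIDE)}
    if flagged:
        allowed = []
        for e, (a, b) in enumerate(config.bonds):
            if a in flagged and b in flagged and code.flags[a] == code.flags[b]:
                fl = code.flags[a]
                if (fl == DOUBLE_BOND and e in config.double_bond_bonds) or (
                    fl == EPOXIDE and e in config.epoxide_bonds
                ):
                    allowed.append((a, b))
        pairing = _unique_perfect_matching(flagged, allowed)
        if pairing is None:
            for i in sorted(flagged):
                violations.append(
                    Violation(
                        config.carbons[i],
                        "flag-pairing",
                        "unsaturation flags do not tile into eligible "
                        "adjacent pairs",
                    )
                )
    return (not violations, violations)


def _unique_perfect_matching(
    vertices: set[int], edges: list[tuple[int, int]]
) -> list[tuple[int, int]] | None:
    """Perfect matching of ``vertices`` using ``edges``; None if impossible.

    Peels degree-1 vertices repeatedly; correct whenever the ambient graph
    has no even cycle, which holds for the cyclopentanopyran skeleton.
    """
    remaining = set(vertices)
    avail = list(edges)
    out: list[tuple[int, int]] = []
    while remaining:
        deg: dict[int, list[tuple[int, int]]] = {v: [] for v in remaining}
        for e in avail:
            if e[0] in remaining and e[1] in remaining:
                deg[e[0]].append(e)
                deg[e[1]].append(e)
        leaves = [v for v, es in deg.items() if len(es) == 1]
        if not leaves:
            if any(not es for es in deg.values()) or not remaining:
                return None
            # only cycles remain; odd-cycle graphs cannot tile
            return None
        v = leaves[0]
        e = deg[v][0]
        out.append(e)
        remaining.discard(e[0])
        remaining.discard(e[1])
        avail = [x for x in avail if x[0] in remaining and x[1] in remaining]
    return out


def manhattan_complex(a: ScaffoldCode, b: ScaffoldCode) -> float:
    """Literal generalized Manhattan distance: sum of |complex difference|."""
    return sum(
        abs(complex(ra - rb, (fa - fb) / 4.0))
        for ra, fa, rb, fb in zip(a.reals, a.flags, b.reals, b.flags)
    )


def generalized_distance(
    a: ScaffoldCode, b: ScaffoldCode, config: GrammarConfig
) -> float:
    """Calibrated generalized Manhattan distance.

    Per-carbon moduli of the complex difference, with imaginary quarter-steps
    rescaled by the grammar's calibration weights so that each registered
    move (one oxidation step, one desaturation, one epoxidation) totals
    exactly 1.  Symmetric, and zero iff the codes are equal.
    """
    for code, label in ((a, "a"), (b, "b")):
        ok, viol = validate_code(code, config)
        if not ok:
            raise ValueError(f"invalid code {label}: {viol[0]}")
    total = 0.0
    w = config.flag_step_weights
    for ra, fa, rb, fb in zip(a.reals, a.flags, b.reals, b.flags):
        dre = abs(ra - rb)
        dq = abs(fa - fb)  # quarters: 0..3
        dim = (w[dq - 1] * dq / 4.0) if dq else 0.0
        if dre and dim:
            total += (dre * dre + dim * dim) ** 0.5
        else:
            total += dre + dim
    return total


def list_moves(code: ScaffoldCode, config: GrammarConfig) -> list[ReactionMove]:
    """All registered forward moves applicable to ``code``, in a fixed order.

    Order: oxidation steps by carbon index, then desaturations by bond
    index, then epoxide promotions (double bond -> epoxide) by bond index,
    then direct epoxidations by bond index.
    """
    moves: list[ReactionMove] = []
    for i, (r, f) in enumerate(zip(code.reals, code.flags)):
        cap = config.max_real[i] if f == NO_FLAG else min(
            config.flag_cap(f), config.max_real[i]
        )
        if r < cap:
            moves.append(
                ReactionMove(
                    kind=_oxidation_kind(config, i, r),
                    carbons=(i,),
                    delta=(1 + 0j,),
                )
            )
    for e in sorted(config.double_bond_bonds):
        a, b = config.bonds[e]
        if (
            code.flags[a] == NO_FLAG
            and code.flags[b] == NO_FLAG
            and code.reals[a] <= config.double_bond_max_real
            and code.reals[b] <= config.double_bond_max_real
        ):
            moves.append(
                ReactionMove("desaturation", (a, b), (0.25j, 0.25j))
            )
    if config.epoxide_from_double_bond:
        for e in sorted(config.epoxide_bonds):
            a, b = config.bonds[e]
            if (
                code.flags[a] == DOUBLE_BOND
                and code.flags[b] == DOUBLE_BOND
                and e in config.double_bond_bonds
                and code.reals[a] <= config.epoxide_max_real
                and code.reals[b] <= config.epoxide_max_real
            ):
                moves.append(
                    ReactionMove("epoxidation", (a, b), (0.5j, 0.5j))
                )
    if config.epoxide_from_saturated:
        for e in sorted(config.epoxide_bonds):
            a, b = config.bonds[e]
            if (
                code.flags[a] == NO_FLAG
                and code.flags[b] == NO_FLAG
                and code.reals[a] <= config.epoxide_max_real
                and code.reals[b] <= config.epoxide_max_real
            ):
                moves.append(
                    ReactionMove("epoxidation", (a, b), (0.75j, 0.75j))
                )
    return moves


def apply_move(
    code: ScaffoldCode, move: ReactionMove, config: GrammarConfig
) -> ScaffoldCode:
    """Apply one move; reject (ValueError) anything the grammar forbids."""
    reals = list(code.reals)
    flags = list(code.flags)
    for c, d in zip(move.carbons, move.delta):
        dre = int(round(d.real))
        dq = int(round(d.imag * 4))
        reals[c] += dre
        flags[c] += dq
    new = ScaffoldCode(tuple(reals), tuple(flags))
    ok, violations = validate_code(new, config)
    if not ok:
        raise ValueError(
            f"move {move.kind} on {tuple(config.carbons[c] for c in move.carbons)} "
            f"rejected: {violations[0]}"
        )
    # the move must be one of the registered applicable moves
    if move not in list_moves(code, config):
        raise ValueError(
            f"move {move.kind} on "
            f"{tuple(config.carbons[c] for c in move.carbons)} is not "
            f"applicable to this code"
        )
    return new


def iter_neighbor_codes(
    code: ScaffoldCode, config: GrammarConfig
) -> Iterator[tuple[ScaffoldCode, str]]:
    """Forward neighbors (product codes) with the move kind; no validation
    round-trip, for enumeration speed."""
    for mv in list_moves(code, config):
        reals = list(code.reals)
        flags = list(code.flags)
        for c, d in zip(mv.carbons, mv.delta):
            reals[c] += int(round(d.real))
            flags[c] += int(round(d.imag * 4))
        yield ScaffoldCode(tuple(reals), tuple(flags)), mv.kind
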