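"""Enumerate the complete set of elementary flux modes of a metabolic model.

An elementary mode (EM) is a minimal steady-state flux vector: it satisfies
``N_int v = 0`` exactly, runs every irreversible reaction forward, and no
proper subset of its active reactions admits a nonzero steady-state flux.
Enumeration works on the reversible-split network, where the EMs are
exactly the extreme rays of the pointed polyhedral cone
``{v >= 0 : N_int v = 0}``; the double description method builds these rays
by imposing one steady-state equality at a time, using the combinatorial
(zero-set) adjacency test.  All arithmetic is exact rational so that
support minimality is a purely combinatorial property.

``brute_force_modes`` is an independent oracle for small networks: it
checks every candidate support directly against the algebraic
characterisation (rank deficiency one plus strict sign feasibility) and is
used to verify the double description implementation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

from structflux.model_io import (
    MetabolicModel,
    ReversibleSplit,
    split_reversible,
)

__all__ = [
    "ElementaryMode",
    "ModeSet",
    "ModeCountCapError",
    "enumerate_elementary_modes",
    "brute_force_modes",
    "mode_contains",
]

DEFAULT_MODE_CAP = 10_000_000


class ModeCountCapError(RuntimeError):
    """Raised when enumeration would exceed the configured mode-count cap."""


@dataclass(frozen=True)
class ElementaryMode:
    """A minimal steady-state flux vector in canonical scaling.

    ``coefficients`` maps reaction id -> signed exact rational flux; only
    nonzero entries are stored.  Canonical scaling divides by the smallest
    nonzero absolute coefficient, so that value is always 1.  For modes
    using only reversible reactions, the sign is fixed by making the first
    active reaction (in model declaration order) positive.
    """

    coefficients: tuple[tuple[str, Fraction], ...]

    @property
    def support(self) -> frozenset[str]:
        return frozenset(r for r, _ in self.coefficients)

    @property
    def signature(self) -> tuple[str, ...]:
        return tuple(sorted(r for r, _ in self.coefficients))

    def coefficient(self, reaction_id: str) -> Fraction:
        for r, c in self.coefficients:
            if r == reaction_id:
                return c
        return Fraction(0)

    def as_dict(self) -> dict[str, Fraction]:
        return dict(self.coefficients)

    @classmethod
    def from_vector(
        cls, vector: dict[str, Fraction], reaction_order: Sequence[str]
    ) -> "ElementaryMode":
        """Build a mode in canonical scaling from a sparse signed vector."""
        nonzero = {r: c for r, c in vector.items() if c != 0}
        if not nonzero:
            raise ValueError("elementary mode cannot be the zero vector")
        scale = min(abs(c) for c in nonzero.values())
        entries = tuple(
            (r, nonzero[r] / scale) for r in reaction_order if r in nonzero
        )
        return cls(coefficients=entries)


@dataclass
class ModeSet:
    """The complete, deduplicated, deterministically ordered EM collection
    of one model."""

    model: MetabolicModel
    modes: list[ElementaryMode] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.modes)

    def __iter__(self):
        return iter(self.modes)

    def __len__(self) -> int:
        return len(self.modes)

    def signatures(self) -> set[tuple[str, ...]]:
        return {m.signature for m in self.modes}

    # -- serialisation -------------------------------------------------

    def to_tsv(self) -> str:
        """One mode per row, columns = model reactions, rational strings."""
        header = "\t".join(self.model.reaction_ids)
        lines = [header]
        for mode in self.modes:
            coeffs = mode.as_dict()
            lines.append(
                "\t".join(
                    _format_rational(coeffs.get(r, Fraction(0)))
                    for r in self.model.reaction_ids
                )
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, model: MetabolicModel) -> "ModeSet":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            return cls(model=model)
        header = lines[0].split("\t")
        if header != model.reaction_ids:
            raise ValueError("mode table header does not match model reactions")
        modes = []
        for ln in lines[1:]:
            values = [Fraction(tok) for tok in ln.split("\t")]
            vector = {r: v for r, v in zip(header, values) if v != 0}
            modes.append(ElementaryMode.from_vector(vector, model.reaction_ids))
        return cls(model=model, modes=modes)


def _format_rational(value: Fraction) -> str:
    if value.denominator == 1:
        return str(value.numerator)
    return f"{value.numerator}/{value.denominator}"


# ---------------------------------------------------------------------------
# Exact linear algebra on Fraction matrices
# ---------------------------------------------------------------------------


def _rref(rows: list[list[Fraction]]) -> tuple[list[list[Fraction]], list[int]]:
    """Reduced row echelon form; returns (matrix, pivot column indices)."""
    mat = [row[:] for row in rows]
    n_rows = len(mat)
    n_cols = len(mat[0]) if mat else 0
    pivots: list[int] = []
    r = 0
    for c in range(n_cols):
        pivot_row = next((i for i in range(r, n_rows) if mat[i][c] != 0), None)
        if pivot_row is None:
            continue
        mat[r], mat[pivot_row] = mat[pivot_row], mat[r]
        pv = mat[r][c]
        mat[r] = [x / pv for x in mat[r]]
        for i in range(n_rows):
            if i != r and mat[i][c] != 0:
                factor = mat[i][c]
                mat[i] = [a - factor * b for a, b in zip(mat[i], mat[r])]
        pivots.append(c)
        r += 1
        if r == n_rows:
            break
    return mat, pivots


def _nullspace(rows: list[list[Fraction]], n_cols: int) -> list[list[Fraction]]:
    """Exact rational nullspace basis (list of length-n_cols vectors)."""
    if not rows:
        return [
            [Fraction(1) if j == i else Fraction(0) for j in range(n_cols)]
            for i in range(n_cols)
        ]
    mat, pivots = _rref(rows)
    free = [c for c in range(n_cols) if c not in pivots]
    basis = []
    for fc in free:
        vec = [Fraction(0)] * n_cols
        vec[fc] = Fraction(1)
        for r_idx, pc in enumerate(pivots):
            vec[pc] = -mat[r_idx][fc]
        basis.append(vec)
    return basis


# ---------------------------------------------------------------------------
# Double description enumeration
# ---------------------------------------------------------------------------


def _normalise_ray(ray: Sequence[Fraction]) -> tuple[Fraction, ...]:
    scale = min(abs(x) for x in ray if x != 0)
    return tuple(x / scale for x in ray)


def _extreme_rays(
    matrix_rows: list[list[Fraction]], n: int, max_rays: int | None = None
) -> list[tuple[Fraction, ...]]:
    """Extreme rays of the cone {v >= 0 : M v = 0}.

    Starts from the nonnegative orthant (rays = unit vectors) and imposes
    each equality in turn.  Pairs of rays on opposite sides of a
    hyperplane are combined only when adjacent, decided by the zero-set
    test: (p, q) are adjacent iff no third ray's zero set contains
    Z(p) & Z(q).
    """
    rays: list[tuple[Fraction, ...]] = [
        tuple(Fraction(1) if j == i else Fraction(0) for j in range(n))
        for i in range(n)
    ]
    zero = Fraction(0)
    for row in matrix_rows:
        if all(x == 0 for x in row):
            continue
        dots = [sum(r * a for r, a in zip(ray, row) if a != 0) for ray in rays]
        pos = [i for i, d in enumerate(dots) if d > 0]
        neg = [i for i, d in enumerate(dots) if d < 0]
        keep = [rays[i] for i, d in enumerate(dots) if d == 0]
        zero_sets = [frozenset(j for j, x in enumerate(ray) if x == 0) for ray in rays]
        new_rays: list[tuple[Fraction, ...]] = []
        for ip in pos:
            zp = zero_sets[ip]
            for iq in neg:
                meet = zp & zero_sets[iq]
                adjacent = True
                for k, zk in enumerate(zero_sets):
                    if k == ip or k == iq:
                        continue
                    if meet <= zk:
                        adjacent = False
                        break
                if not adjacent:
                    continue
                wp, wq = -dots[iq], dots[ip]  # both positive
                combo = tuple(
                    wp * a + wq * b for a, b in zip(rays[ip], rays[iq])
                )
                new_rays.append(_normalise_ray(combo))
        rays = keep + new_rays
        if max_rays is not None and len(rays) > max_rays:
            raise ModeCountCapError(
                f"intermediate ray count {len(rays)} exceeds cap {max_rays}"
            )
    # dedupe proportional rays (normalised form is canonical)
    seen: set[tuple[Fraction, ...]] = set()
    out: list[tuple[Fraction, ...]] = []
    for ray in rays:
        nr = _normalise_ray(ray)
        if nr not in seen:
            seen.add(nr)
            out.append(nr)
    return out


def _postprocess_split_rays(
    rays: Iterable[Sequence[Fraction]], split: ReversibleSplit
) -> list[ElementaryMode]:
    """Map split-network rays back to signed original-space modes.

    Drops the spurious forward+backward two-cycles created by reversible
    splitting, fixes the sign of reversible-only modes (first active
    reaction positive), and deduplicates.
    """
    expanded_ids = split.expanded.reaction_ids
    order = split.original.reaction_ids
    order_index = {r: i for i, r in enumerate(order)}
    modes: dict[tuple, ElementaryMode] = {}
    for ray in rays:
        sparse = {
            rid: val for rid, val in zip(expanded_ids, ray) if val != 0
        }
        origs = {split.direction[rid][0] for rid in sparse}
        if len(origs) == 1 and len(sparse) == 2:
            continue  # forward+backward 2-cycle of one reversible reaction
        try:
            signed = split.recombine(sparse)
        except ValueError:
            # both directions active: decomposable, not an original-space EM
            continue
        # canonical sign: if the whole mode is reversible in the original
        # model, both +v and -v are valid; pick first active reaction > 0
        if all(split.original.reversible[r] for r in signed):
            first = min(signed, key=lambda r: order_index[r])
            if signed[first] < 0:
                signed = {r: -c for r, c in signed.items()}
        mode = ElementaryMode.from_vector(signed, order)
        modes[mode.coefficients] = mode
    ordered = sorted(
        modes.values(),
        key=lambda m: (
            tuple(sorted(order_index[r] for r in m.support)),
            tuple(m.coefficient(r) for r in order),
        ),
    )
    return ordered


def enumerate_elementary_modes(
    model: MetabolicModel, max_modes: int = DEFAULT_MODE_CAP
) -> ModeSet:
    """Enumerate every elementary mode of ``model`` exactly once.

    Parameters
    ----------
    model:
        A structurally valid metabolic model.
    max_modes:
        Hard cap on the number of rays kept at any stage; exceeding it
        raises :class:`ModeCountCapError` rather than silently truncating.

    Returns
    -------
    ModeSet
        Canonically scaled modes in deterministic (signature-sorted) order.
    """
    model.check_invariants()
    if model.n_reactions == 0:
        return ModeSet(model=model)
    split = split_reversible(model)
    matrix = split.expanded.internal_matrix()
    rays = _extreme_rays(matrix, split.expanded.n_reactions, max_rays=max_modes)
    modes = _postprocess_split_rays(rays, split)
    if len(modes) > max_modes:
        raise ModeCountCapError(f"mode count {len(modes)} exceeds cap {max_modes}")
    return ModeSet(model=model, modes=modes)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

BRUTE_FORCE_MAX_REACTIONS = 14


def brute_force_modes(model: MetabolicModel) -> ModeSet:
    """Definitionally complete EM enumeration by exhaustive support check.

    For every candidate support S of the reversible-split network, S
    carries an elementary mode iff the internal stoichiometric matrix
    restricted to S has a one-dimensional nullspace whose basis vector is
    nonzero on all of S and sign-feasible (all entries of one sign).
    Intended as an independent verification oracle; refuses networks with
    more than 14 reactions after splitting.
    """
    model.check_invariants()
    if model.n_reactions == 0:
        return ModeSet(model=model)
    split = split_reversible(model)
    n = split.expanded.n_reactions
    if n > BRUTE_FORCE_MAX_REACTIONS:
        raise ValueError(
            f"brute-force oracle limited to {BRUTE_FORCE_MAX_REACTIONS} "
            f"reactions after splitting; got {n}"
        )
    matrix = split.expanded.internal_matrix()
    rays: list[list[Fraction]] = []
    for size in range(1, n + 1):
        for subset in itertools.combinations(range(n), size):
            sub = [[row[j] for j in subset] for row in matrix]
            basis = _nullspace(sub, size)
            if len(basis) != 1:
                continue
            vec = basis[0]
            if any(x == 0 for x in vec):
                continue  # actual support smaller; found at its own size
            if all(x > 0 for x in vec):
                signed = vec
            elif all(x < 0 for x in vec):
                signed = [-x for x in vec]
            else:
                continue  # sign-infeasible on the split network
            full = [Fraction(0)] * n
            for j, x in zip(subset, signed):
                full[j] = x
            rays.append(full)
    modes = _postprocess_split_rays(rays, split)
    return ModeSet(model=model, modes=modes)


def mode_contains(
    mode: ElementaryMode, reaction_id: str, model: MetabolicModel
) -> bool:
    """True iff ``reaction_id`` carries nonzero flux in ``mode``."""
    if reaction_id not in model.reversible:
        raise KeyError(f"reaction {reaction_id!r} not declared in the model")
    return reaction_id in mode.support
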