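"""Item pools, block allocation procedures, and questionnaire forms.

A three-form planned missing data design splits the item pool into four
blocks: an X-block administered to every participant and A-, B-, C-blocks
administered to two thirds of participants each.  The three fielded forms are
XAB, XAC, and XBC.  This module provides the allocation procedures that
produce such splits:

* :func:`allocate_ria` — random item allocation: items are assigned to blocks
  uniformly at random subject only to target counts, ignoring scale
  membership.  Appropriate for large scales (roughly 12+ items).
* :func:`allocate_hybrid` — conditional randomization for small scales (5-11
  items) guaranteeing every block at least one item from the scale.
* :func:`allocate_tiny` — deterministic rule for very small scales (<= 4
  items): one item per block, X first.
* :func:`allocate_deterministic` — the classical between-block (spread items
  evenly over A/B/C) and within-block (all items in one block) assignments.
* :func:`build_design` — the full workflow combining the above per scale, with
  forced-X items, singleton handling, and optional X-coverage retries.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import CoverageRetryError, InvalidSpecError

BLOCKS = ("X", "A", "B", "C")
FORM_LABELS = ("XAB", "XAC", "XBC")
#: blocks contained in each form
FORM_BLOCKS = {"XAB": ("X", "A", "B"), "XAC": ("X", "A", "C"), "XBC": ("X", "B", "C")}


@dataclass(frozen=True)
class Scale:
    """A named scale with an ordered list of item identifiers."""

    scale_id: str
    items: tuple[str, ...]

    def __init__(self, scale_id: str, items: Iterable[str]):
        object.__setattr__(self, "scale_id", scale_id)
        object.__setattr__(self, "items", tuple(items))
        if len(set(self.items)) != len(self.items):
            raise InvalidSpecError(f"duplicate items within scale {scale_id!r}")

    @property
    def size(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class ItemPool:
    """All items of a study: scales plus singleton items.

    ``singletons`` holds items that belong to no scale (demographics,
    covariates, auxiliaries, univariate outcomes).  ``forced_x`` names the
    items that must land in the X-block; singletons *not* in ``forced_x`` are
    considered unimportant and are randomized over the A-, B-, and C-blocks
    by :func:`build_design`.
    """

    scales: tuple[Scale, ...]
    singletons: tuple[str, ...] = ()
    forced_x: frozenset[str] = frozenset()

    def __init__(
        self,
        scales: Iterable[Scale],
        singletons: Iterable[str] = (),
        forced_x: Iterable[str] = (),
    ):
        object.__setattr__(self, "scales", tuple(scales))
        object.__setattr__(self, "singletons", tuple(singletons))
        object.__setattr__(self, "forced_x", frozenset(forced_x))
        seen: set[str] = set()
        for sc in self.scales:
            for it in sc.items:
                if it in seen:
                    raise InvalidSpecError(f"item {it!r} appears in more than one scale")
                seen.add(it)
        for it in self.singletons:
            if it in seen:
                raise InvalidSpecError(f"singleton {it!r} also belongs to a scale")
            seen.add(it)
        unknown = self.forced_x - seen
        if unknown:
            raise InvalidSpecError(f"forced_x names unknown items: {sorted(unknown)}")

    @property
    def all_items(self) -> tuple[str, ...]:
        out: list[str] = []
        for sc in self.scales:
            out.extend(sc.items)
        out.extend(self.singletons)
        return tuple(out)

    @property
    def scale_items(self) -> tuple[str, ...]:
        out: list[str] = []
        for sc in self.scales:
            out.extend(sc.items)
        return tuple(out)


@dataclass(frozen=True)
class DesignSpec:
    """Options controlling :func:`build_design`.

    Parameters
    ----------
    p_x
        Target number of large-scale items allocated to the X-block by RIA
        (forced-X items do not count toward this target).
    small_scale_threshold
        Scales with fewer items than this are routed to the hybrid / tiny
        procedures; the rest are pooled through basic RIA.
    method
        Default procedure for large scales (``"ria"``), or a mapping
        ``scale_id -> method`` with per-scale overrides among
        ``{"ria", "hybrid", "between", "within"}``.
    require_x_coverage
        Rerun the pooled RIA draw until every large scale contributes at least
        one item to the X-block.
    """

    p_x: int = 0
    small_scale_threshold: int = 12
    method: str | Mapping[str, str] = "ria"
    require_x_coverage: bool = False
    max_retries: int = 100
    seed: int | None = None

    def __post_init__(self):
        if self.p_x < 0:
            raise InvalidSpecError("p_x must be nonnegative")
        if self.small_scale_threshold < 5:
            raise InvalidSpecError("small_scale_threshold must be at least 5")

    def method_for(self, scale_id: str) -> str | None:
        """Explicit per-scale method override, or None."""
        if isinstance(self.method, Mapping):
            return self.method.get(scale_id)
        return None

    @property
    def default_method(self) -> str:
        return self.method if isinstance(self.method, str) else "ria"


@dataclass
class BlockAllocation:
    """A total mapping of items to blocks, with per-item provenance.

    ``assignment`` preserves the original item order (insertion order), so
    block listings and forms keep the input item ordering.
    """

    assignment: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        bad = {b for b in self.assignment.values()} - set(BLOCKS)
        if bad:
            raise InvalidSpecError(f"unknown blocks in assignment: {sorted(bad)}")

    def items_in(self, block: str) -> tuple[str, ...]:
        return tuple(it for it, b in self.assignment.items() if b == block)

    def block_counts(self) -> dict[str, int]:
        counts = {b: 0 for b in BLOCKS}
        for b in self.assignment.values():
            counts[b] += 1
        return counts

    def merge(self, other: "BlockAllocation") -> "BlockAllocation":
        """Blockwise union of two allocations over disjoint item sets."""
        overlap = set(self.assignment) & set(other.assignment)
        if overlap:
            raise InvalidSpecError(f"allocations overlap on items: {sorted(overlap)}")
        return BlockAllocation(
            assignment={**self.assignment, **other.assignment},
            provenance={**self.provenance, **other.provenance},
        )


@dataclass(frozen=True)
class FormSet:
    """The three questionnaire forms XAB, XAC, XBC as ordered item lists."""

    forms: dict[str, tuple[str, ...]]

    def __post_init__(self):
        if set(self.forms) != set(FORM_LABELS):
            raise InvalidSpecError(f"forms must be exactly {FORM_LABELS}")

    def items(self) -> tuple[str, ...]:
        """All items appearing on any form, first-appearance order."""
        seen: dict[str, None] = {}
        for label in FORM_LABELS:
            for it in self.forms[label]:
                seen.setdefault(it)
        return tuple(seen)

    def __getitem__(self, label: str) -> tuple[str, ...]:
        return self.forms[label]


@dataclass
class ValidationIssue:
    severity: str  # "error" | "warning"
    code: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def codes(self) -> set[str]:
        return {i.code for i in self.issues}


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _child_rng(seed: int, label: str) -> np.random.Generator:
    """Stable per-label child stream so adding a scale does not perturb others."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode("utf-8"))])
    )


def allocate_ria(
    items: Sequence[str],
    counts: Mapping[str, int],
    rng: np.random.Generator | int | None = None,
) -> BlockAllocation:
    """Random item allocation: a uniform partition honoring per-block counts.

    ``counts`` maps block labels (subset of X/A/B/C, missing = 0) to target
    sizes; the counts must be nonnegative and sum to ``len(items)``.
    """
    rng = _as_rng(rng)
    counts_full = {b: int(counts.get(b, 0)) for b in BLOCKS}
    if any(c < 0 for c in counts_full.values()):
        raise InvalidSpecError("block counts must be nonnegative")
    if sum(counts_full.values()) != len(items):
        raise InvalidSpecError(
            f"block counts sum to {sum(counts_full.values())} but there are "
            f"{len(items)} items"
        )
    items = list(items)
    perm = list(rng.permutation(len(items)))
    labels: dict[str, str] = {}
    pos = 0
    for b in BLOCKS:
        for k in perm[pos : pos + counts_full[b]]:
            labels[items[k]] = b
        pos += counts_full[b]
    # preserve the input item order in the assignment mapping
    assignment = {it: labels[it] for it in items}
    return BlockAllocation(assignment, {it: "ria" for it in items})


def allocate_tiny(
    scale: Scale,
    rng: np.random.Generator | int | None = None,
    randomize: bool = False,
) -> BlockAllocation:
    """Deterministic rule for scales of at most four items.

    One item goes to the X-block; the rest fill A, then B, then C, one item
    each, so a four-item scale lands one item in every block and a three-item
    scale leaves C empty.  With ``randomize=True`` the order in which A/B/C
    are filled is shuffled instead (so the empty block is random).
    """
    if scale.size == 0:
        raise InvalidSpecError(f"scale {scale.scale_id!r} has no items")
    if scale.size > 4:
        raise InvalidSpecError(
            f"allocate_tiny requires at most 4 items; scale {scale.scale_id!r} "
            f"has {scale.size} (route to allocate_hybrid or allocate_ria)"
        )
    targets = ["A", "B", "C"]
    if randomize:
        rng = _as_rng(rng)
        targets = [targets[i] for i in rng.permutation(3)]
    assignment = {scale.items[0]: "X"}
    for it, b in zip(scale.items[1:], targets):
        assignment[it] = b
    return BlockAllocation(assignment, {it: "tiny" for it in scale.items})


def allocate_hybrid(
    scale: Scale,
    rng: np.random.Generator | int | None = None,
    upper: int = 11,
) -> BlockAllocation:
    """Conditional randomization for small scales (5 to ``upper`` items).

    Every block — X included — receives at least one item from the scale, and
    the block counts are as even as possible (all four differ by at most one;
    which blocks absorb the surplus is random).  Item-to-block assignment is
    uniform given the counts.
    """
    P = scale.size
    if not 5 <= P <= upper:
        raise InvalidSpecError(
            f"allocate_hybrid requires 5 <= P <= {upper}; scale "
            f"{scale.scale_id!r} has P={P} (route to allocate_tiny or allocate_ria)"
        )
    rng = _as_rng(rng)
    base, extra = divmod(P, 4)
    counts = {b: base for b in BLOCKS}
    for i in rng.choice(4, size=extra, replace=False):
        counts[BLOCKS[i]] += 1
    alloc = allocate_ria(scale.items, counts, rng)
    alloc.provenance = {it: "hybrid" for it in scale.items}
    return alloc


def allocate_deterministic(
    scale: Scale,
    method: str,
    rng: np.random.Generator | int | None = None,
) -> BlockAllocation:
    """Classical between-/within-block assignment over A, B, C.

    ``between`` spreads the scale's items across A, B, C with counts
    differing by at most one (which blocks get the surplus is random);
    ``within`` puts every item into one randomly chosen block.  Neither
    touches the X-block.
    """
    if scale.size == 0:
        raise InvalidSpecError(f"scale {scale.scale_id!r} has no items")
    rng = _as_rng(rng)
    if method == "within":
        blk = ("A", "B", "C")[rng.integers(3)]
        assignment = {it: blk for it in scale.items}
    elif method == "between":
        order = [("A", "B", "C")[i] for i in rng.permutation(3)]
        assignment = {it: order[k % 3] for k, it in enumerate(scale.items)}
    else:
        raise InvalidSpecError(f"method must be 'between' or 'within', got {method!r}")
    return BlockAllocation(assignment, {it: method for it in scale.items})


def _abc_counts(n: int, rng: np.random.Generator) -> dict[str, int]:
    """Split n items over A/B/C; surplus blocks drawn without replacement."""
    base, rem = divmod(n, 3)
    counts = {"A": base, "B": base, "C": base}
    if rem:
        warnings.warn(
            f"{n} items are not evenly divisible by three; form lengths will be "
            "unequal (choose p_x so that P - p_x is divisible by 3 to avoid this)",
            stacklevel=3,
        )
        for i in rng.choice(3, size=rem, replace=False):
            counts[("A", "B", "C")[i]] += 1
    return counts


def build_design(
    pool: ItemPool,
    spec: DesignSpec,
    rng: np.random.Generator | None = None,
) -> BlockAllocation:
    """Full design workflow: forced X, scale routing, pooled RIA, union.

    Steps: (1) forced-X items (demographics, covariates, auxiliaries) go to
    the X-block; (2) scales are classified against ``small_scale_threshold``;
    (3) large scales are pooled and allocated through basic RIA with ``p_x``
    items in X; (4) small scales go through the hybrid (5-11 items) or tiny
    (<= 4 items) procedure; per-scale method overrides can force
    between-/within-block assignment instead; (5) the final blocks are the
    blockwise union; unimportant singletons are randomized over A, B, C.

    With ``require_x_coverage`` the pooled RIA draw is repeated until every
    large scale has at least one item in X (failing with
    :class:`CoverageRetryError` after ``max_retries`` attempts).
    """

    def stream(label: str) -> np.random.Generator:
        if rng is not None:
            return rng
        return _child_rng(spec.seed if spec.seed is not None else 0, label)

    alloc = BlockAllocation()
    # step 1: forced-X items
    for it in pool.all_items:
        if it in pool.forced_x:
            alloc.assignment[it] = "X"
            alloc.provenance[it] = "forced_x"

    # step 2: classify the scales
    pooled_scales: list[Scale] = []
    small_scales: list[Scale] = []
    overridden: list[tuple[Scale, str]] = []
    for sc in pool.scales:
        remaining = tuple(it for it in sc.items if it not in pool.forced_x)
        if not remaining:
            continue
        sub = Scale(sc.scale_id, remaining)
        override = spec.method_for(sc.scale_id)
        if override in ("between", "within"):
            overridden.append((sub, override))
        elif override == "hybrid" and sub.size >= 5:
            small_scales.append(sub)
        elif sub.size >= spec.small_scale_threshold:
            pooled_scales.append(sub)
        else:
            small_scales.append(sub)

    # step 3: pooled RIA over the large scales
    if pooled_scales:
        pooled_items = [it for sc in pooled_scales for it in sc.items]
        if spec.p_x > len(pooled_items):
            raise InvalidSpecError(
                f"p_x={spec.p_x} exceeds the {len(pooled_items)} pooled scale items"
            )
        r = stream("pooled_ria")
        counts = {"X": spec.p_x, **_abc_counts(len(pooled_items) - spec.p_x, r)}
        for attempt in range(max(1, spec.max_retries)):
            ria = allocate_ria(pooled_items, counts, r)
            if not spec.require_x_coverage:
                break
            x_set = {it for it, b in ria.assignment.items() if b == "X"}
            if all(any(it in x_set for it in sc.items) for sc in pooled_scales):
                break
        else:
            raise CoverageRetryError(
                f"no X-block covering every large scale after {spec.max_retries} "
                "RIA draws (increase p_x or max_retries)"
            )
        alloc = alloc.merge(ria)

    # step 4: small scales (hybrid / tiny) and explicit between/within scales
    for sc in small_scales:
        r = stream(f"scale:{sc.scale_id}")
        sub_alloc = (
            allocate_hybrid(sc, r, upper=max(sc.size, spec.small_scale_threshold - 1))
            if sc.size >= 5
            else allocate_tiny(sc, r)
        )
        alloc = alloc.merge(sub_alloc)
    for sc, method in overridden:
        alloc = alloc.merge(allocate_deterministic(sc, method, stream(f"scale:{sc.scale_id}")))

    # unimportant singletons scatter over A, B, C
    loose = [it for it in pool.singletons if it not in pool.forced_x]
    if loose:
        r = stream("singletons")
        for it in loose:
            alloc.assignment[it] = ("A", "B", "C")[r.integers(3)]
            alloc.provenance[it] = "singleton_random"

    # re-order the mapping to the pool's canonical item order
    ordered = {it: alloc.assignment[it] for it in pool.all_items}
    return BlockAllocation(ordered, {it: alloc.provenance[it] for it in pool.all_items})


def build_forms(
    allocation: BlockAllocation,
    shuffle: bool = False,
    rng: np.random.Generator | int | None = None,
) -> FormSet:
    """Combine blocks into the three forms XAB, XAC, XBC.

    Within each form the X-items come first (participants complete the common
    block before the rotating blocks), then the two rotating blocks in label
    order, preserving item order within blocks.  ``shuffle=True`` randomizes
    item order within each form instead.
    """
    by_block = {b: list(allocation.items_in(b)) for b in BLOCKS}
    forms: dict[str, tuple[str, ...]] = {}
    rng = _as_rng(rng) if shuffle else None
    for label in FORM_LABELS:
        items: list[str] = []
        for b in FORM_BLOCKS[label]:
            items.extend(by_block[b])
        if shuffle:
            items = [items[i] for i in rng.permutation(len(items))]
        forms[label] = tuple(items)
    return FormSet(forms)


def validate_allocation(pool: ItemPool, allocation: BlockAllocation) -> ValidationReport:
    """Diagnose an allocation: partition, X coverage, block balance."""
    report = ValidationReport()
    pool_items = set(pool.all_items)
    assigned = set(allocation.assignment)
    missing = pool_items - assigned
    if missing:
        report.issues.append(
            ValidationIssue("error", "unassigned-items", f"items not assigned: {sorted(missing)}")
        )
    extra = assigned - pool_items
    if extra:
        report.issues.append(
            ValidationIssue("error", "unknown-items", f"assigned items not in pool: {sorted(extra)}")
        )
    x_set = {it for it, b in allocation.assignment.items() if b == "X"}
    for sc in pool.scales:
        if not any(it in x_set for it in sc.items):
            report.issues.append(
                ValidationIssue(
                    "warning",
                    "empty-x-scale",
                    f"scale {sc.scale_id!r} has no items in the X-block",
                )
            )
    counts = allocation.block_counts()
    abc = [counts["A"], counts["B"], counts["C"]]
    if max(abc) - min(abc) > 0:
        report.issues.append(
            ValidationIssue(
                "warning",
                "unequal-blocks",
                f"A/B/C block sizes unequal: {dict(zip('ABC', abc))} "
                "(form lengths will differ)",
            )
        )
    n_scale_abc = sum(
        1
        for it in pool.scale_items
        if allocation.assignment.get(it) in ("A", "B", "C")
    )
    if n_scale_abc % 3:
        report.issues.append(
            ValidationIssue(
                "warning",
                "divisibility",
                f"{n_scale_abc} scale items outside X is not divisible by three",
            )
        )
    return report
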