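"""Expression preprocessing: log conversion, ID resolution, concentrations, filtering.

miRNA expression levels enter the binding model as *concentrations*: the
fraction each miRNA contributes to the total expression of a sample.  This
module converts declared-log inputs back to the linear scale, resolves
miRNA IDs against an alias map and a known-ID universe (dropping and
reporting unknowns), normalizes each sample to a concentration vector, and
applies the top-expression filter that focuses the analysis on the most
abundant miRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .io import ExpressionTable, FormatError

__all__ = [
    "ConcentrationVector",
    "FilterPolicy",
    "log_to_linear",
    "resolve_ids",
    "to_concentrations",
    "apply_filter",
    "expand_modes",
]

#: Reason codes attached to dropped miRNAs.
REASON_UNKNOWN_ID = "unknown_id"
REASON_BELOW_COVERAGE = "below_coverage"
REASON_BELOW_MIN_LEVEL = "below_min_level"


@dataclass
class ConcentrationVector:
    """Per-sample miRNA concentrations (fractions of total expression).

    ``concentrations[i]`` is x_i / sum(x) computed before any filtering;
    after :func:`apply_filter` the retained entries keep their original
    fractions unless renormalization was requested, so the vector may sum
    to less than 1.  ``levels`` keeps the linear-scale values for
    min-level thresholding.  Dropped miRNAs are recorded with a reason.
    """

    sample_id: str
    mirna_ids: list[str]
    concentrations: np.ndarray
    levels: np.ndarray
    dropped_ids: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        n = len(self.mirna_ids)
        if self.concentrations.shape != (n,) or self.levels.shape != (n,):
            raise ValueError("concentration/level arrays inconsistent with IDs")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be nonnegative")

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.mirna_ids, self.concentrations.tolist()))


@dataclass(frozen=True)
class FilterPolicy:
    """Top-expression filter configuration.

    ``coverage_percent``: keep the minimal prefix of miRNAs, sorted by
    descending concentration, whose cumulative fraction reaches this
    percentage of the total.  ``min_level`` additionally requires the
    linear expression level to reach a threshold (the two filters
    intersect).  ``always_keep`` miRNAs are exempt from both.  ``mode``
    selects whether the list is analysed as one combined set per sample or
    as independent single miRNAs at concentration 1.
    """

    coverage_percent: float = 100.0
    min_level: float = 0.0
    always_keep: tuple[str, ...] = ()
    mode: str = "set"  # or "single_mirna"
    renormalize: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.coverage_percent <= 100.0:
            raise ValueError("coverage_percent must be in (0, 100]")
        if self.min_level < 0:
            raise ValueError("min_level must be nonnegative")
        if self.mode not in ("set", "single_mirna"):
            raise ValueError(f"unknown mode {self.mode!r}")


def log_to_linear(table: ExpressionTable, base: float = 2.0) -> ExpressionTable:
    """Convert a declared-log expression table to the linear scale (x -> base**x)."""
    if base <= 1:
        raise ValueError("log base must be > 1")
    if not table.is_log_input:
        raise ValueError("table is not declared log-scale")
    return ExpressionTable(
        mirna_ids=list(table.mirna_ids),
        sample_ids=list(table.sample_ids),
        levels=np.power(float(base), table.levels),
        is_log_input=False,
        dropped_ids=list(table.dropped_ids),
    )


def resolve_ids(
    table: ExpressionTable,
    alias_map: Mapping[str, str] | None,
    known_ids: Iterable[str],
) -> ExpressionTable:
    """Rename aliased miRNA IDs and drop IDs outside the known universe.

    Dropped IDs are recorded on the returned table (``dropped_ids`` with
    reason ``unknown_id``) so the caller can notify the user.  An alias
    that collides with an existing row is an error rather than a silent
    merge.
    """
    alias_map = dict(alias_map or {})
    known = set(known_ids)
    renamed = [alias_map.get(mid, mid) for mid in table.mirna_ids]
    dup = {x for x in renamed if renamed.count(x) > 1}
    if dup:
        raise FormatError(f"alias resolution creates duplicate miRNA IDs: {sorted(dup)}")
    keep = [i for i, mid in enumerate(renamed) if mid in known]
    dropped = [
        (renamed[i], REASON_UNKNOWN_ID)
        for i in range(len(renamed))
        if renamed[i] not in known
    ]
    return ExpressionTable(
        mirna_ids=[renamed[i] for i in keep],
        sample_ids=list(table.sample_ids),
        levels=table.levels[keep, :],
        is_log_input=table.is_log_input,
        dropped_ids=list(table.dropped_ids) + dropped,
    )


def to_concentrations(table: ExpressionTable) -> list[ConcentrationVector]:
    """Normalize each sample to fractions of its total expression."""
    if table.is_log_input:
        raise ValueError("convert log-scale input to linear before normalizing")
    vectors = []
    for j, sample in enumerate(table.sample_ids):
        levels = table.levels[:, j]
        total = levels.sum()
        if total <= 0:
            raise ValueError(f"sample {sample!r} has zero total expression")
        vectors.append(
            ConcentrationVector(
                sample_id=sample,
                mirna_ids=list(table.mirna_ids),
                concentrations=levels / total,
                levels=levels.copy(),
                dropped_ids=list(table.dropped_ids),
            )
        )
    return vectors


def apply_filter(vec: ConcentrationVector, policy: FilterPolicy) -> ConcentrationVector:
    """Restrict a concentration vector to the top-expressed miRNAs.

    Retained set = (minimal descending-concentration prefix whose cumulative
    fraction reaches ``coverage_percent``) intersected with (linear level >=
    ``min_level``), united with ``always_keep``.  Retained concentrations are
    the original fractions unless ``policy.renormalize`` is set.  The
    operation is idempotent.  An empty retained set is allowed but the
    dropped list then explains every miRNA.
    """
    n = len(vec.mirna_ids)
    if n == 0:
        return vec
    # Deterministic sort: descending concentration, ties broken by ID.
    order = sorted(range(n), key=lambda i: (-vec.concentrations[i], vec.mirna_ids[i]))
    # Concentrations are fractions of the sample total, so the coverage
    # threshold is absolute; if a pre-filtered vector's remaining mass never
    # reaches it the loop keeps everything, which makes filtering idempotent.
    threshold = policy.coverage_percent / 100.0
    cum = 0.0
    in_coverage: set[int] = set()
    for i in order:
        in_coverage.add(i)
        cum += vec.concentrations[i]
        if cum >= threshold - 1e-12:
            break
    always = set(policy.always_keep)
    keep: list[int] = []
    dropped: list[tuple[str, str]] = []
    for i in range(n):
        mid = vec.mirna_ids[i]
        if mid in always:
            keep.append(i)
        elif i not in in_coverage:
            dropped.append((mid, REASON_BELOW_COVERAGE))
        elif vec.levels[i] < policy.min_level:
            dropped.append((mid, REASON_BELOW_MIN_LEVEL))
        else:
            keep.append(i)
    conc = vec.concentrations[keep]
    if policy.renormalize and conc.sum() > 0:
        conc = conc / conc.sum()
    return ConcentrationVector(
        sample_id=vec.sample_id,
        mirna_ids=[vec.mirna_ids[i] for i in keep],
        concentrations=conc,
        levels=vec.levels[keep],
        dropped_ids=list(vec.dropped_ids) + dropped,
    )


def expand_modes(
    vectors: list[ConcentrationVector], policy: FilterPolicy
) -> list[tuple[str, ConcentrationVector]]:
    """Expand concentration vectors into labeled analysis units.

    ``set`` mode yields one labeled vector per sample (labels are sample
    IDs).  ``single_mirna`` mode yields one vector per miRNA, each holding
    only that miRNA at concentration 1 regardless of the supplied levels,
    so each miRNA's individual contribution can be scored.
    """
    if policy.mode == "set":
        return [(vec.sample_id, vec) for vec in vectors]
    mirna_ids: list[str] = []
    for vec in vectors:
        for mid in vec.mirna_ids:
            if mid not in mirna_ids:
                mirna_ids.append(mid)
    return [
        (
            mid,
            ConcentrationVector(
                sample_id=mid,
                mirna_ids=[mid],
                concentrations=np.array([1.0]),
                levels=np.array([1.0]),
            ),
        )
        for mid in mirna_ids
    ]
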