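"""Per-site scoring: seed-match scanning and duplex-energy estimation.

Two of the four scoring channels can be computed self-contained from
sequence alone:

* the seed channel reports every occurrence on the target of a
  Watson-Crick match to the miRNA seed (nucleotides 2-8 from the 5' end),
  classified into the canonical site taxonomy (6mer, 7mer-A1, 7mer-m8,
  8mer; no conservation information is used) — the per-gene single-target
  score is simply the number of detected sites;
* the energy channel assigns each seed-anchored site an ungapped
  RNA:RNA duplex free energy from a nearest-neighbor stacking model
  (kcal/mol, more negative = stronger binding).

The accessibility-corrected (ΔΔG) and regression-based (mirSVR-type)
channels depend on external models and are import-only: their per-site
scores are supplied as tables (see :func:`comir.io.read_site_scores`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping

from .io import (
    Channel,
    FormatError,
    SiteScore,
    SiteScoreTable,
    TargetSequence,
    canonicalize_sequence,
)

__all__ = [
    "SiteClass",
    "SeedDefinition",
    "EnergyModel",
    "revcomp",
    "scan_seed_sites",
    "duplex_energy",
    "compute_channel_sites",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement in the internal DNA alphabet (N self-complementary)."""
    return seq.translate(_COMP)[::-1]


class SiteClass(IntEnum):
    """Canonical seed-site classes, ordered by increasing strength."""

    SIX_MER = 1
    SEVEN_MER_A1 = 2
    SEVEN_MER_M8 = 3
    EIGHT_MER = 4

    @property
    def label(self) -> str:
        return _CLASS_LABELS[self]


_CLASS_LABELS = {
    SiteClass.SIX_MER: "6mer",
    SiteClass.SEVEN_MER_A1: "7mer_A1",
    SiteClass.SEVEN_MER_M8: "7mer_m8",
    SiteClass.EIGHT_MER: "8mer",
}


@dataclass(frozen=True)
class SeedDefinition:
    """Which site classes the seed scanner reports.

    The seed itself is fixed at miRNA positions 2-8 (1-based from the 5'
    end).  A physical site is reported once, with the strongest accepted
    class it qualifies for, so an 8mer site is still reported (as a 7mer)
    when only 7mer classes are accepted.
    """

    accepted_classes: frozenset[SiteClass] = frozenset(
        {SiteClass.SEVEN_MER_A1, SiteClass.SEVEN_MER_M8, SiteClass.EIGHT_MER}
    )

    def __post_init__(self) -> None:
        if not self.accepted_classes:
            raise ValueError("accepted_classes must be non-empty")


DEFAULT_SEED = SeedDefinition()
ALL_CLASSES_SEED = SeedDefinition(accepted_classes=frozenset(SiteClass))

_WC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")})
_WOBBLE_PAIRS = frozenset({("G", "T"), ("T", "G")})


def _class_interval(s: int, cls: SiteClass) -> tuple[int, int]:
    # s is the start of the 6-nt seed core (pairs miRNA positions 2-7).
    if cls is SiteClass.EIGHT_MER:
        return s - 1, s + 7
    if cls is SiteClass.SEVEN_MER_M8:
        return s - 1, s + 6
    if cls is SiteClass.SEVEN_MER_A1:
        return s, s + 7
    return s, s + 6


def scan_seed_sites(
    target: TargetSequence,
    mirna_id: str,
    mirna_sequence: str,
    seed_def: SeedDefinition = DEFAULT_SEED,
) -> SiteScoreTable:
    """Find all seed-complementary sites of one miRNA on one target.

    Scans for exact Watson-Crick complements of the seed core (miRNA
    positions 2-7), classifies each occurrence by the flanking m8 match and
    the A opposite position 1, and reports overlapping occurrences
    individually.  Windows containing ambiguous bases never match.  Each
    record scores 1.0; the per-gene seed-channel score is the record count.
    """
    mirna = canonicalize_sequence(mirna_sequence, context=f"miRNA {mirna_id!r}")
    if len(mirna) < 8:
        raise ValueError(f"miRNA {mirna_id!r} shorter than 8 nt")
    if "N" in mirna[:8]:
        raise ValueError(f"miRNA {mirna_id!r} has ambiguous bases in its seed")
    core = revcomp(mirna[1:7])  # pairs miRNA positions 2-7
    m8_partner = revcomp(mirna[7])  # target base pairing miRNA position 8
    t = target.sequence
    records: list[SiteScore] = []
    s = t.find(core)
    while s != -1:
        has_m8 = s >= 1 and t[s - 1] == m8_partner
        has_a1 = s + 6 < len(t) and t[s + 6] == "A"
        if has_m8 and has_a1:
            quals = [SiteClass.EIGHT_MER, SiteClass.SEVEN_MER_M8,
                     SiteClass.SEVEN_MER_A1, SiteClass.SIX_MER]
        elif has_m8:
            quals = [SiteClass.SEVEN_MER_M8, SiteClass.SIX_MER]
        elif has_a1:
            quals = [SiteClass.SEVEN_MER_A1, SiteClass.SIX_MER]
        else:
            quals = [SiteClass.SIX_MER]
        cls = next((c for c in quals if c in seed_def.accepted_classes), None)
        if cls is not None:
            start, end = _class_interval(s, cls)
            records.append(
                SiteScore(
                    gene_id=target.gene_id,
                    mirna_id=mirna_id,
                    start=start,
                    end=end,
                    channel=Channel.TARGETSCAN_SEED,
                    score=1.0,
                    site_class=cls.label,
                )
            )
        s = t.find(core, s + 1)
    return SiteScoreTable(channel=Channel.TARGETSCAN_SEED, records=records)


# ---------------------------------------------------------------------------
# Nearest-neighbor duplex energies
# ---------------------------------------------------------------------------

def _build_stack_table(
    wobble_single: float, wobble_double: float
) -> dict[tuple[tuple[str, str], tuple[str, str]], float]:
    """Nearest-neighbor RNA:RNA stacking free energies (kcal/mol, 37 C).

    Watson-Crick values are the standard unified nearest-neighbor set; a
    stack is keyed by its two base pairs read 5'->3' along the miRNA
    strand, ((x1, y1), (x2, y2)) with y_i the target partner of x_i, and
    the table is closed under duplex reversal.  Stacks containing G:U
    wobbles use two coarse class values rather than the full wobble table.
    """
    # 5'x1x2 / 3'y1y2 notation; T stands for U internally.
    wc = {
        ("AA", "TT"): -0.93,
        ("AT", "AT"): -1.10,
        ("TA", "TA"): -1.33,
        ("CT", "AG"): -2.08,
        ("CA", "TG"): -2.11,
        ("GT", "AC"): -2.24,
        ("GA", "TC"): -2.35,
        ("CG", "CG"): -2.36,
        ("GG", "CC"): -3.26,
        ("GC", "GC"): -3.42,
    }
    table: dict[tuple[tuple[str, str], tuple[str, str]], float] = {}

    def put(x1: str, y1: str, x2: str, y2: str, dg: float) -> None:
        table[((x1, y1), (x2, y2))] = dg
        table[((y2, x2), (y1, x1))] = dg  # duplex reversal symmetry

    for (top, bottom), dg in wc.items():
        # top = 5'x1x2 3', bottom = 3'y1y2 5' written 5'->3' => reverse it.
        x1, x2 = top[0], top[1]
        y2, y1 = bottom[0], bottom[1]
        put(x1, y1, x2, y2, dg)
    pairs = list(_WC_PAIRS | _WOBBLE_PAIRS)
    for p1 in pairs:
        for p2 in pairs:
            n_wob = (p1 in _WOBBLE_PAIRS) + (p2 in _WOBBLE_PAIRS)
            if n_wob == 1:
                put(p1[0], p1[1], p2[0], p2[1], wobble_single)
            elif n_wob == 2:
                put(p1[0], p1[1], p2[0], p2[1], wobble_double)
    return table


@dataclass(frozen=True)
class EnergyModel:
    """Ungapped nearest-neighbor duplex-energy model.

    ``initiation`` is the duplex initiation penalty (kcal/mol, positive);
    ``wobble_single``/``wobble_double`` are the stack values used when one
    or both pairs of a stack are G:U wobbles.  ``stacks`` is derived and
    symmetric under duplex reversal.
    """

    initiation: float = 4.09
    wobble_single: float = -1.3
    wobble_double: float = -0.5
    stacks: Mapping[tuple[tuple[str, str], tuple[str, str]], float] = field(
        default=None, compare=False
    )

    def __post_init__(self) -> None:
        table = _build_stack_table(self.wobble_single, self.wobble_double)
        for v in table.values():
            if not (v == v and abs(v) < 1e6):  # finite
                raise ValueError("non-finite stack parameter")
        object.__setattr__(self, "stacks", table)

    @staticmethod
    def is_paired(x: str, y: str) -> bool:
        return (x, y) in _WC_PAIRS or (x, y) in _WOBBLE_PAIRS


DEFAULT_ENERGY_MODEL = EnergyModel()


def duplex_energy(
    target_window: str,
    mirna_sequence: str,
    model: EnergyModel = DEFAULT_ENERGY_MODEL,
) -> float:
    """Free energy (kcal/mol) of the ungapped duplex of a miRNA on a window.

    The miRNA 5' end is anchored at the 3' end of the window (antiparallel:
    miRNA position p pairs window base ``len(window) - p``), and the energy
    is the initiation penalty plus the sum of nearest-neighbor stack terms
    over consecutive paired positions (Watson-Crick or G:U).  Deterministic;
    more negative means stronger predicted binding.
    """
    window = canonicalize_sequence(target_window, context="target window")
    mirna = canonicalize_sequence(mirna_sequence, context="miRNA")
    if len(window) < 6:
        raise ValueError("target window shorter than 6 nt")
    n = min(len(mirna), len(window))
    paired = [
        model.is_paired(mirna[i], window[len(window) - 1 - i]) for i in range(n)
    ]
    energy = model.initiation
    for i in range(n - 1):
        if paired[i] and paired[i + 1]:
            key = (
                (mirna[i], window[len(window) - 1 - i]),
                (mirna[i + 1], window[len(window) - 2 - i]),
            )
            energy += model.stacks[key]
    return energy


def _energy_sites(
    target: TargetSequence,
    mirna_id: str,
    mirna_sequence: str,
    model: EnergyModel,
) -> list[SiteScore]:
    """Seed-anchored duplex-energy sites for one miRNA on one target.

    Candidate sites are all seed matches (any class); each is extended to
    the full ungapped duplex and scored; only sites with negative free
    energy are emitted.
    """
    mirna = canonicalize_sequence(mirna_sequence, context=f"miRNA {mirna_id!r}")
    seeds = scan_seed_sites(target, mirna_id, mirna, seed_def=ALL_CLASSES_SEED)
    t = target.sequence
    out: list[SiteScore] = []
    for seed_site in seeds.records:
        # Recover the seed-core start from the reported class interval.
        cls = seed_site.site_class
        s = seed_site.start + 1 if cls in ("8mer", "7mer_m8") else seed_site.start
        # miRNA position p pairs target index s + 7 - p  (p = 1 .. len).
        lo = max(0, s + 7 - len(mirna))
        window = t[lo : s + 7]
        energy = duplex_energy(window, mirna, model)
        if energy < 0:
            out.append(
                SiteScore(
                    gene_id=target.gene_id,
                    mirna_id=mirna_id,
                    start=lo,
                    end=s + 7,
                    channel=Channel.MIRANDA_ENERGY,
                    score=energy,
                    site_class="energy_site",
                )
            )
    return out


def compute_channel_sites(
    targets: Iterable[TargetSequence],
    mirnas: Mapping[str, str],
    channel: Channel | str,
    imported: SiteScoreTable | None = None,
    *,
    seed_def: SeedDefinition = DEFAULT_SEED,
    energy_model: EnergyModel = DEFAULT_ENERGY_MODEL,
) -> SiteScoreTable:
    """Build the unified per-site table for one channel.

    The seed and energy channels are computed from sequence by the built-in
    scanners unless an imported table is supplied (imported tables always
    take precedence); the ΔΔG and mirSVR-type channels require an imported
    table.  Imported tables are validated against the supplied sequences.
    """
    channel = Channel(channel)
    targets = list(targets)
    if imported is not None:
        if imported.channel != channel:
            raise ValueError(
                f"imported table channel {imported.channel} != requested {channel}"
            )
        imported.validate_against(targets)
        return imported
    if channel is Channel.TARGETSCAN_SEED:
        records: list[SiteScore] = []
        for target in targets:
            for mirna_id, seq in mirnas.items():
                records.extend(
                    scan_seed_sites(target, mirna_id, seq, seed_def).records
                )
        return SiteScoreTable(channel=channel, records=records)
    if channel is Channel.MIRANDA_ENERGY:
        records = []
        for target in targets:
            for mirna_id, seq in mirnas.items():
                records.extend(_energy_sites(target, mirna_id, seq, energy_model))
        return SiteScoreTable(channel=channel, records=records)
    raise FormatError(
        f"channel {channel.value} has no built-in scanner; import a per-site "
        f"score table (gene_id, mirna_id, start, end, score TSV)"
    )
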