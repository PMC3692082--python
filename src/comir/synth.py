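"""Synthetic fixture generation: sequences, expression, imported scores, labels.

The generator builds a fully self-contained study: random-background
3'UTR-like target sequences in which "target-class" genes carry planted
exact 8mer seed-complement sites for the most highly expressed miRNAs,
while "decoy" genes contain sites only at the chance background rate; a
power-law miRNA expression table over multiple samples; per-site score
tables for the two import-only channels (accessibility-corrected ΔΔG and
mirSVR-type scores) whose values track the planted site strengths plus
Gaussian noise; and target/non-target labels for SVM training.  Outputs
are byte-identical for a fixed seed.

The generated data emulates combinatorial, expression-dependent targeting
signal; it does not attempt realistic 3'UTR base composition, site
conservation, or the noise structure of immunoprecipitation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    Channel,
    ExpressionTable,
    SiteScore,
    SiteScoreTable,
    TargetSequence,
    write_fasta,
    write_site_scores,
)
from .sites import revcomp

__all__ = [
    "FixtureSpec",
    "PlantedSite",
    "FixtureBundle",
    "generate_fixture",
    "fixture_snp_pair",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study.

    Defaults describe the standard test condition: 200 genes (half
    targets, half decoys), 20 miRNAs with power-law expression over 2
    samples, 2-4 planted 8mer sites per target gene drawn from the 5 most
    expressed miRNAs.
    """

    n_genes: int = 200
    n_mirnas: int = 20
    n_samples: int = 2
    utr_length: tuple[int, int] = (300, 800)
    mirna_length: int = 22
    target_fraction: float = 0.5
    planted_sites: tuple[int, int] = (2, 4)  # inclusive range per target gene
    n_planted_mirnas: int = 5  # planted miRNAs come from the top expressed
    decoy_site_rate: float = 0.3  # mean imported-channel background sites/gene
    expression_exponent: float = 1.0  # power-law slope of miRNA abundances
    sample_jitter_sd: float = 0.25  # log-normal between-sample variation
    pita_noise_sd: float = 1.0  # kcal/mol noise on synthetic ΔΔG
    mirsvr_noise_sd: float = 0.05
    gc_content: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.utr_length[0] < 8:
            raise ValueError("UTRs must be at least one seed site (8 nt) long")
        if not 0 < self.target_fraction < 1:
            raise ValueError("target_fraction must be in (0, 1) so both classes exist")
        if self.planted_sites[0] < 1 or self.planted_sites[1] < self.planted_sites[0]:
            raise ValueError("planted_sites must be a nonempty positive range")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")

    @property
    def n_targets(self) -> int:
        return max(1, round(self.n_genes * self.target_fraction))


@dataclass(frozen=True)
class PlantedSite:
    gene_id: str
    mirna_id: str
    start: int
    end: int  # start + 8, 0-based half-open
    strength: float


@dataclass
class FixtureBundle:
    """Everything one synthetic study produces."""

    spec: FixtureSpec
    targets: list[TargetSequence]
    mirna_sequences: dict[str, str]
    expression: ExpressionTable
    pita_sites: SiteScoreTable
    mirsvr_sites: SiteScoreTable
    labels: pd.Series  # gene_id -> 1 (target class) / 0 (decoy)
    planted: list[PlantedSite] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return [t.gene_id for t in self.targets]

    def planted_for(self, gene_id: str) -> list[PlantedSite]:
        return [p for p in self.planted if p.gene_id == gene_id]

    def core_position(self, gene_id: str) -> int:
        """A position inside the seed core of the gene's first planted site."""
        sites = self.planted_for(gene_id)
        if not sites:
            raise ValueError(f"gene {gene_id!r} has no planted sites")
        return sites[0].start + 3

    def snp_pair(self, gene_id: str, position: int) -> tuple[TargetSequence, TargetSequence]:
        """Wild-type / variant pair differing by one planted-site substitution.

        The variant carries a single base change at ``position`` chosen to
        break the planted miRNA:target complementarity at that position;
        the position must fall inside a planted site of the gene.
        """
        target = next((t for t in self.targets if t.gene_id == gene_id), None)
        if target is None:
            raise KeyError(f"unknown gene {gene_id!r}")
        site = next(
            (p for p in self.planted_for(gene_id) if p.start <= position < p.end),
            None,
        )
        if site is None:
            raise ValueError(
                f"position {position} lies outside every planted site of {gene_id!r}"
            )
        mirna = self.mirna_sequences[site.mirna_id]
        offset = position - site.start
        if offset == 7:  # the A anchored opposite miRNA position 1
            new_base = "C"
        else:
            # target index start+k pairs miRNA base m[7-k]; substituting the
            # target base with the miRNA base itself can never pair (no
            # Watson-Crick or wobble pair is a self-pair).
            new_base = mirna[7 - offset]
            if new_base == target.sequence[position]:  # defensive; cannot pair anyway
                new_base = next(b for b in "ACGT" if b != target.sequence[position])
        seq = target.sequence
        variant = seq[:position] + new_base + seq[position + 1 :]
        wt = TargetSequence(f"{gene_id}_wt", seq, source="custom")
        var = TargetSequence(f"{gene_id}_variant", variant, source="custom")
        return wt, var

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write the bundle as plain-text files; returns the path map."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "targets": directory / "targets.fasta",
            "mirnas": directory / "mirnas.fasta",
            "expression": directory / "expression.csv",
            "pita": directory / "pita_sites.tsv",
            "mirsvr": directory / "mirsvr_sites.tsv",
            "labels": directory / "labels.csv",
        }
        write_fasta(self.targets, paths["targets"])
        write_fasta(
            [TargetSequence(mid, seq, source="custom")
             for mid, seq in self.mirna_sequences.items()],
            paths["mirnas"],
        )
        self.expression.to_frame().to_csv(paths["expression"], index_label="mirna_id")
        write_site_scores(self.pita_sites, paths["pita"])
        write_site_scores(self.mirsvr_sites, paths["mirsvr"])
        self.labels.rename("is_target").to_csv(paths["labels"], index_label="gene_id")
        return paths


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=probs))


def _random_mirnas(rng: np.random.Generator, spec: FixtureSpec) -> dict[str, str]:
    """Random mature miRNA sequences with mutually distinct seed cores."""
    out: dict[str, str] = {}
    cores: set[str] = set()
    width = len(str(spec.n_mirnas))
    while len(out) < spec.n_mirnas:
        seq = _random_sequence(rng, spec.mirna_length, spec.gc_content)
        core = seq[1:7]
        if core in cores:
            continue
        cores.add(core)
        out[f"mir-{len(out) + 1:0{width}d}"] = seq
    return out


def generate_fixture(spec: FixtureSpec = FixtureSpec()) -> FixtureBundle:
    """Build one synthetic study bundle, deterministically from the spec seed."""
    rng = np.random.default_rng(spec.seed)
    mirnas = _random_mirnas(rng, spec)
    mirna_ids = list(mirnas)

    # Power-law abundances with per-sample multiplicative jitter.
    base = 1000.0 * (np.arange(1, spec.n_mirnas + 1) ** -spec.expression_exponent)
    jitter = rng.lognormal(
        mean=0.0, sigma=spec.sample_jitter_sd, size=(spec.n_mirnas, spec.n_samples)
    )
    expression = ExpressionTable(
        mirna_ids=mirna_ids,
        sample_ids=[f"sample_{j + 1}" for j in range(spec.n_samples)],
        levels=base[:, None] * jitter,
    )
    planted_pool = mirna_ids[: spec.n_planted_mirnas]

    gene_width = len(str(spec.n_genes))
    targets: list[TargetSequence] = []
    planted: list[PlantedSite] = []
    labels = {}
    pita_records: list[SiteScore] = []
    mirsvr_records: list[SiteScore] = []

    for g in range(spec.n_genes):
        gene_id = f"gene_{g + 1:0{gene_width}d}"
        is_target = g < spec.n_targets
        labels[gene_id] = int(is_target)
        length = int(rng.integers(spec.utr_length[0], spec.utr_length[1] + 1))
        seq = list(_random_sequence(rng, length, spec.gc_content))

        if is_target:
            n_sites = int(
                rng.integers(spec.planted_sites[0], spec.planted_sites[1] + 1)
            )
            occupied: list[tuple[int, int]] = []
            for _ in range(n_sites):
                mirna_id = planted_pool[int(rng.integers(len(planted_pool)))]
                site = revcomp(mirnas[mirna_id][1:8]) + "A"  # exact 8mer site
                for _attempt in range(50):
                    start = int(rng.integers(0, length - 8 + 1))
                    if all(start + 8 <= a or start >= b for a, b in occupied):
                        break
                else:
                    continue
                occupied.append((start, start + 8))
                seq[start : start + 8] = list(site)
                strength = float(rng.uniform(1.0, 3.0))
                planted.append(
                    PlantedSite(gene_id, mirna_id, start, start + 8, strength)
                )
                pita_records.append(
                    SiteScore(
                        gene_id, mirna_id, start, start + 8, Channel.PITA_DDG,
                        min(
                            -0.1,
                            -(6.0 + 3.0 * strength)
                            + rng.normal(0.0, spec.pita_noise_sd),
                        ),
                    )
                )
                mirsvr_records.append(
                    SiteScore(
                        gene_id, mirna_id, start, start + 8, Channel.MIRSVR,
                        min(
                            -0.001,
                            -(0.1 + 0.12 * strength)
                            + rng.normal(0.0, spec.mirsvr_noise_sd),
                        ),
                    )
                )
        # Weak background sites on the imported channels, for every gene.
        for _ in range(rng.poisson(spec.decoy_site_rate)):
            start = int(rng.integers(0, length - 8 + 1))
            mirna_id = mirna_ids[int(rng.integers(spec.n_mirnas))]
            pita_records.append(
                SiteScore(
                    gene_id, mirna_id, start, start + 8, Channel.PITA_DDG,
                    -float(rng.uniform(0.3, 2.0)),
                )
            )
            mirsvr_records.append(
                SiteScore(
                    gene_id, mirna_id, start, start + 8, Channel.MIRSVR,
                    -float(rng.uniform(0.005, 0.05)),
                )
            )
        targets.append(TargetSequence(gene_id, "".join(seq)))

    return FixtureBundle(
        spec=spec,
        targets=targets,
        mirna_sequences=mirnas,
        expression=expression,
        pita_sites=SiteScoreTable(Channel.PITA_DDG, pita_records),
        mirsvr_sites=SiteScoreTable(Channel.MIRSVR, mirsvr_records),
        labels=pd.Series(labels, name="is_target"),
        planted=planted,
    )


def fixture_snp_pair(
    spec: FixtureSpec, gene_id: str, position: int
) -> tuple[TargetSequence, TargetSequence]:
    """Wild-type / variant custom-sequence pair for the SNP workflow.

    Generates the fixture for ``spec`` and substitutes one base at
    ``position`` (which must lie inside a planted site of ``gene_id``) so
    that the planted seed match is destroyed; everything else is identical.
    """
    return generate_fixture(spec).snp_pair(gene_id, position)
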