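"""Expression-aware combination of per-site scores into per-gene channel scores.

The binding model treats each predicted site as an independent binding
reaction whose occupancy follows Fermi-Dirac statistics: a site of energy
E on a miRNA present at concentration c is occupied with probability

    p = 1 / (1 + exp((E - mu) / kT)),      mu = mu0 + kT * ln(c),

so higher miRNA concentration raises the chemical potential mu and with it
the occupancy, and lower (more negative) site energy does the same.  The
per-gene score of an energy channel is the expected number of occupied
sites: the sum of p over all sites of all miRNAs in the set.  The count
and regression channels use a simpler concentration-weighted sum,
S_k = sum_i c_i * s_ik, with s_ik the per-(miRNA, gene) single-target
score (site count, or summed per-site scores).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .expression import ConcentrationVector
from .io import Channel, ENERGY_CHANNELS, SiteScoreTable, WEIGHTED_SUM_CHANNELS

__all__ = [
    "FermiDiracParams",
    "ChannelScoreMatrix",
    "fermi_dirac_probability",
    "combine_fermi_dirac",
    "per_gene_mirna_scores",
    "combine_weighted_sum",
    "build_channel_matrix",
]


@dataclass(frozen=True)
class FermiDiracParams:
    """Parameters of the Fermi-Dirac occupancy model.

    kT is the thermal scale in kcal/mol (default RT at 25 C); mu0 offsets
    the chemical potential; epsilon floors concentrations so mu stays
    finite for absent miRNAs.  Defaults are calibration choices exposed in
    configuration, not measured constants.
    """

    kT: float = 0.593
    mu0: float = 0.0
    epsilon: float = 1e-9

    def __post_init__(self) -> None:
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must be in (0, 1)")

    def mu(self, concentration: float) -> float:
        return self.mu0 + self.kT * math.log(max(concentration, self.epsilon))


def fermi_dirac_probability(
    energy: float,
    concentration: float,
    params: FermiDiracParams = FermiDiracParams(),
) -> float:
    """Occupancy probability of one site: 1 / (1 + exp((E - mu(c)) / kT)).

    Strictly decreasing in the energy and strictly increasing in the
    concentration; saturates to 0/1 without overflow.
    """
    x = (energy - params.mu(concentration)) / params.kT
    return float(expit(-x))


def combine_fermi_dirac(
    sites: SiteScoreTable,
    vec: ConcentrationVector,
    params: FermiDiracParams = FermiDiracParams(),
    gene_ids: list[str] | None = None,
) -> pd.Series:
    """Per-gene Fermi-Dirac channel score: sum of site occupancies.

    S_k = sum over miRNAs i and their sites j on gene k of
    p(E_ijk, c_i).  Genes without sites score exactly 0.  Sites whose
    miRNA is absent from the concentration vector (filtered upstream)
    contribute nothing; their count is reported in the result's
    ``attrs["n_ignored_sites"]``.
    """
    if sites.channel not in ENERGY_CHANNELS:
        raise ValueError(
            f"channel {sites.channel.value} is not an energy channel"
        )
    conc = vec.as_mapping()
    totals: dict[str, float] = {}
    n_ignored = 0
    for rec in sites.records:
        c = conc.get(rec.mirna_id)
        if c is None:
            n_ignored += 1
            continue
        totals[rec.gene_id] = totals.get(rec.gene_id, 0.0) + fermi_dirac_probability(
            rec.score, c, params
        )
    index = gene_ids if gene_ids is not None else sorted(totals)
    out = pd.Series([totals.get(g, 0.0) for g in index], index=index, dtype=float)
    out.attrs["n_ignored_sites"] = n_ignored
    return out


def per_gene_mirna_scores(
    sites: SiteScoreTable, *, mode: str
) -> pd.DataFrame:
    """Collapse a site table to the s_ik matrix (genes x miRNAs).

    ``mode="count"`` gives the number of sites per pair (seed channel);
    ``mode="sum"`` gives the summed per-site scores (mirSVR-type channel).
    """
    if mode not in ("count", "sum"):
        raise ValueError(f"unknown mode {mode!r}")
    cells: dict[tuple[str, str], float] = {}
    for rec in sites.records:
        key = (rec.gene_id, rec.mirna_id)
        cells[key] = cells.get(key, 0.0) + (1.0 if mode == "count" else rec.score)
    if not cells:
        return pd.DataFrame(dtype=float)
    frame = pd.Series(cells).unstack(fill_value=0.0)
    frame.index.name = "gene_id"
    return frame


def combine_weighted_sum(
    scores_ik: pd.DataFrame,
    vec: ConcentrationVector,
    gene_ids: list[str] | None = None,
) -> pd.Series:
    """Concentration-weighted sum S_k = sum_i c_i * s_ik.

    ``scores_ik`` is the genes x miRNAs matrix from
    :func:`per_gene_mirna_scores`; miRNAs absent from the vector get
    weight 0 (they were filtered out upstream).
    """
    conc = vec.as_mapping()
    if scores_ik.empty:
        out = pd.Series(0.0, index=gene_ids if gene_ids is not None else [])
    else:
        weights = np.array([conc.get(m, 0.0) for m in scores_ik.columns])
        out = pd.Series(scores_ik.to_numpy() @ weights, index=scores_ik.index)
        if gene_ids is not None:
            out = out.reindex(gene_ids, fill_value=0.0)
    return out.astype(float)


@dataclass
class ChannelScoreMatrix:
    """Genes x (label, channel) matrix of expression-combined scores.

    One column block per labeled concentration vector (a sample in set
    mode, a miRNA in single-miRNA mode); ``channels`` records which of the
    four channels are actually present — absent channels are not silently
    zero-filled.
    """

    scores: pd.DataFrame  # columns: MultiIndex (label, channel value)
    channels: tuple[Channel, ...]
    labels: tuple[str, ...]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.scores.index)

    def block(self, label: str) -> pd.DataFrame:
        """Genes x channels score block for one label."""
        if label not in self.labels:
            raise KeyError(f"unknown label {label!r}")
        return self.scores[label]


def build_channel_matrix(
    channel_tables: dict[Channel, SiteScoreTable],
    labeled_vectors: list[tuple[str, ConcentrationVector]],
    gene_ids: list[str],
    params: FermiDiracParams = FermiDiracParams(),
) -> ChannelScoreMatrix:
    """Combine every available channel for every labeled vector.

    Energy channels go through the Fermi-Dirac combiner, count/score
    channels through the weighted sum.  At least one channel must be
    present.
    """
    if not channel_tables:
        raise ValueError("at least one scoring channel is required")
    channels = tuple(Channel(c) for c in channel_tables)
    cached_sik = {
        ch: per_gene_mirna_scores(
            tbl, mode="count" if ch is Channel.TARGETSCAN_SEED else "sum"
        )
        for ch, tbl in channel_tables.items()
        if ch in WEIGHTED_SUM_CHANNELS
    }
    columns: dict[tuple[str, str], pd.Series] = {}
    for label, vec in labeled_vectors:
        for ch, tbl in channel_tables.items():
            if ch in ENERGY_CHANNELS:
                col = combine_fermi_dirac(tbl, vec, params, gene_ids=gene_ids)
            else:
                col = combine_weighted_sum(cached_sik[ch], vec, gene_ids=gene_ids)
            columns[(label, ch.value)] = col
    frame = pd.DataFrame(columns)
    frame.index = pd.Index(gene_ids, name="gene_id")
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["label", "channel"])
    return ChannelScoreMatrix(
        scores=frame,
        channels=channels,
        labels=tuple(label for label, _ in labeled_vectors),
    )
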