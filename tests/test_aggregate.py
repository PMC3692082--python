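import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comir.aggregate import (
    ChannelScoreMatrix,
    FermiDiracParams,
    build_channel_matrix,
    combine_fermi_dirac,
    combine_weighted_sum,
    fermi_dirac_probability,
    per_gene_mirna_scores,
)
from comir.expression import ConcentrationVector
from comir.io import Channel, SiteScore, SiteScoreTable


def make_vec(conc, sample="s"):
    ids = list(conc)
    c = np.array([conc[i] for i in ids])
    return ConcentrationVector(sample, ids, c, c * 100)


def random_energy_table(rng, n_genes, n_mirnas, channel=Channel.MIRANDA_ENERGY):
    records = []
    for _ in range(int(rng.integers(1, 4 * n_genes))):
        g = f"g{rng.integers(n_genes)}"
        m = f"m{rng.integers(n_mirnas)}"
        start = int(rng.integers(0, 500))
        records.append(
            SiteScore(g, m, start, start + 8, channel, float(rng.uniform(-25, -0.5)))
        )
    return SiteScoreTable(channel, records)


def naive_fd_combine(records, conc, params):
    """Independent per-site double loop using math.* only."""
    out = {}
    for rec in records:
        if rec.mirna_id not in conc:
            continue
        mu = params.mu0 + params.kT * math.log(max(conc[rec.mirna_id], params.epsilon))
        p = 1.0 / (1.0 + math.exp((rec.score - mu) / params.kT))
        out[rec.gene_id] = out.get(rec.gene_id, 0.0) + p
    return out


class TestFermiDiracProbability:
    def test_half_at_chemical_potential(self):
        params = FermiDiracParams(kT=0.593, mu0=-3.0)
        mu = params.mu(0.2)
        assert fermi_dirac_probability(mu, 0.2, params) == pytest.approx(0.5, abs=1e-15)

    def test_closed_form_quarter(self):
        params = FermiDiracParams(kT=1.0, mu0=0.0)
        # mu = 0 at concentration 1; E = ln 3 gives 1/(1+3)
        assert fermi_dirac_probability(math.log(3.0), 1.0, params) == pytest.approx(
            0.25, abs=1e-12
        )

    def test_saturation_limits_without_overflow(self):
        params = FermiDiracParams(kT=0.593, mu0=0.0)
        assert fermi_dirac_probability(-50.0, 1.0, params) == pytest.approx(1.0, abs=1e-12)
        assert fermi_dirac_probability(500.0, 1.0, params) == 0.0
        assert fermi_dirac_probability(-5000.0, 1.0, params) == 1.0

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        e1=st.floats(-30, 10),
        de=st.floats(0.01, 10),
        c=st.floats(1e-6, 1.0),
        dc=st.floats(0.01, 1.0),
    )
    def test_monotone_in_energy_and_concentration(self, e1, de, c, dc):
        params = FermiDiracParams()
        assert fermi_dirac_probability(e1 + de, c, params) < fermi_dirac_probability(
            e1, c, params
        )
        assert fermi_dirac_probability(e1, min(c + dc, 1.0) , params) >= \
            fermi_dirac_probability(e1, c, params)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            FermiDiracParams(kT=0.0)
        with pytest.raises(ValueError):
            FermiDiracParams(epsilon=0.0)


class TestCombineFermiDirac:
    def test_gene_without_sites_scores_zero(self):
        table = SiteScoreTable(Channel.MIRANDA_ENERGY, [])
        s = combine_fermi_dirac(table, make_vec({"m0": 1.0}), gene_ids=["g0", "g1"])
        assert s.tolist() == [0.0, 0.0]

    def test_additive_in_sites(self):
        params = FermiDiracParams(kT=1.0, mu0=0.0)
        recs = [
            SiteScore("g", "m", 10 * i, 10 * i + 8, Channel.MIRANDA_ENERGY, 0.0)
            for i in range(3)
        ]
        s = combine_fermi_dirac(
            SiteScoreTable(Channel.MIRANDA_ENERGY, recs), make_vec({"m": 1.0}), params
        )
        assert s["g"] == pytest.approx(1.5, abs=1e-12)  # three sites at p = 0.5

    def test_matches_double_loop_oracle_on_random_fixtures(self, rng):
        params = FermiDiracParams()
        for _ in range(100):
            n_genes = int(rng.integers(1, 51))
            n_mirnas = int(rng.integers(1, 11))
            table = random_energy_table(rng, n_genes, n_mirnas)
            raw = rng.uniform(0.01, 1.0, n_mirnas)
            conc = {f"m{i}": v for i, v in enumerate(raw / raw.sum())}
            got = combine_fermi_dirac(table, make_vec(conc), params)
            expected = naive_fd_combine(table.records, conc, params)
            assert set(got.index) == set(expected)
            for g in expected:
                assert got[g] == pytest.approx(expected[g], abs=1e-12)

    def test_unknown_mirna_sites_ignored_and_tallied(self):
        recs = [
            SiteScore("g", "m", 0, 8, Channel.MIRANDA_ENERGY, -10.0),
            SiteScore("g", "filtered", 10, 18, Channel.MIRANDA_ENERGY, -10.0),
        ]
        s = combine_fermi_dirac(
            SiteScoreTable(Channel.MIRANDA_ENERGY, recs), make_vec({"m": 1.0})
        )
        assert s.attrs["n_ignored_sites"] == 1

    def test_rejects_non_energy_channel(self):
        table = SiteScoreTable(Channel.TARGETSCAN_SEED, [])
        with pytest.raises(ValueError, match="energy"):
            combine_fermi_dirac(table, make_vec({"m": 1.0}))

    def test_bounded_by_site_count_and_saturates(self):
        params = FermiDiracParams()
        recs = [
            SiteScore("g", "m", 10 * i, 10 * i + 8, Channel.MIRANDA_ENERGY, -500.0)
            for i in range(4)
        ]
        s = combine_fermi_dirac(
            SiteScoreTable(Channel.MIRANDA_ENERGY, recs), make_vec({"m": 1.0}), params
        )
        assert s["g"] == pytest.approx(4.0, abs=1e-9)  # E -> -inf limit: the count

    def test_disjoint_site_sets_add(self, rng):
        params = FermiDiracParams()
        table = random_energy_table(rng, 10, 3)
        half = len(table.records) // 2
        vec = make_vec({f"m{i}": 1 / 3 for i in range(3)})
        a = combine_fermi_dirac(
            SiteScoreTable(table.channel, table.records[:half]), vec, params,
            gene_ids=[f"g{i}" for i in range(10)],
        )
        b = combine_fermi_dirac(
            SiteScoreTable(table.channel, table.records[half:]), vec, params,
            gene_ids=[f"g{i}" for i in range(10)],
        )
        whole = combine_fermi_dirac(
            table, vec, params, gene_ids=[f"g{i}" for i in range(10)]
        )
        assert np.allclose(whole, a + b, atol=1e-12)


class TestWeightedSum:
    def test_single_term_product(self):
        sik = pd.DataFrame({"a": {"g": 4.0}, "b": {"g": 0.0}})
        s = combine_weighted_sum(sik, make_vec({"a": 0.25, "b": 0.75}))
        assert s["g"] == pytest.approx(1.0)

    def test_uniform_concentrations_recover_count(self):
        sik = pd.DataFrame({f"m{i}": {"g": 6.0} for i in range(4)})
        s = combine_weighted_sum(sik, make_vec({f"m{i}": 0.25 for i in range(4)}))
        assert s["g"] == pytest.approx(6.0)

    def test_mirsvr_hand_arithmetic(self):
        sik = pd.DataFrame({"a": {"g": -1.2}, "b": {"g": -0.4}})
        s = combine_weighted_sum(sik, make_vec({"a": 0.5, "b": 0.5}))
        assert s["g"] == pytest.approx(-0.8)

    def test_linearity_in_scores(self, rng):
        sik = pd.DataFrame(
            rng.normal(size=(8, 4)),
            index=[f"g{i}" for i in range(8)],
            columns=[f"m{i}" for i in range(4)],
        )
        vec = make_vec({f"m{i}": 0.25 for i in range(4)})
        assert np.allclose(
            combine_weighted_sum(3.5 * sik, vec), 3.5 * combine_weighted_sum(sik, vec)
        )

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(100):
            n_genes = int(rng.integers(1, 51))
            n_mirnas = int(rng.integers(1, 11))
            table = random_energy_table(rng, n_genes, n_mirnas, Channel.MIRSVR)
            raw = rng.uniform(0.01, 1.0, n_mirnas)
            conc = {f"m{i}": v for i, v in enumerate(raw / raw.sum())}
            sik = per_gene_mirna_scores(table, mode="sum")
            got = combine_weighted_sum(sik, make_vec(conc))
            expected = {}
            for rec in table.records:
                expected[rec.gene_id] = (
                    expected.get(rec.gene_id, 0.0) + conc[rec.mirna_id] * rec.score
                )
            for g, v in expected.items():
                assert got[g] == pytest.approx(v, abs=1e-12)

    def test_per_gene_counts(self):
        recs = [
            SiteScore("g", "m", 0, 8, Channel.TARGETSCAN_SEED, 1.0),
            SiteScore("g", "m", 20, 28, Channel.TARGETSCAN_SEED, 1.0),
        ]
        sik = per_gene_mirna_scores(
            SiteScoreTable(Channel.TARGETSCAN_SEED, recs), mode="count"
        )
        assert sik.loc["g", "m"] == 2.0


class TestBuildChannelMatrix:
    def _tables(self, rng):
        return {
            Channel.MIRANDA_ENERGY: random_energy_table(rng, 20, 4),
            Channel.MIRSVR: random_energy_table(rng, 20, 4, Channel.MIRSVR),
        }

    def test_shape_contract(self, rng):
        tables = self._tables(rng)
        vec = make_vec({f"m{i}": 0.25 for i in range(4)})
        genes = [f"g{i}" for i in range(20)]
        matrix = build_channel_matrix(tables, [("s1", vec), ("s2", vec)], genes)
        assert matrix.scores.shape == (20, 4)  # 2 channels x 2 labels
        assert matrix.labels == ("s1", "s2")
        assert set(matrix.channels) == set(tables)

    def test_identical_samples_give_identical_blocks(self, rng):
        tables = self._tables(rng)
        vec = make_vec({f"m{i}": 0.25 for i in range(4)})
        genes = [f"g{i}" for i in range(20)]
        matrix = build_channel_matrix(tables, [("s1", vec), ("s2", vec)], genes)
        assert matrix.block("s1").equals(matrix.block("s2"))

    def test_doubling_concentration_only_moves_genes_with_sites(self, rng):
        tables = {Channel.MIRANDA_ENERGY: random_energy_table(rng, 20, 4)}
        genes = [f"g{i}" for i in range(20)]
        base = {f"m{i}": 0.2 for i in range(4)}
        bumped = dict(base, m0=0.4)
        m1 = build_channel_matrix(tables, [("s", make_vec(base))], genes)
        m2 = build_channel_matrix(tables, [("s", make_vec(bumped))], genes)
        with_sites = {r.gene_id for r in tables[Channel.MIRANDA_ENERGY] if r.mirna_id == "m0"}
        diff = (m2.scores - m1.scores)[("s", Channel.MIRANDA_ENERGY.value)]
        for g in genes:
            if g in with_sites:
                assert diff[g] > 0
            else:
                assert diff[g] == 0

    def test_zero_channels_rejected(self):
        with pytest.raises(ValueError):
            build_channel_matrix({}, [("s", make_vec({"m": 1.0}))], ["g"])

    def test_unknown_label_lookup_fails(self, rng):
        tables = self._tables(rng)
        matrix = build_channel_matrix(
            tables, [("s", make_vec({f"m{i}": 0.25 for i in range(4)}))], ["g0"]
        )
        with pytest.raises(KeyError):
            matrix.block("nope")
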