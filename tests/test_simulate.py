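import json
import math

import numpy as np
import pytest

from gametolog import (ConversionEvent, SimConfig, pairwise_syn,
                       read_alignment, read_tag_map, simulate_gametologs,
                       window_profile, write_fixture)
from gametolog.alignment_io import second_position_sites
from gametolog.phylogeny import classify_informative_sites
from gametolog.simulate import SimulationError, jc_expected_p


def _p_distance(a: str, b: str) -> float:
    same = sum(1 for x, y in zip(a, b) if x == y)
    return 1 - same / len(a)


class TestConfigValidation:
    def test_event_must_postdate_split(self):
        ev = ConversionEvent(clade="eutherian", direction="Y->X",
                             start_codon=0, end_codon=10, t_event=2e8)
        with pytest.raises(SimulationError):
            SimConfig(n_codons=100, T_split=1.6e8, T_arrest=1.8e8,
                      conversion_events=[ev])

    def test_region_inside_gene(self):
        ev = ConversionEvent(clade="eutherian", direction="Y->X",
                             start_codon=0, end_codon=200, t_event=1e7)
        with pytest.raises(SimulationError):
            SimConfig(n_codons=100, conversion_events=[ev])

    def test_arrest_after_split_rejected(self):
        with pytest.raises(SimulationError):
            SimConfig(T_split=2e8, T_arrest=1e8)


class TestSimulation:
    def test_zero_rate_keeps_sequences_identical(self):
        aln, truth = simulate_gametologs(SimConfig(n_codons=200, m_f=0.0, seed=1))
        assert len(set(aln.rows)) == 1
        assert all(v == 0 for v in truth.branch_substitutions.values())

    def test_seed_reproducibility(self):
        a1, t1 = simulate_gametologs(SimConfig(n_codons=400, seed=77))
        a2, t2 = simulate_gametologs(SimConfig(n_codons=400, seed=77))
        assert a1.rows == a2.rows
        assert t1.branch_substitutions == t2.branch_substitutions
        a3, _ = simulate_gametologs(SimConfig(n_codons=400, seed=78))
        assert a3.rows != a1.rows

    def test_fourfold_scaffold_gives_clean_syn_sites(self):
        aln, _ = simulate_gametologs(SimConfig(n_codons=300, seed=5))
        r = pairwise_syn(aln.row("EX"), aln.row("EY"))
        assert r.S == 300  # every codon contributes exactly one synonymous site

    def test_third_position_divergence_matches_jc_expectation(self):
        # X-Y divergence at arrest time: d = (m_X + m_Y) * T_arrest
        cfg = SimConfig(n_codons=10_000, T_arrest=1.8e8, T_split=1.6e8,
                        alpha=2.0, m_f=2e-9, seed=42)
        aln, truth = simulate_gametologs(cfg)
        d = (cfg.m_X + cfg.m_Y) * cfg.T_arrest
        expected = jc_expected_p(d)
        assert truth.expected_p["EX-EY"] == pytest.approx(expected)
        thirds1 = aln.row("EX")[2::3]
        thirds2 = aln.row("EY")[2::3]
        obs = _p_distance(thirds1, thirds2)
        se = math.sqrt(expected * (1 - expected) / cfg.n_codons)
        assert abs(obs - expected) < 3 * se

    def test_converted_region_coalesces_at_event_time(self):
        ev = ConversionEvent(clade="eutherian", direction="Y->X",
                             start_codon=6000, end_codon=10_000, t_event=5e7)
        cfg = SimConfig(n_codons=10_000, conversion_events=[ev], seed=43)
        aln, truth = simulate_gametologs(cfg)
        thirds1 = np.array(list(aln.row("EX")[2::3]))
        thirds2 = np.array(list(aln.row("EY")[2::3]))
        rate_sum = cfg.m_X + cfg.m_Y
        p_conv = jc_expected_p(rate_sum * ev.t_event)
        p_free = jc_expected_p(rate_sum * cfg.T_arrest)
        obs_conv = np.mean(thirds1[6000:] != thirds2[6000:])
        obs_free = np.mean(thirds1[:6000] != thirds2[:6000])
        assert truth.region_expected_p[0]["expected_p"] == pytest.approx(p_conv)
        assert abs(obs_conv - p_conv) < 3 * math.sqrt(p_conv * (1 - p_conv) / 4000)
        assert abs(obs_free - p_free) < 3 * math.sqrt(p_free * (1 - p_free) / 6000)

    def test_marsupial_lineage_unaffected_by_eutherian_event(self):
        ev = ConversionEvent(clade="eutherian", direction="Y->X",
                             start_codon=0, end_codon=5000, t_event=1e7)
        cfg = SimConfig(n_codons=5000, conversion_events=[ev], seed=44)
        _, truth = simulate_gametologs(cfg)
        assert truth.converted_regions[0]["recipient"] == "EX"
        aln, _ = simulate_gametologs(cfg)
        p_mxmy = _p_distance(aln.row("MX")[2::3], aln.row("MY")[2::3])
        expected = jc_expected_p((cfg.m_X + cfg.m_Y) * cfg.T_arrest)
        assert abs(p_mxmy - expected) < 3 * math.sqrt(expected * (1 - expected) / 5000)


class TestInformativeSitePolarity:
    # strong-signal scenario (arrest long before speciation) so the internal
    # branches carry unambiguous shared substitutions
    def test_no_conversion_favours_cross_clade_pairing(self):
        wins = 0
        for seed in range(10):
            aln, _ = simulate_gametologs(
                SimConfig(n_codons=1500, T_split=5e7, T_arrest=1.8e8, seed=seed))
            # second positions are frozen in the fourfold scaffold; use thirds
            counts = _third_position_partition(aln)
            wins += counts.nA > counts.nB
        assert wins >= 9

    def test_whole_gene_conversion_flips_polarity(self):
        wins = 0
        for seed in range(10):
            ev = ConversionEvent(clade="eutherian", direction="Y->X",
                                 start_codon=0, end_codon=1500, t_event=1e7)
            cfg = SimConfig(n_codons=1500, T_split=5e7, T_arrest=1.8e8,
                            conversion_events=[ev], seed=seed)
            aln, _ = simulate_gametologs(cfg)
            counts = _third_position_partition(aln)
            wins += counts.nB > counts.nA
        assert wins >= 9


def _third_position_partition(aln):
    rows = {k: aln.row(k)[2::3] for k in ("EX", "EY", "MX", "MY")}
    sites = [(3 * j + 2, (rows["EX"][j], rows["EY"][j], rows["MX"][j], rows["MY"][j]))
             for j in range(len(rows["EX"]))]
    return classify_informative_sites(sites)


class TestFixtureFiles:
    def test_files_readable_by_alignment_io(self, sim_fixture_dir):
        tags = read_tag_map(sim_fixture_dir["tags"])
        aln = read_alignment(sim_fixture_dir["fasta"], mode="codon", tag_map=tags)
        assert sorted(aln.ids) == ["EX", "EY", "MX", "MY", "OUT"]
        assert aln.taxa[aln.index_of("EX")].chromosome == "X"
        truth = json.loads(sim_fixture_dir["truth"].read_text())
        assert "expected_p" in truth and "branch_substitutions" in truth

    def test_fixture_bytes_deterministic(self, tmp_path):
        cfg = SimConfig(n_codons=200, seed=3)
        for sub in ("a", "b"):
            aln, truth = simulate_gametologs(cfg)
            write_fixture(aln, truth, tmp_path / sub)
        assert ((tmp_path / "a" / "alignment.fasta").read_bytes()
                == (tmp_path / "b" / "alignment.fasta").read_bytes())
        assert ((tmp_path / "a" / "truth.json").read_bytes()
                == (tmp_path / "b" / "truth.json").read_bytes())
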