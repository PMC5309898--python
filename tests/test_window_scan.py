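"""fd window scans, ancestry painting, tract merging and the tract-length law."""

import numpy as np
import pandas as pd
import pytest

import hybridtrace as ht
from hybridtrace import window_scan as ws
from hybridtrace.errors import ConfigurationError, UndefinedStatisticError

from conftest import make_freq_table


class TestExpectedTractLength:
    def test_study_parameter_values(self):
        assert ws.expected_tract_length(0.2, 2.5e-8, 100_000) == pytest.approx(500.0)
        assert ws.expected_tract_length(0.2, 2.5e-8, 50_000) == pytest.approx(1000.0)

    def test_doubling_time_halves_length(self):
        a = ws.expected_tract_length(0.3, 1e-8, 1000)
        b = ws.expected_tract_length(0.3, 1e-8, 2000)
        assert a == pytest.approx(2 * b)

    @pytest.mark.parametrize("m,r,t", [(0.0, 1e-8, 10), (1.0, 1e-8, 10),
                                       (0.2, 0.0, 10), (0.2, 1e-8, 0)])
    def test_domain_errors(self, m, r, t):
        with pytest.raises(ConfigurationError):
            ws.expected_tract_length(m, r, t)


def freq_table_positions(freq_by_group, positions, scaffold="s1"):
    ft = make_freq_table(freq_by_group, scaffold=scaffold)
    ft.sites["pos"] = positions
    return ft


class TestFdWindows:
    def test_complete_sharing_gives_fd_one(self):
        """P2 identical to P3 in every site: S_obs equals the donor bound."""
        rng = np.random.default_rng(0)
        p2 = rng.uniform(0.3, 0.9, 30)
        ft = freq_table_positions(
            {"p1": np.zeros(30), "p2": p2, "p3": p2, "og": np.zeros(30)},
            np.arange(1, 31) * 10,
        )
        out = ws.fd_windows(ft, "p1", "p2", "p3", "og", window_bp=1000, min_patterns=1)
        assert out["fd"].iloc[0] == pytest.approx(1.0)

    def test_negative_d_window_set_to_zero(self):
        ft = freq_table_positions(
            {"p1": np.ones(10), "p2": np.zeros(10), "p3": np.ones(10), "og": np.zeros(10)},
            np.arange(1, 11),
        )
        out = ws.fd_windows(ft, "p1", "p2", "p3", "og", window_bp=100, min_patterns=1)
        assert out["fd"].iloc[0] == 0.0

    def test_below_min_patterns_excluded(self):
        """Weighted ABBA+BABA total of 4.5 is excluded at a minimum of 5."""
        # 9 sites, each abba weight 0.5: total 4.5
        ft = freq_table_positions(
            {"p1": np.zeros(9), "p2": np.full(9, 0.5), "p3": np.ones(9), "og": np.zeros(9)},
            np.arange(1, 10),
        )
        out = ws.fd_windows(ft, "p1", "p2", "p3", "og", window_bp=100, min_patterns=5)
        assert np.isnan(out["fd"].iloc[0])
        assert out["n_informative"].iloc[0] == pytest.approx(4.5)

    def test_three_site_window_matches_hand_computation(self):
        p1 = np.array([0.1, 0.0, 0.2])
        p2 = np.array([0.6, 0.5, 0.9])
        p3 = np.array([0.8, 0.9, 0.4])
        og = np.zeros(3)
        ft = freq_table_positions({"p1": p1, "p2": p2, "p3": p3, "og": og}, [1, 2, 3])
        out = ws.fd_windows(ft, "p1", "p2", "p3", "og", window_bp=10, min_patterns=0)

        s_obs = sum(
            (1 - p1[i]) * p2[i] * p3[i] - p1[i] * (1 - p2[i]) * p3[i] for i in range(3)
        )
        pd_ = np.maximum(p2, p3)
        s_max = sum(
            (1 - p1[i]) * pd_[i] * pd_[i] - p1[i] * (1 - pd_[i]) * pd_[i] for i in range(3)
        )
        assert out["fd"].iloc[0] == pytest.approx(s_obs / s_max)


class TestFdCorrelation:
    def make_table(self, fd_values):
        n = len(fd_values)
        return pd.DataFrame(
            {"scaffold": "s1", "start": np.arange(n) * 1000,
             "end": (np.arange(n) + 1) * 1000, "n_informative": 5.0, "fd": fd_values}
        )

    def test_identical_tables_r_one(self):
        t = self.make_table([0.1, 0.5, 0.9, 0.3])
        r, _ = ws.fd_correlation(t, t)
        assert r == pytest.approx(1.0)

    def test_mirrored_tables_r_minus_one(self):
        fd = np.array([0.1, 0.5, 0.9, 0.3])
        r, _ = ws.fd_correlation(self.make_table(fd), self.make_table(2 * fd.mean() - fd))
        assert r == pytest.approx(-1.0)

    def test_too_few_windows_errors(self):
        t = self.make_table([0.1, np.nan, np.nan, 0.3])
        with pytest.raises(UndefinedStatisticError):
            ws.fd_correlation(t, t)

    def test_shared_history_correlated(self):
        """Two daughter species of one swarm show correlated fd landscapes."""
        cfg = ht.SimulationConfig(seed=21, n_sites=20_000, chrom_length=4_000_000,
                                  t_admix=2000, n_species=2, n_diploids=5,
                                  n_control_pairs=0)
        ds = ht.simulate_hybrid_swarm(cfg)
        ft = ht.allele_freqs(ds.gm, ds.popmap)
        wa = ws.fd_windows(ft, "congolese", "lv_1", "upper_nile", "outgroup")
        wb = ws.fd_windows(ft, "congolese", "lv_2", "upper_nile", "outgroup")
        r, p = ws.fd_correlation(wa, wb)
        assert r > 0 and p < 0.01


class TestAncestryWindows:
    def paint(self, pc, pt, pn, **kw):
        n = len(pc)
        ft = freq_table_positions(
            {"c": pc, "t": pt, "n": pn, "og": np.zeros(n)}, np.arange(1, n + 1)
        )
        kw.setdefault("min_scaffold_bp", 0)
        return ws.ancestry_windows(ft, "c", "t", "n", "og", window_bp=100, **kw)

    def test_pure_bbaa_window_is_congolese(self):
        out = self.paint(np.ones(5), np.ones(5), np.zeros(5))
        assert out["colour"].iloc[0] == ws.COLOUR_CONGO
        assert out["abba_prop"].iloc[0] == 0.0

    def test_exact_070_threshold_is_upper_nile(self):
        """ABBA:BBAA of 7:3 sits exactly at the 0.7 colour threshold."""
        pc = np.array([0.0] * 7 + [1.0] * 3)
        pn = np.array([1.0] * 7 + [0.0] * 3)
        out = self.paint(pc, np.ones(10), pn)
        assert out["abba_prop"].iloc[0] == pytest.approx(0.7)
        assert out["colour"].iloc[0] == ws.COLOUR_NILE

    def test_total_not_exceeding_one_is_no_data(self):
        out = self.paint(np.zeros(1), np.ones(1), np.ones(1))  # single ABBA of weight 1
        assert out["colour"].iloc[0] == ws.COLOUR_NO_DATA

    def test_short_scaffolds_dropped(self):
        n = 50
        ft = freq_table_positions(
            {"c": np.ones(n), "t": np.ones(n), "n": np.zeros(n), "og": np.zeros(n)},
            np.arange(1, n + 1) * 10,
        )
        kept = ws.ancestry_windows(ft, "c", "t", "n", "og", window_bp=100, min_scaffold_bp=400)
        dropped = ws.ancestry_windows(ft, "c", "t", "n", "og", window_bp=100, min_scaffold_bp=10_000)
        assert len(kept) > 0 and len(dropped) == 0


def wins(colours, scaffold="s1", window=100):
    return pd.DataFrame(
        {"scaffold": scaffold, "start": np.arange(len(colours)) * window,
         "end": (np.arange(len(colours)) + 1) * window,
         "n_informative": 5.0, "abba_prop": 0.5, "colour": colours}
    )


class TestMergeTracts:
    N, C, U, X = ws.COLOUR_NILE, ws.COLOUR_CONGO, ws.COLOUR_UNASSIGNED, ws.COLOUR_NO_DATA

    def test_single_gap_bridged(self):
        tracts = ws.merge_tracts(wins([self.N, self.X, self.N]))
        assert len(tracts) == 1
        t = tracts[0]
        assert (t.start, t.end, t.colour, t.n_windows) == (0, 300, self.N, 2)

    def test_double_gap_breaks(self):
        tracts = ws.merge_tracts(wins([self.N, self.X, self.X, self.N]))
        assert len(tracts) == 2

    def test_adjacent_colours_give_two_tracts(self):
        tracts = ws.merge_tracts(wins([self.N, self.C]))
        assert [(t.colour, t.start, t.end) for t in tracts] == [
            (self.N, 0, 100), (self.C, 100, 200)
        ]

    def test_unassigned_always_breaks(self):
        tracts = ws.merge_tracts(wins([self.N, self.U, self.N]))
        assert len(tracts) == 2

    def test_no_two_same_colour_tracts_adjacent(self):
        rng = np.random.default_rng(1)
        colours = rng.choice([self.N, self.C, self.U, self.X], size=300).tolist()
        tracts = ws.merge_tracts(wins(colours))
        for a, b in zip(tracts, tracts[1:]):
            assert not (a.colour == b.colour and a.end == b.start)

    def test_tract_ends_exclude_trailing_gap(self):
        tracts = ws.merge_tracts(wins([self.N, self.X]))
        assert tracts[0].end == 100


class TestTractLengthSummary:
    def test_empty_input(self):
        assert ws.tract_length_summary([]).empty

    def test_simple_bins(self):
        tracts = [
            ws.AncestryTract("s1", 0, 3000, ws.COLOUR_NILE, 1),
            ws.AncestryTract("s1", 5000, 8000, ws.COLOUR_NILE, 1),
            ws.AncestryTract("s1", 10_000, 16_000, ws.COLOUR_NILE, 2),
        ]
        out = ws.tract_length_summary(tracts, bin_edges=np.array([0, 3001, 6001]))
        assert out["count"].tolist() == [2, 1]

    def test_inferred_length_tracks_admixture_time(self):
        """Mean painted minor-ancestry tract length shrinks as t grows,
        following 1/((1-m)rt) down to the window-resolution floor."""
        means = []
        for t_admix in (1000, 5000, 20_000):
            cfg = ht.SimulationConfig(
                seed=9, n_sites=30_000, chrom_length=3_000_000, t_admix=t_admix,
                n_species=1, n_diploids=2, f_species=0.01, frac_bdm=0.2,
                f_congo=0.5, f_nile=0.5, shared_species_tracts=True,
                n_control_pairs=0,
            )
            ds = ht.simulate_hybrid_swarm(cfg)
            ft = ht.allele_freqs(ds.gm, ds.popmap)
            aw = ws.ancestry_windows(ft, "congolese", "lv_1", "upper_nile", "outgroup",
                                     min_scaffold_bp=0)
            lens = [t.length for t in ws.merge_tracts(aw) if t.colour == ws.COLOUR_NILE]
            means.append(np.mean(lens))
        assert means[0] > means[1] > means[2]
        # longest-tract regime resolvable above the 3-kb window floor
        assert means[0] > 3 * 3000
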