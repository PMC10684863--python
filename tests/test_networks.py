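import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from immunorhythm import (build_group_network, classify_edges, generate_cohort,
                          study_params, spearman)
from immunorhythm.networks import (EdgeRecord, _strength, edges_to_frame,
                                   export_network, spearman_matrix)
from immunorhythm.panel import PHENOTYPES


def spearman_bruteforce(x, y):
    """Oracle: rho as plain Pearson on ranks, exact p by enumerating all
    n! permutations one by one."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = np.corrcoef(rx, ry)[0, 1]
    count = total = 0
    for perm in itertools.permutations(ry):
        r = np.corrcoef(rx, perm)[0, 1]
        count += abs(r) >= abs(rho) - 1e-12
        total += 1
    return rho, count / total


class TestSpearman:
    def test_rank_invariance_under_monotone_transform(self):
        x = np.linspace(0.1, 3.0, 12)
        res = spearman(x, np.exp(x), mode="t")
        assert res.rho == pytest.approx(1.0)
        res = spearman(x, -x, mode="t")
        assert res.rho == pytest.approx(-1.0)
        assert res.p == 0.0

    @pytest.mark.parametrize("n,seed", [(5, 0), (6, 1), (7, 2), (8, 3)])
    def test_exact_p_matches_full_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=n), rng.normal(size=n)
        res = spearman(x, y, mode="exact")
        rho_bf, p_bf = spearman_bruteforce(x, y)
        assert res.rho == pytest.approx(rho_bf, abs=1e-12)
        assert res.p == pytest.approx(p_bf, abs=1e-12)

    def test_exact_handles_ties_via_midranks(self):
        x = [1.0, 1.0, 2.0, 3.0, 4.0]
        y = [2.0, 1.0, 2.0, 5.0, 4.0]
        res = spearman(x, y, mode="exact")
        rho_bf, p_bf = spearman_bruteforce(x, y)
        assert res.rho == pytest.approx(rho_bf, abs=1e-12)
        assert res.p == pytest.approx(p_bf, abs=1e-12)

    def test_t_approximation_matches_scipy(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=60), rng.normal(size=60)
        res = spearman(x, y, mode="t")
        ref = stats.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_constant_series_warns_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            res = spearman([1.0] * 6, [1, 2, 3, 4, 5, 6])
        assert np.isnan(res.rho)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2, 3])  # n < 4
        with pytest.raises(ValueError):
            spearman(np.arange(12), np.arange(12), mode="exact")  # n > 10

    def test_matrix_equals_pairwise(self, study_cohort):
        df = study_cohort.frequencies("2Yrs").iloc[:, :6]
        rho, p = spearman_matrix(df)
        for a, b in itertools.combinations(df.columns, 2):
            res = spearman(df[a], df[b], mode="t")
            assert rho.loc[a, b] == pytest.approx(res.rho, abs=1e-12)
            assert p.loc[a, b] == pytest.approx(res.p, abs=1e-12)


class TestStrengthBands:
    @pytest.mark.parametrize("rho,band", [
        (0.67, "strong"), (-0.67, "strong"), (1.0, "strong"),
        (0.6699999, "weak_moderate"), (0.1, "weak_moderate"),
        (-0.3, "weak_moderate"), (0.0999999, "sub_threshold_weak"),
        (0.0, "sub_threshold_weak"),
    ])
    def test_boundaries_exact(self, rho, band):
        assert _strength(rho) == band


class TestBuildGroupNetwork:
    def test_sixty_six_candidate_pairs(self, study_cohort):
        edges = build_group_network(study_cohort, "2Yrs")
        assert len(edges) == 66
        assert all(e.sign == ("positive" if e.rho >= 0 else "negative")
                   for e in edges)

    def test_undersized_group_warns_empty(self):
        params = study_params()
        params.group_sizes = {g: ((2, 1) if g == "2Yrs" else (10, 10))
                              for g in params.scheme.labels}
        cohort = generate_cohort(params, seed=0)
        with pytest.warns(UserWarning, match="empty network"):
            assert build_group_network(cohort, "2Yrs") == []

    def test_closure_induces_structural_within_lineage_edges(self, null_cohort):
        # compositional closure: even under an identity latent correlation,
        # same-lineage pairs carry structural correlation — negative between
        # the dominant naive component and each minor one (minor components
        # may correlate positively with each other, all being squeezed by
        # the dominant share)
        for g in ("2Yrs", "8-10Yrs"):
            edges = build_group_network(null_cohort, g)
            within_sig = [e for e in edges
                          if not e.cross_lineage and e.significant]
            assert len(within_sig) >= 6, "structural closure edges expected"
            naive_edges = [e for e in within_sig
                           if e.source.startswith("N") or
                           e.target.startswith("N")]
            assert naive_edges
            assert all(e.sign == "negative" for e in naive_edges)


class TestClassifyEdges:
    def _edge(self, a, b, g, rho=0.5, p=0.01, sig=True):
        return EdgeRecord(source=a, target=b, group=g, rho=rho, p=p,
                          sign="positive" if rho >= 0 else "negative",
                          strength=_strength(rho), significant=sig)

    def test_common_selective_and_neither(self):
        groups = ["G1", "G2", "G3"]
        nets = {g: [] for g in groups}
        for g in groups:  # significant everywhere, same sign -> common
            nets[g].append(self._edge("NCD4", "NCD8", g))
        nets["G3"].append(self._edge("CMCD4", "CMCD8", "G3"))  # one group
        for g in ("G1", "G3"):  # two of three groups -> neither
            nets[g].append(self._edge("EMCD4", "EMCD8", g))
        summary = classify_edges(nets)
        assert summary.common == [("NCD4", "NCD8")]
        assert summary.selective["G3"] == [("CMCD4", "CMCD8")]
        assert summary.selective["G1"] == []
        assert summary.total == {"G1": 2, "G2": 1, "G3": 3}

    def test_sign_flip_blocks_common_unless_agnostic(self):
        groups = ["G1", "G2"]
        nets = {"G1": [self._edge("NCD4", "NCD8", "G1", rho=0.5)],
                "G2": [self._edge("NCD4", "NCD8", "G2", rho=-0.5)]}
        assert classify_edges(nets).common == []
        agnostic = classify_edges(nets, sign_consistent_common=False)
        assert agnostic.common == [("NCD4", "NCD8")]

    def test_common_and_selective_disjoint(self, study_cohort):
        nets = {g: build_group_network(study_cohort, g)
                for g in study_cohort.scheme.labels}
        summary = classify_edges(nets)
        common = set(summary.common)
        for g, pairs in summary.selective.items():
            assert common.isdisjoint(pairs)
            assert len(pairs) <= summary.total[g]
        assert len(summary.common) <= min(summary.total.values())

    def test_strong_nodes_flagged(self):
        nets = {"G1": [self._edge("NCD4", "NCD8", "G1", rho=0.8)],
                "G2": [self._edge("NCD4", "NCD8", "G2", rho=0.3)]}
        summary = classify_edges(nets)
        assert summary.strong_nodes["G1"] == ["NCD4", "NCD8"]
        assert summary.strong_nodes["G2"] == []

    def test_preset_conserved_axes_recovered(self):
        params = study_params()
        for seed in range(5):
            cohort = generate_cohort(params, seed=seed)
            nets = {g: build_group_network(cohort, g)
                    for g in cohort.scheme.labels}
            common = set(classify_edges(nets).common)
            assert ("NCD4", "NCD8") in common
            assert ("CMCD4", "CMCD8") in common


class TestExport:
    def _toy(self):
        e = [EdgeRecord("NCD4", "NCD8", "G1", 0.8, 0.001, "positive",
                        "strong", True),
             EdgeRecord("NCD4", "CMCD4", "G1", -0.5, 0.01, "negative",
                        "weak_moderate", True),
             EdgeRecord("EMCD4", "EMCD8", "G1", 0.7, 0.02, "positive",
                        "strong", True)]
        f = [EdgeRecord("NCD4", "NCD8", "G2", 0.6, 0.01, "positive",
                        "weak_moderate", True)]
        return {"G1": e, "G2": f}

    def test_sif_lines_and_csv(self, tmp_path):
        nets = self._toy()
        summary = classify_edges(nets)
        written = export_network(nets, summary, tmp_path,
                                 formats=("edge-csv", "sif"))
        sif = (tmp_path / "network_G1.sif").read_text().strip().splitlines()
        assert len(sif) == 3
        assert all(len(line.split("\t")) == 3 for line in sif)
        assert (tmp_path / "conserved_axes.csv").exists()

    def test_empty_network_header_only_csv(self, tmp_path):
        nets = {"G1": [], "G2": [EdgeRecord("NCD4", "NCD8", "G2", 0.6, 0.01,
                                            "positive", "weak_moderate",
                                            True)]}
        summary = classify_edges(nets)
        export_network(nets, summary, tmp_path, formats=("edge-csv",))
        lines = (tmp_path / "network_G1.csv").read_text().strip().splitlines()
        assert len(lines) == 1  # header only

    def test_graphml_roundtrip_preserves_attributes(self, tmp_path):
        nets = self._toy()
        summary = classify_edges(nets)
        export_network(nets, summary, tmp_path, formats=("graphml",))
        G = nx.read_graphml(tmp_path / "network_G1.graphml")
        assert G.number_of_nodes() == 12
        attrs = G.edges[("NCD4", "NCD8")]
        assert attrs["rho"] == 0.8
        assert attrs["strength"] == "strong"
        assert G.nodes["NCD4"]["family"] == "N"
        assert G.nodes["NCD4"]["strong_node"]

    def test_unknown_format_rejected(self, tmp_path):
        nets = self._toy()
        with pytest.raises(ValueError, match="unknown format"):
            export_network(nets, classify_edges(nets), tmp_path,
                           formats=("xml",))

    def test_edge_frame_tags(self):
        nets = self._toy()
        summary = classify_edges(nets)
        frame = edges_to_frame(nets, summary)
        tags = frame.set_index(["group", "source", "target"])["tag"]
        assert tags.loc[("G1", "NCD4", "NCD8")] == "common"
        assert tags.loc[("G1", "EMCD4", "EMCD8")] == "selective"


class TestInjectedEdgePower:
    def test_strong_injected_edge_recovered(self):
        # a rank correlation injected at 0.8 should be retained and
        # classified strong at the adolescent group size
        from immunorhythm import inject_correlation
        params = study_params()
        params, rep = inject_correlation(params, ("CMCD4", "EMCD8"),
                                         "11-18Yrs", 0.8, cal_n=3000)
        assert abs(rep.attained - 0.8) <= 0.1
        hits = 0
        for seed in range(5):
            cohort = generate_cohort(params, seed=seed)
            edges = build_group_network(cohort, "11-18Yrs")
            e = next(e for e in edges if set(e.pair) == {"CMCD4", "EMCD8"})
            hits += e.significant and e.strength == "strong"
        assert hits >= 4
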