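"""Network assembly, region attribution, seed scanning and export."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from leukosplice import network as nw


def _de(mirnas_called, mirnas_uncalled=()):
    rows = []
    for m in mirnas_called:
        rows.append((m, 1.5, 2.0, True))
    for m in mirnas_uncalled:
        rows.append((m, -0.2, -1.0, False))
    return pd.DataFrame(
        rows, columns=["feature", "log2_fc", "b_statistic", "called"]
    ).set_index("feature")


def _events(genes_called, genes_uncalled=()):
    rows = []
    for g in genes_called:
        rows.append((g, f"{g}_incl", f"{g}_excl", "inclusion", True))
    for g in genes_uncalled:
        rows.append((g, f"{g}_incl", f"{g}_excl", "exclusion", False))
    return pd.DataFrame(
        rows,
        columns=["gene", "inclusion_probe_set", "exclusion_probe_set", "direction", "called"],
    )


def _table(pairs, region="3UTR"):
    return pd.DataFrame(
        [(m, g, region, i) for i, (m, g) in enumerate(pairs)],
        columns=["mirna", "gene", "region", "site_offset"],
    )


class TestBuildNetwork:
    def test_full_product_of_calls(self):
        de = _de(["m1", "m2"])
        ev = _events(["g1", "g2", "g3"])
        table = _table([(m, g) for m in ["m1", "m2"] for g in ["g1", "g2", "g3"]])
        net = nw.build_network(de, ev, table, ("HC", "PD"))
        assert net.n_edges == 6

    def test_empty_prediction_table_empty_network(self):
        net = nw.build_network(
            _de(["m1"]), _events(["g1"]), _table([]), ("HC", "PD")
        )
        assert net.n_edges == 0

    def test_uncalled_mirna_contributes_no_edges(self):
        de = _de(["m1"], mirnas_uncalled=["m2"])
        ev = _events(["g1"])
        table = _table([("m1", "g1"), ("m2", "g1")])
        net = nw.build_network(de, ev, table, ("HC", "PD"))
        assert net.mirna_nodes == ["m1"]
        assert net.n_edges == 1

    def test_uncalled_gene_contributes_no_edges(self):
        de = _de(["m1"])
        ev = _events(["g1"], genes_uncalled=["g2"])
        table = _table([("m1", "g1"), ("m1", "g2")])
        net = nw.build_network(de, ev, table, ("HC", "PD"))
        assert net.gene_nodes == ["g1"]

    def test_multi_region_pairs_collapse_to_one_edge(self):
        de = _de(["m1"])
        ev = _events(["g1"])
        table = pd.DataFrame(
            [("m1", "g1", "3UTR", 5), ("m1", "g1", "CDS", 90)],
            columns=["mirna", "gene", "region", "site_offset"],
        )
        net = nw.build_network(de, ev, table, ("HC", "PD"))
        assert net.n_edges == 1
        assert net.graph.edges["m1", "g1"]["regions"] == "CDS,3UTR"

    def test_edge_gate_soundness_recount(self):
        rng = np.random.default_rng(0)
        mirnas = [f"m{i}" for i in range(8)]
        genes = [f"g{i}" for i in range(12)]
        de = _de(mirnas[:4], mirnas[4:])
        ev = _events(genes[:6], genes[6:])
        pairs = [
            (m, g)
            for m in mirnas
            for g in genes
            if rng.random() < 0.4
        ]
        table = _table(pairs)
        net = nw.build_network(de, ev, table, ("HC", "PD"))
        # independent recount from the inputs
        expected = {
            (m, g)
            for m, g in pairs
            if m in set(mirnas[:4]) and g in set(genes[:6])
        }
        assert set(net.graph.edges()) == expected


class TestRegionDistribution:
    def test_counting_example(self):
        de = _de(["m1", "m2", "m3", "m4"])
        ev = _events(["g1", "g2"])
        table = pd.DataFrame(
            [
                ("m1", "g1", "3UTR", 0),
                ("m2", "g1", "3UTR", 1),
                ("m3", "g2", "CDS", 2),
                ("m4", "g2", "5UTR", 3),
            ],
            columns=["mirna", "gene", "region", "site_offset"],
        )
        net = nw.build_network(de, ev, table, ("HC", "PD"))
        dist = nw.region_distribution(net)
        assert dist["fractions"] == {"5UTR": 0.25, "CDS": 0.25, "3UTR": 0.50}
        assert dist["mean_sites_per_gene"] == 2.0

    def test_fractions_sum_to_one(self):
        de = _de(["m1", "m2"])
        ev = _events(["g1", "g2", "g3"])
        table = _table(
            [(m, g) for m in ["m1", "m2"] for g in ["g1", "g2", "g3"]], region="CDS"
        )
        dist = nw.region_distribution(nw.build_network(de, ev, table, ("HC", "PD")))
        assert sum(dist["fractions"].values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_network_all_zero(self):
        dist = nw.region_distribution(
            nw.build_network(_de([]), _events([]), _table([]), ("HC", "PD"))
        )
        assert dist["edges"] == 0
        assert dist["mean_sites_per_gene"] == 0.0


def brute_force_scan(mirna: str, probe: str, start: int = 2, length: int = 7):
    comp = {"A": "T", "C": "G", "G": "C", "U": "A", "T": "A"}
    seed = mirna[start - 1 : start - 1 + length]
    motif = "".join(comp[c] for c in reversed(seed))
    return [i for i in range(len(probe) - length + 1) if probe[i : i + length] == motif]


class TestSeedScan:
    def test_worked_example(self):
        # seed AGCAGCA -> motif TGCTGCT at offset 3
        hits = nw.seed_scan("UAGCAGCACGUA", "AAATGCTGCTAAA")
        assert hits == [3]

    def test_no_motif_empty(self):
        assert nw.seed_scan("UAGCAGCACGUA", "AAAAAAAAAAAA") == []

    def test_tandem_motif_both_offsets(self):
        motif = "TGCTGCT"
        assert nw.seed_scan("UAGCAGCACGUA", motif + motif) == [0, 7]

    def test_short_probe_empty(self):
        assert nw.seed_scan("UAGCAGCACGUA", "TGC") == []

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError):
            nw.seed_scan("UAGCAG", "TGCTGCTTGCTGCT")

    @settings(max_examples=250, deadline=None, derandomize=True)
    @given(
        st.text(alphabet="ACGU", min_size=10, max_size=25),
        st.text(alphabet="ACGT", min_size=7, max_size=60),
    )
    def test_matches_brute_force_scan(self, mirna, probe):
        assert nw.seed_scan(mirna, probe) == brute_force_scan(mirna, probe)

    def test_overlapping_occurrences_found(self):
        # palindromic-ish motif overlapping itself
        mirna = "UAAAAAAACGUA"  # seed AAAAAAA -> motif TTTTTTT
        assert nw.seed_scan(mirna, "TTTTTTTTT") == [0, 1, 2]


class TestVerifySeeds:
    @staticmethod
    def _setup(motif_in_called: bool):
        mirna = "UAGCAGCACGUA"  # motif TGCTGCT
        de = _de(["m1"])
        ev = _events(["g1"])
        table = _table([("m1", "g1")])
        net = nw.build_network(de, ev, table, ("HC", "PD"))
        probe_seqs = {
            "g1_incl": ("AAA" + "TGCTGCT" + "AA") if motif_in_called else "A" * 12,
            "g1_other": "TGCTGCTAAAA",
        }
        return net, {"m1": mirna}, ev, probe_seqs

    def test_motif_in_called_probe_verifies_edge(self):
        net, seqs, ev, probes = self._setup(True)
        summary = nw.verify_network_seeds(net, seqs, ev, probes)
        assert summary["verified_edges"] == 1
        assert net.graph.edges["m1", "g1"]["seed_verified"]

    def test_motif_only_in_noncalled_probe_not_verified(self):
        net, seqs, ev, probes = self._setup(False)
        summary = nw.verify_network_seeds(net, seqs, ev, probes)
        assert summary["verified_edges"] == 0
        assert not net.graph.edges["m1", "g1"]["seed_verified"]

    def test_summary_matches_brute_force_recount(self):
        rng = np.random.default_rng(3)
        mirnas = {f"m{i}": "".join(rng.choice(list("ACGU"), 22)) for i in range(5)}
        genes = [f"g{i}" for i in range(6)]
        de = _de(list(mirnas))
        ev = _events(genes)
        table = _table([(m, g) for m in mirnas for g in genes])
        probes = {}
        for g in genes:
            seq = "".join(rng.choice(list("ACGT"), 40))
            probes[f"{g}_incl"] = seq
            probes[f"{g}_excl"] = "".join(rng.choice(list("ACGT"), 40))
        # plant one known motif
        m0 = list(mirnas)[0]
        probes["g0_incl"] = "AA" + brute_force_motif(mirnas[m0]) + probes["g0_incl"][9:]
        net = nw.build_network(de, ev, table, ("HC", "PD"))
        summary = nw.verify_network_seeds(net, mirnas, ev, probes)
        expected = 0
        for m, g in net.graph.edges():
            found = any(
                brute_force_scan(mirnas[m], probes[p])
                for p in (f"{g}_incl", f"{g}_excl")
            )
            expected += int(found)
        assert summary["verified_edges"] == expected
        assert summary["verified_edges"] >= 1


def brute_force_motif(mirna: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "U": "A"}
    return "".join(comp[c] for c in reversed(mirna[1:8]))


class TestExport:
    @staticmethod
    def _net():
        de = _de(["m1", "m2"])
        ev = _events(["g1", "g2", "g3"])
        table = _table([(m, g) for m in ["m1", "m2"] for g in ["g1", "g2", "g3"]])
        return nw.build_network(de, ev, table, ("HC", "PD"))

    def test_sif_line_per_edge(self, tmp_path):
        path = tmp_path / "net.sif"
        nw.export_network(self._net(), path, "SIF")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 6
        assert all(line.split("\t")[1] == "targets" for line in lines)

    def test_graphml_roundtrip_byte_identical(self, tmp_path):
        p1, p2 = tmp_path / "a.graphml", tmp_path / "b.graphml"
        net = self._net()
        nw.export_network(net, p1, "GraphML")
        back = nw.import_graphml(p1)
        nw.export_network(back, p2, "GraphML")
        assert p1.read_bytes() == p2.read_bytes()
        assert set(back.graph.edges()) == set(net.graph.edges())

    def test_empty_network_valid_documents(self, tmp_path):
        empty = nw.build_network(_de([]), _events([]), _table([]), ("HC", "PD"))
        nw.export_network(empty, tmp_path / "e.sif", "SIF")
        nw.export_network(empty, tmp_path / "e.graphml", "GraphML")
        assert (tmp_path / "e.sif").read_text() == ""
        back = nw.import_graphml(tmp_path / "e.graphml")
        assert back.n_edges == 0

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            nw.export_network(self._net(), tmp_path / "x", "DOT")


def test_target_table_validation():
    bad_region = pd.DataFrame(
        [("m", "g", "UTR9", 1)], columns=["mirna", "gene", "region", "site_offset"]
    )
    with pytest.raises(ValueError):
        nw.validate_target_table(bad_region)
    dup = pd.DataFrame(
        [("m", "g", "CDS", 1)] * 2, columns=["mirna", "gene", "region", "site_offset"]
    )
    with pytest.raises(ValueError):
        nw.validate_target_table(dup)
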