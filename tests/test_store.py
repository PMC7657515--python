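"""Relational store: persistence, fuzzy name curation, cross-entity queries."""

import pytest

import callstore as cs
from callstore.datamodel import GenotypingProtocol, MarkerInfo, SampleCallset
from callstore.store import (
    GenotypeStore,
    PhenotypeRecord,
    PedigreeRecord,
    StoreConflictError,
    name_similarity,
    normalize_name,
)


@pytest.fixture
def stored(example_protocol):
    protocol, block = example_protocol
    store = GenotypeStore()
    pid = store.store_protocol(protocol)
    for s in block.sample_names:
        store.add_stock(s)
    callsets = cs.transpose_to_sample_first(block, protocol)
    store.store_callsets(pid, callsets)
    return store, pid, protocol, callsets


class TestProtocolPersistence:
    def test_marker_names_retrievable(self, stored):
        store, pid, _, _ = stored
        details = store.get_protocolprop(pid, "vcf_map_details")
        assert details["marker_names"] == ["S2_20032", "S2_20033"]

    def test_markers_document_is_name_to_mio(self, stored):
        store, pid, _, _ = stored
        doc = store.get_protocolprop(pid, "vcf_map_details_markers")
        assert doc["S2_20032"]["ref"] == "C"
        assert doc["S2_20032"]["alt"] == "G,T"

    def test_store_then_fetch_is_identity(self, stored):
        store, pid, protocol, _ = stored
        back = store.get_protocol(pid)
        assert back.marker_names == protocol.marker_names
        for n in protocol.marker_names:
            assert back.markers[n].to_json() == protocol.markers[n].to_json()

    def test_duplicate_protocol_name_conflicts(self, stored, example_protocol):
        store, _, _, _ = stored
        protocol, _ = example_protocol
        with pytest.raises(StoreConflictError):
            store.store_protocol(protocol)

    def test_indexed_marker_lookup_matches_fullscan(self, stored):
        store, pid, _, _ = stored
        for name in ("S2_20032", "S2_20033", "nonexistent"):
            assert store.protocols_with_marker(name) == \
                store.protocols_with_marker_fullscan(name)


class TestCallsetPersistence:
    def test_fetch_returns_exact_document(self, stored):
        store, pid, _, callsets = stored
        back = store.get_callset("SAMP1", pid)
        assert back.to_json() == callsets[0].to_json()

    def test_restore_same_pair_conflicts(self, stored):
        store, pid, _, callsets = stored
        with pytest.raises(StoreConflictError):
            store.store_callsets(pid, callsets)

    def test_unknown_sample_listed_in_error(self, stored, example_protocol):
        store, pid, _, _ = stored
        ghost = SampleCallset("GHOST", str(pid), {})
        with pytest.raises(KeyError, match="GHOST"):
            store.store_callsets(pid, [ghost])

    def test_experiment_links_resolve(self, stored):
        store, _, _, _ = stored
        assert store.consistency_sweep() == []


class TestNameCuration:
    def test_typographic_variant_flagged(self):
        store = GenotypeStore()
        store.add_stock("TX-303")
        report = store.register_samples(["Tx303"])
        assert "Tx303" in report.flagged
        cand, score = report.flagged["Tx303"][0]
        assert cand == "TX-303" and score == 1.0

    def test_identical_name_is_exact(self):
        store = GenotypeStore()
        store.add_stock("B73")
        report = store.register_samples(["B73"])
        assert report.exact == ["B73"] and not report.flagged

    def test_unrelated_name_is_new(self):
        report = GenotypeStore().register_samples(["Tx303"], catalogue=["Zm999"])
        assert report.new == ["Tx303"]
        assert name_similarity("Tx303", "Zm999") < 0.85

    def test_normalization(self):
        assert normalize_name("TX-303") == "TX303" == normalize_name("Tx303")
        assert name_similarity("Tx303", "TX-303") == 1.0


def _triploid_store():
    """Hand-enumerable fixture for the conjunctive genotype+phenotype query:
    marker S8_0880 (ref T), protocol-level DP=15/GQ=95, three stocks."""
    mio = MarkerInfo(name="S8_0880", chrom="8", pos=880, ref="T", alt=["A"],
                     format="GT:NT:DS", extra={"DP": "15", "GQ": "95"})
    protocol = GenotypingProtocol(
        protocol_id="p", name="2019_GT_MAP",
        marker_names=["S8_0880"], markers={"S8_0880": mio}, markers_array=[mio])
    store = GenotypeStore()
    pid = store.store_protocol(protocol)
    gts = {"stockA": "0/0/0", "stockB": "0/0/1", "stockC": "0|0|0"}
    for name, gt in gts.items():
        store.add_stock(name)
    callsets = []
    for name, gt in gts.items():
        call = cs.build_genotype_call(["GT"], [gt], mio)
        callsets.append(SampleCallset(name, str(pid), {"S8_0880": call}))
    store.store_callsets(pid, callsets)
    heights = {"stockA": "6", "stockB": "7", "stockC": "9"}
    store.store_phenotypes([
        PhenotypeRecord(n, "plant height in cm", v, "2019_CA_MT")
        for n, v in heights.items()
    ])
    return store, pid


class TestCrossEntityQueries:
    def test_markers_and_trait_conjunction(self, stored):
        store, pid, _, _ = stored
        store.store_phenotypes([
            PhenotypeRecord("SAMP1", "plant height in cm", "12", "2019_CA_MT")])
        hits = store.query_stocks_markers_and_trait(
            ["S2_20032", "S11_0112"], "plant height in cm", "2019_CA_MT")
        assert hits == ["SAMP1"]

    def test_empty_marker_list_empty_result(self, stored):
        store, _, _, _ = stored
        assert store.query_stocks_markers_and_trait(
            [], "plant height in cm", "2019_CA_MT") == []

    def test_trait_in_other_project_excluded(self, stored):
        store, _, _, _ = stored
        store.store_phenotypes([
            PhenotypeRecord("SAMP1", "plant height in cm", "12", "OTHER_TRIAL")])
        assert store.query_stocks_markers_and_trait(
            ["S2_20032"], "plant height in cm", "2019_CA_MT") == []

    def test_triploid_allele_and_threshold_query(self):
        store, _ = _triploid_store()
        hits = store.query_stocks_genotype_and_phenotype(
            "2019_GT_MAP", "S8_0880",
            marker_dp_min=10, marker_gq_min=90,
            required_nt="T,T,T", required_gt="0/0/0",
            trait_name="plant height in cm", trait_min=5)
        assert hits == ["stockA"]  # B fails NT/GT, C is phased

    def test_phased_call_fails_exact_gt_match(self):
        store, _ = _triploid_store()
        hits = store.query_stocks_genotype_and_phenotype(
            "2019_GT_MAP", "S8_0880", required_gt="0/0/0")
        assert "stockC" not in hits

    def test_trait_min_above_all_values_empty(self):
        store, _ = _triploid_store()
        assert store.query_stocks_genotype_and_phenotype(
            "2019_GT_MAP", "S8_0880", required_gt="0/0/0",
            trait_name="plant height in cm", trait_min=100) == []

    def test_protocol_dp_threshold_gates_everything(self):
        store, _ = _triploid_store()
        assert store.query_stocks_genotype_and_phenotype(
            "2019_GT_MAP", "S8_0880", marker_dp_min=20) == []

    def test_non_numeric_phenotype_skipped_with_warning(self, caplog):
        store, _ = _triploid_store()
        store.store_phenotypes([
            PhenotypeRecord("stockB", "plant height in cm", "tall", "2019_CA_MT")])
        import logging
        with caplog.at_level(logging.WARNING, logger="callstore.store"):
            hits = store.query_stocks_genotype_and_phenotype(
                "2019_GT_MAP", "S8_0880",
                trait_name="plant height in cm", trait_min=5)
        assert "non-numeric" in caplog.text
        assert "stockB" in hits  # its numeric record ("7") still qualifies

    def test_result_invariant_to_insertion_order(self):
        def build(order):
            mio = MarkerInfo(name="m1", chrom="1", pos=10, ref="A", alt=["C"])
            protocol = GenotypingProtocol(
                protocol_id="p", name="P", marker_names=["m1"],
                markers={"m1": mio}, markers_array=[mio])
            store = GenotypeStore()
            pid = store.store_protocol(protocol)
            for s in order:
                store.add_stock(s)
            store.store_callsets(pid, [
                SampleCallset(s, str(pid),
                              {"m1": cs.build_genotype_call(["GT"], ["0/1"], mio)})
                for s in order
            ])
            store.store_phenotypes([
                PhenotypeRecord(s, "t", "1", "proj") for s in order])
            return store.query_stocks_markers_and_trait(["m1"], "t", "proj")

        assert build(["a", "b", "c"]) == build(["c", "a", "b"])


class TestPedigree:
    def test_parents_roundtrip(self):
        store = GenotypeStore()
        for s in ("P1", "P2", "H1"):
            store.add_stock(s)
        store.load_pedigree([("H1", "P1", "P2")])
        assert store.get_parents("H1") == ("P1", "P2")
        assert store.get_parents("P1") is None

    def test_self_parenting_rejected(self):
        with pytest.raises(ValueError):
            PedigreeRecord("X", "X", "Y")


def test_generation_bumps_on_writes(stored):
    store, _, _, _ = stored
    g0 = store.generation
    store.add_stock("NEW1")
    assert store.generation == g0 + 1
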