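"""Persist protocols/callsets/phenotypes and query across them.

Shows the three stored protocol documents, fuzzy accession-name
curation, and the two cross-entity query styles: marker+trait+trial
membership, and exact NT/GT matching combined with a numeric trait
threshold.
"""

import callstore as cs
from callstore.fixtures import preset, generate_vcf, generate_phenotypes
from callstore.popgen import DosageMatrix
from callstore.store import PhenotypeRecord

vcf_text, truth = generate_vcf(preset("toy", seed=2))
header, block = cs.read_vcf(vcf_text)
protocol = cs.build_protocol(header, block, "pending", "2019_GT_MAP")
callsets = cs.transpose_to_sample_first(block, protocol)

store = cs.GenotypeStore()           # embedded, in-memory
pid = store.store_protocol(protocol)
for s in block.sample_names:
    store.add_stock(s)
store.store_callsets(pid, callsets)

details = store.get_protocolprop(pid, "vcf_map_details")
print("stored protocol keys:", sorted(details))
print("first markers:", details["marker_names"][:3])

# name curation: a typographic variant is flagged, never auto-merged
report = store.register_samples([block.sample_names[0],
                                 block.sample_names[1].lower() + "-",
                                 "UNRELATED999"])
print("\nname curation -> exact:", report.exact)
print("flagged near-matches:", {k: v[0] for k, v in report.flagged.items()})
print("new:", report.new)

dm = DosageMatrix.from_callsets(protocol, callsets)
store.store_phenotypes(generate_phenotypes(
    preset("toy", seed=2), truth, dm, trait_name="plant height in cm",
    project_name="2019_CA_MT"))

marker = protocol.marker_names[0]
hits = store.query_stocks_markers_and_trait(
    [marker], "plant height in cm", "2019_CA_MT")
print(f"\nstocks genotyped at {marker} AND phenotyped in 2019_CA_MT: "
      f"{len(hits)} (e.g. {hits[:3]})")

mio = protocol.markers[marker]
nt_hom_ref = ",".join([mio.ref, mio.ref])
rich = store.query_stocks_genotype_and_phenotype(
    "2019_GT_MAP", marker, required_nt=nt_hom_ref, required_gt="0/0",
    trait_name="plant height in cm", trait_min=90)
print(f"stocks with NT={nt_hom_ref}, GT=0/0 and trait > 90: {rich}")
# GT matching is exact string equality, so a phased "0|0" would not count.
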