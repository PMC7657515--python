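"""Progeny genotypes computed from genotyped parents.

Hybrids without their own genotyping get, per marker, the mean of
their two parents' dosages (NA if either parent is missing there);
fractional dosages are expected and flow into the GRM unchanged.
"""

import callstore as cs
from callstore.fixtures import preset, generate_vcf
from callstore.popgen import compute_from_parents
from callstore.store import PedigreeRecord

vcf_text, _ = generate_vcf(preset("toy", seed=6))
header, block = cs.read_vcf(vcf_text)
protocol = cs.build_protocol(header, block, "p", "founder_panel")
callsets = cs.transpose_to_sample_first(block, protocol)
by_name = {c.sample_name: c for c in callsets}
founders = block.sample_names

pedigree = [
    PedigreeRecord("HYB001", founders[0], founders[1]),
    PedigreeRecord("HYB002", founders[2], founders[3]),
    PedigreeRecord("HYB003", founders[0], "NOT_GENOTYPED"),
]
progeny, skipped = compute_from_parents(pedigree, by_name, protocol)
print(f"computed genotypes for {progeny.sample_names}; skipped {skipped} "
      "(fewer than two genotyped parents)")

m = protocol.marker_names[0]
i = progeny.marker_names.index(m)
p1 = by_name[founders[0]].calls[m].DS
p2 = by_name[founders[1]].calls[m].DS
print(f"\nmarker {m}: parent dosages {p1} and {p2} "
      f"-> HYB001 dosage {progeny.values[i, 0]}")
# A 2 x 1 cross gives 1.5 — a mid-parent expectation, not a real call,
# which is why these records carry DS only and no GT.
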