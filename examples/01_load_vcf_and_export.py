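"""Load a VCF into the sample-first model and export it back.

Generates a small synthetic VCF, transposes it into per-sample
callsets (deriving the NT nucleotide string and DS dosage for every
call), then writes both a VCF and a dosage matrix from the stored form.
"""

import callstore as cs
from callstore.fixtures import preset, generate_vcf

vcf_text, truth = generate_vcf(preset("toy", seed=1))
header, block = cs.read_vcf(vcf_text)
protocol = cs.build_protocol(header, block, "p1", "demo_protocol",
                             reference_genome_name="demo_ref_v1",
                             species_name="Zea mays")
callsets = cs.transpose_to_sample_first(block, protocol)

first = callsets[0]
marker = protocol.marker_names[0]
call = first.calls[marker]
print(f"sample {first.sample_name}, marker {marker}:")
print(f"  GT={call.GT}  NT={call.NT}  DS={call.DS}  extra={call.extra}")
# GT is the VCF allele-index string; NT spells it in nucleotides in the
# same order; DS counts the reference alleles (missing slots give NA).

out_vcf = "".join(cs.write_vcf(protocol, callsets,
                               sample_order=block.sample_names))
print("\nfirst exported data row (note NT/DS appended to FORMAT):")
print([ln for ln in out_vcf.splitlines() if not ln.startswith("#")][0])

dosage = list(cs.write_dosage_matrix(protocol, callsets))
print("\ndosage matrix head:")
print("".join(dosage[:3]), end="")
# Each row is one marker; cells are DS values, "NA" where the call is
# missing — this file feeds the GRM/GWAS steps directly.
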