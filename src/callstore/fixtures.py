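"""Deterministic synthetic genotype/phenotype/pedigree generators.

The generators emulate the shape of real genotyping-by-sequencing (GBS)
breeding datasets — a VCF with mixed phasing, missing calls,
multi-allelic sites and indels; replicated multi-environment trial
phenotypes; and hybrid pedigrees with the typographic name variants
that real pedigree files carry — at a scale where every query is
checkable by hand.  Every generator is a pure function of its spec:
the seed is mandatory and the same spec yields byte-identical output.

Per-marker allele frequencies are drawn from Beta(0.8, 0.8) truncated
to [0.05, 0.95], a U-shaped spread typical of GBS panels; read depths
follow a Poisson model so AD/DP/GQ carry realistic variation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .store import PedigreeRecord, PhenotypeRecord

__all__ = [
    "FixtureSpec",
    "PRESETS",
    "preset",
    "generate_vcf",
    "generate_phenotypes",
    "generate_pedigree",
    "make_fixture",
]

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset (all fractions in [0, 1])."""

    seed: int
    n_samples: int = 20
    n_markers: int = 50
    ploidy: int = 2
    phased_fraction: float = 0.1
    missing_rate: float = 0.05
    multiallelic_fraction: float = 0.1
    indel_fraction: float = 0.05
    n_chromosomes: int = 3
    n_locations: int = 2
    n_years: int = 2
    n_replicates: int = 2
    n_causal_markers: int = 1
    effect_size: float = 1.0
    heritability: float = 0.4
    mean_depth: float = 20.0
    n_progeny: int = 6

    def __post_init__(self) -> None:
        for name in ("phased_fraction", "missing_rate", "multiallelic_fraction",
                     "indel_fraction", "heritability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.ploidy not in (2, 3):
            raise ValueError("ploidy must be 2 or 3")
        for name in ("n_samples", "n_markers", "n_chromosomes", "n_locations",
                     "n_years", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


#: Toy-scale stand-ins for the three benchmark dataset shapes (a
#: triploid banana-like GBS panel, a diploid cassava-like panel, and a
#: diploid maize-like panel with hybrid pedigrees) plus a minimal toy.
PRESETS: dict[str, dict] = {
    "toy": dict(n_samples=10, n_markers=20, ploidy=2, n_chromosomes=2),
    "banana-like": dict(n_samples=30, n_markers=300, ploidy=3, n_chromosomes=4,
                        missing_rate=0.08),
    "cassava-like": dict(n_samples=40, n_markers=300, ploidy=2, n_chromosomes=4,
                         missing_rate=0.1),
    "maize-like": dict(n_samples=60, n_markers=500, ploidy=2, n_chromosomes=5,
                       missing_rate=0.05, n_progeny=10),
}


def preset(name: str, seed: int, **overrides) -> FixtureSpec:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return FixtureSpec(seed=seed, **kwargs)


def _sample_names(spec: FixtureSpec) -> list[str]:
    return [f"ACC{i + 1:04d}" for i in range(spec.n_samples)]


def generate_vcf(spec: FixtureSpec) -> tuple[str, dict]:
    """Emit VCF text plus a truth record of the generating parameters.

    The truth record retains per-marker alternate allele frequencies,
    the causal marker names and effect sizes, and the name lists —
    enough for recovery checks without re-deriving anything from the
    file.
    """
    rng = np.random.default_rng(spec.seed)
    samples = _sample_names(spec)

    # markers in contiguous chromosome blocks, positions increasing
    per_chrom = np.full(spec.n_chromosomes, spec.n_markers // spec.n_chromosomes)
    per_chrom[: spec.n_markers % spec.n_chromosomes] += 1
    chroms, positions = [], []
    for c, count in enumerate(per_chrom, start=1):
        pos = np.sort(rng.choice(np.arange(100, 100 + 1000 * max(count, 1) * 10, 10),
                                 size=count, replace=False))
        chroms.extend([str(c)] * count)
        positions.extend(int(p) for p in pos)

    freqs = np.clip(rng.beta(0.8, 0.8, size=spec.n_markers), 0.05, 0.95)
    causal_idx = sorted(
        rng.choice(spec.n_markers, size=min(spec.n_causal_markers, spec.n_markers),
                   replace=False).tolist()
    ) if spec.n_causal_markers else []

    header = [
        "##fileformat=VCFv4.3",
        "##source=callstore synthetic fixture",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    ]
    lines = list(header)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )

    marker_names = []
    for i in range(spec.n_markers):
        chrom, pos = chroms[i], positions[i]
        name = f"S{chrom}_{pos}"
        marker_names.append(name)
        ref, alt1, alt2 = rng.choice(_BASES, size=3, replace=False)
        n_alt = 2 if rng.random() < spec.multiallelic_fraction else 1
        alts = [alt1, alt2][:n_alt]
        if rng.random() < spec.indel_fraction:
            alts[0] = ref + "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
        p = freqs[i]
        af = f"{p:.3f}" if n_alt == 1 else f"{p * 0.7:.3f},{p * 0.3:.3f}"
        row = [chrom, str(pos), name, ref, ",".join(alts), "99", "PASS",
               f"AF={af}", "GT:AD:DP:GQ"]
        for _ in samples:
            if rng.random() < spec.missing_rate:
                gt = "/".join(["."] * spec.ploidy)
                row.append(f"{gt}:.:.:.")
                continue
            slots = []
            for _s in range(spec.ploidy):
                if rng.random() < p:
                    slots.append(str(int(rng.integers(1, n_alt + 1))))
                else:
                    slots.append("0")
            sep = "|" if rng.random() < spec.phased_fraction else "/"
            gt = sep.join(slots)
            dp = max(1, int(rng.poisson(spec.mean_depth)))
            counts = np.zeros(n_alt + 1, dtype=int)
            for s in slots:
                counts[int(s)] += 1
            ad = rng.multinomial(dp, counts / counts.sum())
            gq = int(min(99, rng.integers(30, 100)))
            row.append(f"{gt}:{','.join(map(str, ad))}:{dp}:{gq}")
        lines.append("\t".join(row))

    truth = {
        "spec": asdict(spec),
        "sample_names": samples,
        "marker_names": marker_names,
        "allele_freqs": freqs.tolist(),
        "causal_markers": [marker_names[i] for i in causal_idx],
        "effect_sizes": [spec.effect_size] * len(causal_idx),
        "heritability": spec.heritability,
    }
    return "\n".join(lines) + "\n", truth


def generate_phenotypes(
    spec: FixtureSpec,
    truth: dict,
    genotype_matrix,  # popgen.DosageMatrix over the fixture samples
    trait_name: str = "trait1",
    project_name: str = "trial1",
    trait_index: int = 0,
) -> list[PhenotypeRecord]:
    """Simulate plot-level phenotypes over the trial design.

    One observation per sample per (location, year, replicate) cell:
    ``y = mu + location + year + replicate + sum(causal dosage * effect)
    + polygenic + noise``.  The polygenic term is a genomic random
    effect (a weighted sum over all markers), and the noise variance is
    set so the genetic fraction of variance equals the spec's
    heritability; ``heritability = 0`` removes the genetic terms
    entirely.
    """
    rng = np.random.default_rng([spec.seed, 7919, trait_index])
    samples = list(genotype_matrix.sample_names)
    Xa = np.nan_to_num(genotype_matrix.alt_scaled(), nan=1.0)  # markers x samples

    causal = [m for m in truth.get("causal_markers", [])
              if m in genotype_matrix.marker_names]
    effects = truth.get("effect_sizes", [spec.effect_size] * len(causal))
    g_causal = np.zeros(len(samples))
    for name, eff in zip(causal, effects):
        k = genotype_matrix.marker_names.index(name)
        g_causal += eff * Xa[k]

    w = rng.normal(size=Xa.shape[0])
    g_poly = (Xa.T @ w) / np.sqrt(max(Xa.shape[0], 1))

    h2 = spec.heritability
    if h2 <= 0 or (not causal and np.allclose(g_poly.var(), 0)):
        g = np.zeros(len(samples))
        noise_sd = 1.0
    else:
        # split genetic variance between the causal and polygenic parts
        g_poly = g_poly - g_poly.mean()
        var_causal = float(np.var(g_causal))
        target_poly = max(var_causal, 0.5)  # polygenic background comparable
        if g_poly.std() > 0:
            g_poly = g_poly / g_poly.std() * np.sqrt(target_poly)
        g = g_causal + g_poly
        var_g = float(np.var(g))
        noise_sd = float(np.sqrt(var_g * (1 - h2) / h2)) if var_g > 0 else 1.0

    loc_effects = rng.normal(0, 1, size=spec.n_locations)
    year_effects = rng.normal(0, 1, size=spec.n_years)
    rep_effects = rng.normal(0, 0.5, size=spec.n_replicates)

    records = []
    for li in range(spec.n_locations):
        for yi in range(spec.n_years):
            for ri in range(spec.n_replicates):
                noise = rng.normal(0, noise_sd, size=len(samples))
                for j, s in enumerate(samples):
                    y = (100.0 + loc_effects[li] + year_effects[yi]
                         + rep_effects[ri] + g[j] + noise[j])
                    records.append(PhenotypeRecord(
                        uniquename=s, trait_name=trait_name, value=f"{y:.6f}",
                        project_name=project_name, location=f"loc{li + 1}",
                        year=str(2018 + yi), replicate=str(ri + 1),
                    ))
    return records


def generate_pedigree(
    spec: FixtureSpec, founders: Sequence[str] | None = None
) -> tuple[list[PedigreeRecord], dict[str, str]]:
    """Hybrid pedigree rows plus deliberate name misspellings.

    Each progeny gets two distinct genotyped founders.  A few parent
    names are emitted as case/punctuation variants (``Tx303`` ->
    ``TX-303`` style) to exercise the fuzzy name matcher; the returned
    mapping goes from variant to true name.
    """
    rng = np.random.default_rng([spec.seed, 104729])
    if founders is None:
        founders = _sample_names(spec)
    if len(founders) < 2:
        raise ValueError("need at least 2 founders")
    records = []
    misspellings: dict[str, str] = {}
    for i in range(spec.n_progeny):
        p1, p2 = rng.choice(len(founders), size=2, replace=False)
        name1, name2 = founders[p1], founders[p2]
        if i % 3 == 2:  # every third row carries a typo variant of parent1
            variant = f"{name1[:3].lower()}-{name1[3:]}"
            misspellings[variant] = name1
            name1_out = variant
        else:
            name1_out = name1
        records.append(PedigreeRecord(
            progeny=f"HYB{i + 1:03d}", parent1=name1_out, parent2=name2
        ))
    return records, misspellings


def make_fixture(spec: FixtureSpec, outdir: str | Path) -> dict[str, str]:
    """Write vcf + phenotypes.csv + pedigree.csv + truth.json to a
    directory; returns the paths."""
    from .popgen import DosageMatrix
    from .vcf_io import build_protocol, read_vcf, transpose_to_sample_first

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vcf_text, truth = generate_vcf(spec)
    vcf_path = outdir / "fixture.vcf"
    vcf_path.write_text(vcf_text)

    header, block = read_vcf(vcf_text)
    protocol = build_protocol(header, block, "p1", "fixture_protocol")
    callsets = transpose_to_sample_first(block, protocol)
    dm = DosageMatrix.from_callsets(protocol, callsets, ploidy=spec.ploidy)

    pheno_path = outdir / "phenotypes.csv"
    with open(pheno_path, "w") as fh:
        fh.write("uniquename,trait,value,project,location,year,replicate\n")
        for t_idx, trait in enumerate(("trait1", "trait2")):
            for r in generate_phenotypes(spec, truth, dm, trait_name=trait,
                                         trait_index=t_idx):
                fh.write(f"{r.uniquename},{r.trait_name},{r.value},"
                         f"{r.project_name},{r.location},{r.year},{r.replicate}\n")

    ped_records, misspellings = generate_pedigree(spec)
    ped_path = outdir / "pedigree.csv"
    with open(ped_path, "w") as fh:
        fh.write("progeny,parent1,parent2\n")
        for rec in ped_records:
            fh.write(f"{rec.progeny},{rec.parent1},{rec.parent2}\n")

    truth["misspellings"] = misspellings
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1))
    return {
        "vcf": str(vcf_path),
        "phenotypes": str(pheno_path),
        "pedigree": str(ped_path),
        "truth": str(truth_path),
    }
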