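"""End-to-end convenience pipelines over a populated store.

These are the library equivalents of the packaged GRM/GWAS queries: fetch
callsets (optionally computing progeny genotypes from genotyped
parents), build the dosage matrix, filter, impute, and hand off to the
genetics layer.
"""

from __future__ import annotations

from typing import Sequence

from .popgen import (
    DosageMatrix,
    FilterParams,
    FilterReport,
    GwasResult,
    KinshipMatrix,
    compute_grm,
    filter_dosage,
    impute_em,
    mid_parent_dosage,
    run_gwas,
)
from .store import GenotypeStore

__all__ = ["dosage_from_store", "grm_pipeline", "gwas_pipeline"]


def dosage_from_store(
    store: GenotypeStore,
    protocol_id: int,
    sample_names: Sequence[str],
    compute_from_parents: bool = False,
) -> tuple[DosageMatrix, list[str]]:
    """Dosage matrix for the requested samples under one protocol.

    With ``compute_from_parents`` the samples are treated as progeny and
    receive mid-parent dosages; samples without two genotyped parents
    are skipped and reported.  Otherwise samples without a stored
    callset are the skipped ones.
    """
    protocol = store.get_protocol(protocol_id)
    genotyped = set(store.genotyped_samples(protocol_id))
    callsets, skipped = [], []
    for s in sample_names:
        if compute_from_parents:
            parents = None
            try:
                parents = store.get_parents(s)
            except KeyError:
                pass
            if parents is None or not set(parents) <= genotyped:
                skipped.append(s)
                continue
            cs1 = store.get_callset(parents[0], protocol_id)
            cs2 = store.get_callset(parents[1], protocol_id)
            callsets.append(mid_parent_dosage(s, cs1, cs2, protocol))
        else:
            if s not in genotyped:
                skipped.append(s)
                continue
            callsets.append(store.get_callset(s, protocol_id))
    dm = DosageMatrix.from_callsets(protocol, callsets)
    return dm, skipped


def grm_pipeline(
    store: GenotypeStore,
    protocol_id: int,
    sample_names: Sequence[str],
    params: FilterParams | None = None,
    compute_from_parents: bool = False,
) -> tuple[KinshipMatrix, FilterReport]:
    """Filter -> impute -> VanRaden GRM for the requested samples."""
    dm, _ = dosage_from_store(store, protocol_id, sample_names,
                              compute_from_parents)
    filtered, report = filter_dosage(dm, params)
    complete = impute_em(filtered)
    return compute_grm(complete), report


def gwas_pipeline(
    store: GenotypeStore,
    protocol_id: int,
    sample_names: Sequence[str],
    trait_names: Sequence[str],
    params: FilterParams | None = None,
    traits_are_repeated_measurements: bool = False,
    compute_from_parents: bool = False,
) -> GwasResult:
    """Filter -> impute -> GRM -> kinship mixed-model scan."""
    dm, _ = dosage_from_store(store, protocol_id, sample_names,
                              compute_from_parents)
    filtered, _ = filter_dosage(dm, params)
    complete = impute_em(filtered)
    K = compute_grm(complete)
    protocol = store.get_protocol(protocol_id)
    marker_meta = {
        name: (protocol.markers[name].chrom, protocol.markers[name].pos)
        for name in complete.marker_names
        if name in protocol.markers
    }
    phenotypes = store.get_phenotypes(
        stock_names=list(complete.sample_names), trait_names=list(trait_names)
    )
    return run_gwas(
        phenotypes, complete, K,
        traits_are_repeated_measurements=traits_are_repeated_measurements,
        marker_meta=marker_meta,
    )
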