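"""Dosage filtering, EM imputation, GRM and mid-parent genotypes."""

import numpy as np
import pytest

from callstore.datamodel import NA, GenotypeCall, GenotypingProtocol, MarkerInfo, SampleCallset
from callstore.popgen import (
    DosageMatrix,
    EmptyMatrixError,
    FilterParams,
    KinshipMatrix,
    compute_from_parents,
    compute_grm,
    filter_dosage,
    format_grm,
    grm_heatmap,
    impute_em,
    marker_maf,
    mid_parent_dosage,
    parse_grm_matrix,
)
from callstore.store import PedigreeRecord

from conftest import sim_dosage


def _dm(values, convention="alternate", ploidy=2, markers=None, samples=None):
    values = np.asarray(values, dtype=float)
    markers = markers or [f"m{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return DosageMatrix(markers, samples, values, convention, ploidy)


NAN = float("nan")


class TestFilterDosage:
    # 4 markers x 5 samples; s4 is entirely missing; m2 has 3/4 missing
    # among surviving samples; m3 is monomorphic (all zero).
    TOY = [
        [0, 1, 2, 1, NAN],
        [1, 0, 1, 2, NAN],
        [NAN, NAN, NAN, 2, NAN],
        [0, 0, 0, 0, NAN],
    ]

    def test_hand_counted_default_filtering(self):
        m = _dm(self.TOY)
        out, report = filter_dosage(m, FilterParams())
        assert report.samples_dropped_missing == ["s4"]    # 100% > 80%
        assert report.markers_dropped_missing == ["m2"]    # 75% > 60%
        assert report.markers_dropped_maf == ["m3"]        # MAF 0 < 0.01
        assert out.marker_names == ["m0", "m1"]
        assert out.sample_names == ["s0", "s1", "s2", "s3"]

    def test_extreme_thresholds_are_identity(self):
        m = _dm(self.TOY)
        out, report = filter_dosage(
            m, FilterParams(minor_allele_frequency=0.0, marker_filter=1.0,
                            individuals_filter=1.0))
        assert out.marker_names == m.marker_names
        assert out.sample_names == m.sample_names
        assert sum(report.counts().values()) == 0

    def test_idempotent(self):
        out1, _ = filter_dosage(_dm(self.TOY), FilterParams())
        out2, rep2 = filter_dosage(out1, FilterParams())
        assert out2.marker_names == out1.marker_names
        assert out2.sample_names == out1.sample_names
        assert sum(rep2.counts().values()) == 0

    def test_all_markers_removed_names_binding_filter(self):
        m = _dm([[0, 0], [0, 0]])
        with pytest.raises(EmptyMatrixError, match="allele_frequency"):
            filter_dosage(m, FilterParams())

    def test_maf_respects_reference_convention(self):
        ref = _dm([[2, 2, 2, 1]], convention="reference")
        alt = _dm([[0, 0, 0, 1]], convention="alternate")
        assert marker_maf(ref) == pytest.approx(marker_maf(alt))

    def test_threshold_bounds_validated(self):
        with pytest.raises(ValueError):
            FilterParams(minor_allele_frequency=1.5)


class TestImputeEm:
    def test_complete_matrix_is_fixed_point(self):
        m = sim_dosage(np.random.default_rng(0), 6, 12)
        out = impute_em(m)
        np.testing.assert_array_equal(out.values, m.values)

    def test_constant_marker_single_gap_imputes_constant(self):
        vals = np.array([
            [2, 2, 2, 2, NAN],
            [0, 0, 0, 0, 0.0],
            [1, 1, 1, 1, 1.0],
            [2, 0, 1, 2, 0.0],
            [0, 2, 2, 0, 1.0],
        ])
        out = impute_em(_dm(vals), tolerance=1e-8)
        assert out.values[0, 4] == pytest.approx(2.0, abs=0.05)
        assert not np.isnan(out.values).any()

    def test_beats_marker_mean_on_structured_matrix(self):
        """Mask 5% of a relatedness-structured matrix; EM should exploit
        the duplicated-sample structure that mean-imputation ignores."""
        rng = np.random.default_rng(42)
        base = sim_dosage(rng, 6, 150)
        # three pairs of near-duplicate samples -> strong sample covariance
        noise = (rng.random(base.values.shape) < 0.05) * rng.choice(
            [-1.0, 1.0], size=base.values.shape)
        dup = np.clip(base.values + noise, 0, 2)
        vals = np.concatenate([base.values, dup], axis=1)
        samples = base.sample_names + [s + "_dup" for s in base.sample_names]
        truth = vals.copy()
        mask = rng.random(vals.shape) < 0.05
        vals = vals.copy()
        vals[mask] = np.nan
        m = DosageMatrix(base.marker_names, samples, vals, "alternate", 2)

        out = impute_em(m, tolerance=1e-5, max_iterations=200)
        em_rmse = float(np.sqrt(np.mean((out.values[mask] - truth[mask]) ** 2)))

        col_filled = vals.copy()
        row_mean = np.nanmean(col_filled, axis=1)
        mean_rmse = float(np.sqrt(np.mean(
            (np.take(row_mean, np.where(mask)[0]) - truth[mask]) ** 2)))
        assert em_rmse < mean_rmse

    def test_all_missing_marker_rejected(self):
        with pytest.raises(ValueError):
            impute_em(_dm([[NAN, NAN], [0, 1]]))


def brute_force_vanraden(m: DosageMatrix) -> np.ndarray:
    """Element-by-element evaluation of G_ij = sum_k w_ki w_kj / c."""
    Xa = m.alt_scaled()
    n_mark, n_samp = Xa.shape
    p = [sum(Xa[k]) / (2 * n_samp) for k in range(n_mark)]
    mean = [sum(Xa[k]) / n_samp for k in range(n_mark)]
    c = sum(2 * pk * (1 - pk) for pk in p)
    G = np.zeros((n_samp, n_samp))
    for i in range(n_samp):
        for j in range(n_samp):
            G[i, j] = sum(
                (Xa[k, i] - mean[k]) * (Xa[k, j] - mean[k]) for k in range(n_mark)
            ) / c
    return G


class TestGrm:
    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for rep in range(5):
            m = sim_dosage(rng, 5, 8)
            G = compute_grm(m).values
            np.testing.assert_allclose(G, brute_force_vanraden(m), atol=1e-10)

    def test_duplicating_every_marker_leaves_grm_unchanged(self):
        m = sim_dosage(np.random.default_rng(6), 5, 8)
        dup = DosageMatrix(
            m.marker_names + [n + "_b" for n in m.marker_names],
            m.sample_names, np.vstack([m.values, m.values]),
            m.dosage_convention, m.ploidy)
        np.testing.assert_allclose(compute_grm(dup).values,
                                   compute_grm(m).values, atol=1e-12)

    def test_identical_samples_share_row_and_diagonal(self):
        m = sim_dosage(np.random.default_rng(7), 4, 6)
        vals = m.values.copy()
        vals[:, 1] = vals[:, 0]
        G = compute_grm(_dm(vals)).values
        assert G[0, 1] == pytest.approx(G[0, 0], abs=1e-12)
        np.testing.assert_allclose(G[0], G[1], atol=1e-12)

    def test_monomorphic_matrix_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            compute_grm(_dm([[0, 0, 0], [2, 2, 2]]))

    def test_triploid_dosages_rescaled_to_diploid_range(self):
        m = _dm([[0, 3, 3], [3, 0, 0]], ploidy=3)
        assert float(m.alt_scaled().max()) == pytest.approx(2.0)
        G = compute_grm(m).values
        assert np.isfinite(G).all()


class TestGrmFormats:
    def _k(self):
        m = sim_dosage(np.random.default_rng(8), 6, 4)
        return compute_grm(m)

    def test_three_column_row_count(self):
        K = self._k()
        n = len(K.sample_names)
        rows = list(format_grm(K, "three_column"))
        assert len(rows) == n * (n + 1) // 2

    def test_three_column_values_match_matrix_cells(self):
        K = self._k()
        cells = {}
        for line in format_grm(K, "three_column"):
            a, b, v = line.rstrip("\n").split("\t")
            cells[(a, b)] = float(v)
        for i, si in enumerate(K.sample_names):
            for j in range(i + 1):
                assert cells[(si, K.sample_names[j])] == K.values[i, j]

    def test_matrix_tsv_roundtrip(self):
        K = self._k()
        back = parse_grm_matrix("".join(format_grm(K, "matrix")))
        assert back.sample_names == K.sample_names
        np.testing.assert_array_equal(back.values, K.values)

    def test_heatmap_ships_with_underlying_tsv(self, tmp_path):
        K = self._k()
        paths = grm_heatmap(K, tmp_path / "grm.pdf", tmp_path / "grm.tsv")
        assert (tmp_path / "grm.pdf").stat().st_size > 0
        back = parse_grm_matrix((tmp_path / "grm.tsv").read_text())
        np.testing.assert_array_equal(back.values, K.values)


def _parent_fixture():
    mios = [MarkerInfo(name=f"m{i}", chrom="1", pos=10 + i, ref="A", alt=["C"])
            for i in range(3)]
    protocol = GenotypingProtocol(
        protocol_id="p", name="P", marker_names=[m.name for m in mios],
        markers={m.name: m for m in mios}, markers_array=mios)

    def callset(name, dosages):
        calls = {}
        for m, ds in zip(mios, dosages):
            calls[m.name] = GenotypeCall(GT="./." if ds == NA else "0/1",
                                         NT=".", DS=ds)
        return SampleCallset(name, "p", calls)

    parents = {
        "P1": callset("P1", [2, 2, NA]),
        "P2": callset("P2", [0, 1, 1]),
    }
    return protocol, parents


class TestComputeFromParents:
    def test_mid_parent_means_and_na_propagation(self):
        protocol, parents = _parent_fixture()
        ped = [PedigreeRecord("H1", "P1", "P2")]
        dm, skipped = compute_from_parents(ped, parents, protocol)
        assert skipped == []
        assert dm.values[0, 0] == 1.0          # (2+0)/2
        assert dm.values[1, 0] == 1.5          # (2+1)/2, fractional allowed
        assert np.isnan(dm.values[2, 0])       # parent NA propagates

    def test_ungenotyped_parent_skipped_and_reported(self):
        protocol, parents = _parent_fixture()
        ped = [PedigreeRecord("H1", "P1", "GHOST"),
               PedigreeRecord("H2", "P1", "P2")]
        dm, skipped = compute_from_parents(ped, parents, protocol)
        assert skipped == ["H1"]
        assert dm.sample_names == ["H2"]

    def test_identical_parents_reproduce_parent_grm_row(self):
        rng = np.random.default_rng(9)
        base = sim_dosage(rng, 8, 5)
        mios = [MarkerInfo(name=n, chrom="1", pos=10 + i, ref="A", alt=["C"])
                for i, n in enumerate(base.marker_names)]
        protocol = GenotypingProtocol(
            protocol_id="p", name="P", marker_names=base.marker_names,
            markers={m.name: m for m in mios}, markers_array=mios)
        parents = {}
        for j, s in enumerate(base.sample_names):
            calls = {n: GenotypeCall(GT="0/1", NT=".",
                                     DS=int(2 - base.values[i, j]))
                     for i, n in enumerate(base.marker_names)}
            parents[s] = SampleCallset(s, "p", calls)
        # PedigreeRecord forbids self-parenting; emulate identical parents
        # via a duplicate-genotype stock instead.
        dup_name = "CLONE0"
        parents[dup_name] = SampleCallset(dup_name, "p",
                                          parents[base.sample_names[0]].calls)
        ped = [PedigreeRecord("SELF1", base.sample_names[0], dup_name)]
        prog, _ = compute_from_parents(ped, parents, protocol)
        np.testing.assert_array_equal(
            prog.values[:, 0],
            2 - base.values[:, 0])  # reference-convention parent dosages

        combined = DosageMatrix(
            base.marker_names, base.sample_names + ["SELF1"],
            np.concatenate([2 - base.values, prog.values], axis=1),
            "reference", 2)
        G = compute_grm(combined).values
        np.testing.assert_allclose(G[-1], G[0], atol=1e-12)

    def test_mid_parent_callset_has_no_gt(self):
        protocol, parents = _parent_fixture()
        cs_ = mid_parent_dosage("H1", parents["P1"], parents["P2"], protocol)
        assert all(c.GT == "./." for c in cs_.calls.values())
        assert cs_.calls["m1"].DS == 1.5


def test_kinship_matrix_validates_shape_and_symmetry():
    with pytest.raises(ValueError):
        KinshipMatrix(["a", "b"], np.array([[1.0, 0.5], [0.4, 1.0]]))
    with pytest.raises(ValueError):
        KinshipMatrix(["a"], np.array([[np.inf]]))
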