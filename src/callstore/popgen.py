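"""Downstream genetics on dosage matrices.

The chain mirrors the standard breeding workflow: filter a dosage
matrix by missingness and minor allele frequency, impute the remaining
gaps with an expectation-maximization (EM) algorithm, compute a genomic
relationship matrix (GRM, VanRaden method 1), and run a kinship
mixed-model association scan with the P3D approximation (variance
components estimated once under the null, reused for every marker).

Dosage conventions: a matrix records either reference-allele counts
(the storage default) or alternate-allele counts (what association and
prediction tools expect).  All genetics here converts internally to
alternate counts rescaled to a diploid-equivalent [0, 2] range, so
triploid protocols and fractional mid-parent dosages flow through the
same formulas.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datamodel import NA, GenotypeCall, GenotypingProtocol, SampleCallset
from .store import PedigreeRecord, PhenotypeRecord

__all__ = [
    "DosageMatrix",
    "FilterParams",
    "FilterReport",
    "KinshipMatrix",
    "GwasResult",
    "filter_dosage",
    "impute_em",
    "compute_grm",
    "format_grm",
    "parse_grm_matrix",
    "grm_heatmap",
    "compute_from_parents",
    "mid_parent_dosage",
    "run_gwas",
    "format_gwas",
    "gwas_plots",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# dosage matrix


@dataclass
class DosageMatrix:
    """Markers x samples dosage table; missing entries are NaN."""

    marker_names: list[str]
    sample_names: list[str]
    values: np.ndarray  # float, shape (markers, samples), NaN = missing
    dosage_convention: str = "reference"
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.marker_names), len(self.sample_names)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.marker_names)} markers x {len(self.sample_names)} samples"
            )
        with np.errstate(invalid="ignore"):
            if np.any(self.values[~np.isnan(self.values)] < 0) or np.any(
                self.values[~np.isnan(self.values)] > self.ploidy
            ):
                raise ValueError(f"dosages must lie in [0, {self.ploidy}] or be NaN")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.marker_names, columns=self.sample_names
        )

    def alt_scaled(self) -> np.ndarray:
        """Alternate-count dosages rescaled to the diploid [0, 2] range."""
        v = self.values
        if self.dosage_convention == "reference":
            v = self.ploidy - v
        return v * (2.0 / self.ploidy)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @classmethod
    def from_callsets(
        cls,
        protocol: GenotypingProtocol,
        callsets: Sequence[SampleCallset],
        dosage_convention: str = "reference",
        ploidy: int | None = None,
    ) -> "DosageMatrix":
        samples = [cs.sample_name for cs in callsets]
        markers = list(protocol.marker_names)
        vals = np.full((len(markers), len(samples)), np.nan)
        max_ploidy = 2
        for j, cs in enumerate(callsets):
            for i, name in enumerate(markers):
                call = cs.calls.get(name)
                if call is None:
                    continue
                vals[i, j] = call.dosage_value()
                if call.GT and call.GT != "./.":
                    try:
                        max_ploidy = max(max_ploidy, call.ploidy)
                    except ValueError:
                        pass
        return cls(markers, samples, vals,
                   dosage_convention=dosage_convention,
                   ploidy=ploidy if ploidy is not None else max_ploidy)

    @classmethod
    def from_tsv(
        cls,
        source: str | IO[str] | Iterable[str],
        dosage_convention: str = "reference",
        ploidy: int = 2,
    ) -> "DosageMatrix":
        """Read the ``Marker``-headed TSV emitted by the dosage writer."""
        if isinstance(source, str):
            lines = source.splitlines()
        else:
            lines = [ln.rstrip("\n") for ln in source]
        header = lines[0].split("\t")
        samples = header[1:]
        markers, rows = [], []
        for line in lines[1:]:
            if not line:
                continue
            parts = line.split("\t")
            markers.append(parts[0])
            rows.append([np.nan if c == NA else float(c) for c in parts[1:]])
        return cls(markers, samples, np.array(rows).reshape(len(markers), len(samples)),
                   dosage_convention=dosage_convention, ploidy=ploidy)


# ---------------------------------------------------------------------------
# filtering


@dataclass
class FilterParams:
    """Pre-GRM filter thresholds.

    ``minor_allele_frequency``: markers below this MAF are dropped.
    ``marker_filter`` / ``individuals_filter``: maximum tolerated
    missing fraction per marker / per sample.
    """

    minor_allele_frequency: float = 0.01
    marker_filter: float = 0.6
    individuals_filter: float = 0.8

    def __post_init__(self) -> None:
        for name in ("minor_allele_frequency", "marker_filter", "individuals_filter"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class FilterReport:
    samples_dropped_missing: list[str] = field(default_factory=list)
    markers_dropped_missing: list[str] = field(default_factory=list)
    markers_dropped_maf: list[str] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {
            "samples_dropped_missing": len(self.samples_dropped_missing),
            "markers_dropped_missing": len(self.markers_dropped_missing),
            "markers_dropped_maf": len(self.markers_dropped_maf),
        }


class EmptyMatrixError(RuntimeError):
    """Filtering removed everything; names the binding filter."""


def marker_maf(m: DosageMatrix) -> np.ndarray:
    """Per-marker minor allele frequency from mean dosage."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        p = np.nanmean(m.alt_scaled(), axis=1) / 2.0
    return np.minimum(p, 1.0 - p)


def filter_dosage(
    m: DosageMatrix, params: FilterParams | None = None
) -> tuple[DosageMatrix, FilterReport]:
    """Filter samples then markers by missingness, then markers by MAF.

    Order matters and is fixed: samples whose missing fraction exceeds
    ``individuals_filter`` go first, marker missingness and allele
    frequencies are then recomputed on the surviving samples.
    """
    params = params or FilterParams()
    report = FilterReport()

    miss = m.missing_mask()
    n_mark = len(m.marker_names)
    sample_missing = miss.mean(axis=0) if n_mark else np.zeros(len(m.sample_names))
    keep_s = sample_missing <= params.individuals_filter
    report.samples_dropped_missing = [
        s for s, k in zip(m.sample_names, keep_s) if not k
    ]
    if not keep_s.any():
        raise EmptyMatrixError(
            "individuals_filter removed every sample "
            f"(threshold {params.individuals_filter})"
        )

    vals = m.values[:, keep_s]
    samples = [s for s, k in zip(m.sample_names, keep_s) if k]
    inter = DosageMatrix(m.marker_names, samples, vals,
                         dosage_convention=m.dosage_convention, ploidy=m.ploidy)

    marker_missing = inter.missing_mask().mean(axis=1)
    keep_miss = marker_missing <= params.marker_filter
    report.markers_dropped_missing = [
        n for n, k in zip(inter.marker_names, keep_miss) if not k
    ]
    if not keep_miss.any():
        raise EmptyMatrixError(
            f"marker_filter removed every marker (threshold {params.marker_filter})"
        )

    inter2 = DosageMatrix(
        [n for n, k in zip(inter.marker_names, keep_miss) if k],
        samples, inter.values[keep_miss],
        dosage_convention=m.dosage_convention, ploidy=m.ploidy,
    )
    maf = marker_maf(inter2)
    keep_maf = maf >= params.minor_allele_frequency
    report.markers_dropped_maf = [
        n for n, k in zip(inter2.marker_names, keep_maf) if not k
    ]
    if not keep_maf.any():
        raise EmptyMatrixError(
            "minor_allele_frequency removed every marker "
            f"(threshold {params.minor_allele_frequency})"
        )
    out = DosageMatrix(
        [n for n, k in zip(inter2.marker_names, keep_maf) if k],
        samples, inter2.values[keep_maf],
        dosage_convention=m.dosage_convention, ploidy=m.ploidy,
    )
    return out, report


# ---------------------------------------------------------------------------
# EM imputation


def impute_em(
    m: DosageMatrix, tolerance: float = 1e-4, max_iterations: int = 100
) -> DosageMatrix:
    """Impute missing dosages by EM under a multivariate normal model.

    Each marker row is treated as one draw from an n-sample multivariate
    normal whose covariance captures sample relatedness; missing cells
    are replaced by their conditional expectation given the observed
    cells of the same marker, and mean/covariance are re-estimated until
    the imputed values move less than ``tolerance``.  A matrix with no
    missing cells is returned unchanged.
    """
    miss = m.missing_mask()
    if not miss.any():
        return DosageMatrix(list(m.marker_names), list(m.sample_names),
                            m.values.copy(), m.dosage_convention, m.ploidy)
    if miss.all(axis=1).any() or miss.all(axis=0).any():
        raise ValueError("impute_em requires no all-missing marker or sample")

    X = m.values.copy()
    n_mark, n_samp = X.shape
    col_mean = np.nanmean(X, axis=0)
    X[miss] = np.take(col_mean, np.where(miss)[1])

    rows_with_missing = np.where(miss.any(axis=1))[0]
    prev = X[miss].copy()
    converged = False
    for _ in range(max_iterations):
        mu = X.mean(axis=0)
        Xc = X - mu
        S = (Xc.T @ Xc) / n_mark
        ridge = 1e-6 * (np.trace(S) / n_samp + 1e-12)
        S_reg = S + ridge * np.eye(n_samp)
        for i in rows_with_missing:
            mis = miss[i]
            obs = ~mis
            Soo = S_reg[np.ix_(obs, obs)]
            Smo = S_reg[np.ix_(mis, obs)]
            resid = X[i, obs] - mu[obs]
            X[i, mis] = mu[mis] + Smo @ np.linalg.solve(Soo, resid)
        cur = X[miss]
        delta = np.max(np.abs(cur - prev))
        prev = cur.copy()
        if delta < tolerance:
            converged = True
            break
    if not converged:
        logger.warning(
            "EM imputation did not converge in %d iterations (last delta %.3g)",
            max_iterations, delta,
        )
    np.clip(X, 0.0, float(m.ploidy), out=X)
    return DosageMatrix(list(m.marker_names), list(m.sample_names), X,
                        m.dosage_convention, m.ploidy)


# ---------------------------------------------------------------------------
# GRM


@dataclass
class KinshipMatrix:
    """Symmetric genomic relationship matrix over samples."""

    sample_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_names)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix must be square over sample_names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("kinship matrix entries must be finite")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_names,
                            columns=self.sample_names)

    def reorder(self, sample_names: Sequence[str]) -> "KinshipMatrix":
        idx = [self.sample_names.index(s) for s in sample_names]
        return KinshipMatrix(list(sample_names), self.values[np.ix_(idx, idx)])


def compute_grm(m: DosageMatrix) -> KinshipMatrix:
    """VanRaden method-1 GRM: G = W'W / (sum 2 p_k (1 - p_k)).

    W holds per-marker mean-centered alternate dosages on the diploid
    [0, 2] scale; p_k is the alternate allele frequency.  Duplicating a
    marker scales numerator and normalizer alike, leaving G unchanged.
    """
    if len(m.sample_names) < 2:
        raise ValueError("GRM needs at least two samples")
    if m.missing_mask().any():
        raise ValueError("GRM requires a complete (imputed) dosage matrix")
    Xa = m.alt_scaled()
    p = Xa.mean(axis=1) / 2.0
    W = Xa - Xa.mean(axis=1, keepdims=True)
    c = float(np.sum(2.0 * p * (1.0 - p)))
    if c <= 0.0:
        raise ValueError("all markers are monomorphic; GRM normalizer is zero")
    G = (W.T @ W) / c
    G = (G + G.T) / 2.0  # enforce exact symmetry against rounding
    return KinshipMatrix(list(m.sample_names), G)


def format_grm(K: KinshipMatrix, fmt: str = "matrix") -> Iterator[str]:
    """Render a GRM as TSV lines.

    ``matrix``: header row/column of sample names.  ``three_column``:
    ``sample_i<TAB>sample_j<TAB>value`` for the lower triangle including
    the diagonal (the layout mixed-model tools ingest).
    """
    if fmt == "matrix":
        yield "\t".join(["sample"] + K.sample_names) + "\n"
        for i, s in enumerate(K.sample_names):
            yield "\t".join([s] + [repr(float(v)) for v in K.values[i]]) + "\n"
    elif fmt == "three_column":
        for i, si in enumerate(K.sample_names):
            for j in range(i + 1):
                yield f"{si}\t{K.sample_names[j]}\t{float(K.values[i, j])!r}\n"
    else:
        raise ValueError("fmt must be 'matrix' or 'three_column' (see grm_heatmap)")


def parse_grm_matrix(source: str | Iterable[str]) -> KinshipMatrix:
    lines = source.splitlines() if isinstance(source, str) else [
        ln.rstrip("\n") for ln in source
    ]
    names = lines[0].split("\t")[1:]
    vals = [[float(x) for x in ln.split("\t")[1:]] for ln in lines[1:] if ln]
    return KinshipMatrix(names, np.array(vals))


def grm_heatmap(K: KinshipMatrix, out_pdf, out_tsv) -> list[str]:
    """Write the GRM heatmap figure and its underlying matrix TSV."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    with open(out_tsv, "w") as fh:
        fh.writelines(format_grm(K, "matrix"))
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(K.values, cmap="viridis")
    ax.set_title("Genomic relationship matrix")
    ax.set_xticks(range(len(K.sample_names)))
    ax.set_yticks(range(len(K.sample_names)))
    if len(K.sample_names) <= 30:
        ax.set_xticklabels(K.sample_names, rotation=90, fontsize=6)
        ax.set_yticklabels(K.sample_names, fontsize=6)
    else:
        ax.set_xticklabels([])
        ax.set_yticklabels([])
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(out_pdf)
    plt.close(fig)
    return [str(out_pdf), str(out_tsv)]


# ---------------------------------------------------------------------------
# compute-from-parents


def mid_parent_dosage(
    progeny_name: str,
    parent1: SampleCallset,
    parent2: SampleCallset,
    protocol: GenotypingProtocol,
) -> SampleCallset:
    """Synthesize a progeny callset whose DS is the parents' mean.

    Fractional means have no integer GT, so GT is left missing and only
    DS (plus NT ``"."``) is carried.  Either parent missing at a marker
    makes the progeny missing there.
    """
    calls: dict[str, GenotypeCall] = {}
    for name in protocol.marker_names:
        c1, c2 = parent1.calls.get(name), parent2.calls.get(name)
        if c1 is None or c2 is None or c1.DS == NA or c2.DS == NA:
            ds: object = NA
        else:
            mean = (float(c1.DS) + float(c2.DS)) / 2.0
            ds = int(mean) if mean.is_integer() else mean
        calls[name] = GenotypeCall(GT="./.", NT=".", DS=ds)
    return SampleCallset(sample_name=progeny_name,
                         protocol_id=protocol.protocol_id, calls=calls)


def compute_from_parents(
    pedigree: Sequence[PedigreeRecord],
    parent_callsets: Mapping[str, SampleCallset],
    protocol: GenotypingProtocol,
    dosage_convention: str = "reference",
    ploidy: int = 2,
) -> tuple[DosageMatrix, list[str]]:
    """Mid-parent dosage matrix for progeny of genotyped parents.

    Progeny with fewer than two genotyped parents are skipped and
    reported, never errored.
    """
    callsets, skipped = [], []
    for rec in pedigree:
        p1 = parent_callsets.get(rec.parent1)
        p2 = parent_callsets.get(rec.parent2)
        if p1 is None or p2 is None:
            skipped.append(rec.progeny)
            continue
        callsets.append(mid_parent_dosage(rec.progeny, p1, p2, protocol))
    if not callsets:
        return (
            DosageMatrix(list(protocol.marker_names), [],
                         np.empty((len(protocol.marker_names), 0)),
                         dosage_convention, ploidy),
            skipped,
        )
    # mid-parent means are fractional; build values directly
    markers = list(protocol.marker_names)
    vals = np.full((len(markers), len(callsets)), np.nan)
    for j, cs in enumerate(callsets):
        for i, name in enumerate(markers):
            vals[i, j] = cs.calls[name].dosage_value()
    return (
        DosageMatrix(markers, [cs.sample_name for cs in callsets], vals,
                     dosage_convention, ploidy),
        skipped,
    )


# ---------------------------------------------------------------------------
# mixed-model GWAS


@dataclass
class GwasResult:
    """Association scan results: one row per (trait, marker)."""

    table: pd.DataFrame  # columns: trait, marker, chrom, pos, score, p_value
    metadata: dict = field(default_factory=dict)


def _design_matrix(
    records: Sequence[PhenotypeRecord],
) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-coded location/year/replicate factors.

    Confounded (rank-deficient) columns are dropped with a warning so a
    sparse design never breaks the fit.
    """
    df = pd.DataFrame(
        {
            "location": [r.location or "NA" for r in records],
            "year": [r.year or "NA" for r in records],
            "replicate": [r.replicate or "NA" for r in records],
        }
    )
    X = pd.get_dummies(df, drop_first=True, dtype=float)
    cols = ["intercept"] + list(X.columns)
    M = np.column_stack([np.ones(len(records)), X.to_numpy()]) if len(X.columns) else (
        np.ones((len(records), 1))
    )
    # pivoted QR to find and drop linearly dependent columns
    from scipy.linalg import qr

    _, R, piv = qr(M, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(M.shape) * np.finfo(float).eps * (diag[0] if diag.size else 1.0)
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    dropped = [cols[i] for i in piv[rank:]]
    if dropped:
        logger.warning("dropping confounded design columns: %s", dropped)
    return M[:, keep], [cols[i] for i in keep]


def _reml_delta(
    yt: np.ndarray, Xt: np.ndarray, s: np.ndarray
) -> tuple[float, float, float]:
    """Profile REML over delta = sigma_e^2 / sigma_g^2 in the rotated
    model; returns (delta, sigma_g^2, sigma_e^2)."""
    n, p = Xt.shape

    def neg_restricted_ll(log_delta: float) -> float:
        d = s + np.exp(log_delta)
        w = 1.0 / d
        XtW = Xt * w[:, None]
        XtWX = Xt.T @ XtW
        beta = np.linalg.solve(XtWX, XtW.T @ yt)
        resid = yt - Xt @ beta
        rss = float(np.sum(resid**2 * w))
        sigma_g2 = rss / (n - p)
        _, logdet_XtWX = np.linalg.slogdet(XtWX)
        _, logdet_XtX = np.linalg.slogdet(Xt.T @ Xt)
        ll = -0.5 * (
            (n - p) * np.log(2 * np.pi * sigma_g2)
            + (n - p)
            + np.sum(np.log(d))
            + logdet_XtWX
            - logdet_XtX
        )
        return -ll

    grid = np.linspace(np.log(1e-5), np.log(1e5), 61)
    vals = [neg_restricted_ll(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(lo, hi),
                                   method="bounded")
    delta = float(np.exp(res.x))
    d = s + delta
    w = 1.0 / d
    XtW = Xt * w[:, None]
    beta = np.linalg.solve(Xt.T @ XtW, XtW.T @ yt)
    rss = float(np.sum((yt - Xt @ beta) ** 2 * w))
    sigma_g2 = rss / (n - Xt.shape[1])
    return delta, sigma_g2, sigma_g2 * delta


def _marker_scan(
    yt: np.ndarray, Xt: np.ndarray, Gt: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker generalized least squares t-test of the marker effect.

    ``Gt`` holds one rotated marker column per row; ``weights`` are the
    inverse rotated variances.  Returns (p_values, effects).
    """
    n, p = Xt.shape
    df = n - p - 1
    if df <= 0:
        raise ValueError("fewer observations than model parameters")
    pvals = np.ones(Gt.shape[0])
    effects = np.zeros(Gt.shape[0])
    sw = np.sqrt(weights)
    Xw = Xt * sw[:, None]
    yw = yt * sw
    for k in range(Gt.shape[0]):
        xw = Gt[k] * sw
        A = np.column_stack([Xw, xw])
        AtA = A.T @ A
        Aty = A.T @ yw
        try:
            beta = np.linalg.solve(AtA, Aty)
            cov_unscaled = np.linalg.inv(AtA)
        except np.linalg.LinAlgError:
            continue  # marker collinear with the design; p = 1
        resid = yw - A @ beta
        sigma2 = float(resid @ resid) / df
        se = np.sqrt(sigma2 * cov_unscaled[-1, -1])
        if se == 0 or not np.isfinite(se):
            continue
        t = beta[-1] / se
        pvals[k] = 2.0 * stats.t.sf(abs(t), df)
        effects[k] = beta[-1]
    return pvals, effects


def run_gwas(
    phenotypes: Sequence[PhenotypeRecord],
    dosage: DosageMatrix,
    K: KinshipMatrix,
    traits_are_repeated_measurements: bool = False,
    marker_meta: Mapping[str, tuple[str, int]] | None = None,
    variance_components: tuple[float, float] | None = None,
    reml_per_marker: bool = False,
) -> GwasResult:
    """Kinship mixed-model association scan.

    Model per observation: ``y = X beta + x_m alpha_m + u + e`` with
    ``u ~ N(0, sigma_g^2 K)`` at the sample level and ``X`` encoding
    intercept, location, year and replicate.  Variance components are
    estimated once by spectral REML under the null and reused for every
    marker (P3D); set ``reml_per_marker=True`` for exact per-marker
    REML.  ``variance_components=(sigma_g2, sigma_e2)`` bypasses
    estimation (with ``sigma_g2=0`` the scan reduces to ordinary least
    squares).  Scores are ``-log10 p``.

    Repeated-measurements mode pools every trait's records as replicate
    observations of a single trait; otherwise each trait is scanned
    independently.
    """
    if dosage.missing_mask().any():
        raise ValueError("GWAS requires a complete (imputed) dosage matrix")

    geno_samples = list(dosage.sample_names)
    sample_idx = {s: i for i, s in enumerate(geno_samples)}
    Xa = dosage.alt_scaled()  # markers x samples, [0, 2]

    records = [
        r for r in phenotypes
        if r.uniquename in sample_idx and r.numeric_value() is not None
    ]
    skipped = [r for r in phenotypes if r.numeric_value() is None]
    if skipped:
        logger.warning("skipping %d non-numeric phenotype values", len(skipped))
    if not records:
        raise ValueError("no numeric phenotypes overlap the genotyped samples")

    if traits_are_repeated_measurements:
        trait_groups = {
            "+".join(sorted({r.trait_name for r in records})): records
        }
    else:
        trait_groups = {}
        for r in records:
            trait_groups.setdefault(r.trait_name, []).append(r)

    Kv = K.reorder(geno_samples).values
    rows = []
    meta: dict = {"traits": {}, "model": "MLM kinship (P3D spectral REML)",
                  "dosage_scale": "alternate [0,2] diploid-equivalent"}
    for trait, recs in trait_groups.items():
        y = np.array([r.numeric_value() for r in recs], dtype=float)
        obs_sample = [sample_idx[r.uniquename] for r in recs]
        X, fixed_names = _design_matrix(recs)
        n, p = X.shape
        if n <= p:
            raise ValueError(
                f"trait {trait!r}: {n} observations for {p} fixed-effect columns"
            )

        Z = np.zeros((n, len(geno_samples)))
        Z[np.arange(n), obs_sample] = 1.0
        H = Z @ Kv @ Z.T
        s, U = np.linalg.eigh(H)
        s = np.clip(s, 0.0, None)
        yt = U.T @ y
        Xt = U.T @ X
        Gt_full = (Xa @ Z.T) @ U  # markers x n, rotated marker columns
        Gt = np.ascontiguousarray(Gt_full)

        if variance_components is not None:
            sigma_g2, sigma_e2 = variance_components
            if sigma_g2 <= 0:
                weights = np.full(n, 1.0 / sigma_e2)
                delta = np.inf
            else:
                delta = sigma_e2 / sigma_g2
                weights = 1.0 / (s + delta)
        else:
            delta, sigma_g2, sigma_e2 = _reml_delta(yt, Xt, s)
            weights = 1.0 / (s + delta)

        if reml_per_marker and variance_components is None:
            pvals = np.ones(Gt.shape[0])
            effects = np.zeros(Gt.shape[0])
            for k in range(Gt.shape[0]):
                Xk = np.column_stack([Xt, Gt[k]])
                dk, _, _ = _reml_delta(yt, Xk, s)
                pk, ek = _marker_scan(yt, Xt, Gt[k:k + 1], 1.0 / (s + dk))
                pvals[k], effects[k] = pk[0], ek[0]
        else:
            pvals, effects = _marker_scan(yt, Xt, Gt, weights)

        meta["traits"][trait] = {
            "n_obs": n,
            "fixed_effects": fixed_names,
            "delta": float(delta) if np.isfinite(delta) else "inf",
            "sigma_g2": float(sigma_g2),
            "sigma_e2": float(sigma_e2),
        }
        for k, name in enumerate(dosage.marker_names):
            chrom, pos = (
                marker_meta[name] if marker_meta and name in marker_meta
                else ("0", k + 1)
            )
            pv = float(pvals[k])
            rows.append(
                {
                    "trait": trait,
                    "marker": name,
                    "chrom": str(chrom),
                    "pos": int(pos),
                    "p_value": pv,
                    "score": float(-np.log10(max(pv, 1e-300))),
                    "effect": float(effects[k]),
                }
            )
    table = pd.DataFrame(rows, columns=[
        "trait", "marker", "chrom", "pos", "p_value", "score", "effect"
    ])
    return GwasResult(table=table, metadata=meta)


def format_gwas(r: GwasResult, fmt: str = "results_tsv") -> Iterator[str]:
    """Render scan results as TSV lines (``trait`` .. ``score``)."""
    if fmt != "results_tsv":
        raise ValueError("fmt must be 'results_tsv' (see gwas_plots)")
    yield "trait\tmarker\tchrom\tpos\tscore\n"
    for row in r.table.itertuples(index=False):
        yield (f"{row.trait}\t{row.marker}\t{row.chrom}\t{int(row.pos)}\t"
               f"{float(row.score)!r}\n")


def gwas_plots(r: GwasResult, out_prefix) -> list[str]:
    """Manhattan and QQ figures plus their underlying TSVs.

    QQ expected quantiles are ``-log10((i - 0.5) / k)`` for the *i*-th
    smallest p-value of *k*.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_prefix = str(out_prefix)
    paths = []
    tsv = out_prefix + "_results.tsv"
    with open(tsv, "w") as fh:
        fh.writelines(format_gwas(r))
    paths.append(tsv)

    for trait, sub in r.table.groupby("trait", sort=True):
        tag = "".join(c if c.isalnum() else "_" for c in trait)
        fig, ax = plt.subplots(figsize=(8, 3))
        offset = 0
        for ci, (chrom, chunk) in enumerate(sub.groupby("chrom", sort=True)):
            chunk = chunk.sort_values("pos")
            ax.scatter(offset + chunk["pos"], chunk["score"], s=8,
                       color=f"C{ci % 10}", label=str(chrom))
            offset += int(chunk["pos"].max()) + 1
        ax.set_xlabel("position (concatenated chromosomes)")
        ax.set_ylabel("-log10 p")
        ax.set_title(f"Manhattan: {trait}")
        man = f"{out_prefix}_{tag}_manhattan.pdf"
        fig.tight_layout()
        fig.savefig(man)
        plt.close(fig)
        paths.append(man)

        obs = np.sort(sub["p_value"].to_numpy())
        k = len(obs)
        exp = -np.log10((np.arange(1, k + 1) - 0.5) / k)
        obs_l = -np.log10(np.maximum(obs, 1e-300))
        qq_tsv = f"{out_prefix}_{tag}_qq.tsv"
        with open(qq_tsv, "w") as fh:
            fh.write("expected\tobserved\n")
            for e, o in zip(exp, obs_l):
                fh.write(f"{float(e)!r}\t{float(o)!r}\n")
        paths.append(qq_tsv)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(exp, obs_l, s=8)
        lim = max(float(exp.max()), float(obs_l.max()), 1.0)
        ax.plot([0, lim], [0, lim], color="grey", lw=1)
        ax.set_xlabel("expected -log10 p")
        ax.set_ylabel("observed -log10 p")
        ax.set_title(f"QQ: {trait}")
        qq = f"{out_prefix}_{tag}_qq.pdf"
        fig.tight_layout()
        fig.savefig(qq)
        plt.close(fig)
        paths.append(qq)
    return paths
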