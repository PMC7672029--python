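"""Pooled-frequency genotype container, SNP selection, kinship and M_eff.

Genotypes are pool-seq allele frequencies: each accession is a DNA pool of
several plants, and each SNP is scored as the proportion of the panel-major
allele in the pool, a continuous dosage in [0, 1]. SNP selection applies,
in order: 100% call rate, biallelic frequency sum >= 0.95, minor allele
frequency >= 2%, and major-allele-frequency standard deviation >= 0.1.

The genomic relationship matrix follows the VanRaden construction on the
0-2 dosage scale (dosage = 2 x major-allele proportion):
K = Z Z' / (2 sum_j p_j (1 - p_j)), Z the column-centred dosage matrix.

The effective number of independent markers (the Bonferroni divisor) uses
the Li-Ji eigenvalue decomposition of marker correlation matrices, applied
per scaffold in windows of bounded size and summed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import QCThresholds

logger = logging.getLogger(__name__)

ALLELES = ("A", "C", "G", "T")

_MARKER_RE = re.compile(r"^(?P<scaffold>.+)_(?P<pos>\d+)$")


def parse_marker_id(marker_id: str) -> tuple[str, int]:
    """Split 'scaffold82158_8091' or 'C32110397_2120' into (scaffold, position)."""
    m = _MARKER_RE.match(marker_id)
    if m is None:
        raise ValueError(f"marker id {marker_id!r} does not parse to scaffold_position")
    return m.group("scaffold"), int(m.group("pos"))


@dataclass
class GenotypeMatrix:
    """Accession x marker matrix of panel-major-allele proportions.

    ``markers`` is a DataFrame with columns marker_id, scaffold, position,
    major, minor and optionally top2_sum (mean frequency sum of the two most
    frequent alleles, used by the biallelic filter). ``values`` has shape
    (n_accessions, n_markers); NaN marks missing calls (pre-filter only).
    """

    accessions: list[str]
    markers: pd.DataFrame
    values: np.ndarray

    def __post_init__(self) -> None:
        self.accessions = list(self.accessions)
        self.values = np.asarray(self.values, dtype=float)
        self.markers = self.markers.reset_index(drop=True)
        if self.values.shape != (len(self.accessions), len(self.markers)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.accessions)} accessions x {len(self.markers)} markers"
            )
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("non-missing genotype values must lie in [0, 1]")

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return self.markers["marker_id"].tolist()

    def column(self, marker_id: str) -> np.ndarray:
        idx = self.markers.index[self.markers["marker_id"] == marker_id]
        if len(idx) == 0:
            raise KeyError(f"marker {marker_id} not in matrix")
        return self.values[:, idx[0]]

    def subset_markers(self, marker_ids) -> "GenotypeMatrix":
        order = {m: i for i, m in enumerate(self.markers["marker_id"])}
        cols = [order[m] for m in marker_ids]
        return GenotypeMatrix(
            self.accessions,
            self.markers.iloc[cols].reset_index(drop=True),
            self.values[:, cols].copy(),
        )

    def subset_accessions(self, accession_ids) -> "GenotypeMatrix":
        order = {a: i for i, a in enumerate(self.accessions)}
        rows = [order[a] for a in accession_ids]
        return GenotypeMatrix(
            list(accession_ids), self.markers.copy(), self.values[rows].copy()
        )


def score_major_allele(freq_table: pd.DataFrame) -> GenotypeMatrix:
    """Score each SNP as the proportion of the panel-major allele.

    ``freq_table`` is long-format with columns accession_id, marker_id and
    A, C, G, T per-accession allele frequencies (optionally scaffold and
    position; otherwise parsed from the marker id). The panel-major allele
    of a marker is the allele with the largest mean frequency over all
    accessions; ties break by the fixed allele order A < C < G < T (logged).
    Per-accession allele frequencies must sum to 1 within 1e-6.
    """
    required = {"accession_id", "marker_id", *ALLELES}
    missing = required - set(freq_table.columns)
    if missing:
        raise ValueError(f"frequency table missing columns {sorted(missing)}")

    sums = freq_table[list(ALLELES)].sum(axis=1)
    bad = freq_table.loc[(sums - 1.0).abs() > 1e-6, "marker_id"].unique()
    if len(bad):
        raise ValueError(
            "allele frequencies do not sum to 1 for markers: "
            + ", ".join(map(str, bad[:10]))
        )

    accessions = list(pd.unique(freq_table["accession_id"]))
    marker_ids = list(pd.unique(freq_table["marker_id"]))
    wide = {
        a: freq_table.pivot(index="accession_id", columns="marker_id", values=a)
        .reindex(index=accessions, columns=marker_ids)
        .to_numpy()
        for a in ALLELES
    }
    stack = np.stack([wide[a] for a in ALLELES])  # (4, n_acc, n_markers)
    mean_freqs = np.nanmean(stack, axis=1)  # (4, n_markers)

    # argmax with fixed-order tie-break: argmax returns the first maximum,
    # and ALLELES is already in the fixed order A < C < G < T
    major_idx = np.argmax(mean_freqs, axis=0)
    n_ties = int((np.sum(mean_freqs == mean_freqs.max(axis=0), axis=0) > 1).sum())
    if n_ties:
        logger.info(
            "score_major_allele: %d markers with tied major-allele means; "
            "broken by allele order A<C<G<T", n_ties,
        )

    values = np.take_along_axis(
        stack, major_idx[None, None, :].repeat(len(accessions), axis=1), axis=0
    )[0]
    sorted_means = np.sort(mean_freqs, axis=0)
    top2_sum = sorted_means[-1] + sorted_means[-2]
    minor_idx = np.argsort(mean_freqs, axis=0, kind="stable")[-2]

    scaffolds, positions = zip(*(parse_marker_id(m) for m in marker_ids))
    markers = pd.DataFrame(
        {
            "marker_id": marker_ids,
            "scaffold": scaffolds,
            "position": positions,
            "major": [ALLELES[i] for i in major_idx],
            "minor": [ALLELES[i] for i in minor_idx],
            "top2_sum": top2_sum,
        }
    )
    return GenotypeMatrix(accessions, markers, values)


FILTER_RULES = ("call_rate", "biallelic", "maf", "major_freq_sd")


def filter_snps(
    g: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the four SNP-selection rules; return the surviving matrix and a
    report of markers removed per rule (in application order).

    Rules: (1) call rate >= call_rate_min (default 1.0: no missing values);
    (2) biallelic: top-two allele frequency sum >= biallelic_sum_min (passes
    trivially when the matrix carries no ``top2_sum`` metadata); (3) minor
    allele frequency >= maf_min, i.e. mean major proportion <= 1 - maf_min;
    (4) standard deviation of the major-allele proportion >= major_freq_sd_min.
    """
    t = thresholds or QCThresholds()
    v = g.values
    n_acc = v.shape[0]

    call_rate = 1.0 - np.isnan(v).sum(axis=0) / n_acc
    mean_major = np.nanmean(np.where(np.isnan(v), np.nan, v), axis=0)
    sd_major = np.nanstd(v, axis=0, ddof=1)
    if "top2_sum" in g.markers.columns:
        top2 = g.markers["top2_sum"].to_numpy(dtype=float)
    else:
        top2 = np.ones(g.n_markers)

    keep = np.ones(g.n_markers, dtype=bool)
    removed = {}
    for rule, pred in (
        ("call_rate", call_rate >= t.call_rate_min),
        ("biallelic", top2 >= t.biallelic_sum_min),
        ("maf", mean_major <= 1.0 - t.maf_min),
        ("major_freq_sd", sd_major >= t.major_freq_sd_min),
    ):
        newly = keep & ~pred
        removed[rule] = int(newly.sum())
        keep &= pred

    report = pd.DataFrame(
        {"rule": list(FILTER_RULES), "removed_count": [removed[r] for r in FILTER_RULES]}
    )
    if not keep.any():
        logger.warning("filter_snps: no markers survived the filters")
    out = GenotypeMatrix(
        g.accessions, g.markers.loc[keep].reset_index(drop=True), v[:, keep].copy()
    )
    logger.info(
        "filter_snps: %d of %d markers retained", out.n_markers, g.n_markers
    )
    return out, report


@dataclass
class KinshipMatrix:
    """Genomic relationship matrix over accessions (the K of the mixed model)."""

    accessions: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.accessions = list(self.accessions)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.accessions)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape inconsistent with accessions")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix not symmetric")
        eigmin = float(np.linalg.eigvalsh(self.values).min())
        if eigmin < -1e-8:
            raise ValueError(f"kinship matrix not PSD (min eigenvalue {eigmin:.3g})")

    def subset(self, accession_ids) -> "KinshipMatrix":
        order = {a: i for i, a in enumerate(self.accessions)}
        idx = np.array([order[a] for a in accession_ids])
        return KinshipMatrix(list(accession_ids), self.values[np.ix_(idx, idx)])


def compute_kinship(g: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden genomic relationship matrix from pooled-frequency dosages.

    Dosage x = 2 x major-allele proportion (0-2 scale); Z is the
    column-centred dosage matrix; K = Z Z' / (2 sum_j p_j (1 - p_j)) with
    p_j the mean proportion of marker j. Markers fixed at 0 or 1 carry no
    information and are excluded from both the product and the scaling sum.
    """
    if g.n_accessions < 2:
        raise ValueError("kinship needs at least 2 accessions")
    if np.isnan(g.values).any():
        raise ValueError("kinship requires a complete (filtered) matrix")
    p = g.values.mean(axis=0)
    informative = (p > 0.0) & (p < 1.0)
    if informative.sum() < 1:
        raise ValueError("kinship needs at least 1 polymorphic marker")
    dosage = 2.0 * g.values[:, informative]
    pbar = p[informative]
    Z = dosage - dosage.mean(axis=0, keepdims=True)
    denom = 2.0 * float(np.sum(pbar * (1.0 - pbar)))
    K = (Z @ Z.T) / denom
    K = 0.5 * (K + K.T)
    return KinshipMatrix(g.accessions, K)


def _li_ji(corr: np.ndarray) -> float:
    """Li-Ji effective test count from a correlation matrix: for eigenvalues
    lambda_i, M_eff = sum_i [ 1(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ]."""
    lam = np.linalg.eigvalsh(corr)
    lam = np.clip(lam, 0.0, None)
    # round before flooring: the formula is discontinuous at integers and
    # eigenvalues of exact-duplicate blocks land there up to FP noise
    lam = np.round(lam, 8)
    return float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))


def effective_marker_number(g: GenotypeMatrix, window: int = 200) -> float:
    """Effective number of independent markers, summed over per-scaffold
    correlation blocks of at most ``window`` markers (markers ordered by
    position within scaffold). Satisfies 1 <= M_eff <= M."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if np.isnan(g.values).any():
        raise ValueError("M_eff requires a complete (filtered) matrix")
    total = 0.0
    markers = g.markers.assign(_col=np.arange(g.n_markers))
    for _, block in markers.groupby("scaffold", sort=False):
        cols = block.sort_values("position")["_col"].to_numpy()
        for start in range(0, len(cols), window):
            chunk = cols[start : start + window]
            sub = g.values[:, chunk]
            sd = sub.std(axis=0)
            n_const = int((sd == 0).sum())
            total += n_const  # constant markers count as independent singletons
            sub = sub[:, sd > 0]
            if sub.shape[1] == 1:
                total += 1.0
            elif sub.shape[1] > 1:
                corr = np.corrcoef(sub, rowvar=False)
                total += _li_ji(corr)
    return min(total, float(g.n_markers)) if g.n_markers else 0.0
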