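"""MultiQTL modelling: forward selection with collinearity clustering,
explained variance, marker-profile PCA and cross-location consolidation.

A QTL is a cluster of significant, mutually collinear markers represented
by the member that explains the most phenotypic variance. Forward selection
repeatedly picks the remaining candidate with the largest incremental
explained variance, then absorbs every candidate correlated with it at
|r| >= r_threshold (default 0.3, i.e. r^2 >= 0.1 on the genotype profiles)
as members of that QTL. The full model's explained variance is the squared
Pearson correlation between fitted and observed trait values.

QTLs are consolidated across locations by correlating representative
markers between the per-location models: connected components of the
|r| >= r_threshold graph that span at least two locations are reported as
cross-location QTLs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .qc import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class QTL:
    representative: str
    members: list[str]
    trait: str
    location_id: str
    incremental_r2: float
    order: int


@dataclass
class MultiQTLModel:
    trait: str
    location_id: str
    qtls: list[QTL] = field(default_factory=list)
    full_r2: float = float("nan")

    @property
    def representatives(self) -> list[str]:
        return [q.representative for q in self.qtls]

    @property
    def all_markers(self) -> list[str]:
        out = []
        for q in self.qtls:
            out.append(q.representative)
            out.extend(q.members)
        return out


@dataclass
class CrossLocationQTL:
    """Correlated representative markers spanning >= 2 locations."""

    name: str
    trait: str
    members: dict[str, list[str]]  # location_id -> representative marker ids

    @property
    def n_locations(self) -> int:
        return len(self.members)


def _complete_case(
    y: pd.Series | np.ndarray, g: GenotypeMatrix
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(y, pd.Series):
        y = y.reindex(g.accessions).to_numpy(dtype=float)
    else:
        y = np.asarray(y, dtype=float)
    mask = ~np.isnan(y)
    return y[mask], g.values[mask, :]


def _r2_fitted_vs_observed(X: np.ndarray, yv: np.ndarray) -> float:
    """Squared Pearson correlation between least-squares fitted values
    (design = intercept + X) and the observed trait values."""
    design = np.column_stack([np.ones(len(yv)), X])
    coef, _, rank, _ = np.linalg.lstsq(design, yv, rcond=None)
    fitted = design @ coef
    if np.std(fitted) == 0 or np.std(yv) == 0:
        return 0.0
    r = np.corrcoef(fitted, yv)[0, 1]
    return float(r * r)


def explained_variance(
    representatives: list[str] | MultiQTLModel,
    g: GenotypeMatrix,
    y: pd.Series | np.ndarray,
) -> float:
    """Explained variance of a joint model on the representative markers:
    r^2 between fitted and observed trait values."""
    if isinstance(representatives, MultiQTLModel):
        representatives = representatives.representatives
    if not representatives:
        raise ValueError("explained_variance needs a non-empty model")
    yv, G = _complete_case(y, g)
    cols = {m: i for i, m in enumerate(g.markers["marker_id"])}
    X = G[:, [cols[m] for m in representatives]]
    design = np.column_stack([np.ones(len(yv)), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("representative set is collinear; cannot fit jointly")
    return _r2_fitted_vs_observed(X, yv)


def forward_select(
    significant: pd.DataFrame,
    g: GenotypeMatrix,
    y: pd.Series | np.ndarray,
    config: AnalysisConfig | None = None,
    trait: str = "",
    location_id: str = "",
) -> MultiQTLModel:
    """Build the MultiQTL model from the significant scan records.

    Each iteration selects, among remaining candidates, the marker with the
    largest incremental explained variance given the representatives already
    in the model (at the first step this is the largest marginal r^2 with
    the trait; ties break by larger Wald, then lexicographic marker id).
    Every remaining candidate with |r| >= r_threshold to the new
    representative becomes a member of that QTL and leaves candidacy, so the
    input markers end up partitioned into representatives and members.
    """
    config = config or AnalysisConfig()
    trait = trait or (significant["trait"].iloc[0] if len(significant) else "")
    location_id = location_id or (
        significant["location_id"].iloc[0] if len(significant) else ""
    )
    model = MultiQTLModel(trait=trait, location_id=location_id)
    if len(significant) == 0:
        logger.info("forward_select: empty significant list; empty model")
        return model

    marker_ids = significant["marker_id"].tolist()
    wald = dict(zip(significant["marker_id"], significant["wald"]))
    yv, G = _complete_case(y, g)
    cols = {m: i for i, m in enumerate(g.markers["marker_id"])}
    missing = [m for m in marker_ids if m not in cols]
    if missing:
        raise KeyError(f"significant markers absent from genotype matrix: {missing[:5]}")

    X = G[:, [cols[m] for m in marker_ids]]
    candidates = list(range(len(marker_ids)))
    chosen: list[int] = []
    base_r2 = 0.0
    corr = np.corrcoef(X, rowvar=False) if len(marker_ids) > 1 else np.ones((1, 1))

    while candidates:
        best = None
        for j in candidates:
            r2 = _r2_fitted_vs_observed(X[:, chosen + [j]], yv)
            key = (r2, wald[marker_ids[j]], _NegStr(marker_ids[j]))
            if best is None or key > best[0]:
                best = (key, j, r2)
        _, j_star, full_r2 = best
        inc = full_r2 - base_r2
        members = [
            k for k in candidates
            if k != j_star and abs(corr[j_star, k]) >= config.r_threshold
        ]
        model.qtls.append(
            QTL(
                representative=marker_ids[j_star],
                members=[marker_ids[k] for k in members],
                trait=trait,
                location_id=location_id,
                incremental_r2=float(inc),
                order=len(model.qtls) + 1,
            )
        )
        chosen.append(j_star)
        drop = set(members) | {j_star}
        candidates = [k for k in candidates if k not in drop]
        base_r2 = full_r2

    model.full_r2 = _r2_fitted_vs_observed(X[:, chosen], yv)
    return model


class _NegStr(str):
    """Reverses string comparison so that max() prefers the lexicographically
    smallest marker id on ties."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def pca_marker_profiles(
    g: GenotypeMatrix, records: pd.DataFrame
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the allele-frequency profiles of significant markers.

    Markers are the observations, accessions the variables: the significant
    rows of g' (markers x accessions) are column-centred and decomposed by
    SVD. Returns per-marker (PC1, PC2, neg_log10_p) - the coordinates of the
    3D QTL-cluster plots - plus the PC variance fractions. Sign convention:
    the largest-magnitude loading of each PC is positive.
    """
    sig = records.loc[records["significant"], ["marker_id", "neg_log10_p"]]
    if len(sig) < 3:
        raise ValueError(f"PCA needs at least 3 significant markers, got {len(sig)}")
    sub = g.subset_markers(sig["marker_id"].tolist())
    M = sub.values.T  # markers x accessions
    M = M - M.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    # fix signs from the loadings (rows of Vt)
    for k in range(min(2, len(S))):
        i = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, i] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U * S
    var_frac = (S**2) / float(np.sum(S**2))
    out = pd.DataFrame(
        {
            "marker_id": sig["marker_id"].to_numpy(),
            "PC1": scores[:, 0],
            "PC2": scores[:, 1] if scores.shape[1] > 1 else 0.0,
            "neg_log10_p": sig["neg_log10_p"].to_numpy(),
        }
    )
    return out, var_frac


def consolidate_across_locations(
    models: list[MultiQTLModel],
    g: GenotypeMatrix,
    config: AnalysisConfig | None = None,
) -> list[CrossLocationQTL]:
    """Group representative markers from different-location models into
    cross-location QTLs.

    Pearson |r| is computed between the genotype vectors of every pair of
    representatives from different locations; edges at |r| >= r_threshold
    define a graph whose connected components spanning >= 2 locations are
    reported, named QTL_<trait>_<k>. Components confined to one location are
    dropped. The output is invariant to the ordering of the input models
    (components are numbered by their smallest (marker, location) node).
    """
    config = config or AnalysisConfig()
    traits = {m.trait for m in models}
    if len(traits) != 1:
        raise ValueError(f"models mix traits {sorted(traits)}; consolidate one trait")
    trait = traits.pop()
    if len({m.location_id for m in models}) < 2:
        raise ValueError("need models from at least 2 locations")

    nodes = sorted(
        {(q.representative, m.location_id) for m in models for q in m.qtls}
    )
    if not nodes:
        return []
    cols = {m: i for i, m in enumerate(g.markers["marker_id"])}
    vec = {n: g.values[:, cols[n[0]]] for n in nodes}

    parent = list(range(len(nodes)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if nodes[i][1] == nodes[j][1]:
                continue  # edges only between different locations
            xi, xj = vec[nodes[i]], vec[nodes[j]]
            if np.std(xi) == 0 or np.std(xj) == 0:
                continue
            r = np.corrcoef(xi, xj)[0, 1]
            if abs(r) >= config.r_threshold:
                union(i, j)

    components: dict[int, list[tuple[str, str]]] = {}
    for i, node in enumerate(nodes):
        components.setdefault(find(i), []).append(node)

    out: list[CrossLocationQTL] = []
    k = 0
    for root in sorted(components):  # root index order == smallest-node order
        comp = components[root]
        locs = {loc for _, loc in comp}
        if len(locs) < 2:
            continue
        k += 1
        members: dict[str, list[str]] = {}
        for marker, loc in comp:
            members.setdefault(loc, []).append(marker)
        for loc in members:
            members[loc] = sorted(set(members[loc]))
        out.append(CrossLocationQTL(name=f"QTL_{trait}_{k}", trait=trait, members=members))
    return out
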