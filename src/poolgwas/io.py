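"""Readers and writers for the pipeline's tabular formats.

Everything is plain text: genotype matrices and marker metadata as TSV,
temperature series and plot phenology as CSV, scan results, MultiQTL
models, cross-location QTL tables and motif hits as TSV with headers.
Writers and readers round-trip: reading a written file reproduces the
in-memory object.
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .multiqtl import QTL, MultiQTLModel, CrossLocationQTL
from .phenology import PlotPhenologyRecord, TemperatureSeries
from .qc import GenotypeMatrix, KinshipMatrix
from .simulate import ResolvedQTL, TruthRecord

_FLOAT_FMT = "%.10g"


# -- genotypes ---------------------------------------------------------------

def write_genotypes(g: GenotypeMatrix, values_path: str, markers_path: str) -> None:
    df = pd.DataFrame(g.values, index=pd.Index(g.accessions, name="accession_id"),
                      columns=g.marker_ids)
    df.to_csv(values_path, sep="\t", float_format=_FLOAT_FMT)
    g.markers.to_csv(markers_path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_genotypes(values_path: str, markers_path: str) -> GenotypeMatrix:
    df = pd.read_csv(values_path, sep="\t", index_col="accession_id")
    markers = pd.read_csv(markers_path, sep="\t")
    markers = (
        markers.set_index("marker_id")
        .loc[list(df.columns)]
        .rename_axis("marker_id")
        .reset_index()
    )
    return GenotypeMatrix(list(df.index), markers, df.to_numpy(dtype=float))


# -- kinship -----------------------------------------------------------------

def write_kinship(K: KinshipMatrix, path: str) -> None:
    pd.DataFrame(
        K.values, index=pd.Index(K.accessions, name="accession_id"),
        columns=K.accessions,
    ).to_csv(path, sep="\t", float_format="%.12g")


def read_kinship(path: str) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col="accession_id")
    return KinshipMatrix(list(df.index), df.to_numpy(dtype=float))


# -- temperatures and phenology ----------------------------------------------

def write_temperature(series: TemperatureSeries, path: str) -> None:
    pd.DataFrame(
        {
            "location_id": series.location_id,
            "date": [d.isoformat() for d in series.dates],
            "tmean_c": series.tmean,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_temperature(path: str) -> TemperatureSeries:
    df = pd.read_csv(path)
    loc = str(df["location_id"].iloc[0])
    dates = [dt.date.fromisoformat(d) for d in df["date"]]
    return TemperatureSeries(loc, dates, df["tmean_c"].to_numpy(dtype=float))


def write_phenology(records: Iterable[PlotPhenologyRecord], path: str) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "location_id": r.location_id,
                "accession_id": r.accession_id,
                "plot_id": r.plot_id,
                "sowing_date": r.sowing_date.isoformat(),
                "emergence_date": r.emergence_date.isoformat(),
                "begin_flowering_date": (
                    r.begin_flowering_date.isoformat()
                    if r.begin_flowering_date else ""
                ),
                "full_flowering_date": (
                    r.full_flowering_date.isoformat()
                    if r.full_flowering_date else ""
                ),
                "sex_score": r.sex_score,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_phenology(path: str) -> list[PlotPhenologyRecord]:
    df = pd.read_csv(path, dtype=str).fillna("")
    out = []
    for _, r in df.iterrows():
        out.append(
            PlotPhenologyRecord(
                location_id=r["location_id"],
                accession_id=r["accession_id"],
                plot_id=r["plot_id"],
                sowing_date=dt.date.fromisoformat(r["sowing_date"]),
                emergence_date=dt.date.fromisoformat(r["emergence_date"]),
                begin_flowering_date=(
                    dt.date.fromisoformat(r["begin_flowering_date"])
                    if r["begin_flowering_date"] else None
                ),
                full_flowering_date=(
                    dt.date.fromisoformat(r["full_flowering_date"])
                    if r["full_flowering_date"] else None
                ),
                sex_score=int(r["sex_score"]),
            )
        )
    return out


def write_trait_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", float_format="%.12g")


def read_trait_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=["accession_id", "location_id"])


# -- scan results and models --------------------------------------------------

def write_scan(records: pd.DataFrame, path: str) -> None:
    records.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_scan(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["significant"] = df["significant"].astype(bool)
    for col in ("trait", "location_id"):
        df[col] = df[col].fillna("").astype(str)
    return df


def write_models(models: Iterable[MultiQTLModel], path: str) -> None:
    rows = []
    for m in models:
        for q in m.qtls:
            rows.append(
                {
                    "trait": m.trait,
                    "location_id": m.location_id,
                    "order": q.order,
                    "representative": q.representative,
                    "members": ";".join(q.members),
                    "incremental_r2": q.incremental_r2,
                    "full_r2": m.full_r2,
                }
            )
    pd.DataFrame(
        rows,
        columns=["trait", "location_id", "order", "representative", "members",
                 "incremental_r2", "full_r2"],
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_models(path: str) -> list[MultiQTLModel]:
    df = pd.read_csv(path, sep="\t").fillna({"members": ""})
    models = []
    for (trait, loc), grp in df.groupby(["trait", "location_id"], sort=False):
        m = MultiQTLModel(trait=str(trait), location_id=str(loc),
                          full_r2=float(grp["full_r2"].iloc[0]))
        for _, r in grp.sort_values("order").iterrows():
            members = [x for x in str(r["members"]).split(";") if x]
            m.qtls.append(
                QTL(
                    representative=r["representative"],
                    members=members,
                    trait=str(trait),
                    location_id=str(loc),
                    incremental_r2=float(r["incremental_r2"]),
                    order=int(r["order"]),
                )
            )
        models.append(m)
    return models


def write_model_summary(models: Iterable[MultiQTLModel], path: str) -> None:
    """QTL-count / explained-variance summary, one row per trait x location
    (explained variance as a percentage)."""
    rows = [
        {
            "trait": m.trait,
            "location_id": m.location_id,
            "n_qtls": len(m.qtls),
            "explained_variance": round(100.0 * m.full_r2, 2)
            if np.isfinite(m.full_r2) else "",
            "representative_markers": "; ".join(m.representatives),
        }
        for m in models
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_crossloc(
    qtls: Iterable[CrossLocationQTL], locations: list[str], path: str
) -> None:
    """Cross-location QTL table: one row per QTL, one column per location,
    '-' where the QTL has no representative in that location."""
    rows = []
    for q in qtls:
        row = {"qtl": q.name, "trait": q.trait}
        for loc in locations:
            row[loc] = ";".join(q.members[loc]) if loc in q.members else "-"
        rows.append(row)
    pd.DataFrame(rows, columns=["qtl", "trait", *locations]).to_csv(
        path, sep="\t", index=False
    )


def read_crossloc(path: str) -> list[CrossLocationQTL]:
    df = pd.read_csv(path, sep="\t")
    locations = [c for c in df.columns if c not in ("qtl", "trait")]
    out = []
    for _, r in df.iterrows():
        members = {
            loc: r[loc].split(";") for loc in locations if r[loc] != "-"
        }
        out.append(CrossLocationQTL(name=r["qtl"], trait=r["trait"], members=members))
    return out


# -- truth record --------------------------------------------------------------

def write_truth(truth: TruthRecord, path: str) -> None:
    """Structured-text dump of the truth record (YAML; the bulky per-plant
    genotypes used only by in-memory oracles are not serialised)."""
    doc = {
        "accessions": truth.accessions,
        "marker_ids": truth.marker_ids,
        "pool_size": truth.pool_size,
        "subpop": truth.subpop.tolist(),
        "true_freqs": np.round(truth.true_freqs, 10).tolist(),
        "qtls": [
            {
                "marker_id": q.marker_id,
                "trait": q.trait,
                "variance_fraction": q.variance_fraction,
                "shared_across_locations": q.shared_across_locations,
                "effects": {k: float(v) for k, v in q.effects.items()},
            }
            for q in truth.qtls
        ],
        "genetic_values": {
            f"{t}|{loc}": np.round(v, 10).tolist()
            for (t, loc), v in truth.genetic_values.items()
        },
        "variance_decomposition": {
            f"{t}|{loc}": {k: float(x) for k, x in vd.items()}
            for (t, loc), vd in truth.variance_decomposition.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_truth(path: str) -> TruthRecord:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    truth = TruthRecord(
        accessions=doc["accessions"],
        marker_ids=doc["marker_ids"],
        subpop=np.array(doc["subpop"]),
        true_freqs=np.array(doc["true_freqs"], dtype=float),
        individual_genotypes=np.empty((0, 0), dtype=np.int8),
        pool_size=doc["pool_size"],
    )
    truth.qtls = [
        ResolvedQTL(
            marker_id=q["marker_id"],
            trait=q["trait"],
            variance_fraction=q["variance_fraction"],
            shared_across_locations=q["shared_across_locations"],
            effects=dict(q["effects"]),
        )
        for q in doc["qtls"]
    ]
    for key, v in doc.get("genetic_values", {}).items():
        t, loc = key.split("|")
        truth.genetic_values[(t, loc)] = np.array(v, dtype=float)
    for key, vd in doc.get("variance_decomposition", {}).items():
        t, loc = key.split("|")
        truth.variance_decomposition[(t, loc)] = dict(vd)
    return truth
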