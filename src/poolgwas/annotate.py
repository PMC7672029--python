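"""QTL scaffold mapping, candidate-gene joins, and motif (miRNA) search.

On a fragmented assembly a QTL is anchored to the genomic scaffolds that
carry its markers; candidate genes are attached by joining those scaffolds
against an annotation table of flowering/sex-related transcripts. Short
regulatory sequences (mature miRNAs, ~20 nt) are located in scaffold
sequences by exact or near-exact (Hamming-distance) matching on both
strands; gapped alignment is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .multiqtl import MultiQTLModel, CrossLocationQTL
from .qc import parse_marker_id

_VALID_MOTIF = set("ACGT")


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; coordinates are 1-based inclusive on the
    forward strand regardless of the hit strand."""

    scaffold_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    motif_id: str


def map_qtl_scaffolds(
    qtls: Iterable[MultiQTLModel | CrossLocationQTL],
    include_members: bool = False,
) -> dict[str, list[str]]:
    """Scaffold sets per QTL, parsed from marker ids.

    For MultiQTL models the key is "<trait>@<location>:<representative>"
    per QTL; for cross-location QTLs the key is the QTL name. With
    ``include_members`` the member markers' scaffolds are included too
    (cross-location QTLs list only representatives by construction).
    Scaffold lists are deduplicated and sorted.
    """
    out: dict[str, list[str]] = {}
    for item in qtls:
        if isinstance(item, CrossLocationQTL):
            markers = [m for locs in item.members.values() for m in locs]
            out[item.name] = sorted({parse_marker_id(m)[0] for m in markers})
        elif isinstance(item, MultiQTLModel):
            for q in item.qtls:
                markers = [q.representative] + (q.members if include_members else [])
                key = f"{item.trait}@{item.location_id}:{q.representative}"
                out[key] = sorted({parse_marker_id(m)[0] for m in markers})
        else:
            raise TypeError(f"cannot map scaffolds for {type(item).__name__}")
    return out


def read_annotations(path: str) -> pd.DataFrame:
    """Candidate-gene annotations from TSV, GFF3 or BED.

    Returns columns scaffold_id, transcript_id, description, start, end,
    tags (start/end 1-based inclusive; NaN when absent). TSV input must
    carry at least scaffold_id and transcript_id; BED half-open intervals
    are converted to 1-based inclusive.
    """
    lower = path.lower()
    if lower.endswith((".gff", ".gff3")):
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                rows.append(
                    {
                        "scaffold_id": f[0],
                        "transcript_id": attrs.get("ID", attrs.get("Name", "")),
                        "description": attrs.get(
                            "description", attrs.get("product", attrs.get("Note", ""))
                        ),
                        "start": int(f[3]),
                        "end": int(f[4]),
                        "tags": attrs.get("tags", ""),
                    }
                )
        df = pd.DataFrame(rows)
    elif lower.endswith(".bed"):
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        df = df.iloc[:, :4]
        df.columns = ["scaffold_id", "start0", "end", "transcript_id"]
        df["start"] = df.pop("start0") + 1  # BED is 0-based half-open
        df["description"] = ""
        df["tags"] = ""
    else:
        df = pd.read_csv(path, sep="\t")
        if "scaffold_id" not in df or "transcript_id" not in df:
            raise ValueError("annotation TSV needs scaffold_id and transcript_id")
        for col, default in (("description", ""), ("start", np.nan),
                             ("end", np.nan), ("tags", "")):
            if col not in df:
                df[col] = default
    bad = df.dropna(subset=["start", "end"])
    if len(bad) and (bad["start"] > bad["end"]).any():
        raise ValueError("annotation with start > end")
    return df[["scaffold_id", "transcript_id", "description", "start", "end", "tags"]]


def candidate_genes_for_qtls(
    scaffolds_per_qtl: Mapping[str, Iterable[str]],
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    """Inner join of QTL scaffolds against the annotation table.

    Returns rows (qtl, scaffold_id, transcript_id, description, tags); empty
    when no QTL scaffold is annotated.
    """
    pairs = [
        {"qtl": q, "scaffold_id": s}
        for q, scaffolds in scaffolds_per_qtl.items()
        for s in scaffolds
    ]
    cols = ["qtl", "scaffold_id", "transcript_id", "description", "tags"]
    if not pairs:
        return pd.DataFrame(columns=cols)
    joined = pd.DataFrame(pairs).merge(annotations, on="scaffold_id", how="inner")
    return joined[cols].sort_values(cols[:3]).reset_index(drop=True)


def _hamming_hits(seq_arr: np.ndarray, motif: str, max_mismatch: int) -> np.ndarray:
    """Start offsets (0-based) and mismatch counts of windows within distance."""
    m = len(motif)
    if len(seq_arr) < m:
        return np.empty((0, 2), dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(seq_arr, m)
    mism = (windows != np.frombuffer(motif.encode(), dtype=np.uint8)).sum(axis=1)
    starts = np.flatnonzero(mism <= max_mismatch)
    return np.column_stack([starts, mism[starts]])


def find_motif(
    scaffolds: Mapping[str, str] | str,
    motif: str,
    motif_id: str = "motif",
    max_mismatch: int = 0,
    search_both_strands: bool = True,
) -> list[MotifHit]:
    """All occurrences of a short nucleotide motif within Hamming distance
    ``max_mismatch``, on both strands unless disabled.

    ``scaffolds`` is a FASTA path or a mapping scaffold_id -> sequence.
    'N' (or any non-ACGT symbol) in the subject never matches. Reverse
    strand hits are reported with forward-strand coordinates (1-based
    inclusive). Hits are ordered by (scaffold, start, strand).
    """
    motif = motif.upper()
    if len(motif) < 8:
        raise ValueError("motif must be at least 8 nt")
    invalid = set(motif) - _VALID_MOTIF
    if invalid:
        raise ValueError(f"motif contains invalid characters {sorted(invalid)}")

    if isinstance(scaffolds, str):
        seqs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(scaffolds, "fasta")
        }
    else:
        seqs = {k: v.upper() for k, v in scaffolds.items()}

    probes = [(motif, "+")]
    if search_both_strands:
        probes.append((str(Seq(motif).reverse_complement()), "-"))

    hits: list[MotifHit] = []
    m = len(motif)
    for sid in seqs:
        arr = np.frombuffer(seqs[sid].encode(), dtype=np.uint8)
        for probe, strand in probes:
            for start0, mism in _hamming_hits(arr, probe, max_mismatch):
                hits.append(
                    MotifHit(
                        scaffold_id=sid,
                        start=int(start0) + 1,
                        end=int(start0) + m,
                        strand=strand,
                        mismatches=int(mism),
                        motif_id=motif_id,
                    )
                )
    hits.sort(key=lambda h: (h.scaffold_id, h.start, h.strand))
    return hits


def motif_hits_table(hits: list[MotifHit], table1_style: bool = False) -> pd.DataFrame:
    """Hits as a DataFrame; ``table1_style`` shifts the end coordinate to
    start + length (an end-exclusive convention seen in some reports)."""
    df = pd.DataFrame(
        [
            {
                "motif_id": h.motif_id,
                "scaffold_id": h.scaffold_id,
                "start": h.start,
                "end": h.end + 1 if table1_style else h.end,
                "strand": h.strand,
                "mismatches": h.mismatches,
            }
            for h in hits
        ],
        columns=["motif_id", "scaffold_id", "start", "end", "strand", "mismatches"],
    )
    return df
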