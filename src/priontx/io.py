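"""Readers and writers for the pipeline's external formats.

All tabular formats are tab-separated UTF-8 with ``#`` comment lines
ignored. Gene identifiers are opaque, case-sensitive strings; no
systematic/standard-name aliasing is performed. Parsers never silently
drop rows: anything rejected raises with the offending line.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import (
    CountMatrix,
    GeneRecord,
    GeneSet,
    RegulonEdge,
    TFAlteration,
)


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield i, line


# ---------------------------------------------------------------------------
# count matrices

def read_count_matrix(
    path: str | Path,
    design: Mapping[str, str],
    replicate_of: Mapping[str, int] | None = None,
) -> CountMatrix:
    """Read a genes x samples count TSV (first column gene ids, header row
    sample labels) into a :class:`CountMatrix`.

    ``design`` maps every sample label to its condition; samples present in
    the design but absent from the file are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.number):
            bad = vals[pd.to_numeric(vals, errors="coerce").isna()]
            raise ValueError(
                f"{path}: non-numeric count in column {col!r}, gene {bad.index[0]!r}"
            )
        arr = vals.to_numpy()
        if (arr < 0).any():
            g = vals.index[np.argmax(arr < 0)]
            raise ValueError(f"{path}: negative count at gene {g!r}, sample {col!r}")
        if not np.allclose(arr, np.round(arr)):
            g = vals.index[np.argmax(~np.isclose(arr, np.round(arr)))]
            raise ValueError(f"{path}: non-integer count at gene {g!r}, sample {col!r}")
    return CountMatrix(df.astype(np.int64), design, replicate_of)


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_count_matrix_mtx(
    mtx_path: str | Path,
    genes_path: str | Path,
    samples_path: str | Path,
    design: Mapping[str, str],
) -> CountMatrix:
    """Read a MatrixMarket coordinate triplet (matrix + gene and sample
    label files, one label per line)."""
    from scipy.io import mmread

    mat = mmread(mtx_path).toarray()
    genes = [l for _, l in _data_lines(genes_path)]
    samples = [l for _, l in _data_lines(samples_path)]
    if mat.shape != (len(genes), len(samples)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(genes)} genes x "
            f"{len(samples)} samples"
        )
    df = pd.DataFrame(mat, index=genes, columns=samples)
    return CountMatrix(df, design)


# ---------------------------------------------------------------------------
# annotations

def read_annotation(path: str | Path) -> list[GeneRecord]:
    """Read a gene annotation TSV with columns gene_id, name, chromosome,
    feature_class."""
    records: list[GeneRecord] = []
    seen: set[str] = set()
    header: list[str] | None = None
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if header is None:
            header = fields
            expected = ["gene_id", "name", "chromosome", "feature_class"]
            if header != expected:
                raise ValueError(f"{path}: expected columns {expected}, got {header}")
            continue
        if len(fields) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
        gid, name, chrom, fclass = fields
        if gid in seen:
            raise ValueError(f"{path}:{lineno}: duplicate gene id {gid!r}")
        seen.add(gid)
        records.append(GeneRecord(gid, name, chrom, fclass))
    return records


def write_annotation(records: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tname\tchromosome\tfeature_class\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.name}\t{r.chromosome}\t{r.feature_class}\n")


# ---------------------------------------------------------------------------
# regulons

def read_regulons(path: str | Path) -> list[RegulonEdge]:
    """Read a signed TF->target regulon TSV (columns tf_id, target_id, role,
    evidence), deduplicating on (tf, target, role).

    The same TF/target pair may legitimately appear with both activator and
    inhibitor roles — TFs can act in either direction depending on target —
    so deduplication keys on the role as well.
    """
    edges: list[RegulonEdge] = []
    seen: set[tuple[str, str, str]] = set()
    header: list[str] | None = None
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if header is None and fields[0] == "tf_id":
            header = fields
            continue
        if len(fields) == 3:
            tf, tgt, role = fields
            ev = "both"
        elif len(fields) == 4:
            tf, tgt, role, ev = fields
        else:
            raise ValueError(f"{path}:{lineno}: expected 3-4 fields, got {len(fields)}")
        try:
            edge = RegulonEdge(tf, tgt, role, ev)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        key = (edge.tf_id, edge.target_id, edge.role)
        if key in seen:
            continue
        seen.add(key)
        edges.append(edge)
    return edges


def write_regulons(edges: Sequence[RegulonEdge], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tf_id\ttarget_id\trole\tevidence\n")
        for e in edges:
            fh.write(f"{e.tf_id}\t{e.target_id}\t{e.role}\t{e.evidence}\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read a GMT file (set name, description, then member ids, tab-sep)."""
    sets: list[GeneSet] = []
    names: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: gene set {fields[0]!r} has no members")
        name, _desc, *members = fields
        members = [m for m in members if m]
        if not members:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
        if name in names:
            raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
        names.add(name)
        sets.append(GeneSet(name, frozenset(members)))
    return sets


def write_gene_sets(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# TF alterations and aggregation inputs

def read_alterations(path: str | Path) -> list[TFAlteration]:
    """Read a TSV of TF states: tf_id, transcriptional, aggregation."""
    out: list[TFAlteration] = []
    header: list[str] | None = None
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if header is None and fields[0] == "tf_id":
            header = fields
            continue
        if len(fields) == 2:
            fields.append("unknown")
        if len(fields) != 3:
            raise ValueError(f"{path}:{lineno}: expected 2-3 fields")
        try:
            out.append(TFAlteration(*fields))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    return out


def write_alterations(alts: Sequence[TFAlteration], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tf_id\ttranscriptional\taggregation\n")
        for a in alts:
            fh.write(f"{a.tf_id}\t{a.transcriptional}\t{a.aggregation}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences from FASTA into an id -> sequence dict."""
    try:
        from Bio import SeqIO

        return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    except ImportError:  # pragma: no cover - biopython is a soft dependency
        seqs: dict[str, list[str]] = {}
        current: str | None = None
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    current = line[1:].split()[0]
                    seqs[current] = []
                elif current is not None:
                    seqs[current].append(line)
        return {k: "".join(v) for k, v in seqs.items()}


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read external aggregation-propensity scores (tf_id, camsol, pwaltz).
    Empty cells become NaN (score not computed for that TF)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "tf_id" not in df.columns:
        raise ValueError(f"{path}: missing tf_id column")
    return df.set_index("tf_id")


# ---------------------------------------------------------------------------
# configuration and reports

def read_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def write_json_report(obj: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
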