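"""Readers and writers for the external formats the pipeline touches.

Supported inputs: plain tab-delimited expression matrices, the table block
of a GEO Series Matrix file (subset dialect: only the
``!series_matrix_table_begin`` ... ``!series_matrix_table_end`` block plus
``!Sample_title`` are consumed), sample-metadata TSVs, and GMT gene-set
files. Outputs are TSV tables (12 significant digits, losslessly
round-trippable), Newick dendrograms and a JSON run-metadata sidecar.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .containers import (
    ClusterTree,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    SampleInfo,
)
from .errors import DuplicateProbe, FormatError

FLOAT_FMT = "%.12g"

# Sample-title pattern yielding metadata, e.g. "J82_frankincense_2h_rep1"
# or "sandalwood 0.5h". Unmatched titles leave metadata unset.
_TITLE_RE = re.compile(
    r"(?P<treatment>[A-Za-z][A-Za-z0-9.-]*)[_ ](?P<time>\d+(?:\.\d+)?)\s*h"
    r"(?:[_ ]rep(?P<rep>\d+))?$"
)


def _parse_cells(path: Path) -> tuple[list[str], list[list[str]]]:
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if not lines:
        raise FormatError(f"{path}: empty file")
    rows = [ln.split("\t") for ln in lines]
    header = rows[0]
    width = len(header)
    for i, r in enumerate(rows[1:], start=2):
        if len(r) != width:
            raise FormatError(f"{path}: ragged row at line {i}")
    return header, rows[1:]


def read_expression_tsv(path, samples: Optional[list[SampleInfo]] = None) -> ExpressionMatrix:
    """Read a tab-delimited matrix: first row array ids, first column probe ids.

    Column order is preserved; values are declared ``raw``.
    """
    header, rows = _parse_cells(Path(path))
    array_ids = [c.strip() for c in header[1:]]
    probe_ids = []
    data = np.empty((len(rows), len(array_ids)))
    for i, r in enumerate(rows):
        probe_ids.append(r[0].strip())
        for j, cell in enumerate(r[1:]):
            try:
                data[i, j] = float(cell)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} for probe {r[0]!r}"
                ) from exc
    if len(set(probe_ids)) != len(probe_ids):
        seen: set[str] = set()
        dup = next(p for p in probe_ids if p in seen or seen.add(p))
        raise DuplicateProbe(f"{path}: duplicate probe id {dup!r}")
    df = pd.DataFrame(data, index=probe_ids, columns=array_ids)
    return ExpressionMatrix(df, samples or [], value_space="raw")


def _unquote(s: str) -> str:
    s = s.strip()
    if len(s) >= 2 and s[0] == s[-1] and s[0] in "\"'":
        s = s[1:-1]
    return s


def read_series_matrix(path) -> ExpressionMatrix:
    """Read the table block of a GEO Series Matrix file.

    Only the expression table and ``!Sample_title`` lines are consumed.
    Treatment / time / replicate are filled in when a title matches the
    documented ``<treatment>_<time>h[_rep<k>]`` pattern, else left unset.
    Tolerates LF and CRLF line endings and quoted identifiers.
    """
    text = Path(path).read_text()
    lines = text.replace("\r\n", "\n").split("\n")
    titles: list[str] = []
    table: list[list[str]] = []
    in_table = False
    saw_begin = saw_end = False
    for ln in lines:
        if ln.startswith("!Sample_title"):
            titles = [_unquote(c) for c in ln.split("\t")[1:]]
        elif ln.startswith("!series_matrix_table_begin"):
            in_table, saw_begin = True, True
        elif ln.startswith("!series_matrix_table_end"):
            in_table, saw_end = False, True
        elif in_table and ln.strip():
            table.append([_unquote(c) for c in ln.split("\t")])
    if not saw_begin or not saw_end:
        raise FormatError(f"{path}: missing series_matrix_table delimiters")
    if not table:
        raise FormatError(f"{path}: empty series matrix table")
    header, rows = table[0], table[1:]
    array_ids = header[1:]
    width = len(header)
    probe_ids, data = [], []
    for r in rows:
        if len(r) != width:
            raise FormatError(f"{path}: ragged series matrix row {r[0]!r}")
        probe_ids.append(r[0])
        try:
            data.append([float(c) for c in r[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric cell in row {r[0]!r}") from exc
    if len(set(probe_ids)) != len(probe_ids):
        raise DuplicateProbe(f"{path}: duplicate probe id in series matrix")
    samples = []
    for j, aid in enumerate(array_ids):
        info = SampleInfo(aid)
        if j < len(titles):
            m = _TITLE_RE.search(titles[j])
            if m:
                info.treatment = m.group("treatment")
                info.time_hours = float(m.group("time"))
                if m.group("rep"):
                    info.replicate = int(m.group("rep"))
        samples.append(info)
    df = pd.DataFrame(data, index=probe_ids, columns=array_ids)
    return ExpressionMatrix(df, samples, value_space="raw")


def read_samples_tsv(path) -> list[SampleInfo]:
    """Read per-array metadata: columns array_id, treatment, time_hours, replicate."""
    df = pd.read_csv(path, sep="\t", dtype={"array_id": str})
    required = {"array_id", "treatment", "time_hours"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: need columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SampleInfo(
                array_id=str(row["array_id"]),
                treatment=str(row["treatment"]),
                time_hours=float(row["time_hours"]),
                replicate=int(row["replicate"]) if "replicate" in df.columns else None,
            )
        )
    return out


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: term, description, members, tab-separated.

    Duplicate members within a set are collapsed (set semantics).
    """
    sets = []
    for i, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        fields = ln.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: line {i} has fewer than 3 fields")
        members = frozenset(m.strip() for m in fields[2:] if m.strip())
        sets.append(GeneSet(fields[0].strip(), fields[1].strip(), members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.term_id, s.term_name, *sorted(s.members)]) + "\n")


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="probe_id")


def write_results(
    tables: Mapping[str, pd.DataFrame],
    tree: Optional[ClusterTree],
    path_prefix,
    metadata: Optional[dict] = None,
) -> list[Path]:
    """Persist stage outputs: one TSV per table, the dendrogram as Newick,
    and a JSON sidecar with run metadata. Returns the written paths."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = prefix.parent / f"{prefix.name}.{name}.tsv"
        df.to_csv(p, sep="\t", float_format=FLOAT_FMT)
        written.append(p)
    if tree is not None:
        p = prefix.parent / f"{prefix.name}.tree.nwk"
        p.write_text(tree.to_newick() + "\n")
        written.append(p)
    meta = dict(metadata or {})
    meta.setdefault("tool", "hvtime")
    from . import __version__

    meta.setdefault("version", __version__)
    p = prefix.parent / f"{prefix.name}.meta.json"
    p.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
    written.append(p)
    return written


def read_table(path) -> pd.DataFrame:
    """Generic reader for TSVs produced by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", index_col=0)
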